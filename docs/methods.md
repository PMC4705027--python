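# Methods

`healthdemog` estimates the demographics of users of health-related
social outlets (general social networks, drug-review sites, health Web
forums) from profile metadata and post text, and compares outlets with
standard significance and correlation machinery.  This note documents
the models, the parameters that matter, the synthetic data the package
is validated on, and the design choices made where the procedure was
genuinely open.

## Name-based gender classification

A first-name lookup table is aggregated from SSA-style yearly birth
name files (`yob<YYYY>.txt`, rows `name,M|F,count`).  For each cleaned
name (lowercased, non-alphabetic characters removed) the counts are
summed over all years and both sexes; the *discriminative gender
probability* is max(male, female)/total and the label is the argmax.
Names with aggregate frequency below **10,000** or probability below
**95%** are dropped; both thresholds are keep-at-boundary (a name at
exactly 10,000 or exactly 0.95 survives, matching the "remove below"
reading of the filter).  An optional `top_k_per_year` rank cut
reproduces the top-1000-per-year-per-sex construction when the reader
is fed complete yearly files; by default no rank cut is applied because
the cut is a property of the source files, not of the aggregation.

Per-user resolution precedence is **reported gender > display-name
first name > screen-name first name**; every call carries provenance.
Display-name matching defaults to whole-token matching (split on
whitespace/punctuation, clean, look up), because literal substring
containment produces false positives ("ann" inside "Hannah"); a
`substring` mode implementing containment with longest-match preference
is provided for fidelity with the original description, and every
token-mode match is by construction also a substring-mode match.

Screen-name extraction is a reconstruction (the original procedure is
unspecified): the screen name is segmented at separators (`_ . -`),
digit runs, and lower-to-upper camel-case boundaries; a segment exactly
equal to a table name wins first (earlier segments preferred), then the
longest table name that is a prefix (at least 2 characters) of a
segment.  These tie-breaks are fixed so the classifier is deterministic
and testable.

## Surname-based ethnicity classification

A census-2000-style surname file (`name,count,pctwhite,pctblack,
pctapi,pcthispanic`, suppressed cells `(S)` read as zero) provides a
per-surname ethnicity distribution over four categories (white, black,
Asian, Hispanic; Hispanic is treated as a single category).  Surnames
with frequency below **1000** or majority share below **80%** are
dropped (keep-at-boundary); exact ties for the majority are dropped as
unclassifiable.  Classification is an exact lookup of the cleaned last
whitespace token of the display name (compound surnames resolve to
their final token, matching the census file's single-token keys);
screen names are never used, as screen-name-derived surnames are too
noisy to classify.  The canonical worked example: the Hernandez row
(4.55% white, 0.38% black, 0.27% Asian, 93.81% Hispanic) classifies any
"… Hernandez" user as Hispanic with probability 0.9381.

## Age

Reported ages are an exact integer, an inclusive range ("35-45"), or
missing (the sink state for anything unparseable or outside [0, 120]).
Range-reported users are spread **uniformly over each year of the
range** — (35, 45) spans 11 years, so each year receives 1/11 of the
user — producing fractional user-equivalents that flow through the
percentage tables as reals.  Ages bin into the census brackets 0-17,
18-34, 35-44, 45-64, 65+.  Range endpoints are read as closed on both
sides; mass is conserved to 1e-9 by construction.

## Writing level

The Flesch-Kincaid grade

    grade = 0.39 · ASL + 11.8 · ASW − 15.59

is computed per user over the concatenation of all posts and the
profile description, with two modifications for social-media text:
**sentences longer than 30 words are omitted** (run-on unpunctuated
posts otherwise inflate ASL) and **users with fewer than 100 retained
words are excluded**.  URL, hashtag and @-mention tokens are stripped
first (@-mentions are treated like hashtags: non-lexical tokens).
Sentence splitting is the naive punctuation rule (`. ! ?` and newline
runs), with a newline boundary inserted between posts so two posts
never merge into one sentence; "Dr. Smith left." is two sentences, a
documented artifact accepted because the formula assumes conventionally
punctuated prose anyway.

Syllables are counted by a deterministic heuristic — maximal vowel
groups (a e i o u y), minus one for a terminal silent "e" that is not a
consonant-"le" cluster, floored at 1 — because ASW is the dominant term
(×11.8) and the choice must be explicit.  The counter is pluggable
(any `word -> int` callable) and its outputs are pinned in the tests.
Grades bin into three brackets with midpoint cuts at 5.5 and 9.5
(inclusive upper bounds); out-of-range grades clamp into the end
brackets.

## Location

Free-text locations are normalized (lowercase, non-alphanumerics
removed, spaces collapsed: "NY, NY" → "ny ny"); strings with per-source
corpus frequency below **14** are dropped; survivors are resolved by an
**exact-match offline gazetteer** CSV rather than a live geocoding API,
so runs are deterministic and network-free (a live-geocoder adapter
could implement the same mapping interface).  Non-US resolutions are
kept but excluded from state analyses; sources that report a state
directly bypass normalization and geocoding.  Per-capita participation
is users-per-state divided by state population, with zero-user states
present at rate 0; frequencies are computed per source (pooled counting
is a one-line change in the driver if wanted).

## Statistics

Percentage tables are computed over users with the attribute *known*;
unknowns never enter the base.  Pairwise outlet comparisons use
Pearson's chi-square test of independence on the 2×k category-count
table (fractional age user-equivalents rounded half-to-even first,
since count tests need integers; empty categories are dropped to keep
the degrees of freedom honest) and the two-sided Mann-Whitney U test.
The Mann-Whitney comparison is per category on **binary membership
indicators** (1 if the user is in the category), the only reading
consistent with a per-category-per-pair p-value layout; for
range-reported ages the indicator uses the bracket of the range
midpoint.  Exact Mann-Whitney p-values are used when both samples have
≤ 8 observations and no ties; otherwise the normal approximation with
tie and continuity corrections.  No multiple-testing correction is
applied by default (a Bonferroni switch exists).  State-covariate
association uses the Pearson product-moment correlation over the states
common to all outlets (Spearman available behind a flag), reported to
two decimals.

The standard tests themselves are delegated to scipy
(`chi2_contingency` with no continuity correction, `mannwhitneyu`,
`pearsonr`); the test suite checks them against independent oracles —
the 2×2 closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), brute-force
enumeration of all rank assignments, and the covariance/σσ hand form.

## Synthetic data

The generator replaces crawled corpora no longer obtainable; it emits
every input dialect the readers consume (SSA yearly files, census
surname file, gazetteer, populations, covariates) plus JSONL corpora
with per-user ground truth.  Key properties:

* **Quota assignment.** Categorical attributes (gender, ethnicity, age
  bracket, writing bracket, state) are assigned by largest-remainder
  quota and shuffled, not drawn i.i.d., so a 0.70 mixture at n = 200 is
  exactly 140 users.  Recovery tests can then assert equality; binomial
  noise enters only through downstream interactions (e.g. the location
  frequency filter).
* **Closed word banks.** Post text is composed from word banks whose
  syllable counts the default counter reproduces exactly; a greedy
  per-word schedule tracks the ASW needed for a target grade, landing
  within ±0.5 of it (10-word sentences by default, shorter for very low
  targets).  Constant-bank text gives exactly known ASL/ASW, e.g.
  10-word monosyllabic sentences score exactly 0.39·10 + 11.8·1 − 15.59
  = 0.11.
* **Exercised edge cases.** The reference fixtures contain names at
  exactly 10,000 / one below, at probability exactly 0.95 / just below,
  a unisex name, surnames at exactly 0.80 / 0.79, a frequency-999
  surname, a suppressed `(S)` cell, and the Hernandez row.
* **Determinism.** All randomness flows from one integer seed through
  one `numpy` generator; a repeated run reproduces every byte.

Default corpus conditions mirror a drug-review-style outlet (78.48%
female; ages concentrated in 45-64; writing mostly in the 6-9 bracket;
social-network-style ethnicity shares; ~80% gender reporting, ~61% age,
~62% location).  What the generator does **not** emulate: natural
language (posts are word-bank text, so content-based methods would find
nothing), out-of-bracket age ranges (ranges are drawn inside one census
bracket so bracket ground truth is unambiguous), name-demographic
correlations beyond the table labels, timestamps, and any network
structure.  Passing recovery tests therefore demonstrate that the
pipeline's plumbing and decision rules are correct under known
conditions — not that the classifiers are accurate on real profiles,
which depends on real name-demographic joint distributions the
synthetic corpus cannot supply.

## Problem sizes and numerical choices

The analysis drivers simulate 800-1500 users per outlet and the test
suite uses corpora of 200-5000 users; these sizes put quota-exact
mixtures well inside the tolerances asserted and keep a full run in
seconds.  Floating-point mass conservation is asserted at 1e-9;
chi-square oracle agreement at 1e-9; exact Mann-Whitney agreement at
1e-9.  Degenerate inputs are contracts, not crashes where the sink
state is meaningful: unparseable ages are missing, unmatched names are
unknown calls, users below 100 words carry a `None` bracket, while
empty keyword lists, empty gazetteers and zero-margin contingency
tables raise.

## Known limitations

Classifier accuracy on real data is unmeasurable here (no labeled real
profiles); the screen-name segmentation and the Mann-Whitney indicator
reading are documented reconstructions; the sentence splitter has the
abbreviation artifact noted above; non-ASCII letters are stripped by
name cleaning, so non-Latin names never match; the gazetteer is exact
match only.
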