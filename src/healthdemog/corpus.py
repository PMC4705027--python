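"""User/post data model, JSONL corpus IO, and health-keyword filtering.

A corpus is a JSON-lines file: one user object per line with at least a
``user_id``; unknown keys are ignored.  Posts are objects with ``text``
and an optional ISO timestamp.  Reported attributes (gender, age,
location, state) are optional and pass through untouched except for
light normalization of gender strings and age values.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from . import age as _age
from ._util import ConfigurationError, FormatError, ParseResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Post:
    text: str
    timestamp: Optional[str] = None


_GENDER_ALIASES = {
    "m": "male", "male": "male", "man": "male",
    "f": "female", "female": "female", "woman": "female",
}


def normalize_reported_gender(raw) -> Optional[str]:
    """Map common gender encodings to male/female; anything else is missing."""
    if raw is None:
        return None
    return _GENDER_ALIASES.get(str(raw).strip().lower())


@dataclass
class UserRecord:
    user_id: str
    source: str = ""
    display_name: Optional[str] = None
    screen_name: Optional[str] = None
    reported_gender: Optional[str] = None  # "male" | "female" | None
    reported_age: Optional[_age.AgeReport] = None
    location_string: Optional[str] = None
    reported_state: Optional[str] = None  # pre-resolved 2-letter state code
    description: Optional[str] = None
    posts: list = field(default_factory=list)

    def to_json(self) -> dict:
        d = {
            "user_id": self.user_id,
            "source": self.source,
            "display_name": self.display_name,
            "screen_name": self.screen_name,
            "reported_gender": self.reported_gender,
            "location_string": self.location_string,
            "reported_state": self.reported_state,
            "description": self.description,
            "posts": [
                {"text": p.text, **({"timestamp": p.timestamp} if p.timestamp else {})}
                for p in self.posts
            ],
        }
        if self.reported_age is not None and self.reported_age.kind != "missing":
            if self.reported_age.kind == "exact":
                d["reported_age"] = self.reported_age.value
            else:
                d["reported_age"] = f"{self.reported_age.low}-{self.reported_age.high}"
        return {k: v for k, v in d.items() if v is not None}


def _user_from_json(obj: dict) -> UserRecord:
    if not isinstance(obj, dict) or "user_id" not in obj or obj["user_id"] in (None, ""):
        raise FormatError("user object missing user_id")
    posts = []
    for p in obj.get("posts", []) or []:
        if isinstance(p, str):
            posts.append(Post(text=p))
        elif isinstance(p, dict) and "text" in p:
            posts.append(Post(text=str(p["text"]), timestamp=p.get("timestamp")))
        else:
            raise FormatError("post without text")
    return UserRecord(
        user_id=str(obj["user_id"]),
        source=str(obj.get("source", "")),
        display_name=obj.get("display_name"),
        screen_name=obj.get("screen_name"),
        reported_gender=normalize_reported_gender(obj.get("reported_gender")),
        reported_age=_age.coerce_age(obj.get("reported_age")),
        location_string=obj.get("location_string"),
        reported_state=obj.get("reported_state"),
        description=obj.get("description"),
        posts=posts,
    )


def read_corpus(source: Union[str, Path, IO[str]]) -> ParseResult:
    """Read a JSONL corpus; invalid lines are logged and counted.

    Raises :class:`FormatError` if no line parses to a valid user.
    Duplicate user_ids raise: the corpus contract requires uniqueness.
    """
    if isinstance(source, (str, Path)):
        fh = open(source, "r", encoding="utf-8")
        needs_close = True
    else:
        fh, needs_close = source, False
    result: ParseResult = ParseResult()
    seen: set = set()
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                user = _user_from_json(json.loads(line))
            except (json.JSONDecodeError, FormatError) as exc:
                logger.warning("corpus line %d skipped: %s", lineno, exc)
                result.skipped += 1
                continue
            if user.user_id in seen:
                raise FormatError(f"duplicate user_id {user.user_id!r} at line {lineno}")
            seen.add(user.user_id)
            result.records.append(user)
    finally:
        if needs_close:
            fh.close()
    if not result.records:
        raise FormatError("corpus contains no valid user lines")
    return result


def write_corpus(users: Iterable[UserRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in users:
            fh.write(json.dumps(u.to_json(), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# health-keyword filtering

_CATEGORIES = ("drug", "hashtag", "disorder", "pharmaceutical", "insurance")


@dataclass
class KeywordList:
    """Deduplicated lowercase phrases, optionally tagged by category."""

    phrases: list
    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        seen, deduped = set(), []
        for p in self.phrases:
            p = p.strip().lower()
            if p and p not in seen:
                seen.add(p)
                deduped.append(p)
        self.phrases = deduped
        if not self.phrases:
            raise ConfigurationError("keyword list is empty")


def load_keywords(source: Union[str, Path, IO[str], None] = None) -> KeywordList:
    """Load a keyword list: one phrase per line, ``//`` comments allowed.

    A comment line naming a category (e.g. ``// disorders``) tags the
    phrases that follow; ``#``-prefixed lines are literal hashtags.
    With no argument, the packaged ~30-phrase example list is loaded.
    """
    if source is None:
        text = (resources.files("healthdemog") / "data" / "health_keywords.txt").read_text()
        lines = text.splitlines()
    elif isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source.read().splitlines()

    phrases, categories = [], {}
    current = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("//"):
            tag = line.lstrip("/").strip().lower().rstrip("s")
            if tag in _CATEGORIES:
                current = tag
            continue
        phrase = line.lower()
        phrases.append(phrase)
        if current:
            categories[phrase] = current
    return KeywordList(phrases=phrases, categories=categories)


# word-ish tokens; '#' kept attached so hashtags match as single tokens
_TOKEN_RE = re.compile(r"#?[a-z0-9']+")


def _tokens(text: str) -> list:
    return _TOKEN_RE.findall(text.lower())


def contains_keyword(text: str, keywords: KeywordList) -> bool:
    """Whole-token match: multi-word phrases match as consecutive tokens."""
    toks = _tokens(text)
    tokset = set(toks)
    for phrase in keywords.phrases:
        ptoks = _tokens(phrase)
        if not ptoks:
            continue
        if len(ptoks) == 1:
            if ptoks[0] in tokset:
                return True
        else:
            n = len(ptoks)
            if any(toks[i : i + n] == ptoks for i in range(len(toks) - n + 1)):
                return True
    return False


def filter_health_posts(posts: Iterable[Post], keywords: KeywordList) -> list:
    """Retain posts containing at least one keyword phrase, order preserved."""
    if not keywords.phrases:
        raise ConfigurationError("cannot filter with an empty keyword list")
    return [p for p in posts if contains_keyword(p.text, keywords)]
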