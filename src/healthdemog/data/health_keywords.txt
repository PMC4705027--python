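// Example health-keyword list covering the five filter categories.
// Supply your own list for real analyses; phrases match as whole
// tokens, case-insensitive, hashtags as single tokens.

// drugs
metformin
lisinopril
ibuprofen
insulin
amoxicillin
atorvastatin
omeprazole
birth control

// hashtags
#hcsm
#health
#diabetes
#cancer

// disorders
cancer
diabetes
alzheimer
asthma
depression
flu
migraine
arthritis
hypertension
miscarriage
ovulation

// pharmaceuticals
pfizer
merck
novartis

// insurance
medicare
medicaid
humana
aetna
blue cross
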