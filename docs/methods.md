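# Methods

## Problem and model

`oculink` links two rosters describing the same patients: an imaging-side
table consolidated from DICOM metadata and a registry-side roster with
demographics and ICD diagnosis codes. Linkage is deterministic: two records
refer to the same patient only when an exact-agreement rule over normalized
identifiers holds. Four rules are used, all requiring the imaging practice
location to belong to the registry patient's location set, plus exact
equality of {name, birthdate, MRN} (R1), {name, birthdate, gender} (R2),
{name, MRN} (R3), or {birthdate, MRN} (R4). A pair linked by any rule is a
candidate; the number of satisfied rules is the edge weight.

Key assumptions:

- **Missing fails.** A field absent on either side fails any rule naming it.
  Wildcarding absent MRNs or names would mass-link unrelated records; the
  cost is that records with sparse metadata simply cannot link, which is the
  phenomenon the missingness sweep quantifies.
- **Location blocks.** Registry patients may hold several practice
  affiliations; the imaging location must be one of them. Because every rule
  requires location plus at least one of name/birthdate/MRN, generating
  candidates only within (location × shared-key) blocks is exactly
  equivalent to evaluating all pairs; a brute-force oracle test asserts this
  equivalence on 200-patient cohorts.
- **One-to-one resolution.** The candidate graph is bipartite; the final
  mapping is a maximum-cardinality matching, and among those one of maximum
  total weight, computed per connected component with a linear assignment
  solve (weights offset by a big-M constant so cardinality dominates).
  Among equally optimal matchings the lexicographically smallest edge set
  (by patient key, then registry id) is forced greedily, making output
  independent of input order. Components above 200 nodes take the assignment
  solution directly (still optimal and deterministic via canonical node
  ordering; realistic linkage components are tiny). A `greedy` mode (scan by
  descending weight) and a `strict_ambiguity_drop` mode (components with
  more than one optimal matching contribute no links) are available; the
  optimal mode is the default because it is oracle-verifiable.

## Extraction and harmonization

Only the first two metadata levels of each DICOM object are read: top-level
attributes plus attributes directly inside one level of sequence nesting;
deeper content is dropped (logged at debug). Pixel data is never loaded.
"Level" is read minimally as nesting depth; column values are taken from the
standard carriers (PatientID as the practice MRN, DA dates as YYYYMMDD,
unparseable dates become missing rather than errors). Image categories (OCT,
FAF, IR, COLOR, FA, ICGA, BR) come from a config-driven table over
(Modality, ImageType tokens, SOP class, manufacturer); unmapped combinations
are OTHER and are reported, never dropped. One calendar acquisition date per
patient defines a visit. Imaging patients are deduplicated on (location, raw
name, birthdate, MRN); conflicting genders within a duplicate group keep the
modal value.

Normalization upper-cases names, collapses whitespace, and strips only `.`
and `,`: digits and any other special characters deliberately survive into
the canonical name so the QC rules can detect them. MRNs lose whitespace and
leading zeros; gender maps to {M, F, O, missing}. Normalization is
idempotent (property-tested under fuzzing).

## QC exclusions

Three mutually exclusive flags, assigned in report-row priority order:

1. `NAME_NUMERIC_OR_SPECIAL` — any token containing a digit that is not
   wholly a canonical Roman numeral, or any character outside
   [A–Z, space, hyphen, apostrophe]. Roman-numeral generational suffixes
   ("III", "IV") are explicitly exempt; the grammar is tested against an
   independent enumeration of all numerals 1–3999.
2. `ABNORMAL_DOB` — birthdate before 1900-01-01 or after the archive cutoff
   date (default: the archive's latest acquisition date; configurable).
3. `TEST_NAME` — "TEST" as a substring of the normalized name. Substring
   matching flags "TESTER" too; a word-boundary switch is provided for
   stricter deployments.

Flags are computed on the imaging side only (the registry roster is assumed
curated). "Cleaned" rates remove flagged patients and their images from the
denominators only — flagged records cannot link under any rule with a
corrupted key field, so exclusion re-expresses the rate over the eligible
pool; numerators are untouched.

## De-identification

Masking runs after linkage. The policy maps DICOM tags to one of
blank / fixed-literal / remove-value; masked attributes keep their tag and
VR so the output re-serializes as standards-valid DICOM with an identical
(tag, VR) census. Fixed literals fall back to blank for non-text VRs.
Linkage-critical UIDs (SOP class/instance, study, series, referenced
instance) are rejected by policy validation. The shipped policy enumerates
the common direct-identifier attributes and is a starting point to be
certified per deployment, not a compliance guarantee; burned-in pixel
annotations and free text are out of scope. Patient IDs become HMAC-SHA256
tokens truncated to 128 bits, keyed by a user-supplied salt (empty salts are
refused; tokens would otherwise be reversible by dictionary attack).

## Reporting

Rates are `100·linked/total` with half-up rounding (decimal arithmetic, not
binary floats): headline rates at one decimal, stratum rates at two,
matching the convention of archive-scale reports. Year strata are
consecutive 12-month windows anchored at the archive cutoff date, labeled
`YYYY-YYYY+1` by window end, counting images by their patient's last-visit
window; calendar anchoring is a configuration away. Image-type strata count
unique patients per category, so a patient with OCT and FAF images appears
in both rows. Diagnosis cohorts match registry ICD codes by prefix against
an editable YAML map (the shipped map is an approximate stand-in, flagged as
such in the file); a multi-diagnosis patient counts in every matching
cohort, contributing all of their imaging visits and images; follow-up is
(last − first imaging visit)/365.25 years, reported as mean and sample SD.

## Synthetic cohorts

The generator emulates a two-practice archive and its registry roster with a
shared true mapping. Defaults encode archive-shaped conditions: 1000
patients across 2 practices; visits per patient ~ 1 + negative binomial
(mean 4.6, dispersion 2); images per visit ~ 1 + negative binomial (mean
9.1, dispersion 3); an image-type mix proportional to archive per-type image
counts (FA 0.31, IR 0.27, OCT 0.20, COLOR 0.12, FAF 0.05, ICGA 0.03, BR
0.02); contamination rates 2365/54896, 118/54896 and 17/54896 for numeric
names, abnormal birthdates and test names; registry-absent probability 0.118
(the complement of a cleaned patient rate of 88.2%, modeling archive/registry
timeframe mismatch); acquisition dates uniform over 2014-01-01–2020-06-01;
10% of OCT scans spawn an encapsulated-PDF measurement referencing the
scan's SOP instance UID. Per-field missingness defaults to zero and is
exercised by explicit sweeps. Names come from packaged synthetic pools
(including Roman-numeral suffixes to exercise the QC exemption); identities
are unique per location by construction, and under heavy missingness a
dedup-key collision deterministically restores the colliding patient's MRN.

What the generator does **not** emulate: real-world name variants (nicknames,
transliteration, hyphenation drift), MRN reuse across practices, clock skew
between device and EHR dates, vendor-specific private tags beyond a token
example, or realistic pixel content. Passing tests therefore demonstrate the
pipeline's correctness under exact-match assumptions and its bookkeeping
integrity — not robustness to fuzzy identity variation, which deterministic
rules by design do not address.

## Numerical and design choices

- Rounding is half-up via `decimal`; float division would misround
  half-way cases.
- Matching determinism is defined as: identical `LinkResult` for any
  permutation of input rows (tested), achieved by canonical sorting plus
  lexicographic tie-forcing.
- Patient keys are SHA-1 prefixes (16 hex chars) of the dedup identity
  tuple — opaque, deterministic, and stable across runs.
- Degenerate inputs: empty registry → empty edge set; total = 0 → rate is an
  error, not NaN; empty ICD sets produce zero-count rows with a warning;
  duplicate SOP instance UIDs keep the first occurrence.
- Problem sizes in the test and acceptance runs (200–1000 patients, 1000
  random matching instances ≤ 8+8 nodes, 10⁵ tokenization ids) were chosen
  as the smallest scales at which every property is non-trivially exercised;
  all complete in seconds.

## Known limitations

- Deterministic exact matching cannot recover pairs whose identifiers
  disagree by a single character; probabilistic (Fellegi–Sunter) or phonetic
  matching is deliberately out of scope.
- The cleaned-rate semantics assume flagged records are unlinkable; if a
  deployment's flagged records can in fact link, cleaned rates overstate
  performance.
- The shipped PHI policy and ICD map are editable stand-ins requiring
  per-deployment certification.
- Visit-level linkage of imaging visits to registry encounters is not
  attempted; links are patient-level, maximizing linked images at the cost
  of possible visit mismatch at the boundaries of registry coverage.
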