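# Methods

This note records the models, rules, and design choices behind
`cohortforge`, in the order the pipeline applies them, together with
what the synthetic fixtures do and do not establish about real data.

## Cohort definition

A registry row enters the cohort iff it passes **all** of: modality in
the whitelist (default `{CT}`); exam year equal to the study year
(default 2012); exam description containing the substring `Abd`
(case-insensitive); exam group outside the excluded set (`chest`,
`hdnk`, `unclassified`, `resp`, `lextr`, `cspin`); patient type not
`inpatient`; age in [18, 99], inclusive at both bounds. Rows whose date
or age cannot be parsed are quarantined into a rejects frame with a
reason rather than dropped, so every stage's counts telescope.

One exam per patient is kept: the minimum under (date, time, accession).
A missing exam time sorts after any present time, and the unique
accession breaks any remaining tie, so selection is deterministic and
invariant to input row order.

The mislabeled-exam filter excludes a description iff, lowercased, it
contains any of the twelve keywords (`ablation, fna, biopsy, drainage,
guidance, drain, drg, bx, interventional, interv, perc, bone`) as a
substring. Substring semantics make `drainage` redundant given `drain`;
the list is kept verbatim so the configuration is auditable against its
source conventions.

## Identifier normalization

Rules are per-site data, not code: a zero-pad width for MRNs (pad-left
to *k* digits if shorter; never truncate) and a literal accession prefix
(stripped at most once from position 0). Both normalizers are
idempotent; raw values are preserved alongside canonical ones, and an
exam counts as "reformatted" when either field changed. Non-numeric
MRNs are padded as-is and flagged in an audit column rather than
rejected, since no digit constraint is inherent in the rule.

## Accession resolution

Candidates for (MRN, date, window *w*) are CT studies of that MRN with
|study_date − date| ≤ *w* and image_count **strictly** greater than 20
(a 20-image study is excluded). The cascade is:

1. *w* = 0, body part ∈ {abdomen, GI, GU, body};
2. *w* = 0, pelvis; then chest (pelvis strictly preferred — chest
   linkage only occurs when chest/abdomen/pelvis were acquired
   together, so it is the rarer carrier);
3. *w* = 4 days, replaying the **full** body-part preference rather than
   only the abdomen tier — once the date is known to be unreliable
   there is no reason to trust it more for pelvis-linked studies.

Within a tier, ties break by smallest |date difference|, then largest
image count, then lexicographic accession. The ordering favors the
study most plausibly carrying the diagnostic series while staying
deterministic and candidate-order-invariant; the module's property
tests check the choice against a brute-force enumeration of the
preference order for candidate sets up to size 6.

Body-part strings are canonicalized through a configurable vocabulary
(case-folded, trimmed; `ABD`/`Abdomen` → `abdomen`, `PEL` → `pelvis`,
…); unknown spellings map to `other` and never match a tier.

Against fixtures with ground truth, mis-resolutions (chosen ≠ true
image-bearing accession) are counted and emitted as an override table;
replaying the table onto the results is the programmatic analogue of
manually correcting the affected exams, and the pipeline applies it
before triage.

## Triage

Each cohort exam receives exactly one disposition, in precedence order
**identifier discrepancy → missing → encoding error → corrupted →
topogram-only → test patient → included**. Identifier-level faults
dominate content-level faults because a study retrieved under the wrong
patient is unusable regardless of its pixel content; among content
faults, parse failures precede decode failures precede semantic checks
because each later check presupposes the earlier one succeeded.

Rule details:

* *discrepancy*: the exam's accession exists in some PACS index but only
  under a different MRN than the registry's canonical MRN;
* *missing*: no resolvable study anywhere, or an expected study
  directory absent/empty at triage time (logged distinctly);
* *encoding*: any instance fails to parse as DICOM at all;
* *corrupted*: all instances parse but at least one pixel payload fails
  to decode;
* *topogram-only*: every decodable instance carries the ImageType value
  `LOCALIZER` — the study has scouts but no cross-sectional content;
* *test patient*: the patient name matches a configurable sentinel list
  (defaults `TEST`, `PHANTOM`, `ZZZ`).

Studies not materialized as files are triaged on index-level evidence
alone. The attrition report hard-fails (`PartitionError`, with the
offending exam keys) if dispositions duplicate or fail to partition the
cohort, so conservation — initial = final + Σ exclusions — is checked on
every run, not assumed.

## Transfer model

Bulk transfer is a producer–consumer buffer in study units. The fluid
model: while the producer runs (volume/λ active hours) the buffer grows
at λ − μ; overflow occurs when it would exceed capacity *C*, at time
*C*/(λ − μ); otherwise the residue drains at μ and completion is at
volume/μ (volume/λ when μ ≥ λ). A retrieval window of *h* hours per day
rescales active time to wall-clock time by 24/*h* — a pure duty-cycle
multiplier. Zero write rate with a buffer too large to overflow is
reported as a non-terminating scenario rather than looping. The
discrete-event oracle moves one study at a time and agrees with the
fluid solution to within one event's granularity (property-tested over
a random scenario sweep). Modeling is per-study, not per-byte: no
study-size distribution is assumed.

## Synthetic fixtures

The generator emits, deterministically per (config, seed): a registry
export with raw identifiers, per-hospital PACS indices with canonical
identifiers, a ground-truth label per exam, and a manifest of studies to
render as DICOM files. Design points:

* **Counts are bookkeeping, not sampling.** Each injected mode is
  assigned to exactly the configured number of patients (a seeded
  permutation decides *which* patients); the seed moves dates, image
  counts, and site assignment but never a count. The replica preset
  therefore reproduces its attrition exactly under any seed.
* **Scale.** The replica emits only the 33,182 filter-surviving rows
  plus 500 decoy rows (one per upstream filter category) — enough to
  exercise every filter without bulk. Repeat exams per patient are
  placed at least 10 days after the primary so they can never intrude
  into a ±4-day resolution window.
* **Identifier corruption** applies at the one site whose conventions
  require it; dropped-zero MRNs are corrupted per *patient* (all of a
  patient's rows share the export form), since per-exam corruption
  would split patients under raw-identifier grouping.
* **Linkage modes**: the registry accession appears as a billing shell
  (≤ 5 images) and the true study carries >20 images under an abdomen,
  pelvis, or chest accession (default split 0.6/0.3/0.1, largest-
  remainder rounding). A configurable fraction of clean exams also get
  billing-shell siblings to exercise the >20-image filter without
  changing any count.
* **Adversarial records** pair the registry accession with a decoy
  abdomen study (25–40 images, same day) while the true images sit under
  a same-day pelvis accession; tier 1 provably prefers the decoy. The
  construction is verified at generation time by running the resolver.
  This is one plausible mechanism for cascade mis-selection, chosen for
  testability rather than claimed as the mechanism in any real system.
* **Topogram-only studies** carry 24 all-localizer instances so they
  pass the >20-image candidate filter and are caught by the content
  check; a 2-image scout study would instead fail resolution and triage
  as missing, collapsing two categories the fixture must keep distinct.
* **DICOM rendering** covers only studies needing content-level triage
  (topogram/corrupted/encoding/test, plus 10 clean studies by default),
  24 instances of 32×32 synthetic gradient pixels each; everything else
  exists only as index rows. Corruption truncates a pixel payload
  (metadata parses, decode fails); the encoding fault mangles the
  Part 10 magic bytes, which makes the file undecodable to a
  conformance-respecting reader.

**What passing fixtures shows — and does not.** The fixtures prove the
rules are internally consistent: each injected fault is recovered with
100% sensitivity and specificity, and the attrition telescopes exactly.
They do not establish performance on real registries, where failure
modes co-occur on one exam, identifier conventions drift within a site,
body-part vocabularies are dirtier than the packaged mapping, and the
relative frequencies of faults are unknown a priori. Real deployments
should re-estimate keyword lists and vocabulary mappings from their own
data; the configuration objects exist precisely so none of that is code.

## Numerical and degenerate-input choices

* Strict `> 20` image threshold (boundary tested at 20 vs 21).
* Age bounds inclusive at 18 and 99.
* Earliest-exam tie-break treats a missing time as later than any known
  time: a record with a known earlier time should win a same-day tie.
* Empty cohorts flow through every stage and produce an all-zero report.
* Overflow in the fluid model is strict (`peak > capacity`); scenarios
  whose fluid peak grazes the capacity may legitimately differ from the
  discrete oracle by one study, and the tests allow exactly that.
* Seeds feed `numpy.random.default_rng`; byte-identical CSV output is a
  tested contract, not an accident of implementation.

## Problem sizes

The packaged replica runs metadata-only for ~33.7k registry rows and
renders 36 studies (≈ 870 small DICOM files); a full generate + resolve
+ triage + report cycle takes on the order of ten seconds on one CPU.
Property suites run on 60–80-row fixtures, which cover every injected
mode while keeping the default test run fast.
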