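# cohort-forge

Curation of large radiology imaging cohorts: registry filtering, record
linkage, de-novo accession resolution against PACS, retrieval triage, and
attrition accounting — plus a deterministic synthetic RIS/PACS fixture
generator that injects every documented failure mode with ground-truth
labels.

## The problem

Assembling a multi-thousand-exam CT dataset for machine learning looks
like a database query but behaves like a record-linkage problem. A
research registry export of "all abdominal CTs in one year" arrives with:

* **mislabeled exams** — interventional and MSK procedures coded as
  abdominal CT, detectable only from the free-text description;
* **inconsistent identifiers** — one hospital drops the leading zeros of
  its 8-digit MRNs on export and prepends a legacy `A` to accessions
  minted before an EMR migration;
* **billing-only accessions** — a CT abdomen/pelvis order can mint
  separate accessions for abdomen, pelvis and contrast, only one of which
  carries images, and *which* one varies by era and site;
* **date drift** — the registry's exam date can be the acquisition date,
  the PACS receipt date, or the report-signing date, up to ±4 days apart;
* a residue of **non-recoverable failures**: registry/PACS MRN–accession
  discrepancies, topogram-only studies, missing studies, corrupted pixel
  data, scanner test "patients", and undecodable DICOM files.

`cohort-forge` implements the curation pipeline that survives all of
this, and scores itself against synthetic fixtures with known injected
faults.

## The method

The image-bearing accession for each exam is re-identified *de novo*
from the PACS study index, ignoring the registry's accession. For an
exam with canonical MRN *m* and registry date *d*:

1. **candidates** = CT studies of *m* with |study_date − d| ≤ *w* and
   image_count > 20 (strict; excludes billing shells and partial imports);
2. at window *w* = 0: prefer body part ∈ {abdomen, GI, GU, body}; else
   pelvis; else chest;
3. if nothing matched, repeat the full body-part preference at *w* = 4 days;
4. within a tier, break ties by smallest |date difference|, then largest
   image count, then lexicographic accession.

Resolution is followed by triage with a fixed precedence
(identifier discrepancy → missing → encoding error → corrupted →
topogram-only → test patient → included), and the attrition report
verifies that the dispositions exactly partition the cohort.

Bulk transfer is modeled as a producer–consumer buffer: pushing at rate
λ against a storage write rate μ < λ overflows a buffer of capacity *C*
at time *C*/(λ−μ); a closed-form fluid solution is cross-checked against
a discrete-event oracle to one study's granularity.

## Worked example

Run the packaged replica fixture end to end (generation, DICOM rendering
of the failure studies, resolution, triage, reporting — about 10 s):

```bash
$ cohort-forge run --preset paper-replica --out replica_out --seed 2012
registry rows                              33682
rows passing registry filters              33182
rows removed by registry filters             500
rows rejected (unparseable)                    0
selected cohort (one exam per patient)     23186
excluded by description keywords             283
cohort after keyword exclusion             22903
failed_mrn_acc_discrepancy                    17
failed_topogram_only                           7
failed_missing                                 8
failed_corrupted                               3
failed_test_patient                            1
failed_encoding                               15
non-recoverable failures (total)              51
final valid exams                          22852
```

Reading the table: of 33,682 synthetic registry rows, 500 decoys fall to
the registry filters (modality, year, description, group, patient type,
age 18–99), leaving 33,182 exams over 23,186 patients; the earliest exam
per patient gives a 23,186-exam cohort; 283 descriptions reveal
mislabeled interventional/MSK procedures; of the 22,903 remaining exams,
51 are non-recoverable for the six reasons shown, yielding 22,852 valid
exams. Along the way the pipeline reformats identifiers for 10,089
exams, chooses a non-registry accession for 838, and mis-resolves (then
corrects via the ground-truth replay) the 24 adversarially constructed
records — every count exactly matching the fixture's injections.

The same stages are available as library calls:

```python
from cohortforge import paper_replica_config, generate_fixture, run_bundle

bundle = generate_fixture(paper_replica_config(seed=2012))
result = run_bundle(bundle, "replica_out")
print(result.attrition.to_text())
print(result.n_reformatted, result.n_differs_from_registry, result.n_misresolved)
```

And the transfer capacity model:

```bash
$ cohort-forge simulate-transfer --push 150 --write 100 --capacity 1000 --volume 100000
buffer overflow after 20.00 h (peak buffer 1000 studies)
```

## Layout

| module | role |
| --- | --- |
| `cohortforge.fixtures` | synthetic registry / PACS / ground-truth generation, replica preset |
| `cohortforge.dicomgen` | DICOM Part 10 study rendering with injected faults |
| `cohortforge.cohort` | registry filters, earliest-exam selection, keyword exclusion |
| `cohortforge.identifiers` | per-site MRN/accession canonicalization |
| `cohortforge.resolution` | PACS index, candidate search, body-part cascade |
| `cohortforge.transfer` | producer–consumer transfer model (fluid + discrete oracle) |
| `cohortforge.triage` | failure classification, attrition report |
| `cohortforge.pipeline`, `cohortforge.cli` | orchestration and the `cohort-forge` command |

See `docs/methods.md` for the modeling assumptions and design choices.
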