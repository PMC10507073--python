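# icureadmit

Multimodality prediction of **unplanned ICU readmission** — a return ICU
admission within 30 days of hospital discharge, for adult patients with no
ICU stay in the preceding year and no in-window death.

The package implements the full analysis pipeline over MIMIC-III-schema
EHR tables and ships a synthetic EHR generator so every stage is testable
and reproducible without credentialed data access:

* **Cohort construction** — inclusion filters (age ≥ 18, 1 ≤ LOS ≤ 30 days,
  ≥ 1 measurement of each of 12 lab concepts, ≥ 5 of each of 5 chart
  concepts, no death during the stay or within 30 days of discharge),
  30-day labels, first-index-stay-per-rolling-year selection, and
  patient-level stratified 5-fold splits.
* **Knowledge-based temporal abstraction** — 17 clinical concepts with
  state cutoffs (e.g. body temperature < 36.2 °C → *Hypothermia*,
  36.2–37.2 → *Normal*, > 37.2 → *Fever*), gradient abstraction
  (*Increasing*/*Decreasing*/*Stable* from the sign of consecutive
  differences, optionally thresholded by a per-concept Δ and stable
  window), temporal-linear interpolation onto the union grid, and
  flattened or multivariate model-ready encodings.
* **Modality encodings** — ICD-9 code sequences (padded index vectors or
  comma-joined textual descriptions with a demographics preamble),
  demographics one-hot, and cleaned/tokenized/chunked discharge notes.
* **Models** — a bidirectional GRU with attention (BIRNN): embedding of
  width ⌊D^(1/4)⌋ for vocabulary size D, one forward and one time-reversed
  GRU, learned attention pooling over valid timesteps, optional static
  vector concatenation, and a single affine score; a tiny transformer
  text scorer for note chunks; joint multimodal fusion on concatenated
  pre-classifier vectors; and a random-forest tabular baseline. All
  neural components run on a compact numpy autodiff engine bundled with
  the package.
* **Training protocol** — batches of 64, validation AUPRC every
  `eval_every_steps` steps, checkpoint on improvement, learning-rate decay
  (×0.9 for text models from 2·10⁻⁵, ×0.97 from 10⁻³ otherwise) on
  non-improvement, stop after the patience ("stop loss" of 7) is exceeded,
  return the last saved model.
* **Evaluation** — AUROC, AUPRC, F1, precision, recall at a validation-
  selected optimal threshold; note-chunk aggregation
  `P = (P_max + P_mean·n/2)/(1 + n/2)`; the "conclusively better" rule
  (strictly higher on ≥ 3 of 5 metrics); per-fold reports and
  "mean ± std" cross-fold summaries.

## Worked example

```python
import icureadmit as m

tables = m.generate_ehr(m.SynthConfig(n_patients=600, seed=11))
kb = m.load_knowledge_base()
cohort, report = m.build_cohort(tables, kb)
print(len(cohort), int(cohort.label.sum()))          # 600 68

folds = m.make_folds(cohort, k=5, seed=1)
from icureadmit.experiment import ExperimentConfig, run_experiment
from icureadmit.cohort import FoldSplit
cfg = ExperimentConfig(hidden_size=24, charts_gradients="simple",
                       max_steps=200, eval_every_steps=40, seed=1)
res = run_experiment(tables, cohort, FoldSplit(folds.folds[:1]), "A", cfg)
print(round(res.reports[0].auroc, 3))                # 0.999
```

600 synthetic patients yield a cohort of 600 index stays with 68 (≈ 11 %)
readmitted. Training the charts BIRNN with gradient abstraction on one
fold and scoring its held-out test patients gives AUROC ≈ 0.999 here: the
generator injects a strong mean shift into the positive class's vital-sign
trajectories, which the state abstraction exposes almost perfectly at this
effect size. With `signal_strength={"charts": 0}` the same pipeline scores
at chance.

The same pipeline is exposed on the command line:

```bash
icureadmit generate --n-patients 600 --seed 11 --out ehr/
icureadmit cohort --ehr ehr/ --out cohort.csv --folds folds.json --seed 1
icureadmit run --ehr ehr/ --cohort cohort.csv --modality A --gradients simple --out report.json
```

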