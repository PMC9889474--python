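# deltarad

**Time-serial CT delta-radiomics for progression-free survival under
EGFR-TKI therapy** — a tested, reusable implementation of the full
analysis chain: peritumoral ring geometry, intra-/peritumoral feature
extraction at two timepoints, per-day delta features, test–retest ICC
stability filtering, Boruta + random-survival-forest signature
construction, clinical Cox baselines, C-index model comparison,
maximally-selected log-rank risk stratification, and time-dependent ROC.

## The problem

Most lung adenocarcinoma patients on EGFR tyrosine-kinase inhibitors
eventually progress as resistance develops, and progression is usually
recognized only after it has happened.  The idea tested here is that the
*change* of quantitative imaging features between the pre-therapy CT
(F0) and the first follow-up CT (F1) — in the tumor and in the 5 mm and
10 mm peritumoral rings around it — predicts progression-free survival
(PFS) earlier than baseline imaging or clinical covariates.  Because
follow-up timing varies per patient, each feature's change is normalized
to a **percentage variation per unit time**:

```
Δf = (f_F1 − f_F0) / (f_F0 · Diff_time)        [per day]
```

Features that are not reproducible between repeated segmentations
(intraclass correlation ICC ≤ 0.80 on re-test contours) are discarded;
the remaining baseline, follow-up and delta features feed a Boruta
all-relevant selection wrapped around random survival forests, and the
ten most important features form the radiomics signature.  Signatures
built from all features (`model_all`), baseline features only
(`model_baseline`) and intratumoral features only (`model_intratumor`)
are compared — via Harrell's C with a paired bootstrap test — against a
forward-AIC clinical Cox model and a combined clinico-radiomics model.
The best signature's score, dichotomized at the maximally-selected
log-rank cutoff, stratifies patients into rapid/slow progression groups,
with prognostic accuracy quantified by IPCW time-dependent ROC at 6, 9
and 12 months.

No patient data ship with the package.  A synthetic cohort generator
(`deltarad.synth`) renders time-serial lesion pairs with a *planted*
prognostic signal — per-day volume, texture and peritumoral rates drive
an exponential proportional-hazards PFS — so the whole chain runs and is
tested end-to-end under known ground truth.  See `docs/methods.md` for
the model, all defaults, and what the synthetic data do and do not show.

## Worked example

One command runs the complete study replica on the default synthetic
cohort (131 training / 41 validation patients):

```bash
deltarad run-all --seed 1 --out run1
```

or equivalently from Python:

```python
from deltarad import PipelineConfig, run_all
result = run_all(PipelineConfig(), seed=1, out_dir="run1")
```

With seed 1 this prints/writes (`run1/report.json`):

| model            | C-index train | C-index valid |
|------------------|--------------:|--------------:|
| model_all        | 0.845         | 0.780         |
| model_intratumor | 0.806         | 0.659         |
| model_baseline   | 0.752         | 0.644         |
| model_clinical   | 0.500         | 0.500         |
| model_combined   | 0.845         | 0.780         |

Reading: the time-serial intra+peritumoral signature (`model_all`)
predicts held-out PFS far better than chance, beats the intratumoral-only
and baseline-only signatures (paired bootstrap p = 0.043 and p = 0.002
in training), and the clinical model adds nothing (p = 1.0) — exactly
the hierarchy the generator plants (the signal lives in the per-day
deltas, partly peritumoral; clinical covariates are independent of
risk).  Nine of the ten selected features are deltas and six are
peritumoral.  The signature cutoff 71.9 splits both cohorts into groups
with median PFS 1.5 vs 18.2 months (training) and 1.7 vs 20.9 months
(validation), and the time-dependent AUC at {6, 9, 12} months is
0.91–0.93 in training and 0.79–0.90 in validation.

Every stage is also a file-in/file-out subcommand (`simulate`, `rings`,
`extract`, `icc-filter`, `delta`, `select`, `fit-signature`, `score`,
`clinical-fit`, `compare`, `stratify`), so any step can be re-run in
isolation; `deltarad --help` lists them.

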