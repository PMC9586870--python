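# cfmethyl

Window-level analysis of methylation-capture (MBD/MeDIP-style)
sequencing of cell-free DNA, built for the small cell lung cancer
(SCLC) liquid-biopsy setting: sensitive blood-based tumor detection,
transcription-factor subtype calling (ASCL1 / NEUROD1 /
double-negative), and a prognostic methylation score.

Methylation capture enriches fragments in proportion to both their
methylation level and their CpG density, so raw window counts conflate
the two. `cfmethyl` quantifies fragments into 300-bp windows, normalizes
to nrpm (normalized reads per million, TMM against a pooled
normal-control reference) and converts nrpm to **β-values** — scaled
methylation in [0, 1] — through a CpG-density-stratified *blind
calibration*: per density stratum, the least-enriched decile anchors
β = 0 and the most-enriched decile is assumed near-fully methylated
(β₀ = 0.8), giving a per-density linear map

    β̂ = clamp( (nrpm − bg(d)) / (full(d) − bg(d)), 0, 1 ).

On top of the β/count machinery the package provides:

- **Differential methylation** — per-window negative-binomial GLMs with
  library-size offsets, trend-moderated dispersions and
  likelihood-ratio tests; BH FDR (0.001) with Δβ effect filters (0.5 for
  tissue, 0.3 for cfDNA contrasts) and CGI / shore / shelf annotation.
- **In-silico spike-ins** — multinomial count-level mixtures of tumor
  and background cfDNA at known tumor fraction, with manifests that make
  source-aware train/test splits and leakage checks possible.
- **Tumor/healthy detection** — a 100-member gradient-boosted ensemble
  (500 trees, learning rate 0.02), each member trained on mixtures from
  80% of tumor and background sources; the median member score is
  thresholded at the balanced-accuracy-optimal cutoff derived from
  out-of-bag mixtures on a 0.01 grid.
- **SCLC subtyping** — methylation-array profiles of subtyped cell lines
  converted to pseudo-counts via the calibration lookup (max probe β per
  window), 50+50 extreme-Δβ windows per contrast, two ensembles with
  ASCL1 undersampling, jointly optimized sequential cutoffs, and a 4%
  tumor-fraction gate (below it a sample is "not evaluable").
- **Prognosis** — a methylation score (mean β over the detection
  windows) as a tumor-burden surrogate; Kaplan–Meier / log-rank on the
  median-dichotomized score and Cox models adjusting for age, sex and
  stage, compared by AIC/BIC/concordance.

Real cohorts for this assay are controlled-access, so the package ships
a first-class synthetic-cohort generator (`cfmethyl.simulate`) encoding
the assumed statistical structure — CGI-like bimodal CpG density, a
saturating negative-binomial capture model, tumor methylomes with 69%
hypermethylated DMRs (75% in CGI context), subtype-specific DMR blocks,
cfDNA mixtures at known tumor fraction, array probes and survival
outcomes — and every analysis stage is validated against that
generator's ground truth. See `docs/methods.md` for models, parameter
rationale and limitations.

## Worked example

```python
from cfmethyl import small_config, simulate_cohort, workflow, prognosis

cohort = simulate_cohort(small_config(seed=2))   # 4,000-window cohort
q = workflow.quantify_cohort(cohort)             # TMM + calibration + beta

run = workflow.train_detector(q, n_mixtures=240, n_members=20, seed=5)
print(f"detection windows: {len(run.feature_windows)}")
print(f"cutoff: {run.cutoff_result.cutoff:.2f} "
      f"(sens {run.cutoff_result.sensitivity:.2f}, "
      f"spec {run.cutoff_result.specificity:.2f}, "
      f"balanced accuracy {run.cutoff_result.balanced_accuracy:.2f})")

ev = workflow.evaluate_detector(run, n_mixtures=120, p_range=(0.02, 0.05), seed=6)
print(f"held-out balanced accuracy (2-5% tumor): {ev['balanced_accuracy']:.3f}")

s = cohort.samples
cf = list(s.index[s["sample_type"] == "cfdna_sclc"])
scores = prognosis.methylation_scores(q.beta[cf], run.feature_windows)
for sid in cf[:3]:
    print(f"{sid}: methylation score {scores[sid]:.3f} "
          f"(true tumor fraction {s.loc[sid, 'tumor_fraction']:.2f})")
```

prints

```
detection windows: 150
cutoff: 0.39 (sens 0.88, spec 0.96, balanced accuracy 0.92)
held-out balanced accuracy (2-5% tumor): 0.992
CF_ASCL1_01: methylation score 0.321 (true tumor fraction 0.20)
CF_ASCL1_02: methylation score 0.321 (true tumor fraction 0.24)
CF_ASCL1_03: methylation score 0.350 (true tumor fraction 0.32)
```

The 150 detection windows are the direction-consistent DMRs shared by
the tumor-vs-healthy-lung and tumor-vs-NCC contrasts; the 0.39 cutoff is
the grid value maximizing out-of-bag balanced accuracy; held-out
mixtures at 2–5% tumor content are classified with balanced accuracy
0.99; and the methylation score rises with the (generator-known) tumor
fraction, which is what makes it usable as a burden surrogate in the
survival models.

A thin CLI mirrors the main stages on cohort directories:

```bash
cfmethyl simulate --out cohort/ --seed 3
cfmethyl qc --cohort cohort/ --out qc.json
cfmethyl dmr --cohort cohort/ --group-a T_ASCL1_01,... --group-b HL_01,... --out dmrs.tsv
cfmethyl train-detector --cohort cohort/ --out detector/ --seed 11
cfmethyl predict --cohort cohort/ --model detector/ --out calls.tsv
cfmethyl survival --cohort cohort/ --model detector/ --out survival.json
```

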