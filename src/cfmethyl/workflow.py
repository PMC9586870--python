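"""End-to-end orchestration of the cfDNA methylome pipeline.

These helpers chain the library stages the way an analysis run would:
quantify a cohort (TMM against a pooled NCC reference, blind calibration,
beta estimation), call detection DMRs and train the tumor/healthy
ensemble on spike-in mixtures, train the subtype ensembles from
array-derived cell-line counts, and run survival studies. The CLI, the
test suite and the acceptance script all go through this module so the
pipeline wiring exists in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from . import detection, dmr, prognosis, quantify, spikein, subtyping
from .config import SimConfig
from .containers import CalibrationTable, CountMatrix, derive_rng
from .simulate import SimulatedCohort, SUBTYPES, mixed_beta, simulate_counts, \
    simulate_genome, simulate_methylomes, simulate_survival


@dataclass
class QuantifiedCohort:
    """A cohort plus its normalization, calibration and beta matrix."""

    cohort: SimulatedCohort
    counts: CountMatrix
    calibration: CalibrationTable
    beta: pd.DataFrame
    reference_pool: list


def reference_pool(cohort: SimulatedCohort) -> list:
    """The NCC training samples used as the pooled normalization reference."""
    s = cohort.samples
    pool = s.index[(s["sample_type"] == "cfdna_ncc") & (s["role"] == "train")]
    return list(pool)


def quantify_cohort(cohort: SimulatedCohort,
                    min_expected: float = 1.0) -> QuantifiedCohort:
    """TMM-normalize, fit the blind calibration and estimate beta-values."""
    pool = reference_pool(cohort)
    ref = quantify.pooled_reference(cohort.counts, pool)
    counts = quantify.tmm_normalize(cohort.counts, reference=ref)
    calibration = quantify.fit_calibration(counts, cohort.windows, pool=pool)
    beta = quantify.estimate_beta(counts, calibration, cohort.windows,
                                  min_expected=min_expected)
    return QuantifiedCohort(cohort=cohort, counts=counts,
                            calibration=calibration, beta=beta,
                            reference_pool=pool)


def _beta_for_mixtures(q: QuantifiedCohort, mix: CountMatrix) -> pd.DataFrame:
    ref = quantify.pooled_reference(q.counts, q.reference_pool)
    normed = quantify.tmm_normalize(mix, reference=ref)
    return quantify.estimate_beta(normed, q.calibration, q.cohort.windows)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionRun:
    q: QuantifiedCohort
    feature_windows: list
    model: detection.EnsembleModel
    cutoff_result: detection.CutoffResult
    manifest: pd.DataFrame
    dmrs_vs_tissue: pd.DataFrame
    dmrs_vs_ncc: pd.DataFrame


def detection_dmr_windows(q: QuantifiedCohort, fdr: float = 0.001,
                          min_delta: float = 0.5):
    """Detection window panel: DMRs against both healthy tissue and NCC."""
    s = q.cohort.samples
    tumors = list(s.index[s["sample_type"] == "tissue_tumor"])
    healthy = list(s.index[s["sample_type"] == "tissue_healthy"])
    ncc_train = q.reference_pool
    d_tissue = dmr.filter_significant(
        dmr.call_dmrs(q.counts, q.cohort.windows, q.calibration,
                      tumors, healthy, beta=q.beta),
        fdr=fdr, min_abs_delta_beta=min_delta)
    d_ncc = dmr.filter_significant(
        dmr.call_dmrs(q.counts, q.cohort.windows, q.calibration,
                      tumors, ncc_train, beta=q.beta),
        fdr=fdr, min_abs_delta_beta=min_delta)
    selected = detection.select_detection_windows(d_tissue, d_ncc)
    return selected, d_tissue, d_ncc


def train_detector(
    q: QuantifiedCohort,
    n_mixtures: int = 240,
    n_members: int = 100,
    p_range: tuple = (0.005, 0.05),
    m_range: tuple | None = None,
    seed: int = 0,
    xgb_params: dict | None = None,
) -> DetectionRun:
    """Full detection training: windows, mixtures, ensemble, OOB cutoff."""
    s = q.cohort.samples
    selected, d_tissue, d_ncc = detection_dmr_windows(q)
    tumors = list(s.index[s["sample_type"] == "tissue_tumor"])
    ncc_train = q.reference_pool
    if m_range is None:
        lib = int(q.cohort.config.library_size)
        m_range = (max(lib // 4, 1), lib)
    mix, manifest = spikein.generate_mixture_collection(
        q.counts, tumor_sources=tumors, background_sources=ncc_train,
        n=n_mixtures, p_range=p_range, m_range=m_range, seed=seed)
    features = detection.build_feature_matrix(
        _beta_for_mixtures(q, mix), selected["window"])
    model = detection.train_ensemble(features, manifest,
                                     n_members=n_members, seed=seed,
                                     xgb_params=xgb_params)
    oob = detection.oob_scores(model, features, manifest)
    labels = manifest.set_index("mixture_id").loc[features.index, "label"]
    cut = detection.derive_cutoff(labels.to_numpy(), oob.to_numpy())
    model.cutoff = cut.cutoff
    return DetectionRun(q=q, feature_windows=list(features.columns),
                        model=model, cutoff_result=cut, manifest=manifest,
                        dmrs_vs_tissue=d_tissue, dmrs_vs_ncc=d_ncc)


def evaluate_detector(
    run: DetectionRun,
    n_mixtures: int = 120,
    p_range: tuple = (0.02, 0.05),
    seed: int = 1,
) -> dict:
    """Held-out balanced accuracy on fresh mixtures from validation NCCs."""
    q = run.q
    s = q.cohort.samples
    ncc_val = list(s.index[(s["sample_type"] == "cfdna_ncc")
                           & (s["role"] == "validation")])
    tumors = list(s.index[s["sample_type"] == "tissue_tumor"])
    lib = int(q.cohort.config.library_size)
    mix, manifest = spikein.generate_mixture_collection(
        q.counts, tumor_sources=tumors, background_sources=ncc_val,
        n=n_mixtures, p_range=p_range,
        m_range=(max(lib // 4, 1), lib), seed=seed, prefix="val")
    features = detection.build_feature_matrix(
        _beta_for_mixtures(q, mix), run.feature_windows)
    pred = detection.predict_median_score(run.model, features)
    labels = manifest.set_index("mixture_id").loc[features.index, "label"].to_numpy()
    calls = (pred["median_score"] >= run.model.cutoff).to_numpy()
    sens = calls[labels == 1].mean()
    spec = (~calls[labels == 0]).mean()
    return {"balanced_accuracy": detection.balanced_accuracy(sens, spec),
            "sensitivity": float(sens), "specificity": float(spec),
            "scores": pred, "labels": labels}


def dilution_ladder(
    run: DetectionRun,
    proportions=None,
    n_replicates: int = 11,
    seed: int = 2,
) -> pd.DataFrame:
    """Detector score along an in-silico dilution series.

    Each proportion is diluted in ``n_replicates`` independent experiments
    (rotating the background sample) and the per-proportion score is the
    median over replicates of the ensemble median score, mirroring how
    limit-of-detection dilutions are summarized.
    """
    q = run.q
    s = q.cohort.samples
    if proportions is None:
        proportions = [0.0, 0.002, 0.005, 0.01, 0.02, 0.03, 0.05, 0.08,
                       0.12, 0.20, 0.30]
    tumors = list(s.index[s["sample_type"] == "tissue_tumor"])
    ncc_val = list(s.index[(s["sample_type"] == "cfdna_ncc")
                           & (s["role"] == "validation")])
    lib = int(q.cohort.config.library_size)
    frames = []
    for rep in range(n_replicates):
        mix, manifest = spikein.dilution_series(
            q.counts, tumor_source=tumors[0],
            background_source=ncc_val[rep % len(ncc_val)],
            proportions=list(proportions), total_fragments=lib // 2,
            seed=seed * 1009 + rep, prefix=f"dil{rep}")
        features = detection.build_feature_matrix(
            _beta_for_mixtures(q, mix), run.feature_windows)
        pred = detection.predict_median_score(run.model, features)
        frame = manifest.set_index("mixture_id")[["proportion"]].copy()
        frame["score"] = pred["median_score"]
        frame["replicate"] = rep
        frames.append(frame.reset_index(drop=True))
    scores = pd.concat(frames, ignore_index=True)
    out = (scores.groupby("proportion", sort=True)["score"].median()
           .rename("median_score").reset_index())
    return out


def ladder_monotonicity(proportions, scores) -> float:
    """Kendall-type rank correlation of score with dilution proportion.

    Uses the gamma variant — (concordant - discordant) / (concordant +
    discordant) over pairs with distinct proportions — so that pairs tied
    in score (the detector saturates near 1 above its detection limit) are
    uninformative rather than penalized. A weakly non-decreasing ladder
    scores exactly 1.
    """
    p = np.asarray(proportions, dtype=float)
    s = np.asarray(scores, dtype=float)
    conc = disc = 0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            if p[i] == p[j] or s[i] == s[j]:
                continue
            if (p[j] - p[i]) * (s[j] - s[i]) > 0:
                conc += 1
            else:
                disc += 1
    if conc + disc == 0:
        return float("nan")
    return (conc - disc) / (conc + disc)


# ---------------------------------------------------------------------------
# subtyping
# ---------------------------------------------------------------------------

@dataclass
class SubtypeRun:
    q: QuantifiedCohort
    bundle: subtyping.SubtypeModelBundle
    cutoffs: subtyping.SequentialCutoffResult
    manifest: pd.DataFrame
    source_subtypes: dict
    target_windows: dict


def cell_line_counts(q: QuantifiedCohort,
                     target_library_size: int | None = None) -> CountMatrix:
    """Array profiles of every cell line converted to pseudo count columns.

    Conversion happens at the pooled-reference depth by default. The
    resulting columns are on the reference nrpm scale by construction, so
    their library size is the conversion target with norm factor 1 — no
    TMM re-estimation (which would be biased by the tumor-specific
    methylome) is needed or wanted.
    """
    cohort = q.cohort
    if target_library_size is None:
        target_library_size = int(
            quantify.pooled_reference(q.counts, q.reference_pool).sum())
    cols = {}
    for name, profile in cohort.arrays.groupby("sample_id", sort=False):
        col, covered, _ = subtyping.array_to_counts(
            profile, q.calibration, cohort.windows,
            target_library_size=target_library_size)
        cols[name] = col
    return CountMatrix(pd.DataFrame(cols, index=q.counts.counts.index),
                       pd.Series(float(target_library_size),
                                 index=list(cols)))


def subtype_window_panels(q: QuantifiedCohort, cl_counts: CountMatrix,
                          fdr: float = 0.001,
                          n_per_direction: int = 50) -> dict:
    """Per-target subtype window lists from cell-line contrasts."""
    cohort = q.cohort
    expr = cohort.expression
    groups = {s: [i for i in cl_counts.samples
                  if expr.loc[i, "subtype_truth"] == s] for s in SUBTYPES}
    # cell-line columns are already on the reference nrpm scale
    normed = cl_counts
    beta = quantify.estimate_beta(normed, q.calibration, cohort.windows)
    panels = {}
    for target in ("NEUROD1", "ASCL1"):
        contrasts = {}
        for other in [s for s in SUBTYPES if s != target]:
            contrasts[f"{target}_vs_{other}"] = dmr.call_dmrs(
                normed, cohort.windows, q.calibration,
                groups[target], groups[other], beta=beta)
        panels[target] = subtyping.select_subtype_dmrs(
            contrasts, n_per_direction=n_per_direction, fdr=fdr)
    return panels


def train_subtyper(
    q: QuantifiedCohort,
    n_mixtures: int = 240,
    n_members: int = 100,
    p_range: tuple = (0.05, 0.40),
    seed: int = 0,
    xgb_params: dict | None = None,
    n_per_direction: int = 50,
) -> SubtypeRun:
    """Train both subtype ensembles and derive the joint sequential cutoffs."""
    cohort = q.cohort
    cl_counts = cell_line_counts(q)
    panels = subtype_window_panels(q, cl_counts,
                                   n_per_direction=n_per_direction)
    source_subtypes = {i: cohort.expression.loc[i, "subtype_truth"]
                       for i in cl_counts.samples}
    stacked = q.counts.subset(q.reference_pool).hstack(cl_counts)
    lib = int(cohort.config.library_size)
    mix, manifest = spikein.generate_mixture_collection(
        stacked, tumor_sources=cl_counts.samples,
        background_sources=q.reference_pool,
        n=n_mixtures, p_range=p_range, m_range=(max(lib // 4, 1), lib),
        seed=seed, positive_fraction=1.0, prefix="smix")
    beta_mix = _beta_for_mixtures(q, mix)
    feats = {t: detection.build_feature_matrix(beta_mix, panels[t])
             for t in ("NEUROD1", "ASCL1")}
    bundle = subtyping.train_subtype_ensembles(
        feats["NEUROD1"], feats["ASCL1"], manifest, source_subtypes,
        n_members=n_members, seed=seed, xgb_params=xgb_params)
    oob_n = detection.oob_scores(bundle.neurod1_model, feats["NEUROD1"], manifest)
    oob_a = detection.oob_scores(bundle.ascl1_model, feats["ASCL1"], manifest)
    truth = manifest.set_index("mixture_id")["tumor_source"].map(source_subtypes)
    cutoffs = subtyping.derive_sequential_cutoffs(
        truth.loc[oob_n.index].to_numpy(), oob_n.to_numpy(), oob_a.to_numpy())
    bundle.neurod1_model.cutoff = cutoffs.neurod1_cutoff
    bundle.ascl1_model.cutoff = cutoffs.ascl1_cutoff
    return SubtypeRun(q=q, bundle=bundle, cutoffs=cutoffs, manifest=manifest,
                      source_subtypes=source_subtypes, target_windows=panels)


def call_cfdna_subtypes(run: SubtypeRun, beta: pd.DataFrame,
                        tumor_fractions: pd.Series) -> pd.DataFrame:
    """Sequential subtype calls for cfDNA samples with known tumor fraction."""
    bundle = run.bundle
    f_n = detection.build_feature_matrix(beta, bundle.neurod1_windows)
    f_a = detection.build_feature_matrix(beta, bundle.ascl1_windows)
    s_n = detection.predict_median_score(bundle.neurod1_model, f_n)["median_score"]
    s_a = detection.predict_median_score(bundle.ascl1_model, f_a)["median_score"]
    rows = []
    for sid in beta.columns:
        call = subtyping.call_subtype(
            sid, s_n[sid], s_a[sid], float(tumor_fractions[sid]),
            bundle.neurod1_model.cutoff, bundle.ascl1_model.cutoff,
            gate=bundle.tumor_fraction_gate)
        rows.append({"sample_id": sid, "neurod1_score": call.neurod1_score,
                     "ascl1_score": call.ascl1_score, "call": call.call,
                     "tumor_fraction": call.tumor_fraction})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# survival studies
# ---------------------------------------------------------------------------

def survival_replicate(
    config: SimConfig,
    seed: int,
    n_patients: int = 80,
    tf_range: tuple = (0.02, 0.5),
    n_reference: int = 8,
) -> dict:
    """One survival-study replicate: simulate, score, test, fit.

    Simulates a patient cohort of cfDNA mixtures with tumor fractions in
    ``tf_range``, estimates beta-values against a simulated NCC reference
    pool, computes methylation scores over the ground-truth pan-tumor DMR
    panel, and returns the dichotomized-score log-rank p-value plus the
    Cox fit of the burden covariate z = tf / tf_scale (coefficient, CI).
    """
    cfg = SimConfig(**{**config.to_dict(), "seed": seed})
    windows = simulate_genome(cfg)
    methylomes, dmr_truth = simulate_methylomes(windows, cfg)
    rng = derive_rng(seed, 909)
    cols = {}
    for i in range(n_reference):
        cols[f"NCC_{i:02d}"] = simulate_counts(methylomes["normal"].beta,
                                               windows, cfg, rng)
    tfs = rng.uniform(tf_range[0], tf_range[1], n_patients)
    for i, tf in enumerate(tfs):
        beta = mixed_beta(methylomes["tumor_ASCL1"].beta,
                          methylomes["normal"].beta, float(tf))
        cols[f"P_{i:03d}"] = simulate_counts(beta, windows, cfg, rng)
    counts = CountMatrix(pd.DataFrame(cols, index=pd.RangeIndex(len(windows))),
                         pd.Series({k: float(v.sum()) for k, v in cols.items()}))
    pool = [f"NCC_{i:02d}" for i in range(n_reference)]
    ref = quantify.pooled_reference(counts, pool)
    counts = quantify.tmm_normalize(counts, reference=ref)
    calibration = quantify.fit_calibration(counts, windows, pool=pool)
    patient_ids = [f"P_{i:03d}" for i in range(n_patients)]
    beta_hat = quantify.estimate_beta(counts.subset(patient_ids),
                                      calibration, windows)
    panel = dmr_truth.loc[dmr_truth["role"] == "pan", "window"].to_numpy()
    scores = prognosis.methylation_scores(beta_hat, panel)

    samples = pd.DataFrame({"tumor_fraction": tfs}, index=patient_ids)
    samples = simulate_survival(samples, cfg, derive_rng(seed, 910))
    samples["methylation_score"] = scores
    samples["score_group"] = prognosis.dichotomize_median(scores)
    km = prognosis.km_logrank(samples)

    z = samples["tumor_fraction"].to_numpy() / cfg.tf_scale
    df = pd.DataFrame({"z": z,
                       "os_months": samples["os_months"].astype(float),
                       "os_event": samples["os_event"].astype(float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_months", event_col="os_event")
    coef = float(cph.params_["z"])
    se = float(cph.standard_errors_["z"])
    return {
        "logrank_p": km["logrank_p"],
        "median_os": km["median_os"],
        "cox_coef": coef,
        "cox_ci": (coef - 1.959964 * se, coef + 1.959964 * se),
        "score_tf_corr": float(np.corrcoef(scores, tfs)[0, 1]),
        "samples": samples,
    }
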