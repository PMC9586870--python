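"""SCLC transcription-factor subtype calling from cfDNA methylation.

Subtype truth for reference material comes from expression of the ASCL1,
NEUROD1, POU2F3 and YAP1 transcription factors. Methylation-array profiles
of subtyped cell lines are converted to pseudo capture counts through the
calibration lookup, subtype-discriminating windows are picked as the most
hyper- and hypomethylated significant DMRs per contrast (50 + 50 each),
and two gradient-boosted ensembles (NEUROD1 and ASCL1) are trained on
spike-in mixtures. Calls are sequential: NEUROD1 first, then ASCL1 among
NEUROD1-negative samples, else double negative — with samples below a
tumor-fraction gate (default 4%) declared not evaluable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CalibrationTable, derive_rng
from .detection import EnsembleModel, train_ensemble

_S_SUBTYPE = 303

SUBTYPE_CALLS = ("NEUROD1", "ASCL1", "double_negative", "not_evaluable")


# ---------------------------------------------------------------------------
# expression-based truth
# ---------------------------------------------------------------------------

def assign_subtype_from_expression(
    expression: dict,
    context: str = "cell_line",
    threshold: float = 9.0,
) -> str:
    """Assign a subtype label from normalized TF expression values.

    ``cell_line`` context thresholds each gene at ``threshold``: samples
    expressing both ASCL1 and NEUROD1 are ``excluded``; POU2F3- or
    YAP1-only samples are ``double_negative``; nothing above threshold is
    ``unclassified``. ``model`` context takes the arg-max among ASCL1,
    NEUROD1 and POU2F3 (POU2F3 mapping to double negative), resolving
    ASCL1/NEUROD1 co-expression to NEUROD1.
    """
    required = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")
    missing = [g for g in required if g not in expression]
    if missing:
        raise ValueError(f"expression values missing for {missing}")
    a, n = expression["ASCL1"], expression["NEUROD1"]
    p, y = expression["POU2F3"], expression["YAP1"]
    if context == "cell_line":
        if a >= threshold and n >= threshold:
            return "excluded"
        if a >= threshold:
            return "ASCL1"
        if n >= threshold:
            return "NEUROD1"
        if p >= threshold or y >= threshold:
            return "double_negative"
        return "unclassified"
    if context == "model":
        if a >= threshold and n >= threshold:
            return "NEUROD1"
        top = max(("ASCL1", a), ("NEUROD1", n), ("POU2F3", p), key=lambda kv: kv[1])[0]
        return "double_negative" if top == "POU2F3" else top
    raise ValueError(f"unknown context {context!r}")


# ---------------------------------------------------------------------------
# array-to-count conversion
# ---------------------------------------------------------------------------

def array_to_counts(
    profile: pd.DataFrame,
    calibration: CalibrationTable,
    windows: pd.DataFrame,
    target_library_size: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Convert an array beta profile into an expected capture count column.

    Per window the beta is the maximum over its probes; expected nrpm is
    the calibration interpolation ``bg(d) + beta * (full(d) - bg(d))``,
    converted to integer counts at the target library size. Probes mapping
    to excluded windows are dropped (tallied); windows without probes stay
    at zero with a False coverage mask so they can be masked downstream
    rather than mistaken for hypomethylation.

    Returns ``(counts, covered_mask, n_probes_dropped)``.
    """
    required = {"window", "beta"}
    if required - set(profile.columns):
        raise ValueError("array profile needs 'window' and 'beta' columns")
    excluded = windows["excluded"].to_numpy()
    win = profile["window"].to_numpy(dtype=np.int64)
    if (win < 0).any() or (win >= len(windows)).any():
        raise ValueError("array profile references windows outside the genome")
    drop = excluded[win]
    n_dropped = int(drop.sum())
    kept = profile.loc[~drop]
    beta_w = kept.groupby("window")["beta"].max()
    covered = np.zeros(len(windows), dtype=bool)
    covered[beta_w.index.to_numpy()] = True
    bg, full = calibration.lookup(windows["cpg_count"].to_numpy())
    nrpm = np.zeros(len(windows))
    idx = beta_w.index.to_numpy()
    nrpm[idx] = bg[idx] + beta_w.to_numpy() * (full[idx] - bg[idx])
    counts = np.rint(nrpm * target_library_size / 1e6).astype(np.int64)
    counts[~covered] = 0
    return counts, covered, n_dropped


# ---------------------------------------------------------------------------
# subtype window selection
# ---------------------------------------------------------------------------

def select_subtype_dmrs(
    contrast_dmrs: dict,
    n_per_direction: int = 50,
    fdr: float = 0.001,
) -> list:
    """Rank per-contrast DMRs by delta beta and pool the extremes.

    ``contrast_dmrs`` maps contrast names to DMR tables oriented target
    minus other group. Per contrast the ``n_per_direction`` most hyper- and
    most hypomethylated significant windows are taken (with a warning when
    a direction runs short); the concatenation is deduplicated preserving
    first appearance. With three disjoint contrasts at full depth this
    yields exactly ``6 * n_per_direction`` (300) windows.
    """
    chosen: list = []
    seen = set()
    for name, table in contrast_dmrs.items():
        sig = table[table["q_value"] <= fdr].sort_values(
            "delta_beta", ascending=False, kind="stable")
        hyper = sig.head(n_per_direction)
        hypo = sig.tail(min(n_per_direction, max(len(sig) - len(hyper), 0)))
        if len(hyper) < n_per_direction or len(hypo) < n_per_direction:
            warnings.warn(
                f"contrast {name!r}: fewer than {n_per_direction} significant "
                f"windows in some direction; taking all available")
        for w in pd.concat([hyper, hypo])["window"]:
            if w not in seen:
                seen.add(w)
                chosen.append(w)
    return chosen


# ---------------------------------------------------------------------------
# ensembles and sequential cutoffs
# ---------------------------------------------------------------------------

@dataclass
class SubtypeModelBundle:
    """The two subtype ensembles plus their jointly derived cutoffs."""

    neurod1_model: EnsembleModel
    ascl1_model: EnsembleModel
    neurod1_windows: list
    ascl1_windows: list
    tumor_fraction_gate: float = 0.04

    @property
    def subtype_windows(self) -> list:
        out = list(self.neurod1_windows)
        out += [w for w in self.ascl1_windows if w not in set(self.neurod1_windows)]
        return out


@dataclass
class SubtypeCall:
    sample_id: str
    neurod1_score: float
    ascl1_score: float
    call: str
    tumor_fraction: float


def _undersampling_sampler(source_subtypes: dict, background_pool: list,
                           subsample: float):
    """Member source sampler with ASCL1 undersampling for class balance.

    Takes ``subsample`` of the NEUROD1 and double-negative source pools,
    then draws ASCL1 sources to match that combined count (within one),
    plus ``subsample`` of the NCC background pool.
    """
    pools = {s: sorted(k for k, v in source_subtypes.items() if v == s)
             for s in ("ASCL1", "NEUROD1", "DN")}

    def sampler(rng):
        n_sub = max(1, int(round(subsample * len(pools["NEUROD1"]))))
        d_sub = max(1, int(round(subsample * len(pools["DN"]))))
        pick_n = sorted(rng.choice(pools["NEUROD1"], n_sub, replace=False).tolist())
        pick_d = sorted(rng.choice(pools["DN"], d_sub, replace=False).tolist())
        n_a = min(len(pools["ASCL1"]), len(pick_n) + len(pick_d))
        pick_a = sorted(rng.choice(pools["ASCL1"], n_a, replace=False).tolist())
        n_b = max(1, int(round(subsample * len(background_pool))))
        pick_b = sorted(rng.choice(background_pool, n_b, replace=False).tolist())
        return {"tumor": pick_n + pick_d + pick_a, "background": pick_b}

    return sampler


def train_subtype_ensembles(
    neurod1_features: pd.DataFrame,
    ascl1_features: pd.DataFrame,
    manifest: pd.DataFrame,
    source_subtypes: dict,
    n_members: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    xgb_params: dict | None = None,
    gate: float = 0.04,
) -> SubtypeModelBundle:
    """Train the NEUROD1 and ASCL1 ensembles on subtype spike-in mixtures.

    ``manifest`` is a mixture manifest whose tumor sources are cell-line
    samples; ``source_subtypes`` maps each tumor source to its subtype
    truth. Positives for each ensemble are mixtures of that subtype; every
    member undersamples the (majority) ASCL1 source pool for class
    balance. Cutoffs are left unset until
    :func:`derive_sequential_cutoffs` runs.
    """
    manifest = manifest.copy()
    subtype = manifest["tumor_source"].map(source_subtypes)
    if subtype.isna().any():
        bad = manifest.loc[subtype.isna(), "tumor_source"].unique()
        raise ValueError(f"mixtures with unknown source subtype: {bad[:5]}")
    for s in ("ASCL1", "NEUROD1", "DN"):
        if (subtype == s).sum() == 0:
            raise ValueError(f"no mixtures of subtype {s}")
    manifest["mixture_subtype"] = subtype
    manifest["label_neurod1"] = (subtype == "NEUROD1").astype(int)
    manifest["label_ascl1"] = (subtype == "ASCL1").astype(int)
    _, bg_pool = _manifest_background(manifest)
    sampler = _undersampling_sampler(source_subtypes, bg_pool, subsample)
    neurod1_model = train_ensemble(
        neurod1_features, manifest, label_col="label_neurod1",
        n_members=n_members, subsample=subsample,
        seed=derive_int(seed, 1), xgb_params=xgb_params, source_sampler=sampler)
    ascl1_model = train_ensemble(
        ascl1_features, manifest, label_col="label_ascl1",
        n_members=n_members, subsample=subsample,
        seed=derive_int(seed, 2), xgb_params=xgb_params, source_sampler=sampler)
    return SubtypeModelBundle(
        neurod1_model=neurod1_model,
        ascl1_model=ascl1_model,
        neurod1_windows=list(neurod1_features.columns),
        ascl1_windows=list(ascl1_features.columns),
        tumor_fraction_gate=gate,
    )


def derive_int(seed: int, key: int) -> int:
    """A derived sub-seed below 2**31."""
    return int(derive_rng(seed, _S_SUBTYPE, key).integers(0, 2 ** 31 - 1))


def _manifest_background(manifest: pd.DataFrame):
    bg = set(manifest["background_source"].dropna())
    if "background_source_2" in manifest:
        bg |= set(manifest["background_source_2"].dropna())
    return None, sorted(bg)


@dataclass
class SequentialCutoffResult:
    neurod1_cutoff: float
    ascl1_cutoff: float
    avg_balanced_accuracy: float
    neurod1_metrics: dict
    ascl1_metrics: dict


def derive_sequential_cutoffs(
    subtype_truth: np.ndarray,
    neurod1_scores: np.ndarray,
    ascl1_scores: np.ndarray,
    grid_step: float = 0.01,
) -> SequentialCutoffResult:
    """Jointly optimize the two cutoffs over a 2-D grid.

    For each pair (c_N, c_A): NEUROD1 balanced accuracy is evaluated on all
    samples at c_N; ASCL1 balanced accuracy at c_A only on samples the
    NEUROD1 classifier left unclassified (score < c_N), mirroring the
    sequential call rule. The objective is the mean of the two balanced
    accuracies; grid cells whose conditional ASCL1 evaluation has no
    positives or no negatives are undefined and skipped. Ties resolve to
    the lexicographically smallest (c_N, c_A).
    """
    truth = np.asarray(subtype_truth, dtype=object)
    s_n = np.asarray(neurod1_scores, dtype=float)
    s_a = np.asarray(ascl1_scores, dtype=float)
    ok = ~(np.isnan(s_n) | np.isnan(s_a))
    truth, s_n, s_a = truth[ok], s_n[ok], s_a[ok]
    is_n = truth == "NEUROD1"
    is_a = truth == "ASCL1"
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    best = None
    for c_n in grid:
        call_n = s_n >= c_n
        sens_n = call_n[is_n].mean() if is_n.any() else np.nan
        spec_n = (~call_n[~is_n]).mean() if (~is_n).any() else np.nan
        if np.isnan(sens_n) or np.isnan(spec_n):
            continue
        ba_n = (sens_n + spec_n) / 2.0
        elig = ~call_n
        pos = elig & is_a
        neg = elig & ~is_a
        if not pos.any() or not neg.any():
            continue
        calls_a = s_a[None, :] >= grid[:, None]
        sens_a = calls_a[:, pos].mean(axis=1)
        spec_a = (~calls_a[:, neg]).mean(axis=1)
        ba_a = (sens_a + spec_a) / 2.0
        obj = (ba_n + ba_a) / 2.0
        # smallest c_A attaining the row optimum (explicit tie-break)
        j = int(np.flatnonzero(obj >= np.nanmax(obj) - 1e-12)[0])
        if best is None or obj[j] > best[0] + 1e-12:
            best = (obj[j], float(c_n), float(grid[j]),
                    {"balanced_accuracy": float(ba_n), "sensitivity": float(sens_n),
                     "specificity": float(spec_n)},
                    {"balanced_accuracy": float(ba_a[j]), "sensitivity": float(sens_a[j]),
                     "specificity": float(spec_a[j])})
    if best is None:
        raise ValueError("no grid cell admits a defined sequential objective")
    return SequentialCutoffResult(
        neurod1_cutoff=best[1], ascl1_cutoff=best[2],
        avg_balanced_accuracy=float(best[0]),
        neurod1_metrics=best[3], ascl1_metrics=best[4])


def call_subtype(
    sample_id: str,
    neurod1_score: float,
    ascl1_score: float,
    tumor_fraction: float,
    neurod1_cutoff: float,
    ascl1_cutoff: float,
    gate: float = 0.04,
) -> SubtypeCall:
    """Sequential subtype call with a tumor-fraction gate.

    Samples below the gate (default 4% tumor fraction) are not evaluable
    regardless of score; otherwise NEUROD1 wins at its cutoff, then ASCL1
    among NEUROD1-negative samples, else double negative. Exactly one call
    per sample, and the NEUROD1 call never consults the ASCL1 score.
    """
    if tumor_fraction is None or (isinstance(tumor_fraction, float)
                                  and np.isnan(tumor_fraction)):
        raise ValueError("tumor fraction is required for subtype gating")
    if tumor_fraction < gate:
        call = "not_evaluable"
    elif neurod1_score >= neurod1_cutoff:
        call = "NEUROD1"
    elif ascl1_score >= ascl1_cutoff:
        call = "ASCL1"
    else:
        call = "double_negative"
    return SubtypeCall(sample_id=sample_id, neurod1_score=float(neurod1_score),
                       ascl1_score=float(ascl1_score), call=call,
                       tumor_fraction=float(tumor_fraction))
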