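"""Window-level quantification for MBD-capture sequencing.

Fragments are assigned to fixed-width windows by midpoint, counts are
normalized to nrpm with a TMM factor against a pooled reference, and nrpm
values are converted to beta-values via a CpG-density-stratified "blind"
calibration: within each density stratum the least enriched windows anchor
the unmethylated level and the most enriched windows are assumed to sit
near full methylation (beta0, default 0.8). Enrichment-based capture grows
with both methylation and CpG density, so the calibration is a per-density
linear interpolation between those two anchors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .containers import CalibrationTable, CountMatrix, QCReport

MAPQ_MIN = 10
FRAGMENT_LEN_MIN = 50
FRAGMENT_LEN_MAX = 1000


# ---------------------------------------------------------------------------
# fragment assignment
# ---------------------------------------------------------------------------

def assign_fragments(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    window_size: int = 300,
) -> tuple[np.ndarray, dict]:
    """Count fragments into windows by midpoint location.

    Keeps fragments with MAPQ >= 10 and length in [50, 1000]; each
    surviving fragment increments exactly one non-excluded window, the one
    containing floor((start + end) / 2). Fragments on unknown contigs or
    falling into excluded/absent windows are tallied as rejects, not
    raised.

    Returns ``(counts, rejects)`` where ``counts`` aligns with ``windows``
    and sums to the surviving-fragment library size.
    """
    required = {"contig", "start", "end", "mapq"}
    missing = required - set(fragments.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    start = fragments["start"].to_numpy(np.int64)
    end = fragments["end"].to_numpy(np.int64)
    if (start >= end).any():
        raise ValueError("fragments must satisfy start < end")
    length = end - start
    keep = ((fragments["mapq"].to_numpy() >= MAPQ_MIN)
            & (length >= FRAGMENT_LEN_MIN) & (length <= FRAGMENT_LEN_MAX))
    rejects = {"filtered": int((~keep).sum()), "unknown_contig": 0,
               "outside_windows": 0, "excluded_window": 0}

    counts = np.zeros(len(windows), dtype=np.int64)
    mid = (start + end) // 2
    contig_groups = {c: grp for c, grp in windows.groupby("contig", sort=False)}
    for contig, frag_idx in fragments.groupby("contig", sort=False).groups.items():
        frag_idx = np.asarray(frag_idx)
        kept = frag_idx[keep[frag_idx]]
        if contig not in contig_groups:
            rejects["unknown_contig"] += len(kept)
            continue
        grp = contig_groups[contig]
        w_start = grp["start"].to_numpy()
        n_win = len(grp)
        widx = mid[kept] // window_size
        inside = (widx >= 0) & (widx < n_win) & (mid[kept] >= w_start[0])
        rejects["outside_windows"] += int((~inside).sum())
        widx = widx[inside]
        excl = grp["excluded"].to_numpy()[widx]
        rejects["excluded_window"] += int(excl.sum())
        widx = widx[~excl]
        np.add.at(counts, grp.index.to_numpy()[widx], 1)
    return counts, rejects


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def pooled_reference(counts: CountMatrix, samples: list[str] | None = None) -> pd.Series:
    """Sum counts over a reference pool into a single pseudo-sample."""
    cols = counts.samples if samples is None else list(samples)
    return counts.counts[cols].sum(axis=1)


def tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float | None = None,
    lib_ref: float | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Trimmed mean of M-values factor of ``obs`` against ``ref``.

    Windows are trimmed 30% on each tail of M (log ratio) and 5% on each
    tail of A (log abundance); the surviving log-ratios are averaged with
    inverse-variance (delta-method) weights and exponentiated. A sample
    with no usable overlap gets factor 1 with a warning.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_obs = float(obs.sum()) if lib_obs is None else float(lib_obs)
    n_ref = float(ref.sum()) if lib_ref is None else float(lib_ref)
    ok = (obs > 0) & (ref > 0)
    if not ok.any() or n_obs == 0 or n_ref == 0:
        warnings.warn("no usable windows shared with the reference; factor set to 1")
        return 1.0
    p_obs = obs[ok] / n_obs
    p_ref = ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def tmm_normalize(
    counts: CountMatrix,
    reference: pd.Series | str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> CountMatrix:
    """Attach TMM normalization factors computed against a pooled reference.

    ``reference`` may be a sample id, an explicit pooled count column, or
    None (pool of all samples). The reference normalized against itself has
    factor 1 by construction. Excluded windows carry zero counts and drop
    out of the trimmed mean automatically.
    """
    if reference is None:
        ref = pooled_reference(counts)
    elif isinstance(reference, str):
        ref = counts.counts[reference]
    else:
        ref = reference
    ref = np.asarray(ref, dtype=float)
    factors = {}
    for s in counts.samples:
        factors[s] = tmm_factor(counts.counts[s].to_numpy(), ref,
                                lib_obs=counts.library_size[s],
                                trim_m=trim_m, trim_a=trim_a)
    out = CountMatrix(counts.counts, counts.library_size,
                      pd.Series(factors, index=counts.counts.columns))
    return out


# ---------------------------------------------------------------------------
# blind calibration and beta estimation
# ---------------------------------------------------------------------------

def _density_strata(d: np.ndarray, usable: np.ndarray, min_support: int) -> list[tuple[int, int]]:
    """Greedily merge consecutive CpG counts into strata with enough support."""
    values, counts_per = np.unique(d[usable], return_counts=True)
    strata: list[tuple[int, int]] = []
    lo = None
    acc = 0
    for v, c in zip(values, counts_per):
        if lo is None:
            lo = v
        acc += c
        if acc >= min_support:
            strata.append((int(lo), int(v)))
            lo, acc = None, 0
    if lo is not None:
        if strata:
            prev_lo, _ = strata[-1]
            strata[-1] = (prev_lo, int(values[-1]))
        else:
            strata.append((int(lo), int(values[-1])))
    return strata


def fit_calibration(
    counts: CountMatrix,
    windows: pd.DataFrame,
    pool: list[str] | None = None,
    beta0: float = 0.8,
    decile: float = 0.10,
    min_support: int = 50,
) -> CalibrationTable:
    """Fit the blind nrpm-to-beta calibration from a reference pool.

    Per density stratum, the unmethylated anchor ``bg(d)`` is the mean nrpm
    of the least enriched decile and the most enriched decile is assumed to
    average beta0, giving ``full(d) = bg + (upper-decile mean - bg) / beta0``.
    ``full(d)`` is then made non-decreasing in density by isotonic
    regression (weighted by stratum support) and clipped at ``bg``.
    """
    if pool is None:
        pool = counts.samples
    if len(pool) < 1:
        raise ValueError("calibration pool must contain at least one sample")
    pooled = pooled_reference(counts, pool).to_numpy(dtype=float)
    lib = float(pooled.sum())
    if lib == 0:
        raise ValueError("calibration pool has zero total counts")
    nrpm = pooled / lib * 1e6
    d = windows["cpg_count"].to_numpy()
    usable = ~windows["excluded"].to_numpy()
    strata = _density_strata(d, usable, min_support)
    rows = []
    for lo, hi in strata:
        in_stratum = usable & (d >= lo) & (d <= hi)
        vals = np.sort(nrpm[in_stratum])
        n = len(vals)
        k = max(1, int(np.floor(n * decile)))
        bg = float(vals[:k].mean())
        upper = float(vals[-k:].mean())
        full = bg + max(upper - bg, 0.0) / beta0
        rows.append({"d_min": lo, "d_max": hi,
                     "d_mean": float(d[in_stratum].mean()),
                     "bg": bg, "full": full, "n": n})
    table = pd.DataFrame(rows)
    if len(table) > 1:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        table["full"] = iso.fit_transform(table["d_mean"], table["full"],
                                          sample_weight=table["n"])
    table["full"] = np.maximum(table["full"], table["bg"])
    return CalibrationTable(strata=table, beta0=beta0)


def estimate_beta(
    counts: CountMatrix,
    calibration: CalibrationTable,
    windows: pd.DataFrame,
    min_expected: float = 1.0,
) -> pd.DataFrame:
    """Convert nrpm to beta-values via the calibration.

    beta = clamp((nrpm - bg(d)) / (full(d) - bg(d)), 0, 1); windows whose
    dynamic range ``full - bg`` falls below ``min_expected`` nrpm (or that
    are excluded) cannot support an estimate and come back as NaN.
    """
    bg, full = calibration.lookup(windows["cpg_count"].to_numpy())
    span = full - bg
    invalid = (span < min_expected) | windows["excluded"].to_numpy()
    nrpm = counts.nrpm()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (nrpm.to_numpy() - bg[:, None]) / span[:, None]
    beta = np.clip(beta, 0.0, 1.0)
    beta[invalid, :] = np.nan
    return pd.DataFrame(beta, index=counts.counts.index, columns=counts.samples)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def relative_enrichment(counts_column: np.ndarray, windows: pd.DataFrame,
                        window_size: int = 300) -> float:
    """CpG-density enrichment of captured fragments over the genome.

    Mean CpG density of the windows weighted by their fragment counts,
    divided by the unweighted mean density, over non-excluded windows.
    A well-enriched methylation capture concentrates fragments in CpG-dense
    windows, pushing the ratio well above 1.
    """
    use = ~windows["excluded"].to_numpy()
    c = np.asarray(counts_column, dtype=float)[use]
    d = windows["cpg_count"].to_numpy(dtype=float)[use]
    total = c.sum()
    mean_d = d.mean()
    if total == 0 or mean_d == 0:
        return float("nan")
    return float((c @ d / total) / mean_d)


def qc_always_methylated(beta_column: pd.Series | np.ndarray,
                         windows: pd.DataFrame,
                         beta_min: float = 0.8) -> float:
    """Fraction of always-methylated QC windows reaching ``beta_min``.

    Windows with a missing beta count as below threshold. Raises if the
    window table flags no QC windows.
    """
    qc = windows["qc_always_methylated"].to_numpy()
    if not qc.any():
        raise ValueError("no always-methylated QC windows flagged")
    b = np.asarray(beta_column, dtype=float)[qc]
    high = np.nan_to_num(b, nan=-1.0) >= beta_min
    return float(high.mean())


def qc_sample(counts: CountMatrix, beta: pd.DataFrame, windows: pd.DataFrame,
              sample: str) -> QCReport:
    """Full QC report (enrichment + always-methylated check) for a sample."""
    ratio = relative_enrichment(counts.counts[sample].to_numpy(), windows)
    frac = qc_always_methylated(beta[sample], windows)
    return QCReport(
        sample=sample,
        relative_enrichment=ratio,
        pass_enrichment=bool(np.isfinite(ratio) and ratio >= QCReport.ENRICHMENT_MIN),
        frac_qc_windows_high=frac,
        pass_always_methylated=bool(frac >= QCReport.QC_FRACTION_MIN),
    )


# ---------------------------------------------------------------------------
# unsupervised analysis
# ---------------------------------------------------------------------------

def pca_variable_windows(
    beta: pd.DataFrame,
    batch: pd.Series | None = None,
    k_windows: int = 50_000,
    n_components: int = 10,
) -> dict:
    """PCA of samples on the most variable windows, after batch centering.

    Windows with any missing beta are dropped. Per window, batch means are
    removed (identity when a single batch is present), values are centered,
    and the ``k_windows`` windows with the largest s.d. across samples feed
    an SVD. Returns sample coordinates, explained variance ratios, the
    window ids used and a degeneracy flag (all-zero variance input).
    """
    if beta.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    x = beta.dropna(axis=0, how="any")
    samples = list(x.columns)
    mat = x.to_numpy(dtype=float).T  # samples x windows
    if batch is not None:
        batch = pd.Series(batch).loc[samples]
        for b in batch.unique():
            rows = (batch == b).to_numpy()
            mat[rows] -= mat[rows].mean(axis=0, keepdims=True)
    mat -= mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0)
    k = min(k_windows, mat.shape[1])
    top = np.argsort(sd)[::-1][:k]
    sub = mat[:, np.sort(top)]
    used_windows = x.index.to_numpy()[np.sort(top)]
    degenerate = bool(np.allclose(sub, 0.0))
    n_comp = min(n_components, sub.shape[0] - 1, sub.shape[1])
    u, s, _ = np.linalg.svd(sub, full_matrices=False)
    coords = u[:, :n_comp] * s[:n_comp]
    total_var = float((s ** 2).sum())
    evr = (s[:n_comp] ** 2 / total_var) if total_var > 0 else np.zeros(n_comp)
    return {
        "coordinates": pd.DataFrame(
            coords, index=samples,
            columns=[f"PC{i + 1}" for i in range(n_comp)]),
        "explained_variance_ratio": evr,
        "windows_used": used_windows,
        "degenerate": degenerate,
    }
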