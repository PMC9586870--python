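"""Differential methylation via per-window negative-binomial GLMs.

Each window is tested with an NB generalized linear model on fragment
counts with per-sample offsets ``log(library_size * norm_factor)`` and a
two-group design. Per-window dispersions are method-of-moments estimates
shrunk toward a CpG-density-dependent trend, and significance comes from a
likelihood-ratio test against the pooled null. The density-dependent
capture weight of a window is constant across samples and is absorbed by
the window's intercept, so it does not enter the offset explicitly.

Effect sizes are reported as the difference of group-mean beta-values
(delta beta), the quantity the downstream filters operate on.

The fitter is vectorized across windows (Fisher scoring on the one-
dimensional group-mean parameters), which keeps genome-scale null and
power studies tractable; tests cross-check it against statsmodels on small
panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy

from .containers import CalibrationTable, CountMatrix
from .quantify import estimate_beta
from .windows import window_context

DMR_COLUMNS = ["window", "log2_fc", "p_value", "q_value", "delta_beta",
               "direction", "converged"]


# ---------------------------------------------------------------------------
# vectorized NB fitting
# ---------------------------------------------------------------------------

def _nb_fit_mean(y: np.ndarray, log_off: np.ndarray, r: np.ndarray,
                 max_iter: int = 60, tol: float = 1e-10):
    """MLE of a single log-mean parameter per window (vectorized).

    Model: y_ij ~ NB(mu_ij, r_j) with log mu_ij = log_off_i + theta_j.
    Returns (theta, converged) arrays of shape (J,).
    """
    off = np.exp(log_off)[None, :]
    tot = y.sum(axis=1)
    theta = np.log((tot + 0.5) / off.sum())
    r_col = r[:, None]
    converged = np.zeros(len(theta), dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(theta)[:, None] * off
        wt = r_col / (r_col + mu)
        score = ((y - mu) * wt).sum(axis=1)
        info = (mu * wt).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + step
        converged = np.abs(step) < 1e-8
        if converged.all():
            break
    return theta, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    r_col = r[:, None]
    mu = np.maximum(mu, 1e-300)
    ll = (gammaln(y + r_col) - gammaln(r_col) - gammaln(y + 1)
          + r_col * np.log(r_col / (r_col + mu))
          + xlogy(y, mu / (r_col + mu)))
    return ll.sum(axis=1)


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Method-of-moments dispersion with a small-sample correction."""
    n = y.shape[1]
    resid2 = (y - mu) ** 2
    num = (resid2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    phi = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    correction = n / max(n - n_params, 1)
    return phi * correction


def _dispersion_trend(phi_hat: np.ndarray, d: np.ndarray,
                      n_bins: int = 10) -> np.ndarray:
    """Median dispersion per CpG-density bin, propagated to each window."""
    clipped = np.clip(phi_hat, 0.0, np.nanquantile(phi_hat, 0.99))
    order = np.argsort(d, kind="stable")
    bins = np.array_split(order, min(n_bins, max(len(d) // 50, 1)))
    trend = np.empty(len(d))
    for b in bins:
        trend[b] = np.median(clipped[b])
    return np.maximum(trend, 1e-6)


def nb_lrt_two_groups(
    y: np.ndarray,
    log_offsets: np.ndarray,
    group: np.ndarray,
    cpg_count: np.ndarray,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Vectorized NB likelihood-ratio test, one window per row.

    ``y`` is (windows x samples), ``group`` a boolean sample vector (True =
    group A). Dispersions are moment estimates from the group-mean fit,
    shrunk toward a CpG-density trend with ``prior_df`` prior degrees of
    freedom. Returns log2 fold change (A over B), the LRT statistic,
    p-values and a convergence flag.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=bool)
    n = y.shape[1]
    if group.sum() < 2 or (~group).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    # pilot fit with a small working dispersion to get group means
    phi0 = np.full(y.shape[0], 0.01)
    r0 = 1.0 / phi0
    th_a0, _ = _nb_fit_mean(y[:, group], log_offsets[group], r0)
    th_b0, _ = _nb_fit_mean(y[:, ~group], log_offsets[~group], r0)
    mu = np.empty_like(y)
    mu[:, group] = np.exp(th_a0[:, None] + log_offsets[None, group])
    mu[:, ~group] = np.exp(th_b0[:, None] + log_offsets[None, ~group])

    phi_hat = _moment_dispersion(y, mu, n_params=2)
    trend = _dispersion_trend(phi_hat, cpg_count)
    df_res = max(n - 2, 1)
    phi = (prior_df * trend + df_res * np.clip(phi_hat, 0.0, None)) / (prior_df + df_res)
    phi = np.clip(phi, 1e-6, 10.0)
    r = 1.0 / phi

    th_a, conv_a = _nb_fit_mean(y[:, group], log_offsets[group], r)
    th_b, conv_b = _nb_fit_mean(y[:, ~group], log_offsets[~group], r)
    th_0, conv_0 = _nb_fit_mean(y, log_offsets, r)

    mu_full = np.empty_like(y)
    mu_full[:, group] = np.exp(th_a[:, None] + log_offsets[None, group])
    mu_full[:, ~group] = np.exp(th_b[:, None] + log_offsets[None, ~group])
    mu_null = np.exp(th_0[:, None] + log_offsets[None, :])

    lrt = 2.0 * (_nb_loglik(y, mu_full, r) - _nb_loglik(y, mu_null, r))
    lrt = np.maximum(lrt, 0.0)
    lrt[lrt < 1e-10] = 0.0  # numerically null fits report p = 1 exactly
    converged = conv_a & conv_b & conv_0
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(converged, p, 1.0)
    return pd.DataFrame({
        "log2_fc": (th_a - th_b) / np.log(2.0),
        "lrt": lrt,
        "p_value": p,
        "dispersion": phi,
        "converged": converged,
    })


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(
    counts: CountMatrix,
    windows: pd.DataFrame,
    calibration: CalibrationTable,
    group_a: list[str],
    group_b: list[str],
    beta: pd.DataFrame | None = None,
    min_nrpm: float = 1.0,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Call differential methylation between two sample groups.

    Windows are prefiltered to nrpm > ``min_nrpm`` in at least one sample
    of the contrast (excluded windows never tested); the NB LRT supplies
    p-values, Benjamini-Hochberg q-values are computed across the tested
    windows, and delta beta is the difference of group-mean beta-values
    (group A minus group B). Non-convergent windows are kept with p = 1
    and flagged.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    cols = group_a + group_b
    sub = counts.subset(cols)
    nrpm = sub.nrpm()
    tested = ((nrpm > min_nrpm).any(axis=1).to_numpy()
              & ~windows["excluded"].to_numpy())
    test_idx = np.flatnonzero(tested)
    if len(test_idx) == 0:
        raise ValueError("no windows pass the nrpm prefilter")

    y = sub.counts.to_numpy(dtype=float)[test_idx]
    eff_lib = (sub.library_size * sub.norm_factor).loc[cols].to_numpy()
    log_off = np.log(eff_lib) - np.log(eff_lib).mean()
    group = np.array([c in set(group_a) for c in cols])
    res = nb_lrt_two_groups(y, log_off, group,
                            windows["cpg_count"].to_numpy()[test_idx],
                            prior_df=prior_df)

    if beta is None:
        beta = estimate_beta(sub, calibration, windows)
    d_beta = (beta[group_a].iloc[test_idx].mean(axis=1)
              - beta[group_b].iloc[test_idx].mean(axis=1)).to_numpy()

    q = stats.false_discovery_control(res["p_value"].to_numpy(), method="bh")
    out = pd.DataFrame({
        "window": test_idx,
        "log2_fc": res["log2_fc"].to_numpy(),
        "p_value": res["p_value"].to_numpy(),
        "q_value": np.maximum(q, res["p_value"].to_numpy()),
        "delta_beta": d_beta,
        "direction": np.sign(np.nan_to_num(d_beta)).astype(int),
        "converged": res["converged"].to_numpy(),
    })
    return out


def filter_significant(
    dmrs: pd.DataFrame,
    fdr: float = 0.001,
    min_abs_delta_beta: float = 0.5,
) -> pd.DataFrame:
    """Keep windows at q <= fdr with |delta beta| >= the threshold.

    Conventional defaults are 0.5 for tissue contrasts and 0.3 for
    cfDNA contrasts (pass ``min_abs_delta_beta=0.3``).
    """
    keep = ((dmrs["q_value"] <= fdr)
            & (dmrs["delta_beta"].abs() >= min_abs_delta_beta))
    return dmrs.loc[keep].reset_index(drop=True)


def annotate_cgi_context(
    dmrs: pd.DataFrame,
    cgi: pd.DataFrame,
    windows: pd.DataFrame,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> pd.DataFrame:
    """Attach CGI / shore / shelf / open_sea context to a DMR table.

    CGIs extended by ``shore_bp`` define shores and by a further
    ``shelf_bp`` define shelves; precedence CGI > shore > shelf.
    """
    context = window_context(windows, cgi, shore_bp=shore_bp, shelf_bp=shelf_bp)
    out = dmrs.copy()
    out["context"] = context[out["window"].to_numpy()]
    return out


def intersect_dmr_sets(**named_sets) -> dict:
    """Exact Venn-partition counts over window-id sets.

    Returns a dict mapping each non-empty membership combination (a sorted
    tuple of set names) to the number of windows belonging to exactly those
    sets.
    """
    sets = {k: set(v) for k, v in named_sets.items()}
    names = sorted(sets)
    partition: dict[tuple, int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for w in universe:
        member = tuple(n for n in names if w in sets[n])
        partition[member] = partition.get(member, 0) + 1
    return partition


def overlap_count(set_a, set_b) -> int:
    """Number of window ids shared by two DMR sets."""
    return len(set(set_a) & set(set_b))
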