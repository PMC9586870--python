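"""Synthetic MBD-capture cohort generator.

Produces complete cohorts — genome windows with CGI-like bimodal CpG
density, class methylomes with spiked differential methylation, negative-
binomial capture counts, cfDNA tumor/normal mixtures at known tumor
fraction, methylation-array probe profiles, subtype expression values and
survival outcomes — with the statistical structure the analysis pipeline
assumes.

The capture forward model is a saturating density response: a window with
true methylation beta and CpG count d captures fragments in proportion to
``w = background_capture + beta * g(d)`` with ``g(d) = d^a / (k^a + d^a)``,
and per-window counts are negative binomial with the expectations
``library_size * w / sum(w)``. The blind calibration stage inverts exactly
this class of model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .containers import CountMatrix, derive_rng
from .windows import cgi_intervals, window_context

SUBTYPES = ("ASCL1", "NEUROD1", "DN")
TF_GENES = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")

# stage keys for seed derivation
_S_GENOME, _S_METH, _S_COUNTS, _S_ARRAY, _S_EXPR, _S_SURV, _S_COHORT = range(7)


@dataclass
class TrueMethylome:
    """Ground-truth per-window methylation for one sample class."""

    beta: np.ndarray
    class_label: str
    #: +1 where this class is hypermethylated relative to the normal
    #: baseline, -1 hypomethylated, 0 identical
    dmr_mask: np.ndarray

    def __post_init__(self) -> None:
        if ((self.beta < 0) | (self.beta > 1)).any():
            raise ValueError("beta_true must lie in [0, 1]")


@dataclass
class SimulatedCohort:
    """Bundle of everything a pipeline run needs, fully seed-determined."""

    config: SimConfig
    windows: pd.DataFrame
    cgi: pd.DataFrame
    counts: CountMatrix
    samples: pd.DataFrame
    methylomes: dict
    dmr_truth: pd.DataFrame
    arrays: pd.DataFrame
    expression: pd.DataFrame

    def true_beta(self, sample_id: str) -> np.ndarray:
        """Ground-truth beta for any sample, mixing classes by tumor fraction."""
        row = self.samples.loc[sample_id]
        label = row["class_label"]
        if label == "normal":
            return self.methylomes["normal"].beta
        tumor = self.methylomes[label].beta
        tf = row["tumor_fraction"]
        if np.isnan(tf):
            raise ValueError(f"sample {sample_id} has no tumor fraction")
        return mixed_beta(tumor, self.methylomes["normal"].beta, tf)


def mixed_beta(beta_tumor: np.ndarray, beta_normal: np.ndarray, tf: float) -> np.ndarray:
    """Convex combination of tumor and normal methylomes at tumor fraction tf."""
    if not 0.0 <= tf <= 1.0:
        raise ValueError(f"tumor fraction must lie in [0, 1], got {tf}")
    return tf * beta_tumor + (1.0 - tf) * beta_normal


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> pd.DataFrame:
    """Simulate tiled windows on one synthetic contig.

    Windows are contiguous and half-open ([300i, 300(i+1))). CGI-like
    islands are geometric runs of windows covering ``cgi_fraction`` of the
    genome; CpG counts are Poisson with the island or background rate. A
    random subset is flagged excluded and a background subset serves as the
    always-methylated QC set.
    """
    config.validate()
    n = int(config.n_windows)
    if n < 100:
        raise ConfigError("n_windows must be >= 100")
    rng = derive_rng(config.seed, _S_GENOME)

    cgi = np.zeros(n, dtype=bool)
    f = config.cgi_fraction
    if f > 0:
        if f >= 1:
            cgi[:] = True
        else:
            mean_gap = config.mean_island_len * (1 - f) / f
            pos = 0
            while pos < n:
                gap = rng.geometric(1.0 / max(mean_gap, 1.0))
                pos += gap
                run = rng.geometric(1.0 / config.mean_island_len)
                cgi[pos: pos + run] = True
                pos += run
    cpg = np.where(cgi, rng.poisson(config.cpg_rate_cgi, n),
                   rng.poisson(config.cpg_rate_bg, n)).astype(np.int64)

    excluded = rng.random(n) < config.excluded_fraction
    qc = np.zeros(n, dtype=bool)
    bg_pool = np.flatnonzero(~cgi & ~excluded)
    n_qc = min(config.n_qc_windows, len(bg_pool))
    qc[rng.choice(bg_pool, size=n_qc, replace=False)] = True

    starts = np.arange(n, dtype=np.int64) * config.window_size
    return pd.DataFrame({
        "contig": "sim1",
        "start": starts,
        "end": starts + config.window_size,
        "cpg_count": cpg,
        "excluded": excluded,
        "qc_always_methylated": qc,
        "cgi": cgi,
    })


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, low, high, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, low, high)


def simulate_methylomes(
    windows: pd.DataFrame, config: SimConfig
) -> tuple[dict, pd.DataFrame]:
    """Build the normal methylome and three tumor subtype methylomes.

    The normal baseline has low beta in CGI-like windows (a configurable
    minority of islands is constitutively methylated) and high beta in the
    background, QC windows pinned at beta = 1. Pan-tumor DMRs are spiked
    with ``frac_hyper`` hypermethylated in the tumor and
    ``frac_dmr_cgi_context`` placed in CGI/shore/shelf context; each
    subtype additionally gets hyper- and hypo-methylated block windows
    distinguishing it from the two other subtypes and from normal.

    Returns ``(methylomes, dmr_truth)`` where ``methylomes`` maps
    ``normal`` / ``tumor_ASCL1`` / ``tumor_NEUROD1`` / ``tumor_DN`` to
    :class:`TrueMethylome` and ``dmr_truth`` records every spiked window
    (role ``pan`` or a subtype, direction +1/-1 in the affected class).
    """
    config.validate()
    rng = derive_rng(config.seed, _S_METH)
    n = len(windows)
    eff = config.dmr_effect_size
    cgi_flag = windows["cgi"].to_numpy()
    qc = windows["qc_always_methylated"].to_numpy()
    excluded = windows["excluded"].to_numpy()

    base = _truncated_normal(rng, config.beta_high, config.beta_sd, 0, 1, n)
    low = _truncated_normal(rng, config.beta_low, config.beta_sd, 0, 1, n)
    meth_cgi = rng.random(n) < config.cgi_methylated_fraction
    unmeth_bg = rng.random(n) < config.bg_unmethylated_fraction
    unmethylated = (cgi_flag & ~meth_cgi) | (~cgi_flag & unmeth_bg)
    normal = np.where(unmethylated, low, base)
    normal[qc] = 1.0

    context = window_context(windows, cgi_intervals(windows))
    eligible = (~qc & ~excluded
                & (windows["cpg_count"].to_numpy() >= config.min_dmr_cpg))
    in_ctx = eligible & np.isin(context, ["CGI", "shore", "shelf"])
    open_sea = eligible & (context == "open_sea")

    n_ctx = int(round(config.frac_dmr_cgi_context * config.n_dmrs))
    n_open = config.n_dmrs - n_ctx
    n_sub_total = 6 * config.n_subtype_dmrs_per_contrast
    if n_ctx > in_ctx.sum() or n_open > open_sea.sum():
        raise ConfigError("DMR demand exceeds available windows in the requested context")
    ctx_pool = rng.choice(np.flatnonzero(in_ctx), size=n_ctx, replace=False)
    open_pool = rng.choice(np.flatnonzero(open_sea), size=n_open, replace=False)
    pan = rng.permutation(np.concatenate([ctx_pool, open_pool]).astype(np.int64))

    remaining = np.flatnonzero(eligible & ~np.isin(np.arange(n), pan))
    if n_sub_total > len(remaining):
        raise ConfigError("subtype DMR demand exceeds available windows")
    sub_windows = rng.choice(remaining, size=n_sub_total, replace=False)

    n_hyper = int(round(config.frac_hyper * config.n_dmrs))
    hyper = pan[:n_hyper]
    hypo = pan[n_hyper:]

    # pan-tumor effects: exact +/- eff relative to the normal baseline
    normal[hyper] = _truncated_normal(rng, config.beta_low, config.beta_sd,
                                      0, 1 - eff, len(hyper))
    normal[hypo] = _truncated_normal(rng, config.beta_low, config.beta_sd,
                                     0, 1 - eff, len(hypo)) + eff
    tumor_shared = normal.copy()
    tumor_shared[hyper] += eff
    tumor_shared[hypo] -= eff

    betas = {s: tumor_shared.copy() for s in SUBTYPES}
    truth_rows = [
        *[{"window": int(j), "role": "pan", "direction": 1} for j in hyper],
        *[{"window": int(j), "role": "pan", "direction": -1} for j in hypo],
    ]
    m = config.n_subtype_dmrs_per_contrast
    blocks = sub_windows.reshape(6, m) if m > 0 else np.empty((6, 0), dtype=int)
    for i, s in enumerate(SUBTYPES):
        hyper_blk, hypo_blk = blocks[2 * i], blocks[2 * i + 1]
        lo_h = _truncated_normal(rng, config.beta_low, config.beta_sd,
                                 0, 1 - eff, m)
        normal[hyper_blk] = lo_h
        for t in SUBTYPES:
            betas[t][hyper_blk] = lo_h
        betas[s][hyper_blk] = lo_h + eff
        hi_h = _truncated_normal(rng, config.beta_low, config.beta_sd,
                                 0, 1 - eff, m) + eff
        normal[hypo_blk] = hi_h
        for t in SUBTYPES:
            betas[t][hypo_blk] = hi_h
        betas[s][hypo_blk] = hi_h - eff
        truth_rows += [{"window": int(j), "role": s, "direction": 1} for j in hyper_blk]
        truth_rows += [{"window": int(j), "role": s, "direction": -1} for j in hypo_blk]

    normal[qc] = 1.0
    for s in SUBTYPES:
        betas[s][qc] = 1.0

    methylomes = {"normal": TrueMethylome(normal, "normal",
                                          np.zeros(n, dtype=np.int8))}
    for s in SUBTYPES:
        diff = betas[s] - normal
        mask = np.sign(np.where(np.abs(diff) > 1e-12, diff, 0.0)).astype(np.int8)
        methylomes[f"tumor_{s}"] = TrueMethylome(betas[s], f"tumor_{s}", mask)
    dmr_truth = pd.DataFrame(truth_rows).sort_values("window").reset_index(drop=True)
    return methylomes, dmr_truth


# ---------------------------------------------------------------------------
# capture counts
# ---------------------------------------------------------------------------

def density_response(d: np.ndarray, config: SimConfig) -> np.ndarray:
    """Saturating CpG-density response g(d) = d^a / (k^a + d^a)."""
    a, k = config.capture_saturation
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(d > 0, d ** a / (k ** a + d ** a), 0.0)
    return g


def capture_mean(
    beta: np.ndarray, windows: pd.DataFrame, config: SimConfig,
    library_size: float | None = None,
) -> np.ndarray:
    """Expected per-window counts under the forward model.

    Excluded windows have zero capture weight; expected counts sum to the
    library size exactly.
    """
    g = density_response(windows["cpg_count"].to_numpy(), config)
    w = config.background_capture + np.asarray(beta, dtype=float) * g
    w = np.where(windows["excluded"].to_numpy(), 0.0, w)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate forward model: zero total capture weight")
    lib = config.library_size if library_size is None else library_size
    return lib * w / total


def simulate_counts(
    beta: np.ndarray | TrueMethylome,
    windows: pd.DataFrame,
    config: SimConfig,
    seed_or_rng,
    library_size: float | None = None,
) -> np.ndarray:
    """Draw one NB count column from the capture forward model."""
    if isinstance(beta, TrueMethylome):
        beta = beta.beta
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else derive_rng(seed_or_rng, _S_COUNTS)
    mu = capture_mean(beta, windows, config, library_size)
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_cfdna_sample(
    tumor: TrueMethylome | np.ndarray,
    normal: TrueMethylome | np.ndarray,
    tf: float,
    windows: pd.DataFrame,
    config: SimConfig,
    seed_or_rng,
    library_size: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate a cfDNA sample as a tumor/normal mixture at tumor fraction tf."""
    t = tumor.beta if isinstance(tumor, TrueMethylome) else np.asarray(tumor)
    m = normal.beta if isinstance(normal, TrueMethylome) else np.asarray(normal)
    beta = mixed_beta(t, m, tf)
    counts = simulate_counts(beta, windows, config, seed_or_rng, library_size)
    truth = {"tumor_fraction": float(tf)}
    return counts, truth


# ---------------------------------------------------------------------------
# arrays, expression, survival
# ---------------------------------------------------------------------------

def simulate_array(
    methylome: TrueMethylome | np.ndarray,
    windows: pd.DataFrame,
    config: SimConfig,
    seed_or_rng,
    sample_id: str = "array",
) -> pd.DataFrame:
    """Simulate methylation-array probes over the non-excluded windows.

    Every covered window gets at least one probe (the probe-count
    distribution comes from ``probes_per_window``); probe beta is the true
    window beta plus truncated Gaussian noise.
    """
    beta = methylome.beta if isinstance(methylome, TrueMethylome) else np.asarray(methylome)
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else derive_rng(seed_or_rng, _S_ARRAY)
    covered = np.flatnonzero(~windows["excluded"].to_numpy())
    n_probes = rng.choice(np.arange(1, len(config.probes_per_window) + 1),
                          size=len(covered), p=config.probes_per_window)
    win = np.repeat(covered, n_probes)
    noisy = np.clip(beta[win] + rng.normal(0, config.array_noise_sd, len(win)),
                    0.0, 1.0)
    return pd.DataFrame({
        "sample_id": sample_id,
        "probe_id": [f"{sample_id}_p{i}" for i in range(len(win))],
        "window": win.astype(np.int64),
        "beta": noisy,
    })


def simulate_expression(subtype: str, config: SimConfig, rng,
                        context: str = "cell_line") -> dict:
    """Normalized TF expression for ASCL1/NEUROD1/POU2F3/YAP1.

    The subtype's defining gene sits well above the threshold. For the
    double-negative class, cell lines may be POU2F3- or YAP1-driven;
    tumor models are POU2F3-driven (the model assignment rule takes the
    arg-max among ASCL1/NEUROD1/POU2F3 only).
    """
    vals = {g: rng.normal(config.expr_low_mean, config.expr_sd) for g in TF_GENES}
    if subtype == "DN":
        if context == "model":
            gene = "POU2F3"
        else:
            gene = "POU2F3" if rng.random() < 0.5 else "YAP1"
    elif subtype in ("ASCL1", "NEUROD1"):
        gene = subtype
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    vals[gene] = rng.normal(config.expr_high_mean, config.expr_sd)
    return vals


def simulate_survival(
    samples: pd.DataFrame, config: SimConfig, seed_or_rng=None
) -> pd.DataFrame:
    """Attach overall-survival fields to samples carrying a tumor fraction.

    Event times are exponential with log-hazard linear in the burden
    covariate z = tumor_fraction / tf_scale (coefficient ``surv_log_hr``);
    censoring is an independent exponential calibrated so that roughly
    ``censor_rate`` of baseline-hazard subjects are censored. Age, sex and
    stage covariates are attached (stage tracks tumor burden with some
    noise, mimicking higher-stage disease shedding more ctDNA).
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else derive_rng(config.seed if seed_or_rng is None else seed_or_rng, _S_SURV)
    out = samples.copy()
    for col in ["os_months", "os_event", "age"]:
        if col not in out.columns:
            out[col] = np.nan
    for col in ["sex", "stage"]:
        if col not in out.columns:
            out[col] = pd.Series(pd.NA, index=out.index, dtype="object")
    has_tf = out["tumor_fraction"].notna() & (out["tumor_fraction"] > 0)
    idx = out.index[has_tf]
    n = len(idx)
    if n == 0:
        return out
    tf = out.loc[idx, "tumor_fraction"].to_numpy(dtype=float)
    z = tf / config.tf_scale
    rate = config.baseline_hazard * np.exp(config.surv_log_hr * z)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        c_rate = config.baseline_hazard * config.censor_rate / (1 - config.censor_rate) \
            if config.censor_rate < 1 else np.inf
        t_cens = rng.exponential(1.0 / c_rate, size=n) if np.isfinite(c_rate) \
            else np.zeros(n)
    else:
        t_cens = np.full(n, np.inf)
    observed = t_event <= t_cens
    out.loc[idx, "os_months"] = np.minimum(t_event, t_cens)
    out.loc[idx, "os_event"] = observed.astype(int)
    out.loc[idx, "age"] = np.round(rng.normal(67, 8, n)).clip(35, 90)
    out.loc[idx, "sex"] = np.where(rng.random(n) < 0.5, "F", "M")
    noisy_tf = tf + rng.normal(0, 0.05, n)
    out.loc[idx, "stage"] = np.where(noisy_tf > 0.12, "ES", "LS")
    return out


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a complete cohort bundle, reproducible from the seed.

    Contains healthy lung tissue, high-purity tumor tissue models per
    subtype, NCC cfDNA (split into training and validation roles), SCLC
    cfDNA mixtures at known tumor fractions with survival outcomes, and
    cell-line array profiles with matching expression values.
    """
    config.validate()
    windows = simulate_genome(config)
    methylomes, dmr_truth = simulate_methylomes(windows, config)
    rng = derive_rng(config.seed, _S_COHORT)

    names, types, labels, tfs, roles = [], [], [], [], []
    cols = {}

    def add_count_sample(name, stype, label, tf, role, beta):
        names.append(name)
        types.append(stype)
        labels.append(label)
        tfs.append(tf)
        roles.append(role)
        cols[name] = simulate_counts(beta, windows, config, rng)

    normal = methylomes["normal"]
    for i in range(config.n_healthy_tissue):
        add_count_sample(f"HL_{i + 1:02d}", "tissue_healthy", "normal",
                         np.nan, "", normal.beta)
    for s, n_models in zip(SUBTYPES, config.n_tumor_models):
        for i in range(n_models):
            add_count_sample(f"T_{s}_{i + 1:02d}", "tissue_tumor",
                             f"tumor_{s}", 1.0, "", methylomes[f"tumor_{s}"].beta)
    n_train = int(np.ceil(config.ncc_train_fraction * config.n_ncc))
    for i in range(config.n_ncc):
        role = "train" if i < n_train else "validation"
        add_count_sample(f"NCC_{i + 1:02d}", "cfdna_ncc", "normal",
                         np.nan, role, normal.beta)
    lo, hi = config.tf_range
    for s, n_cf in zip(SUBTYPES, config.n_sclc_cfdna):
        for i in range(n_cf):
            tf = float(rng.uniform(lo, hi))
            beta = mixed_beta(methylomes[f"tumor_{s}"].beta, normal.beta, tf)
            add_count_sample(f"CF_{s}_{i + 1:02d}", "cfdna_sclc",
                             f"tumor_{s}", tf, "validation", beta)

    counts = CountMatrix(
        pd.DataFrame(cols, index=pd.RangeIndex(len(windows), name="window")),
        pd.Series({k: float(v.sum()) for k, v in cols.items()}),
    )
    samples = pd.DataFrame({
        "sample_type": types,
        "class_label": labels,
        "tumor_fraction": tfs,
        "role": roles,
    }, index=pd.Index(names, name="sample_id"))
    samples["batch"] = [f"b{i % config.n_batches + 1}" for i in range(len(samples))]

    # cell-line array profiles + expression truth
    array_frames, expr_rows = [], []
    arr_rng = derive_rng(config.seed, _S_ARRAY)
    expr_rng = derive_rng(config.seed, _S_EXPR)
    cl_samples = []
    for s, n_cl in zip(SUBTYPES, config.n_cell_lines):
        for i in range(n_cl):
            name = f"CL_{s}_{i + 1:02d}"
            jitter = np.clip(methylomes[f"tumor_{s}"].beta
                             + arr_rng.normal(0, config.cell_line_beta_sd,
                                              len(windows)), 0, 1)
            array_frames.append(simulate_array(jitter, windows, config,
                                               arr_rng, sample_id=name))
            expr = simulate_expression(s, config, expr_rng)
            expr_rows.append({"sample_id": name, "context": "cell_line",
                              "subtype_truth": s, **expr})
            cl_samples.append({"sample_id": name, "sample_type": "cell_line_array",
                               "class_label": f"tumor_{s}", "tumor_fraction": np.nan,
                               "role": "", "batch": ""})
    for name in samples.index[samples["sample_type"] == "tissue_tumor"]:
        s = samples.loc[name, "class_label"].removeprefix("tumor_")
        expr = simulate_expression(s, config, expr_rng, context="model")
        expr_rows.append({"sample_id": name, "context": "model",
                          "subtype_truth": s, **expr})
    arrays = pd.concat(array_frames, ignore_index=True) if array_frames \
        else pd.DataFrame(columns=["sample_id", "probe_id", "window", "beta"])
    expression = pd.DataFrame(expr_rows).set_index("sample_id") if expr_rows \
        else pd.DataFrame()
    if cl_samples:
        samples = pd.concat([samples,
                             pd.DataFrame(cl_samples).set_index("sample_id")])

    samples = simulate_survival(samples, config,
                                derive_rng(config.seed, _S_SURV))
    return SimulatedCohort(
        config=config, windows=windows, cgi=cgi_intervals(windows),
        counts=counts, samples=samples, methylomes=methylomes,
        dmr_truth=dmr_truth, arrays=arrays, expression=expression,
    )
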