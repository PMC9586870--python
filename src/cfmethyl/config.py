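"""Simulation configuration for synthetic MBD-capture cohorts.

A :class:`SimConfig` pins down every stochastic choice the cohort generator
makes: genome geometry, the CpG-density mixture, where differential
methylation is spiked in and how strong it is, the negative-binomial capture
forward model, array-probe noise, expression levels used for subtype truth,
and the survival model. Together with a seed it fully determines a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` field is out of its valid range."""


@dataclass(frozen=True)
class SimConfig:
    # --- genome geometry ---------------------------------------------------
    n_windows: int = 20_000
    window_size: int = 300
    #: fraction of windows lying inside CGI-like islands
    cgi_fraction: float = 0.15
    #: Poisson CpG rate per window inside islands / in background
    cpg_rate_cgi: float = 15.0
    cpg_rate_bg: float = 2.0
    #: mean island length in windows (geometric)
    mean_island_len: float = 4.0
    #: windows flagged as always-methylated QC controls (background windows,
    #: beta = 1 in every class)
    n_qc_windows: int = 200
    #: fraction of windows flagged excluded (blacklist-like)
    excluded_fraction: float = 0.01

    # --- methylomes --------------------------------------------------------
    n_dmrs: int = 300
    #: fraction of pan-tumor DMRs hypermethylated in the tumor
    frac_hyper: float = 0.69
    #: fraction of pan-tumor DMRs placed in CGI/shore/shelf context
    frac_dmr_cgi_context: float = 0.75
    dmr_effect_size: float = 0.80
    #: minimum CpG count for a window to host a spiked DMR — differential
    #: methylation of a window with (almost) no CpGs is not meaningful and
    #: carries no capture signal
    min_dmr_cpg: int = 3
    n_subtype_dmrs_per_contrast: int = 60
    #: unmethylated / methylated state means on the beta scale
    beta_low: float = 0.08
    beta_high: float = 0.80
    beta_sd: float = 0.04
    #: fraction of CGI-like windows that are constitutively methylated
    cgi_methylated_fraction: float = 0.25
    #: fraction of background windows that are unmethylated (open sea is
    #: mostly methylated but not uniformly so; this minority also anchors
    #: the blind calibration's background level at low densities)
    bg_unmethylated_fraction: float = 0.10

    # --- capture forward model --------------------------------------------
    library_size: int = 2_000_000
    #: NB dispersion phi (var = mu + phi * mu^2)
    dispersion: float = 0.005
    #: (a, k) of the saturating density response g(d) = d^a / (k^a + d^a)
    capture_saturation: tuple[float, float] = (3.0, 8.0)
    #: density-independent capture level at beta = 0
    background_capture: float = 0.01

    # --- methylation arrays -------------------------------------------------
    array_noise_sd: float = 0.03
    #: P(1), P(2), P(3) probes for a covered window
    probes_per_window: tuple[float, ...] = (0.7, 0.2, 0.1)
    #: per-cell-line beta jitter (biological variability between lines)
    cell_line_beta_sd: float = 0.02

    # --- expression truth for subtyping ------------------------------------
    expr_high_mean: float = 11.0
    expr_low_mean: float = 5.0
    expr_sd: float = 0.8
    expr_threshold: float = 9.0

    # --- survival model -----------------------------------------------------
    #: log hazard ratio per unit of the burden covariate z = tf / tf_scale
    surv_log_hr: float = math.log(3.6)
    tf_scale: float = 0.25
    #: exponential baseline hazard per month (median OS 12 months at z = 0)
    baseline_hazard: float = math.log(2.0) / 12.0
    censor_rate: float = 0.30

    # --- cohort composition -------------------------------------------------
    n_healthy_tissue: int = 8
    #: tumor tissue models per subtype (ASCL1, NEUROD1, double-negative)
    n_tumor_models: tuple[int, int, int] = (6, 4, 3)
    n_ncc: int = 16
    #: fraction of NCC cfDNA samples assigned to the training split
    ncc_train_fraction: float = 0.6
    #: SCLC cfDNA samples per subtype
    n_sclc_cfdna: tuple[int, int, int] = (5, 4, 3)
    tf_range: tuple[float, float] = (0.05, 0.40)
    #: array cell lines per subtype (ASCL1-heavy, as in public panels)
    n_cell_lines: tuple[int, int, int] = (10, 4, 4)
    n_batches: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # Each check names the offending field so config errors are actionable.
    def validate(self) -> None:
        pos_counts = ["n_windows", "window_size", "library_size",
                      "n_healthy_tissue", "n_ncc", "n_batches"]
        for name in pos_counts:
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive integer")
        nonneg_counts = ["n_dmrs", "n_subtype_dmrs_per_contrast",
                         "n_qc_windows"]
        for name in nonneg_counts:
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        proportions = ["cgi_fraction", "frac_hyper", "frac_dmr_cgi_context",
                       "censor_rate", "excluded_fraction", "beta_low",
                       "beta_high", "cgi_methylated_fraction",
                       "bg_unmethylated_fraction", "ncc_train_fraction"]
        for name in proportions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ["cpg_rate_cgi", "cpg_rate_bg", "background_capture",
                     "array_noise_sd", "beta_sd", "cell_line_beta_sd"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be strictly positive")
        a, k = self.capture_saturation
        if a <= 0 or k <= 0:
            raise ConfigError("capture_saturation components must be > 0")
        if self.mean_island_len < 1:
            raise ConfigError("mean_island_len must be >= 1")
        if not math.isclose(sum(self.probes_per_window), 1.0, abs_tol=1e-9):
            raise ConfigError("probes_per_window probabilities must sum to 1")
        if any(p < 0 for p in self.probes_per_window):
            raise ConfigError("probes_per_window probabilities must be >= 0")
        if not 0 <= self.dmr_effect_size <= 1:
            raise ConfigError("dmr_effect_size must lie in [0, 1]")
        lo, hi = self.tf_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("tf_range must satisfy 0 <= lo <= hi <= 1")
        if self.tf_scale <= 0:
            raise ConfigError("tf_scale must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if any(n < 0 for n in self.n_tumor_models + self.n_sclc_cfdna
               + self.n_cell_lines):
            raise ConfigError("cohort composition counts must be >= 0")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced-genome configuration for fast end-to-end runs.

    Keeps per-window depth (fragments per window) identical to the default
    configuration so that beta noise, DMR power and classifier behaviour are
    representative of the full-size cohort.
    """
    base = dict(
        n_windows=4_000,
        library_size=400_000,
        n_dmrs=150,
        n_subtype_dmrs_per_contrast=40,
        n_qc_windows=60,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
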