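"""Core in-memory containers shared across the pipeline.

Genomic windows and beta matrices are plain :class:`pandas.DataFrame`
objects with documented columns; the containers here add the bookkeeping
(library sizes, normalization factors, calibration strata) that several
stages need to agree on.

Window tables (``GenomeWindows``) carry the columns::

    contig, start, end        0-based half-open, fixed width
    cpg_count                 CpGs per window (density d)
    excluded                  bool, never receives counts downstream
    qc_always_methylated      bool, always-methylated QC subset
    cgi                       bool, window lies in a CGI-like island

Beta matrices are window x sample DataFrames of floats in [0, 1] with NaN
for windows where a beta value could not be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["contig", "start", "end", "cpg_count", "excluded",
                  "qc_always_methylated", "cgi"]


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic generator for a (seed, stage-key...) combination."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]]))


@dataclass
class CountMatrix:
    """Per-window fragment counts for a set of samples.

    ``counts`` is a window x sample DataFrame of non-negative integers.
    ``library_size`` holds the surviving-fragment total per sample and
    ``norm_factor`` the TMM factor (1.0 until normalization runs).
    """

    counts: pd.DataFrame
    library_size: pd.Series
    norm_factor: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.norm_factor is None:
            self.norm_factor = pd.Series(1.0, index=self.counts.columns)
        self.library_size = self.library_size.astype(float)
        missing = set(self.counts.columns) - set(self.library_size.index)
        if missing:
            raise ValueError(f"library_size missing for samples: {sorted(missing)}")
        if (self.library_size.loc[self.counts.columns] < 0).any():
            raise ValueError("library sizes must be non-negative")
        if (self.norm_factor <= 0).any():
            raise ValueError("norm_factor must be strictly positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def nrpm(self, samples: list[str] | None = None) -> pd.DataFrame:
        """Normalized reads per million: count / (library * factor) * 1e6."""
        cols = self.samples if samples is None else list(samples)
        eff = (self.library_size.loc[cols] * self.norm_factor.loc[cols])
        return self.counts[cols] / eff.replace(0, np.nan) * 1e6

    def subset(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)].copy(),
                           self.library_size.loc[list(samples)].copy(),
                           self.norm_factor.loc[list(samples)].copy())

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        if not self.counts.index.equals(other.counts.index):
            raise ValueError("window universes differ")
        dup = set(self.samples) & set(other.samples)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        return CountMatrix(
            pd.concat([self.counts, other.counts], axis=1),
            pd.concat([self.library_size, other.library_size]),
            pd.concat([self.norm_factor, other.norm_factor]),
        )


@dataclass
class CalibrationTable:
    """CpG-density-stratified map between nrpm and beta.

    One row per density stratum: ``d_min``/``d_max`` (inclusive bounds on
    CpG count), ``bg`` (nrpm at beta = 0), ``full`` (nrpm at beta = 1,
    isotonically non-decreasing in density) and ``n`` (supporting windows).
    """

    strata: pd.DataFrame
    beta0: float = 0.8

    def __post_init__(self) -> None:
        s = self.strata
        if (s["full"] + 1e-9 < s["bg"]).any():
            raise ValueError("calibration requires full(d) >= bg(d)")
        if (s["bg"] < 0).any():
            raise ValueError("background nrpm must be >= 0")
        if not s["d_min"].is_monotonic_increasing:
            raise ValueError("strata must be ordered by density")

    def lookup(self, cpg_count: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (bg, full) nrpm levels for each window density.

        Anchors are interpolated linearly in density between the stratum
        means (the capture response is smooth in CpG count, so a step
        function over merged strata would bias windows at the stratum
        edges) and clamped at the outermost strata.
        """
        d = np.asarray(cpg_count, dtype=float)
        nodes = self.strata["d_mean"].to_numpy(dtype=float)
        bg = np.interp(d, nodes, self.strata["bg"].to_numpy(dtype=float))
        full = np.interp(d, nodes, self.strata["full"].to_numpy(dtype=float))
        return bg, np.maximum(full, bg)


@dataclass
class QCReport:
    """Per-sample quality control summary."""

    sample: str
    relative_enrichment: float
    pass_enrichment: bool
    frac_qc_windows_high: float
    pass_always_methylated: bool

    ENRICHMENT_MIN = 2.5
    QC_FRACTION_MIN = 0.40

    @property
    def passed(self) -> bool:
        return self.pass_enrichment and self.pass_always_methylated

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "relative_enrichment": self.relative_enrichment,
            "pass_enrichment": bool(self.pass_enrichment),
            "frac_qc_windows_high": self.frac_qc_windows_high,
            "pass_always_methylated": bool(self.pass_always_methylated),
            "passed": bool(self.passed),
        }
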