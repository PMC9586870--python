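"""In-silico spike-in mixtures of per-window fragment counts.

Low tumor fractions are emulated by multinomially downsampling a tumor
source and a background (NCC cfDNA) source and summing the two columns, so
a mixture at proportion p with M total fragments carries round(p * M)
tumor fragments. Negative mixtures combine two background samples the same
way. Mixing happens at count level throughout: the downstream classifiers
consume window counts, so fragment-level resampling would add cost without
changing what they see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, derive_rng

_S_MIX = 101


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for one synthetic mixture column."""

    background_source: str
    proportion: float
    total_fragments: int
    seed: int
    tumor_source: str | None = None
    #: second background used for negative (tumor-free) mixtures
    background_source_2: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must lie in [0, 1]")
        if self.total_fragments <= 0:
            raise ValueError("total_fragments must be positive")

    @property
    def sources(self) -> set[str]:
        out = {self.background_source}
        if self.tumor_source is not None:
            out.add(self.tumor_source)
        if self.background_source_2 is not None:
            out.add(self.background_source_2)
        return out

    @property
    def label(self) -> int:
        """1 for tumor-containing mixtures, 0 for background-only."""
        return int(self.tumor_source is not None)


def downsample_counts(column: np.ndarray, m: int, rng) -> np.ndarray:
    """Multinomial subsample of ``m`` fragments from a count column."""
    column = np.asarray(column, dtype=np.int64)
    total = int(column.sum())
    if m > total:
        raise ValueError(f"cannot downsample to {m} fragments from a column of {total}")
    if m == 0:
        return np.zeros_like(column)
    if m == total:
        return column.copy()
    if not isinstance(rng, np.random.Generator):
        rng = derive_rng(rng, _S_MIX)
    p = column / total
    return rng.multinomial(m, p).astype(np.int64)


def mix_counts(spec: MixtureSpec, counts: CountMatrix) -> tuple[np.ndarray, dict]:
    """Realize a mixture column from its spec.

    Sums a downsample of the tumor source (round(p * M) fragments) with a
    downsample of the background making up the remainder; when no tumor
    source is named, the proportion instead comes from a second background
    sample. Returns the column and a truth record.
    """
    rng = derive_rng(spec.seed, _S_MIX)
    m_spike = int(round(spec.proportion * spec.total_fragments))
    m_bg = spec.total_fragments - m_spike
    spike_source = spec.tumor_source if spec.tumor_source is not None \
        else (spec.background_source_2 or spec.background_source)
    for name, m_need in [(spike_source, m_spike), (spec.background_source, m_bg)]:
        if name not in counts.samples:
            raise ValueError(f"mixture source {name!r} not present in counts")
        if m_need > counts.counts[name].sum():
            raise ValueError(f"mixture source {name!r} has insufficient depth "
                             f"({int(counts.counts[name].sum())} < {m_need})")
    col = (downsample_counts(counts.counts[spike_source].to_numpy(), m_spike, rng)
           + downsample_counts(counts.counts[spec.background_source].to_numpy(), m_bg, rng))
    truth = {"tumor_source": spec.tumor_source,
             "background_source": spec.background_source,
             "background_source_2": spec.background_source_2,
             "proportion": spec.proportion,
             "total_fragments": spec.total_fragments,
             "label": spec.label}
    return col, truth


def generate_mixture_collection(
    counts: CountMatrix,
    tumor_sources: list[str],
    background_sources: list[str],
    n: int,
    p_range: tuple[float, float] = (0.005, 0.05),
    m_range: tuple[int, int] = (500_000, 2_000_000),
    seed: int = 0,
    positive_fraction: float = 0.5,
    prefix: str = "mix",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Build a balanced, reproducible set of mixtures with a manifest.

    Positives spike a random tumor source into a random background at a
    proportion uniform in ``p_range``; negatives mix two distinct
    backgrounds at the same proportions. Total fragment counts are drawn
    log-uniformly over ``m_range``. The manifest records every spec so
    source-aware train/test splits (and member-level leakage checks) stay
    possible.
    """
    if n == 0:
        empty = CountMatrix(pd.DataFrame(index=counts.counts.index),
                            pd.Series(dtype=float))
        return empty, pd.DataFrame(columns=[
            "mixture_id", "tumor_source", "background_source",
            "background_source_2", "proportion", "total_fragments",
            "label", "seed"])
    if not tumor_sources or not background_sources:
        raise ValueError("source pools must be non-empty")
    rng = derive_rng(seed, _S_MIX, 1)
    lo_p, hi_p = p_range
    lo_m, hi_m = m_range
    n_pos = int(round(positive_fraction * n))
    rows, cols = [], {}
    for i in range(n):
        positive = i < n_pos
        p = float(rng.uniform(lo_p, hi_p))
        m = int(np.exp(rng.uniform(np.log(lo_m), np.log(hi_m))))
        bg = str(rng.choice(background_sources))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        if positive:
            spec = MixtureSpec(background_source=bg, proportion=p,
                               total_fragments=m, seed=sub_seed,
                               tumor_source=str(rng.choice(tumor_sources)))
        else:
            others = [b for b in background_sources if b != bg] or [bg]
            spec = MixtureSpec(background_source=bg, proportion=p,
                               total_fragments=m, seed=sub_seed,
                               background_source_2=str(rng.choice(others)))
        col, truth = mix_counts(spec, counts)
        name = f"{prefix}_{i + 1:04d}"
        cols[name] = col
        rows.append({"mixture_id": name, **truth, "seed": sub_seed})
    mat = CountMatrix(pd.DataFrame(cols, index=counts.counts.index),
                      pd.Series({k: float(v.sum()) for k, v in cols.items()}))
    manifest = pd.DataFrame(rows)
    return mat, manifest


def dilution_series(
    counts: CountMatrix,
    tumor_source: str,
    background_source: str,
    proportions: list[float],
    total_fragments: int = 1_000_000,
    seed: int = 0,
    prefix: str = "dil",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Ordered mixture ladder at fixed depth for limit-of-detection curves."""
    if list(proportions) != sorted(proportions):
        raise ValueError("proportions must be sorted ascending")
    rng = derive_rng(seed, _S_MIX, 2)
    rows, cols = [], {}
    for i, p in enumerate(proportions):
        spec = MixtureSpec(background_source=background_source,
                           proportion=float(p),
                           total_fragments=total_fragments,
                           seed=int(rng.integers(0, 2 ** 31 - 1)),
                           tumor_source=tumor_source if p > 0 else None)
        col, truth = mix_counts(spec, counts)
        name = f"{prefix}_{i + 1:02d}"
        cols[name] = col
        rows.append({"mixture_id": name, **truth})
    mat = CountMatrix(pd.DataFrame(cols, index=counts.counts.index),
                      pd.Series({k: float(v.sum()) for k, v in cols.items()}))
    return mat, pd.DataFrame(rows)
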