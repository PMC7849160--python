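"""Normalization regimes: rarefaction, relative abundance, size-factor log transform, row z-scores.

Three regimes mirror the robustness checks applied to the stability index:
rarefaction to a fixed depth (default convention: one seeded draw without
replacement per sample), per-sample relative abundance, and median-of-ratios
size-factor scaling followed by a shifted log2 (the count-normalization family
popularized by differential-abundance tools).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stabilome.io_model import CountTable

__all__ = [
    "NormalizationSpec",
    "rarefy",
    "relative_abundance",
    "size_factor_log_normalize",
    "zscore_rows",
    "RarefactionResult",
]


@dataclass
class NormalizationSpec:
    method: str = "rarefy"  # rarefy | relative | size_factor_log
    depth: int = 11020
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("rarefy", "relative", "size_factor_log"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def apply(self, table: CountTable) -> CountTable:
        if self.method == "rarefy":
            return rarefy(table, self.depth, self.seed).table
        if self.method == "relative":
            return relative_abundance(table)
        return size_factor_log_normalize(table).table


@dataclass
class RarefactionResult:
    table: CountTable
    depth: int
    seed: int
    dropped_samples: list = field(default_factory=list)


def rarefy(table: CountTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample column to exactly ``depth`` reads without replacement.

    Samples whose total is below the depth are dropped and reported in the
    result rather than padded. One multivariate-hypergeometric draw per sample,
    reproducible for a given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    vals = table.values
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(vals).astype(np.int64)
    rng = np.random.default_rng(seed)
    kept_cols, dropped = [], []
    out = {}
    for j, sid in enumerate(table.samples):
        total = int(counts[:, j].sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            out[sid] = counts[:, j]
        else:
            out[sid] = rng.multivariate_hypergeometric(counts[:, j], depth)
        kept_cols.append(sid)
    if not kept_cols:
        raise ValueError(f"all samples have fewer than {depth} reads; nothing to rarefy")
    df = pd.DataFrame(out, index=table.features, columns=kept_cols)
    return RarefactionResult(CountTable(df), depth=depth, seed=seed, dropped_samples=dropped)


def relative_abundance(table: CountTable) -> CountTable:
    """Divide each sample column by its total; idempotent."""
    vals = table.values.astype(float)
    sums = vals.sum(axis=0)
    if (sums <= 0).any():
        bad = table.samples[int(np.argmax(sums <= 0))]
        raise ValueError(f"sample {bad!r} has zero total; cannot normalize")
    df = pd.DataFrame(vals / sums, index=table.features, columns=table.samples)
    return CountTable(df, is_normalized=True)


@dataclass
class SizeFactorResult:
    table: CountTable
    size_factors: pd.Series


def size_factor_log_normalize(table: CountTable, pseudocount: float = 1.0) -> SizeFactorResult:
    """Median-of-ratios size factors then log2(count / size_factor + pseudocount).

    Size factors are each sample's median ratio to the per-feature geometric
    mean over features detected in every sample, rescaled to geometric mean 1.
    """
    counts = table.values.astype(float)
    detected = (counts > 0).all(axis=1)
    if not detected.any():
        raise ValueError(
            "no feature is detected in all samples; filter low-prevalence features first"
        )
    ref = counts[detected]
    log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.log(ref) - log_gm
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean exactly 1
    norm = np.log2(counts / sf + pseudocount)
    df = pd.DataFrame(norm, index=table.features, columns=table.samples)
    return SizeFactorResult(CountTable(df), pd.Series(sf, index=table.samples, name="size_factor"))


def zscore_rows(matrix: pd.DataFrame | np.ndarray, ddof: int = 1) -> pd.DataFrame | np.ndarray:
    """Standardize each row to mean 0, sd 1 (sample sd by default)."""
    arr = np.asarray(matrix, dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    if (sd <= 0).any():
        bad = int(np.argmax(sd.ravel() <= 0))
        raise ValueError(f"row {bad} is constant; cannot standardize")
    z = (arr - mu) / sd
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z
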