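"""Average variation degree (AVD): a replicate-dispersion index of community stability.

For a group of k replicate communities, each feature's variation degree in each
sample is the absolute z-score of its abundance against the within-group mean
and standard deviation,

    |a_i| = |x_i - xbar_i| / delta_i,

and the group AVD is the mean of all defined |a_i| terms,

    AVD = sum(|a_i|) / (k * n),

where n counts features whose within-group standard deviation delta_i is
positive (constant features carry no variation signal and would otherwise be
0/0). Lower AVD means a more stable community. With sample-sd semantics
(ddof=1) a k=2 group of non-constant features yields AVD = sqrt(2)/2 exactly;
with ddof=0 it is exactly 1 — the two-sample algebraic identity documents the
ddof choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stabilome.io_model import CountTable, SampleMetadata
from stabilome.normalization import NormalizationSpec

__all__ = ["AvdResult", "variation_degrees", "avd", "avd_by_group", "consortium_removal_screen"]


@dataclass
class AvdResult:
    group: str
    k: int
    n_total: int
    n_effective: int
    avd: float
    deviations: pd.DataFrame  # |a_i| per retained feature x sample
    n_excluded: int = 0
    normalization: str = "as-provided"

    def __post_init__(self) -> None:
        if self.avd < 0:
            raise ValueError("AVD cannot be negative")


def variation_degrees(
    table: CountTable,
    group_samples: list,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-feature, per-sample |a_i| within one replicate group.

    Returns (deviation matrix over features with positive within-group sd,
    index of excluded zero-variance features).
    """
    if len(group_samples) < 2:
        raise ValueError(f"group needs k >= 2 samples, got {len(group_samples)}")
    sub = table.subset_samples(group_samples)
    x = sub.values.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    defined = sd.ravel() > 0
    a = np.abs(x[defined] - mu[defined]) / sd[defined]
    dev = pd.DataFrame(a, index=sub.data.index[defined], columns=group_samples)
    excluded = sub.data.index[~defined]
    return dev, excluded


def avd(
    table: CountTable,
    group_samples: list,
    ddof: int = 1,
    group: str = "group",
    keep_constant_as_zero: bool = False,
) -> AvdResult:
    """Group-level AVD over one set of replicate samples.

    ``keep_constant_as_zero`` switches to the sensitivity mode in which
    zero-variance features contribute zero deviation but stay in n.
    """
    dev, excluded = variation_degrees(table, group_samples, ddof=ddof)
    k = len(group_samples)
    n_total = len(table.features)
    n_eff = dev.shape[0]
    if keep_constant_as_zero:
        n_eff = n_total
    if n_eff == 0:
        raise ValueError(f"group {group!r}: every feature is constant; AVD undefined")
    value = float(dev.to_numpy().sum() / (k * n_eff))
    return AvdResult(
        group=group,
        k=k,
        n_total=n_total,
        n_effective=n_eff,
        avd=value,
        deviations=dev,
        n_excluded=len(excluded),
    )


def avd_by_group(
    table: CountTable,
    metadata: SampleMetadata,
    normalization: NormalizationSpec | None = None,
    ddof: int = 1,
    keep_constant_as_zero: bool = False,
) -> dict[str, AvdResult]:
    """One AvdResult per metadata group (dilution, or dilution x pH).

    The optional normalization is applied to the full table first so every
    group is computed under the same provenance (rarefied-11020, rarefied-8000
    and size-factor variants stay comparable).
    """
    metadata.require_cover(table)
    prov = "as-provided"
    if normalization is not None:
        table = normalization.apply(table)
        prov = f"{normalization.method}:{normalization.depth}" if (
            normalization.method == "rarefy"
        ) else normalization.method
    results: dict[str, AvdResult] = {}
    for label, samples in metadata.groups().items():
        samples = [s for s in samples if s in table.data.columns]
        res = avd(table, samples, ddof=ddof, group=label,
                  keep_constant_as_zero=keep_constant_as_zero)
        res.normalization = prov
        results[label] = res
    return results


def consortium_removal_screen(
    series: dict[str, CountTable],
    ddof: int = 1,
) -> pd.DataFrame:
    """Rank removal conditions of a defined consortium by AVD.

    ``series`` maps a condition label (e.g. ``full``, ``-Ecl``) to a table of
    replicate samples for that condition. Each condition's replicates form one
    AVD group; conditions are returned ranked by descending AVD. The top
    condition is the putative keystone removal: losing a stabilizing member
    inflates replicate-to-replicate compositional variation.
    """
    rows = []
    for label, tab in series.items():
        if len(tab.samples) < 2:
            raise ValueError(f"condition {label!r} has < 2 replicate samples")
        res = avd(tab, tab.samples, ddof=ddof, group=label)
        rows.append({"condition": label, "k": res.k, "n_effective": res.n_effective,
                     "avd": res.avd})
    df = pd.DataFrame(rows).sort_values("avd", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def avd_summary_frame(results: dict[str, AvdResult]) -> pd.DataFrame:
    """Flatten AvdResults into the TSV-ready one-row-per-group summary."""
    rows = [
        {
            "group": r.group, "k": r.k, "n_total": r.n_total,
            "n_effective": r.n_effective, "n_excluded": r.n_excluded,
            "avd": r.avd, "normalization": r.normalization,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)
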