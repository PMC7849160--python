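"""Phylogenetic diversity, UniFrac dissimilarity, and betaMNTD/betaNTI assembly inference.

Faith's PD and weighted UniFrac are standard phylogenetic measures and are
delegated to scikit-bio. betaMNTD (between-community mean nearest-taxon
distance) and its null-model z-score betaNTI are implemented here on the
patristic distance matrix: the null shuffles taxon labels across the tips of
the tree (richness-preserving), and

    betaNTI = (observed betaMNTD - null mean) / null sd.

betaNTI > 2 indicates variable selection (more phylogenetic turnover than the
null), betaNTI < -2 homogeneous selection, and |betaNTI| <= 2 is consistent
with stochastic assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from stabilome.io_model import CountTable, IdentifierError
from stabilome.normalization import relative_abundance

__all__ = [
    "faith_pd",
    "weighted_unifrac",
    "bmntd",
    "bnti",
    "classify_assembly",
    "BetaNtiResult",
    "VARIABLE_SELECTION",
    "HOMOGENEOUS_SELECTION",
    "STOCHASTIC",
]

VARIABLE_SELECTION = "variable_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
STOCHASTIC = "stochastic"


def _check_features_in_tree(table: CountTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [f for f in table.features if f not in tips]
    if missing:
        raise IdentifierError(f"features absent from tree: {missing[:5]}")


def faith_pd(table: CountTable, tree: TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity per sample (root-inclusive spanning subtree)."""
    _check_features_in_tree(table, tree)
    vals = table.values
    out = {}
    for j, sid in enumerate(table.samples):
        col = vals[:, j]
        if col.sum() <= 0:
            raise ValueError(f"sample {sid!r} is empty; PD undefined")
        presence = (col > 0).astype(int)  # PD uses presence; robust to float tables
        out[sid] = float(_skbio_faith_pd(presence, taxa=table.features, tree=tree))
    return pd.Series(out, name="faith_pd")


def _branch_proportions(table: CountTable, tree: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch x sample matrix of subtree abundance proportions).

    Post-order accumulation: each branch carries the summed relative abundance
    of the tips below it, per sample.
    """
    rel = table if table.is_normalized else relative_abundance(table)
    feat_row = {f: i for i, f in enumerate(rel.features)}
    vals = rel.values
    n_samples = vals.shape[1]
    lengths, rows = [], []
    acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            if node.name in feat_row:
                p = vals[feat_row[node.name]].astype(float)
            else:
                p = np.zeros(n_samples)
        else:
            p = sum(acc.pop(id(c)) for c in node.children)
        acc[id(node)] = p
        lengths.append(node.length)
        rows.append(p)
    return np.asarray(lengths), np.vstack(rows)


def weighted_unifrac(table: CountTable, tree: TreeNode, normalized: bool = True) -> pd.DataFrame:
    """Weighted UniFrac distance matrix between all sample pairs.

    The table is converted to relative abundance first. Each branch contributes
    its length times |p_A - p_B|, the absolute difference of the relative
    abundance summed over the tips below it; the normalized variant divides by
    the branch-length-weighted total abundance so values fall in [0, 1].
    """
    _check_features_in_tree(table, tree)
    lengths, B = _branch_proportions(table, tree)
    samples = table.samples
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = float(lengths @ np.abs(B[:, i] - B[:, j]))
            if normalized:
                den = float(lengths @ (B[:, i] + B[:, j]))
                diff = diff / den if den > 0 else 0.0
            D[i, j] = D[j, i] = diff
    return pd.DataFrame(D, index=samples, columns=samples)


def _mntd_one_direction(D: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                        wa: np.ndarray | None) -> float:
    """Mean distance from each taxon in A to its nearest taxon in B."""
    nearest = D[np.ix_(ia, ib)].min(axis=1)
    if wa is None:
        return float(nearest.mean())
    return float(nearest @ wa)


def bmntd(
    table: CountTable,
    tree: TreeNode,
    pair: tuple,
    abundance_weighted: bool = True,
) -> float:
    """betaMNTD between two samples: two-direction mean nearest-taxon distance."""
    _check_features_in_tree(table, tree)
    dm = tree.tip_tip_distances()
    D = dm.data
    idx = {name: i for i, name in enumerate(dm.ids)}
    feat_idx = np.array([idx[f] for f in table.features])
    cols = {s: j for j, s in enumerate(table.samples)}
    a, b = pair
    return _bmntd_from_matrix(
        D, feat_idx,
        table.values[:, cols[a]].astype(float),
        table.values[:, cols[b]].astype(float),
        abundance_weighted,
    )


def _bmntd_from_matrix(D, feat_idx, xa, xb, abundance_weighted) -> float:
    pa, pb = xa > 0, xb > 0
    if not pa.any() or not pb.any():
        raise ValueError("betaMNTD undefined for an empty community")
    ia, ib = feat_idx[pa], feat_idx[pb]
    if abundance_weighted:
        wa = xa[pa] / xa[pa].sum()
        wb = xb[pb] / xb[pb].sum()
    else:
        wa = wb = None
    return 0.5 * (_mntd_one_direction(D, ia, ib, wa) + _mntd_one_direction(D, ib, ia, wb))


@dataclass
class BetaNtiResult:
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    bnti: pd.DataFrame
    n_null: int
    seed: int
    undefined_pairs: list

    def long_frame(self) -> pd.DataFrame:
        """Long-format (pair, observed, null mean, null sd, betaNTI, class) table."""
        rows = []
        ids = list(self.observed.index)
        classes = classify_assembly(self)
        for a, b in combinations(ids, 2):
            rows.append({
                "sample_a": a, "sample_b": b,
                "observed_bmntd": self.observed.loc[a, b],
                "null_mean": self.null_mean.loc[a, b],
                "null_sd": self.null_sd.loc[a, b],
                "bnti": self.bnti.loc[a, b],
                "assembly_class": classes.loc[a, b],
            })
        return pd.DataFrame(rows)


def bnti(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    max_undefined_fraction: float = 0.05,
) -> BetaNtiResult:
    """betaNTI for every sample pair against a tip-label-shuffling null.

    Each null draw applies one fresh seeded permutation of taxon labels across
    all tree tips and recomputes betaMNTD for every pair, so pairs share the
    same null ensemble. Pairs whose null sd collapses (< 1e-12) are reported
    undefined rather than given an infinite score.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99 for a usable null distribution")
    _check_features_in_tree(table, tree)
    dm = tree.tip_tip_distances()
    D = dm.data
    idx = {name: i for i, name in enumerate(dm.ids)}
    feat_idx = np.array([idx[f] for f in table.features])
    n_tips = D.shape[0]
    X = table.values.astype(float)
    samples = list(table.samples)
    pairs = list(combinations(range(len(samples)), 2))

    def all_pairs(fidx: np.ndarray) -> np.ndarray:
        return np.array([
            _bmntd_from_matrix(D, fidx, X[:, a], X[:, b], abundance_weighted)
            for a, b in pairs
        ])

    observed = all_pairs(feat_idx)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(pairs)))
    for d in range(n_null):
        perm = rng.permutation(n_tips)
        nulls[d] = all_pairs(perm[feat_idx])
    mu, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)

    def square(vec: np.ndarray) -> pd.DataFrame:
        M = np.zeros((len(samples), len(samples)))
        for (a, b), v in zip(pairs, vec):
            M[a, b] = M[b, a] = v
        return pd.DataFrame(M, index=samples, columns=samples)

    undefined = [
        (samples[a], samples[b]) for (a, b), s in zip(pairs, sd) if s < 1e-12
    ]
    if len(undefined) > max_undefined_fraction * len(pairs):
        raise ValueError(
            f"{len(undefined)}/{len(pairs)} pairs have degenerate null sd; "
            "tree or table too small for a betaNTI null model"
        )
    z = np.full_like(observed, np.nan)
    ok = sd >= 1e-12
    z[ok] = (observed[ok] - mu[ok]) / sd[ok]
    return BetaNtiResult(
        observed=square(observed), null_mean=square(mu), null_sd=square(sd),
        bnti=square(z), n_null=n_null, seed=seed, undefined_pairs=undefined,
    )


def classify_assembly(result: BetaNtiResult | pd.DataFrame) -> pd.DataFrame:
    """Assembly-process class per pair from the +/-2 betaNTI thresholds."""
    z = result.bnti if isinstance(result, BetaNtiResult) else result
    arr = z.to_numpy()
    out = np.full(arr.shape, STOCHASTIC, dtype=object)
    out[arr > 2] = VARIABLE_SELECTION
    out[arr < -2] = HOMOGENEOUS_SELECTION
    out[np.isnan(arr)] = "undefined"
    np.fill_diagonal(out, "")
    return pd.DataFrame(out, index=z.index, columns=z.columns)
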