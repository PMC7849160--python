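"""Seeded synthetic generators emulating a dilution-to-extinction x pH microcosm study.

The generators provide offline, fully parameterized stand-ins for the study's
processed data products: an OTU count table over a known phylogeny for a
4-dilution x 5-pH x replicate design, a functional-category relative-abundance
table with planted correlation modules and keystone categories, and a 7-member
consortium removal series with one planted stabilizing member.

Design of the planted effects
-----------------------------
* Dilution removes taxa: each dilution level retains a decreasing fraction of
  a log-normal regional pool (sampled once per level, since replicate
  microcosms of one level share an inoculum).
* pH selects taxa: each taxon carries a pH optimum evolved on the tree under a
  Brownian-motion-style model (so the trait has phylogenetic signal), and
  survives filtering with a Gaussian kernel whose strength rises with dilution
  (fewer taxa means weaker buffering against the imposed gradient).
* Replicate instability is planted as occupancy turnover - taxa blinking in
  and out across replicate microcosms - plus log-normal abundance noise. The
  average variation degree is a mean absolute within-group z-score, which is
  insensitive to pure variance scaling, so the turnover rate (which reshapes
  per-taxon profiles toward the bimodal high-|z| limit) is the dispersion dial
  that makes AVD rise with dilution.
* The consortium generator plants a keystone member whose removal lets the
  community flip between two alternative compositional states across
  replicates; removing any other member causes only a mild shift. The regime
  separation for the keystone removal is ``minor_shift * dispersion_factor``
  log units (factor 1 erases the keystone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

import stabilome.functional_classes as fc
from stabilome.io_model import CountTable, SampleMetadata

__all__ = [
    "DilutionScenario",
    "FunctionalScenario",
    "random_tree",
    "brownian_trait",
    "simulate_dilution_design",
    "simulate_functional_profiles",
    "simulate_consortium",
    "random_communities",
    "clade_restricted_communities",
]


# ---------------------------------------------------------------------------
# trees and traits


def random_tree(n_taxa: int, seed: int, depth_scaling: float = 1.0,
                jitter: float = 0.2) -> TreeNode:
    """Random ultrametric hierarchy with clade height scaling as (clade size)^a.

    Emulates the nested structure of microbial phylogenies: small clades are
    shallow while basal splits are deep, so clade membership carries strong
    patristic signal (within-clade distances are small relative to
    between-clade ones). ``depth_scaling`` is the exponent a (larger = sharper
    hierarchy); ``jitter`` multiplies each node height by a log-normal factor
    so trees are not perfectly clock-like. Tips are named ``OTU0001`` onward.
    """
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    names = [f"OTU{i + 1:04d}" for i in rng.permutation(n_taxa)]

    def height(m: int) -> float:
        base = (m / n_taxa) ** depth_scaling
        return base * float(np.exp(rng.normal(0.0, jitter)))

    def build(members: list[str], parent_height: float) -> TreeNode:
        if len(members) == 1:
            return TreeNode(name=members[0], length=parent_height)
        h = min(height(len(members)), parent_height * 0.95)
        left_n = 1 + int(rng.binomial(len(members) - 2, 0.5))
        idx = rng.permutation(len(members))
        left = [members[i] for i in idx[:left_n]]
        right = [members[i] for i in idx[left_n:]]
        node = TreeNode(length=parent_height - h)
        node.extend([build(left, h), build(right, h)])
        return node

    root_h = height(n_taxa)
    root = TreeNode(length=0.0)
    left_n = 1 + int(rng.binomial(n_taxa - 2, 0.5))
    idx = rng.permutation(n_taxa)
    root.extend([
        build([names[i] for i in idx[:left_n]], root_h),
        build([names[i] for i in idx[left_n:]], root_h),
    ])
    return root


def brownian_trait(tree: TreeNode, seed: int, rate: float = 1.0) -> pd.Series:
    """Continuous trait evolved root-to-tip with Normal(0, rate * branch) increments."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(rate * max(node.length, 1e-12)))
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({t.name: values[id(t)] for t in tree.tips()})


# ---------------------------------------------------------------------------
# dilution x pH design


@dataclass
class DilutionScenario:
    """Parameters of the emulated dilution-to-extinction design.

    The schedules are indexed by dilution level, least to most dilute. The
    richness-retention curve must be decreasing and the turnover (dispersion)
    schedule non-decreasing.
    """

    n_taxa: int = 200
    dilution_exponents: tuple = (-1, -4, -7, -10)
    ph_levels: tuple = (4.5, 5.5, 6.5, 7.5, 8.5)
    replicates: int = 6
    depth: int = 15000
    richness_retention: tuple = (1.0, 0.70, 0.45, 0.25)
    ph_filter_strength: tuple = (0.05, 0.10, 0.15, 0.20)
    ph_niche_width: tuple = (float("inf"),) * 4  # pH distance beyond which a taxon dies out
    evenness: tuple = (0.0, 0.3, 0.6, 0.8)  # regrowth-to-carrying-capacity flattening
    turnover: tuple = (0.05, 0.20, 0.30, 0.45)
    replicate_sigma: tuple = (0.30, 0.35, 0.40, 0.45)
    pool_sigma: float = 1.2
    phylo_signal: float = 0.8  # 0 = pH optima independent of the tree, 1 = pure Brownian
    seed: int = 0

    def __post_init__(self) -> None:
        n_levels = len(self.dilution_exponents)
        for name in ("richness_retention", "ph_filter_strength", "ph_niche_width",
                     "evenness", "turnover", "replicate_sigma"):
            if len(getattr(self, name)) != n_levels:
                raise ValueError(f"{name} must have one entry per dilution level")
        if any(b < a for a, b in zip(self.richness_retention[1:], self.richness_retention)):
            raise ValueError("richness retention must be non-increasing with dilution")
        if any(b < a for a, b in zip(self.turnover, self.turnover[1:])):
            raise ValueError("turnover (dispersion) must be non-decreasing with dilution")
        if max(self.richness_retention) > 1.0:
            raise ValueError("retention fractions cannot exceed the pool size")
        if not 0.0 <= self.phylo_signal <= 1.0:
            raise ValueError("phylo_signal must be in [0, 1]")

    def manifest(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}

    @classmethod
    def strong_selection(cls, seed: int = 0) -> "DilutionScenario":
        """Variant emphasizing deterministic pH assembly rather than instability.

        Narrowing pH niche widths with dilution makes community membership at
        different target pH phylogenetically divergent, the construction under
        which betaNTI detects variable selection between pH levels. The
        default scenario instead emphasizes the replicate-instability (AVD)
        patterns; membership exclusion sparsifies within-group profiles and
        would distort the planted AVD gradient, so the two effects are planted
        in separate scenario presets.
        """
        return cls(
            seed=seed,
            n_taxa=96,
            replicates=3,
            ph_levels=(4.5, 6.5, 8.5),
            ph_niche_width=(10.0, 5.0, 3.0, 1.8),
            phylo_signal=0.95,
            turnover=(0.05, 0.1, 0.1, 0.1),
            replicate_sigma=(0.3, 0.3, 0.3, 0.3),
            evenness=(0.0, 0.2, 0.4, 0.6),
            richness_retention=(1.0, 0.8, 0.65, 0.5),
            depth=4000,
        )


def _ph_optima(tree: TreeNode, scenario: DilutionScenario, rng: np.random.Generator) -> pd.Series:
    bm = brownian_trait(tree, seed=int(rng.integers(2**31 - 1)))
    z = (bm - bm.mean()) / (bm.std(ddof=0) + 1e-12)
    noise = pd.Series(rng.normal(size=len(z)), index=z.index)
    s = scenario.phylo_signal
    mixed = s * z + np.sqrt(max(1.0 - s**2, 0.0)) * noise
    lo, hi = min(scenario.ph_levels) - 0.5, max(scenario.ph_levels) + 0.5
    ranks = mixed.rank(method="first")
    return lo + (hi - lo) * (ranks - 0.5) / len(ranks)


def simulate_dilution_design(
    scenario: DilutionScenario,
) -> tuple[CountTable, TreeNode, SampleMetadata]:
    """Generate (OTU count table, phylogeny, metadata) for the full design."""
    rng = np.random.default_rng(scenario.seed)
    tree = random_tree(scenario.n_taxa, seed=int(rng.integers(2**31 - 1)))
    taxa = [t.name for t in tree.tips()]
    pool = pd.Series(
        np.exp(rng.normal(0.0, scenario.pool_sigma, scenario.n_taxa)), index=taxa
    )
    optima = _ph_optima(tree, scenario, rng)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for lvl, exponent in enumerate(scenario.dilution_exponents):
        n_keep = max(2, int(round(scenario.richness_retention[lvl] * scenario.n_taxa)))
        # one inoculum per dilution level: taxa survive dilution in proportion
        # to their pool abundance
        p = (pool / pool.sum()).to_numpy()
        kept = rng.choice(scenario.n_taxa, size=n_keep, replace=False, p=p)
        kept_mask = np.zeros(scenario.n_taxa, dtype=bool)
        kept_mask[kept] = True
        strength = scenario.ph_filter_strength[lvl]
        width = scenario.ph_niche_width[lvl]
        flat = 1.0 - scenario.evenness[lvl]
        q, sigma = scenario.turnover[lvl], scenario.replicate_sigma[lvl]
        for ph in scenario.ph_levels:
            dist = np.abs(optima.to_numpy() - ph)
            fitness = np.exp(-strength * dist**2)
            survives = dist <= width
            if not (kept_mask & survives).any():
                raise ValueError(
                    f"pH niche width {width} leaves no survivor at pH {ph}, "
                    f"dilution {exponent}"
                )
            # regrowth to carrying capacity compresses abundance differences
            # (pool dominance and selection strength alike) in the sparser,
            # more diluted communities; membership selection stays crisp
            base = (pool.to_numpy() * fitness) ** flat * (kept_mask & survives)
            for rep in range(1, scenario.replicates + 1):
                present = base * (rng.random(scenario.n_taxa) >= q)
                weights = present * np.exp(rng.normal(0.0, sigma, scenario.n_taxa))
                if weights.sum() <= 0:  # pathological corner; keep the cell non-empty
                    weights = base
                counts = rng.multinomial(scenario.depth, weights / weights.sum())
                sid = f"D{exponent}_pH{ph:g}_r{rep}"
                columns[sid] = counts
                meta_rows.append(
                    {"sample": sid, "dilution_exponent": exponent, "pH": ph, "replicate": rep}
                )
    table = CountTable(pd.DataFrame(columns, index=taxa))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample"))
    return table, tree, meta


# ---------------------------------------------------------------------------
# functional-category profiles


@dataclass
class FunctionalScenario:
    """Planted correlation-module structure for functional categories.

    Categories come from the shipped vocabulary; the specialized and broad
    metabolic classes form the two main correlated blocks, with opposite
    dilution trends, and the planted keystone categories additionally co-vary
    (negatively) with the per-group dispersion that drives AVD.
    """

    categories: tuple = ()  # empty = full shipped vocabulary
    within_module_rho: float = 0.95
    cross_module_rho: float = 0.0
    trend_strength: float = 1.0  # specialized down / broad up across dilution
    keystones: tuple = ("Nitrogen metabolism", "Phosphonate and phosphinate metabolism")
    keystone_coupling: float = 1.5
    noise_scale: float = 0.5
    seed: int = 0

    def resolved_categories(self) -> list[str]:
        if self.categories:
            return list(self.categories)
        return (
            list(fc.SPECIALIZED_CATEGORIES)
            + ["Phosphonate and phosphinate metabolism"]
            + list(fc.BROAD_CATEGORIES)
            + list(fc._GENETIC_CATEGORIES)
            + list(fc._CELLULAR_CATEGORIES)
            + list(fc._ENVIRONMENTAL_CATEGORIES)
            + list(fc._ORGANISMAL_CATEGORIES)
        )

    def correlation_matrix(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """(PSD target correlation, category names, module id per category)."""
        cats = self.resolved_categories()
        classes = [fc.functional_class_of(c) for c in cats]
        module = np.array([
            0 if cl == fc.SPECIALIZED_METABOLIC else 1 if cl == fc.BROAD_METABOLIC else 2
            for cl in classes
        ])
        n = len(cats)
        corr = np.full((n, n), 0.0)
        for a in range(n):
            for b in range(n):
                if a == b:
                    corr[a, b] = 1.0
                elif module[a] == module[b] and module[a] in (0, 1):
                    corr[a, b] = self.within_module_rho
                elif {module[a], module[b]} == {0, 1}:
                    corr[a, b] = self.cross_module_rho
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-8:
            raise ValueError(
                "planted correlation matrix is not positive semi-definite; "
                "reduce |cross_module_rho| or project to the nearest PSD matrix"
            )
        return corr, cats, module


def simulate_functional_profiles(
    scenario: FunctionalScenario,
    metadata: SampleMetadata,
    sample_instability: pd.Series | None = None,
) -> CountTable:
    """Relative-abundance table of functional categories per sample.

    Latent Gaussian-copula draws honor the planted correlation blocks; class
    means trend with dilution (specialized decline, broad rise); keystone
    categories are pushed down in proportion to each sample's instability
    score. ``sample_instability`` is any per-sample stability measure (e.g.
    the community's mean variation degree); when omitted the group's dilution
    rank is used, a coarse group-level proxy. A per-sample score is what makes
    the keystones carry information no trend-following category duplicates.
    """
    corr, cats, module = scenario.correlation_matrix()
    rng = np.random.default_rng(scenario.seed)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(cats)))
    meta = metadata.table
    exps = sorted(set(meta["dilution_exponent"]), reverse=True)  # -1 first
    dil_rank = {e: i / max(len(exps) - 1, 1) for i, e in enumerate(exps)}
    if sample_instability is None:
        disp = np.array([dil_rank[e] for e in meta["dilution_exponent"]])
    else:
        missing = [s for s in meta.index if s not in sample_instability.index]
        if missing:
            raise ValueError(f"sample_instability misses samples: {missing[:5]}")
        disp = sample_instability.loc[meta.index].to_numpy(dtype=float)
    disp_z = (disp - disp.mean()) / (disp.std(ddof=0) + 1e-12)

    n_samples = len(meta)
    z = (chol @ rng.normal(size=(len(cats), n_samples)))
    base = np.log(np.full(len(cats), 1.0 / len(cats))).reshape(-1, 1)
    trend = np.array([
        -scenario.trend_strength if m == 0 else scenario.trend_strength if m == 1 else 0.0
        for m in module
    ]).reshape(-1, 1)
    t = np.array([dil_rank[e] for e in meta["dilution_exponent"]]).reshape(1, -1)
    logab = base + trend * t + scenario.noise_scale * z
    keystone_rows = [i for i, c in enumerate(cats) if c in scenario.keystones]
    for i in keystone_rows:
        logab[i] -= scenario.keystone_coupling * disp_z
    ab = np.exp(logab)
    ab /= ab.sum(axis=0, keepdims=True)
    df = pd.DataFrame(ab, index=cats, columns=list(meta.index))
    return CountTable(df, is_normalized=True)


# ---------------------------------------------------------------------------
# consortium removal series

CONSORTIUM_MEMBERS = ("Ecl", "Sma", "Opi", "Hfr", "Ppu", "Cpu", "Cin")


def simulate_consortium(
    n_members: int = 7,
    keystone_index: int = 0,
    replicates: int = 10,
    seed: int = 0,
    depth: int = 10000,
    sigma0: float = 0.2,
    minor_shift: float = 0.3,
    dispersion_factor: float = 4.0,
) -> dict[str, CountTable]:
    """Full consortium plus every single-member removal, with a planted keystone.

    Each condition is ``replicates`` multinomial count columns. Replicates of a
    removal condition alternate (balanced) between two compositional regimes
    separated by random-signed log shifts of magnitude ``minor_shift`` - or
    ``minor_shift * dispersion_factor`` when the keystone was removed, in which
    case the community flips between genuinely alternative states and every
    member's replicate profile becomes bimodal (high AVD). ``dispersion_factor
    = 1`` removes the planted keystone effect.
    """
    if not 0 <= keystone_index < n_members:
        raise ValueError("keystone_index out of range")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    members = [CONSORTIUM_MEMBERS[i] if i < len(CONSORTIUM_MEMBERS) else f"M{i + 1}"
               for i in range(n_members)]
    base_log = rng.normal(0.0, 0.5, n_members)

    def condition(label: str, removed: int | None) -> CountTable:
        keep = [i for i in range(n_members) if i != removed]
        logs = base_log[keep]
        if removed is None:
            shift = np.zeros(len(keep))
        else:
            magnitude = minor_shift * (dispersion_factor if removed == keystone_index else 1.0)
            # balanced signs: the two regimes are genuinely different compositions
            # (an all-same-sign shift would cancel under closure)
            signs = np.array([1.0, -1.0] * ((len(keep) + 1) // 2))[: len(keep)]
            rng.shuffle(signs)
            shift = magnitude * signs
        regimes = np.array([-0.5, 0.5] * ((replicates + 1) // 2))[:replicates]
        rng.shuffle(regimes)
        cols = {}
        for r in range(replicates):
            lg = logs + regimes[r] * shift + rng.normal(0.0, sigma0, len(keep))
            p = np.exp(lg)
            cols[f"{label}_r{r + 1}"] = rng.multinomial(depth, p / p.sum())
        return CountTable(pd.DataFrame(cols, index=[members[i] for i in keep]))

    series = {"full": condition("full", None)}
    for i, name in enumerate(members):
        series[f"-{name}"] = condition(f"-{name}", i)
    return series


# ---------------------------------------------------------------------------
# community helpers for the assembly null model


def random_communities(
    tree: TreeNode, n_communities: int, richness: int, seed: int, depth: int = 2000
) -> CountTable:
    """Communities of uniformly sampled tips - the no-selection null construction."""
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    if richness > len(taxa):
        raise ValueError("richness exceeds number of tips")
    cols = {}
    for c in range(n_communities):
        chosen = rng.choice(len(taxa), size=richness, replace=False)
        counts = np.zeros(len(taxa), dtype=int)
        counts[chosen] = rng.multinomial(depth, np.full(richness, 1.0 / richness))
        cols[f"rand{c + 1}"] = counts
    return CountTable(pd.DataFrame(cols, index=taxa))


def clade_restricted_communities(
    tree: TreeNode, n_communities: int, richness: int, seed: int,
    depth: int = 2000,
) -> CountTable:
    """Communities drawn from one small clade - phylogenetically clustered pairs.

    The smallest clade holding at least twice the requested richness is used:
    large enough that the sampled taxon sets stay distinct (identical sets
    have a degenerate betaMNTD null), small enough to be a genuine clade
    restriction.
    """
    rng = np.random.default_rng(seed)
    taxa = [t.name for t in tree.tips()]
    n_tips = len(taxa)
    candidates = [
        [t.name for t in node.tips()]
        for node in tree.non_tips()
        if 2 * richness <= len(list(node.tips())) <= n_tips // 2
    ]
    if not candidates:
        raise ValueError("no clade holds 2x the requested richness; lower richness")
    clade = min(candidates, key=len)
    cols = {}
    for c in range(n_communities):
        chosen = rng.choice(len(clade), size=richness, replace=False)
        counts = pd.Series(0, index=taxa)
        picked = [clade[i] for i in chosen]
        counts[picked] = rng.multinomial(depth, np.full(richness, 1.0 / richness))
        cols[f"clade{c + 1}"] = counts.to_numpy()
    return CountTable(pd.DataFrame(cols, index=taxa))
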