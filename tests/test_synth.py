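import numpy as np
import pandas as pd
import pytest

from stabilome.io_model import CountTable
from stabilome.normalization import NormalizationSpec
from stabilome.phylo import weighted_unifrac
from stabilome.stability import avd_by_group
from stabilome.synth import (
    DilutionScenario,
    FunctionalScenario,
    brownian_trait,
    clade_restricted_communities,
    random_communities,
    random_tree,
    simulate_consortium,
    simulate_dilution_design,
    simulate_functional_profiles,
)

DILUTION_ORDER = ["10^-1", "10^-4", "10^-7", "10^-10"]


class TestRandomTree:
    def test_tip_count_names_and_branch_lengths(self):
        tree = random_tree(50, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 50
        assert len({t.name for t in tips}) == 50
        assert all(n.length >= 0 for n in tree.traverse(include_self=False))

    def test_deterministic_given_seed(self):
        a = random_tree(20, seed=5)
        b = random_tree(20, seed=5)
        assert str(a) == str(b)

    def test_small_clades_are_shallow(self):
        """Hierarchy: mean within-clade distance below mean between-clade distance."""
        tree = random_tree(64, seed=1)
        dm = tree.tip_tip_distances()
        half = [t.name for t in list(tree.children[0].tips())]
        other = [t.name for t in list(tree.children[1].tips())]
        ids = list(dm.ids)
        D = pd.DataFrame(dm.data, index=ids, columns=ids)
        within = D.loc[half, half].to_numpy()
        between = D.loc[half, other].to_numpy()
        assert within[np.triu_indices(len(half), 1)].mean() < between.mean()


class TestBrownianTrait:
    def test_phylogenetic_signal(self):
        """Closely related tips carry more similar trait values than distant ones."""
        tree = random_tree(64, seed=2)
        trait = brownian_trait(tree, seed=3)
        dm = tree.tip_tip_distances()
        ids = list(dm.ids)
        iu = np.triu_indices(len(ids), 1)
        phylo_d = dm.data[iu]
        trait_d = np.abs(trait[np.array(ids)[iu[0]]].to_numpy()
                         - trait[np.array(ids)[iu[1]]].to_numpy())
        rho = pd.Series(phylo_d).corr(pd.Series(trait_d), method="spearman")
        assert rho > 0.3


class TestDilutionDesign:
    def test_shapes_metadata_and_validity(self):
        counts, tree, meta = simulate_dilution_design(DilutionScenario(seed=0))
        assert len(counts.samples) == 4 * 5 * 6
        assert (counts.values >= 0).all()
        assert set(counts.features) == {t.name for t in tree.tips()}
        meta.require_cover(counts)
        assert len(meta.groups()) == 4

    def test_deterministic_given_seed(self):
        c1, _, _ = simulate_dilution_design(DilutionScenario(seed=8))
        c2, _, _ = simulate_dilution_design(DilutionScenario(seed=8))
        assert (c1.values == c2.values).all()

    def test_richness_decreases_with_dilution(self):
        drops = 0
        for seed in range(5):
            counts, _, meta = simulate_dilution_design(DilutionScenario(seed=seed))
            rich = [
                np.mean((counts.subset_samples(meta.groups()[g]).values > 0).sum(axis=0))
                for g in DILUTION_ORDER
            ]
            drops += all(a > b for a, b in zip(rich, rich[1:]))
        assert drops == 5

    def test_no_filtering_no_ph_effect_on_unifrac(self):
        sc = DilutionScenario(
            seed=3, n_taxa=60, replicates=2, ph_levels=(4.5, 6.5, 8.5),
            ph_filter_strength=(0.0,) * 4, depth=3000,
        )
        counts, tree, meta = simulate_dilution_design(sc)
        ids = meta.groups()["10^-1"]
        sub = counts.subset_samples(ids)
        sub = CountTable(sub.data.loc[(sub.values > 0).any(axis=1)])
        d = weighted_unifrac(sub, tree)
        ph = meta.table["pH"]
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                (within if ph[a] == ph[b] else between).append(d.loc[a, b])
        assert abs(np.mean(between) - np.mean(within)) < 0.1

    def test_constant_dispersion_gives_flat_avd(self):
        sc = DilutionScenario(
            seed=4,
            turnover=(0.1, 0.1, 0.1, 0.1),
            replicate_sigma=(0.3,) * 4,
            evenness=(0.0,) * 4,
            richness_retention=(1.0, 1.0, 1.0, 1.0),
            ph_filter_strength=(0.05,) * 4,
        )
        counts, _, meta = simulate_dilution_design(sc)
        res = avd_by_group(counts, meta, NormalizationSpec("rarefy", depth=11020, seed=4))
        avds = [res[g].avd for g in DILUTION_ORDER]
        assert max(avds) - min(avds) < 0.03

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError, match="retention"):
            DilutionScenario(richness_retention=(0.3, 0.5, 0.7, 1.0))
        with pytest.raises(ValueError, match="non-decreasing"):
            DilutionScenario(turnover=(0.5, 0.3, 0.2, 0.1))


class TestFunctionalProfiles:
    def test_columns_are_relative_abundances(self, design_metadata):
        ft = simulate_functional_profiles(FunctionalScenario(seed=0), design_metadata)
        assert np.allclose(ft.values.sum(axis=0), 1.0, atol=1e-9)
        assert ft.is_normalized

    def test_non_psd_target_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            FunctionalScenario(cross_module_rho=-0.99).correlation_matrix()

    def test_planted_blocks_recovered_by_thresholded_network(self, design_metadata):
        from stabilome.conet import build_network, correlate_all_pairs

        sc = FunctionalScenario(seed=1, trend_strength=0.0, keystone_coupling=0.0)
        ft = simulate_functional_profiles(sc, design_metadata)
        _, cats, module = sc.correlation_matrix()
        net = build_network(correlate_all_pairs(ft))
        import itertools

        within_hit = within_tot = cross_hit = cross_tot = 0
        mod = dict(zip(cats, module))
        for a, b in itertools.combinations(cats, 2):
            if mod[a] == mod[b] and mod[a] in (0, 1):
                within_tot += 1
                within_hit += net.has_edge(a, b)
            elif {mod[a], mod[b]} == {0, 1}:
                cross_tot += 1
                cross_hit += net.has_edge(a, b)
        assert within_hit / within_tot >= 0.8
        assert cross_hit / cross_tot < 0.05

    def test_detected_modularity_beats_random(self, design_metadata):
        from stabilome.conet import (
            build_network,
            correlate_all_pairs,
            partition_modules,
            random_ensemble_summary,
        )

        sc = FunctionalScenario(seed=2, trend_strength=0.0, keystone_coupling=0.0)
        ft = simulate_functional_profiles(sc, design_metadata)
        net = build_network(correlate_all_pairs(ft))
        _, m = partition_modules(net, seed=2)
        ens = random_ensemble_summary(net, n_draws=30, seed=2)
        assert m > ens.loc["modularity", "mean"]

    def test_keystone_wiring_yields_module_hub(self):
        """A node wired densely inside its module classifies as a module hub."""
        import networkx as nx

        from stabilome.conet import node_roles

        g = nx.Graph()
        members = [f"m{i}" for i in range(12)]
        for m in members:
            g.add_edge("Nitrogen metabolism", m)  # keystone touches all
        g.add_edges_from([(members[i], members[i + 1]) for i in range(0, 10, 2)])
        g.add_edge("Nitrogen metabolism", "outside")
        partition = {m: 0 for m in members} | {"Nitrogen metabolism": 0, "outside": 1}
        roles = node_roles(g, partition)
        assert roles.loc["Nitrogen metabolism", "role"] == "module_hub"


class TestConsortium:
    def test_structure_and_determinism(self):
        series = simulate_consortium(seed=0)
        assert set(series) == {"full", "-Ecl", "-Sma", "-Opi", "-Hfr", "-Ppu", "-Cpu", "-Cin"}
        assert len(series["full"].features) == 7
        assert len(series["-Ecl"].features) == 6
        again = simulate_consortium(seed=0)
        assert (series["-Ecl"].values == again["-Ecl"].values).all()

    def test_keystone_removal_avd_exceeds_full(self):
        from stabilome.stability import avd

        for seed in range(5):
            series = simulate_consortium(seed=seed)
            a_key = avd(series["-Ecl"], series["-Ecl"].samples).avd
            a_full = avd(series["full"], series["full"].samples).avd
            assert a_key > a_full

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_consortium(replicates=1)
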