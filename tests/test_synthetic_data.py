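import numpy as np
import pytest

import assemblage.synthetic_data as syn
from assemblage.core_data import tree_to_distances, validate_bundle
from assemblage.synthetic_data import (
    ScenarioConfig,
    competition_factor,
    gen_functions,
    gen_hosts,
    gen_sources,
    gen_tree,
    generate_scenario,
)


class TestGenTree:
    def test_two_tips(self):
        d = tree_to_distances(gen_tree(2, seed=0))
        assert len(d.otu_ids) == 2

    def test_deterministic(self):
        assert gen_tree(10, seed=5) == gen_tree(10, seed=5)
        assert gen_tree(10, seed=5) != gen_tree(10, seed=6)

    def test_yule_shape(self):
        nwk = gen_tree(50, seed=1)
        d = tree_to_distances(nwk)
        assert len(d.otu_ids) == 50
        assert nwk.count("(") == 49  # binary: n-1 splits including root

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            gen_tree(1, seed=0)


class TestGenSources:
    def test_zero_turnover_shares_membership(self):
        cfg = ScenarioConfig(n_stations=4, n_otus_pool=60,
                             station_turnover=0.0, seed=3)
        table, _ = gen_sources(cfg)
        memberships = [frozenset(np.flatnonzero(row)) for row in table.counts]
        assert len(set(memberships)) == 1

    def test_full_turnover_disjoint_neighbours(self):
        cfg = ScenarioConfig(n_stations=3, n_otus_pool=400,
                             station_occupancy=0.25, station_turnover=1.0,
                             seed=3)
        table, _ = gen_sources(cfg)
        for s in range(2):
            a = set(np.flatnonzero(table.counts[s]))
            b = set(np.flatnonzero(table.counts[s + 1]))
            assert not (a & b)

    def test_richness_near_occupancy_expectation(self):
        cfg0 = ScenarioConfig(n_otus_pool=200, station_occupancy=0.5)
        expect = cfg0.n_otus_pool * cfg0.station_occupancy
        for seed in range(20):
            table, _ = gen_sources(ScenarioConfig(
                n_otus_pool=200, station_occupancy=0.5, seed=seed))
            rich = (table.counts > 0).sum(axis=1)
            assert (np.abs(rich - expect) <= 0.5 * expect).all()

    def test_depth_approximate(self):
        table, _ = gen_sources(ScenarioConfig(seed=1))
        totals = table.sample_totals()
        assert (np.abs(totals - 50_000) < 2_000).all()


class TestGenHosts:
    def test_no_phylo_signal_no_tree_structure(self):
        cfg = ScenarioConfig(n_stations=2, n_otus_pool=40,
                             n_cultures_per_station=6, phylo_signal=0.0, seed=2)
        tree = tree_to_distances(gen_tree(cfg.n_otus_pool, cfg.seed))
        sources, _ = gen_sources(cfg)
        _, aff = gen_hosts(cfg, tree, sources)
        # columns should be exchangeable: correlation of host-affinity columns
        # between sister and distant OTU pairs indistinguishable over seeds
        assert aff.shape == (12, 40)

    def test_identical_genotypes_identical_rows(self, monkeypatch):
        cfg = ScenarioConfig(n_stations=2, n_otus_pool=30,
                             n_cultures_per_station=2, seed=4)
        tree = tree_to_distances(gen_tree(cfg.n_otus_pool, cfg.seed))
        sources, _ = gen_sources(cfg)
        dup = np.array([[0.0, 0.0, 0.4, 0.4],
                        [0.0, 0.0, 0.4, 0.4],
                        [0.4, 0.4, 0.0, 0.2],
                        [0.4, 0.4, 0.2, 0.0]])
        monkeypatch.setattr(syn, "_p_distances_from_tree",
                            lambda n, rng, **kw: dup)
        _, aff = gen_hosts(cfg, tree, sources)
        np.testing.assert_array_equal(aff[0], aff[1])
        assert not np.array_equal(aff[2], aff[3])

    def test_sister_otus_more_correlated_with_signal(self):
        # Monte-Carlo: with phylo_signal > 0, affinity correlation between
        # the closest OTU pair exceeds that between the farthest pair
        closer_wins = 0
        for seed in range(50):
            cfg = ScenarioConfig(n_stations=3, n_otus_pool=25,
                                 n_cultures_per_station=10, phylo_signal=2.0,
                                 seed=seed)
            tree = tree_to_distances(gen_tree(cfg.n_otus_pool, cfg.seed))
            sources, _ = gen_sources(cfg)
            _, aff = gen_hosts(cfg, tree, sources)
            d = tree.dist.copy()
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            far = np.unravel_index(np.argmax(tree.dist), d.shape)
            c_near = np.corrcoef(aff[:, i], aff[:, j])[0, 1]
            c_far = np.corrcoef(aff[:, far[0]], aff[:, far[1]])[0, 1]
            closer_wins += c_near > c_far
        assert closer_wins >= 40


class TestCompetitionFactor:
    def test_rho_zero_is_one(self):
        np.testing.assert_array_equal(
            competition_factor(np.array([0.1, 2.0]), 0.0), [1.0, 1.0])

    def test_limit_proportional_to_distance(self):
        # rho -> inf: factor ~ d/rho, so the relative weight of the nearest
        # (sister) tip vanishes relative to distant tips
        d = np.array([0.01, 1.0])
        f = competition_factor(d, 1e6)
        assert f[0] / f[1] == pytest.approx(0.01, rel=1e-3)

    def test_monotone_in_distance(self):
        d = np.linspace(0, 5, 50)
        f = competition_factor(d, 1.0)
        assert (np.diff(f) > 0).all() and f[0] == 0.0


class TestGenCultures:
    def test_neutral_limit_detection_tracks_abundance(self):
        cfg = ScenarioConfig(n_stations=1, n_otus_pool=120,
                             n_cultures_per_station=200,
                             selection_strength=0.0, competition_strength=0.0,
                             seed=9)
        bundle = generate_scenario(cfg)
        present = np.flatnonzero(bundle.sources.counts[0])
        freq = (bundle.cultures.counts[:, present] > 0).mean(axis=0)
        ab = bundle.sources.counts[0, present]
        from scipy.stats import spearmanr

        rho, _ = spearmanr(ab, freq)
        assert rho > 0.8

    def test_strong_selection_targets_top_affinity(self):
        cfg = ScenarioConfig(n_stations=1, n_otus_pool=100,
                             station_occupancy=0.8, n_cultures_per_station=30,
                             richness_lambda=3.0, selection_strength=10.0,
                             otu_abundance_sigma=0.01,  # near-flat lottery
                             seed=13)
        bundle = generate_scenario(cfg)
        aff = bundle.truth.affinity
        present = np.flatnonzero(bundle.sources.counts[0])
        hits = total = 0
        for ci, culture in enumerate(bundle.cultures.sample_ids):
            cutoff = np.quantile(aff[ci, present], 0.9)
            for j in np.flatnonzero(bundle.cultures.counts[ci]):
                total += 1
                hits += aff[ci, j] >= cutoff
        assert hits / total >= 0.9

    def test_channels_partition_culture_otus(self, toy_bundle):
        for culture, pairs in toy_bundle.truth.channels.items():
            otus = {o for o, _ in pairs}
            row = toy_bundle.cultures.row(culture)
            observed = {toy_bundle.cultures.otu_ids[j]
                        for j in np.flatnonzero(row)}
            assert otus == observed
            assert {ch for _, ch in pairs} <= {"lottery", "selection"}

    def test_richness_bounds(self, toy_bundle):
        rich = (toy_bundle.cultures.counts > 0).sum(axis=1)
        assert rich.min() >= 1 and rich.max() <= 19

    def test_adding_cultures_preserves_earlier_draws(self):
        small = ScenarioConfig(n_stations=2, n_otus_pool=50,
                               n_cultures_per_station=3, seed=21)
        big = ScenarioConfig(n_stations=2, n_otus_pool=50,
                             n_cultures_per_station=5, seed=21)
        b_small = generate_scenario(small)
        b_big = generate_scenario(big)
        for culture in b_small.cultures.sample_ids:
            np.testing.assert_array_equal(
                b_small.cultures.row(culture), b_big.cultures.row(culture))


class TestFunctions:
    def test_clade_structure_and_nesting(self):
        nwk = gen_tree(40, seed=2)
        fmap = gen_functions(nwk, 12, seed=2)
        # nesting follows strict clade containment
        clades = {}
        for otu, funcs in fmap.assignments.items():
            for f in funcs:
                clades.setdefault(f, set()).add(otu)
        for narrow, broad in fmap.nesting:
            assert clades[narrow] < clades[broad]

    def test_deterministic(self):
        nwk = gen_tree(30, seed=7)
        a = gen_functions(nwk, 8, seed=7)
        b = gen_functions(nwk, 8, seed=7)
        assert a.assignments == b.assignments


class TestScenario:
    def test_bundle_validates(self, toy_bundle):
        report = validate_bundle(toy_bundle.cultures, toy_bundle.frame,
                                 toy_bundle.tree, toy_bundle.fmap)
        assert report.ok

    def test_neutral_truth_records_m(self, neutral_bundle, toy_bundle):
        assert neutral_bundle.truth.true_m_at_depth is not None
        cfg_sel = ScenarioConfig(n_stations=2, n_otus_pool=40,
                                 n_cultures_per_station=2,
                                 selection_strength=1.0, seed=1)
        assert generate_scenario(cfg_sel).truth.true_m_at_depth is None

    def test_deterministic_bundle(self):
        cfg = ScenarioConfig(n_stations=2, n_otus_pool=40,
                             n_cultures_per_station=3, seed=17)
        a = generate_scenario(cfg)
        b = generate_scenario(cfg)
        assert a.cultures == b.cultures
        assert a.tree_newick == b.tree_newick

    def test_write_bundle_round_trip(self, tmp_path):
        from assemblage.core_data import (read_count_table, read_function_map,
                                          read_sample_frame)

        cfg = ScenarioConfig(n_stations=2, n_otus_pool=30,
                             n_cultures_per_station=3, seed=8)
        bundle = generate_scenario(cfg)
        syn.write_bundle(bundle, tmp_path)
        assert read_count_table(tmp_path / "cultures.tsv") == bundle.cultures
        assert read_count_table(tmp_path / "sources.tsv") == bundle.sources
        frame = read_sample_frame(tmp_path / "samples.tsv")
        assert set(frame.sample_ids) == set(bundle.frame.sample_ids)
        fmap = read_function_map(tmp_path / "functions.tsv",
                                 tmp_path / "nesting.tsv")
        for otu in bundle.fmap.assignments:
            assert fmap.functions_of(otu) == bundle.fmap.functions_of(otu)
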