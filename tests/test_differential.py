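"""ANOVA filtering, standardization and complete-linkage clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from retroflux.differential import (anova_filter, standardize,
                                    hierarchical_cluster, heatmap_export,
                                    order_matrix)
from retroflux.errors import ConfigurationError, RetrofluxError

from conftest import build_matrix


def brute_force_anova(groups):
    """Independent sum-of-squares decomposition of the one-way F test."""
    from scipy.stats import f as fdist
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum((x - m) ** 2 for g, m in zip(groups, means) for x in g)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, fdist.sf(f, df1, df2)


class TestAnova:
    def test_constant_spot_is_null(self):
        m = build_matrix(np.full((1, 12), 5.0))
        res = anova_filter(m)
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert not res["significant"].iloc[0]

    def test_zero_within_group_variance_is_significant(self):
        values = np.repeat([[1.0, 2.0, 3.0, 4.0]], 3, axis=1)
        res = anova_filter(build_matrix(values))
        assert np.isinf(res["F"].iloc[0])
        assert res["p"].iloc[0] == 0.0
        assert res["significant"].iloc[0]

    def test_matches_brute_force_decomposition(self, rng):
        values = rng.normal(10, 2, size=(20, 12))
        res = anova_filter(build_matrix(values))
        for i, spot in enumerate(res.index):
            groups = [values[i, 0:3], values[i, 3:6], values[i, 6:9], values[i, 9:12]]
            f, p = brute_force_anova([list(g) for g in groups])
            assert res.loc[spot, "F"] == pytest.approx(f, abs=1e-10)
            assert res.loc[spot, "p"] == pytest.approx(p, abs=1e-10)
            assert res.loc[spot, "df1"] == 3
            assert res.loc[spot, "df2"] == 8

    def test_matches_scipy_f_oneway(self, rng):
        from scipy.stats import f_oneway
        values = rng.normal(0, 1, size=(10, 12)) ** 2 + 0.1
        res = anova_filter(build_matrix(values))
        for i, spot in enumerate(res.index):
            f, p = f_oneway(values[i, 0:3], values[i, 3:6], values[i, 6:9],
                            values[i, 9:12])
            assert res.loc[spot, "F"] == pytest.approx(f, rel=1e-10)
            assert res.loc[spot, "p"] == pytest.approx(p, rel=1e-8)

    def test_partial_missing_data_uses_available_replicates(self, rng):
        values = rng.normal(10, 1, size=(1, 12))
        m = build_matrix(values)
        m.data.iloc[0, 0] = np.nan  # drop one L replicate
        res = anova_filter(m)
        groups = [values[0, 1:3], values[0, 3:6], values[0, 6:9], values[0, 9:12]]
        f, p = brute_force_anova([list(g) for g in groups])
        assert res["F"].iloc[0] == pytest.approx(f, abs=1e-10)
        assert res["df2"].iloc[0] == 7

    def test_all_missing_spot_excluded(self):
        values = np.ones((2, 12))
        m = build_matrix(values)
        m.data.iloc[0, :] = np.nan
        res = anova_filter(m)
        assert len(res) == 1


class TestStandardize:
    def test_sample_sd_default_and_population_option(self):
        profile = pd.DataFrame([[1.0, 2.0, 3.0]], index=["s1"])
        z_sample = standardize(profile, ddof=1)
        np.testing.assert_allclose(z_sample.iloc[0], [-1.0, 0.0, 1.0])
        z_pop = standardize(profile, ddof=0)
        np.testing.assert_allclose(z_pop.iloc[0],
                                   [-1.224744871391589, 0.0, 1.224744871391589])

    def test_constant_profile_excluded(self, caplog):
        profiles = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                                index=["flat", "ok"])
        with caplog.at_level("INFO"):
            z = standardize(profiles)
        assert list(z.index) == ["ok"]

    def test_mean_zero_unit_variance(self, rng):
        profiles = pd.DataFrame(rng.normal(5, 3, size=(40, 12)))
        z = standardize(profiles)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.var(axis=1, ddof=1), 1.0, atol=1e-6)


def brute_force_complete_linkage(points):
    """Naive agglomeration over all pairwise maxima; returns merged member-sets."""
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(abs(points[i] - points[j])
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((d, merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


class TestHierarchicalCluster:
    def test_merge_sequence_matches_brute_force_on_1d_toy(self):
        points = [0.0, 1.1, 2.9, 6.0, 7.4, 9.9]
        z = pd.DataFrame({"x": points}, index=[f"p{i}" for i in range(6)])
        assignment = hierarchical_cluster(z, k=1)
        link = assignment.linkage
        # reconstruct member sets created by each scipy merge
        members = {i: frozenset([i]) for i in range(6)}
        scipy_merges = []
        for row_i, (a, b, height, _n) in enumerate(link):
            merged = members[int(a)] | members[int(b)]
            members[6 + row_i] = merged
            scipy_merges.append((height, merged))
        oracle = brute_force_complete_linkage(points)
        for (h1, m1), (h2, m2) in zip(scipy_merges, oracle):
            assert h1 == pytest.approx(h2)
            assert m1 == m2

    def test_k_equals_n_gives_singletons(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 4)))
        assignment = hierarchical_cluster(z, k=5)
        assert sorted(assignment.clusters) == [1, 2, 3, 4, 5]

    def test_two_planted_archetypes_fully_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        from retroflux.simulate import SimulationConfig, generate_experiment
        from retroflux.normalize import normalize_total
        cfg = SimulationConfig(n_spots=60, archetype_proportions=(0.5, 0.5, 0, 0, 0),
                               noise_sd=0.05, dominant_spot_share=0.0,
                               nd_dropout_rate=0.0, discordance_fraction=0.0, seed=2)
        exp = generate_experiment(cfg)
        z = standardize(normalize_total(exp.autoradiogram).data)
        assignment = hierarchical_cluster(z, k=2)
        truth = exp.ground_truth.loc[z.index, "archetype"]
        assert adjusted_rand_score(truth, assignment.clusters) == 1.0

    def test_k_larger_than_n_rejected(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(z, k=4)

    def test_cluster_labels_follow_leaf_order(self, rng):
        z = pd.DataFrame(rng.normal(size=(12, 6)))
        assignment = hierarchical_cluster(z, k=3)
        seen = []
        for leaf in assignment.leaf_order:
            c = assignment.clusters.iloc[leaf]
            if c not in seen:
                seen.append(c)
        assert seen == [1, 2, 3]


class TestHeatmapExport:
    def test_ordered_matrix_rows_match_dendrogram(self, tmp_path, rng):
        z = pd.DataFrame(rng.normal(size=(10, 12)),
                         index=[f"s{i}" for i in range(10)],
                         columns=build_matrix(np.ones((1, 12))).data.columns)
        assignment = hierarchical_cluster(z, k=3)
        out = heatmap_export(z, assignment, tmp_path / "h.png", tmp_path / "h.tsv")
        expected_rows = [z.index[i] for i in assignment.leaf_order]
        assert list(out.index) == expected_rows
        assert (tmp_path / "h.png").exists()

    def test_columns_grouped_by_condition(self, rng):
        cols = build_matrix(np.ones((1, 12))).data.columns
        shuffled = list(cols)
        rng.shuffle(shuffled)
        z = pd.DataFrame(rng.normal(size=(6, 12)), columns=shuffled)
        assignment = hierarchical_cluster(z, k=2)
        ordered = order_matrix(z, assignment)
        conds = [c.rsplit("_", 2)[0] for c in ordered.columns]
        assert conds == ["L"] * 3 + ["L→H"] * 3 + ["N"] * 3 + ["N→H"] * 3

    def test_empty_input_rejected(self, tmp_path):
        z = pd.DataFrame(np.empty((0, 12)),
                         columns=build_matrix(np.ones((1, 12))).data.columns)
        with pytest.raises(RetrofluxError):
            heatmap_export(z, None, tmp_path / "h.png", tmp_path / "h.tsv")

    def test_rerun_writes_identical_table(self, tmp_path, rng):
        z = pd.DataFrame(rng.normal(size=(8, 12)),
                         columns=build_matrix(np.ones((1, 12))).data.columns)
        assignment = hierarchical_cluster(z, k=2)
        heatmap_export(z, assignment, tmp_path / "a.png", tmp_path / "a.tsv")
        heatmap_export(z, assignment, tmp_path / "b.png", tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
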