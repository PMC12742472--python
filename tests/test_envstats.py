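"""Environmental statistics: standardization, clustering, exceedance,
abundance filtering, and Spearman screens."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

import karstclpp as k
from karstclpp.envstats import spearman_exact_p


def env_from_matrix(values: pd.DataFrame, **kwargs) -> k.EnvTable:
    return k.EnvTable(
        values=values,
        units=pd.Series("a.u.", index=values.index),
        censored=pd.DataFrame(False, index=values.index, columns=values.columns),
        **kwargs,
    )


class TestStandardize:
    def test_closed_form(self):
        env = env_from_matrix(pd.DataFrame({"A": [1.0], "B": [2.0], "C": [3.0]},
                                           index=["p"]))
        z = k.standardize(env)
        assert z["p"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_parameter_dropped_with_warning(self):
        env = env_from_matrix(pd.DataFrame(
            {"A": [1.0, 5.0], "B": [2.0, 5.0], "C": [3.0, 5.0]},
            index=["p", "q"],
        ))
        with pytest.warns(UserWarning, match="constant"):
            z = k.standardize(env)
        assert list(z.columns) == ["p"]

    def test_censored_half_limit_substitution(self):
        values = pd.DataFrame({"A": [0.40], "B": [1.0], "C": [2.0]}, index=["Cd"])
        censored = pd.DataFrame({"A": [True], "B": [False], "C": [False]},
                                index=["Cd"])
        env = k.EnvTable(values=values, censored=censored,
                         units=pd.Series("mg/kg", index=["Cd"]))
        sub = env.substituted("half_limit")
        assert sub.loc["Cd", "A"] == pytest.approx(0.20)
        z = k.standardize(env)  # standardization runs on substituted values
        assert z.shape == (3, 1)

    def test_too_few_samples_rejected(self):
        env = env_from_matrix(pd.DataFrame({"A": [1.0]}, index=["p"]))
        with pytest.raises(k.ValidationError, match=">= 2 samples"):
            k.standardize(env)


class TestEuclideanDistance:
    def test_metric_properties(self):
        mat = pd.DataFrame([[0, 0], [3, 4], [1, 1]], index=list("abc"))
        d = k.euclidean_distance(mat)
        assert d.loc["a", "b"] == pytest.approx(5.0)  # 3-4-5 triangle
        assert d.loc["a", "a"] == 0.0
        assert np.allclose(d, d.T)
        for x, y, z in itertools.permutations("abc"):
            assert d.loc[x, z] <= d.loc[x, y] + d.loc[y, z] + 1e-12

    def test_missing_values_named(self):
        mat = pd.DataFrame([[0.0, np.nan]], index=["a"], columns=["u", "v"])
        with pytest.raises(k.ValidationError, match="'a'.*'v'"):
            k.euclidean_distance(mat)


class TestCompleteLinkage:
    def test_three_points_on_a_line(self):
        # brute force over the 3 possible merge orders: {0,1} at height 1,
        # then with {10} at height 10
        mat = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        dendro = k.complete_linkage(k.euclidean_distance(mat))
        assert dendro.merges[0] == (("a",), ("b",), pytest.approx(1.0))
        assert dendro.merges[1][2] == pytest.approx(10.0)

    def test_identical_points_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        dendro = k.complete_linkage(k.euclidean_distance(mat))
        assert dendro.merges == [(("a",), ("b",), 0.0)]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(12, 4)),
                           index=[f"s{i}" for i in range(12)])
        dendro = k.complete_linkage(k.euclidean_distance(mat))
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.normal(size=(10, 5)),
                           index=[f"s{i:02d}" for i in range(10)])
        dendro = k.complete_linkage(k.euclidean_distance(mat))
        ref = linkage(pdist(mat.to_numpy()), method="complete")
        assert dendro.heights == pytest.approx(ref[:, 2].tolist())
        # same partitions at every cut level
        from scipy.cluster.hierarchy import fcluster
        for cut in (2, 3, 5):
            ours = {frozenset(g) for g in dendro.cut(cut)}
            labels = fcluster(ref, cut, criterion="maxclust")
            theirs = {
                frozenset(mat.index[labels == c]) for c in np.unique(labels)
            }
            assert ours == theirs

    def test_lexicographic_tie_break(self):
        # equilateral configuration: all pairs tie; (a, b) must merge first
        d = pd.DataFrame(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]],
            index=list("cab"), columns=list("cab"), dtype=float,
        )
        dendro = k.complete_linkage(d)
        assert dendro.merges[0][:2] == (("a",), ("b",))

    def test_newick_export_parses(self):
        mat = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        nwk = k.complete_linkage(k.euclidean_distance(mat)).to_newick()
        import io
        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]

    def test_last_singleton_identifies_outlier(self):
        mat = pd.DataFrame([[0.0], [1.0], [1.5], [50.0]],
                           index=["a", "b", "c", "z"])
        dendro = k.complete_linkage(k.euclidean_distance(mat))
        assert dendro.last_singleton() == "z"


class TestGeochemistryClustering:
    @pytest.mark.parametrize("policy", ["half_limit", "zero", "limit"])
    def test_sample_grouping_is_stable_across_policies(self, policy):
        env = k.load_sediment_geochemistry()
        dendro = k.cluster_samples(env, censored_policy=policy)
        assert dendro.last_singleton() == "S4"
        assert dendro.cut(3) == [
            ("S1", "S2", "S3"), ("S4",), ("S5", "S6", "S7", "S8"),
        ]

    def test_deterministic_across_runs(self):
        env = k.load_sediment_geochemistry()
        a = k.cluster_samples(env)
        b = k.cluster_samples(env)
        assert a.merges == b.merges


class TestExceedance:
    def test_strict_exceedance_and_censoring(self):
        values = pd.DataFrame({"A": [5.0], "B": [10.0], "C": [10.0]},
                              index=["m"])
        censored = pd.DataFrame({"A": [False], "B": [False], "C": [True]},
                                index=["m"])
        env = k.EnvTable(
            values=values, censored=censored,
            units=pd.Series("mg/kg", index=["m"]),
            regulatory_limit=pd.Series({"m": 10.0}),
        )
        # B equals the limit (not above); C is censored (never exceeds)
        assert k.exceedance_report(env) == {"m": []}

    def test_invariant_under_joint_rescaling(self):
        env = k.load_sediment_geochemistry()
        base = k.exceedance_report(env)
        scaled = k.EnvTable(
            values=env.values * 1000.0, units=env.units,
            censored=env.censored,
            regulatory_limit=env.regulatory_limit * 1000.0,
        )
        assert k.exceedance_report(scaled) == base

    def test_missing_limits_rejected(self):
        env = env_from_matrix(pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["p"]))
        with pytest.raises(k.ValidationError, match="limits"):
            k.exceedance_report(env)


class TestAbundanceFilter:
    def test_strict_percentage_cutoff(self):
        mat = pd.DataFrame(
            {"S1": [26.2, 3.0, 0.05, 3.01], "S2": [1.0, 2.0, 0.01, 0.5]},
            index=["dominant", "borderline", "rare", "justover"],
        )
        kept = k.abundance_filter(mat, min_percent=3.0)
        assert kept == ["dominant", "justover"]


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = np.arange(8, dtype=float)
        rho, _ = spearman_exact_p(x, x ** 3 + 2)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_exact_p(x, -np.sqrt(x + 1))
        assert rho == pytest.approx(-1.0)

    def test_exact_enumeration_oracle_n5(self):
        # rho = 1 - 6*sum d^2 / (n(n^2-1)) = 0.8; independent full
        # enumeration over all 5! rank orders gives the two-sided p
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = [1, 3, 2, 5, 4]

        def pearson(a, b):
            a = a - np.mean(a)
            b = np.asarray(b, dtype=float) - np.mean(b)
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        obs = pearson(x, y)
        oracle_p = np.mean([
            abs(pearson(x, perm)) >= abs(obs) - 1e-12
            for perm in itertools.permutations(y)
        ])
        assert oracle_p == pytest.approx(16 / 120)

        rho, p = spearman_exact_p(x, y)
        assert rho == pytest.approx(0.8)
        assert p == pytest.approx(oracle_p)

    def test_screen_t_approx_and_flags(self):
        samples = [f"S{i}" for i in range(1, 9)]
        taxa = pd.DataFrame(
            [np.arange(8.0), -np.arange(8.0), np.ones(8)],
            index=["up", "down", "flat"], columns=samples,
        )
        env = pd.DataFrame({s: [i] for i, s in enumerate(samples)},
                           index=["grad"]).astype(float)
        screen = k.spearman_screen(taxa, env, alpha=0.05)
        t = screen.table.set_index("taxon")
        assert t.loc["up", "rho"] == pytest.approx(1.0)
        assert t.loc["down", "rho"] == pytest.approx(-1.0)
        assert bool(t.loc["up", "significant"])
        assert bool(t.loc["flat", "undefined"])
        assert not bool(t.loc["flat", "significant"])

    def test_exact_mode_agrees_with_t_approx_ordering(self):
        rng = np.random.default_rng(7)
        taxa = pd.DataFrame(rng.normal(size=(2, 8)),
                            index=["t1", "t2"],
                            columns=[f"S{i}" for i in range(8)])
        env = pd.DataFrame(rng.normal(size=(2, 8)),
                           index=["p1", "p2"],
                           columns=[f"S{i}" for i in range(8)])
        t_scr = k.spearman_screen(taxa, env, p_mode="t_approx")
        e_scr = k.spearman_screen(taxa, env, p_mode="exact_permutation")
        assert t_scr.table["rho"].tolist() == pytest.approx(
            e_scr.table["rho"].tolist()
        )

    def test_too_few_shared_samples_rejected(self):
        taxa = pd.DataFrame([[1, 2, 3]], index=["t"], columns=["A", "B", "C"])
        env = pd.DataFrame([[1, 2, 3]], index=["p"], columns=["A", "B", "C"])
        with pytest.raises(k.ValidationError, match="4 shared"):
            k.spearman_screen(taxa, env)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rank_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho_xy, _ = spearman_exact_p(x, y)
        rho_rev, _ = spearman_exact_p(x, -y)
        assert rho_rev == pytest.approx(-rho_xy)
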