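"""Shannon H, Bray-Curtis, and the sequential-SS PERMANOVA against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from phyllonet.diversity import (
    DesignError,
    Permanova,
    bray_curtis,
    diversity_env_correlation,
    env_permanova_screen,
    shannon,
)


def one_way_ss_oracle(d: np.ndarray, groups: np.ndarray):
    """Brute-force one-way partitioning directly from pairwise distances.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum over groups of the same
    quantity within the group; SS_between = SS_total - SS_within.  This is an
    independent route: no Gower centring, no projections.
    """
    n = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = (d[iu] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        iu_g = np.triu_indices(len(idx), 1)
        ss_within += (sub[iu_g] ** 2).sum() / len(idx)
    return ss_total - ss_within, ss_within, ss_total


class TestShannon:
    def test_uniform_and_single_taxon(self):
        t = pd.DataFrame({"a": [5, 5, 5, 5], "b": [9, 0, 0, 0]})
        h = shannon(t)
        assert h["a"] == pytest.approx(np.log(4))
        assert h["b"] == 0.0

    def test_closed_form_and_scale_invariance(self):
        h = shannon(pd.DataFrame({"a": [4, 4, 8]}))
        assert h["a"] == pytest.approx(
            -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        )
        # H depends only on proportions, not depth
        assert shannon(pd.DataFrame({"a": [40, 40, 80]}))["a"] == pytest.approx(
            h["a"]
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon(pd.DataFrame({"a": [0, 0]}))


class TestBrayCurtis:
    def test_identical_disjoint_and_toy(self):
        t = pd.DataFrame(
            {"a": [1, 0], "b": [1, 0], "c": [0, 3]}, index=["x", "y"]
        )
        dm = bray_curtis(t, transform=False)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0  # disjoint supports

    def test_invariant_to_per_sample_scaling_after_ra(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(0, 50, (10, 4)), columns=list("abcd"))
        t2 = t.copy()
        t2["a"] *= 10  # scale one sample's raw counts
        assert np.allclose(bray_curtis(t).data, bray_curtis(t2).data, atol=1e-12)


class TestPermanova:
    @staticmethod
    def _points(rng, n=12, groups=2):
        X = rng.normal(size=(n, 3))
        labels = np.repeat([f"g{i}" for i in range(groups)], n // groups)
        ids = [f"s{i}" for i in range(n)]
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(X))
        data = pd.DataFrame({"group": labels}, index=ids)
        return DistanceMatrix(d, ids=ids), data

    def test_separated_groups_r2_near_one_p_at_floor(self, rng):
        X = np.vstack([np.zeros((6, 2)), np.full((6, 2), 50.0)])
        X += rng.normal(0, 1e-6, X.shape)
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(12)]
        dm = DistanceMatrix(squareform(pdist(X)), ids=ids)
        data = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6}, index=ids)
        res = Permanova(dm, data, ["group"]).fit(n_permutations=199, seed=1)
        assert res["group"]["R2"] > 0.999
        assert res["group"]["Pr(>F)"] == pytest.approx(1 / 200, abs=0.02)

    def test_partition_matches_brute_force_oracle(self, rng):
        dm, data = self._points(rng)
        res = Permanova(dm, data, ["group"]).fit(n_permutations=99, seed=0)
        ss_b, ss_w, ss_t = one_way_ss_oracle(dm.data, data["group"].to_numpy())
        assert res["group"]["SumOfSqs"] == pytest.approx(ss_b, rel=1e-9)
        assert res["Residual"]["SumOfSqs"] == pytest.approx(ss_w, rel=1e-9)
        assert res["Total"]["SumOfSqs"] == pytest.approx(ss_t, rel=1e-9)

    def test_pseudo_f_matches_skbio(self, rng):
        dm, data = self._points(rng)
        res = Permanova(dm, data, ["group"]).fit(n_permutations=99, seed=0)
        sk = skbio_permanova(dm, data, column="group", permutations=99)
        assert res["group"]["F"] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_r2_sums_to_one_and_level_relabeling_invariance(self, rng):
        dm, data = self._points(rng, n=12, groups=3)
        data["other"] = list("xyz") * 4
        res = Permanova(dm, data, ["group", "other"]).fit(99, seed=2)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
        relabeled = data.replace({"group": {"g0": "zz", "g1": "aa", "g2": "mm"}})
        res2 = Permanova(dm, relabeled, ["group", "other"]).fit(99, seed=2)
        assert np.allclose(
            res.table[["df", "SumOfSqs", "R2"]].to_numpy(),
            res2.table[["df", "SumOfSqs", "R2"]].to_numpy(),
        )

    def test_confounded_term_named_in_error(self, rng):
        dm, data = self._points(rng)
        data["dup"] = data["group"]  # perfectly confounded
        with pytest.raises(DesignError, match="dup"):
            Permanova(dm, data, ["group", "dup"]).fit(9)

    def test_interaction_term_accepted(self, rng):
        dm, data = self._points(rng, n=12, groups=2)
        data["season"] = ["f", "s"] * 6
        res = Permanova(dm, data, ["group", "season", "group:season"]).fit(49, seed=0)
        assert res["group:season"]["df"] == 1

    def test_exact_enumeration_matches_direct_computation(self, rng):
        # 5 samples, 2 groups: enumerate all 5! relabelings by brute force
        # with the distance-based oracle, compare to the exact fit
        from itertools import permutations as iperm
        from scipy.spatial.distance import pdist, squareform

        X = rng.normal(size=(5, 2))
        d = squareform(pdist(X))
        groups = np.array(["a", "a", "b", "b", "b"])
        ids = [f"s{i}" for i in range(5)]
        res = Permanova(
            DistanceMatrix(d, ids=ids),
            pd.DataFrame({"g": groups}, index=ids),
            ["g"],
        ).fit(exact=True)

        def f_stat(labels):
            ss_b, ss_w, _ = one_way_ss_oracle(d, np.asarray(labels))
            return (ss_b / 1) / (ss_w / 3)

        f_obs = f_stat(groups)
        fs = [f_stat(np.array(groups)[list(p)]) for p in iperm(range(5))]
        p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res["g"]["F"] == pytest.approx(f_obs, rel=1e-9)
        assert res["g"]["Pr(>F)"] == pytest.approx(p_oracle, abs=1e-12)

    def test_pvalues_never_zero(self, rng):
        dm, data = self._points(rng)
        res = Permanova(dm, data, ["group"]).fit(n_permutations=9, seed=3)
        assert res["group"]["Pr(>F)"] >= 1 / 10


class TestEnvScreen:
    def test_planted_factor_has_largest_r2(self, rng):
        # community distances driven by factor f1; f2, f3 pure noise
        n = 30
        f1 = rng.normal(size=n)
        X = np.column_stack([f1, 0.2 * rng.normal(size=n)])
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(X)), ids=ids)
        env = pd.DataFrame(
            {"f1": f1, "f2": rng.normal(size=n), "f3": rng.normal(size=n)},
            index=ids,
        )
        screen = env_permanova_screen(dm, env, n_permutations=99, seed=0)
        assert screen["R2"].idxmax() == "f1"
        assert ((screen["R2"] > 0) & (screen["R2"] < 1)).all()

    def test_constant_factor_rejected(self, rng):
        n = 8
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(rng.normal(size=(n, 2)))), ids=ids)
        env = pd.DataFrame({"flat": np.ones(n)}, index=ids)
        with pytest.raises(DesignError, match="constant"):
            env_permanova_screen(dm, env, n_permutations=9)


class TestDiversityEnvCorrelation:
    def test_monotone_and_reversed(self):
        h = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        env = pd.DataFrame(
            {"up": [10, 20, 30, 40], "down": [8, 6, 4, 2]}, index=list("abcd")
        )
        out = diversity_env_correlation(h, env)
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_ties_match_midrank_formula(self):
        # hand midranks: x=[1,2,2,3] -> [1, 2.5, 2.5, 4]; y=[1,1,2,3] ->
        # [1.5, 1.5, 3, 4]; Spearman rho = Pearson r of the midranks
        x = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        env = pd.DataFrame({"y": [1.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
        rx, ry = rankdata(x), rankdata(env["y"])
        assert list(rx) == [1, 2.5, 2.5, 4] and list(ry) == [1.5, 1.5, 3, 4]
        expected = np.corrcoef(rx, ry)[0, 1]
        out = diversity_env_correlation(x, env)
        assert out.loc["y", "rho"] == pytest.approx(expected, abs=1e-12)


class TestStrataPermutation:
    def test_within_strata_permutations_respect_blocks(self, rng):
        # a factor perfectly aligned with strata never varies under
        # within-block permutation, so its p-value is maximal
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        n = 12
        ids = [f"s{i}" for i in range(n)]
        d = squareform(pdist(rng.normal(size=(n, 3))))
        data = pd.DataFrame(
            {"group": ["a"] * 6 + ["b"] * 6, "block": ["a"] * 6 + ["b"] * 6},
            index=ids,
        )
        res = Permanova(DistanceMatrix(d, ids=ids), data, ["group"]).fit(
            n_permutations=99, seed=0, strata="block"
        )
        assert res["group"]["Pr(>F)"] == 1.0
        with pytest.raises(DesignError, match="strata"):
            Permanova(DistanceMatrix(d, ids=ids), data, ["group"]).fit(
                n_permutations=9, strata="missing"
            )
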