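"""Comparison statistics: enumeration oracles, invariances, grid shape."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phytocompare.compare import (
    fit_loglog,
    mann_whitney_u,
    normalization_grid,
    presence_overlap,
    rare_taxa,
    replicate_cv,
    spearman_rho,
    top_genera_union,
    volume_saturation,
)


# ---------------------------------------------------------------------------
# Mann-Whitney

def brute_force_mw(x, y):
    """Enumerate every assignment of the pooled values to the two groups."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    n = len(pooled)

    def u_of(xs, ys):
        xs, ys = np.asarray(xs), np.asarray(ys)
        return (xs[:, None] > ys[None, :]).sum() + 0.5 * (xs[:, None] == ys[None, :]).sum()

    u_obs = u_of(x, y)
    us = [u_of(pooled[list(idx)], np.delete(pooled, list(idx)))
          for idx in itertools.combinations(range(n), nx)]
    us = np.asarray(us, dtype=float)
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


class TestMannWhitney:
    def test_separated_pairs(self):
        u, p = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_interleaved_pairs_symmetric(self):
        u, p = mann_whitney_u([1, 4], [2, 3], mode="exact")
        assert u == 2  # = nx*ny/2
        assert p == pytest.approx(1.0)

    def test_single_tied_pair(self):
        u, p = mann_whitney_u([5], [5])
        assert u == 0.5
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_u([1, 2], [2, 3], mode="exact")

    def test_exact_equals_enumeration_exhaustively(self):
        # every tie-free partition shape with n_x + n_y <= 8
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            values = rng.permutation(np.arange(1, n + 1)).astype(float)
            for nx in range(1, n):
                for idx in itertools.combinations(range(n), nx):
                    x = values[list(idx)]
                    y = np.delete(values, list(idx))
                    u_impl, p_impl = mann_whitney_u(x, y, mode="exact")
                    u_ref, p_ref = brute_force_mw(x, y)
                    assert u_impl == u_ref
                    assert p_impl == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            u, p = mann_whitney_u(x, y, mode="exact")
            ref = stats.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=18).astype(float)
            u, p = mann_whitney_u(x, y, mode="approx")
            ref = stats.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Replicate CV

class TestReplicateCV:
    def test_constant_replicates_cv_zero(self):
        df = pd.DataFrame({"Dino": [0.2, 0.2, 0.2], "Crypto": [0.8, 0.8, 0.8]})
        cv, excluded = replicate_cv(df)
        assert cv["Dino"] == pytest.approx(0.0, abs=1e-12) and not excluded

    def test_direct_arithmetic(self):
        cv, _ = replicate_cv(pd.DataFrame({"c": [1.0, 2.0, 3.0]}))
        assert cv["c"] == pytest.approx(0.5)

    def test_zero_mean_class_excluded(self):
        df = pd.DataFrame({"absent": [0.0, 0.0], "there": [0.5, 0.7]})
        cv, excluded = replicate_cv(df)
        assert excluded == ["absent"] and "absent" not in cv

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            replicate_cv(pd.DataFrame({"c": [1.0]}))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 1000), st.lists(st.floats(0.1, 10), min_size=2, max_size=6))
    def test_scale_invariance(self, k, values):
        df = pd.DataFrame({"c": values})
        cv1, _ = replicate_cv(df)
        cv2, _ = replicate_cv(df * k)
        assert cv2["c"] == pytest.approx(cv1["c"], rel=1e-9)


# ---------------------------------------------------------------------------
# Presence overlap / rarity / top genera

class TestPresenceOverlap:
    def _grouping(self, index, basins):
        return pd.Series(basins, index=index)

    def test_identical_matrices(self):
        a = pd.DataFrame([[True, False]] * 4, columns=["g1", "g2"],
                         index=list("wxyz"))
        table, totals = presence_overlap(a, a.copy(), self._grouping(a.index, ["B"] * 4))
        assert totals["a_only"] == 0 and totals["b_only"] == 0
        assert totals["overlap_share"] == 1.0

    def test_disjoint_matrices(self):
        idx = [f"s{i}" for i in range(7)]
        a = pd.DataFrame(True, index=idx, columns=["g"])
        b = pd.DataFrame(False, index=idx, columns=["g"])
        table, totals = presence_overlap(a, b, self._grouping(idx, ["B"] * 7))
        assert totals == {"both": 0, "a_only": 7, "b_only": 0, "neither": 0,
                          "n_union_observations": 7,
                          "overlap_share": 0.0}

    def test_counts_match_brute_force(self, rng):
        idx = [f"s{i}" for i in range(20)]
        cols = [f"g{j}" for j in range(5)]
        a = pd.DataFrame(rng.random((20, 5)) < 0.5, index=idx, columns=cols)
        b = pd.DataFrame(rng.random((20, 5)) < 0.5, index=idx, columns=cols)
        basins = self._grouping(idx, [f"B{i % 3}" for i in range(20)])
        table, _ = presence_overlap(a, b, basins)
        for _, row in table.iterrows():
            samples = [s for s in idx if basins[s] == row["basin"]]
            both = sum(a.loc[s, row["genus"]] and b.loc[s, row["genus"]] for s in samples)
            assert row["both"] == both
            assert row["both"] + row["a_only"] + row["b_only"] + row["neither"] == len(samples)

    def test_shape_mismatch_rejected(self):
        a = pd.DataFrame([[True]], columns=["g"], index=["s"])
        b = pd.DataFrame([[True]], columns=["h"], index=["s"])
        with pytest.raises(ValueError):
            presence_overlap(a, b, pd.Series({"s": "B"}))


class TestRareTaxa:
    def test_quantifier_over_all_samples(self):
        m = pd.DataFrame({"loud_once": [2e-4, 0.0], "quiet": [5e-5, 5e-5]})
        res = rare_taxa(m)
        assert "loud_once" not in res.rare_everywhere
        assert "quiet" in res.rare_everywhere

    def test_absent_taxon_rare_and_flagged(self):
        m = pd.DataFrame({"ghost": [0.0, 0.0], "there": [0.5, 0.5]})
        res = rare_taxa(m)
        assert "ghost" in res.rare_everywhere and "ghost" in res.never_observed

    def test_matches_brute_force_scan(self, rng):
        m = pd.DataFrame(rng.random((5, 4)) * 3e-4, columns=list("abcd"))
        res = rare_taxa(m)
        expected = {c for c in m.columns if all(m[c] < 1e-4)}
        assert set(res.rare_everywhere) == expected
        expected_cum = {c for c in m.columns if m[c].sum() < 1e-4}
        assert set(res.rare_cumulative) == expected_cum


class TestTopGeneraUnion:
    def _matrix(self, means, n_samples=4):
        return pd.DataFrame(np.tile(list(means.values()), (n_samples, 1)),
                            columns=list(means))

    def test_identical_matrices_union_is_k(self):
        m = self._matrix({f"g{i}": 20 - i for i in range(20)})
        res = top_genera_union(m, m, k=15)
        assert len(res.union) == 15

    def test_disjoint_top_lists(self):
        a = self._matrix({f"a{i}": 30 - i for i in range(15)} | {f"b{i}": 0.0 for i in range(15)})
        b = self._matrix({f"a{i}": 0.0 for i in range(15)} | {f"b{i}": 30 - i for i in range(15)})
        res = top_genera_union(a, b, k=15)
        assert len(res.union) == 30

    def test_partial_overlap_counts(self):
        shared = {f"s{i}": 50 - i for i in range(7)}
        a = self._matrix(shared | {f"a{i}": 20 - i for i in range(8)})
        b = self._matrix(shared | {f"b{i}": 20 - i for i in range(8)})
        res = top_genera_union(a, b, k=15)
        assert len(res.union) == 23
        assert res.membership["in_a"].sum() == 15

    def test_ties_broken_lexicographically(self):
        m = self._matrix({"zeta": 1.0, "alpha": 1.0, "mid": 2.0})
        res = top_genera_union(m, m, k=2)
        assert res.top_a == ("mid", "alpha")


# ---------------------------------------------------------------------------
# Volume saturation

class TestVolumeSaturation:
    def _totals(self, richness_by_group):
        rows = []
        vols = []
        for vol, values in richness_by_group.items():
            for i, r in enumerate(values):
                rows.append({"total_reads": 1000, "phyto_reads": 800,
                             "phyto_richness": r})
                vols.append(vol)
        idx = [f"s{i}" for i in range(len(rows))]
        return pd.Series(vols, index=idx), pd.DataFrame(rows, index=idx)

    def test_identical_multisets_p_one(self):
        vols, totals = self._totals({0.2: [5, 6, 7, 8, 9], 0.5: [5, 6, 7, 8, 9]})
        _, pairs = volume_saturation(vols, totals)
        row = pairs.iloc[0]
        assert row["U"] == pytest.approx(12.5)
        assert row["p"] == pytest.approx(1.0)

    def test_strictly_separated_groups(self):
        vols, totals = self._totals({0.01: [1, 2, 3, 4, 5], 0.2: [6, 7, 8, 9, 10]})
        _, pairs = volume_saturation(vols, totals)
        row = pairs.iloc[0]
        assert row["U"] == 0.0
        assert row["p"] == pytest.approx(2 / 252)

    def test_single_group_rejected(self):
        vols, totals = self._totals({0.2: [5, 6, 7]})
        with pytest.raises(ValueError):
            volume_saturation(vols, totals)

    def test_small_group_excluded(self):
        vols, totals = self._totals({0.2: [5, 6, 7], 0.5: [5, 6, 7], 0.1: [4]})
        summary, pairs = volume_saturation(vols, totals)
        assert 0.1 not in set(summary["volume"])
        assert len(pairs) == 1


# ---------------------------------------------------------------------------
# Regression / Spearman

class TestFitLoglog:
    def test_exact_log_linearity(self):
        x = np.logspace(0, 4, 20)
        res = fit_loglog(x, 10 * x)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_drop_policy_counts_exclusions(self):
        x = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        res = fit_loglog(x, np.ones(5))
        assert res.n == 4 and res.n_excluded == 1

    def test_pseudocount_policy_keeps_n(self):
        x = np.array([0.0, 1.0, 10.0, 100.0])
        res = fit_loglog(x, np.array([1.0, 2.0, 3.0, 4.0]), zero_policy="pseudocount")
        assert res.n == 4 and res.n_excluded == 0

    def test_r2_matches_brute_force(self, rng):
        x = rng.lognormal(0, 1, 50)
        y = rng.lognormal(0, 1, 50) * x
        res = fit_loglog(x, y)
        lx, ly = np.log10(x), np.log10(y)
        beta, alpha = np.polyfit(lx, ly, 1)
        sse = ((ly - (alpha + beta * lx)) ** 2).sum()
        sst = ((ly - ly.mean()) ** 2).sum()
        assert res.r2 == pytest.approx(1 - sse / sst, rel=1e-9)
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * 49 / 48, rel=1e-9)

    def test_too_few_points_not_fitted(self):
        res = fit_loglog([1.0, 2.0], [1.0, 2.0])
        assert not res.fitted and math.isnan(res.slope)

    def test_scale_invariance_of_r2(self, rng):
        x = rng.lognormal(0, 1, 30)
        y = x ** 1.2 * rng.lognormal(0, 0.2, 30)
        r2 = fit_loglog(x, y).r2
        assert fit_loglog(x * 137.0, y).r2 == pytest.approx(r2, rel=1e-9)
        assert fit_loglog(x, y * 0.003).r2 == pytest.approx(r2, rel=1e-9)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 300, 4000]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3, 4], [5, 4, 3, 1]) == pytest.approx(-1.0)

    def test_midrank_value_by_hand(self):
        # ranks of x=(1,1,2) are (1.5,1.5,3); Pearson with (1,2,3) = 1.5/sqrt(3)
        rho = spearman_rho([1, 1, 2], [1, 2, 3])
        assert rho == pytest.approx(1.5 / math.sqrt(3), rel=1e-12)

    def test_constant_vector_flagged_nan(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho, rel=1e-12)
        assert spearman_rho(x, y ** 3) == pytest.approx(rho, rel=1e-12)


# ---------------------------------------------------------------------------
# Normalization grid

class TestNormalizationGrid:
    @pytest.fixture
    def harmonized_inputs(self):
        from phytocompare.simulate import SimulationConfig, simulate_dataset
        from phytocompare.taxonomy import apply_centrales_rule, lump_diatom_classes

        cfg = SimulationConfig(stations_per_basin=1, samples_per_station=2,
                               taxa_per_class=2, depth=20_000)
        truth, asv, meta, tax, micro = simulate_dataset(cfg, 11)
        tax = apply_centrales_rule(lump_diatom_classes(tax))
        micro = apply_centrales_rule(lump_diatom_classes(micro))
        return asv, micro, meta, tax

    def test_grid_size(self, harmonized_inputs):
        asv, micro, meta, tax = harmonized_inputs
        grid = normalization_grid(asv, micro, meta, tax)
        n_basins = meta["basin"].nunique()
        expected = 4 * 3 * 2 * (1 + n_basins)
        assert len(grid) == expected

    def test_identical_inputs_give_perfect_fit(self, harmonized_inputs):
        # feed the microscopy cell matrix as both methods: R^2 = 1
        asv, micro, meta, tax = harmonized_inputs
        from phytocompare.normalize import microscopy_matrix
        cells = microscopy_matrix(micro, "cells_per_liter", "class").data
        x = cells.to_numpy().ravel()
        res = fit_loglog(x, x)
        assert res.r2 == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)
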