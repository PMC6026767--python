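"""Permutation null, candidate rules, local FDR and the fixation scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from poolsweep import scan
from poolsweep.scan import (
    call_candidates,
    exhaustive_pvalues,
    fixation_scan,
    local_fdr,
    observed_difference,
    permutation_test,
)


def _track(d_values, chrom="lg1", width=10_000):
    starts = np.arange(len(d_values)) * width
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + width,
        "group": "g", "S": 1, "pi": 0.0, "pi_per_bp": 0.0,
        "D": np.asarray(d_values, dtype=float), "n_sites": 1,
    })


def brute_force_joint_pvalues(d_a, d_b):
    """Oracle: enumerate every (perm_A, perm_B) pair explicitly."""
    m = len(d_a)
    delta = np.asarray(d_a) - np.asarray(d_b)
    counts = np.zeros(m)
    total = 0
    for pa in itertools.permutations(d_a):
        for pb in itertools.permutations(d_b):
            total += 1
            for i in range(m):
                if pa[i] - pb[i] >= delta[i] - 1e-12:
                    counts[i] += 1
    return counts / total


class TestObservedDifference:
    def test_identical_tracks_zero(self):
        t = _track([0.3, -1.2, 0.8])
        out = observed_difference(t, t)
        assert (out["delta"] == 0).all()

    def test_wild_minus_orchard_table_value(self):
        # one window with wild D 1.23 and orchard D -1.65 -> delta 2.88
        wild = _track([1.23, 0.0])
        orchard = _track([-1.65, 0.0])
        out = observed_difference(wild, orchard)
        assert out.loc[0, "delta"] == pytest.approx(2.88)

    def test_missing_propagates(self):
        out = observed_difference(_track([np.nan, 1.0]), _track([0.5, np.nan]))
        assert out["delta"].isna().tolist() == [True, True]

    def test_mismatched_grids_rejected_with_location(self):
        a = _track([1.0, 2.0])
        b = _track([1.0, 2.0])
        b.loc[1, "start"] = 99_999
        with pytest.raises(ValueError, match="row 1"):
            observed_difference(a, b)


class TestPermutationTest:
    def test_constant_tracks_give_p_one(self):
        res = permutation_test(np.array([1.0] * 5), np.array([0.2] * 5),
                               n_perm=200, seed=0)
        assert (res.table["p_value"] == 1.0).all()

    def test_three_window_exhaustive_example(self):
        """Orchard (0, 0, -3) vs wild (0, 0, 0): window 3 has raw p = 2/6."""
        p = exhaustive_pvalues(np.zeros(3), np.array([0.0, 0.0, -3.0]))
        assert p[2] == pytest.approx(2 / 6)

    @pytest.mark.parametrize("m", [3, 4])
    def test_marginal_reduction_equals_joint_enumeration(self, m):
        rng = np.random.default_rng(m)
        d_a = rng.normal(size=m)
        d_b = rng.normal(size=m)
        np.testing.assert_allclose(
            exhaustive_pvalues(d_a, d_b), brute_force_joint_pvalues(d_a, d_b),
            atol=1e-12)

    def test_auto_exhaustive_for_tiny_tracks(self):
        res = permutation_test(np.array([1.0, 2.0, 0.5]),
                               np.array([0.1, 0.0, 0.2]), n_perm=1000, seed=1)
        assert res.mode == "exhaustive"
        np.testing.assert_allclose(
            res.table["p_value"].to_numpy(),
            exhaustive_pvalues(np.array([1.0, 2.0, 0.5]), np.array([0.1, 0.0, 0.2])))

    def test_monte_carlo_close_to_exhaustive(self):
        """m = 5, 6: sampled p within 3 binomial SEs of the exact value."""
        rng = np.random.default_rng(10)
        n_perm = 5000
        for m in (5, 6):
            d_a = rng.normal(size=m)
            d_b = rng.normal(size=m)
            exact = exhaustive_pvalues(d_a, d_b)
            res = permutation_test(d_a, d_b, n_perm=n_perm, seed=11)
            mc = res.table["exceed_count"].to_numpy() / n_perm
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert np.all(np.abs(mc - exact) <= 3 * se + 1e-12)

    def test_pooled_null_mode_runs_and_bounds(self):
        rng = np.random.default_rng(2)
        res = permutation_test(rng.normal(size=30), rng.normal(size=30),
                               n_perm=200, seed=3, mode="pooled-null")
        p = res.table["p_value"]
        assert ((p > 0) & (p <= 1)).all()

    def test_missing_windows_excluded(self):
        d_a = np.array([np.nan, 1.0, 2.0, 0.0, 1.5])
        d_b = np.array([0.0, 0.5, np.nan, 0.1, 0.4])
        res = permutation_test(d_a, d_b, n_perm=100, seed=4)
        assert res.table["p_value"].isna().tolist() == [True, False, True, False, False]

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones(3), np.zeros(3), n_perm=0)


class TestCallCandidates:
    def _table(self, pvals):
        t = _track(np.zeros(len(pvals)))
        t = t[["chrom", "start", "end"]].copy()
        t["p_value"] = pvals
        return t

    def test_both_rules_fire(self):
        calls = call_candidates(self._table([0.5, 0.005, 0.008, 0.2, 0.0009, 0.5]))
        assert len(calls) == 2
        run = next(c for c in calls if c.rule == "consecutive_p01")
        single = next(c for c in calls if c.rule == "single_p001")
        assert (run.start, run.end, run.run_length) == (10_000, 30_000, 2)
        assert (single.start, single.end) == (40_000, 50_000)

    def test_no_calls_when_flat(self):
        assert call_candidates(self._table([0.5] * 6)) == []

    def test_run_of_three_merges_to_30kb(self):
        calls = call_candidates(self._table([0.5, 0.004, 0.004, 0.004, 0.5]))
        assert len(calls) == 1
        assert calls[0].end - calls[0].start == 30_000
        assert calls[0].run_length == 3

    def test_calls_disjoint_after_merging(self):
        rng = np.random.default_rng(0)
        pvals = rng.uniform(size=300)
        pvals[rng.choice(300, 40, replace=False)] = 0.001
        calls = call_candidates(self._table(pvals))
        calls = sorted(calls, key=lambda c: c.start)
        for a, b in zip(calls, calls[1:]):
            assert a.end <= b.start

    def test_chromosome_boundary_breaks_runs(self):
        t = pd.concat([
            self._table([0.004]).assign(chrom="lg1"),
            self._table([0.004]).assign(chrom="lg2"),
        ], ignore_index=True)
        calls = call_candidates(t)
        assert calls == []  # two isolated p=0.004 windows on different chroms


class TestLocalFdr:
    def test_all_large_p_gives_pi0_one(self):
        rng = np.random.default_rng(1)
        res = local_fdr(rng.uniform(0.51, 1.0, size=200))
        assert res.pi0_hat == 1.0

    def test_half_above_half_point_gives_pi0_one(self):
        p = np.concatenate([np.linspace(0.01, 0.49, 100),
                            np.linspace(0.51, 0.99, 100)])
        assert local_fdr(p).pi0_hat == 1.0

    def test_mixture_pi0_recovery(self):
        """90% uniform + 10% Beta(0.1, 1): pi0_hat lands in [0.8, 1.0]."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = np.concatenate([rng.uniform(size=1800), rng.beta(0.1, 1.0, size=200)])
            res = local_fdr(p)
            assert 0.8 <= res.pi0_hat <= 1.0

    def test_lfdr_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.beta(0.2, 1, 300), rng.uniform(size=700)])
        res = local_fdr(p)
        assert np.all((res.lfdr >= 0) & (res.lfdr <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(res.lfdr[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            local_fdr(np.array([0.5] * 60 + [1.2]))

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError, match="50"):
            local_fdr(np.array([0.5] * 10))


def _gene_table(freqs, chrom="lg1"):
    n = len(freqs)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": chrom,
        "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 500,
        "annotated": True,
        "group": "x",
        "mean_major_freq": freqs,
        "n_snps": 5,
    })


class TestFixationScan:
    def test_identical_tables_no_outliers(self):
        g = _gene_table(np.full(100, 0.7))
        out = fixation_scan(g, g)
        assert all(not o.flagged for o in out)
        assert all(o.z_sd == 0.0 for o in out)

    def test_constructed_single_outlier(self):
        """100 intervals, one delta = 0.35, rest 0: exactly that one flags at 3 SD."""
        base = np.full(1000, 0.6)
        shifted = base.copy()
        shifted[120:130] += 0.35  # genes of interval 12
        a = _gene_table(shifted)
        b = _gene_table(base)
        out = fixation_scan(a, b, sd_multiplier=3.0)
        assert len(out) == 100
        flagged = [i for i, o in enumerate(out) if o.flagged]
        assert flagged == [12]
        # direct arithmetic on the constructed delta vector
        deltas = np.zeros(100)
        deltas[12] = 0.35
        assert out[12].delta == pytest.approx(0.35)
        assert out[12].z_sd == pytest.approx(
            (0.35 - deltas.mean()) / deltas.std())

    def test_flag_threshold_strictly_above_multiplier(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.6, 0.8, size=500)
        a = _gene_table(base + rng.normal(0, 0.005, size=500))
        b = _gene_table(base)
        out = fixation_scan(a, b, sd_multiplier=3.0)
        deltas = np.array([o.delta for o in out])
        mu, sd = deltas.mean(), deltas.std()
        for o in out:
            assert o.flagged == (o.delta > mu + 3.0 * sd)

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(0.55, 0.95, size=300)
        other = rng.uniform(0.55, 0.95, size=300)
        a, b = _gene_table(base), _gene_table(other)
        out1 = fixation_scan(a, b)
        a2 = _gene_table(np.clip(base + 0.02, None, None))
        b2 = _gene_table(other + 0.02)
        out2 = fixation_scan(a2, b2)
        assert [o.flagged for o in out1] == [o.flagged for o in out2]

    def test_unannotated_and_snpless_genes_excluded(self):
        a = _gene_table(np.full(25, 0.7))
        b = _gene_table(np.full(25, 0.7))
        a.loc[0, "annotated"] = False
        b.loc[0, "annotated"] = False
        a.loc[1, "n_snps"] = 0
        out = fixation_scan(a, b, interval_size=10)
        # 23 usable genes -> 2 full intervals, 3 trailing dropped
        assert len(out) == 2

    def test_regional_default_multiplier_is_two(self):
        base = np.full(200, 0.7)
        shifted = base.copy()
        shifted[100:110] += 0.05
        out3 = fixation_scan(_gene_table(shifted), _gene_table(base),
                             contrast="domestication")
        out2 = fixation_scan(_gene_table(shifted), _gene_table(base),
                             contrast="regional")
        # same deltas, looser regional threshold flags at least as many
        assert sum(o.flagged for o in out2) >= sum(o.flagged for o in out3)
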