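"""Stochastic resection simulator: closed forms, symmetry, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from resectra import (SimParams, foci_loss_times, make_genome, sample_onsets,
                      simulate_cell, simulate_machine, simulate_population,
                      survival_profile)


def forced_onset(params: SimParams) -> SimParams:
    """Effectively immediate cutting in every cell."""
    return replace(params, onset_rate=1e9)


class TestOnsets:
    def test_zero_rate_never_cuts(self):
        onsets = sample_onsets(1000, 0.0, 3600.0, seed=1)
        assert np.all(np.isinf(onsets))

    def test_cut_fraction_matches_closed_form(self):
        n, lam, t = 10_000, 0.4, 3600.0
        onsets = sample_onsets(n, lam, t, seed=2)
        frac = np.mean(onsets <= t)
        p = 1.0 - np.exp(-lam)  # 0.3297
        # 99% binomial envelope
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 2.576 * se

    def test_fixed_seed_bit_identical(self):
        a = sample_onsets(500, 0.4, 3600.0, seed=3)
        b = sample_onsets(500, 0.4, 3600.0, seed=3)
        assert np.array_equal(a, b)


class TestMachine:
    def test_pure_fast_extent(self):
        p = SimParams(k_fast=400.0, p_chi=0.0, k_slow=0.0)
        traj = simulate_machine([], p, 60.0, np.random.default_rng(0))
        assert traj.extent(60.0) == pytest.approx(24_000.0)

    def test_piecewise_extent_after_commitment(self):
        p = SimParams(k_fast=400.0, p_chi=1.0, k_slow=100.0)
        traj = simulate_machine([1000.0], p, 10.0, np.random.default_rng(0))
        assert traj.commit_distance == pytest.approx(1000.0)
        assert traj.extent(10.0) == pytest.approx(1000.0 + 7.5 * 100.0)

    def test_extent_nondecreasing_and_slope_change(self):
        p = SimParams(k_fast=400.0, p_chi=1.0, k_slow=50.0, k_off=0.5)
        traj = simulate_machine([2000.0], p, 600.0, np.random.default_rng(1))
        t = np.linspace(0, 600, 500)
        e = traj.extent(t)
        assert np.all(np.diff(e) >= -1e-9)
        if traj.stop_time is not None:
            assert traj.extent(traj.stop_time + 100) == pytest.approx(
                traj.extent(traj.stop_time))

    def test_never_commit_fraction_matches_geometric(self):
        # 15-site tandem array: P(no commitment) = (1-p)^15 ~ 0.0198
        p_chi = 0.23
        chi = [1000.0 + 8 * i for i in range(15)]
        genome = make_genome(length=200_000, dsb=50_000,
                             chi_layout={"reverse": [50_000 + int(c) for c in chi]})
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=p_chi,
                           k_slow=100.0, t_total=3600.0, n_cells=20_000, seed=4)
        pop = simulate_population(genome, params)
        frac = np.mean(~np.isfinite(pop.commit_dist_right))
        expected = (1 - p_chi) ** 15
        se = np.sqrt(expected * (1 - expected) / params.n_cells)
        assert abs(frac - expected) < 3 * se


class TestPopulation:
    def test_single_cell_no_chi_deterministic_interval(self, chi_free_genome):
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=0.0,
                           k_slow=0.0, t_total=60.0, n_cells=1, seed=5)
        pop = simulate_population(chi_free_genome, params)
        left, right = pop.extents_at()
        assert left[0] == pytest.approx(24_000.0, rel=1e-6)
        assert right[0] == pytest.approx(24_000.0, rel=1e-6)

    def test_symmetric_chi_gives_exchangeable_arms(self):
        g = make_genome(length=400_000, dsb=100_000,
                        chi_layout={"left_spacing": 5_000, "right_spacing": 5_000})
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=0.25,
                           k_slow=50.0, t_total=600.0, n_cells=5_000, seed=6)
        pop = simulate_population(g, params)
        left, right = pop.extents_at()
        assert stats.ks_2samp(left, right).pvalue > 0.01

    def test_chi_on_one_side_shortens_that_arm(self):
        g = make_genome(length=400_000, dsb=100_000,
                        chi_layout={"left_spacing": 5_000, "right_spacing": None})
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=0.25,
                           k_slow=30.0, t_total=600.0, n_cells=4_000, seed=7)
        pop = simulate_population(g, params)
        left, right = pop.extents_at()
        assert right.mean() > left.mean()

    def test_shuffling_chi_irrelevant_when_p_zero(self):
        base = make_genome(length=400_000, dsb=100_000,
                           chi_layout={"left_spacing": 5_000, "right_spacing": 20_000})
        shuffled = make_genome(length=400_000, dsb=100_000,
                               chi_layout={"left_spacing": 13_000, "right_spacing": 7_000})
        params = SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.0,
                           k_slow=50.0, t_total=3600.0, n_cells=3_000, seed=8)
        a = survival_profile(simulate_population(base, params), n_bins=400)
        b = survival_profile(simulate_population(shuffled, params), n_bins=400)
        assert np.array_equal(a.survival, b.survival)

    def test_fixed_seed_bit_identical_population(self, small_genome, fast_params):
        a = simulate_population(small_genome, fast_params)
        b = simulate_population(small_genome, fast_params)
        for attr in ("onset_s", "commit_dist_left", "commit_dist_right",
                     "dwell_left", "dwell_right"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_single_cell_reconstruction_matches_population(self, small_genome, fast_params):
        params = replace(fast_params, k_off=0.1, n_cells=50)
        pop = simulate_population(small_genome, params)
        for i in (0, 13, 49):
            cell = simulate_cell(small_genome, params, i)
            assert cell["onset_s"] == pop.onset_s[i]
            assert cell["commit_dist_left"] == pop.commit_dist_left[i]
            assert cell["dwell_right"] == pop.dwell_right[i]


class TestSurvivalProfile:
    def test_uncut_population_survives_everywhere(self, small_genome):
        params = SimParams(onset_rate=0.0, t_total=3600.0, n_cells=500, seed=9)
        pop = simulate_population(small_genome, params)
        prof = survival_profile(pop, n_bins=100)
        assert np.all(prof.survival == 1.0)

    def test_step_profile_for_deterministic_fronts(self, chi_free_genome):
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=0.0, k_slow=0.0,
                           k_off=0.0, t_total=60.0, n_cells=200, seed=10)
        pop = simulate_population(chi_free_genome, params)
        prof = survival_profile(pop, n_bins=2000)
        g = chi_free_genome
        d = np.minimum((prof.bin_centers - g.dsb_position) % g.length,
                       (g.dsb_position - prof.bin_centers) % g.length)
        inside = d < 24_000 - 100
        outside = d > 24_000 + 100
        assert np.all(prof.survival[inside] == 0.0)
        assert np.all(prof.survival[outside] == 1.0)

    def test_survival_monotone_along_each_arm(self, small_genome):
        params = SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.23, k_slow=100.0,
                           k_off=0.05, t_total=7200.0, n_cells=3_000, seed=11)
        prof = survival_profile(simulate_population(small_genome, params), n_bins=500)
        g = small_genome
        dr = (prof.bin_centers - g.dsb_position) % g.length
        for arm_sel in (dr <= g.length / 2, dr > g.length / 2):
            d_arm = np.minimum(dr[arm_sel], g.length - dr[arm_sel])
            order = np.argsort(d_arm)
            assert np.all(np.diff(prof.survival[arm_sel][order]) >= -1e-12)

    def test_matches_analytic_mixture_with_two_chi_per_side(self):
        """Quadrature-free closed-form survival for <=2 chi per side."""
        L, dsb = 400_000, 200_000
        chi_d = [10_000.0, 30_000.0]  # same layout both arms
        g = make_genome(length=L, dsb=dsb,
                        chi_layout={"forward": [dsb - int(c) for c in chi_d],
                                    "reverse": [dsb + int(c) for c in chi_d]})
        lam_h, kf, p, ks, koff_m = 0.8, 400.0, 0.3, 60.0, 0.05
        t_tot = 3600.0
        params = SimParams(onset_rate=lam_h, k_fast=kf, p_chi=p, k_slow=ks,
                           k_off=koff_m, t_total=t_tot, n_cells=40_000, seed=12)
        pop = simulate_population(g, params)
        prof = survival_profile(pop, n_bins=200)

        lam = lam_h / 3600.0
        koff = koff_m / 60.0

        def analytic_loss(d):
            """P(position at distance d on one arm lost by t_tot)."""
            branches = []
            # commit at chi_1 / chi_2 / never
            for i, (prob, cd) in enumerate(
                    [(p, chi_d[0]), ((1 - p) * p, chi_d[1])]):
                if d <= cd:
                    t_reach = d / kf
                    surv_diss = 1.0
                else:
                    t_reach = cd / kf + (d - cd) / ks
                    surv_diss = np.exp(-koff * (d - cd) / ks)
                branches.append((prob, t_reach, surv_diss))
            branches.append(((1 - p) ** 2, d / kf, 1.0))
            total = 0.0
            for prob, t_reach, surv_diss in branches:
                if t_reach < t_tot:
                    p_onset = 1.0 - np.exp(-lam * (t_tot - t_reach))
                    total += prob * p_onset * surv_diss
            return total

        d_r = (prof.bin_centers - dsb) % L
        sel = (d_r > 0) & (d_r < 100_000)
        expect = 1.0 - np.array([analytic_loss(d) for d in d_r[sel]])
        mc = prof.survival[sel]
        se = np.sqrt(np.maximum(expect * (1 - expect), 1e-6) / params.n_cells)
        assert np.all(np.abs(mc - expect) < np.maximum(3 * se, 0.01))

    def test_qpcr_observable_at_least_sequencing(self, small_genome):
        params = SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.3, k_slow=100.0,
                           t_total=3600.0, n_cells=3_000, seed=13)
        pop = simulate_population(small_genome, params)
        seq = survival_profile(pop, n_bins=200)
        qp = survival_profile(pop, n_bins=200, observable="qpcr")
        assert np.all(qp.survival >= seq.survival - 1e-12)
        assert qp.survival.sum() > seq.survival.sum()


class TestFoci:
    def test_interval_is_pure_slow_transit(self, ):
        # commitment right at the break, slow phase covers both loci
        g = make_genome(length=2_000_000, dsb=780_000,
                        chi_layout={"forward": [780_000]})
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=1.0,
                           k_slow=340.0, k_off=0.0, t_total=7200.0,
                           n_cells=10, seed=14)
        pop = simulate_population(g, params)
        tbl = foci_loss_times(pop, {"near": -38_000.0, "far": -230_000.0})
        interval = tbl.events["far"] - tbl.events["near"]
        assert np.allclose(interval, 192_000.0 / 340.0)
        assert interval.iloc[0] / 60.0 == pytest.approx(9.41, abs=0.01)

    def test_dissociation_censors_but_does_not_bias_completers(self):
        g = make_genome(length=2_000_000, dsb=780_000,
                        chi_layout={"forward": [780_000]})
        base = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=1.0, k_slow=340.0,
                         k_off=0.0, t_total=7200.0, n_cells=4_000, seed=15)
        heavy = replace(base, k_off=0.1)
        loci = {"near": -38_000.0, "far": -230_000.0}
        tbl0 = foci_loss_times(simulate_population(g, base), loci)
        tbl1 = foci_loss_times(simulate_population(g, heavy), loci)
        both0 = tbl0.events.dropna()
        both1 = tbl1.events.dropna()
        assert len(both1) < 0.5 * len(both0)  # heavy censoring
        iv0 = (both0["far"] - both0["near"]).mean()
        iv1 = (both1["far"] - both1["near"]).mean()
        assert iv1 == pytest.approx(iv0, rel=0.01)

    def test_opposite_arm_intervals_uncorrelated(self):
        g = make_genome(length=2_000_000, dsb=780_000,
                        chi_layout={"left_spacing": 5_000, "right_spacing": 5_000})
        params = SimParams(onset_rate=1e9, k_fast=400.0, p_chi=0.25,
                           k_slow=100.0, t_total=7200.0, n_cells=5_000, seed=16)
        pop = simulate_population(g, params)
        tbl = foci_loss_times(pop, {"l": -100_000.0, "r": 100_000.0})
        both = tbl.events.dropna()
        r = np.corrcoef(both["l"], both["r"])[0, 1]
        assert abs(r) < 0.05

    def test_zero_offset_rejected(self, small_genome, fast_params):
        pop = simulate_population(small_genome, fast_params)
        with pytest.raises(ValueError):
            pop.loss_times(0.0)
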