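import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coassoc.simulate import (SimulationConfig, calibrate_capacity,
                              default_env_correlation,
                              interpolate_environments, sample_populations,
                              selection_surface, simulate_landscape,
                              synthetic_environments, weir_fst)


class TestSelectionSurface:
    def test_pure_cline_is_linear_in_latitude(self):
        cfg = SimulationConfig(width=8, height=10, cline_weight=1.0, seed=1)
        s = selection_surface(cfg)
        # constant across columns, linear from -1 (north) to +1 (south)
        assert np.allclose(s, s[:, :1])
        np.testing.assert_allclose(s[:, 0], np.linspace(-1, 1, 10), atol=1e-12)

    def test_range_bounded(self):
        cfg = SimulationConfig(width=16, height=16, cline_weight=0.3, seed=2)
        s = selection_surface(cfg)
        assert s.min() == pytest.approx(-1) and s.max() == pytest.approx(1)

    def test_reproducible_from_seed(self):
        cfg = SimulationConfig(width=12, height=12, seed=3)
        np.testing.assert_array_equal(selection_surface(cfg),
                                      selection_surface(cfg))

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cline_weight=1.5)


class TestRecurrence:
    def test_neutral_deterministic_torus_conserves_mean(self):
        cfg = SimulationConfig(width=12, height=12, capacity=None,
                               n_neutral=4, n_selected=0, generations=80,
                               boundary="wrap", seed=4)
        rng = np.random.default_rng(4)
        selection_surface(cfg, rng)
        p0 = rng.uniform(0.1, 0.9, 4)
        state = simulate_landscape(cfg)
        np.testing.assert_allclose(np.nanmean(state.freqs, axis=(1, 2)), p0,
                                   atol=1e-12)

    @pytest.mark.parametrize("p_fixed", [0.0, 1.0])
    def test_fixed_loci_stay_fixed_under_selection(self, p_fixed):
        cfg = SimulationConfig(width=8, height=8, capacity=None, n_neutral=0,
                               n_selected=2, generations=60,
                               p0_range=(p_fixed, p_fixed), seed=5,
                               s_classes=(0.1,))
        state = simulate_landscape(cfg)
        assert np.all(state.freqs == p_fixed)

    def test_one_deme_logistic_recurrence_matches_direct_iteration(self):
        s, gens, p0 = 0.1, 500, 0.01
        cfg = SimulationConfig(width=1, height=1, capacity=None, n_neutral=0,
                               n_selected=1, generations=gens,
                               p0_range=(p0, p0), s_classes=(s,), seed=6)
        state = simulate_landscape(cfg, surface=np.ones((1, 1)))
        p = p0
        for _ in range(gens):
            p = p * (1 + s) / (p * (1 + s) + (1 - p))
        assert state.freqs[0, 0, 0] == pytest.approx(p, rel=1e-9)
        assert p > 0.99

    def test_expansion_mask_grows_and_offmask_is_nan(self):
        cfg = SimulationConfig(width=16, height=16, capacity=50, n_neutral=10,
                               n_selected=0, demography="1R", generations=5,
                               seed=7)
        state = simulate_landscape(cfg)
        assert 4 < state.mask.sum() < 256  # grown but not yet full
        assert np.isnan(state.freqs[:, ~state.mask]).all()
        assert np.isfinite(state.freqs[:, state.mask]).all()
        longer = simulate_landscape(
            SimulationConfig(width=16, height=16, capacity=50, n_neutral=10,
                             n_selected=0, demography="1R", generations=30,
                             seed=7))
        assert longer.mask.sum() >= state.mask.sum()

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6),
           dem=st.sampled_from(["IBD", "1R", "2R"]),
           k=st.sampled_from([2, 10, 100]))
    def test_frequencies_always_in_unit_interval(self, seed, dem, k):
        cfg = SimulationConfig(width=10, height=10, capacity=k, n_neutral=5,
                               n_selected=2, demography=dem, generations=25,
                               seed=seed)
        state = simulate_landscape(cfg)
        vals = state.freqs[:, state.mask]
        assert np.all((vals >= 0) & (vals <= 1))


class TestFst:
    def test_equal_frequencies_give_zero(self):
        fst, mean = weir_fst(np.full((3, 5), 0.4))
        assert mean == pytest.approx(0.0)

    def test_fully_diverged_two_demes_give_one(self):
        fst, mean = weir_fst(np.array([[0.0, 1.0]]))
        assert mean == pytest.approx(1.0)

    def test_hand_computed_variance_ratio(self):
        # freqs (0.2, 0.4, 0.6): var = 0.02666..., pbar(1-pbar) = 0.24
        fst, mean = weir_fst(np.array([[0.2, 0.4, 0.6]]))
        assert mean == pytest.approx((0.08 / 3) / 0.24)

    def test_monomorphic_locus_excluded_from_mean(self):
        fst, mean = weir_fst(np.array([[0.0, 0.0], [0.2, 0.4]]))
        assert np.isnan(fst[0])
        assert mean == pytest.approx(weir_fst(np.array([[0.2, 0.4]]))[1])

    def test_fst_decreases_with_capacity_and_dispersal(self):
        def mean_fst(K, sigma):
            vals = []
            for sd in range(3):
                cfg = SimulationConfig(width=16, height=16, capacity=K,
                                       sigma=sigma, n_neutral=80,
                                       n_selected=0, generations=100,
                                       boundary="wrap", seed=60 + sd)
                vals.append(weir_fst(simulate_landscape(cfg))[1])
            return np.mean(vals)

        assert mean_fst(20, 1.0) > mean_fst(80, 1.0)   # more drift, higher FST
        assert mean_fst(20, 0.6) > mean_fst(20, 1.6)   # less migration, higher


class TestDemographicScenarios:
    def test_fst_variance_ordering_2r_1r_ibd(self):
        # founder effects and secondary contact widen the FST distribution
        out = {}
        for dem in ("IBD", "1R", "2R"):
            vs = []
            for sd in range(10):
                cfg = SimulationConfig(width=16, height=16, capacity=25,
                                       n_neutral=60, n_selected=0,
                                       demography=dem, seed=300 + sd)
                fst, _ = weir_fst(simulate_landscape(cfg))
                vs.append(np.nanvar(fst))
            out[dem] = np.mean(vs)
        assert out["2R"] > out["1R"] > out["IBD"]

    def test_selected_loci_track_surface_above_neutral_quantile(
            self, ibd_sim_with_selection):
        tt = ibd_sim_with_selection.truth_table()
        neutral_q99 = tt.loc[tt["s"] == 0, "surface_corr"].abs().quantile(0.99)
        strong = tt[tt["s"] >= 0.01]
        frac = (strong["surface_corr"].abs() > neutral_q99).mean()
        assert frac >= 0.8


class TestCalibration:
    def test_capacity_already_on_target_returned_unchanged(self):
        cfg = SimulationConfig(width=12, height=12, capacity=40, n_neutral=50,
                               n_selected=0, generations=80, boundary="wrap",
                               seed=8)
        achieved = np.mean([weir_fst(simulate_landscape(
            SimulationConfig(width=12, height=12, capacity=40, n_neutral=50,
                             n_selected=0, generations=80, boundary="wrap",
                             seed=cfg.seed + 1000 + i)))[1] for i in range(2)])
        K = calibrate_capacity(cfg, fst_target=achieved, tolerance=0.01,
                               n_seeds=2)
        assert K == 40

    def test_unreachable_target_reports_bracket(self):
        cfg = SimulationConfig(width=8, height=8, capacity=20, n_neutral=30,
                               n_selected=0, generations=40, seed=9)
        with pytest.raises(ValueError, match="calibration|bracket"):
            calibrate_capacity(cfg, fst_target=0.9, tolerance=0.001,
                               n_seeds=1, k_bounds=(4, 16), max_iter=3)


class TestSyntheticEnvironments:
    def test_identity_target_small_cross_correlations(self):
        n = 400
        em, h = synthetic_environments(n, 6, target_corr=np.eye(6), seed=10)
        C = np.corrcoef(em.values.to_numpy(), rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() <= 3 / np.sqrt(n) + 0.05

    def test_hidden_variable_band_is_respected(self):
        em, h = synthetic_environments(250, 22, selective_corr_max=0.2, seed=11)
        corrs = [abs(np.corrcoef(h, em.values[c])[0, 1])
                 for c in em.variables]
        assert max(corrs) <= 0.2 + 1e-8

    def test_block_correlation_recovered(self):
        # 0.9-correlated block, checked against a plain Cholesky construction
        R = np.eye(5)
        R[:3, :3] = 0.9
        np.fill_diagonal(R, 1.0)
        n = 250
        em, _ = synthetic_environments(n, 5, target_corr=R, seed=12,
                                       selective_corr_max=0.1)
        C = np.corrcoef(em.values.to_numpy(), rowvar=False)
        rng = np.random.default_rng(12)
        oracle = (np.linalg.cholesky(R) @ rng.standard_normal((5, n))).T
        Co = np.corrcoef(oracle, rowvar=False)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(C[:3, :3][off] - 0.9).max() < 0.05
        assert np.abs(Co[:3, :3][off] - 0.9).max() < 0.05

    def test_default_target_is_psd_with_categories(self):
        R, cats = default_env_correlation(22)
        assert np.linalg.eigvalsh(R).min() > -1e-10
        assert set(cats.values()) == {"Aridity", "Freezing", "Geography",
                                      "other"}

    def test_non_psd_target_rejected(self):
        bad = np.array([[1.0, 0.99], [0.99, -1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            synthetic_environments(50, 2, target_corr=bad)

    def test_spatially_smooth_residuals_with_coords(self):
        rng = np.random.default_rng(13)
        xy = rng.uniform(0, 32, (150, 2))
        em, h = synthetic_environments(150, 4, target_corr=np.eye(4), seed=13,
                                       coords=xy, spatial_scale=8.0)
        # nearby sites more similar than distant ones for each variable
        from scipy.spatial.distance import pdist

        d = pdist(xy)
        near, far = d < 4, d > 20
        for c in em.variables:
            v = em.values[c].to_numpy()
            dv = pdist(v[:, None]) ** 2
            assert dv[near].mean() < dv[far].mean()


class TestInterpolation:
    def test_coincident_query_returns_site_value(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        v = np.array([3.0, 5.0, 9.0])
        out = interpolate_environments(xy, v, np.array([[1.0, 0.0]]))
        assert out[0] == pytest.approx(5.0)

    def test_midpoint_of_equal_values(self):
        xy = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 5.0]])
        v = np.array([4.0, 4.0, 4.0])
        out = interpolate_environments(xy, v, np.array([[1.0, 0.0]]))
        assert out[0] == pytest.approx(4.0)

    def test_equidistant_sites_average(self):
        xy = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 40.0], [1.0, -40.0]])
        v = np.array([0.0, 1.0, 0.5, 0.5])
        out = interpolate_environments(xy, v, np.array([[1.0, 0.0]]), k=2)
        assert out[0] == pytest.approx(0.5)

    def test_outside_hull_falls_back_to_nearest(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        v = np.array([3.0, 5.0, 9.0])
        with pytest.warns(UserWarning, match="convex hull"):
            out = interpolate_environments(xy, v, np.array([[10.0, 0.0]]))
        assert out[0] == pytest.approx(5.0)


class TestSampling:
    def test_sampled_frequencies_match_grid(self):
        cfg = SimulationConfig(width=10, height=10, capacity=30, n_neutral=5,
                               n_selected=0, generations=20, seed=14)
        state = simulate_landscape(cfg)
        fm, coords = sample_populations(state, n_pops=12, seed=14)
        for pop in fm.pop_ids[:3]:
            r, c = int(coords.loc[pop, "row"]), int(coords.loc[pop, "col"])
            np.testing.assert_allclose(fm.freq.loc[pop].to_numpy(),
                                       state.freqs[:, r, c])

    def test_oversampling_rejected(self):
        cfg = SimulationConfig(width=4, height=4, capacity=30, n_neutral=2,
                               n_selected=0, generations=5, seed=15)
        state = simulate_landscape(cfg)
        with pytest.raises(ValueError):
            sample_populations(state, n_pops=17)
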