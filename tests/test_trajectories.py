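"""Spline trajectory fitting, growth-series assembly and plasticity."""

import numpy as np
import pytest

import defol
from defol.datatypes import HarvestObservation, RunConfig, SmoothingPolicy
from defol.errors import DomainError, FitError
from defol.trajectories import (
    _fit_scatter,
    assemble_growth_series,
    defoliation_aligned_grid,
    fit_log_mass_spline,
    fit_trait_splines,
    mask_nonpositive_rgr,
    ontogenetic_plasticity_test,
    plasticity_series,
    signed_plasticity,
)


def _obs_from_arrays(t, shoot, sla=400.0, lwr=0.5, ecotype="PN", treatment="control"):
    """Build observations with prescribed shoot mass and constant SLA/LWR."""
    out = []
    for i, (ti, mi) in enumerate(zip(t, shoot)):
        leaf = lwr * mi
        out.append(
            HarvestObservation(
                plant_id=f"{treatment}-{i}",
                ecotype=ecotype,
                treatment=treatment,
                time_h=float(ti),
                leaf_mass_g=leaf,
                support_mass_g=mi - leaf,
                repro_mass_g=0.0,
                leaf_area_cm2=sla * leaf,
            )
        )
    return out


class TestLogMassSpline:
    def test_exponential_growth_gives_constant_rgr(self):
        """Noise-free exponential growth M = 0.5 e^{0.01 t} has RGR 0.01
        everywhere; the spline derivative must recover it within 1e-3."""
        t = np.linspace(10.0, 400.0, 12)
        obs = _obs_from_arrays(t, 0.5 * np.exp(0.01 * t))
        fit = fit_log_mass_spline(obs)
        tt = np.linspace(t[0], t[-1], 200)
        assert np.max(np.abs(fit.derivative(tt) - 0.01)) < 1e-3

    def test_derivative_matches_finite_differences_of_same_fit(self):
        """Analytical derivative vs central differences of the fitted curve
        on a 0.1 h grid: discrepancy below 1e-6 (both describe one spline)."""
        rng = np.random.default_rng(5)
        t = np.repeat(np.linspace(1416.0, 1782.0, 20), 2)
        m = 0.5 * np.exp(0.01 * (t - 1416.0) - 8e-6 * (t - 1416.0) ** 2)
        m *= np.exp(rng.normal(0, 0.02, t.size))
        fit = fit_log_mass_spline(_obs_from_arrays(t, m))
        h = 0.1
        tt = np.arange(1416.0 + h, 1782.0 - h, h)
        fd = (fit(tt + h) - fit(tt - h)) / (2 * h)
        assert np.max(np.abs(fit.derivative(tt) - fd)) < 1e-6

    def test_too_few_observations_or_times(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(FitError):
            fit_log_mass_spline(_obs_from_arrays(t, np.exp(t)))
        t = np.repeat([1.0, 2.0], 4)  # 8 obs, 2 distinct times
        with pytest.raises(FitError):
            fit_log_mass_spline(_obs_from_arrays(t, np.exp(t)))


class TestTraitSplines:
    def test_constant_sla_is_reproduced_exactly(self):
        t = np.repeat(np.linspace(0.0, 100.0, 10), 2)
        obs = _obs_from_arrays(t, np.exp(0.01 * t), sla=400.0)
        fit = fit_trait_splines(obs, "sla")
        tt = np.linspace(0, 100, 50)
        assert np.max(np.abs(fit(tt) - 400.0)) < 1e-6

    def test_linear_sla_endpoints_recovered(self):
        """SLA declining linearly 412 -> 276 cm2 g-1, noise free: fitted
        endpoints within 2 % of the generating line."""
        t = np.repeat(np.linspace(1416.0, 1782.0, 15), 2)
        sla_line = 412.0 + (276.0 - 412.0) * (t - 1416.0) / (1782.0 - 1416.0)
        obs = []
        for i, (ti, si) in enumerate(zip(t, sla_line)):
            leaf = 0.3
            obs.append(
                HarvestObservation(f"p{i}", "PN", "control", ti, leaf, 0.3, 0.0,
                                   si * leaf)
            )
        fit = fit_trait_splines(obs, "sla")
        assert fit(1416.0)[0] == pytest.approx(412.0, rel=0.02)
        assert fit(1782.0)[0] == pytest.approx(276.0, rel=0.02)

    def test_lwr_predictions_clipped_at_one(self):
        rng = np.random.default_rng(0)
        t = np.repeat(np.linspace(0.0, 100.0, 8), 3)
        obs = []
        for i, ti in enumerate(t):
            # leaf-only plants with measurement noise push LWR around 1
            leaf = 1.0
            support = max(0.0, rng.normal(0.0, 0.02))
            obs.append(
                HarvestObservation(f"p{i}", "PN", "control", ti + 1, leaf,
                                   support, 0.0, 400.0)
            )
        fit = fit_trait_splines(obs, "lwr")
        assert np.all(fit(np.linspace(1, 101, 60)) <= 1.0)

    def test_zero_leaf_mass_plants_excluded_for_sla(self):
        t = np.linspace(1.0, 10.0, 10)
        obs = _obs_from_arrays(t, np.exp(0.1 * t))
        # a leafless plant is legal (area 0) but uninformative for SLA
        obs.append(HarvestObservation("bare", "PN", "control", 5.0, 0.0, 1.0, 0.0, 0.0))
        fit = fit_trait_splines(obs, "sla")
        assert np.max(np.abs(fit(t) - 400.0)) < 1e-6


class TestAssembly:
    def _series_pair(self, rgr_c=0.02, rgr_d=0.02, sla=400.0, lwr=0.5):
        grid = np.linspace(1416.0, 1782.0, 62)
        t = np.repeat(np.concatenate([grid[::3], grid[-1:]]), 2)

        def mk(rgr, treatment):
            obs = _obs_from_arrays(
                t, 0.5 * np.exp(rgr * (t - 1416.0)), sla=sla, lwr=lwr,
                treatment=treatment,
            )
            lnm = fit_log_mass_spline(obs)
            return assemble_growth_series(
                lnm,
                fit_trait_splines(obs, "sla"),
                fit_trait_splines(obs, "lwr"),
                grid,
                ecotype="PN",
                treatment=treatment,
            )

        return mk(rgr_c, "control"), mk(rgr_d, "defoliated")

    def test_nar_is_rgr_over_sla_lwr(self):
        c, _ = self._series_pair()
        # rgr 0.02, sla 400, lwr 0.5 -> nar 1e-4 g cm-2 h-1
        assert np.allclose(c.nar, 0.02 / (400.0 * 0.5), rtol=1e-3)
        # identity holds at machine precision at every grid point
        np.testing.assert_allclose(c.rgr, c.nar * c.lar, rtol=0, atol=0)
        np.testing.assert_allclose(c.rgr, c.nar * c.sla * c.lwr, rtol=5e-16)
        np.testing.assert_allclose(c.lar, c.sla * c.lwr, rtol=0, atol=0)

    def test_printed_component_product_matches_printed_rgr(self):
        # NAR 1.2e-4 g cm-2 h-1, SLA 412, LWR 0.51 multiply to
        # 25.2 mg g-1 h-1, within 1 % of the printed control RGR 25.1
        rgr = 1.2e-4 * 412.0 * 0.51
        assert 1000.0 * rgr == pytest.approx(25.2, abs=0.05)
        assert 1000.0 * rgr == pytest.approx(25.1, rel=0.01)

    def test_grid_outside_range_raises(self):
        c, _ = self._series_pair()
        obs = _obs_from_arrays(np.linspace(1416, 1782, 12), np.ones(12))
        lnm = fit_log_mass_spline(obs)
        with pytest.raises(DomainError):
            assemble_growth_series(
                lnm, fit_trait_splines(obs, "sla"), fit_trait_splines(obs, "lwr"),
                np.linspace(1400.0, 1500.0, 5),
            )

    def test_mask_counts_nonpositive_rgr_points(self):
        c, d = self._series_pair()
        # force two negative predicted RGR points in the control series
        c.rgr[-2:] = -1e-5
        valid = mask_nonpositive_rgr(c, d)
        assert int(np.sum(~valid)) == 2
        # oracle: direct scan
        assert np.array_equal(~valid, np.minimum(c.rgr, d.rgr) <= 0)

    def test_all_positive_rgr_leaves_mask_empty(self):
        c, d = self._series_pair()
        assert np.all(mask_nonpositive_rgr(c, d))


class TestPlasticity:
    def test_printed_shock_values(self):
        assert signed_plasticity(4.7, 25.1) == pytest.approx(-0.81, abs=0.005)
        assert signed_plasticity(4.1, 12.4) == pytest.approx(-0.67, abs=0.005)

    def test_identical_series_have_zero_plasticity(self):
        pair = TestAssembly()._series_pair()
        p = plasticity_series(pair[0], pair[1], "rgr", 1464.0)
        assert np.allclose(p.value[p.valid], 0.0, atol=1e-12)
        assert np.all(p.grid_t >= 1464.0)

    def test_nonpositive_control_is_masked(self):
        c, d = TestAssembly()._series_pair()
        c.rgr[-1] = 0.0
        p = plasticity_series(c, d, "rgr", 1464.0)
        assert not p.valid[-1]
        assert np.isnan(p.value[-1])


class TestPermutationTest:
    def test_relabelled_identical_data_gives_p_one(self, fast_config):
        """If the defoliated series is the control data relabeled, the
        observed statistic is 0 and p = 1."""
        t = np.repeat(np.arange(1464.0, 1764.0, 30.0), 2)
        m = 0.5 * np.exp(0.005 * (t - 1464.0))
        obs = _obs_from_arrays(t, m, treatment="control")
        obs += _obs_from_arrays(t, m, treatment="defoliated")
        cfg = RunConfig(n_permutations=99)
        stat, p = ontogenetic_plasticity_test(obs, "ln_shoot_mass", cfg, seed=3)
        assert stat == 0.0
        assert p == 1.0

    def test_seed_reproducibility_and_id_invariance(self):
        rng = np.random.default_rng(1)
        t = np.repeat(np.arange(1464.0, 1764.0, 30.0), 2)
        mc = 0.5 * np.exp(0.005 * (t - 1464.0) + rng.normal(0, 0.05, t.size))
        md = 0.5 * np.exp(0.005 * (t - 1464.0) + rng.normal(0, 0.05, t.size))
        obs = _obs_from_arrays(t, mc, treatment="control")
        obs += _obs_from_arrays(t, md, treatment="defoliated")
        cfg = RunConfig(n_permutations=99)
        r1 = ontogenetic_plasticity_test(obs, "ln_shoot_mass", cfg, seed=9)
        r2 = ontogenetic_plasticity_test(obs, "ln_shoot_mass", cfg, seed=9)
        assert r1 == r2
        # renaming plants does not change the test
        renamed = [
            HarvestObservation(f"x{i}", o.ecotype, o.treatment, o.time_h,
                               o.leaf_mass_g, o.support_mass_g, o.repro_mass_g,
                               o.leaf_area_cm2)
            for i, o in enumerate(obs)
        ]
        assert ontogenetic_plasticity_test(renamed, "ln_shoot_mass", cfg, seed=9) == r1

    def test_single_treatment_blocks_dropped(self):
        t = np.repeat(np.arange(1464.0, 1764.0, 30.0), 2)
        m = 0.5 * np.exp(0.005 * (t - 1464.0))
        obs = _obs_from_arrays(t, m, treatment="control")
        obs += _obs_from_arrays(t[:-4], m[:-4] * 1.2, treatment="defoliated")
        cfg = RunConfig(n_permutations=99)
        stat, p = ontogenetic_plasticity_test(obs, "ln_shoot_mass", cfg, seed=3)
        assert 0 < p <= 1.0

    def test_shock_detected_on_noise_free_preset(self, noise_free_experiment):
        """Noise-free defoliation shock: shoot mass and LWR show ontogenetic
        plasticity at p <= 0.05 with 999 permutations."""
        obs = [o for o in noise_free_experiment.observations if o.ecotype == "PN"]
        cfg = RunConfig(n_permutations=999)
        for trait in ("ln_shoot_mass", "lwr"):
            _, p = ontogenetic_plasticity_test(obs, trait, cfg, seed=2)
            assert p <= 0.05


def test_defoliation_aligned_grid_contains_t_def():
    grid = defoliation_aligned_grid(1416.0, 1782.0, 1464.0, 6.0)
    assert 1464.0 in grid
    assert grid[0] == 1416.0 and grid[-1] == 1782.0
    assert np.allclose(np.diff(grid), 6.0)


def test_bootstrap_spread_positive_for_noisy_data(noisy_experiment):
    obs = [
        o for o in noisy_experiment.observations
        if o.ecotype == "PN" and o.treatment == "control"
    ]
    grid = np.linspace(1416.0, 1782.0, 20)
    sd = defol.bootstrap_spread(obs, "ln_shoot_mass", grid, n_boot=30, seed=1)
    assert sd.shape == grid.shape
    assert np.all(sd > 0)
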