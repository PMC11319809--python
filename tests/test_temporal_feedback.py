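"""Group changes, feedback-factor fits, and space-for-time prediction."""

import math

import numpy as np
import pytest

import borealec as bc
from borealec.temporal_feedback import FeedbackFitError, GroupChange


def _change(n, delta_g, delta_T, se=0.0):
    return GroupChange(
        n=n, delta_g=delta_g, delta_C=math.exp(delta_g), delta_T=delta_T,
        se_delta_g=se,
    )


class TestGroupChange:
    def test_geometric_mean_identity(self):
        g_s2 = np.array([[1.0, 1.0], [2.0, 8.0]])
        g_s1 = np.array([[1.0, 1.0], [1.0, 1.0]])
        t_s2 = np.array([[0.0, 0.0], [1.0, 1.0]])
        c = bc.group_change(g_s1, g_s2, t_s2, 2)
        assert c.delta_C == pytest.approx(math.sqrt(2 * 8), rel=1e-12)

    def test_identical_scenarios_null_change(self):
        g = np.array([[1.0, 2.0], [3.0, 4.0]])
        t = np.array([[0.0, 0.0], [1.0, 1.0]])
        c = bc.group_change(g, g, t, 2)
        assert c.delta_C == pytest.approx(1.0)
        assert c.delta_g == pytest.approx(0.0)

    def test_noise_free_run_obeys_exponential_in_every_group(self, noisefree_analysis, noisefree_config):
        """delta_C = exp(b delta_T) exactly for each group, b = true d."""
        d_true = noisefree_config.models[0].d_gpp
        fit = noisefree_analysis.gamma["GPP"]
        assert fit.b == pytest.approx(d_true, rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        g_s1 = rng.lognormal(0, 0.1, (3, 20))
        g_s2 = rng.lognormal(0.2, 0.1, (3, 20))
        t = rng.normal(10, 1, (3, 20))
        base = bc.group_change(g_s1, g_s2, t, 3)
        perm = rng.permutation(20)
        out = bc.group_change(g_s1[:, perm], g_s2[:, perm], t[:, perm], 3)
        assert out.delta_g == pytest.approx(base.delta_g, rel=1e-12)
        assert out.delta_T == pytest.approx(base.delta_T, rel=1e-12)

    def test_initial_state_cancellation(self):
        """A per-cell constant factor applied to both scenarios cancels."""
        rng = np.random.default_rng(1)
        g_s1 = rng.lognormal(0, 0.1, (2, 15))
        g_s2 = rng.lognormal(0.1, 0.1, (2, 15))
        t = np.vstack([np.full(15, 10.0), np.full(15, 11.0)])
        factor = rng.lognormal(0, 0.5, 15)
        base = bc.group_change(g_s1, g_s2, t, 2)
        out = bc.group_change(g_s1 * factor, g_s2 * factor, t, 2)
        assert out.delta_g == pytest.approx(base.delta_g, rel=1e-12)

    def test_nonpositive_cells_dropped(self):
        g_s2 = np.array([[1.0, 1.0], [2.0, -1.0]])
        g_s1 = np.ones((2, 2))
        t = np.array([[0.0, 0.0], [1.0, 1.0]])
        c = bc.group_change(g_s1, g_s2, t, 2)
        assert c.n_dropped == 1
        assert c.delta_C == pytest.approx(2.0)

    def test_all_cells_dropped_raises(self):
        g_s2 = np.array([[1.0], [-2.0]])
        g_s1 = np.ones((2, 1))
        t = np.zeros((2, 1))
        with pytest.raises(FeedbackFitError):
            bc.group_change(g_s1, g_s2, t, 2)

    def test_s2_only_mode_includes_co2(self, small_grid):
        cfg = bc.EnsembleConfig.default(
            n_models=2, seed=9, noise_cv=0.0, grid=small_grid, co2_log_growth=0.002
        )
        s1, s2 = bc.generate_model(cfg, 0)
        ana = bc.analyze_pair(s1, s2)
        # climate-only gamma matches truth up to the small interaction of the
        # secular CO2 factor with the repeating-climate windows
        assert ana.gamma["GPP"].gamma == pytest.approx(cfg.models[0].p_gpp, rel=5e-3)
        assert ana.gamma_s2only["GPP"].gamma > ana.gamma["GPP"].gamma + 1.0


class TestFitGamma:
    def test_closed_form_coefficient(self):
        dT = np.arange(0.2, 1.81, 0.2)
        changes = [_change(n + 2, 0.05 * t, t) for n, t in enumerate(dT)]
        fit = bc.fit_gamma(changes)
        assert fit.b == pytest.approx(0.05, rel=1e-12)
        assert fit.gamma == pytest.approx((math.exp(0.05) - 1) * 100, rel=1e-12)
        assert fit.gamma == pytest.approx(5.127, abs=1e-3)

    def test_null_changes_zero_gamma(self):
        changes = [_change(n, 0.0, 0.25 * (n - 1)) for n in range(2, 11)]
        fit = bc.fit_gamma(changes)
        assert fit.gamma == 0.0

    def test_degenerate_warming_rejected(self):
        changes = [_change(n, 0.01, 1.0) for n in range(2, 6)]
        with pytest.raises(FeedbackFitError):
            bc.fit_gamma(changes)

    def test_single_cell_limit_exact(self, small_grid):
        """With m = 1 cell the fitted gamma equals the true (e^b - 1)*100."""
        cfg = bc.EnsembleConfig.default(n_models=2, seed=2, noise_cv=0.0, grid=small_grid)
        s1, s2 = bc.generate_model(cfg, 0)
        groups = bc.temporal_groups(1901, 2010)
        gpp1 = s1.data["gpp"].values[:, 3:4, 2]
        gpp2 = s2.data["gpp"].values[:, 3:4, 2]
        tas2 = s2.data["tas"].values[:, 3:4, 2]
        clim = bc.monthly_climatology(gpp2, groups[0], 1901)
        gs = bc.define_growing_season(clim)
        m1 = np.array([bc.growing_season_mean(gpp1, gs, g, 1901) for g in groups])
        m2 = np.array([bc.growing_season_mean(gpp2, gs, g, 1901) for g in groups])
        t2 = np.array([bc.growing_season_mean(tas2, gs, g, 1901) for g in groups])
        changes = [bc.group_change(m1, m2, t2, n) for n in range(2, 11)]
        fit = bc.fit_gamma(changes)
        assert fit.gamma == pytest.approx(cfg.models[0].p_gpp, rel=1e-9)

    def test_two_sigma_coverage_on_noisy_ensembles(self):
        """Recovered gamma within 2 sigma of truth in >= 95% of 200 replicates."""
        true_p = 12.0
        hits = 0
        for rep in range(200):
            cfg = bc.EnsembleConfig.default(
                n_models=2, seed=20000 + rep, noise_cv=0.1,
                p_gpp_range=(true_p, 20.0),
                grid=bc.GridSpec(n_lat=7, n_lon=6, lat_bounds=(50, 78), lon_bounds=(0, 30)),
            )
            s1, s2 = bc.generate_model(cfg, 0)
            fit = bc.analyze_pair(s1, s2).gamma["GPP"]
            hits += abs(fit.gamma - true_p) <= 2 * fit.sigma_gamma
        assert hits >= 190


class TestPredictFromSpatial:
    def test_no_warming_no_change(self):
        assert bc.predict_temporal_from_spatial(0.1, [10.0, 12.0], [10.0, 12.0]) == 0.0

    def test_single_cell_closed_form(self):
        dh = bc.predict_temporal_from_spatial(0.1, [10.0], [11.0])
        assert dh == pytest.approx((math.exp(0.1) - 1) * 100, rel=1e-12)

    def test_two_cell_hand_value(self):
        dh = bc.predict_temporal_from_spatial(0.1, [5.0, 10.0], [6.0, 12.0])
        assert dh == pytest.approx(17.75, abs=0.01)

    def test_cell_order_invariant(self):
        dh1 = bc.predict_temporal_from_spatial(0.1, [5.0, 10.0], [6.0, 12.0])
        dh2 = bc.predict_temporal_from_spatial(0.1, [10.0, 5.0], [12.0, 6.0])
        assert dh1 == pytest.approx(dh2, rel=1e-14)

    def test_predicted_equals_fitted_on_noise_free_runs(self, noisefree_ensemble):
        """Space-derived prediction and simulated feedback coincide (1:1 line)."""
        _, analysis = noisefree_ensemble
        for m in analysis.models:
            for var in ("GPP", "LAI"):
                assert m.predicted_gamma[var] == pytest.approx(
                    m.gamma[var].gamma, abs=1e-6
                )
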