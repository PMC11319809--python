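"""Growing-season definition, climatologies, GS means, persistent cells."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import borealec as bc
from borealec.growing_season import EmptyCellSetError, GroupSpanError

HAND_CLIM = [0.5, 0.5, 1, 3, 6, 10, 8, 5, 2, 0.5, 0.5, 0.5]


class TestTemporalGroups:
    def test_default_decade_windows(self):
        groups = bc.temporal_groups()
        assert len(groups) == 10
        assert (groups[0].start_year, groups[0].end_year) == (1901, 1920)
        assert (groups[9].start_year, groups[9].end_year) == (1991, 2010)
        assert all(g.n_years == 20 for g in groups)

    def test_non_tiling_span_rejected(self):
        with pytest.raises(GroupSpanError):
            bc.temporal_groups(1901, 2015)


class TestClimatology:
    def test_constant_field(self):
        field = np.full((240, 2, 2), 4.5)
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        clim = bc.monthly_climatology(field, group, 1901)
        np.testing.assert_allclose(clim, 4.5)

    def test_alternating_years_average(self):
        field = np.zeros((240, 1, 1))
        field[5::24] = 2.0  # June of even years
        field[17::24] = 4.0  # June of odd years
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        clim = bc.monthly_climatology(field, group, 1901)
        assert clim[5, 0, 0] == pytest.approx(3.0)

    def test_group_outside_span_rejected(self):
        field = np.zeros((240, 1, 1))
        with pytest.raises(GroupSpanError):
            bc.monthly_climatology(field, bc.TemporalGroupSpec(2, 1911, 1930), 1901)

    def test_matches_synthetic_shape(self, noisefree_pair):
        from borealec.synthetic_ensemble import seasonal_shape

        _, s2 = noisefree_pair
        group = bc.temporal_groups(s2.start_year, s2.end_year)[0]
        clim = bc.monthly_climatology(s2.data["gpp"].values, group, s2.start_year)
        s, _ = seasonal_shape(
            bc.GridSpec(
                n_lat=s2.lat.size,
                n_lon=s2.lon.size,
                lat_bounds=(50.0, 78.0),
                lon_bounds=(0.0, 30.0),
            )
        )
        # climatology is proportional to the seasonal shape cell by cell
        ratio = clim / s
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[6:7], ratio.shape), rtol=1e-12
        )


class TestDefineGrowingSeason:
    def test_hand_evaluated_fixture(self):
        gs = bc.define_growing_season(HAND_CLIM)
        assert gs.month_indices() == [3, 4, 5, 6, 7]  # Apr..Aug; Sep==2 excluded
        assert bool(gs.valid)
        assert list(np.nonzero(gs.spring)[0]) == [3, 4]
        assert list(np.nonzero(gs.fall)[0]) == [7]

    def test_flat_climatology_invalid(self):
        gs = bc.define_growing_season([1.0] * 12)
        assert not bool(gs.valid)

    def test_all_zero_invalid_not_error(self):
        gs = bc.define_growing_season([0.0] * 12)
        assert not bool(gs.valid)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_threshold_is_relative(self, scale):
        base = bc.define_growing_season(HAND_CLIM)
        scaled = bc.define_growing_season([scale * c for c in HAND_CLIM])
        np.testing.assert_array_equal(base.months, scaled.months)
        assert bool(base.valid) == bool(scaled.valid)

    def test_contiguous_for_unimodal_synthetic(self, noisefree_pair):
        _, s2 = noisefree_pair
        group = bc.temporal_groups(s2.start_year, s2.end_year)[0]
        clim = bc.monthly_climatology(s2.data["gpp"].values, group, s2.start_year)
        gs = bc.define_growing_season(clim)
        flat = gs.months.reshape(12, -1)
        for col in flat.T:
            assert (np.abs(np.diff(col.astype(int))) == 1).sum() <= 2

    def test_negative_climatology_rejected(self):
        with pytest.raises(ValueError):
            bc.define_growing_season([-1.0] + [1.0] * 11)


class TestGrowingSeasonMean:
    def _gs(self):
        return bc.define_growing_season(HAND_CLIM)

    def test_constant_field(self):
        field = np.full((240,), 7.0)[:, None]
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        gs = bc.define_growing_season(np.asarray(HAND_CLIM, float)[:, None])
        out = bc.growing_season_mean(field, gs, group, 1901)
        assert out[0] == pytest.approx(7.0)

    def test_two_month_season_mean(self):
        clim = np.zeros(12)
        clim[[4, 5, 6, 7]] = [5, 10, 9, 5]  # valid 4-month season
        gs = bc.define_growing_season(clim[:, None])
        field = np.zeros((240, 1))
        field[4::12] = 10.0
        field[5::12] = 20.0
        field[6::12] = 10.0
        field[7::12] = 20.0
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        out = bc.growing_season_mean(field, gs, group, 1901)
        assert out[0] == pytest.approx(15.0)

    def test_invalid_cell_masked(self):
        gs = bc.define_growing_season(np.zeros((12, 1)))
        field = np.ones((240, 1))
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        out = bc.growing_season_mean(field, gs, group, 1901)
        assert np.isnan(out[0])

    def test_matches_brute_force_on_synthetic(self, noisefree_pair):
        """Vectorised GS mean equals a per-cell loop over raw months."""
        _, s2 = noisefree_pair
        group = bc.temporal_groups(s2.start_year, s2.end_year)[2]
        gpp = s2.data["gpp"].values
        clim = bc.monthly_climatology(gpp, group, s2.start_year)
        gs = bc.define_growing_season(clim)
        out = bc.growing_season_mean(gpp, gs, group, s2.start_year)
        y0 = group.start_year - s2.start_year
        for i in range(0, gpp.shape[1], 3):
            for j in range(0, gpp.shape[2], 2):
                if not gs.valid[i, j]:
                    continue
                samples = [
                    gpp[(y0 + y) * 12 + m, i, j]
                    for y in range(20)
                    for m in range(12)
                    if gs.months[m, i, j]
                ]
                assert out[i, j] == pytest.approx(np.mean(samples), rel=1e-12)

    def test_group_mean_invariant_to_year_order(self):
        rng = np.random.default_rng(1)
        field = rng.lognormal(0, 0.3, (240, 1))
        clim = np.asarray(HAND_CLIM, float)[:, None]
        gs = bc.define_growing_season(clim)
        group = bc.TemporalGroupSpec(1, 1901, 1920)
        base = bc.growing_season_mean(field, gs, group, 1901)
        shuffled = field.reshape(20, 12, 1)[::-1].reshape(240, 1)
        out = bc.growing_season_mean(shuffled, gs, group, 1901)
        assert out[0] == pytest.approx(base[0], rel=1e-12)


class TestPersistentCells:
    def test_intersection_semantics(self):
        v = [np.array([True, True]), np.array([True, False])]
        out = bc.persistent_valid_cells(v)
        assert out.tolist() == [True, False]

    def test_all_valid_reduces_to_eligibility(self):
        v = [np.ones(3, bool)] * 10
        elig = np.array([True, False, True])
        out = bc.persistent_valid_cells(v, elig)
        assert out.tolist() == [True, False, True]

    def test_empty_set_raises_advice(self):
        with pytest.raises(EmptyCellSetError, match="revise"):
            bc.persistent_valid_cells([np.zeros(3, bool)])

    def test_synthetic_default_keeps_enough_cells(self, noisefree_analysis):
        assert noisefree_analysis.m_cells >= 20
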