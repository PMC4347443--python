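"""Possibility-line evaluation, 50%-point extraction and fitting."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chillforce import (
    PossibilityLine,
    SeedlingRecord,
    TreatmentPoint,
    accumulate_units,
    fifty_percent_point,
    fit_possibility_line,
    is_budburst_possible,
    required_forcing,
)
from chillforce.possibility import BudburstObservationSet, FitError

from conftest import SEASON_START, make_sinusoidal_series


class TestRequiredForcing:
    def test_flat_line_when_rate_zero(self):
        line = PossibilityLine(a0=100.0, a1=3.0, a2=0.0)
        for c in (0.0, 500.0, 5000.0):
            assert required_forcing(line, c) == pytest.approx(100.0 + math.exp(3.0))

    def test_asymptote_at_high_chilling(self):
        line = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        assert required_forcing(line, 1e6) == pytest.approx(150.0, abs=1e-9)

    def test_direct_evaluation(self):
        # independent evaluation via math.exp on the stated closed form
        line = PossibilityLine(a0=100.0, a1=7.0, a2=-0.002)
        assert required_forcing(line, 1000.0) == pytest.approx(
            100.0 + math.exp(5.0), rel=1e-14
        )

    def test_obligate_threshold_gives_infinity(self):
        line = PossibilityLine(a0=100.0, a1=7.0, a2=-0.002, c_min=200.0)
        assert required_forcing(line, 199.9) == math.inf
        assert math.isfinite(required_forcing(line, 200.0))

    def test_negative_chilling_rejected(self):
        with pytest.raises(ValueError):
            required_forcing(PossibilityLine(1.0, 1.0, 0.0), -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PossibilityLine(a0=-1.0, a1=0.0, a2=0.0)
        with pytest.raises(ValueError):
            PossibilityLine(a0=0.0, a1=0.0, a2=0.5)


class TestIsBudburstPossible:
    LINE = PossibilityLine(a0=200.0, a1=8.0, a2=-0.001)

    def test_boundary_is_inclusive(self):
        req = required_forcing(self.LINE, 1000.0)
        assert is_budburst_possible(self.LINE, 1000.0, req)
        assert not is_budburst_possible(self.LINE, 1000.0, req - 1e-6)

    def test_obligate_line_blocks_unchilled_plants(self):
        """No amount of forcing substitutes for a missing obligate chill."""
        line = PossibilityLine(a0=200.0, a1=8.0, a2=-0.001, c_min=200.0)
        assert not is_budburst_possible(line, 0.0, 1e6)
        assert is_budburst_possible(line, 5000.0, 1e6)

    def test_agrees_with_sign_of_excess_on_random_grid(self):
        rng = np.random.default_rng(5)
        chill = rng.uniform(0, 5000, 300)
        force = rng.uniform(0, 6000, 300)
        got = is_budburst_possible(self.LINE, chill, force)
        want = (force - required_forcing(self.LINE, chill)) >= 0
        np.testing.assert_array_equal(got, want)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.floats(0, 5000),
        st.floats(0, 6000),
        st.floats(0, 1000),
        st.floats(0, 1000),
    )
    def test_monotone_in_both_arguments(self, chill, force, dc, df):
        """More chilling or more forcing never flips possible -> impossible."""
        if is_budburst_possible(self.LINE, chill, force):
            assert is_budburst_possible(self.LINE, chill + dc, force + df)


def _obs(treatment, checks_per_seedling):
    seedlings = tuple(
        SeedlingRecord(f"s{i}", tuple(checks))
        for i, checks in enumerate(checks_per_seedling)
    )
    return BudburstObservationSet(treatment, seedlings)


def _dates(*day_offsets):
    return [SEASON_START + dt.timedelta(days=d) for d in day_offsets]


class TestFiftyPercentPoint:
    @pytest.fixture
    def trajectory(self, curves, sinusoidal_series):
        return accumulate_units(sinusoidal_series, *curves, SEASON_START)

    def test_immediate_crossing_uses_first_check(self, trajectory):
        d1, d2 = _dates(30, 37)
        checks = [[(d1, i < 10), (d2, i < 10)] for i in range(20)]
        point = fifty_percent_point(_obs("t", checks), trajectory)
        assert point.reached_50
        from chillforce import units_at

        assert (point.chill_units, point.force_units) == units_at(trajectory, d1)

    def test_linear_interpolation_between_checks(self, trajectory):
        # fractions 0.4 then 0.6, checks 7 days apart -> crossing at +3.5 d
        d1, d2 = _dates(30, 37)
        checks = [[(d1, i < 8), (d2, i < 12)] for i in range(20)]
        point = fifty_percent_point(_obs("t", checks), trajectory)
        from chillforce import units_at

        expected = units_at(trajectory, d1 + dt.timedelta(days=3.5))
        assert point.chill_units == pytest.approx(expected[0])
        assert point.force_units == pytest.approx(expected[1])

    def test_abnormal_seedlings_never_count_as_burst(self, trajectory):
        d1 = _dates(30)[0]
        seedlings = [SeedlingRecord(f"s{i}", ((d1, True),)) for i in range(10)]
        seedlings += [
            SeedlingRecord(f"a{i}", ((d1, True),), abnormal=True) for i in range(11)
        ]
        point = fifty_percent_point(
            BudburstObservationSet("t", tuple(seedlings)), trajectory
        )
        assert not point.reached_50  # 10/21 < 0.5

    def test_never_reaching_half_flags_point(self, trajectory):
        d1, d2 = _dates(30, 37)
        checks = [[(d1, False), (d2, i < 5)] for i in range(20)]
        point = fifty_percent_point(_obs("t", checks), trajectory)
        assert not point.reached_50

    def test_burst_is_absorbing(self):
        d1, d2 = _dates(10, 17)
        s = SeedlingRecord("s", ((d1, True), (d2, False)))
        assert s.checks[1][1] is True


def points_on_line(line, chill_values):
    return [
        TreatmentPoint(f"t{i}", c, required_forcing(line, c))
        for i, c in enumerate(chill_values)
    ]


class TestFit:
    def test_noiseless_recovery(self):
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        pts = points_on_line(truth, [200, 700, 1300, 2000, 2800, 3600])
        line, diag = fit_possibility_line(pts)
        assert line.a0 == pytest.approx(truth.a0, rel=1e-6)
        assert line.a1 == pytest.approx(truth.a1, rel=1e-6)
        assert line.a2 == pytest.approx(truth.a2, rel=1e-6)
        assert diag["rss"] < 1e-8
        assert diag["converged"]

    def test_noisy_recovery_median_within_ten_percent(self):
        """200 replicates, 5% Gaussian forcing noise: median error < 10%."""
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        chill = np.array([200, 700, 1300, 2000, 2800, 3600], dtype=float)
        req = np.array([required_forcing(truth, c) for c in chill])
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(200):
            force = req * (1 + rng.normal(0, 0.05, size=len(req)))
            pts = [
                TreatmentPoint(f"t{i}", c, max(f, 0.0))
                for i, (c, f) in enumerate(zip(chill, force))
            ]
            line, _ = fit_possibility_line(pts)
            errs.append(
                [
                    abs(line.a0 - truth.a0) / truth.a0,
                    abs(line.a1 - truth.a1) / abs(truth.a1),
                    abs(line.a2 - truth.a2) / abs(truth.a2),
                ]
            )
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10), med

    def test_flat_relationship_hits_zero_rate_bound(self):
        pts = [
            TreatmentPoint(f"t{i}", c, 500.0)
            for i, c in enumerate([100, 800, 1500, 2500])
        ]
        line, _ = fit_possibility_line(pts)
        assert line.a2 == pytest.approx(0.0, abs=1e-12)
        assert line.a0 + math.exp(line.a1) == pytest.approx(500.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        pts = points_on_line(truth, [200, 900])
        with pytest.raises(FitError, match=">= 3"):
            fit_possibility_line(pts)

    def test_obligate_sets_chilling_threshold(self):
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        pts = points_on_line(truth, [600, 1300, 2000, 3000])
        line, _ = fit_possibility_line(pts, obligate=True, c_min_factor=0.5)
        assert line.c_min == pytest.approx(300.0)
        assert required_forcing(line, 100.0) == math.inf

    def test_unreached_point_above_line_warns(self):
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        pts = points_on_line(truth, [600, 1300, 2000, 3000])
        pts.append(TreatmentPoint("warm", 100.0, 1e6, reached_50=False))
        with pytest.warns(UserWarning, match="warm"):
            fit_possibility_line(pts)

    def test_fitted_lines_always_nonincreasing_in_chilling(self):
        """The tradeoff: fitted requirement never rises with chilling."""
        rng = np.random.default_rng(11)
        grid = np.linspace(0, 6000, 200)
        for _ in range(10):
            chill = np.sort(rng.uniform(0, 4000, 6))
            force = rng.uniform(100, 5000, 6)
            try:
                line, _ = fit_possibility_line(
                    [
                        TreatmentPoint(f"t{i}", c, f)
                        for i, (c, f) in enumerate(zip(chill, force))
                    ]
                )
            except FitError:
                continue
            req = required_forcing(line, grid)
            assert np.all(np.diff(req) <= 1e-9)

    def test_asymmetric_mode_pushes_line_beneath_points(self):
        truth = PossibilityLine(a0=150.0, a1=8.0, a2=-0.0015)
        chill = np.array([200, 700, 1300, 2000, 2800, 3600], dtype=float)
        rng = np.random.default_rng(3)
        force = np.array(
            [required_forcing(truth, c) for c in chill]
        ) * (1 + rng.normal(0, 0.08, 6))
        pts = [
            TreatmentPoint(f"t{i}", c, f) for i, (c, f) in enumerate(zip(chill, force))
        ]
        sym, _ = fit_possibility_line(pts)
        asym, _ = fit_possibility_line(pts, asymmetric=True)
        below_sym = np.sum(force < [required_forcing(sym, c) for c in chill])
        below_asym = np.sum(force < [required_forcing(asym, c) for c in chill])
        assert below_asym <= below_sym


def test_simulated_point_lies_near_true_line(curves, true_line, climate):
    """Round trip: simulate observations, extract the 50% point, compare."""
    from chillforce import generate_treatment_series, simulate_budburst_observations
    from chillforce.synthetic import standard_schedules

    sched = standard_schedules()["ambient"]
    series = generate_treatment_series(sched, climate, SEASON_START, 270, seed=9)
    obs = simulate_budburst_observations(
        series, true_line, curves, n_seedlings=24, sigma=0.05, seed=10
    )
    traj = accumulate_units(series, *curves, SEASON_START)
    point = fifty_percent_point(obs, traj)
    assert point.reached_50
    req = required_forcing(true_line, point.chill_units)
    # within one weekly check interval of forcing accumulation of the line
    week_force = np.max(np.diff(traj.force_units)) * 24 * 7
    assert abs(point.force_units - req) < week_force
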