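"""Effective time constants, regime classification, decontamination window."""

import itertools

import numpy as np
import pytest

from dermdecon.eigensolver import build_eigensystem
from dermdecon.kinetics_window import (
    classify_regime,
    decontamination_window,
    effective_time_constants,
)
from dermdecon.parameters import TimeScale, scenario_from_dimensionless
from dermdecon.steady_state import steady_fractions
from dermdecon.transient_series import transient_curves

GRID = list(itertools.product([0.5, 1, 2, 4, 8, 10], [0.4, 1.2, 2.0]))


class TestEffectiveTimeConstants:
    def test_single_mode_reduces_to_pure_exponential(self, vx):
        eig = build_eigensystem(vx, 1)
        tc = effective_time_constants(eig)
        mu1 = eig.mus[0]
        assert tc.tau_eff_abs == pytest.approx(1.0 / mu1, rel=1e-12)
        assert tc.t98_abs == pytest.approx(-np.log(0.02) / mu1, rel=1e-9)
        assert tc.t98_abs == pytest.approx(3.912 / mu1, rel=1e-3)

    def test_pathway_ordering_under_strong_decontamination(self, tabun_rsdl):
        tc = effective_time_constants(build_eigensystem(tabun_rsdl))
        assert tc.tau_eff_surf < tc.tau_eff_reac < tc.tau_eff_abs

    def test_four_tau_is_about_98pct_completion(self, tabun_rsdl):
        tc = effective_time_constants(build_eigensystem(tabun_rsdl))
        st = steady_fractions(tabun_rsdl)
        curves = transient_curves(tabun_rsdl, np.array([4.0 * tc.tau_eff_abs]))
        completion = 100.0 * curves.M_abs[0] / st.M_abs_inf
        assert completion == pytest.approx(98.0, abs=2.0)

    def test_t98_matches_cumulative_curve(self, tabun_rsdl):
        tc = effective_time_constants(build_eigensystem(tabun_rsdl))
        st = steady_fractions(tabun_rsdl)
        for pathway, cum in (
            ("abs", "M_abs"),
            ("surf", "M_surf"),
            ("reac", "M_reac"),
        ):
            curves = transient_curves(tabun_rsdl, np.array([tc.t98(pathway)]))
            limit = getattr(steady_fractions(tabun_rsdl), f"M_{pathway}_inf")
            assert getattr(curves, cum)[0] / limit == pytest.approx(0.98, abs=1e-6)

    def test_zero_asymptote_pathways_reported_absent(self):
        eig = build_eigensystem(scenario_from_dimensionless(0.0, 0.0))
        tc = effective_time_constants(eig)
        assert tc.tau_eff_surf is None and tc.t98_surf is None
        assert tc.tau_eff_reac is None and tc.t98_reac is None
        assert tc.tau_eff_abs is not None

    @pytest.mark.parametrize("pi", [0.4, 1.2, 2.0])
    def test_time_constants_decrease_with_da(self, pi):
        das = [0.5, 1, 2, 4, 8, 10]
        tcs = [
            effective_time_constants(
                build_eigensystem(scenario_from_dimensionless(da, pi))
            )
            for da in das
        ]
        for pathway in ("abs", "surf", "reac"):
            vals = [tc.tau_eff(pathway) for tc in tcs]
            assert np.all(np.diff(vals) < 0)

    def test_absorption_constant_converges_at_high_da(self):
        pis = np.linspace(0.4, 2.0, 5)

        def rel_spread(da):
            v = [
                effective_time_constants(
                    build_eigensystem(scenario_from_dimensionless(da, p))
                ).tau_eff_abs
                for p in pis
            ]
            return (max(v) - min(v)) / np.mean(v)

        assert rel_spread(10.0) < rel_spread(1.0)

    @pytest.mark.parametrize("da,pi", GRID[::3])
    def test_t98_to_tau_eff_ratio_bounded(self, da, pi):
        """For a pure exponential t98/tau_eff = 3.91.  The lagged absorption
        curve sits below this and the front-loaded surface curve above it;
        the near-exponential reacted pathway stays close to 3.91."""
        tc = effective_time_constants(
            build_eigensystem(scenario_from_dimensionless(da, pi))
        )
        for pathway, lo, hi in (
            ("abs", 2.0, 3.912),
            ("surf", 3.912, 6.0),
            ("reac", 3.3, 4.6),
        ):
            ratio = tc.t98(pathway) / tc.tau_eff(pathway)
            assert lo < ratio < hi


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "da,label",
        [
            (0.0, "diffusion-dominated"),
            (0.88, "diffusion-dominated"),
            (2.999, "diffusion-dominated"),
            (3.0, "intermediate"),
            (5.0, "intermediate"),
            (8.0, "intermediate"),
            (8.001, "bulk reaction-dominated"),
            (10.0, "bulk reaction-dominated"),
        ],
    )
    def test_threshold_boundaries(self, da, label):
        assert classify_regime(da).label == label

    def test_strategy_strings_attached(self):
        assert "surface" in classify_regime(0.88).strategy.lower()
        assert "both" in classify_regime(5.0).strategy.lower()
        assert "reaction" in classify_regime(10.0).strategy.lower()

    def test_negative_da_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(-1.0)


class TestDecontaminationWindow:
    def test_ordering_holds_for_strong_decontamination(self, tabun_rsdl):
        report = decontamination_window(tabun_rsdl)
        assert report.ordering_holds
        m = report.markers_4tau
        assert m["surf"] < m["reac"] < m["abs"]
        assert report.window_extent == pytest.approx(m["abs"] - m["reac"])

    def test_ordering_holds_for_vx(self, vx):
        assert decontamination_window(vx).ordering_holds

    def test_decontamination_reduces_asymptotic_absorption(self, tabun_rsdl):
        report = decontamination_window(tabun_rsdl)
        assert report.M_abs_inf_decon < report.M_abs_inf_baseline

    def test_absent_pathways_flagged(self):
        report = decontamination_window(scenario_from_dimensionless(0.0, 0.0))
        assert set(report.absent_pathways) == {"surf", "reac"}
        assert not report.ordering_holds
        assert report.markers_4tau["surf"] is None

    def test_minutes_reported_only_with_timescale(self, vx):
        bare = decontamination_window(vx)
        assert bare.markers_4tau_min == {}
        ts = TimeScale(t_diff=69.6)
        timed = decontamination_window(vx, timescale=ts)
        assert timed.markers_4tau_min["abs"] == pytest.approx(
            timed.markers_4tau["abs"] * 69.6
        )
        assert timed.window_extent_min == pytest.approx(timed.window_extent * 69.6)

    def test_report_serializes(self, tabun_rsdl):
        import json

        payload = decontamination_window(tabun_rsdl).to_dict()
        text = json.dumps(payload)
        assert "ordering_holds" in text
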