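import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lichenflux import light_response as lr
from lichenflux.light_response import (
    CurveError,
    LightResponseCurve,
    LightStep,
    apply_attenuation,
    dark_respiration,
    fit_nrh,
    gross_assimilation,
    light_compensation_point,
    nrh_net,
    rectangular_lcp,
    reduce_records,
    summarize,
)
from lichenflux.synthetic import GeneratorConfig


def make_curve(par, a_net, **kwargs):
    steps = [LightStep(p, a, 0.0, 10) for p, a in zip(par, a_net)]
    return LightResponseCurve(
        kwargs.get("thallus_id", "t1"), kwargs.get("hydration", "vapor"),
        kwargs.get("temperature_C", 25.0), steps,
    )


STANDARD_PAR = np.array([0.0, 27.0, 55.0, 136.0, 273.0, 544.0, 815.0, 1086.0, 1357.0])


def nrh_curve(phi, a_max, theta, r_d, par=STANDARD_PAR):
    return make_curve(par, nrh_net(par, phi, a_max, theta, r_d))


class TestAttenuation:
    @pytest.mark.parametrize(
        "programmed,realized",
        [(0, 0), (50, 27), (100, 55), (250, 136), (500, 273), (1000, 544), (2000, 1086), (2500, 1357)],
    )
    def test_protocol_levels_use_lookup(self, programmed, realized):
        assert apply_attenuation(programmed) == realized

    def test_off_table_levels_use_generic_factor(self):
        assert apply_attenuation(800.0) == pytest.approx(800 * 0.543)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            apply_attenuation(-1.0)


class TestReduceRecords:
    def _records(self, rows):
        df = pd.DataFrame(
            rows, columns=["thallus_id", "hydration", "temperature_C", "par_programmed", "par_realized", "a_net"]
        )
        df["species"] = "s"
        df["genus"] = "g"
        return df

    def test_replicates_collapse_to_one_step(self):
        rows = [("t1", "vapor", 25.0, 0.0, 0.0, -1.0)] + [("t1", "vapor", 25.0, 1000.0, 544.0, 5.0)] * 10
        (curve,) = reduce_records(self._records(rows))
        step = [s for s in curve.steps if s.par_realized == 544][0]
        assert (step.mean_a_net, step.sd_a_net, step.n_reps) == (5.0, 0.0, 10)

    def test_revisited_level_pools_with_equal_weights(self):
        rows = [("t1", "vapor", 25.0, 0.0, 0.0, -1.0)]
        rows += [("t1", "vapor", 25.0, 1000.0, 544.0, 4.0)] * 5
        rows += [("t1", "vapor", 25.0, 1000.1, 544.0, 6.0)] * 5
        (curve,) = reduce_records(self._records(rows))
        step = [s for s in curve.steps if s.par_realized == 544][0]
        assert step.mean_a_net == pytest.approx(5.0)
        assert step.n_reps == 10

    def test_steps_sorted_ascending(self, noiseless_records):
        curves = reduce_records(noiseless_records)
        for curve in curves:
            par = curve.par
            assert (np.diff(par) > 0).all()
            assert par[0] == 0.0

    def test_group_without_dark_step_is_error(self):
        rows = [("t1", "vapor", 25.0, 1000.0, 544.0, 5.0)] * 3
        with pytest.raises(CurveError, match="t1"):
            reduce_records(self._records(rows))

    def test_noiseless_reduction_equals_generative_flux(self, noiseless_config, noiseless_records):
        curves = reduce_records(noiseless_records)
        cfg = noiseless_config
        for curve in curves[:6]:
            expected = cfg.photosynthesis.gross(
                curve.par, curve.temperature_C, curve.hydration
            ) - float(cfg.respiration.rate(curve.temperature_C, curve.hydration))
            np.testing.assert_allclose(curve.a_net, expected, rtol=1e-12)


class TestDarkAndGross:
    def test_dark_respiration_flips_sign(self):
        curve = make_curve([0.0, 544.0], [-3.2, 5.0])
        assert dark_respiration(curve) == pytest.approx(3.2)

    def test_zero_dark_flux_gives_zero_respiration(self):
        curve = make_curve([0.0, 544.0], [0.0, 5.0])
        assert dark_respiration(curve) == 0.0

    def test_noiseless_liquid_dark_at_reference_equals_r_ref(self, noiseless_config, noiseless_records):
        curves = reduce_records(noiseless_records)
        for curve in curves:
            if curve.hydration == "liquid" and curve.temperature_C == 25.0:
                assert dark_respiration(curve) == pytest.approx(
                    noiseless_config.respiration.r_ref, rel=1e-12
                )

    def test_gross_assimilation_identity(self):
        curve = make_curve([0.0, 544.0], [-3.0, 5.0])
        ga, ga_max = gross_assimilation(curve, 3.0)
        assert ga[0] == 0.0  # dark step: GA == 0 by construction
        assert ga[1] == pytest.approx(8.0)
        assert ga_max == pytest.approx(8.0)

    def test_noiseless_ga_max_matches_generator(self, noiseless_config, noiseless_records):
        curves = reduce_records(noiseless_records)
        cfg = noiseless_config
        for curve in curves:
            r = dark_respiration(curve)
            _, ga_max = gross_assimilation(curve, r)
            truth = float(
                cfg.photosynthesis.gross(curve.par.max(), curve.temperature_C, curve.hydration)
            )
            assert ga_max == pytest.approx(truth, rel=1e-12)


class TestNRHFit:
    def test_recovers_noiseless_parameters(self):
        true = dict(phi=0.01, a_max=8.0, theta=0.7, r_d=2.0)
        fit = fit_nrh(nrh_curve(**true))
        assert fit.converged
        for name, value in true.items():
            assert getattr(fit, name) == pytest.approx(value, rel=1e-6), name

    def test_rectangular_limit_recovered(self):
        fit = fit_nrh(nrh_curve(phi=0.02, a_max=6.0, theta=0.0, r_d=1.0))
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.theta < 1e-3
        assert fit.a_max == pytest.approx(6.0, rel=1e-4)

    def test_constant_zero_curve_is_degenerate(self):
        fit = fit_nrh(make_curve(STANDARD_PAR, np.zeros_like(STANDARD_PAR)))
        assert fit.degenerate and not fit.converged

    def test_too_few_levels_skips_fit(self):
        fit = fit_nrh(make_curve([0.0, 100.0, 200.0], [-1.0, 1.0, 2.0]))
        assert fit.degenerate

    def test_fit_idempotence(self):
        curve = nrh_curve(phi=0.008, a_max=5.0, theta=0.5, r_d=1.5)
        fit1 = fit_nrh(curve)
        refit_curve = make_curve(STANDARD_PAR, nrh_net(STANDARD_PAR, fit1.phi, fit1.a_max, fit1.theta, fit1.r_d))
        fit2 = fit_nrh(refit_curve)
        assert abs(fit2.rss - 0.0) < 1e-9


class TestLCP:
    def test_bisection_matches_rectangular_closed_form(self):
        phi, a_max, r_d = 0.05, 10.0, 1.0
        curve = nrh_curve(phi=phi, a_max=a_max, theta=0.0, r_d=r_d)
        fit = fit_nrh(curve)
        lcp, never = light_compensation_point(fit, curve)
        assert not never
        expected = rectangular_lcp(phi, a_max, r_d)
        assert expected == pytest.approx(r_d * a_max / (phi * (a_max - r_d)))
        assert lcp == pytest.approx(expected, rel=1e-6)

    def test_zero_respiration_gives_zero_lcp(self):
        curve = nrh_curve(phi=0.01, a_max=5.0, theta=0.5, r_d=0.0)
        lcp, never = light_compensation_point(fit_nrh(curve), curve)
        assert lcp == 0.0 and not never

    def test_respiration_above_plateau_never_compensates(self):
        curve = nrh_curve(phi=0.01, a_max=2.0, theta=0.5, r_d=3.0)
        lcp, never = light_compensation_point(fit_nrh(curve), curve)
        assert never and lcp is None

    def test_interpolation_fallback_brackets_zero_crossing(self):
        curve = make_curve([0.0, 100.0, 200.0], [-2.0, 0.0, 2.0])
        lcp, never = light_compensation_point(None, curve)
        assert lcp == pytest.approx(100.0)
        assert not never

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.lists(st.floats(0.1, 4.9), min_size=2, max_size=6, unique=True))
    def test_lcp_monotone_in_respiration(self, r_values):
        """Holding the light curve fixed, higher respiration raises the LCP."""
        lcps = []
        for r_d in sorted(r_values):
            curve = nrh_curve(phi=0.05, a_max=10.0, theta=0.6, r_d=r_d)
            lcp, never = light_compensation_point(fit_nrh(curve), curve)
            assert not never
            lcps.append(lcp)
        assert all(b > a for a, b in zip(lcps, lcps[1:]))


def test_summarize_end_to_end_on_synthetic_curve(noiseless_records):
    curves = reduce_records(noiseless_records)
    summary = summarize(curves[0])
    assert summary.r_dark > 0
    assert summary.ga_max > 0
    assert summary.fit is not None and summary.fit.converged
    assert summary.lcp is not None and summary.lcp > 0


def test_summaries_frame_has_one_row_per_curve(noiseless_records):
    curves = reduce_records(noiseless_records)
    summaries = [summarize(c, fit_curve=False) for c in curves]
    frame = lr.summaries_frame(summaries)
    assert len(frame) == len(curves)
    assert {"r_dark", "ga_max", "lcp", "never_compensates"} <= set(frame.columns)
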