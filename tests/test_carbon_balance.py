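import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lichenflux import carbon_balance as cb
from lichenflux.light_response import PhysiologySummary


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=list(cb.PAIR_COLUMNS))


def pair_row(unit_id="u1", genus="Evernia", ga_v=1.0, ga_l=1.0, r_v=1.0, r_l=1.0):
    return {
        "unit_id": unit_id, "species": f"{genus} sp", "genus": genus,
        "ga_vapor": ga_v, "ga_liquid": ga_l, "r_vapor": r_v, "r_liquid": r_l,
    }


def summary(thallus, hydration, temp, r_dark, ga_max, genus="Evernia"):
    return PhysiologySummary(
        thallus_id=thallus, hydration=hydration, temperature_C=temp,
        r_dark=r_dark, ga_max=ga_max, lcp=None, never_compensates=False,
        fit=None, species=f"{genus} sp", genus=genus,
    )


class TestPairedRegression:
    def test_exactly_proportional_pairs_return_the_constant(self):
        pairs = pairs_frame([pair_row(f"u{i}", r_v=x, r_l=2.13 * x) for i, x in enumerate([1.0, 2.0, 3.0])])
        reg = cb.paired_regression(pairs, quantity="R")
        assert reg.slope == pytest.approx(2.13, rel=1e-12)
        assert reg.r2 == pytest.approx(1.0, abs=1e-12)
        assert reg.df == (1, 2)

    def test_identity_line_has_unit_slope(self):
        pairs = pairs_frame([pair_row(f"u{i}", ga_v=x, ga_l=x) for i, x in enumerate([0.5, 1.0, 4.0])])
        reg = cb.paired_regression(pairs, quantity="GA")
        assert reg.slope == pytest.approx(1.0, rel=1e-12)

    def test_f_statistic_and_df_reported(self, rng):
        x = rng.uniform(1, 5, 20)
        y = 2.0 * x + rng.normal(0, 0.1, 20)
        pairs = pairs_frame([pair_row(f"u{i}", r_v=a, r_l=b) for i, (a, b) in enumerate(zip(x, y))])
        reg = cb.paired_regression(pairs, quantity="R")
        assert reg.df == (1, 19)
        assert reg.f_stat > 100
        assert 0 <= reg.p_value < 1e-6

    def test_too_few_pairs_rejected(self):
        pairs = pairs_frame([pair_row("a"), pair_row("b")])
        with pytest.raises(cb.RegressionError):
            cb.paired_regression(pairs, quantity="R")

    def test_all_zero_abscissa_is_singular(self):
        pairs = pairs_frame([pair_row(f"u{i}", r_v=0.0, r_l=1.0) for i in range(4)])
        with pytest.raises(cb.RegressionError, match="singular"):
            cb.paired_regression(pairs, quantity="R")

    def test_free_intercept_diagnostic_reports_intercept(self):
        pairs = pairs_frame([pair_row(f"u{i}", r_v=x, r_l=2 * x + 1) for i, x in enumerate([1.0, 2.0, 3.0, 4.0])])
        reg = cb.paired_regression(pairs, quantity="R", through_origin=False)
        assert reg.intercept == pytest.approx(1.0, abs=1e-9)
        assert reg.slope == pytest.approx(2.0, rel=1e-9)


class TestBuildPairs:
    def test_pairs_vapor_and_liquid_per_thallus_temperature(self):
        summaries = [
            summary("t1", "vapor", 25.0, 1.0, 4.0),
            summary("t1", "liquid", 25.0, 2.13, 4.0),
            summary("t2", "vapor", 25.0, 1.1, 4.1),  # liquid side missing
        ]
        pairs = cb.build_pairs(summaries)
        assert len(pairs) == 1
        assert pairs.loc[0, "r_liquid"] == 2.13


class TestRespirationRatio:
    def test_simple_ratio(self):
        table = cb.respiration_ratio([summary("t1", "vapor", 25.0, 2.0, 4.0)])
        assert table.loc[0, "ratio"] == pytest.approx(0.5)
        assert not table.loc[0, "unsustainable"]

    def test_zero_ga_is_flagged_infinite(self):
        table = cb.respiration_ratio([summary("t1", "liquid", 30.0, 2.0, 0.0)])
        assert np.isinf(table.loc[0, "ratio"])
        assert bool(table.loc[0, "unsustainable"])

    def test_liquid_exceeds_vapor_by_inverse_rho_when_alpha_unity(self, noiseless_records):
        from lichenflux.light_response import reduce_records, summarize

        summaries = [summarize(c, fit_curve=False) for c in reduce_records(noiseless_records)]
        table = cb.respiration_ratio(summaries).set_index(["hydration", "temperature_C"])
        for temp in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
            liquid = table.loc[("liquid", temp), "ratio"]
            vapor = table.loc[("vapor", temp), "ratio"]
            assert liquid / vapor == pytest.approx(2.13, rel=1e-3)


class TestViabilityThreshold:
    def test_linear_interpolation_between_bracketing_points(self):
        t_star = cb.viability_threshold([15.0, 20.0, 25.0], [0.2, 0.5, 1.5])
        assert t_star == pytest.approx(20.0 + 5.0 * 0.5 / 1.0)

    def test_all_below_one_is_none_in_range(self):
        assert cb.viability_threshold([10.0, 20.0, 30.0], [0.1, 0.2, 0.9]) is None

    def test_already_unsustainable_at_lowest_temperature(self):
        assert cb.viability_threshold([10.0, 20.0, 30.0], [1.2, 1.5, 2.0]) == 10.0

    def test_needs_at_least_three_temperatures(self):
        with pytest.raises(ValueError):
            cb.viability_threshold([20.0, 25.0], [0.5, 1.5])

    def test_matches_generative_root_of_q10_vs_gaussian(self):
        """T* from pipeline ratios agrees with the analytic crossing of
        R_ref*Q10^((T-Tref)/10) and the Gaussian GA_max(T), to the
        linear-interpolation error of a 1-degree grid."""
        from scipy.optimize import brentq

        from lichenflux.synthetic import PhotosynthesisParams, RespirationParams

        resp, photo = RespirationParams(), PhotosynthesisParams()
        f = lambda t: float(resp.rate(t)) - float(photo.ga_max(t))
        root = brentq(f, 20.0, 35.0)
        temps = np.arange(5.0, 35.1, 1.0)
        ratios = resp.rate(temps) / photo.ga_max(temps)
        t_star = cb.viability_threshold(temps, ratios)
        assert t_star == pytest.approx(root, abs=0.1)

    def test_monotone_in_r_ref(self):
        """Raising basal respiration never postpones the threshold."""
        from lichenflux.synthetic import PhotosynthesisParams, RespirationParams

        photo = PhotosynthesisParams()
        temps = np.arange(5.0, 35.1, 1.0)
        last = -np.inf
        for r_ref in (0.01, 0.02, 0.04, 0.08):
            ratios = RespirationParams(r_ref=r_ref).rate(temps) / photo.ga_max(temps)
            t_star = cb.viability_threshold(temps, ratios)
            assert t_star is not None
            assert t_star <= 35.0
            if last != -np.inf:
                assert t_star <= last
            last = t_star


class TestAsymmetryIndex:
    def test_symmetric_activation_gives_zero(self):
        rec = cb.asymmetry_index(pair_row(ga_v=3.0, ga_l=3.0, r_v=1.0, r_l=1.0))
        assert rec.index == 0.0

    def test_published_slope_arithmetic(self):
        rec = cb.asymmetry_index(pair_row(ga_v=1.0, ga_l=1.0, r_v=1.0, r_l=2.13))
        assert rec.a_prop == 1.0
        assert rec.r_prop == pytest.approx(1 / 2.13)
        assert rec.index == pytest.approx(1 - 1 / 2.13)
        assert rec.index == pytest.approx(0.5305, abs=5e-5)

    def test_negative_index_case(self):
        rec = cb.asymmetry_index(pair_row(ga_v=0.2, ga_l=1.0, r_v=0.9, r_l=1.0))
        assert rec.index == pytest.approx(-0.7)

    def test_zero_liquid_denominator_excluded(self):
        assert cb.asymmetry_index(pair_row(ga_l=0.0)) is None
        assert cb.asymmetry_index(pair_row(r_l=0.0)) is None

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        scale=st.floats(1e-3, 1e3),
        ga_v=st.floats(0.01, 10), ga_l=st.floats(0.01, 10),
        r_v=st.floats(0.01, 10), r_l=st.floats(0.01, 10),
    )
    def test_scale_invariance(self, scale, ga_v, ga_l, r_v, r_l):
        """Multiplying all four rates by a common factor leaves the index unchanged."""
        base = cb.asymmetry_index(pair_row(ga_v=ga_v, ga_l=ga_l, r_v=r_v, r_l=r_l))
        scaled = cb.asymmetry_index(
            pair_row(ga_v=scale * ga_v, ga_l=scale * ga_l, r_v=scale * r_v, r_l=scale * r_l)
        )
        assert scaled.index == pytest.approx(base.index, rel=1e-9, abs=1e-12)


class TestGenusAggregation:
    def test_unweighted_mean_per_genus(self):
        specimens = pd.DataFrame(
            {"genus": ["A", "A", "B"], "index": [0.2, 0.4, -0.5]}
        )
        table = cb.aggregate_by_genus(specimens).set_index("genus")
        assert table.loc["A", "index"] == pytest.approx(0.3)
        assert table.loc["A", "n_specimens"] == 2
        assert table.loc["B", "index"] == pytest.approx(-0.5)
        assert table.loc["B", "n_negative"] == 1

    def test_single_specimen_is_its_own_mean(self):
        table = cb.aggregate_by_genus(pd.DataFrame({"genus": ["A"], "index": [0.7]}))
        assert table.loc[0, "index"] == 0.7

    def test_panel_truth_recovered_exactly_at_zero_noise(self):
        from lichenflux.synthetic import generate_asymmetry_panel

        panel, truth = generate_asymmetry_panel(2, n_specimens=3, noise_cv=0.0)
        table = cb.aggregate_by_genus(cb.asymmetry_table(panel)).set_index("genus")
        for genus, entry in truth.items():
            assert table.loc[genus, "index"] == pytest.approx(entry["index"], rel=1e-12)
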