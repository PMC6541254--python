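"""Calibration families: exact fits, published-coefficient recovery, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grapemx import RipeningSample
from grapemx.calibration import (
    CalibrationModel,
    LinearCalibration,
    PolynomialCalibration,
    SigmoidCalibration,
    convert_anth_basis,
    filter_tss_domain,
    fit_linear,
    fit_polynomial,
    fit_sigmoid,
    select_model,
    side_concordance,
)
from grapemx.errors import (
    DegenerateFitError,
    FitFailureError,
    InvalidRatioError,
    OutOfRangeError,
    PairingError,
    SelectionFailureError,
    UnsupportedFamilyError,
)
from grapemx.presets import (
    ANTH_RG_BERRY_MODELS,
    ANTH_RG_SKIN_MODELS,
    FERARI_ANTH_BERRY_MODELS,
    FERARI_ANTH_SKIN_MODELS,
    FLAVONOL_MODELS,
    SIDE_RELATIONS,
    TSS_SFR_MODELS,
)


def sample(tss=15.0, **kw):
    defaults = dict(cultivar="Barbera", doy=230, tss=tss, ta=8.0, ph=3.0,
                    malic=2.0, anth_berry=0.5, anth_skin=5.0,
                    phenols_berry=2.0, flavonols_skin=1.5, berry_mass=1.6,
                    skin_to_berry_pct=10.0)
    defaults.update(kw)
    return RipeningSample(**defaults)


class TestLinear:
    def test_exact_line(self):
        m = fit_linear([0, 1, 2], [1, 3, 5])
        assert m.coefficients == pytest.approx((2.0, 1.0))
        assert m.r2 == pytest.approx(1.0)
        assert m.n == 3

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError):
            fit_linear([0, 1], [0, 1])

    def test_constant_predictor(self):
        with pytest.raises(DegenerateFitError):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_estimator_api(self):
        est = LinearCalibration().fit(np.arange(5.0).reshape(-1, 1),
                                      2 * np.arange(5.0) + 1)
        assert est.slope_ == pytest.approx(2.0)
        assert est.intercept_ == pytest.approx(1.0)
        assert est.predict([[3.0]]) == pytest.approx(7.0)
        assert est.get_params()["x_name"] == "x"


class TestPolynomial:
    def test_exact_quartic(self):
        x = np.linspace(-1, 2, 6)
        m = fit_polynomial(x, x ** 4, degree=4)
        assert m.coefficients[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(m.coefficients[1:], 0.0, atol=1e-9)
        assert m.r2 == pytest.approx(1.0)

    def test_insufficient_points_for_degree(self):
        with pytest.raises(DegenerateFitError):
            fit_polynomial([0, 1, 2, 3], [0, 1, 2, 3], degree=4)

    def test_repeated_x_counted_once(self):
        with pytest.raises(DegenerateFitError):
            fit_polynomial([0, 0, 1, 1, 2], [0, 0, 1, 1, 2], degree=4)


class TestSigmoid:
    def test_zero_noise_recovery_barbera_anth_curve(self):
        truth = FERARI_ANTH_BERRY_MODELS["Barbera"]
        x = np.linspace(0, 1.2, 27)
        m = fit_sigmoid(x, truth.predict(x))
        assert m.coefficients == pytest.approx(truth.coefficients, abs=1e-4)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_y_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_sigmoid(np.linspace(0, 1, 6), np.ones(6))

    def test_negative_y_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_sigmoid(np.linspace(0, 1, 6), np.linspace(-1, 1, 6))

    def test_noisy_recovery_cross_checked_by_grid_search(self, rng):
        """curve_fit must do at least as well (SSE) as an independent coarse
        grid search over (a, b, c) refined around its best cell."""
        truth = FERARI_ANTH_BERRY_MODELS["Ervi"]
        a, b, c = truth.coefficients
        x = np.linspace(0, 1.2, 27)
        y = truth.predict(x) + rng.normal(0, 0.05, size=27)
        y = np.clip(y, 0, None)
        m = fit_sigmoid(x, y)

        def sse(p):
            a_, b_, c_ = p
            return float(np.sum((y - a_ / (1 + np.exp(b_ - c_ * x))) ** 2))

        grids = [np.linspace(0.5 * a, 1.5 * a, 12),
                 np.linspace(0.5 * b, 1.5 * b, 12),
                 np.linspace(0.5 * c, 1.5 * c, 12)]
        best = min(((ai, bi, ci) for ai in grids[0] for bi in grids[1]
                    for ci in grids[2]), key=sse)
        refined = min(((best[0] * fa, best[1] * fb, best[2] * fc)
                       for fa in (0.96, 1.0, 1.04) for fb in (0.96, 1.0, 1.04)
                       for fc in (0.96, 1.0, 1.04)), key=sse)
        assert sse(m.coefficients) <= sse(refined) + 1e-9
        assert m.coefficients[0] == pytest.approx(a, rel=0.1)


PUBLISHED_MODELS = [
    pytest.param(model, np.linspace(*xr, 27), id=f"{label}")
    for label, model, xr in [
        *[(f"tss-sfr-{k}", m, (10.0, 27.2)) for k, m in TSS_SFR_MODELS.items()],
        *[(f"flavonol-{k}", m, (0.3, 3.0)) for k, m in FLAVONOL_MODELS.items()],
        *[(f"ferari-berry-{k}", m, (0.0, 1.2))
          for k, m in FERARI_ANTH_BERRY_MODELS.items()],
        ("ferari-skin-Malvasia R.", FERARI_ANTH_SKIN_MODELS["Malvasia R."],
         (0.0, 1.2)),
        ("ferari-skin-Barbera", FERARI_ANTH_SKIN_MODELS["Barbera"], (0.0, 20.0)),
        ("ferari-skin-Ervi", FERARI_ANTH_SKIN_MODELS["Ervi"], (0.0, 20.0)),
        *[(f"anthrg-berry-{k}", m, (0.0, 2.0))
          for k, m in ANTH_RG_BERRY_MODELS.items()],
        ("anthrg-skin-Malvasia R.", ANTH_RG_SKIN_MODELS["Malvasia R."], (0.0, 2.2)),
        ("anthrg-skin-Barbera", ANTH_RG_SKIN_MODELS["Barbera"], (0.0, 20.0)),
        ("anthrg-skin-Ervi", ANTH_RG_SKIN_MODELS["Ervi"], (0.0, 20.0)),
        *[(f"side-{k}", m, (0.0, 1.5)) for k, m in SIDE_RELATIONS.items()],
    ]
]


@pytest.mark.parametrize("truth, x", PUBLISHED_MODELS)
def test_published_model_recovery_at_zero_noise(truth, x):
    """Refitting each published calibration on exact curve samples returns its
    own coefficients to 1e-4 relative accuracy."""
    y = np.asarray(truth.predict(x), dtype=float)
    if truth.family == "linear":
        fitted = fit_linear(x, y)
    elif truth.family == "polynomial":
        fitted = fit_polynomial(x, y, degree=truth.degree)
    else:
        fitted = fit_sigmoid(x, y)
    for got, want in zip(fitted.coefficients, truth.coefficients):
        assert got == pytest.approx(want, rel=1e-4, abs=1e-10)


class TestPredictInvert:
    def test_sigmoid_inverse_closed_form(self):
        m = CalibrationModel("sigmoid", (1.55, 4.005, 5.261))
        x = m.invert(0.5)
        assert x == pytest.approx((4.005 - np.log(1.55 / 0.5 - 1)) / 5.261)
        assert x == pytest.approx(0.62024, abs=1e-5)

    def test_linear_inverse(self):
        m = CalibrationModel("linear", (2.0, 1.0))
        assert m.invert(5.0) == pytest.approx(2.0)

    def test_sigmoid_out_of_range(self):
        m = CalibrationModel("sigmoid", (1.55, 4.005, 5.261))
        with pytest.raises(OutOfRangeError):
            m.invert(1.6)
        with pytest.raises(OutOfRangeError):
            m.invert(0.0)

    def test_polynomial_not_invertible(self):
        m = CalibrationModel("polynomial", (1.0, 0.0, 0.0), degree=2)
        with pytest.raises(UnsupportedFamilyError):
            m.invert(1.0)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(min_value=-3, max_value=3))
    def test_invert_predict_round_trip(self, x):
        for m in (CalibrationModel("linear", (2.6675, -0.0891)),
                  CalibrationModel("sigmoid", (1.55, 4.005, 5.261))):
            assert m.invert(m.predict(x)) == pytest.approx(x, abs=1e-9)

    def test_sigmoid_monotone_and_bounded(self):
        m = CalibrationModel("sigmoid", (1.55, 4.005, 5.261))
        x = np.linspace(-2, 4, 200)
        y = m.predict(x)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 1.55))

    def test_serialization_round_trip(self):
        m = CalibrationModel("polynomial", (-0.1105, 0.7613, 0.628), degree=2,
                             x_name="flavonols_skin", y_name="flav_uv",
                             domain=(0.0, 3.0), r2=0.35, n=41)
        assert CalibrationModel.from_dict(m.to_dict()) == m


class TestDomainAndBasis:
    def test_tss_filter_counts_and_order(self):
        samples = [sample(tss=v) for v in (4.5, 9.2, 10.0, 22.3)]
        kept = filter_tss_domain(samples, 10.0)
        assert [s.tss for s in kept] == [10.0, 22.3]
        assert filter_tss_domain(samples, 0.0) == samples
        assert filter_tss_domain([], 10.0) == []

    def test_basis_conversion_arithmetic(self):
        assert convert_anth_basis(1.0, 10.0) == pytest.approx(10.0)

    def test_basis_conversion_barbera_harvest(self):
        # 1.68 mg/g berry at the 9.82% harvest skin ratio
        assert convert_anth_basis(1.68, 9.82) == pytest.approx(17.1, abs=0.01)

    def test_basis_conversion_round_trip_and_order(self):
        skin = convert_anth_basis(0.8, 9.5)
        assert skin * 9.5 / 100 == pytest.approx(0.8)
        assert convert_anth_basis(0.9, 9.5) > skin

    def test_zero_ratio_rejected(self):
        with pytest.raises(InvalidRatioError):
            convert_anth_basis(1.0, 0.0)


class TestSideConcordance:
    def test_identical_sides(self):
        v = np.linspace(0.1, 1.2, 10)
        model, mad = side_concordance(v, v)
        assert model.coefficients == pytest.approx((1.0, 0.0), abs=1e-12)
        assert model.r2 == pytest.approx(1.0)
        assert mad == 0.0

    def test_recovers_published_ferari_side_relation(self):
        ne = np.linspace(0.05, 1.4, 27)
        sw = 0.9131 * ne + 0.0026
        model, _ = side_concordance(sw, ne)
        assert model.coefficients == pytest.approx((0.9131, 0.0026), rel=1e-6)

    def test_unequal_lengths(self):
        with pytest.raises(PairingError):
            side_concordance([1, 2, 3], [1, 2])

    def test_two_pairs_degenerate(self):
        with pytest.raises(DegenerateFitError):
            side_concordance([1, 2], [1, 2])


class TestModelSelection:
    def test_parsimony_tie_break_prefers_line(self):
        x = np.linspace(0, 2, 10)
        m = select_model(x, 2 * x + 1, ["linear", ("polynomial", 4)])
        assert m.family == "linear"

    def test_sigmoid_beats_line_on_sigmoid_data(self):
        truth = FERARI_ANTH_BERRY_MODELS["Barbera"]
        x = np.linspace(0, 1.2, 27)
        y = np.asarray(truth.predict(x))
        m = select_model(x, y, ["linear", "sigmoid"])
        assert m.family == "sigmoid"
        # independent check: the winner's SSE is no worse than the loser's
        line = fit_linear(x, y)
        sse = lambda mod: float(np.sum((y - np.asarray(mod.predict(x))) ** 2))
        assert sse(m) <= sse(line)

    def test_empty_candidates(self):
        with pytest.raises(SelectionFailureError):
            select_model([0, 1, 2], [0, 1, 2], [])
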