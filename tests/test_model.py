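"""Unit and property tests for the adimensional rational model."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avrot import (
    AVRResult,
    DomainError,
    InvalidInputError,
    NoRootError,
    RationalModel5,
    SingularModelError,
    evaluate_avr,
    invert_ratio,
    load_model,
    published_model,
    save_model,
    validity_interval,
)

PUBLISHED = (20.22483, -330.5077, 33.46082, -3.93825, -1.322272)


class TestPublishedModel:
    def test_constants_exact(self, model):
        assert model.coefficients() == PUBLISHED

    def test_pure_constant(self):
        assert published_model() == published_model()

    def test_bundled_json_matches_constants(self, model):
        assert load_model() == model


class TestEvaluate:
    def test_representative_pair_thirty_degrees(self, model):
        # the published representative ratio for 30 deg maps back to ~30 deg
        assert evaluate_avr(model, 2.9495).avr_degrees == pytest.approx(30.0, abs=0.05)

    def test_constant_model_degeneracy(self):
        flat = RationalModel5(a=7.0, b=0.0, c=0.0, d_coef=0.0, e=0.0)
        for ratio in (0.3, 1.0, 5.0, 42.0):
            assert evaluate_avr(flat, ratio).avr_degrees == 7.0

    def test_matches_symbolic_evaluation_at_5(self, model):
        # independent oracle: exact rational arithmetic on the printed constants
        import sympy

        x = sympy.Rational(5)
        coefs = [sympy.Rational(str(v)) for v in PUBLISHED]
        expected = float(
            (coefs[0] + coefs[1] * x + coefs[2] * x**2)
            / (1 + coefs[3] * x + coefs[4] * x**2)
        )
        assert evaluate_avr(model, 5.0).avr_degrees == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_ratio(self, model):
        with pytest.raises(InvalidInputError):
            evaluate_avr(model, 0.0)
        with pytest.raises(InvalidInputError):
            evaluate_avr(model, -3.0)

    def test_singularity_raises(self):
        # denominator 1 - x vanishes at x = 1
        m = RationalModel5(a=1.0, b=1.0, c=0.0, d_coef=-1.0, e=0.0)
        with pytest.raises(SingularModelError):
            m(1.0)

    def test_domain_flags_and_policies(self, model, interval):
        inside = evaluate_avr(model, 3.0)
        assert inside.in_domain and not inside.clamped
        below = evaluate_avr(model, 1.0)
        assert not below.in_domain and not below.clamped
        clamped = evaluate_avr(model, 1.0, out_of_domain="clamp")
        assert clamped.clamped
        assert clamped.avr_degrees == pytest.approx(60.0, abs=1e-6)
        with pytest.raises(DomainError):
            evaluate_avr(model, 1.0, out_of_domain="strict")

    def test_result_within_avr_range_when_in_domain(self, model, interval):
        rng = np.random.default_rng(7)
        for ratio in rng.uniform(interval.ratio_lo, interval.ratio_hi, 50):
            res = evaluate_avr(model, ratio)
            assert res.in_domain
            assert 2.0 - 1e-9 <= res.avr_degrees <= 60.0 + 1e-9


class TestInvert:
    @pytest.mark.parametrize(
        "avr, printed, tol",
        [
            # printed representative ratios; the 2-deg row carries the largest
            # residual of the published fit (~0.013 deg over a slope of
            # ~2.3 deg/unit => ~6e-3 in ratio), hence its wider bound
            (2.0, 8.8848, 0.01),
            (30.0, 2.9495, 5e-3),
            (60.0, 1.1434, 5e-3),
        ],
    )
    def test_inverse_near_printed_representatives(self, model, avr, printed, tol):
        assert invert_ratio(model, avr) == pytest.approx(printed, abs=tol)

    def test_inverse_residual_tolerance(self, model):
        for avr in (2.0, 17.3, 41.0, 60.0):
            root = invert_ratio(model, avr)
            assert abs(float(model(root)) - avr) <= 1e-9

    def test_rejects_out_of_range_avr(self, model):
        with pytest.raises(InvalidInputError):
            invert_ratio(model, 75.0)

    def test_extrapolated_inversion_opt_in(self, model):
        root = invert_ratio(model, 1.0, allow_extrapolation=True)
        assert float(model(root)) == pytest.approx(1.0, abs=1e-9)

    def test_no_root_over_narrow_bracket(self, model):
        with pytest.raises(NoRootError):
            invert_ratio(model, 60.0, bracket=(5.0, 9.0))


class TestValidityInterval:
    def test_published_interval_matches_table_endpoints(self, interval):
        assert interval.ratio_lo == pytest.approx(1.1434, abs=5e-3)
        assert interval.ratio_hi == pytest.approx(8.8848, abs=0.01)
        assert interval.ratio_lo < interval.ratio_hi

    def test_strictly_decreasing_on_dense_grid(self, model, interval):
        grid = np.linspace(interval.ratio_lo, interval.ratio_hi, 10_000)
        values = model(grid)
        assert np.all(np.diff(values) < 0.0)

    def test_interval_ordering_enforced(self):
        from avrot.model import ValidityInterval

        with pytest.raises(InvalidInputError):
            ValidityInterval(ratio_lo=3.0, ratio_hi=1.0)


class TestRoundTrip:
    def test_thousand_random_ratios(self, model, interval):
        rng = np.random.default_rng(20260921)
        ratios = rng.uniform(interval.ratio_lo, interval.ratio_hi, 1000)
        for r in ratios:
            avr = evaluate_avr(model, r).avr_degrees
            assert abs(invert_ratio(model, avr) - r) < 1e-6

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1.1436, max_value=8.8789))
    def test_round_trip_property(self, ratio):
        model = published_model()
        avr = evaluate_avr(model, ratio).avr_degrees
        assert abs(invert_ratio(model, avr) - ratio) < 1e-6


class TestSerialization:
    def test_save_load_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        assert set(payload) == {"a", "b", "c", "d", "e", "ratio_lo", "ratio_hi"}
        assert load_model(path) == model

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"a": 1.0, "b": 2.0}')
        with pytest.raises(InvalidInputError):
            load_model(path)

    def test_singular_interval_rejected(self, tmp_path):
        path = tmp_path / "pole.json"
        # denominator 1 - x vanishes at x = 1, inside the claimed interval
        path.write_text(
            '{"a": 1, "b": 1, "c": 0, "d": -1, "e": 0, "ratio_lo": 0.5, "ratio_hi": 2}'
        )
        with pytest.raises(SingularModelError):
            load_model(path)
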