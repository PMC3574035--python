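"""Unit tests of the Hill-type and reciprocal rate laws."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cholsim import ParameterSet
from cholsim.model import (
    DomainError,
    biliary_release_rate,
    bile_salt_synthesis_rate,
    hepatic_synthesis_rate,
    hldlr_synthesis_rate,
    intestinal_synthesis_rate,
    peripheral_synthesis_rate,
    pldlr_synthesis_rate,
)

P = ParameterSet.default()


class TestIntestinalSynthesis:
    def test_half_max_at_threshold(self):
        assert intestinal_synthesis_rate(P.ICt, P) == pytest.approx(50.0)

    def test_maximum_at_zero_pool(self):
        assert intestinal_synthesis_rate(0.0, P) == pytest.approx(100.0)

    def test_documented_pool_value(self):
        # direct arithmetic oracle: ICSmax/(1+(IC/ICt)^IS) at the documented
        # intestinal pool; consistent with the ~49 mg/day synthesis budget
        expected = 100.0 / (1.0 + (3150.0 / 3120.0) ** 5)
        got = intestinal_synthesis_rate(3150.0, P)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(48.8, abs=0.05)

    def test_negative_pool_rejected(self):
        with pytest.raises(DomainError):
            intestinal_synthesis_rate(-1.0, P)


class TestHepaticSynthesis:
    def test_half_max_at_threshold(self):
        assert hepatic_synthesis_rate(93_900.0, P) == pytest.approx(250.0)

    def test_maximum_at_zero_pool(self):
        assert hepatic_synthesis_rate(0.0, P) == pytest.approx(500.0)

    def test_documented_pool_value(self):
        expected = 500.0 / (1.0 + (60_000.0 / 93_900.0) ** 5)
        got = hepatic_synthesis_rate(60_000.0, P)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(451.9, abs=0.05)

    def test_negative_pool_rejected(self):
        with pytest.raises(DomainError):
            hepatic_synthesis_rate(-0.1, P)


class TestPeripheralSynthesis:
    def test_half_max_at_threshold(self):
        assert peripheral_synthesis_rate(80_342.0, P) == pytest.approx(250.0)

    def test_maximum_at_zero_pool(self):
        assert peripheral_synthesis_rate(0.0, P) == pytest.approx(500.0)

    def test_documented_pool_value(self):
        expected = 500.0 / (1.0 + (57_516.8 / 80_342.0) ** 5)
        got = peripheral_synthesis_rate(57_516.8, P)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(420.9, abs=0.05)


class TestBiliaryRelease:
    def test_half_max_at_threshold(self):
        assert biliary_release_rate(55_500.0, P) == pytest.approx(1000.0)

    def test_saturates_at_maximum(self):
        assert biliary_release_rate(1e12, P) == pytest.approx(2000.0, rel=1e-6)

    def test_documented_pool_value(self):
        # ~1200 mg/day of biliary cholesterol at the documented hepatic pool
        expected = 2000.0 / (1.0 + (55_500.0 / 60_000.0) ** 5)
        got = biliary_release_rate(60_000.0, P)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1192.5, abs=0.2)

    def test_zero_pool_limit(self):
        assert biliary_release_rate(0.0, P) == 0.0

    def test_negative_pool_rejected(self):
        with pytest.raises(DomainError):
            biliary_release_rate(-5.0, P)


class TestBileSaltSynthesis:
    def test_documented_pools(self):
        # k5*HFC/HBS = 2.66*60000/400 = 399 mg/day (~400 mg/day of bile
        # salts synthesised and lost daily)
        assert bile_salt_synthesis_rate(60_000.0, 400.0, P) == pytest.approx(399.0)

    def test_unit_ratio_returns_rate_constant(self):
        assert bile_salt_synthesis_rate(123.0, 123.0, P) == pytest.approx(P.k5)

    def test_zero_cholesterol_gives_zero(self):
        assert bile_salt_synthesis_rate(0.0, 400.0, P) == 0.0

    def test_halves_when_pool_doubles(self):
        assert bile_salt_synthesis_rate(5e4, 800.0, P) == pytest.approx(
            bile_salt_synthesis_rate(5e4, 400.0, P) / 2.0)

    def test_empty_bile_pool_singular(self):
        with pytest.raises(DomainError):
            bile_salt_synthesis_rate(100.0, 0.0, P)


class TestReceptorSynthesis:
    def test_balances_degradation_at_documented_state(self):
        # khrs*HRS/HFC at the documented hepatic pool equals the degradation
        # flux k13*HLDLR of a full receptor complement
        assert hldlr_synthesis_rate(60_000.0, P) == pytest.approx(
            P.k13 * 100.0, rel=1e-12)
        assert pldlr_synthesis_rate(57_516.0, P) == pytest.approx(
            P.k22 * 100.0, rel=1e-12)

    def test_reciprocal_in_pool(self):
        assert hldlr_synthesis_rate(120_000.0, P) == pytest.approx(
            hldlr_synthesis_rate(60_000.0, P) / 2.0)

    def test_zero_pool_singular(self):
        with pytest.raises(DomainError):
            hldlr_synthesis_rate(0.0, P)
        with pytest.raises(DomainError):
            pldlr_synthesis_rate(0.0, P)


@st.composite
def hill_params(draw):
    return ParameterSet.default().replace(
        ICSmax=draw(st.floats(1.0, 1e4)),
        ICt=draw(st.floats(10.0, 1e5)),
        IS=draw(st.floats(1.0, 8.0)),
        HCSmax=draw(st.floats(1.0, 1e4)),
        HCSt=draw(st.floats(10.0, 1e6)),
        HS=draw(st.floats(1.0, 8.0)),
        PCSmax=draw(st.floats(1.0, 1e4)),
        PPCt=draw(st.floats(10.0, 1e6)),
        PCSS=draw(st.floats(1.0, 8.0)),
        BCRmax=draw(st.floats(1.0, 1e4)),
        BCRt=draw(st.floats(10.0, 1e6)),
        BS=draw(st.floats(1.0, 8.0)),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(p=hill_params(),
       ratio=st.floats(1e-2, 1e2), factor=st.floats(1.01, 10.0))
def test_feedback_laws_monotone_decreasing(p, ratio, factor):
    """Negative-feedback synthesis falls strictly as its pool grows
    (probed around each law's own threshold, where the feedback acts)."""
    for law, thresh, vmax in (
            (intestinal_synthesis_rate, p.ICt, p.ICSmax),
            (hepatic_synthesis_rate, p.HCSt, p.HCSmax),
            (peripheral_synthesis_rate, p.PPCt, p.PCSmax)):
        lo = thresh * ratio
        a, b = law(lo, p), law(lo * factor, p)
        assert b < a <= vmax
        assert b > 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(p=hill_params(), ratio=st.floats(1e-2, 1e2),
       factor=st.floats(1.01, 10.0))
def test_biliary_feedforward_monotone_increasing(p, ratio, factor):
    """Feed-forward biliary release grows strictly with the hepatic pool."""
    lo = p.BCRt * ratio
    a, b = biliary_release_rate(lo, p), biliary_release_rate(lo * factor, p)
    assert a < b <= p.BCRmax


def test_hill_exponent_below_one_rejected():
    with pytest.raises(DomainError):
        ParameterSet.default().replace(IS=0.5)


def test_negative_rate_constant_rejected():
    with pytest.raises(DomainError):
        ParameterSet.default().replace(k5=-1.0)


def test_nonpositive_threshold_rejected():
    with pytest.raises(DomainError):
        ParameterSet.default().replace(BCRt=0.0)
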