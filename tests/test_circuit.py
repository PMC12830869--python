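"""Closed-form circuit algebra: divider, Thevenin reduction, time constants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxcircuit import (
    CircuitParameters,
    TwoStateSummary,
    capacitance_delivery_product,
    delivery_flux,
    equivalent_resistance,
    invert_summary,
    metabolic_resistance,
    steady_state,
    steady_state_pi,
    time_constant,
)
from oxcircuit.errors import CircuitDomainError, ConfigError

from conftest import random_parameter_sets

resistance = st.floats(min_value=0.05, max_value=20.0)
pressure = st.floats(min_value=20.0, max_value=150.0)
capacitance = st.floats(min_value=1.0, max_value=100.0)


@pytest.mark.parametrize(
    "Pa, Rd, Rm, expected, tol",
    [
        (100.0, 1.0, 1.0, 50.0, 1e-12),          # symmetric divider halves
        (91.9, 1.0, 1e12, 91.9, 1e-9),           # open metabolic branch
        (91.9, 1.0, 2.647, 66.70, 0.01),         # young rest operating point
    ],
)
def test_steady_state_pi_values(Pa, Rd, Rm, expected, tol):
    assert steady_state_pi(Pa, Rd, Rm) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "Rd, Rm, expected, tol",
    [
        (2.0, 2.0, 1.0, 1e-12),
        (1.0, 1e12, 1.0, 1e-9),
        (1.0, 2.647, 0.7258, 1e-4),
    ],
)
def test_equivalent_resistance_values(Rd, Rm, expected, tol):
    assert equivalent_resistance(Rd, Rm) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "C, Rd, Rm, expected, tol",
    [
        (1.0, 1.0, 1.0, 0.5, 1e-12),
        (3.0, 2.0, 2.0, 3.0, 1e-12),
        (21.22, 1.0, 2.647, 15.4, 0.1),           # young rest time constant
    ],
)
def test_time_constant_values(C, Rd, Rm, expected, tol):
    assert time_constant(C, Rd, Rm) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "Pi, Vm, expected",
    [(50.0, 25.0, 2.0), (0.0, 5.0, 0.0), (66.7, 25.2, 2.647)],
)
def test_metabolic_resistance_values(Pi, Vm, expected):
    assert metabolic_resistance(Pi, Vm) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "Pa, Pi, Rd, expected",
    [(91.9, 91.9, 0.1, 0.0), (100.0, 0.0, 2.0, 50.0), (91.9, 66.7, 1.0, 25.2)],
)
def test_delivery_flux_values(Pa, Pi, Rd, expected):
    assert delivery_flux(Pa, Pi, Rd) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "tau, Pa, Pi, expected, tol",
    [
        (1.0, 2.0, 1.0, 2.0, 1e-12),
        (15.4, 91.9, 66.7, 21.22, 0.01),          # rest-state C*Rd, young
        (9.0, 91.9, 42.5, 19.46, 0.01),           # work-state C*Rd, young
    ],
)
def test_capacitance_delivery_product_values(tau, Pa, Pi, expected, tol):
    assert capacitance_delivery_product(tau, Pa, Pi) == pytest.approx(expected, abs=tol)


def test_storage_estimates_agree_across_states(young_summary):
    """Rest- and work-derived C*Rd estimates agree within 10% — the
    single-capacitance model's internal consistency for the young cohort."""
    s = young_summary
    rest = capacitance_delivery_product(s.tau_r, s.Pa, s.Pr)
    work = capacitance_delivery_product(s.tau_w, s.Pa, s.Pw)
    assert abs(rest - work) / rest < 0.10


@pytest.mark.parametrize(
    "func, kwargs, bad",
    [
        (steady_state_pi, dict(Pa=-1.0, Rd=1.0, Rm=1.0), "Pa"),
        (steady_state_pi, dict(Pa=100.0, Rd=0.0, Rm=1.0), "Rd"),
        (steady_state_pi, dict(Pa=100.0, Rd=1.0, Rm=-2.0), "Rm"),
        (equivalent_resistance, dict(Rd=0.0, Rm=1.0), "Rd"),
        (time_constant, dict(C=-1.0, Rd=1.0, Rm=1.0), "C"),
        (metabolic_resistance, dict(Pi=50.0, Vm=0.0), "Vm"),
        (metabolic_resistance, dict(Pi=-1.0, Vm=1.0), "Pi"),
        (delivery_flux, dict(Pa=100.0, Pi=0.0, Rd=0.0), "Rd"),
        (capacitance_delivery_product, dict(tau=1.0, Pa=2.0, Pi=0.0), "Pi"),
    ],
)
def test_domain_errors_name_offender(func, kwargs, bad):
    with pytest.raises(CircuitDomainError, match=bad):
        func(**kwargs)


def test_delivery_flux_rejects_reverse_without_override():
    with pytest.raises(CircuitDomainError, match="allow_reverse"):
        delivery_flux(50.0, 60.0, 1.0)
    assert delivery_flux(50.0, 60.0, 1.0, allow_reverse=True) == pytest.approx(-10.0)


@settings(derandomize=True, max_examples=200)
@given(Pa=pressure, Rd=resistance, Rm=resistance, C=capacitance)
def test_time_constant_identities(Pa, Rd, Rm, C):
    """tau = C*Re equals C*Rd*Pi/Pa (the measurable form), and the inverse
    chain tau*Pa/Pi recovers C*Rd, all to 1e-12 relative."""
    Pi = steady_state_pi(Pa, Rd, Rm)
    tau = time_constant(C, Rd, Rm)
    assert tau == pytest.approx(C * Rd * Pi / Pa, rel=1e-12)
    assert capacitance_delivery_product(tau, Pa, Pi) == pytest.approx(C * Rd, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(Pa=pressure, Rd=resistance, Rm=resistance)
def test_kirchhoff_balance_at_steady_state(Pa, Rd, Rm):
    """Delivery flux equals consumption flux at the divider point."""
    Pi = steady_state_pi(Pa, Rd, Rm)
    assert delivery_flux(Pa, Pi, Rd) == pytest.approx(Pi / Rm, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(Pa=pressure, Rd=resistance, Rm=resistance)
def test_divider_monotonicity_and_bounds(Pa, Rd, Rm):
    Pi = steady_state_pi(Pa, Rd, Rm)
    assert 0.0 < Pi < Pa
    assert steady_state_pi(Pa, Rd, Rm * 1.01) > Pi       # increasing in Rm
    assert steady_state_pi(Pa, Rd * 1.01, Rm) < Pi       # decreasing in Rd
    Re = equivalent_resistance(Rd, Rm)
    assert Re < min(Rd, Rm)


def test_steady_state_struct_consistency():
    p = CircuitParameters(Pa=91.9, Rd=1.0, Rm=2.647, C=21.22)
    ss = steady_state(p)
    assert ss.Pi == pytest.approx(p.pi_infinity, rel=1e-12)
    assert ss.tau == pytest.approx(ss.Re * p.C, rel=1e-12)
    assert ss.Rm == pytest.approx(p.Rm, rel=1e-12)  # resistor recovered from Pi/V


class TestTwoStateSummary:
    def test_ordering_enforced(self):
        with pytest.raises(CircuitDomainError, match="ordering"):
            TwoStateSummary(Pa=80.0, Pr=40.0, Pw=50.0, tau_r=10.0, tau_w=5.0)
        with pytest.raises(CircuitDomainError, match="tau_w"):
            TwoStateSummary(Pa=80.0, Pr=50.0, Pw=40.0, tau_r=10.0, tau_w=-5.0)

    def test_dict_round_trip(self, young_summary):
        d = young_summary.to_dict()
        assert set(d) == {"Pa", "Pr", "Pw", "tau_r", "tau_w", "label"}
        assert TwoStateSummary.from_dict(d) == young_summary

    def test_from_dict_missing_key(self):
        with pytest.raises(ConfigError, match="tau_r"):
            TwoStateSummary.from_dict({"Pa": 90, "Pr": 60, "Pw": 40, "tau_w": 9})


class TestInvertSummary:
    def test_equilibria_and_time_constants_reproduced(self, young_summary):
        """Per-state inversion puts each state's divider point at the
        measured PO2 and its RC time constant at the measured value."""
        params = invert_summary(young_summary)
        s = young_summary
        assert params["rest"].pi_infinity == pytest.approx(s.Pr, rel=1e-12)
        assert params["work"].pi_infinity == pytest.approx(s.Pw, rel=1e-12)
        assert params["rest"].tau == pytest.approx(s.tau_r, rel=1e-12)
        assert params["work"].tau == pytest.approx(s.tau_w, rel=1e-12)

    def test_rest_calibrated_capacitance_is_shared(self, young_summary):
        params = invert_summary(young_summary, capacitance="rest")
        assert params["rest"].C == params["work"].C
        # the single-C work time constant carries the consistency gap
        assert params["work"].tau == pytest.approx(
            params["rest"].C * 1.0 * young_summary.Pw / young_summary.Pa, rel=1e-12)

    def test_unknown_convention_rejected(self, young_summary):
        with pytest.raises(ConfigError, match="capacitance"):
            invert_summary(young_summary, capacitance="work")


def test_randomized_identity_grid():
    """Vectorized spot-check of the algebra on a seeded random grid."""
    p = random_parameter_sets(500, seed=42)
    Pi = steady_state_pi(p["Pa"], p["Rd"], p["Rm"])
    tau = time_constant(p["C"], p["Rd"], p["Rm"])
    assert np.allclose(tau * p["Pa"] / Pi, p["C"] * p["Rd"], rtol=1e-12, atol=0.0)
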