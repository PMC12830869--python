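"""Lumped RC-circuit algebra for tissue oxygen transport.

The model maps oxygen partial pressure to voltage, oxygen flux to current,
transport barriers to resistances, and local oxygen storage to a
capacitance.  Arterial blood is an ideal pressure source ``Pa``; a delivery
resistance ``Rd`` connects it to the interstitial node, from which a
metabolic resistance ``Rm`` drains flux to the zero-potential sink
(oxygen converted to water) and a capacitance ``C`` stores oxygen.

All closed forms here are evaluated directly; the transient simulator
(:mod:`oxcircuit.dynamics`) builds on these primitives.

Units
-----
Pressures are mmHg; fluxes nL O2 cm^-3 s^-1; resistances
mmHg / (nL O2 cm^-3 s^-1) ("R-units"); capacitance nL O2 cm^-3 mmHg^-1
("C-units").  The product of an R-unit and a C-unit is a second, so every
time constant below comes out in seconds.  Absolute resistance magnitudes
are never needed: conventionally the young-cohort delivery resistance is
fixed at ``Rd = 1`` and everything downstream is a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Mapping

import numpy as np

from .errors import CircuitDomainError, ConfigError

__all__ = [
    "CircuitParameters",
    "SteadyState",
    "TwoStateSummary",
    "steady_state_pi",
    "equivalent_resistance",
    "time_constant",
    "metabolic_resistance",
    "delivery_flux",
    "capacitance_delivery_product",
    "steady_state",
    "invert_summary",
]


def _require_positive(**named) -> None:
    """Raise :class:`CircuitDomainError` naming the first non-positive argument."""
    for name, value in named.items():
        if np.any(np.asarray(value) <= 0) or np.any(~np.isfinite(np.asarray(value))):
            raise CircuitDomainError(
                f"{name} must be positive and finite, got {value!r}"
            )


def _require_nonnegative(**named) -> None:
    for name, value in named.items():
        if np.any(np.asarray(value) < 0) or np.any(~np.isfinite(np.asarray(value))):
            raise CircuitDomainError(
                f"{name} must be non-negative and finite, got {value!r}"
            )


def steady_state_pi(Pa, Rd, Rm):
    """Steady-state interstitial PO2 from the voltage-divider principle.

    With the capacitor inactive the interstitial node sits at

    .. math:: P_i = P_a \\frac{R_m}{R_d + R_m}

    strictly increasing in ``Rm`` and strictly decreasing in ``Rd``.

    Parameters
    ----------
    Pa : float or array
        Arterial PO2, mmHg.
    Rd, Rm : float or array
        Delivery and metabolic resistances, R-units.

    Returns
    -------
    float or ndarray
        Interstitial PO2, mmHg, in ``(0, Pa)``.
    """
    _require_positive(Pa=Pa, Rd=Rd, Rm=Rm)
    Pa, Rd, Rm = np.asarray(Pa), np.asarray(Rd), np.asarray(Rm)
    out = Pa * Rm / (Rd + Rm)
    return out.item() if out.ndim == 0 else out


def equivalent_resistance(Rd, Rm):
    """Thevenin equivalent resistance seen by the storage capacitor.

    Short-circuiting the pressure source leaves ``Rd`` and ``Rm`` in
    parallel: ``Re = Rd*Rm/(Rd+Rm)``, always below the smaller branch.
    """
    _require_positive(Rd=Rd, Rm=Rm)
    Rd, Rm = np.asarray(Rd), np.asarray(Rm)
    out = Rd * Rm / (Rd + Rm)
    return out.item() if out.ndim == 0 else out


def time_constant(C, Rd, Rm):
    """Transient time constant ``tau = C * Rd*Rm/(Rd+Rm)`` in seconds.

    Equals ``C * equivalent_resistance(Rd, Rm)`` and, equivalently,
    ``C * Rd * Pi/Pa`` with ``Pi`` the divider steady state — the algebraic
    identity that makes tau measurable from one steady state alone.
    """
    _require_positive(C=C)
    C = np.asarray(C)
    out = C * equivalent_resistance(Rd, Rm)
    return out.item() if np.ndim(out) == 0 else out


def metabolic_resistance(Pi, Vm):
    """Ohm's-law metabolic resistance ``Rm = Pi / Vm``.

    Defined at an operating point where consumption flux ``Vm`` drains the
    interstitial node at pressure ``Pi``; replaces the workload-dependent
    consumption characteristic by a constant resistor for that workload.
    Zero ``Pi`` gives zero resistance; zero consumption leaves the
    resistance undefined and raises.
    """
    _require_nonnegative(Pi=Pi)
    _require_positive(Vm=Vm)
    out = np.asarray(Pi) / np.asarray(Vm)
    return out.item() if out.ndim == 0 else out


def delivery_flux(Pa, Pi, Rd, *, allow_reverse: bool = False):
    """Oxygen delivery flux down the load line, ``Vd = (Pa - Pi)/Rd``.

    Zero exactly at ``Pi = Pa`` (the load line's PO2-axis intercept).
    ``Pi > Pa`` would mean oxygen flowing back into the blood, which the
    circuit has no tissue source to sustain; it is rejected unless
    ``allow_reverse=True`` is passed for exploratory use.
    """
    _require_positive(Rd=Rd)
    _require_nonnegative(Pa=Pa, Pi=Pi)
    if not allow_reverse and np.any(np.asarray(Pi) > np.asarray(Pa)):
        raise CircuitDomainError(
            f"Pi={Pi!r} exceeds Pa={Pa!r}: interstitial PO2 above arterial is "
            "unphysical here (pass allow_reverse=True to override)"
        )
    out = (np.asarray(Pa) - np.asarray(Pi)) / np.asarray(Rd)
    return out.item() if out.ndim == 0 else out


def capacitance_delivery_product(tau, Pa, Pi):
    """Infer ``C*Rd`` (seconds) from one steady state and its time constant.

    Inverts ``tau = C*Rd*Pi/Pa`` to ``C*Rd = tau*Pa/Pi``.  Because neither
    ``C`` nor ``Rd`` is measurable on its own, their product is the natural
    calibration constant; estimates from the rest and work states of the
    same muscle should agree if a single storage capacitance explains both
    transitions.
    """
    _require_positive(tau=tau, Pa=Pa, Pi=Pi)
    if np.any(np.asarray(Pi) > np.asarray(Pa)):
        raise CircuitDomainError(f"Pi={Pi!r} exceeds Pa={Pa!r}")
    out = np.asarray(tau) * np.asarray(Pa) / np.asarray(Pi)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class CircuitParameters:
    """One complete lumped circuit: source, two resistances, storage.

    Attributes
    ----------
    Pa : float
        Arterial PO2, mmHg (ideal source).
    Rd : float
        Delivery resistance, R-units.
    Rm : float
        Metabolic resistance for the represented workload state, R-units.
    C : float
        Oxygen storage capacitance, C-units.
    """

    Pa: float
    Rd: float
    Rm: float
    C: float

    def __post_init__(self):
        _require_positive(Pa=self.Pa, Rd=self.Rd, Rm=self.Rm, C=self.C)

    @property
    def pi_infinity(self) -> float:
        """Divider steady-state interstitial PO2, mmHg."""
        return steady_state_pi(self.Pa, self.Rd, self.Rm)

    @property
    def tau(self) -> float:
        """RC time constant, s."""
        return time_constant(self.C, self.Rd, self.Rm)

    def to_dict(self) -> dict:
        return {"Pa": self.Pa, "Rd": self.Rd, "Rm": self.Rm, "C": self.C}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CircuitParameters":
        try:
            return cls(Pa=float(d["Pa"]), Rd=float(d["Rd"]),
                       Rm=float(d["Rm"]), C=float(d["C"]))
        except KeyError as e:
            raise ConfigError(f"missing circuit parameter key {e.args[0]!r}") from e


@dataclass(frozen=True)
class SteadyState:
    """Operating point of the circuit.

    ``tau`` is ``None`` when no capacitance was involved in deriving the
    point (e.g. a load-line/consumption-curve intersection).
    """

    Pi: float
    V: float
    Re: float
    tau: float | None = None

    @property
    def Rm(self) -> float:
        """Implied metabolic resistance Pi/V at this operating point."""
        return metabolic_resistance(self.Pi, self.V)


def steady_state(params: CircuitParameters) -> SteadyState:
    """Full steady-state solution (Pi, flux, Thevenin Re, tau) of a circuit."""
    Pi = params.pi_infinity
    return SteadyState(
        Pi=Pi,
        V=delivery_flux(params.Pa, Pi, params.Rd),
        Re=equivalent_resistance(params.Rd, params.Rm),
        tau=params.tau,
    )


@dataclass(frozen=True)
class TwoStateSummary:
    """The five measurables characterising one cohort's rest/work behaviour.

    ``Pa`` arterial PO2; ``Pr``/``Pw`` steady interstitial PO2 at rest and
    during work; ``tau_w`` the rest-to-work onset time constant; ``tau_r``
    the work-to-rest recovery time constant (all mmHg / seconds).  The
    physiological ordering ``Pa > Pr > Pw > 0`` is enforced.
    """

    Pa: float
    Pr: float
    Pw: float
    tau_r: float
    tau_w: float
    label: str = ""

    def __post_init__(self):
        _require_positive(Pa=self.Pa, Pr=self.Pr, Pw=self.Pw,
                          tau_r=self.tau_r, tau_w=self.tau_w)
        if not (self.Pa > self.Pr > self.Pw):
            raise CircuitDomainError(
                f"ordering Pa > Pr > Pw violated: "
                f"Pa={self.Pa}, Pr={self.Pr}, Pw={self.Pw}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TwoStateSummary":
        try:
            return cls(
                Pa=float(d["Pa"]), Pr=float(d["Pr"]), Pw=float(d["Pw"]),
                tau_r=float(d["tau_r"]), tau_w=float(d["tau_w"]),
                label=str(d.get("label", "")),
            )
        except KeyError as e:
            raise ConfigError(f"missing summary key {e.args[0]!r}") from e


def invert_summary(
    summary: TwoStateSummary,
    Rd: float = 1.0,
    capacitance: str = "per-state",
) -> dict[str, CircuitParameters]:
    """Invert a two-state summary into rest and work circuit parameters.

    The measurables pin down the resistances relative to ``Rd``
    (``Rr/Rd = Pr/(Pa-Pr)``, ``Rw/Rd = Pw/(Pa-Pw)``) and, per state, the
    product ``C*Rd = tau*Pa/Pi``.

    A single capacitance cannot in general reproduce both measured time
    constants — the rest- and work-derived ``C*Rd`` estimates differ by the
    model-consistency gap (about 8% young, 19% old in the reference
    cohorts).  Two conventions are offered:

    ``capacitance="per-state"`` (default)
        Each state gets the effective capacitance that reproduces its own
        measured time constant, so simulated traces carry exactly the
        measured onset/offset kinetics (this is what measured traces look
        like, and what round-trip extraction tests assume).

    ``capacitance="rest"``
        Strict single-C circuit calibrated on the rest state (the baseline
        equilibrium); the work-state time constant then comes out as
        ``C*Rd*Pw/Pa`` and absorbs the whole consistency gap.

    Returns
    -------
    dict
        ``{"rest": CircuitParameters, "work": CircuitParameters}``.
    """
    if capacitance not in ("per-state", "rest"):
        raise ConfigError(
            f"capacitance must be 'per-state' or 'rest', got {capacitance!r}"
        )
    _require_positive(Rd=Rd)
    s = summary
    Rr = Rd * s.Pr / (s.Pa - s.Pr)
    Rw = Rd * s.Pw / (s.Pa - s.Pw)
    C_rest = capacitance_delivery_product(s.tau_r, s.Pa, s.Pr) / Rd
    if capacitance == "per-state":
        C_work = capacitance_delivery_product(s.tau_w, s.Pa, s.Pw) / Rd
    else:
        C_work = C_rest
    return {
        "rest": CircuitParameters(Pa=s.Pa, Rd=Rd, Rm=Rr, C=C_rest),
        "work": CircuitParameters(Pa=s.Pa, Rd=Rd, Rm=Rw, C=C_work),
    }
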