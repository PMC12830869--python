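"""Interstitial PO2 transients through rest-work-recovery protocols.

Metabolic state switches are modelled as instantaneous (cellular
respiration adjusts within ~1 s, far faster than the several-second PO2
transients), so within each protocol segment the node relaxes
exponentially toward that segment's divider steady state:

    P(t) = P_inf + (P0 - P_inf) * exp(-t / tau),   tau = C * Rd||Rm.

`simulate_protocol` chains these closed forms with PO2 continuity at the
switch instants.  `simulate_nonlinear` integrates the same storage balance

    C * dPi/dt = (Pa - Pi)/Rd - V(Pi)

with an arbitrary consumption characteristic V(.) using a fixed-step
classical Runge-Kutta scheme (reproducible across platforms, no adaptive
stepping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .circuit import CircuitParameters
from .errors import CircuitDomainError, ConfigError, DataError, IntegrationError

__all__ = [
    "Segment",
    "Protocol",
    "PO2Trace",
    "rest_work_recovery",
    "analytic_transition",
    "simulate_protocol",
    "simulate_nonlinear",
]

#: Default sampling interval, s (>= 90 samples per shortest reference
#: time constant).
DEFAULT_DT = 0.1


@dataclass(frozen=True)
class Segment:
    """One protocol phase: ``state`` names the metabolic condition that a
    parameter map must resolve; ``phase`` is the label stamped on samples
    (defaults to ``state`` — distinct labels let a recovery segment reuse
    the rest-state parameters)."""

    duration: float
    state: str
    phase: str | None = None

    def __post_init__(self):
        if self.duration < 0:
            raise DataError(f"segment duration must be >= 0, got {self.duration}")
        if self.phase is None:
            object.__setattr__(self, "phase", self.state)


@dataclass(frozen=True)
class Protocol:
    """Ordered segments plus a common sampling interval."""

    segments: tuple[Segment, ...]
    sampling_interval: float = DEFAULT_DT

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise DataError("protocol needs at least one segment")
        if self.sampling_interval <= 0:
            raise DataError("sampling_interval must be positive")
        positive = [s.duration for s in self.segments if s.duration > 0]
        if not positive:
            raise DataError("protocol needs at least one positive-duration segment")
        if self.sampling_interval > min(positive):
            raise DataError(
                "sampling_interval exceeds the shortest positive segment duration"
            )

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def states(self) -> set[str]:
        return {s.state for s in self.segments}


def rest_work_recovery(rest: float = 10.0, work: float = 90.0,
                       recovery: float = 150.0,
                       sampling_interval: float = DEFAULT_DT) -> Protocol:
    """The standard stimulation protocol: baseline rest, a work bout, and a
    recovery period back at the resting metabolic state (default
    10 s / 90 s / 150 s)."""
    return Protocol(
        segments=(
            Segment(rest, "rest", "rest"),
            Segment(work, "work", "work"),
            Segment(recovery, "rest", "recovery"),
        ),
        sampling_interval=sampling_interval,
    )


@dataclass
class PO2Trace:
    """A sampled interstitial PO2 time course with per-sample phase labels."""

    times: np.ndarray
    po2: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.times.size == self.po2.size == self.phase.size):
            raise DataError("times, po2 and phase must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def segment(self, phase: str) -> "PO2Trace":
        """Sub-trace of all samples stamped with ``phase``."""
        mask = self.phase == phase
        if not np.any(mask):
            raise DataError(f"trace has no samples in phase {phase!r}")
        return PO2Trace(self.times[mask], self.po2[mask], self.phase[mask])

    def phases(self) -> list[str]:
        seen: list[str] = []
        for p in self.phase:
            if p not in seen:
                seen.append(p)
        return seen


def analytic_transition(P0: float, params: CircuitParameters, t) -> float:
    """Closed-form relaxation from ``P0`` toward the circuit's steady state.

    ``P(t) = P_inf + (P0 - P_inf) exp(-t/tau)`` with ``P_inf`` the divider
    value and ``tau = C * Rd||Rm``.  ``t`` may be a scalar or array of
    non-negative times (s).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise CircuitDomainError(f"time must be >= 0, got {t!r}")
    P_inf = params.pi_infinity
    out = P_inf + (P0 - P_inf) * np.exp(-t / params.tau)
    return out.item() if out.ndim == 0 else out


def _check_shared(params_by_state: Mapping[str, CircuitParameters],
                  states: set[str],
                  allow_state_capacitance: bool) -> None:
    missing = states - set(params_by_state)
    if missing:
        raise ConfigError(
            f"protocol states {sorted(missing)} not found in parameter map "
            f"(available: {sorted(params_by_state)})"
        )
    ref = params_by_state[next(iter(sorted(states)))]
    for label in sorted(states):
        p = params_by_state[label]
        for attr in ("Pa", "Rd"):
            if not np.isclose(getattr(p, attr), getattr(ref, attr),
                              rtol=1e-9, atol=0.0):
                raise ConfigError(
                    f"{attr} differs across states ({label!r}: {getattr(p, attr)} "
                    f"vs {getattr(ref, attr)}): only Rm may switch"
                )
        if not allow_state_capacitance and not np.isclose(p.C, ref.C,
                                                          rtol=1e-9, atol=0.0):
            raise ConfigError(
                f"C differs across states ({label!r}: {p.C} vs {ref.C}); a "
                "single storage capacitance is required unless "
                "allow_state_capacitance=True (per-state effective C)"
            )


def simulate_protocol(start: float, protocol: Protocol,
                      params_by_state: Mapping[str, CircuitParameters],
                      *, allow_state_capacitance: bool = False) -> PO2Trace:
    """Piecewise-exponential simulation of a switching protocol.

    The metabolic resistance jumps instantaneously between segment states
    while PO2 stays continuous; within each segment the closed-form
    relaxation applies.  ``Pa`` and ``Rd`` must be shared across states.
    By default a single shared ``C`` is required too; passing
    ``allow_state_capacitance=True`` admits a per-state effective
    capacitance, which is how measured traces (whose onset and offset time
    constants disagree with a single-C circuit by the model-consistency
    gap) are emulated.

    Sampling is on the uniform grid ``k * sampling_interval`` from 0 to
    the total duration inclusive; samples at a switch instant belong to
    the incoming segment.  Zero-duration segments are no-ops.
    """
    if start < 0:
        raise CircuitDomainError(f"start PO2 must be >= 0, got {start}")
    _check_shared(params_by_state, protocol.states(), allow_state_capacitance)

    dt = protocol.sampling_interval
    segs = [s for s in protocol.segments if s.duration > 0]
    starts = np.concatenate([[0.0], np.cumsum([s.duration for s in segs])])
    total = starts[-1]
    n = int(round(total / dt))
    times = np.arange(n + 1) * dt

    # PO2 at each segment boundary, by chaining the closed form
    p_at = [float(start)]
    for seg, t0 in zip(segs, starts[:-1]):
        p_at.append(float(analytic_transition(
            p_at[-1], params_by_state[seg.state], seg.duration)))

    po2 = np.empty_like(times)
    phase = np.empty(times.size, dtype=object)
    # boundary samples belong to the incoming segment
    idx = np.minimum(np.searchsorted(starts, times, side="right") - 1,
                     len(segs) - 1)
    for j, seg in enumerate(segs):
        m = idx == j
        po2[m] = analytic_transition(p_at[j], params_by_state[seg.state],
                                     times[m] - starts[j])
        phase[m] = seg.phase
    return PO2Trace(times=times, po2=po2, phase=phase)


def simulate_nonlinear(start: float, protocol: Protocol, line, C: float,
                       curves_by_state: Mapping, *,
                       substeps: int = 10) -> PO2Trace:
    """Integrate the storage balance with a nonlinear consumption branch.

    Solves ``C dPi/dt = (Pa - Pi)/Rd - V(Pi)`` with the segment's
    consumption characteristic ``V`` (any object with a ``vo2`` method, or
    a callable), using the classical fixed-step 4th-order Runge-Kutta
    scheme at step ``sampling_interval / substeps``.  Raises
    :class:`IntegrationError` if the state leaves ``[-1, Pa + 1]`` mmHg,
    the signature of an unstable step.
    """
    if C <= 0:
        raise CircuitDomainError(f"C must be positive, got {C}")
    if start < 0:
        raise CircuitDomainError(f"start PO2 must be >= 0, got {start}")
    states = protocol.states()
    missing = states - set(curves_by_state)
    if missing:
        raise ConfigError(
            f"protocol states {sorted(missing)} not found in curve map"
        )

    def rhs(P, vo2):
        return (line.flux(P) - vo2(max(P, 0.0))) / C

    dt = protocol.sampling_interval
    h = dt / substeps
    segs = [s for s in protocol.segments if s.duration > 0]

    times_all, po2_all, phase_all = [], [], []
    P = float(start)
    t_global = 0.0
    first = True
    for seg in segs:
        vo2 = curves_by_state[seg.state]
        vo2 = vo2.vo2 if hasattr(vo2, "vo2") else vo2
        n_samples = int(round(seg.duration / dt))
        for k in range(n_samples + 1):
            if k == 0:
                if first:
                    times_all.append(t_global)
                    po2_all.append(P)
                    phase_all.append(seg.phase)
                    first = False
                continue
            for _ in range(substeps):
                k1 = rhs(P, vo2)
                k2 = rhs(P + 0.5 * h * k1, vo2)
                k3 = rhs(P + 0.5 * h * k2, vo2)
                k4 = rhs(P + h * k3, vo2)
                P += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not (-1.0 <= P <= line.Pa + 1.0):
                raise IntegrationError(
                    f"PO2 left [-1, Pa+1] at t={t_global + k * dt:.3f} s "
                    f"(P={P:.3g}); reduce the step (increase substeps)"
                )
            times_all.append(t_global + k * dt)
            po2_all.append(min(max(P, 0.0), line.Pa))
            phase_all.append(seg.phase)
        t_global += n_samples * dt
    return PO2Trace(times=np.asarray(times_all), po2=np.asarray(po2_all),
                    phase=np.asarray(phase_all, dtype=object))
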