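"""Workload-dependent oxygen consumption and the load-line operating point.

At the interstitial node, delivery follows the linear load line
``Vd = (Pa - Pi)/Rd`` while consumption follows a sigmoid VO2(PO2)
characteristic (one Hill curve per workload).  Kirchhoff's balance picks
the unique intersection of the two — the operating point — and the
constant resistor ``Rm = Pi/V`` defined there makes the nonlinear branch
equivalent to a plain resistor for that workload.

Oxygen disappearance curves (PO2 decay after abrupt flow arrest) give the
empirical route to the same characteristic: ``VO2(P) = -alpha * dP/dt``
with ``alpha`` the tissue Bunsen solubility coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .circuit import SteadyState, equivalent_resistance, metabolic_resistance
from .errors import CircuitDomainError, DataError

__all__ = [
    "HillCurve",
    "LinearConsumption",
    "LoadLine",
    "ODCRecord",
    "ODCResult",
    "hill_vo2",
    "operating_point",
    "odc_vo2",
    "fit_load_line",
]


@dataclass(frozen=True)
class HillCurve:
    """Sigmoid consumption characteristic ``V(P) = Vmax P^n / (P50^n + P^n)``.

    ``Vmax`` is the asymptotic consumption for the workload, ``P50`` the
    half-saturation PO2, ``n >= 1`` the Hill exponent.  ``Vmax = 0`` is
    admitted as the no-consumption limit.
    """

    Vmax: float
    P50: float
    n: float = 1.0
    workload_label: str = ""

    def __post_init__(self):
        if self.Vmax < 0:
            raise CircuitDomainError(f"Vmax must be >= 0, got {self.Vmax}")
        if self.P50 <= 0:
            raise CircuitDomainError(f"P50 must be positive, got {self.P50}")
        if self.n < 1:
            raise CircuitDomainError(f"Hill exponent n must be >= 1, got {self.n}")

    def vo2(self, P):
        return hill_vo2(self, P)

    def to_dict(self) -> dict:
        return {"Vmax": self.Vmax, "P50": self.P50, "n": self.n,
                "workload_label": self.workload_label}

    @classmethod
    def from_dict(cls, d) -> "HillCurve":
        return cls(Vmax=float(d["Vmax"]), P50=float(d["P50"]),
                   n=float(d.get("n", 1.0)),
                   workload_label=str(d.get("workload_label", "")))

    @classmethod
    def through_point(cls, P: float, V: float, P50: float, n: float = 2.0,
                      workload_label: str = "") -> "HillCurve":
        """Construct the curve with given shape passing through ``(P, V)``.

        Solves ``V = Vmax P^n/(P50^n + P^n)`` for ``Vmax``; handy for
        building a workload characteristic that reproduces a known
        operating point.
        """
        if P <= 0 or V <= 0:
            raise CircuitDomainError("anchor point must have P > 0 and V > 0")
        Vmax = V * (P50 ** n + P ** n) / P ** n
        return cls(Vmax=Vmax, P50=P50, n=n, workload_label=workload_label)


@dataclass(frozen=True)
class LinearConsumption:
    """Resistor-like consumption branch ``V(P) = P / Rm``.

    The constant-resistor equivalent of a workload characteristic at its
    operating point; accepted anywhere a consumption curve is.
    """

    Rm: float
    workload_label: str = ""

    def __post_init__(self):
        if self.Rm <= 0:
            raise CircuitDomainError(f"Rm must be positive, got {self.Rm}")

    def vo2(self, P):
        P = np.asarray(P, dtype=float)
        if np.any(P < 0):
            raise CircuitDomainError(f"PO2 must be >= 0, got {P!r}")
        out = P / self.Rm
        return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class LoadLine:
    """Delivery constraint ``V = (Pa - Pi)/Rd``: slope -1/Rd, Pi-intercept Pa."""

    Pa: float
    Rd: float

    def __post_init__(self):
        if self.Pa <= 0 or self.Rd <= 0:
            raise CircuitDomainError(
                f"load line requires Pa > 0 and Rd > 0, got Pa={self.Pa}, Rd={self.Rd}"
            )

    def flux(self, Pi):
        return (self.Pa - np.asarray(Pi, dtype=float)) / self.Rd


def hill_vo2(curve: HillCurve, P):
    """Evaluate a Hill consumption curve at PO2 ``P`` (mmHg, >= 0)."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise CircuitDomainError(f"PO2 must be >= 0, got {P!r}")
    with np.errstate(invalid="ignore"):
        Pn = P ** curve.n
        out = np.where(P > 0, curve.Vmax * Pn / (curve.P50 ** curve.n + Pn), 0.0)
    return out.item() if out.ndim == 0 else out


def operating_point(line: LoadLine, curve) -> SteadyState:
    """Intersection of the load line with a consumption characteristic.

    Delivery dominates at ``Pi = 0`` and consumption at ``Pi = Pa``, and
    the two branches are strictly monotone in opposite directions, so a
    unique root of ``(Pa - Pi)/Rd - V(Pi)`` exists on ``[0, Pa]``; it is
    bracketed and polished with Brent's method to 1e-12 mmHg.

    Returns a :class:`SteadyState` whose ``Rm`` property carries the
    constant-resistor replacement ``Pi/V`` of the consumption branch.
    ``tau`` is ``None`` (no capacitance involved).
    """
    vo2 = curve.vo2 if hasattr(curve, "vo2") else curve

    def residual(Pi):
        return line.flux(Pi) - vo2(Pi)

    top = residual(line.Pa)
    if top >= 0.0:
        # no consumption at Pa (e.g. Vmax = 0): node floats up to the source
        Pi = line.Pa
    else:
        Pi = optimize.brentq(residual, 0.0, line.Pa, xtol=1e-12, rtol=1e-15,
                             maxiter=200)
    V = vo2(Pi)
    Re = equivalent_resistance(line.Rd, metabolic_resistance(Pi, V)) if V > 0 \
        else line.Rd
    return SteadyState(Pi=float(Pi), V=float(V), Re=float(Re), tau=None)


@dataclass(frozen=True)
class ODCRecord:
    """Oxygen disappearance curve: PO2 decay after flow arrest.

    ``alpha`` is the tissue Bunsen O2 solubility coefficient
    (nL O2 cm^-3 mmHg^-1) converting the decay slope into consumption.
    """

    times: np.ndarray
    po2: np.ndarray
    alpha: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.po2, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "po2", p)
        if t.size != p.size:
            raise DataError("times and po2 must have equal length")
        if t.size < 3:
            raise DataError(f"need at least 3 samples, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        if self.alpha <= 0:
            raise CircuitDomainError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class ODCResult:
    """Pointwise VO2(P) from an ODC plus the initial-slope consumption."""

    po2: np.ndarray
    vo2: np.ndarray
    initial_vo2: float


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0 or window < 3:
        raise DataError(f"smoothing window must be odd and >= 3, got {window}")
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(yp, kernel, mode="valid")


def odc_vo2(rec: ODCRecord, *, smooth_window: int | None = None,
            initial_samples: int = 5) -> ODCResult:
    """Differentiate an oxygen disappearance curve into VO2(P) points.

    ``VO2 = -alpha * dP/dt`` by central differences (one-sided at the
    ends), paired with the local PO2.  The separately reported
    ``initial_vo2`` is the regression slope of the first
    ``initial_samples`` samples times ``-alpha`` — the conventional
    "initial slope" estimate of consumption at the pre-arrest PO2.

    Smoothing (odd-window moving average) is off by default; raw
    differentiation is the reference behaviour.
    """
    p = rec.po2
    if smooth_window is not None:
        p = _moving_average(p, smooth_window)
    dpdt = np.gradient(p, rec.times)
    vo2 = -rec.alpha * dpdt

    k = min(initial_samples, rec.times.size)
    if k < 2:
        raise DataError("need at least 2 samples for the initial slope")
    slope = stats.linregress(rec.times[:k], rec.po2[:k]).slope
    return ODCResult(po2=p.copy(), vo2=vo2, initial_vo2=float(-rec.alpha * slope))


def fit_load_line(points) -> LoadLine:
    """Least-squares load line through steady-state ``(Pi, V)`` points.

    Fits ``V = a + b*Pi`` and maps to the line's physical parameters:
    ``Rd = -1/b`` and ``Pa = a*Rd``.  The geometry only makes sense for a
    descending line, so a non-negative fitted slope is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("points must be an (n, 2) array of (Pi, V)")
    Pi, V = pts[:, 0], pts[:, 1]
    if np.unique(Pi).size < 2:
        raise DataError("need at least 2 distinct Pi values")
    slope, intercept = np.polyfit(Pi, V, 1)
    if slope >= 0:
        raise DataError(
            f"fitted slope {slope:.4g} is non-negative: points do not lie on a "
            "descending delivery line"
        )
    Rd = -1.0 / slope
    return LoadLine(Pa=float(intercept * Rd), Rd=float(Rd))
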