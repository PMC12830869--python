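"""Estimation of steady levels and time constants from PO2 traces.

Observed interstitial PO2 transitions are monoexponential per metabolic
state, so each transition segment is summarised by three numbers
``(P_start, P_inf, tau)`` fitted by unweighted nonlinear least squares.
`extract_two_state` applies this to a full rest-work-recovery trace and
returns the five measurables of a cohort summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .circuit import TwoStateSummary
from .dynamics import PO2Trace, Protocol
from .errors import (
    CircuitDomainError,
    DataError,
    DegenerateSegmentError,
    FitError,
    InconsistentTraceError,
)

__all__ = ["ExponentialFit", "fit_exponential", "extract_two_state",
           "TwoStateDiagnostics"]


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a monoexponential segment fit (all mmHg / seconds)."""

    P_start: float
    P_inf: float
    tau: float
    rmse: float


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Derivative-free starting point.

    Asymptote from the mean of the final 20% of the segment, start level
    from the first sample, and tau from a log-linear regression of
    ``|y - P_inf0|`` over the first 60% (falling back to a third of the
    span when the log-regression is unusable).
    """
    span = t[-1] - t[0]
    n = t.size
    p_inf0 = float(np.mean(y[max(n - max(n // 5, 1), 1):]))
    p_start0 = float(y[0])
    k = max(int(0.6 * n), 3)
    d = np.abs(y[:k] - p_inf0)
    mask = d > 1e-12
    tau0 = span / 3.0
    if mask.sum() >= 2:
        res = stats.linregress(t[:k][mask] - t[0], np.log(d[mask]))
        if res.slope < 0:
            tau0 = -1.0 / res.slope
    return p_start0, p_inf0, tau0


def fit_exponential(segment: PO2Trace, *, max_iter: int = 500) -> ExponentialFit:
    """Fit ``P(t) = P_inf + (P_start - P_inf) exp(-t/tau)`` to a segment.

    Times are referenced to the segment's first sample.  Convergence is
    declared at a relative parameter change below 1e-10 (scipy ``xtol``)
    within ``max_iter`` residual evaluations; uniform weights.

    Raises
    ------
    DataError
        Fewer than 5 samples.
    DegenerateSegmentError
        Flat segment (variance below 1e-12): no transition to fit.
    FitError
        Non-convergence (carries the last iterate) or a non-positive
        fitted tau, which marks the segment as non-exponential.
    """
    t = segment.times - segment.times[0]
    y = segment.po2
    if t.size < 5:
        raise DataError(f"need at least 5 samples to fit, got {t.size}")
    if float(np.var(y)) < 1e-12:
        raise DegenerateSegmentError(
            "segment is flat (variance < 1e-12); nothing to fit"
        )

    def residual(p):
        p_start, p_inf, tau = p
        # clip the exponent so LM exploration of pathological tau values
        # cannot overflow; the optimum is unaffected
        return p_inf + (p_start - p_inf) * np.exp(np.clip(-t / tau, -700.0,
                                                          700.0)) - y

    x0 = np.asarray(_initial_guess(t, y))
    res = optimize.least_squares(residual, x0, method="lm",
                                 xtol=1e-10, ftol=1e-15, gtol=1e-15,
                                 max_nfev=max_iter)
    if not res.success:
        raise FitError(f"exponential fit did not converge: {res.message}",
                       last_iterate=res.x)
    p_start, p_inf, tau = res.x
    if tau <= 0:
        raise FitError(
            f"fitted tau = {tau:.4g} s is non-positive: segment is not a "
            "decaying exponential", last_iterate=res.x)
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    return ExponentialFit(P_start=float(p_start), P_inf=float(p_inf),
                          tau=float(tau), rmse=rmse)


@dataclass(frozen=True)
class TwoStateDiagnostics:
    """Fit-quality report accompanying an extracted summary.

    ``recovery_P_inf`` is the freely-estimated recovery asymptote; its gap
    to the baseline mean ``Pr`` is a diagnostic of incomplete recovery,
    not a constraint imposed on the fit.
    """

    work_fit: ExponentialFit
    recovery_fit: ExponentialFit
    baseline_sd: float

    @property
    def recovery_P_inf(self) -> float:
        return self.recovery_fit.P_inf

    @property
    def rmse_by_segment(self) -> dict[str, float]:
        return {"work": self.work_fit.rmse, "recovery": self.recovery_fit.rmse}


def extract_two_state(trace: PO2Trace, protocol: Protocol, Pa: float, *,
                      label: str = "",
                      baseline_phase: str = "rest",
                      work_phase: str = "work",
                      recovery_phase: str = "recovery",
                      return_diagnostics: bool = False):
    """Extract ``(Pr, Pw, tau_w, tau_r)`` from a rest-work-recovery trace.

    The baseline is assumed at equilibrium, so ``Pr`` is the plain mean of
    the baseline phase.  The work-onset segment is fitted for ``Pw``
    (asymptote) and ``tau_w``; the recovery segment for ``tau_r`` with a
    freely-estimated asymptote reported as a diagnostic.

    Returns a :class:`~oxcircuit.circuit.TwoStateSummary`, or
    ``(summary, TwoStateDiagnostics)`` when ``return_diagnostics=True``.
    """
    if Pa <= 0:
        raise CircuitDomainError(f"Pa must be positive, got {Pa}")
    for ph in (baseline_phase, work_phase, recovery_phase):
        if ph not in trace.phases():
            raise DataError(f"trace is missing required phase {ph!r}")

    baseline = trace.segment(baseline_phase)
    Pr = float(np.mean(baseline.po2))
    work_fit = fit_exponential(trace.segment(work_phase))
    recovery_fit = fit_exponential(trace.segment(recovery_phase))
    Pw = work_fit.P_inf

    if Pr <= Pw:
        raise InconsistentTraceError(
            f"extracted Pr = {Pr:.3g} <= Pw = {Pw:.3g}: trace is inconsistent "
            "with a rest-work transition"
        )
    summary = TwoStateSummary(Pa=Pa, Pr=Pr, Pw=Pw, tau_r=recovery_fit.tau,
                              tau_w=work_fit.tau, label=label)
    if return_diagnostics:
        return summary, TwoStateDiagnostics(
            work_fit=work_fit, recovery_fit=recovery_fit,
            baseline_sd=float(np.std(baseline.po2)))
    return summary
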