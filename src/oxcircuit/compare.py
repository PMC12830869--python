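"""Dimensionless ratio analysis of two-state summaries.

Everything here is closed-form circuit algebra on the five measurables
``(Pa, Pr, Pw, tau_r, tau_w)``:

* within-cohort ratios — the time-constant ratio ``tau_r/tau_w`` and its
  model prediction ``Pr/Pw``, the state resistances relative to delivery
  ``Rr/Rd = Pr/(Pa-Pr)`` and ``Rw/Rd = Pw/(Pa-Pw)``, their quotient
  ``Rr/Rw``, and the work/rest consumption gain
  ``Vw/Vr = (Rd+Rr)/(Rd+Rw)``;
* the storage-model consistency diagnostic — the percentage by which the
  time-constant ratio exceeds the PO2 ratio (zero when a single storage
  capacitance fully explains the kinetics);
* the between-cohort (young = index 1, old = index 2) conversion — the
  delivery-resistance ratio from each state's time constants,
  ``Rd2/Rd1 = (tau2 * P1 * Pa2)/(tau1 * P2 * Pa1)``, and the consumption
  ratios ``V2/V1 = (Pa2/Pa1) * (Rd1+Rm1)/(Rd2+Rm2)``.

Unrounded values are retained everywhere; display rounding (one decimal
for ratios >= 1, two below 1, matching the conventional table typography)
is applied only at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .circuit import TwoStateSummary
from .errors import CircuitDomainError

__all__ = [
    "RatioReport",
    "AgeComparison",
    "DeliveryResistanceRatio",
    "state_ratios",
    "tau_consistency",
    "delivery_resistance_ratio",
    "age_comparison",
    "display_round",
]


def display_round(x: float) -> float:
    """Table typography: one decimal for ratios >= 1, two decimals below 1."""
    return round(x, 1) if x >= 1 else round(x, 2)


@dataclass(frozen=True)
class RatioReport:
    """The six within-cohort dimensionless ratios."""

    tau_ratio: float        # tau_r / tau_w
    p_ratio: float          # Pr / Pw
    rr_over_rd: float       # Rr / Rd
    rw_over_rd: float       # Rw / Rd
    rr_over_rw: float       # Rr / Rw
    vw_over_vr: float       # Vw / Vr
    provenance: str = ""

    def rounded(self) -> dict[str, float]:
        return {k: display_round(v) for k, v in self.to_dict().items()}

    def to_dict(self) -> dict[str, float]:
        return {
            "tau_r/tau_w": self.tau_ratio,
            "Pr/Pw": self.p_ratio,
            "Rr/Rd": self.rr_over_rd,
            "Rw/Rd": self.rw_over_rd,
            "Rr/Rw": self.rr_over_rw,
            "Vw/Vr": self.vw_over_vr,
        }


class DeliveryResistanceRatio(NamedTuple):
    """Old/young delivery-resistance ratio: the two independent state-based
    sub-estimates and their arithmetic mean."""

    rest_based: float
    work_based: float
    average: float


@dataclass(frozen=True)
class AgeComparison:
    """Old-to-young (index 2 over index 1) parameter ratios.

    ``rd_ratio`` is the averaged delivery-resistance estimate; the two
    sub-estimates are carried alongside so their internal agreement (a
    model-consistency check, not an assertion) stays visible.
    """

    pa_ratio: float            # Pa2 / Pa1
    rd_ratio: float            # Rd2 / Rd1 (average of sub-estimates)
    rd_rest_based: float
    rd_work_based: float
    rr_ratio: float            # Rr2 / Rr1
    rw_ratio: float            # Rw2 / Rw1
    overall_rest_ratio: float  # (Rd2+Rr2) / (Rd1+Rr1)
    overall_work_ratio: float  # (Rd2+Rw2) / (Rd1+Rw1)
    vr_ratio: float            # Vr2 / Vr1
    vw_ratio: float            # Vw2 / Vw1
    young_label: str = ""
    old_label: str = ""

    def to_dict(self) -> dict[str, float]:
        return {
            "Pa2/Pa1": self.pa_ratio,
            "Rd2/Rd1": self.rd_ratio,
            "Rr2/Rr1": self.rr_ratio,
            "Rw2/Rw1": self.rw_ratio,
            "(Rd2+Rr2)/(Rd1+Rr1)": self.overall_rest_ratio,
            "(Rd2+Rw2)/(Rd1+Rw1)": self.overall_work_ratio,
            "Vr2/Vr1": self.vr_ratio,
            "Vw2/Vw1": self.vw_ratio,
        }

    def rounded(self) -> dict[str, float]:
        return {k: display_round(v) for k, v in self.to_dict().items()}


def _check_divider(s: TwoStateSummary) -> None:
    # TwoStateSummary already enforces Pa > Pr > Pw; guard anyway so raw
    # tuples routed here fail loudly.
    if s.Pa <= s.Pr or s.Pa <= s.Pw:
        raise CircuitDomainError(
            f"Pa must exceed Pr and Pw (Pa={s.Pa}, Pr={s.Pr}, Pw={s.Pw})"
        )


def state_ratios(s: TwoStateSummary) -> RatioReport:
    """All six within-cohort ratios from the five measurables alone."""
    _check_divider(s)
    rr = s.Pr / (s.Pa - s.Pr)
    rw = s.Pw / (s.Pa - s.Pw)
    return RatioReport(
        tau_ratio=s.tau_r / s.tau_w,
        p_ratio=s.Pr / s.Pw,
        rr_over_rd=rr,
        rw_over_rd=rw,
        rr_over_rw=rr / rw,
        vw_over_vr=(1.0 + rr) / (1.0 + rw),
        provenance=s.label,
    )


def tau_consistency(s: TwoStateSummary, *, use_display_rounding: bool = False) -> float:
    """Percent excess of the time-constant ratio over the PO2 ratio.

    ``100 * (tau_r/tau_w - Pr/Pw) / (tau_r/tau_w)`` — near zero when the
    storage-capacitance model fully explains the transition kinetics.
    With ``use_display_rounding=True`` the two ratios are first rounded as
    displayed, reproducing diagnostics quoted from rounded tables.
    """
    r = state_ratios(s)
    tau_ratio, p_ratio = r.tau_ratio, r.p_ratio
    if use_display_rounding:
        tau_ratio, p_ratio = display_round(tau_ratio), display_round(p_ratio)
    return 100.0 * (tau_ratio - p_ratio) / tau_ratio


def delivery_resistance_ratio(young: TwoStateSummary,
                              old: TwoStateSummary) -> DeliveryResistanceRatio:
    """Old/young delivery-resistance ratio from each state's kinetics.

    Since ``tau = C*Rd*Pi/Pa`` per state and the storage capacitance is a
    tissue property taken as common, each state yields an independent
    estimate ``Rd2/Rd1 = (tau2 * P1 * Pa2)/(tau1 * P2 * Pa1)``; close
    agreement between the two is a consistency check and their arithmetic
    mean is the working value.
    """
    _check_divider(young)
    _check_divider(old)
    rest = (old.tau_r * young.Pr * old.Pa) / (young.tau_r * old.Pr * young.Pa)
    work = (old.tau_w * young.Pw * old.Pa) / (young.tau_w * old.Pw * young.Pa)
    return DeliveryResistanceRatio(rest_based=rest, work_based=work,
                                   average=0.5 * (rest + work))


def age_comparison(young: TwoStateSummary, old: TwoStateSummary) -> AgeComparison:
    """Full old/young comparison with the young delivery resistance as unit.

    Sets ``Rd1 = 1``, takes ``Rd2`` from the averaged state-based
    estimates, scales each cohort's metabolic resistances by its own
    ``Rd``, and forms every comparison row from unrounded intermediates.
    """
    drr = delivery_resistance_ratio(young, old)
    rd1 = 1.0
    rd2 = drr.average * rd1

    ry, ro = state_ratios(young), state_ratios(old)
    rr1, rw1 = ry.rr_over_rd * rd1, ry.rw_over_rd * rd1
    rr2, rw2 = ro.rr_over_rd * rd2, ro.rw_over_rd * rd2
    pa_ratio = old.Pa / young.Pa
    return AgeComparison(
        pa_ratio=pa_ratio,
        rd_ratio=rd2 / rd1,
        rd_rest_based=drr.rest_based,
        rd_work_based=drr.work_based,
        rr_ratio=rr2 / rr1,
        rw_ratio=rw2 / rw1,
        overall_rest_ratio=(rd2 + rr2) / (rd1 + rr1),
        overall_work_ratio=(rd2 + rw2) / (rd1 + rw1),
        vr_ratio=pa_ratio * (rd1 + rr1) / (rd2 + rr2),
        vw_ratio=pa_ratio * (rd1 + rw1) / (rd2 + rw2),
        young_label=young.label,
        old_label=old.label,
    )
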