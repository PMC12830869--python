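"""Synthetic cohorts and noisy PO2 traces.

The generator emulates the reference study conditions: cohorts summarised
as mean +/- CI95 for the five measurables (arterial PO2 over animals;
tissue PO2 levels and time constants over interstitial profiles), a
10 s rest / 90 s work / 150 s recovery stimulation protocol, and additive
Gaussian measurement noise on the PO2 samples (default SD 1 mmHg at 0.1 s
sampling).

Between-animal variability is normal and independent across parameters —
only means and CI95 are reported, so no covariance is available.  CI95
values are back-converted to population SDs via ``SD = CI95 * sqrt(n) /
1.96`` with ``n`` the relevant count (animals for Pa, profiles for tissue
parameters).  Two variance layouts are offered: ``two_level`` (default)
splits the profile-level variance equally between animals and profiles
and draws animals at ``SD/sqrt(2)``; ``flat`` puts all of it between
animals.  Draws violating the physical ordering ``Pa > Pr > Pw > 0`` or
``tau > 0`` are rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .circuit import TwoStateSummary, invert_summary
from .dynamics import PO2Trace, Protocol, rest_work_recovery, simulate_protocol
from .errors import ConfigError, DataError

__all__ = ["CohortSpec", "sample_cohort", "generate_trace", "PARAM_NAMES"]

PARAM_NAMES = ("Pa", "Pr", "Pw", "tau_r", "tau_w")

#: Default measurement noise SD, mmHg, at the default 0.1 s sampling —
#: gives transient-fit precision comparable to the reference CI95 at the
#: published profile counts.
DEFAULT_NOISE_SD = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of one cohort.

    ``mean`` and ``ci95`` map each of ``Pa, Pr, Pw, tau_r, tau_w`` to its
    cohort mean and 95% confidence half-width.  ``n_animals`` is the count
    behind the arterial PO2 summary, ``n_profiles`` the count behind the
    tissue summaries.
    """

    label: str
    n_animals: int
    n_profiles: int
    mean: Mapping[str, float]
    ci95: Mapping[str, float]
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None

    def __post_init__(self):
        if self.n_animals < 2:
            raise DataError(f"n_animals must be >= 2, got {self.n_animals}")
        if self.n_profiles < 2:
            raise DataError(f"n_profiles must be >= 2, got {self.n_profiles}")
        for k in PARAM_NAMES:
            if k not in self.mean:
                raise ConfigError(f"mean is missing key {k!r}")
            if k not in self.ci95:
                raise ConfigError(f"ci95 is missing key {k!r}")
            if self.mean[k] <= 0:
                raise DataError(f"mean[{k!r}] must be positive")
            if self.ci95[k] < 0:
                raise DataError(f"ci95[{k!r}] must be >= 0")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")

    def population_sd(self, name: str) -> float:
        """Back-convert a CI95 half-width into the population SD."""
        n = self.n_animals if name == "Pa" else self.n_profiles
        return self.ci95[name] * np.sqrt(n) / 1.96


def _valid(draw: dict[str, float]) -> bool:
    return (draw["Pa"] > draw["Pr"] > draw["Pw"] > 0
            and draw["tau_r"] > 0 and draw["tau_w"] > 0)


def sample_cohort(spec: CohortSpec, size: int | None = None, *,
                  mode: str = "two_level",
                  rng: np.random.Generator | None = None,
                  max_resamples: int = 1000) -> list[TwoStateSummary]:
    """Draw per-animal summaries from a cohort specification.

    ``size`` defaults to ``spec.n_animals``.  In ``two_level`` mode
    (default) tissue parameters are drawn at the between-animal share of
    the variance (equal split, i.e. ``SD/sqrt(2)``); ``flat`` mode uses
    the full back-converted SD.  Each animal's five parameters are drawn
    jointly and redrawn (up to ``max_resamples`` times) until the physical
    ordering holds; a spec so wide that this keeps failing is rejected as
    incoherent.  Deterministic for a fixed ``rng``/``spec.seed``.
    """
    if mode not in ("two_level", "flat"):
        raise ConfigError(f"mode must be 'two_level' or 'flat', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = spec.n_animals if size is None else int(size)
    if size < 1:
        raise DataError("size must be >= 1")

    sds = {}
    for name in PARAM_NAMES:
        sd = spec.population_sd(name)
        if mode == "two_level" and name != "Pa":
            sd /= np.sqrt(2.0)
        sds[name] = sd

    out: list[TwoStateSummary] = []
    for i in range(size):
        for attempt in range(max_resamples):
            draw = {name: rng.normal(spec.mean[name], sds[name])
                    for name in PARAM_NAMES}
            if _valid(draw):
                break
        else:
            raise DataError(
                f"could not draw a physically ordered parameter set in "
                f"{max_resamples} attempts: spec {spec.label!r} is incoherent"
            )
        out.append(TwoStateSummary(label=f"{spec.label}-{i:04d}", **draw))
    return out


def generate_trace(summary: TwoStateSummary,
                   protocol: Protocol | None = None,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   seed: int | None = None, *,
                   rng: np.random.Generator | None = None,
                   capacitance: str = "per-state") -> PO2Trace:
    """Simulate one noisy trace realising a cohort summary.

    The summary is inverted to circuit parameters (young-style ``Rd = 1``
    reference; resistances from the divider relations; capacitance per
    the ``capacitance`` convention of
    :func:`~oxcircuit.circuit.invert_summary`), simulated through the
    protocol starting at the resting equilibrium ``Pr``, and overlaid
    with i.i.d. Gaussian measurement noise.  Deterministic under a fixed
    ``seed``.
    """
    if noise_sd < 0:
        raise DataError("noise_sd must be >= 0")
    if protocol is None:
        protocol = rest_work_recovery()
    params = invert_summary(summary, Rd=1.0, capacitance=capacitance)
    trace = simulate_protocol(summary.Pr, protocol, params,
                              allow_state_capacitance=(capacitance == "per-state"))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        trace = PO2Trace(times=trace.times,
                         po2=trace.po2 + rng.normal(0.0, noise_sd,
                                                    trace.po2.size),
                         phase=trace.phase)
    return trace
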