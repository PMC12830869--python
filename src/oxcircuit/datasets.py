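"""Packaged reference inputs: published cohort summaries for young
(3-month) and old (23-month) rat spinotrapezius muscle.

These are the canonical measured inputs of the analysis — arterial PO2,
resting and working interstitial PO2, and onset/offset time constants,
as cohort means with CI95 half-widths.  Everything else the package
computes is derived from them.
"""

from __future__ import annotations

from importlib import resources

from .circuit import TwoStateSummary
from .errors import ConfigError
from .io import cohort_spec_from_config
from .synthetic import CohortSpec

import yaml

__all__ = ["available_cohorts", "reference_summary", "reference_cohort_spec"]


def _load(name: str) -> dict:
    ref = resources.files("oxcircuit.data") / f"{name}.yaml"
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as e:
        raise ConfigError(
            f"no packaged cohort named {name!r}; available: "
            f"{available_cohorts()}"
        ) from e
    return yaml.safe_load(text)


def available_cohorts() -> list[str]:
    return ["young", "old"]


def reference_summary(cohort: str) -> TwoStateSummary:
    """The measured five-parameter summary for ``"young"`` or ``"old"``."""
    d = _load(cohort)
    return TwoStateSummary.from_dict(d)


def reference_cohort_spec(cohort: str) -> CohortSpec:
    """The full statistical spec (means, CI95, counts) for a cohort."""
    return cohort_spec_from_config(_load(cohort))
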