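"""File formats: delimited-text traces and point sets, flat YAML configs.

Traces are 3-column CSV (``time_s, po2_mmhg, phase``) with a header;
steady-state point sets 2-column CSV (``pi_mmhg, vo2``); configs flat
YAML/JSON-style key-value mappings (keys: Pa, Rd, Rr, Rw, C, Pr, Pw,
tau_r, tau_w, label, plus cohort-spec keys).  Comma delimiter, UTF-8,
"." decimal throughout.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .circuit import TwoStateSummary
from .dynamics import PO2Trace
from .errors import ConfigError, DataError
from .synthetic import CohortSpec, PARAM_NAMES

__all__ = [
    "write_trace", "read_trace", "write_points", "read_points",
    "read_config", "write_config", "summary_from_config",
    "cohort_spec_from_config",
]

TRACE_COLUMNS = ["time_s", "po2_mmhg", "phase"]


def write_trace(trace: PO2Trace, path: str | os.PathLike) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "po2_mmhg": trace.po2,
        "phase": trace.phase.astype(str),
    }).to_csv(path, index=False)


def read_trace(path: str | os.PathLike) -> PO2Trace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trace file {path} is missing columns {missing}")
    return PO2Trace(times=df["time_s"].to_numpy(float),
                    po2=df["po2_mmhg"].to_numpy(float),
                    phase=df["phase"].to_numpy(object))


def write_points(points, path: str | os.PathLike) -> None:
    pts = np.asarray(points, dtype=float)
    pd.DataFrame({"pi_mmhg": pts[:, 0], "vo2": pts[:, 1]}).to_csv(path, index=False)


def read_points(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path)
    for c in ("pi_mmhg", "vo2"):
        if c not in df.columns:
            raise DataError(f"points file {path} is missing column {c!r}")
    return df[["pi_mmhg", "vo2"]].to_numpy(float)


def read_config(path: str | os.PathLike) -> dict:
    """Load a flat YAML (or JSON, a YAML subset) mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    return dict(data)


def write_config(data: Mapping, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


def summary_from_config(d: Mapping) -> TwoStateSummary:
    """Build a two-state summary from a flat config mapping."""
    for key in ("Pa", "Pr", "Pw", "tau_r", "tau_w"):
        if key not in d:
            raise ConfigError(f"config is missing required key {key!r}")
    return TwoStateSummary.from_dict(d)


def cohort_spec_from_config(d: Mapping) -> CohortSpec:
    """Build a cohort spec from a flat config.

    Expects ``label``, ``n_animals``, ``n_profiles``, per-parameter means
    under their plain names (``Pa`` ...), CI95 half-widths under
    ``<name>_ci95``, and optional ``noise_sd`` / ``seed``.
    """
    for key in ("label", "n_animals", "n_profiles"):
        if key not in d:
            raise ConfigError(f"cohort config is missing required key {key!r}")
    mean, ci95 = {}, {}
    for name in PARAM_NAMES:
        if name not in d:
            raise ConfigError(f"cohort config is missing required key {name!r}")
        ci_key = f"{name}_ci95"
        if ci_key not in d:
            raise ConfigError(f"cohort config is missing required key {ci_key!r}")
        mean[name] = float(d[name])
        ci95[name] = float(d[ci_key])
    return CohortSpec(
        label=str(d["label"]),
        n_animals=int(d["n_animals"]),
        n_profiles=int(d["n_profiles"]),
        mean=mean,
        ci95=ci95,
        noise_sd=float(d.get("noise_sd", 1.0)),
        seed=(int(d["seed"]) if d.get("seed") is not None else None),
    )
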