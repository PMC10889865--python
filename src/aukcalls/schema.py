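"""Shared record types, column conventions and structured errors.

Every stage of the pipeline exchanges call-level data through a flat table
with one row per call and a fixed column order, so CSV round-trips are
lossless and stages are independently scriptable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Stable column order of the feature table (one row per call).
FEATURE_COLUMNS = [
    "call_id",
    "individual_id",
    "context",
    "duration_s",
    "mean_f0_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "spectral_slope_per_khz",
    "mean_entropy",
]

#: The seven acoustic parameters, in table order.
PARAMETER_COLUMNS = FEATURE_COLUMNS[3:]

#: Behavioural contexts. ``handling`` is the model reference level.
CONTEXTS = ("begging", "handling")


class AukcallsError(Exception):
    """Base class for structured pipeline errors."""


class ConfigError(AukcallsError):
    """Invalid configuration (exit code 2 at the CLI)."""


class DataError(AukcallsError):
    """Invalid or unusable input data (exit code 3 at the CLI)."""


class CallTooShortError(DataError):
    """Waveform shorter than one analysis window."""


class SilentCallError(DataError):
    """Waveform carries no energy."""


@dataclass
class CallRecording:
    """One annotated call: waveform segment plus its labels."""

    samples: np.ndarray          # float amplitudes in [-1, 1]
    sample_rate: int             # Hz
    call_id: str
    individual_id: str
    context: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise DataError(f"call {self.call_id}: empty waveform")
        if self.sample_rate <= 0:
            raise DataError(f"call {self.call_id}: bad sample rate")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class FeatureVector:
    """The seven acoustic parameters of one call.

    ``mean_f0_hz`` is None when no voiced frame was found; such calls are
    flagged and excluded from downstream statistics.
    """

    duration_s: float
    mean_f0_hz: Optional[float]
    q25_hz: float
    q50_hz: float
    q75_hz: float
    spectral_slope_per_khz: float
    mean_entropy: float
    f0_missing: bool = field(default=False)

    def as_row(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "mean_f0_hz": np.nan if self.mean_f0_hz is None else self.mean_f0_hz,
            "q25_hz": self.q25_hz,
            "q50_hz": self.q50_hz,
            "q75_hz": self.q75_hz,
            "spectral_slope_per_khz": self.spectral_slope_per_khz,
            "mean_entropy": self.mean_entropy,
        }


#: Minimal structural schema of the JSON analysis report, versioned.
REPORT_SCHEMA_VERSION = 1

REPORT_SCHEMA = {
    "schema_version": int,
    "seed": int,
    "software_version": str,
    "config": dict,
    "n_calls": int,
    "pdfa": dict,
    "lmm": dict,
    "individuality": dict,
    "logs": dict,
}


def validate_report(report: dict) -> None:
    """Check the analysis report against :data:`REPORT_SCHEMA`.

    Raises ``DataError`` naming the first offending key. Deliberately
    structural (keys and coarse types), not a full JSON-Schema engine.
    """
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise DataError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise DataError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )
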