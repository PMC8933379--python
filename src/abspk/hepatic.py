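"""Hepatic extraction ratio from IV plasma clearance.

For a drug cleared essentially entirely by the liver, the extraction ratio
is hepatic blood clearance over hepatic blood flow:

    E_h = CL_plasma * R_bp / Q_h

with R_bp the blood-to-plasma partitioning ratio (default 0.985) and Q_h the
hepatic blood flow (default 90 L/h, typical for a 70 kg adult). The
allometric mode scales Q_h by (weight/70)^0.75 when a body weight is
supplied. Drugs with E_h < 0.30 are conventionally classed low-extraction,
above 0.70 high-extraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .datamodel import ValidationError

DEFAULT_BLOOD_TO_PLASMA = 0.985
DEFAULT_HEPATIC_BLOOD_FLOW = 90.0  # L/h
REFERENCE_WEIGHT_KG = 70.0
LOW_EXTRACTION_BOUND = 0.30
HIGH_EXTRACTION_BOUND = 0.70


@dataclass(frozen=True)
class ExtractionInputs:
    cl_plasma: float  # L/h
    blood_to_plasma_ratio: float = DEFAULT_BLOOD_TO_PLASMA
    hepatic_blood_flow: float = DEFAULT_HEPATIC_BLOOD_FLOW  # L/h
    body_weight: Optional[float] = None  # kg, for allometric_flow mode

    def __post_init__(self) -> None:
        if self.cl_plasma < 0:
            raise ValidationError("cl_plasma must be >= 0")
        if self.blood_to_plasma_ratio <= 0 or self.hepatic_blood_flow <= 0:
            raise ValidationError("partition ratio and blood flow must be > 0")
        if self.body_weight is not None and self.body_weight <= 0:
            raise ValidationError("body_weight must be > 0 kg")


def hepatic_extraction_ratio(
    inputs: ExtractionInputs, mode: str = "fixed_flow"
) -> float:
    """E_h = blood clearance / hepatic blood flow, clipped to [0, 1].

    ``mode='allometric_flow'`` rescales the blood flow by
    (body_weight/70)^0.75; it requires ``body_weight``.
    """
    q_h = inputs.hepatic_blood_flow
    if mode == "allometric_flow":
        if inputs.body_weight is None:
            raise ValidationError("allometric_flow mode requires body_weight")
        q_h = q_h * (inputs.body_weight / REFERENCE_WEIGHT_KG) ** 0.75
    elif mode != "fixed_flow":
        raise ValidationError(f"unknown mode {mode!r}")
    cl_blood = inputs.cl_plasma * inputs.blood_to_plasma_ratio
    if cl_blood >= q_h:
        warnings.warn(
            "blood clearance exceeds hepatic blood flow; extraction clipped at 1",
            stacklevel=2,
        )
        return 1.0
    return cl_blood / q_h


def classify_extraction(e_h: float) -> str:
    """'low' (< 0.30), 'intermediate', or 'high' (> 0.70)."""
    if not 0.0 <= e_h <= 1.0:
        raise ValidationError("extraction ratio must lie in [0, 1]")
    if e_h < LOW_EXTRACTION_BOUND:
        return "low"
    if e_h > HIGH_EXTRACTION_BOUND:
        return "high"
    return "intermediate"
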