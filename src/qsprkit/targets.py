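"""Target-value processing: negative-log transform and class binarization.

Regression models are trained on pIC50/pEC50 — the negative decadic
logarithm of the potency expressed in molar units — so higher means more
potent. Classification binarizes the nM endpoint at a configured
threshold; a compound at or below the threshold is ACTIVE (more potent),
and ACTIVE is the positive class for every classification measure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

ACTIVE = "ACTIVE"
INACTIVE = "INACTIVE"


def to_plog(endpoint_nM: float) -> float:
    """pIC50/pEC50 = -log10(endpoint in molar); 1000 nM -> 6.0, 1 nM -> 9.0."""
    if endpoint_nM <= 0:
        raise ValidationError(f"endpoint must be positive, got {endpoint_nM}")
    return 9.0 - math.log10(endpoint_nM)


def from_plog(plog: float) -> float:
    """Inverse transform back to nM: 10**(9 - plog)."""
    return 10.0 ** (9.0 - plog)


def binarize(endpoint_nM: float, class_threshold_nM: float) -> str:
    """ACTIVE iff endpoint <= threshold (ties count as ACTIVE)."""
    if endpoint_nM <= 0 or class_threshold_nM <= 0:
        raise ValidationError("endpoint and threshold must both be positive")
    return ACTIVE if endpoint_nM <= class_threshold_nM else INACTIVE


@dataclass
class TargetTransform:
    """Task-dependent endpoint→target mapping, serialized with the artifact."""

    task: str
    class_threshold_nM: Optional[float] = None
    positive_class_name: str = ACTIVE

    def __post_init__(self):
        if self.task == "classification":
            if self.class_threshold_nM is None or self.class_threshold_nM <= 0:
                raise ValidationError(
                    "classification requires a positive class_threshold_nM"
                )

    def apply(self, endpoints_nM: Sequence[float]) -> np.ndarray:
        """Map nM endpoints to model targets: plog values (regression) or
        0/1 labels with 1 = ACTIVE (classification)."""
        if self.task == "regression":
            return np.array([to_plog(v) for v in endpoints_nM])
        return np.array(
            [1 if binarize(v, self.class_threshold_nM) == ACTIVE else 0
             for v in endpoints_nM],
            dtype=int,
        )

    def labels(self, encoded: Sequence[int]):
        return [ACTIVE if int(e) == 1 else INACTIVE for e in encoded]

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "class_threshold_nM": self.class_threshold_nM,
            "positive_class_name": self.positive_class_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetTransform":
        return cls(**d)
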