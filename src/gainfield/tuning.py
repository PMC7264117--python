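"""Shared tuning-curve primitives.

A neuron's internal activation is built from Gaussian components — one per
modality (retinal stimulus location, eye position) — combined additively and
passed through a sigmoid transfer function to yield an instantaneous firing
rate in (0, 1).  Angles are in degrees throughout; activations and rates are
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningSpec",
    "SigmoidSpec",
    "gaussian_activation",
    "combined_activation",
    "sigmoid_rate",
]

#: Exponent arguments are clamped to this magnitude before exponentiation so
#: extreme activations saturate to 0/1 instead of producing non-finite rates.
EXP_CLIP = 700.0


@dataclass(frozen=True)
class TuningSpec:
    """One Gaussian tuning component.

    Parameters
    ----------
    preferred : float
        Location (degrees) at which the component peaks: the preferred
        retinal location or preferred eye position of the neuron.
    width : float
        Standard deviation of the Gaussian (degrees); strictly positive.
    peak : float
        Activation attained at ``preferred``; non-negative, dimensionless.
    """

    preferred: float
    width: float
    peak: float

    def __post_init__(self) -> None:
        for name in ("preferred", "width", "peak"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"TuningSpec.{name} must be finite, got {v!r}")
        if self.width <= 0:
            raise ValueError(f"TuningSpec.width must be > 0, got {self.width}")
        if self.peak < 0:
            raise ValueError(f"TuningSpec.peak must be >= 0, got {self.peak}")


@dataclass(frozen=True)
class SigmoidSpec:
    """Sigmoid rate transfer: ``v = 1 / (1 + exp(-2*slope*(h - threshold)))``."""

    slope: float
    threshold: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.threshold)):
            raise ValueError("SigmoidSpec parameters must be finite")
        if self.slope <= 0:
            raise ValueError(f"SigmoidSpec.slope must be > 0, got {self.slope}")


def _check_finite(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def gaussian_activation(value, spec: TuningSpec):
    """Gaussian activation of a tuned unit evaluated at ``value`` (degrees).

    Returns ``spec.peak * exp(-(value - preferred)^2 / (2 * width^2))``,
    which lies in ``[0, spec.peak]`` and is symmetric about ``preferred``.
    Accepts scalars or arrays.
    """
    v = _check_finite(value, "value")
    exponent = -((v - spec.preferred) ** 2) / (2.0 * spec.width**2)
    out = spec.peak * np.exp(np.maximum(exponent, -EXP_CLIP))
    return out if out.ndim else float(out)


def combined_activation(x, y, retinal: TuningSpec, eye: TuningSpec):
    """Additive combination of retinal and eye-position components.

    ``h(x, y) = h_r(x) + h_e(y)`` where each component is a Gaussian of the
    distance between the evaluation point and the neuron's preferred value.
    """
    return gaussian_activation(x, retinal) + gaussian_activation(y, eye)


def sigmoid_rate(h, spec: SigmoidSpec):
    """Sigmoid transfer from internal activation to firing rate in (0, 1).

    Strictly increasing in ``h``; maps ``h == threshold`` to exactly 0.5.
    Overflow is guarded: extreme activations saturate to 0 or 1 within
    floating-point tolerance.
    """
    hv = _check_finite(h, "h")
    z = np.clip(-2.0 * spec.slope * (hv - spec.threshold), -EXP_CLIP, EXP_CLIP)
    out = 1.0 / (1.0 + np.exp(z))
    return out if out.ndim else float(out)
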