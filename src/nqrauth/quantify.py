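"""Linear API quantification from NQR amplitude: q = (A - c) / m.

Over the thin-sample regime the initial amplitude grows linearly with API
mass, so a per-package straight line A = m*q + c inverts to a mass
estimate.  The six built-in calibrations carry the published constants for
benzocaine in common mail packages; their validity range is the studied
span 6-18 g (the linear approximation breaks down near ~18 g as the depth
integral saturates).  Amplitudes are in the calibrating instrument's
arbitrary units — cross-detector use requires the amplitude normalization
in :mod:`nqrauth.authenticate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "CalibrationModel",
    "QuantityEstimate",
    "builtin_calibrations",
    "estimate_quantity",
    "fit_calibration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Straight-line amplitude-vs-mass model for one package type.

    ``slope`` (m) in arbitrary units per gram, ``offset`` (c) in arbitrary
    units, valid for masses in [q_min, q_max] grams.
    """

    package_name: str
    slope: float
    offset: float
    q_min: float = 6.0
    q_max: float = 18.0
    fit_r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError("slope must be > 0")
        if not (0 <= self.q_min < self.q_max):
            raise DomainError("need 0 <= q_min < q_max")

    def predict_amplitude(self, quantity_g: float) -> float:
        """Forward model A = m*q + c."""
        return self.slope * quantity_g + self.offset

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class QuantityEstimate:
    """Inverted mass estimate with its validity-range status."""

    quantity_g: float
    status: str  # "ok" | "below_range" | "above_range"

    @property
    def in_range(self) -> bool:
        return self.status == "ok"


def builtin_calibrations() -> dict[str, CalibrationModel]:
    """The six published per-package calibration models for benzocaine."""
    raw = json.loads(resources.files("nqrauth.data").joinpath("calibrations.json").read_text())
    return {name: CalibrationModel(package_name=name, **entry) for name, entry in raw.items()}


def estimate_quantity(amplitude: float, model: CalibrationModel) -> QuantityEstimate:
    """Invert the calibration: q = (A - c)/m, flagged against [q_min, q_max].

    Out-of-range estimates are still returned; ``above_range`` signals the
    saturation regime where the linear model under-reads the true mass.
    """
    if model.slope <= 0:
        raise DomainError("invalid model: slope must be > 0")
    q = (amplitude - model.offset) / model.slope
    tol = 1e-9 * (model.q_max - model.q_min)  # guards float round-off at the edges
    if q < model.q_min - tol:
        status = "below_range"
    elif q > model.q_max + tol:
        status = "above_range"
    else:
        status = "ok"
    return QuantityEstimate(quantity_g=float(q), status=status)


def fit_calibration(
    pairs: Sequence[Tuple[float, float]], package_name: str = "custom"
) -> CalibrationModel:
    """Ordinary least squares of amplitude on mass over (grams, amplitude) pairs.

    The regression direction matches the forward model A = m*q + c; the
    validity range is set to the span of calibrated masses.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be (quantity_g, amplitude) tuples")
    q, a = arr[:, 0], arr[:, 1]
    if np.unique(q).size < 2:
        raise InsufficientDataError("need >= 2 distinct quantities")
    res = stats.linregress(q, a)
    if res.slope <= 0:
        raise FitFailureError(f"fitted slope {res.slope:.4g} is not positive")
    return CalibrationModel(
        package_name=package_name,
        slope=float(res.slope),
        offset=float(res.intercept),
        q_min=float(q.min()),
        q_max=float(q.max()),
        fit_r_squared=float(res.rvalue**2),
    )
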