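"""Signature-based package authentication.

Repeated measurements of a genuine (API, package, detector) configuration
yield approximately Gaussian feature distributions; a stored signature
records their per-feature means and standard deviations.  A package under
test is authenticated by z-scoring its measured feature vector against the
signature: every feature within ``k_sigma`` standard deviations passes,
any excursion raises a discrepancy naming the offending features.

Raw amplitudes are detector-specific (they scale with the coil sensitivity
function), so each signature carries an ``amplitude_reference`` — the mean
amplitude of the reference measurements — and amplitudes are rescaled
between detectors before comparison.  T2,eff offsets between detectors are
a mean-RF-field effect handled by per-detector signatures, not by
normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateSpreadError,
    DomainError,
    IncompatibleDataError,
    InsufficientDataError,
    InvalidSignatureError,
)
from .features import FEATURE_NAMES, FeatureVector
from .quantify import CalibrationModel, estimate_quantity

__all__ = [
    "SignatureRecord",
    "DecisionReport",
    "build_signature",
    "normalize_amplitude",
    "authenticate_package",
    "SignatureStore",
]


@dataclass(frozen=True)
class SignatureRecord:
    """Gaussian reference statistics for one (API, package, detector)."""

    api_name: str
    package_name: str
    detector_id: str
    feature_means: dict
    feature_sds: dict
    n_measurements: int
    amplitude_reference: float

    def __post_init__(self) -> None:
        if self.n_measurements < 3:
            raise InsufficientDataError("a signature needs >= 3 measurements")
        for name in FEATURE_NAMES:
            if name not in self.feature_means or name not in self.feature_sds:
                raise InvalidSignatureError(f"missing feature {name!r}")
            if self.feature_sds[name] <= 0:
                raise DegenerateSpreadError(f"feature {name!r} has sd <= 0")
        if self.amplitude_reference <= 0:
            raise InvalidSignatureError("amplitude_reference must be > 0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "api_name": self.api_name,
                "package_name": self.package_name,
                "detector_id": self.detector_id,
                "feature_means": self.feature_means,
                "feature_sds": self.feature_sds,
                "n_measurements": self.n_measurements,
                "amplitude_reference": self.amplitude_reference,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureRecord":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class DecisionReport:
    """Outcome of one authentication: verdict, per-feature z-scores, mass."""

    verdict: str  # "authentic" | "discrepancy"
    z_scores: dict
    offending_features: tuple
    k_sigma: float
    estimated_quantity_g: Optional[float] = None
    quantity_status: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "verdict": self.verdict,
                "z_scores": self.z_scores,
                "offending_features": list(self.offending_features),
                "k_sigma": self.k_sigma,
                "estimated_quantity_g": self.estimated_quantity_g,
                "quantity_status": self.quantity_status,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"verdict: {self.verdict} (k = {self.k_sigma:g})"]
        for name, z in self.z_scores.items():
            flag = "  <-- out of tolerance" if name in self.offending_features else ""
            lines.append(f"  {name}: z = {z:+.2f}{flag}")
        if self.estimated_quantity_g is not None:
            lines.append(
                f"  estimated quantity: {self.estimated_quantity_g:.2f} g "
                f"({self.quantity_status})"
            )
        return "\n".join(lines)


def build_signature(
    features: Sequence[FeatureVector],
    api_name: str,
    package_name: str,
    detector_id: str,
    api_names: Optional[Sequence[str]] = None,
) -> SignatureRecord:
    """Per-feature sample mean and sd over repeated reference measurements.

    ``api_names``, when given, must all equal ``api_name`` — mixing
    measurements of different APIs into one signature is rejected.
    """
    if len(features) < 3:
        raise InsufficientDataError(f"need >= 3 feature vectors, got {len(features)}")
    if api_names is not None and any(a != api_name for a in api_names):
        raise IncompatibleDataError("feature vectors come from mixed api_name inputs")
    means, sds = {}, {}
    for name in FEATURE_NAMES:
        vals = np.array([getattr(fv, name) for fv in features], dtype=float)
        means[name] = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            raise DegenerateSpreadError(
                f"feature {name!r} has zero spread over {len(features)} measurements"
            )
        sds[name] = sd
    return SignatureRecord(
        api_name=api_name,
        package_name=package_name,
        detector_id=detector_id,
        feature_means=means,
        feature_sds=sds,
        n_measurements=len(features),
        amplitude_reference=means["initial_amplitude"],
    )


def normalize_amplitude(
    feature: FeatureVector, from_reference: float, to_reference: float
) -> FeatureVector:
    """Rescale the amplitude between detectors; all other features unchanged."""
    if from_reference <= 0 or to_reference <= 0:
        raise DomainError("amplitude references must be > 0")
    return replace(
        feature,
        initial_amplitude=feature.initial_amplitude * to_reference / from_reference,
    )


def authenticate_package(
    measured: FeatureVector,
    signature: SignatureRecord,
    k_sigma: float = 3.0,
    calibration: Optional[CalibrationModel] = None,
    mahalanobis: bool = False,
) -> DecisionReport:
    """Decide authentic vs discrepancy for one measurement.

    Default rule: per-feature gating at ``k_sigma`` standard deviations.
    With ``mahalanobis=True`` the verdict instead uses the (diagonal)
    Mahalanobis distance against a chi-squared-motivated radius
    ``k_sigma * sqrt(n_features)``; per-feature z-scores are reported
    either way.  A calibration model, when supplied, adds the inverted
    mass estimate to the report.
    """
    if k_sigma <= 0:
        raise DomainError("k_sigma must be > 0")
    z_scores = {}
    for name in FEATURE_NAMES:
        sd = signature.feature_sds[name]
        if sd <= 0:
            raise InvalidSignatureError(f"signature sd for {name!r} is not positive")
        z_scores[name] = (getattr(measured, name) - signature.feature_means[name]) / sd
    if mahalanobis:
        dist = math.sqrt(sum(z * z for z in z_scores.values()))
        offending = tuple(
            n for n, z in sorted(z_scores.items(), key=lambda kv: -abs(kv[1]))
            if abs(z) > k_sigma
        ) if dist > k_sigma * math.sqrt(len(FEATURE_NAMES)) else ()
        verdict = "authentic" if dist <= k_sigma * math.sqrt(len(FEATURE_NAMES)) else "discrepancy"
    else:
        offending = tuple(n for n in FEATURE_NAMES if abs(z_scores[n]) > k_sigma)
        verdict = "authentic" if not offending else "discrepancy"
    est_q = est_status = None
    if calibration is not None:
        est = estimate_quantity(measured.initial_amplitude, calibration)
        est_q, est_status = est.quantity_g, est.status
    return DecisionReport(
        verdict=verdict,
        z_scores={k: float(v) for k, v in z_scores.items()},
        offending_features=offending,
        k_sigma=k_sigma,
        estimated_quantity_g=est_q,
        quantity_status=est_status,
    )


class SignatureStore:
    """Local JSON signature database: one file per (api, package, detector)."""

    def __init__(self, root: Path | str):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, api: str, package: str, detector: str) -> Path:
        return self.root / f"{api}__{package}__{detector}.json"

    def put(self, record: SignatureRecord) -> Path:
        path = self._path(record.api_name, record.package_name, record.detector_id)
        path.write_text(record.to_json())
        return path

    def get(self, api: str, package: str, detector: str) -> SignatureRecord:
        path = self._path(api, package, detector)
        if not path.exists():
            raise InvalidSignatureError(f"no stored signature at {path}")
        return SignatureRecord.from_json(path.read_text())

    def list(self) -> list:
        return sorted(p.stem for p in self.root.glob("*.json"))
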