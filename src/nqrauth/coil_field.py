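"""Planar spiral detector coil: on-axis field, detection efficiency, depth decay.

The detector is a flat PCB spiral (outer outline 7 cm, 11 turns of 0.9 mm
copper trace with 0.2 mm gaps in the reference instrument).  For field
calculations the spiral is approximated as concentric circular loops at the
mid-trace radii — the standard treatment for tightly wound planar coils,
and one that can be checked against a brute-force Biot–Savart line integral.

Field strength per unit current B1/I1 (the coil sensitivity) falls off
steeply with depth ``z`` above the coil plane; over the working range of a
coil this size it follows an approximate ``1/z^(3/2)`` power law, which
:func:`fit_decay_exponent` recovers from a sampled profile.  Detection
efficiency is ``eta = (B1/I1)/sqrt(Rs)`` with ``Rs`` the coil series
resistance; power SNR scales as ``eta**2 * N`` over ``N`` averaged scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import mu_0

from .errors import DomainError, InsufficientDataError, InvalidGeometryError

__all__ = [
    "CoilSpec",
    "FieldProfile",
    "loop_radii",
    "b1_on_axis",
    "detection_efficiency",
    "field_profile",
    "fit_decay_exponent",
]


@dataclass(frozen=True)
class CoilSpec:
    """Geometry and electrical parameters of the planar spiral detector.

    Defaults reproduce the reference instrument: 7 cm outline, 11 turns,
    0.9 mm trace, 0.2 mm gap.  ``series_resistance`` is not printed for the
    reference coil; 0.5 ohm is a typical value for a PCB coil of this size.
    """

    outer_side: float = 0.07
    n_turns: int = 11
    trace_width: float = 9.0e-4
    trace_gap: float = 2.0e-4
    series_resistance: float = 0.5

    def __post_init__(self) -> None:
        if self.n_turns < 1 or int(self.n_turns) != self.n_turns:
            raise InvalidGeometryError(f"n_turns must be a positive integer, got {self.n_turns}")
        for name in ("outer_side", "trace_width", "trace_gap"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.series_resistance <= 0:
            raise InvalidGeometryError("series_resistance must be > 0")
        if self.n_turns * (self.trace_width + self.trace_gap) >= self.outer_side / 2:
            raise InvalidGeometryError(
                "windings do not fit inside the outline: "
                f"{self.n_turns} turns x {(self.trace_width + self.trace_gap) * 1e3:.3g} mm pitch "
                f">= {self.outer_side / 2 * 1e3:.3g} mm half-outline"
            )

    @property
    def pitch(self) -> float:
        """Radial advance per turn (trace width + gap), metres."""
        return self.trace_width + self.trace_gap


@dataclass(frozen=True)
class FieldProfile:
    """Sampled on-axis sensitivity: B1/I1 (T/A) versus depth (m)."""

    depths: np.ndarray
    field_per_current: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "field_per_current", np.asarray(self.field_per_current, dtype=float))
        if self.depths.shape != self.field_per_current.shape or self.depths.size < 2:
            raise DomainError("depths and field_per_current must have equal length >= 2")
        if np.any(np.diff(self.depths) <= 0):
            raise DomainError("depths must be strictly increasing")
        if np.any(self.field_per_current <= 0):
            raise DomainError("field_per_current values must be > 0")
        if np.any(np.diff(self.field_per_current) > 0):
            raise DomainError("field_per_current must be non-increasing with depth")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"depth_m": self.depths, "b1_per_amp_T": self.field_per_current}
        ).to_csv(path, index=False)


def loop_radii(coil: CoilSpec) -> np.ndarray:
    """Radii of the concentric-loop approximation, strictly decreasing.

    The outermost loop sits at the mid-trace radius ``outer_side/2 -
    trace_width/2``; successive loops step inward by one pitch.
    """
    outer = coil.outer_side / 2 - coil.trace_width / 2
    radii = outer - coil.pitch * np.arange(coil.n_turns)
    if radii[-1] <= 0:
        raise InvalidGeometryError("innermost loop radius is non-positive")
    return radii


def b1_on_axis(coil: CoilSpec, depth) -> float | np.ndarray:
    """On-axis field per unit current, tesla per ampere, at ``depth`` metres.

    Sum of circular-loop on-axis fields ``mu0 a^2 / (2 (a^2 + z^2)^(3/2))``
    over the concentric loops.  Accepts scalar or array depth.
    """
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise DomainError("depth must be >= 0")
    a = loop_radii(coil)[:, np.newaxis]
    b = mu_0 * a**2 / (2.0 * (a**2 + np.atleast_1d(z)[np.newaxis, :] ** 2) ** 1.5)
    total = b.sum(axis=0)
    return float(total[0]) if np.isscalar(depth) or z.ndim == 0 else total


def detection_efficiency(coil: CoilSpec, depth) -> float | np.ndarray:
    """Detection efficiency eta = (B1/I1)/sqrt(Rs), units T A^-1 ohm^-1/2."""
    if coil.series_resistance <= 0:  # defensive; CoilSpec already enforces this
        raise DomainError("series_resistance must be > 0")
    return b1_on_axis(coil, depth) / np.sqrt(coil.series_resistance)


def field_profile(coil: CoilSpec, depths) -> FieldProfile:
    """Evaluate the on-axis sensitivity at the given depths."""
    depths = np.asarray(depths, dtype=float)
    return FieldProfile(depths=depths, field_per_current=b1_on_axis(coil, depths))


def fit_decay_exponent(profile: FieldProfile, z_lo: float, z_hi: float) -> float:
    """Magnitude of the power-law exponent ``p`` of ``field ~ z**(-p)``.

    Least-squares line on log(field) vs log(depth) restricted to depths in
    ``[z_lo, z_hi]``; at least four profile points must fall in the window.
    """
    mask = (profile.depths >= z_lo) & (profile.depths <= z_hi)
    if mask.sum() < 4:
        raise InsufficientDataError(
            f"need >= 4 profile points in [{z_lo}, {z_hi}], found {int(mask.sum())}"
        )
    z = profile.depths[mask]
    if np.any(z <= 0):
        raise DomainError("power-law fit requires depths > 0")
    slope, _ = np.polyfit(np.log(z), np.log(profile.field_per_current[mask]), 1)
    return float(abs(slope))
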