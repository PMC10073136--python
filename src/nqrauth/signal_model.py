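"""Depth-integrated SLSE signal amplitude for powder samples above a planar coil.

An RF pulse of length ``tp`` nutates spin-1 nuclei at depth ``z`` through
``theta(z) = gamma * B1(z) * tp``.  For a powder (randomly oriented
crystallites) the initial SLSE echo amplitude varies with flip angle as

    r(theta) = (sin theta - theta cos theta) / theta**2,

which is proportional to ``theta**(-1/2) * J_{3/2}(theta)`` and attains its
first maximum at the optimum flip angle theta_opt ~ 119.5 deg (2.0816 rad).
Because B1 decays steeply with depth, the detected amplitude is a depth
integral weighted by both the flip-angle response (transmit) and the coil
sensitivity B1/I1 (receive, by reciprocity):

    A ~ integral_{zmin}^{zmax} |B1(z)/I1| * w(z) dz

with ``w = r(theta(z))`` in the default ``powder`` mode, or the small-angle
form ``w = gamma*B1(z)*tp`` in ``literal`` mode.  The integral saturates as
sample thickness grows — only a slice near the depth where theta ~ theta_opt
contributes strongly — but is nearly linear for thin samples, which is what
makes linear mass calibration possible for envelopes.

Packaging enters in two ways: the wall thickness sets the standoff zmin,
and a conductive wall attenuates B1 (eddy currents), modelled here as a
scalar factor applied to the transmit field and to the receive sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

import numpy as np
from scipy import integrate, optimize

from .coil_field import CoilSpec, b1_on_axis
from .errors import DomainError, NumericalError

__all__ = [
    "GAMMA_N14",
    "THETA_OPT",
    "PulseSpec",
    "SampleGeometry",
    "PackageSpec",
    "powder_response",
    "optimum_flip_angle",
    "flip_angle_profile",
    "optimum_slice_depth",
    "amplitude_integral",
    "SaturationCurve",
    "saturation_curve",
    "mass_to_thickness",
    "package_presets",
]

#: Gyromagnetic ratio of 14N, rad s^-1 T^-1 (gamma/2pi = 3.0777 MHz/T).
GAMMA_N14 = 2 * np.pi * 3.0777e6

#: Optimum flip angle for spin-1 powders, radians (~119.5 degrees).
THETA_OPT = 2.0816


@dataclass(frozen=True)
class PulseSpec:
    """Excitation pulse: length tp (s), drive current I1 (A), gamma (rad/s/T)."""

    pulse_length: float = 50e-6
    drive_current: float = 10.0
    gyromagnetic_ratio: float = GAMMA_N14

    def __post_init__(self) -> None:
        if self.pulse_length < 0:
            raise DomainError("pulse_length must be >= 0")
        if self.drive_current <= 0 or self.gyromagnetic_ratio <= 0:
            raise DomainError("drive_current and gyromagnetic_ratio must be > 0")


@dataclass(frozen=True)
class SampleGeometry:
    """Sample slab along the coil axis: standoff zmin and thickness zmax - zmin."""

    standoff: float = 0.0
    thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.standoff < 0 or self.thickness < 0:
            raise DomainError("standoff and thickness must be >= 0")


@dataclass(frozen=True)
class PackageSpec:
    """A mail-package type: wall standoff and conductive attenuation factor.

    ``conductive_attenuation`` is the scalar factor by which the package
    wall reduces the B1 field (1 = non-conductive).
    """

    name: str = "custom"
    standoff: float = 0.0
    conductive_attenuation: float = 1.0
    calibration: Optional[object] = None  # CalibrationModel, kept loosely typed

    def __post_init__(self) -> None:
        if not (0.0 < self.conductive_attenuation <= 1.0):
            raise DomainError("conductive_attenuation must be in (0, 1]")
        if self.standoff < 0:
            raise DomainError("standoff must be >= 0")


def package_presets() -> dict[str, PackageSpec]:
    """The six built-in package types with default standoffs and attenuations."""
    raw = json.loads(resources.files("nqrauth.data").joinpath("packages.json").read_text())
    return {
        name: PackageSpec(
            name=name,
            standoff=entry["standoff_m"],
            conductive_attenuation=entry["conductive_attenuation"],
        )
        for name, entry in raw.items()
    }


def powder_response(theta) -> float | np.ndarray:
    """Relative initial echo amplitude of a spin-1 powder at flip angle theta.

    r(theta) = (sin theta - theta cos theta)/theta**2, with r(0) = 0 by
    continuity; equals theta**(-1/2) J_{3/2}(theta) up to a constant and
    peaks at THETA_OPT.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise DomainError("flip angle must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(th > 0, (np.sin(th) - th * np.cos(th)) / np.maximum(th, 1e-300) ** 2, 0.0)
    return float(r) if np.isscalar(theta) else r


def optimum_flip_angle(refine: bool = True) -> float:
    """Flip angle (radians) maximizing :func:`powder_response` on (0, pi].

    A fine grid locates the maximum; ``refine`` polishes it with bounded
    scalar optimization.
    """
    grid = np.linspace(1e-4, np.pi, 20001)
    theta0 = grid[np.argmax(powder_response(grid))]
    if not refine:
        return float(theta0)
    res = optimize.minimize_scalar(
        lambda t: -powder_response(t),
        bounds=(max(theta0 - 0.01, 1e-6), min(theta0 + 0.01, np.pi)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def flip_angle_profile(
    coil: CoilSpec,
    pulse: PulseSpec,
    depth,
    package: Optional[PackageSpec] = None,
) -> float | np.ndarray:
    """Flip angle theta(z) = gamma * B1(z) * tp at the given depth(s).

    B1(z) is the on-axis field at the drive current, reduced by the
    package's conductive attenuation when a package is supplied.
    """
    att = package.conductive_attenuation if package is not None else 1.0
    b1 = b1_on_axis(coil, depth) * pulse.drive_current * att
    return pulse.gyromagnetic_ratio * b1 * pulse.pulse_length


def optimum_slice_depth(
    coil: CoilSpec, pulse: PulseSpec, package: Optional[PackageSpec] = None
) -> Optional[float]:
    """Depth where theta(z) = THETA_OPT, or None if the surface angle is below it.

    When the surface flip angle exceeds the optimum, most of the signal
    arises from a thin slice around this depth.
    """
    if flip_angle_profile(coil, pulse, 0.0, package) <= THETA_OPT:
        return None
    sol = optimize.brentq(
        lambda z: flip_angle_profile(coil, pulse, z, package) - THETA_OPT, 0.0, 1.0
    )
    return float(sol)


def amplitude_integral(
    coil: CoilSpec,
    pulse: PulseSpec,
    geom: SampleGeometry,
    mode: str = "powder",
    package: Optional[PackageSpec] = None,
    field_fn: Optional[Callable] = None,
) -> float:
    """Depth-integrated initial signal amplitude (arbitrary units).

    Quadrature of ``|B1(z)/I1| * w(z)`` over ``[standoff, standoff +
    thickness]`` with ``w = r(theta(z))`` (``powder``, default) or
    ``w = gamma*B1(z)*tp`` (``literal``).  The conductive attenuation of a
    supplied package enters both the flip angle (transmit) and the
    sensitivity term (receive), so in literal mode the amplitude carries
    the reciprocity factor attenuation**2 exactly.

    ``field_fn(z) -> B1/I1`` overrides the coil model (testing hook).
    """
    if mode not in ("powder", "literal"):
        raise DomainError(f"mode must be 'powder' or 'literal', got {mode!r}")
    if geom.thickness == 0:
        return 0.0
    att = package.conductive_attenuation if package is not None else 1.0
    sens = field_fn if field_fn is not None else (lambda z: b1_on_axis(coil, z))

    def integrand(z):
        b1_per_amp = sens(z)
        theta = pulse.gyromagnetic_ratio * b1_per_amp * pulse.drive_current * att * pulse.pulse_length
        w = powder_response(theta) if mode == "powder" else theta
        return att * np.abs(b1_per_amp) * w

    lo, hi = geom.standoff, geom.standoff + geom.thickness
    try:
        value, abserr = integrate.quad(integrand, lo, hi, epsabs=1e-18, epsrel=1e-9, limit=200)
    except Exception as exc:  # pragma: no cover - quad rarely raises here
        raise NumericalError(f"quadrature failed on [{lo}, {hi}]: {exc}") from exc
    if value != 0 and abserr > 1e-4 * abs(value):
        # fallback: dense trapezoid
        z = np.linspace(lo, hi, 10001)
        value = float(np.trapezoid(integrand(z), z))
    return float(value)


@dataclass(frozen=True)
class SaturationCurve:
    """Amplitude versus sample thickness, with the detected linear regime."""

    thicknesses: np.ndarray
    amplitudes: np.ndarray
    linear_limit: float

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"thickness_m": self.thicknesses, "amplitude_au": self.amplitudes}
        ).to_csv(path, index=False)


def saturation_curve(
    coil: CoilSpec,
    pulse: PulseSpec,
    standoff: float,
    thicknesses,
    mode: str = "powder",
    package: Optional[PackageSpec] = None,
    linear_tol: float = 0.05,
) -> SaturationCurve:
    """Amplitude at each thickness plus the largest thickness that is still linear.

    ``linear_limit`` is the largest tested thickness such that a
    through-origin line fitted to all amplitudes up to it leaves relative
    residuals <= ``linear_tol`` at every point.
    """
    t = np.asarray(thicknesses, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise DomainError("thicknesses must be strictly increasing with >= 2 values")
    amps = np.array(
        [
            amplitude_integral(coil, pulse, SampleGeometry(standoff, th), mode, package)
            for th in t
        ]
    )
    linear_limit = float(t[0])
    for k in range(1, t.size + 1):
        tk, ak = t[:k], amps[:k]
        slope = float(np.dot(ak, tk) / np.dot(tk, tk))
        if slope <= 0:
            break
        rel = np.abs(ak - slope * tk) / (slope * tk)
        if np.max(rel) <= linear_tol:
            linear_limit = float(tk[-1])
        else:
            break
    return SaturationCurve(thicknesses=t, amplitudes=amps, linear_limit=linear_limit)


def mass_to_thickness(
    quantity_g: float,
    coil: CoilSpec,
    bulk_density_kg_m3: float = 600.0,
    footprint_area_m2: Optional[float] = None,
) -> float:
    """Slab thickness (m) of a powder of given mass spread over the coil footprint.

    Defaults: bulk density 0.6 g/cm^3 (loose pharmaceutical powder) and the
    coil outline area as footprint.
    """
    if quantity_g < 0:
        raise DomainError("quantity must be >= 0")
    area = footprint_area_m2 if footprint_area_m2 is not None else coil.outer_side**2
    return (quantity_g / 1000.0) / (bulk_density_kg_m3 * area)
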