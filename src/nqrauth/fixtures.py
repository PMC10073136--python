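"""Deterministic fixture bundle: everything needed to exercise the pipeline.

One seed drives four fixture families: (a) a benzocaine echo train in each
of the six built-in package types; (b) a 2.3-2.5 MHz frequency sweep in
10 kHz steps; (c) noiseless calibration sets generated from each built-in
calibration model; (d) a two-detector pair of measurement sets for
amplitude-normalization tests.  A manifest records SHA-256 checksums so
identical seeds provably produce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coil_field import CoilSpec
from .io import write_echo_train
from .quantify import builtin_calibrations
from .signal_model import PulseSpec, package_presets
from .slse_sim import BENZOCAINE, SLSEParams, simulate_echo_train

__all__ = ["generate_fixtures"]

SWEEP_START = 2.3e6
SWEEP_STOP = 2.5e6
SWEEP_STEP = 10e3
CALIBRATION_QUANTITIES = (6.0, 9.0, 12.0, 15.0, 18.0)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(seed: int, output_dir: Path | str, noise_sigma: float = 0.002) -> dict:
    """Write the fixture bundle and return the manifest dictionary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    coil = CoilSpec()
    pulse = PulseSpec()
    params = SLSEParams()
    presets = package_presets()
    files: list[Path] = []

    # (a) benzocaine in each package type
    for i, (name, package) in enumerate(sorted(presets.items())):
        train = simulate_echo_train(
            BENZOCAINE, package, coil, pulse, params, noise_sigma, seed=seed * 1009 + i
        )
        path = out / f"train_benzocaine_{name}.json"
        write_echo_train(train, path)
        files.append(path)

    # (b) frequency sweep, 10 kHz steps
    sweep_dir = out / "sweep"
    sweep_dir.mkdir(exist_ok=True)
    grid = np.arange(SWEEP_START, SWEEP_STOP + SWEEP_STEP / 2, SWEEP_STEP)
    for j, f0 in enumerate(grid):
        train = simulate_echo_train(
            BENZOCAINE,
            presets["thin_paper"],
            coil,
            pulse,
            replace(params, excitation_frequency=float(f0)),
            noise_sigma,
            seed=seed * 2003 + j,
        )
        path = sweep_dir / f"sweep_{int(f0):08d}.json"
        write_echo_train(train, path)
        files.append(path)

    # (c) calibration sets from each built-in model
    for name, model in sorted(builtin_calibrations().items()):
        df = pd.DataFrame(
            {
                "quantity_g": CALIBRATION_QUANTITIES,
                "amplitude_au": [model.predict_amplitude(q) for q in CALIBRATION_QUANTITIES],
            }
        )
        path = out / f"calibration_{name}.csv"
        df.to_csv(path, index=False)
        files.append(path)

    # (d) two-detector pair (different coil sizes -> different sensitivities)
    detectors = {"detector_a": CoilSpec(), "detector_b": CoilSpec(outer_side=0.05, n_turns=9)}
    for name, det_coil in detectors.items():
        for rep in range(5):
            train = simulate_echo_train(
                BENZOCAINE,
                presets["thin_paper"],
                det_coil,
                pulse,
                params,
                noise_sigma,
                seed=int(rng.integers(0, 2**31)),
            )
            path = out / f"pair_{name}_{rep}.json"
            write_echo_train(train, path)
            files.append(path)

    manifest = {
        "seed": seed,
        "sweep_step_hz": SWEEP_STEP,
        "n_packages": len(presets),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
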