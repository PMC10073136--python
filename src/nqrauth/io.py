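"""File I/O and run configuration.

JSON is the canonical echo-train interchange (bit-exact round trip via the
shortest-repr float encoding); CSV with columns
``echo_index,sample_index,time_s,real,imag`` is a convenience dialect that
round-trips to better than 1e-12.  External CSV exports with different
column names (e.g. a raw-data dump from another acquisition system) can be
ingested by supplying a column-mapping profile.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .coil_field import CoilSpec
from .errors import DomainError, FormatError
from .signal_model import PackageSpec, PulseSpec, package_presets
from .slse_sim import BENZOCAINE, NICOTINAMIDE, EchoTrain, SampleSpec, SLSEParams

__all__ = [
    "RunConfig",
    "read_echo_train",
    "write_echo_train",
    "load_config",
]

CSV_COLUMNS = ("echo_index", "sample_index", "time_s", "real", "imag")


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulation run needs, assembled from a config file."""

    coil: CoilSpec
    pulse: PulseSpec
    slse: SLSEParams
    sample: SampleSpec
    package: PackageSpec
    seed: int
    noise_sigma: float = 0.0
    output_dir: Path = Path(".")


_SAMPLE_PRESETS = {"benzocaine": BENZOCAINE, "nicotinamide": NICOTINAMIDE}


def load_config(path: Path | str, seed: Optional[int] = None) -> RunConfig:
    """Build a :class:`RunConfig` from a JSON file.

    Each section (coil, pulse, slse, sample, package) may be omitted to use
    defaults; ``sample`` and ``package`` may be a preset name or a full
    record.  A ``--seed`` given on the command line overrides the file.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a JSON object")

    coil = CoilSpec(**raw.get("coil", {}))
    pulse = PulseSpec(**raw.get("pulse", {}))
    slse = SLSEParams(**raw.get("slse", {}))

    sample_raw = raw.get("sample", "benzocaine")
    if isinstance(sample_raw, str):
        if sample_raw not in _SAMPLE_PRESETS:
            raise FormatError(f"unknown sample preset {sample_raw!r}")
        sample = _SAMPLE_PRESETS[sample_raw]
    else:
        sample = SampleSpec(**sample_raw)

    package_raw = raw.get("package", "thin_paper")
    if isinstance(package_raw, str):
        presets = package_presets()
        if package_raw not in presets:
            raise FormatError(f"unknown package preset {package_raw!r}")
        package = presets[package_raw]
    else:
        package = PackageSpec(**package_raw)

    cfg_seed = seed if seed is not None else raw.get("seed")
    if cfg_seed is None:
        raise DomainError("a seed is required (config 'seed' or --seed)")
    return RunConfig(
        coil=coil,
        pulse=pulse,
        slse=slse,
        sample=sample,
        package=package,
        seed=int(cfg_seed),
        noise_sigma=float(raw.get("noise_sigma", 0.0)),
        output_dir=Path(raw.get("output_dir", ".")),
    )


def write_echo_train(train: EchoTrain, path: Path | str) -> None:
    """Write a train as JSON (default) or CSV, chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(train, path)
    else:
        _write_json(train, path)


def read_echo_train(path: Path | str, profile: Optional[dict] = None) -> EchoTrain:
    """Read a train from JSON or CSV.

    ``profile`` maps the canonical CSV column names to the names used in an
    external export, e.g. ``{"real": "Re", "imag": "Im"}``.
    """
    path = Path(path)
    text_head = path.read_text(errors="replace")[:1] if path.exists() else None
    if text_head is None:
        raise FormatError(f"no such file: {path}")
    if not text_head:
        raise FormatError(f"{path} is empty")
    if path.suffix.lower() == ".csv":
        return _read_csv(path, profile)
    return _read_json(path)


def _write_json(train: EchoTrain, path: Path) -> None:
    doc = {
        "format": "nqrauth-echo-train",
        "version": 1,
        "params": dataclasses.asdict(train.params),
        "noise_sigma": train.noise_sigma,
        "seed": train.seed,
        "provenance": train.provenance,
        "off_resonance": train.off_resonance,
        "echo_times": train.echo_times.tolist(),
        "samples_real": train.samples.real.tolist(),
        "samples_imag": train.samples.imag.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def _read_json(path: Path) -> EchoTrain:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        params = SLSEParams(**doc["params"])
        samples = np.asarray(doc["samples_real"], dtype=float) + 1j * np.asarray(
            doc["samples_imag"], dtype=float
        )
        return EchoTrain(
            params=params,
            echo_times=np.asarray(doc["echo_times"], dtype=float),
            samples=samples,
            noise_sigma=doc.get("noise_sigma", 0.0),
            seed=doc.get("seed"),
            provenance=doc.get("provenance", f"read from {path}"),
            off_resonance=doc.get("off_resonance", False),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed field ({exc})") from exc


def _write_csv(train: EchoTrain, path: Path) -> None:
    n_echo, m = train.samples.shape
    echo_idx = np.repeat(np.arange(n_echo), m)
    sample_idx = np.tile(np.arange(m), n_echo)
    times = (train.echo_times[:, None] + train.time_base[None, :]).ravel()
    pd.DataFrame(
        {
            "echo_index": echo_idx,
            "sample_index": sample_idx,
            "time_s": times,
            "real": train.samples.real.ravel(),
            "imag": train.samples.imag.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def _read_csv(path: Path, profile: Optional[dict] = None) -> EchoTrain:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if profile:
        df = df.rename(columns={v: k for k, v in profile.items()})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    counts = df.groupby("echo_index").size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index[0]
        first_row = int(df.index[df["echo_index"] == bad][0])
        raise FormatError(
            f"{path}: echo block {bad} (first at row {first_row + 2}) has "
            f"{counts[bad]} samples, expected {counts.iloc[0]}"
        )
    n_echo = counts.size
    m = int(counts.iloc[0])
    df = df.sort_values(["echo_index", "sample_index"])
    samples = (df["real"].to_numpy() + 1j * df["imag"].to_numpy()).reshape(n_echo, m)
    # echo centre = timestamp of the sample at the zero of the per-echo time base
    echo_times = df.loc[df["sample_index"] == m // 2, "time_s"].to_numpy()
    dt = float(np.diff(df["time_s"].to_numpy()[:m]).mean())
    sample_rate = 1.0 / dt
    tE = float(np.diff(echo_times).mean()) if n_echo > 1 else float(echo_times[0])
    params = SLSEParams(
        echo_period=tE,
        n_echoes=n_echo,
        sample_rate=sample_rate,
        acquisition_window=m / sample_rate,
        pulse_length=min(50e-6, tE / 2),
    )
    return EchoTrain(
        params=params,
        echo_times=echo_times,
        samples=samples,
        provenance=f"read from {path}",
    )
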