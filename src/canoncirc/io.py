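"""Configuration, file I/O and run provenance.

Run configurations are plain YAML files validated against a strict schema
(unknown keys rejected, defaults recorded).  Arrays are written as .npy with
a JSON sidecar describing axis semantics (0-based indexing, row 0 = top of
image, origin top-left); frame stacks as PNG sequences or multi-page TIFF;
event streams as CSV with header ``x,y,t_ms,polarity``; metrics as
long-format CSV; provenance as JSON with a config hash so every run is
reproducible from its provenance alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .stimuli import EVENT_DTYPE, EventStream, Stimulus


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

class NumericsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dt: float = Field(5.0, gt=0, description="integration step (ms)")
    steps_per_frame: int = Field(2, ge=1)
    duration: float | None = Field(None, gt=0, description="ms, static runs")
    tolerance: float = Field(1e-6, gt=0)


class ArchitectureConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau_r: float = Field(100.0, gt=0)
    tau_q: float = Field(100.0, gt=0)
    n_orientations: int = Field(8, ge=2)
    n_directions: int = Field(8, ge=2)
    speeds: list[float] = Field(default_factory=lambda: [2.0])
    lambda_fb: float | None = Field(None, ge=0)
    overrides: dict = Field(default_factory=dict,
                            description="builder-specific parameter overrides")


class StimulusConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: list[int] = Field(default_factory=lambda: [128, 128])
    overrides: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Validated experiment run configuration."""

    model_config = ConfigDict(extra="forbid")
    experiment: str
    architecture: ArchitectureConfig = Field(default_factory=ArchitectureConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)
    seed: int = 0
    outdir: str = "runs"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Schema violations raise ``ValueError`` naming the offending key and
    constraint; missing keys are filled with documented defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors())
        raise ValueError(f"invalid run config {path}: {details}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Layer-parameter serialization
# --------------------------------------------------------------------------

def save_layer_params(params, path: str | Path) -> None:
    """Write E-I layer constants (and firing-rate specs) as YAML."""
    from dataclasses import asdict
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def load_layer_params(path: str | Path):
    """Read E-I layer constants back from YAML (round-trip identity)."""
    from canoncirc.core import EILayerParams, FiringRateSpec
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("g_spec", "gq_spec"):
        if isinstance(raw.get(key), dict):
            raw[key] = FiringRateSpec(**raw[key])
    return EILayerParams(**raw)


# --------------------------------------------------------------------------
# Array / stimulus / event I/O
# --------------------------------------------------------------------------

def write_array(arr: np.ndarray, path: str | Path, axes: str,
                meta: dict | None = None) -> None:
    """Write an array as .npy plus a JSON sidecar with axis semantics."""
    path = Path(path)
    np.save(path, np.asarray(arr))
    sidecar = dict(shape=list(arr.shape), dtype=str(arr.dtype), axes=axes,
                   indexing="0-based", origin="top-left row 0",
                   **(meta or {}))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_array(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.load(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return arr, meta


def write_frames(stim: Stimulus, path: str | Path) -> None:
    """Write a frame stack as multi-page TIFF (plus provenance sidecar)."""
    path = Path(path)
    data = (np.clip(stim.frames, 0, 1) * 65535).astype(np.uint16)
    iio.imwrite(path, data, extension=".tif")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(dict(frame_interval_ms=stim.frame_interval,
                       provenance=_jsonable(stim.provenance)), fh, indent=1)


def read_frames(path: str | Path) -> Stimulus:
    path = Path(path)
    data = iio.imread(path)
    if data.ndim == 2:
        data = data[None]
    frames = data.astype(float) / 65535.0
    meta = {}
    if path.with_suffix(".json").exists():
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
    return Stimulus(frames, meta.get("frame_interval_ms", 20.0),
                    meta.get("provenance", {}))


def write_events(stream: EventStream, path: str | Path) -> None:
    """Event stream as CSV with header x,y,t_ms,polarity."""
    df = pd.DataFrame({name: stream.events[name]
                       for name in ("x", "y", "t_ms", "polarity")})
    df.to_csv(path, index=False)


def read_events(path: str | Path, shape: tuple[int, int]) -> EventStream:
    df = pd.read_csv(path)
    ev = np.empty(len(df), dtype=EVENT_DTYPE)
    for name in ("x", "y", "t_ms", "polarity"):
        ev[name] = df[name].to_numpy()
    return EventStream(ev, shape)


# --------------------------------------------------------------------------
# Run outputs
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        if obj.size > 64:
            return dict(array_shape=list(obj.shape), summary="omitted")
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(report: dict, outdir: str | Path,
                  overwrite: bool = False) -> dict:
    """Write an experiment report (metrics, arrays, plots, provenance).

    Refuses to write into a directory holding a previous run's manifest
    unless ``overwrite`` is set.  Returns the manifest: a mapping of every
    written file to its SHA-256 content hash.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{outdir} already holds a run (pass overwrite=True to replace)")
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    metrics = report.get("metrics")
    if metrics is not None and len(metrics):
        p = outdir / "metrics.csv"
        metrics.to_csv(p, index=False)
        written.append(p)
    for name, arr in (report.get("arrays") or {}).items():
        p = outdir / f"{name}.npy"
        write_array(arr, p, axes=report.get("array_axes", {}).get(
            name, "unspecified"))
        written += [p, p.with_suffix(".json")]
    for name, fig in (report.get("figures") or {}).items():
        p = outdir / f"{name}.png"
        fig.savefig(p, dpi=120)
        written.append(p)
    prov = outdir / "provenance.json"
    with open(prov, "w") as fh:
        json.dump(_jsonable(report.get("provenance", {})), fh, indent=1)
    written.append(prov)

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in written}
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def verify_manifest(outdir: str | Path) -> dict[str, bool]:
    """Re-hash every file listed in a run manifest; True = intact."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    return {name: (outdir / name).exists()
            and _sha256(outdir / name) == digest
            for name, digest in manifest.items()}
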