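"""TIFF / CSV / JSON input-output with sidecar metadata.

Movies and PSF stacks travel as multi-page TIFF with a JSON sidecar
(``<name>.json`` next to the file) holding the pixel pitch, frame interval and
provenance — portable across readers, no bespoke TIFF tags required.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import ConfigurationError
from .engine import PSFStack
from .tracking import Movie, Trajectory

__all__ = [
    "write_movie",
    "read_movie",
    "write_psf_stack",
    "read_psf_stack",
    "trajectory_to_frame",
    "write_trajectory",
    "read_trajectory",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(
    path: str | Path,
    frames: np.ndarray,
    pixel_pitch_nm: float,
    dt_s: float,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    frames = np.asarray(frames)
    if frames.dtype not in (np.uint8, np.uint16, np.float32):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    side = {"pixel_pitch_nm": pixel_pitch_nm, "dt_s": dt_s}
    side.update(meta or {})
    _sidecar(path).write_text(json.dumps(side, indent=2))


def read_movie(
    path: str | Path,
    dt_s: float | None = None,
    pixel_pitch_nm: float | None = None,
) -> Movie:
    """Load a multi-page TIFF movie; metadata from the sidecar or arguments."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = {}
    if _sidecar(path).exists():
        side = json.loads(_sidecar(path).read_text())
    dt = dt_s if dt_s is not None else side.get("dt_s")
    pitch = pixel_pitch_nm if pixel_pitch_nm is not None else side.get("pixel_pitch_nm")
    if dt is None:
        raise ConfigurationError(f"{path}: frame interval unknown (no sidecar; pass dt_s)")
    if pitch is None:
        raise ConfigurationError(
            f"{path}: pixel pitch unknown (no sidecar; pass pixel_pitch_nm)"
        )
    return Movie(frames=frames, dt_s=float(dt), pixel_pitch_nm=float(pitch))


def write_psf_stack(path: str | Path, psf: PSFStack) -> None:
    path = Path(path)
    meta = {
        "lateral_pitch_nm": psf.lateral_pitch_nm,
        "z_offsets_nm": [float(z) for z in psf.z_offsets_nm],
        "z_origin_nm": psf.z_origin_nm,
        "normalization": psf.normalization,
        **{k: v for k, v in psf.meta.items() if isinstance(v, (str, int, float, bool))},
    }
    tifffile.imwrite(
        path,
        psf.intensity.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_psf_stack(path: str | Path) -> PSFStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar(path).read_text())
    return PSFStack(
        intensity=np.asarray(data, dtype=float),
        lateral_pitch_nm=float(meta["lateral_pitch_nm"]),
        z_offsets_nm=np.asarray(meta["z_offsets_nm"], dtype=float),
        z_origin_nm=float(meta.get("z_origin_nm", 0.0)),
        normalization=meta.get("normalization", "unit-sum"),
        meta=meta,
    )


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    d = {
        "t_s": traj.t_s,
        "x_nm": traj.x_nm,
        "y_nm": traj.y_nm,
        "z_nm": traj.z_nm if traj.z_nm is not None else np.nan,
        "sigma_z_nm": traj.sigma_z_nm if traj.sigma_z_nm is not None else np.nan,
        "flags": [";".join(f) for f in traj.flags] if traj.flags else "",
    }
    return pd.DataFrame(d)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    flags = [
        [] if (isinstance(f, float) and np.isnan(f)) or f == "" else str(f).split(";")
        for f in df.get("flags", [""] * len(df))
    ]
    return Trajectory(
        t_s=df["t_s"].to_numpy(),
        x_nm=df["x_nm"].to_numpy(),
        y_nm=df["y_nm"].to_numpy(),
        z_nm=df["z_nm"].to_numpy() if "z_nm" in df else None,
        sigma_z_nm=df["sigma_z_nm"].to_numpy() if "sigma_z_nm" in df else None,
        flags=flags,
    )
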