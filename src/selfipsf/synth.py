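"""Synthetic camera frames and Brownian trajectories.

Emulates widefield acquisitions of nanoparticle SELFI PSFs: expected photon
images rendered from the PSF engine, Poisson shot noise, a linear camera
(gain, offset), and 3D Brownian motion of the particle.  All generators take
explicit seeds and are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import CameraConfig
from .engine import EmissionBand, ImagingSystem, ParticleModel, selfi_radial_profile
from .stacks import SubstrateStack

__all__ = [
    "render_frame",
    "expected_image",
    "brownian_path",
    "SyntheticMovie",
    "synth_movie",
]


def expected_image(
    psf_frame: np.ndarray,
    emitter_positions_nm,
    photons,
    background: float,
    pixel_pitch_nm: float,
) -> tuple[np.ndarray, list[str]]:
    """Expected photon image: shifted copies of a unit-sum PSF plus background.

    ``emitter_positions_nm`` are (x, y) offsets from the field centre.
    Emitters outside the field are skipped with a warning flag.
    """
    from scipy.ndimage import shift as nd_shift

    frame = np.asarray(psf_frame, dtype=float)
    frame = frame / frame.sum()
    ny, nx = frame.shape
    out = np.full(frame.shape, float(background))
    flags: list[str] = []
    photons = np.broadcast_to(
        np.asarray(photons, dtype=float), (len(emitter_positions_nm),)
    )
    for (x_nm, y_nm), nph in zip(emitter_positions_nm, photons):
        dx = x_nm / pixel_pitch_nm
        dy = y_nm / pixel_pitch_nm
        if abs(dx) > nx / 2 or abs(dy) > ny / 2:
            flags.append(f"emitter_outside_field:({x_nm:.0f},{y_nm:.0f})")
            continue
        out += nph * nd_shift(frame, (dy, dx), order=1, mode="constant", cval=0.0)
    return out, flags


def render_frame(
    expected: np.ndarray,
    camera: CameraConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Integer camera image ``offset + gain * Poisson(expected)`` (uint16)."""
    camera = camera or CameraConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = camera.offset + camera.gain * rng.poisson(np.clip(expected, 0, None))
    return np.clip(np.round(counts), 0, 65535).astype(np.uint16)


def brownian_path(
    d_um2_s: float,
    dt_s: float,
    n_steps: int,
    start_nm=(0.0, 0.0, 200.0),
    seed: int | np.random.Generator = 0,
    reflect_z_nm: tuple[float, float] | None = None,
) -> np.ndarray:
    """3D Brownian trajectory, shape ``(n_steps + 1, 3)`` in nm.

    Increments are independent Gaussians with per-axis variance ``2*D*dt``.
    ``reflect_z_nm`` optionally confines the z coordinate between two
    reflecting planes (particle near a substrate); x and y stay free.
    """
    if d_um2_s < 0 or dt_s <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_nm = math.sqrt(2.0 * d_um2_s * dt_s) * 1000.0
    steps = rng.normal(0.0, sigma_nm, size=(n_steps, 3))
    path = np.empty((n_steps + 1, 3))
    path[0] = start_nm
    path[1:] = np.asarray(start_nm) + np.cumsum(steps, axis=0)
    if reflect_z_nm is not None:
        lo, hi = reflect_z_nm
        if hi <= lo:
            raise ValueError("reflecting interval must have hi > lo")
        span = hi - lo
        z = np.mod(path[:, 2] - lo, 2 * span)
        path[:, 2] = lo + np.where(z > span, 2 * span - z, z)
    return path


@dataclass
class SyntheticMovie:
    """Rendered frames plus the ground truth that generated them."""

    frames: np.ndarray  # (n_frames, ny, nx) uint16
    dt_s: float
    pixel_pitch_nm: float
    truth: np.ndarray  # (n_frames, 3) positions in nm (x, y, z=spacing)
    meta: dict


def synth_movie(
    particle_template: ParticleModel,
    stack: SubstrateStack | None,
    imaging: ImagingSystem,
    band: EmissionBand | float,
    path_nm: np.ndarray,
    dt_s: float,
    photons: float = 1e4,
    background: float = 2.0,
    camera: CameraConfig | None = None,
    seed: int | np.random.Generator = 0,
    focus_offsets_nm: np.ndarray | None = None,
) -> SyntheticMovie:
    """Render a widefield movie of one particle moving along ``path_nm``.

    The z component of the path is the mirror spacing; frames are rendered
    from the radial PSF profile at each spacing (exact sub-pixel placement),
    with the detection plane fixed by ``imaging``'s focus convention.
    ``focus_offsets_nm`` optionally adds a per-frame focus drift.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    camera = camera or CameraConfig()
    n_frames = len(path_nm)
    if focus_offsets_nm is None:
        focus_offsets_nm = np.zeros(n_frames)
    npx = imaging.field_px
    half = (npx - 1) / 2.0
    c = (np.arange(npx) - half) * imaging.pixel_pitch_nm
    xx, yy = np.meshgrid(c, c)

    frames = np.empty((n_frames, npx, npx), dtype=np.uint16)
    r_fine = np.linspace(
        0.0, math.hypot(c[-1] - c[0], c[-1] - c[0]) / 1.4 + 500.0, 1024
    )
    for i, ((x, y, z), foff) in enumerate(zip(path_nm, focus_offsets_nm)):
        particle = ParticleModel(
            spacing_nm=float(z),
            radius_nm=particle_template.radius_nm,
            dipole_weights=particle_template.dipole_weights,
            emitter_averaging_nm=particle_template.emitter_averaging_nm,
        )
        df = imaging.detection_defocus(particle.spacing_nm) + float(foff)
        prof = selfi_radial_profile(
            r_fine, particle, stack, imaging, band, defocus_nm=df
        )
        rr = np.hypot(xx - x, yy - y)
        img = np.interp(rr, r_fine, prof)
        img = img / img.sum() * photons + background
        frames[i] = render_frame(img, camera, rng)

    return SyntheticMovie(
        frames=frames,
        dt_s=dt_s,
        pixel_pitch_nm=imaging.pixel_pitch_nm,
        truth=np.asarray(path_nm, dtype=float),
        meta={
            "photons": photons,
            "background": background,
            "camera": camera.to_dict(),
            "focus_offsets_nm": np.asarray(focus_offsets_nm).tolist(),
        },
    )
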