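"""Deterministic fixture bundles exercising the full pipeline.

Packages the canonical study scenarios as regenerable files: noiseless PSF
stacks over the characteristic spacing series, noisy single frames, a
stair-structure scene whose ground-truth spacings are the step heights plus
the particle radius, a Brownian tracking movie, and a matching calibration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import build_calibration, simulate_feature_samples
from .config import CameraConfig, OpticsConfig, RunConfig
from .engine import ImagingSystem, ParticleModel, selfi_psf
from .io import write_movie, write_psf_stack
from .stacks import SubstrateStack
from .synth import brownian_path, expected_image, render_frame, synth_movie

__all__ = [
    "FixtureSet",
    "make_fixtures",
    "step_scene_spacings",
    "SPACING_SERIES_NM",
    "STEP_HEIGHTS_NM",
    "PARTICLE_RADIUS_NM",
    "BROWNIAN_D_UM2_S",
]

# Characteristic spacing series of the distance-dependent PSF study (nm).
SPACING_SERIES_NM = (71.6, 140.0, 154.9, 214.7, 326.9, 483.9)
# AFM-measured stair heights (nm) of the step-structure sensing scenario.
STEP_HEIGHTS_NM = (88.2, 105.4, 115.4)
PARTICLE_RADIUS_NM = 16.5
# Diffusion coefficient of the tracked particle in glycerol solution.
BROWNIAN_D_UM2_S = 0.0174
BROWNIAN_FRAMES = 130
BROWNIAN_DT_S = 0.1


def step_scene_spacings(
    step_heights_nm=STEP_HEIGHTS_NM, radius_nm: float = PARTICLE_RADIUS_NM
):
    """Mirror spacings of particles resting on spacer steps: height + radius."""
    return tuple(h + radius_nm for h in step_heights_nm)


@dataclass
class FixtureSet:
    root: Path
    manifest: dict

    def path(self, name: str) -> Path:
        return self.root / name


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def make_fixtures(
    seed: int,
    outdir: str | Path,
    optics: OpticsConfig | None = None,
    calibration_step_nm: float = 5.0,
) -> FixtureSet:
    """Write the fixture bundle under ``outdir`` and return its manifest.

    Fully deterministic for a fixed seed: the manifest records per-file
    SHA-256 digests, inputs and the expected summary values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    imaging = ImagingSystem.from_config(optics)
    stack = SubstrateStack.from_config(optics)
    camera = CameraConfig()
    manifest: dict = {"seed": seed, "optics": optics.to_dict(), "files": {}}

    # 1. noiseless PSF stacks for the spacing series
    for s in SPACING_SERIES_NM:
        particle = ParticleModel(spacing_nm=s)
        psf = selfi_psf(
            particle, stack, imaging, optics.wavelength_nm, z_range=[-40.0, 0.0, 40.0]
        )
        name = f"psf_{s:.1f}nm.tif"
        write_psf_stack(outdir / name, psf)
        manifest["files"][name] = {
            "spacing_nm": s,
            "sha256_16": _digest(psf.intensity.astype(np.float32)),
        }

    # 2. noisy single frames at two contrasting spacings
    for s in (SPACING_SERIES_NM[0], SPACING_SERIES_NM[2]):
        particle = ParticleModel(spacing_nm=s)
        psf = selfi_psf(particle, stack, imaging, optics.wavelength_nm)
        exp, _ = expected_image(
            psf.frame(0), [(0.0, 0.0)], 1e4, 2.0, imaging.pixel_pitch_nm
        )
        frame = render_frame(exp, camera, rng)
        name = f"noisy_{s:.1f}nm.tif"
        write_movie(outdir / name, frame[None], imaging.pixel_pitch_nm, 0.02)
        manifest["files"][name] = {"spacing_nm": s, "sha256_16": _digest(frame)}

    # 3. stair-structure scene: three particles, one per step, single frame
    spacings = step_scene_spacings()
    positions = [(-1200.0, 0.0), (0.0, 0.0), (1200.0, 0.0)]
    exp_total = None
    for s, (x, y) in zip(spacings, positions):
        particle = ParticleModel(spacing_nm=s)
        psf = selfi_psf(particle, stack, imaging, optics.wavelength_nm)
        exp, _ = expected_image(
            psf.frame(0), [(x, y)], 1e4, 0.0, imaging.pixel_pitch_nm
        )
        exp_total = exp if exp_total is None else exp_total + exp
    exp_total += 2.0
    step_frame = render_frame(exp_total, camera, rng)
    write_movie(outdir / "step_scene.tif", step_frame[None], imaging.pixel_pitch_nm, 0.02)
    manifest["files"]["step_scene.tif"] = {
        "step_heights_nm": list(STEP_HEIGHTS_NM),
        "particle_radius_nm": PARTICLE_RADIUS_NM,
        "spacings_nm": list(spacings),
        "positions_nm": positions,
        "sha256_16": _digest(step_frame),
    }

    # 4. Brownian tracking movie
    path = brownian_path(
        BROWNIAN_D_UM2_S,
        BROWNIAN_DT_S,
        BROWNIAN_FRAMES - 1,
        start_nm=(0.0, 0.0, 320.0),
        seed=rng,
        reflect_z_nm=(60.0, 480.0),
    )
    movie = synth_movie(
        ParticleModel(spacing_nm=320.0),
        stack,
        imaging,
        optics.wavelength_nm,
        path,
        BROWNIAN_DT_S,
        photons=1e4,
        background=2.0,
        camera=camera,
        seed=rng,
    )
    write_movie(
        outdir / "brownian.tif",
        movie.frames,
        imaging.pixel_pitch_nm,
        BROWNIAN_DT_S,
        meta={"d_um2_s": BROWNIAN_D_UM2_S},
    )
    np.savetxt(
        outdir / "brownian_truth.csv",
        np.column_stack([np.arange(len(path)) * BROWNIAN_DT_S, path]),
        delimiter=",",
        header="t_s,x_nm,y_nm,z_nm",
        comments="",
    )
    manifest["files"]["brownian.tif"] = {
        "d_um2_s": BROWNIAN_D_UM2_S,
        "n_frames": BROWNIAN_FRAMES,
        "dt_s": BROWNIAN_DT_S,
        "sha256_16": _digest(movie.frames),
    }

    # 5. matching calibration
    z_values = np.arange(30.0, 500.0 + 1e-9, calibration_step_nm)
    samples = simulate_feature_samples(optics, z_values)
    calib = build_calibration(
        samples,
        provenance={"kind": "simulated", "optics": optics.to_dict()},
    )
    calib.dump(outdir / "calibration.json")
    manifest["files"]["calibration.json"] = {
        "z_step_nm": calibration_step_nm,
        "n_samples": len(samples),
    }

    RunConfig(optics=optics, camera=camera, seed=seed).dump(outdir / "run_config.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return FixtureSet(root=outdir, manifest=manifest)
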