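"""Feature-versus-distance calibration and its inversion.

The four PSF descriptors vary characteristically with the emitter-mirror
spacing; smooth per-feature calibration curves built from simulated (or
measured) samples can therefore be inverted: a measured feature vector is
matched against all four curves by weighted least squares, the spacing with
the smallest standardized misfit wins, and the local curvature of the misfit
yields the distance uncertainty.  Leave-one-feature-out re-estimation guards
against a single corrupted descriptor, and secondary cost minima are reported
as candidates so that temporal continuity can disambiguate during tracking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .config import OpticsConfig
from .engine import (
    EmissionBand,
    ImagingSystem,
    ParticleModel,
    selfi_psf,
    stationary_defocus,
)
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .stacks import SubstrateStack

__all__ = [
    "CalibrationModel",
    "DistanceEstimate",
    "CalibrationError",
    "build_calibration",
    "simulate_feature_samples",
    "estimate_distance",
    "resolution_curve",
    "defocus_sensitivity",
    "DefocusSensitivity",
    "WORKING_RANGE_DEFAULT",
]

# Working range of mirror-referenced axial sensing (nm): closer than ~30 nm
# metal quenching degrades the signal, beyond ~500 nm the reflected field is
# too weak for usable interference contrast.
WORKING_RANGE_DEFAULT = (30.0, 500.0)


class CalibrationError(ValueError):
    """Unusable calibration input."""


@dataclass
class CalibrationModel:
    """Four feature-vs-distance curves on a common spacing grid.

    ``curves``/``derivs`` hold per-feature values and first derivatives on
    ``z_grid_nm`` (nan outside a feature's validity region); ``sigma`` holds
    per-feature noise scales in feature units.
    """

    z_grid_nm: np.ndarray
    curves: dict
    derivs: dict
    sigma: dict
    valid: dict
    working_range: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def curve(self, name: str) -> np.ndarray:
        return self.curves[name]

    def features_at(self, z_nm: float) -> dict:
        out = {}
        for name in FEATURE_NAMES:
            out[name] = float(np.interp(z_nm, self.z_grid_nm, self.curves[name]))
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(a):
            return [None if not math.isfinite(v) else float(v) for v in a]

        return {
            "z_grid_nm": [float(z) for z in self.z_grid_nm],
            "curves": {k: clean(v) for k, v in self.curves.items()},
            "derivs": {k: clean(v) for k, v in self.derivs.items()},
            "sigma": {k: float(v) for k, v in self.sigma.items()},
            "working_range": list(self.working_range),
            "provenance": self.provenance,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        z = np.asarray(d["z_grid_nm"], dtype=float)

        def arr(v):
            return np.array([np.nan if x is None else x for x in v], dtype=float)

        curves = {k: arr(v) for k, v in d["curves"].items()}
        derivs = {k: arr(v) for k, v in d["derivs"].items()}
        valid = {k: np.isfinite(v) for k, v in curves.items()}
        return cls(
            z_grid_nm=z,
            curves=curves,
            derivs=derivs,
            sigma={k: float(v) for k, v in d["sigma"].items()},
            valid=valid,
            working_range=tuple(d["working_range"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DistanceEstimate:
    """Inverted axial distance with uncertainty and diagnostics."""

    z_hat_nm: float
    sigma_z_nm: float
    cost: float
    candidates: list  # [(z_nm, cost), ...] including the global minimum
    features_used: dict
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# building calibrations


def _pool_replicates(zs: np.ndarray, vals: np.ndarray):
    """Group exact-replicate z values; return knot z, mean, pooled std or None."""
    order = np.argsort(zs, kind="stable")
    zs, vals = zs[order], vals[order]
    knots_z, knots_v, stds = [], [], []
    i = 0
    while i < len(zs):
        j = i
        while j < len(zs) and zs[j] == zs[i]:
            j += 1
        knots_z.append(zs[i])
        knots_v.append(vals[i:j].mean())
        if j - i >= 2:
            stds.append(vals[i:j].std(ddof=1))
        i = j
    pooled = float(np.mean(stds)) if len(stds) >= 3 else None
    return np.array(knots_z), np.array(knots_v), pooled


def build_calibration(
    samples,
    smoothing: float | None = 0.0,
    z_step_nm: float = 1.0,
    working_range: tuple[float, float] = WORKING_RANGE_DEFAULT,
    noise_scales: dict | None = None,
    provenance: dict | None = None,
) -> CalibrationModel:
    """Fit per-feature calibration curves from ``(z_nm, FeatureVector)`` samples.

    ``smoothing=0`` interpolates the (replicate-averaged) knots exactly;
    ``smoothing=None`` selects a smoothing spline by generalized
    cross-validation (use with noisy samples).  Per-feature noise scales come
    from replicate scatter when available, else from ``noise_scales``, else
    default to 2 % of each curve's dynamic range.

    Features that are undefined over part of the range (the inner dip width
    exists only in doughnut regimes) are fitted per contiguous region; regions
    with fewer than 4 knots are dropped.
    """
    if len({z for z, _ in samples}) < 10:
        raise CalibrationError("need at least 10 distinct spacings")
    zs_all = np.array(sorted({z for z, _ in samples}))
    lo, hi = working_range
    if zs_all.max() - zs_all.min() < 0.5 * (hi - lo):
        raise CalibrationError("samples must span the working range")
    lo = max(lo, zs_all.min())
    hi = min(hi, zs_all.max())
    z_grid = np.arange(lo, hi + z_step_nm / 2, z_step_nm)
    typical_gap = float(np.median(np.diff(zs_all)))

    curves, derivs, sigma, valid = {}, {}, {}, {}
    for name in FEATURE_NAMES:
        zk = np.array([z for z, fv in samples if fv.valid.get(name)])
        vk = np.array([fv.value(name) for z, fv in samples if fv.valid.get(name)])
        grid_vals = np.full(z_grid.shape, np.nan)
        grid_der = np.full(z_grid.shape, np.nan)
        pooled = None
        if len(zk) >= 4:
            kz, kv, pooled = _pool_replicates(zk, vk)
            # split into contiguous regions where the feature is defined
            breaks = np.nonzero(np.diff(kz) > 3.0 * typical_gap)[0]
            min_knots = 4 if smoothing == 0.0 else 5
            for seg in np.split(np.arange(len(kz)), breaks + 1):
                if len(seg) < min_knots:
                    continue
                zseg, vseg = kz[seg], kv[seg]
                if smoothing == 0.0:
                    sp = CubicSpline(zseg, vseg)
                else:
                    sp = make_smoothing_spline(zseg, vseg, lam=smoothing)
                m = (z_grid >= zseg[0]) & (z_grid <= zseg[-1])
                grid_vals[m] = sp(z_grid[m])
                grid_der[m] = sp.derivative()(z_grid[m])
        curves[name] = grid_vals
        derivs[name] = grid_der
        valid[name] = np.isfinite(grid_vals)
        if pooled is not None and pooled > 0:
            sigma[name] = pooled
        elif noise_scales and name in noise_scales:
            sigma[name] = float(noise_scales[name])
        else:
            rng_ = np.nanmax(grid_vals) - np.nanmin(grid_vals) if valid[name].any() else 1.0
            sigma[name] = max(0.02 * rng_, 1e-6)

    return CalibrationModel(
        z_grid_nm=z_grid,
        curves=curves,
        derivs=derivs,
        sigma=sigma,
        valid=valid,
        working_range=(lo, hi),
        provenance=provenance or {},
    )


def simulate_feature_samples(
    optics: OpticsConfig,
    z_values_nm,
    particle_kwargs: dict | None = None,
    band: EmissionBand | float | None = None,
    n_angles: int = 16,
    photons: float | None = None,
    background: float = 2.0,
    n_rep: int = 1,
    seed: int = 0,
) -> list:
    """Simulator samples ``[(z, FeatureVector), ...]`` for calibration.

    With ``photons=None`` the samples are noiseless (features straight from
    the simulated PSF).  With a photon budget, ``n_rep`` camera frames are
    rendered per spacing and measured like real data — the calibration then
    shares any small estimator biases with the measurement protocol and its
    noise scales come from the replicate scatter.
    """
    particle_kwargs = dict(particle_kwargs or {})
    imaging = ImagingSystem.from_config(optics)
    stack = SubstrateStack.from_config(optics)
    if band is None:
        band = optics.wavelength_nm
    rng = np.random.default_rng(seed)
    samples = []
    for z in np.atleast_1d(np.asarray(z_values_nm, dtype=float)):
        particle = ParticleModel(spacing_nm=float(z), **particle_kwargs)
        psf = selfi_psf(particle, stack, imaging, band)
        if photons is None:
            fv = extract_features(
                psf.frame(0),
                imaging.pixel_pitch_nm,
                center=((imaging.field_px - 1) / 2.0,) * 2,
                n_angles=n_angles,
            )
            samples.append((float(z), fv))
            continue
        from .config import CameraConfig
        from .synth import expected_image, render_frame

        exp, _ = expected_image(
            psf.frame(0), [(0.0, 0.0)], photons, background, imaging.pixel_pitch_nm
        )
        for _ in range(n_rep):
            frame = render_frame(exp, CameraConfig(), rng).astype(float)
            try:
                fv = extract_features(frame, imaging.pixel_pitch_nm, n_angles=n_angles)
            except Exception:
                continue
            samples.append((float(z), fv))
    return samples


def measure_noise_scales(
    optics: OpticsConfig,
    photons: float = 1e4,
    background: float = 2.0,
    z_probe=(60.0, 120.0, 170.0, 250.0, 330.0, 420.0),
    n_rep: int = 12,
    seed: int = 0,
    particle_kwargs: dict | None = None,
) -> dict:
    """Empirical per-feature noise (std over rendered noisy replicates).

    Renders camera frames at the given photon budget for a handful of probe
    spacings, extracts features from each, and returns the median per-feature
    standard deviation — the ``noise_scales`` a realistic calibration should
    be weighted with.
    """
    from .config import CameraConfig
    from .synth import expected_image, render_frame

    rng = np.random.default_rng(seed)
    imaging = ImagingSystem.from_config(optics)
    stack = SubstrateStack.from_config(optics)
    cam = CameraConfig()
    scales: dict = {k: [] for k in FEATURE_NAMES}
    for z in z_probe:
        particle = ParticleModel(spacing_nm=float(z), **(particle_kwargs or {}))
        psf = selfi_psf(particle, stack, imaging, optics.wavelength_nm)
        exp, _ = expected_image(
            psf.frame(0), [(0.0, 0.0)], photons, background, imaging.pixel_pitch_nm
        )
        vals: dict = {k: [] for k in FEATURE_NAMES}
        for _ in range(n_rep):
            frame = render_frame(exp, cam, rng).astype(float)
            try:
                fv = extract_features(frame, imaging.pixel_pitch_nm)
            except Exception:
                continue
            for k in FEATURE_NAMES:
                vals[k].append(fv.value(k))
        for k in FEATURE_NAMES:
            v = np.asarray(vals[k], dtype=float)
            v = v[np.isfinite(v)]
            if len(v) >= max(4, n_rep // 2):
                scales[k].append(float(np.std(v, ddof=1)))
    return {
        k: float(np.median(v)) for k, v in scales.items() if v
    }


# ---------------------------------------------------------------------------
# inversion


def _grid_cost(fv: FeatureVector, calib: CalibrationModel, names) -> np.ndarray:
    cost_sum = np.zeros_like(calib.z_grid_nm)
    n_contrib = np.zeros_like(calib.z_grid_nm)
    for name in names:
        mask = calib.valid[name]
        res = np.zeros_like(cost_sum)
        res[mask] = (fv.value(name) - calib.curves[name][mask]) / calib.sigma[name]
        cost_sum += np.where(mask, res**2, 0.0)
        n_contrib += mask
    cost = np.where(n_contrib >= 2, cost_sum / np.maximum(n_contrib, 1), np.inf)
    return cost


def _refine(z, cost, i):
    if 0 < i < len(z) - 1 and np.isfinite(cost[i - 1 : i + 2]).all():
        y0, y1, y2 = cost[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            step = z[1] - z[0]
            return float(z[i] + 0.5 * step * (y0 - y2) / denom)
    return float(z[i])


def _sigma_z_at(calib: CalibrationModel, z_hat: float, names) -> float:
    acc = 0.0
    for name in names:
        d = np.interp(z_hat, calib.z_grid_nm, calib.derivs[name])
        if math.isfinite(d):
            acc += (d / calib.sigma[name]) ** 2
    return float(1.0 / math.sqrt(acc)) if acc > 0 else float("inf")


def estimate_distance(
    fv: FeatureVector,
    calib: CalibrationModel,
    prior: tuple[float, float] | None = None,
) -> DistanceEstimate:
    """Invert a feature vector to an axial distance on the calibration grid.

    Minimizes the mean standardized squared residual over all features that
    are valid both in the measurement and the calibration, refines the grid
    minimum parabolically, and cross-validates by leave-one-feature-out
    re-estimation (disagreement beyond 3 sigma_z is flagged).
    """
    names = [
        n
        for n in FEATURE_NAMES
        if fv.valid.get(n) and calib.valid[n].any()
    ]
    if len(names) < 2:
        raise CalibrationError("need at least two valid features to invert")

    z = calib.z_grid_nm
    cost = _grid_cost(fv, calib, names)
    if prior is not None:
        outside = (z < prior[0]) | (z > prior[1])
        cost = np.where(outside, np.inf, cost)
    if not np.isfinite(cost).any():
        raise CalibrationError("no usable grid point (check prior/validity)")

    i_min = int(np.nanargmin(cost))
    z_hat = _refine(z, cost, i_min)
    c_min = float(cost[i_min])

    # secondary minima: keep everything within 2x the global cost, plus an
    # absolute slack of 4 (mean standardized residual^2), so near-degenerate
    # interference branches stay available for continuity-based selection
    candidates = [(z_hat, c_min)]
    finite = np.isfinite(cost)
    thresh = max(2.0 * c_min, c_min + 4.0)
    for i in range(1, len(z) - 1):
        if i == i_min or not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if cost[i] <= cost[i - 1] and cost[i] <= cost[i + 1] and cost[i] <= thresh:
            candidates.append((_refine(z, cost, i), float(cost[i])))
    candidates.sort(key=lambda t: t[1])

    sigma_z = _sigma_z_at(calib, z_hat, names)
    flags: list[str] = []

    if len(names) >= 3:
        disagree = 0
        tol = 3.0 * sigma_z if math.isfinite(sigma_z) else 10.0
        for leave in names:
            sub = [n for n in names if n != leave]
            c2 = _grid_cost(fv, calib, sub)
            if prior is not None:
                c2 = np.where((z < prior[0]) | (z > prior[1]), np.inf, c2)
            if not np.isfinite(c2).any():
                continue
            z_loo = _refine(z, c2, int(np.nanargmin(c2)))
            if abs(z_loo - z_hat) > max(tol, 1.0):
                disagree += 1
        if disagree:
            flags.append("loo_disagreement")
        if disagree == len(names):
            flags.append("ambiguous")

    return DistanceEstimate(
        z_hat_nm=z_hat,
        sigma_z_nm=sigma_z,
        cost=c_min,
        candidates=candidates,
        features_used={n: (n in names) for n in FEATURE_NAMES},
        flags=flags,
    )


def resolution_curve(calib: CalibrationModel) -> np.ndarray:
    """Predicted axial uncertainty sigma_z(z) over the calibration grid.

    Inverse-variance combination of the single-feature sensitivities:
    ``sigma_z = [sum_k (f_k'(z)/sigma_k)^2]^(-1/2)``; infinity where no
    feature has slope.
    """
    z = calib.z_grid_nm
    acc = np.zeros_like(z)
    for name in FEATURE_NAMES:
        d = calib.derivs[name]
        ok = np.isfinite(d)
        acc[ok] += (d[ok] / calib.sigma[name]) ** 2
    with np.errstate(divide="ignore"):
        return np.where(acc > 0, 1.0 / np.sqrt(acc), np.inf)


# ---------------------------------------------------------------------------
# defocus sensitivity


@dataclass
class DefocusSensitivity:
    max_relative_change: float
    per_feature: dict
    reference_defocus_nm: float
    flags: list


def defocus_sensitivity(
    optics: OpticsConfig,
    spacing_nm: float,
    defocus_range_nm,
    center: str = "stationary",
    particle_kwargs: dict | None = None,
) -> DefocusSensitivity:
    """Maximum relative feature change over a detection-plane sweep.

    ``defocus_range_nm`` lists plane offsets relative to the reference plane;
    with ``center="stationary"`` the reference is the axial centre of the
    interference structure (the plane where the dip contrast is stationary,
    i.e. the operational in-focus plane of a drift-immune measurement), with
    ``center="configured"`` it is the imaging system's own convention.
    Features undefined at any offset are excluded and flagged.
    """
    offsets = np.atleast_1d(np.asarray(defocus_range_nm, dtype=float))
    particle = ParticleModel(spacing_nm=spacing_nm, **(particle_kwargs or {}))
    imaging = ImagingSystem.from_config(optics)
    stack = SubstrateStack.from_config(optics)
    band = optics.wavelength_nm

    ref = 0.0
    if center == "stationary":
        ref = stationary_defocus(particle, stack, imaging, band)
    elif center != "configured":
        raise ValueError("center must be 'stationary' or 'configured'")

    def feats(off):
        psf = selfi_psf(particle, stack, imaging, band, z_range=[ref + off])
        return extract_features(
            psf.frame(0),
            imaging.pixel_pitch_nm,
            center=((imaging.field_px - 1) / 2.0,) * 2,
        )

    f0 = feats(0.0)
    per_feature = {}
    flags: list[str] = []
    for name in FEATURE_NAMES:
        per_feature[name] = 0.0
    for off in offsets:
        if off == 0.0:
            continue
        f = feats(off)
        for name in FEATURE_NAMES:
            v0, v = f0.value(name), f.value(name)
            if not (math.isfinite(v0) and math.isfinite(v)) or v0 == 0:
                if name not in [fl.split(":")[-1] for fl in flags]:
                    flags.append(f"undefined_at_some_defocus:{name}")
                continue
            per_feature[name] = max(per_feature[name], abs(v - v0) / abs(v0))
    usable = [
        v
        for name, v in per_feature.items()
        if f"undefined_at_some_defocus:{name}" not in flags and f0.valid.get(name)
    ]
    return DefocusSensitivity(
        max_relative_change=float(max(usable)) if usable else float("nan"),
        per_feature=per_feature,
        reference_defocus_nm=float(ref),
        flags=flags,
    )
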