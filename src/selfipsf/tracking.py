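"""Single-particle detection, linking, axial assignment and diffusion analysis.

The pipeline turns a widefield movie into 3D trajectories: band-pass spot
detection with sub-pixel refinement, greedy nearest-neighbour frame linking,
per-frame feature extraction and calibration inversion for the axial
coordinate (with temporal continuity selecting among interference-ambiguous
candidates), then cumulative displacement, time-averaged mean-square
displacement, a power-law diffusion fit ``MSD = 2*d*D*tau^alpha`` and the
Stokes-Einstein viscosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationModel, estimate_distance
from .features import DetectionError, extract_features, locate_center

__all__ = [
    "Movie",
    "Trajectory",
    "DiffusionFit",
    "ViscosityResult",
    "detect_spots",
    "link",
    "axialize",
    "cumulative_displacement",
    "msd",
    "fit_diffusion",
    "viscosity",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass
class Movie:
    frames: np.ndarray  # (n_frames, ny, nx)
    dt_s: float
    pixel_pitch_nm: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("movie needs a (n_frames, ny, nx) array")
        if self.dt_s <= 0 or self.pixel_pitch_nm <= 0:
            raise ValueError("dt and pixel pitch must be > 0")


@dataclass
class Trajectory:
    """Time-stamped positions in nm; nan marks gaps, flags mark quality."""

    t_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    z_nm: np.ndarray | None = None
    sigma_z_nm: np.ndarray | None = None
    flags: list = field(default_factory=list)  # list[list[str]] per point
    frame_index: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t_s)

    def positions(self) -> np.ndarray:
        z = self.z_nm if self.z_nm is not None else np.zeros_like(self.x_nm)
        return np.column_stack([self.x_nm, self.y_nm, z])


# ---------------------------------------------------------------------------
# detection and linking


def detect_spots(
    frame: np.ndarray,
    pixel_pitch_nm: float,
    psf_radius_nm: float = 250.0,
    k: float = 5.0,
    min_separation_nm: float | None = None,
    refine: bool = True,
) -> list[tuple[float, float, float]]:
    """Band-pass detection of PSF-sized spots; returns ``(x_px, y_px, score)``.

    The band-pass difference of Gaussians is tuned to the expected PSF radius
    so that the two lobes of a doughnut merge into a single detection; maxima
    must exceed ``k`` robust noise standard deviations.  Sub-pixel positions
    come from radial-symmetry refinement on a crop around each maximum.
    """
    img = np.asarray(frame, dtype=float)
    s_small = 0.5 * psf_radius_nm / pixel_pitch_nm
    s_large = 2.0 * psf_radius_nm / pixel_pitch_nm
    bp = ndimage.gaussian_filter(img, s_small) - ndimage.gaussian_filter(img, s_large)
    noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    if min_separation_nm is None:
        min_separation_nm = 2.0 * psf_radius_nm
    size = max(3, int(round(min_separation_nm / pixel_pitch_nm)))
    maxima = (bp == ndimage.maximum_filter(bp, size=size)) & (bp > k * max(noise, 1e-12))
    ys, xs = np.nonzero(maxima)

    out = []
    half = int(round(2.0 * psf_radius_nm / pixel_pitch_nm))
    for y, x in zip(ys, xs):
        score = float(bp[y, x])
        if refine:
            y0, y1 = max(0, y - half), min(img.shape[0], y + half + 1)
            x0, x1 = max(0, x - half), min(img.shape[1], x + half + 1)
            try:
                cx, cy = locate_center(img[y0:y1, x0:x1])
                out.append((x0 + cx, y0 + cy, score))
                continue
            except DetectionError:
                pass
        out.append((float(x), float(y), score))
    out.sort(key=lambda d: -d[2])
    return out


def link(
    detections_per_frame,
    max_disp_nm: float,
    pixel_pitch_nm: float,
    dt_s: float,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour linking of per-frame detections.

    Pairs are assigned in ascending order of displacement (ties broken by
    detection order), unmatched detections start new tracks, and tracks absent
    for more than ``max_gap`` frames are closed.  Suited to the sparse scenes
    of single-particle mirror-sensing experiments.
    """
    if max_disp_nm <= 0:
        raise ValueError("max_disp must be > 0")
    tracks: list[dict] = []  # {"pts": [(frame, x_nm, y_nm, flags)], "last_frame": int}
    open_tracks: list[dict] = []

    for fi, dets in enumerate(detections_per_frame):
        pos = [(d[0] * pixel_pitch_nm, d[1] * pixel_pitch_nm) for d in dets]
        # candidate pairs (distance, track_idx, det_idx), greedy by distance
        pairs = []
        for ti, tr in enumerate(open_tracks):
            gap = fi - tr["last_frame"]
            if gap > max_gap + 1:
                continue
            _, xl, yl, _ = tr["pts"][-1]
            for di, (x, y) in enumerate(pos):
                dist = math.hypot(x - xl, y - yl)
                if dist <= max_disp_nm * gap:
                    pairs.append((dist, ti, di))
        pairs.sort(key=lambda p: p[0])
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = open_tracks[ti]
            gap = fi - tr["last_frame"]
            flags = ["gap_bridged"] if gap > 1 else []
            tr["pts"].append((fi, pos[di][0], pos[di][1], flags))
            tr["last_frame"] = fi
        for di, (x, y) in enumerate(pos):
            if di not in used_d:
                tr = {"pts": [(fi, x, y, [])], "last_frame": fi}
                open_tracks.append(tr)
                tracks.append(tr)
        open_tracks = [t for t in open_tracks if fi - t["last_frame"] <= max_gap]

    out = []
    for tr in tracks:
        pts = tr["pts"]
        out.append(
            Trajectory(
                t_s=np.array([p[0] * dt_s for p in pts]),
                x_nm=np.array([p[1] for p in pts]),
                y_nm=np.array([p[2] for p in pts]),
                flags=[list(p[3]) for p in pts],
                frame_index=np.array([p[0] for p in pts]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# axial assignment


def axialize(
    traj: Trajectory,
    movie: Movie,
    calib: CalibrationModel,
    crop_radius_nm: float = 1300.0,
    psf_radius_nm: float = 250.0,
    motion_scale_nm: float = 100.0,
) -> Trajectory:
    """Assign a mirror spacing to every trajectory point via the calibration.

    Features are extracted from a crop around each lateral position.  The
    calibration curves are periodic-ish in spacing, so the inversion returns
    near-degenerate candidates per frame; the axial path is the global
    minimizer (dynamic programming over the candidate sequences) of the summed
    misfit plus a Gaussian motion penalty ``((z_t - z_{t-1})/motion_scale_nm)^2``
    per step — temporal continuity selects the interference branch.  Points
    where the selected branch is not the per-frame global minimum are flagged
    ``continuity_selected``; ambiguous single-frame estimates (several
    comparable candidates) are flagged ``ambiguous``.
    """
    half_px = int(round(crop_radius_nm / movie.pixel_pitch_nm))
    n = len(traj)
    z = np.full(n, np.nan)
    sz = np.full(n, np.nan)
    flags = [list(f) for f in (traj.flags or [[] for _ in range(n)])]
    estimates: list = [None] * n

    for i in range(n):
        fi = int(traj.frame_index[i]) if traj.frame_index is not None else i
        cx = traj.x_nm[i] / movie.pixel_pitch_nm
        cy = traj.y_nm[i] / movie.pixel_pitch_nm
        x0 = max(0, int(cx) - half_px)
        x1 = min(movie.frames.shape[2], int(cx) + half_px + 1)
        y0 = max(0, int(cy) - half_px)
        y1 = min(movie.frames.shape[1], int(cy) + half_px + 1)
        crop = movie.frames[fi, y0:y1, x0:x1]
        try:
            fv = extract_features(
                crop,
                movie.pixel_pitch_nm,
                center=(cx - x0, cy - y0),
                psf_radius_nm=psf_radius_nm,
            )
            estimates[i] = estimate_distance(fv, calib)
        except Exception:
            flags[i].append("axial_failed")
            continue
        sz[i] = estimates[i].sigma_z_nm
        if len(estimates[i].candidates) > 1:
            flags[i].append("ambiguous")

    # Viterbi over per-frame candidates with a Gaussian motion penalty
    usable = [i for i in range(n) if estimates[i] is not None]
    if usable:
        cand = {i: estimates[i].candidates for i in usable}
        acc = {usable[0]: [c for _, c in cand[usable[0]]]}
        back: dict = {}
        for a, b in zip(usable, usable[1:]):
            gap = max(1, b - a)
            acc_b, back_b = [], []
            for zb, cb in cand[b]:
                best, arg = math.inf, 0
                for j, (za, _) in enumerate(cand[a]):
                    tot = acc[a][j] + ((zb - za) / motion_scale_nm) ** 2 / gap
                    if tot < best:
                        best, arg = tot, j
                acc_b.append(best + cb)
                back_b.append(arg)
            acc[b] = acc_b
            back[b] = back_b
        j = int(np.argmin(acc[usable[-1]]))
        for i in reversed(usable):
            z[i] = cand[i][j][0]
            if cand[i][j][0] != estimates[i].z_hat_nm:
                flags[i].append("continuity_selected")
            if i in back:
                j = back[i][j]

    return Trajectory(
        t_s=traj.t_s.copy(),
        x_nm=traj.x_nm.copy(),
        y_nm=traj.y_nm.copy(),
        z_nm=z,
        sigma_z_nm=sz,
        flags=flags,
        frame_index=None if traj.frame_index is None else traj.frame_index.copy(),
    )


# ---------------------------------------------------------------------------
# displacement statistics


def cumulative_displacement(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Running sum of Euclidean 3D step lengths; skips and flags gap steps."""
    if len(traj) < 2:
        raise ValueError("need at least two points")
    p = traj.positions()
    ok = np.isfinite(p).all(axis=1)
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    good = ok[1:] & ok[:-1]
    steps = np.where(good, steps, 0.0)
    return traj.t_s[1:], np.cumsum(steps)


def msd(traj: Trajectory, max_lag_frac: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean-square displacement (µm²) over all point pairs.

    Lags run up to ``max_lag_frac`` of the trajectory length.  Points with a
    non-finite coordinate are excluded pairwise.
    """
    n = len(traj)
    if n < 10:
        raise ValueError("need at least 10 points")
    p = traj.positions() / 1000.0  # nm -> um
    ok = np.isfinite(p).all(axis=1)
    max_lag = max(4, int(n * max_lag_frac))
    lags = np.arange(1, max_lag + 1)
    out = np.full(lags.shape, np.nan)
    for i, lag in enumerate(lags):
        d = p[lag:] - p[:-lag]
        good = ok[lag:] & ok[:-lag]
        if good.any():
            out[i] = float(np.mean(np.sum(d[good] ** 2, axis=1)))
    dt = (traj.t_s[-1] - traj.t_s[0]) / (n - 1)
    return lags * dt, out


@dataclass
class DiffusionFit:
    """Power-law fit ``MSD = 2*dim*D*tau^alpha`` with diagnostics."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    d_um2_s: float
    alpha: float
    dimensions: int
    fit_range: tuple[int, int]
    residuals: np.ndarray
    d_ci95: tuple[float, float]
    flags: list = field(default_factory=list)

    def summary(self) -> str:
        lo, hi = self.d_ci95
        return (
            f"Diffusion fit ({self.dimensions}D, lags "
            f"{self.lags_s[self.fit_range[0]]:.3g}-"
            f"{self.lags_s[self.fit_range[1] - 1]:.3g} s):\n"
            f"  D     = {self.d_um2_s:.4g} um^2/s  (95% CI {lo:.4g}-{hi:.4g})\n"
            f"  alpha = {self.alpha:.3f}"
        )


def _loglog_fit(lags_s, msd_um2, dimensions, lo, hi):
    lags_fit = lags_s[lo:hi]
    msd_fit = msd_um2[lo:hi]
    good = np.isfinite(msd_fit) & (msd_fit > 0) & (lags_fit > 0)
    if good.sum() < 4:
        raise ValueError("need at least 4 positive MSD values in fit range")
    x = np.log(lags_fit[good])
    y = np.log(msd_fit[good])
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    alpha, intercept = float(coef[0]), float(coef[1])
    d = math.exp(intercept) / (2.0 * dimensions)
    resid = y - A @ coef
    return d, alpha, resid, bool(good.all())


def _msd_of_positions(p_um: np.ndarray, max_lag: int) -> np.ndarray:
    out = np.empty(max_lag)
    for i in range(1, max_lag + 1):
        d = p_um[i:] - p_um[:-i]
        out[i - 1] = np.mean(np.sum(d**2, axis=1))
    return out


def fit_diffusion(
    lags_s: np.ndarray,
    msd_um2: np.ndarray,
    dimensions: int = 3,
    fit_range: tuple[int, int] | None = None,
    n_boot: int = 100,
    boot_seed: int = 0,
) -> DiffusionFit:
    """Log-log least-squares fit of the MSD power law.

    The exponent ``alpha`` is the log-log slope, the diffusion coefficient
    comes from the intercept.  The default fit range is the first quarter of
    the available lags (at least 4); nonpositive MSD values are excluded.

    The 95 % interval on D comes from a parametric bootstrap (``n_boot``
    Brownian trajectories regenerated at the fitted D and refitted with the
    identical protocol), because neighbouring time-averaged MSD points are
    strongly correlated and residual-based intervals would be far too narrow.
    With ``n_boot=0``, or when the fitted exponent is far from 1, a
    residual-based interval is returned with a ``residual_ci`` flag.
    """
    lags_s = np.asarray(lags_s, dtype=float)
    msd_um2 = np.asarray(msd_um2, dtype=float)
    if fit_range is None:
        fit_range = (0, max(4, len(lags_s) // 4))
    lo, hi = fit_range
    flags = []
    d, alpha, resid, all_good = _loglog_fit(lags_s, msd_um2, dimensions, lo, hi)
    if not all_good:
        flags.append("nonpositive_msd_excluded")

    n_lags = len(lags_s)
    dt = float(lags_s[0])
    if n_boot > 0 and abs(alpha - 1.0) <= 0.3 and dt > 0:
        # number of trajectory points consistent with the default lag truncation
        n_points = 4 * n_lags + 1
        rng = np.random.default_rng(boot_seed)
        sigma_um = math.sqrt(2.0 * d * dt)
        boot = []
        for _ in range(n_boot):
            steps = rng.normal(0.0, sigma_um, size=(n_points - 1, dimensions))
            p = np.vstack([np.zeros(dimensions), np.cumsum(steps, axis=0)])
            m_b = _msd_of_positions(p, n_lags)
            try:
                d_b, _, _, _ = _loglog_fit(lags_s, m_b, dimensions, lo, hi)
                boot.append(d_b)
            except ValueError:
                continue
        if len(boot) >= 20:
            q_lo, q_hi = np.percentile(np.log(boot), [2.5, 97.5])
            # basic bootstrap in log space
            ci = (
                float(math.exp(2 * math.log(d) - q_hi)),
                float(math.exp(2 * math.log(d) - q_lo)),
            )
        else:  # pragma: no cover - bootstrap degenerate
            flags.append("residual_ci")
            ci = _residual_ci(d, resid, lags_s, lo, hi)
    else:
        flags.append("residual_ci")
        ci = _residual_ci(d, resid, lags_s, lo, hi)
    return DiffusionFit(
        lags_s=lags_s,
        msd_um2=msd_um2,
        d_um2_s=d,
        alpha=alpha,
        dimensions=dimensions,
        fit_range=(lo, hi),
        residuals=resid,
        d_ci95=ci,
        flags=flags,
    )


def _residual_ci(d, resid, lags_s, lo, hi):
    n = max(len(resid), 3)
    x = np.log(lags_s[lo:hi][: len(resid)])
    s2 = float(resid @ resid) / max(1, n - 2)
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    var_b = s2 * (1.0 / n + xbar**2 / sxx) if sxx > 0 else s2
    half = 1.96 * math.sqrt(max(var_b, 0.0))
    return (d * math.exp(-half), d * math.exp(half))


@dataclass
class ViscosityResult:
    eta_cp: float
    temperature_k: float
    hydrodynamic_radius_nm: float
    d_um2_s: float

    def summary(self) -> str:
        return (
            f"eta = {self.eta_cp:.1f} cP  (Stokes-Einstein with D = "
            f"{self.d_um2_s:.4g} um^2/s, r_h = {self.hydrodynamic_radius_nm:.1f} nm, "
            f"T = {self.temperature_k:.1f} K)"
        )


def viscosity(d_um2_s: float, r_h_nm: float, temperature_k: float = 293.0) -> ViscosityResult:
    """Stokes-Einstein viscosity ``eta = k_B T / (6 pi D r_h)`` in cP.

    The hydrodynamic radius and temperature conventions dominate the result
    and are therefore echoed in the output.
    """
    if d_um2_s <= 0 or r_h_nm <= 0 or temperature_k <= 0:
        raise ValueError("D, r_h and T must all be > 0")
    d_si = d_um2_s * 1e-12  # m^2/s
    r_si = r_h_nm * 1e-9  # m
    eta_pa_s = BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * d_si * r_si)
    return ViscosityResult(
        eta_cp=eta_pa_s * 1000.0,
        temperature_k=temperature_k,
        hydrodynamic_radius_nm=r_h_nm,
        d_um2_s=d_um2_s,
    )
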