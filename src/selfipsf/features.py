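"""Four-parameter description of a lateral SELFI PSF.

A background-subtracted, angle-averaged cross-section profile through the spot
centre is summarized by four descriptors that index the axial calibration
curves:

* ``fwhm``  — outer full width at half the profile maximum (nm),
* ``ifwhm`` — full width of the central dip at half its depth (nm), defined
  only when a dip is present,
* ``area``  — equivalent width: profile integral divided by its maximum (nm),
* ``depth`` — normalized dip contrast ``(I_max - I_center)/I_max`` in [0, 1].

All four are invariant under multiplicative intensity scaling and (after
background subtraction) under a uniform additive offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CrossSectionProfile",
    "FeatureVector",
    "DetectionError",
    "locate_center",
    "averaged_cross_section",
    "outer_fwhm",
    "inner_fwhm",
    "area",
    "depth",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("fwhm", "ifwhm", "area", "depth")

DIP_THRESHOLD_DEFAULT = 0.05


class DetectionError(RuntimeError):
    """No spot found above the background."""


@dataclass
class CrossSectionProfile:
    """Angle-averaged line profile through the PSF centre.

    ``r_nm`` is the signed distance from the centre, sampled symmetrically and
    uniformly; ``intensity`` is background-subtracted and clipped at zero.
    """

    r_nm: np.ndarray
    intensity: np.ndarray
    background: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.r_nm) != len(self.intensity):
            raise ValueError("r and intensity must match")
        if not np.allclose(self.r_nm, -self.r_nm[::-1]):
            raise ValueError("sampling must be symmetric about r = 0")

    @property
    def center_index(self) -> int:
        return len(self.r_nm) // 2


@dataclass
class FeatureVector:
    """The four PSF descriptors with per-feature validity flags."""

    fwhm_nm: float
    ifwhm_nm: float  # nan when undefined
    area_nm: float
    depth: float
    valid: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.valid.setdefault("fwhm", math.isfinite(self.fwhm_nm))
        self.valid.setdefault("ifwhm", math.isfinite(self.ifwhm_nm))
        self.valid.setdefault("area", math.isfinite(self.area_nm))
        self.valid.setdefault("depth", math.isfinite(self.depth))

    def value(self, name: str) -> float:
        return {
            "fwhm": self.fwhm_nm,
            "ifwhm": self.ifwhm_nm,
            "area": self.area_nm,
            "depth": self.depth,
        }[name]

    def as_dict(self) -> dict:
        return {name: self.value(name) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# centre localization by radial symmetry


def locate_center(image: np.ndarray, smooth_px: float = 1.0) -> tuple[float, float]:
    """Sub-pixel centre ``(x, y)`` of a radially symmetric spot.

    Radial-symmetry method: every intensity-gradient vector of a symmetric
    spot points through (or away from) the centre, so the centre is the point
    minimizing the weighted squared distance to all gradient lines.  Works for
    both peaked and doughnut-shaped spots.  Raises :class:`DetectionError`
    when the image has no contrast above the background noise.
    """
    img = np.asarray(image, dtype=float)
    med = np.median(img)
    mad = np.median(np.abs(img - med)) * 1.4826
    if img.max() - med <= 5.0 * max(mad, 1e-12):
        raise DetectionError("no spot above background")
    if smooth_px > 0:
        img = ndimage.gaussian_filter(img, smooth_px)

    # gradients at cell midpoints (Roberts cross on 2x2 cells)
    a = img[:-1, :-1]
    b = img[:-1, 1:]
    c = img[1:, :-1]
    d = img[1:, 1:]
    gx = 0.5 * ((b + d) - (a + c))
    gy = 0.5 * ((c + d) - (a + b))
    ny, nx = gx.shape
    xm, ym = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)

    g2 = gx**2 + gy**2
    w = g2.copy()
    if w.sum() == 0:
        raise DetectionError("flat image")
    # down-weight far-away gradients (noise) by distance to the brightness centroid
    tot = g2.sum()
    cx = (xm * g2).sum() / tot
    cy = (ym * g2).sum() / tot
    dist = np.hypot(xm - cx, ym - cy)
    w = g2 / (dist + 1.0)

    # minimize sum_i w_i * (perpendicular distance to line through (xm,ym) with direction g)^2
    gx2 = w * gx * gx
    gy2 = w * gy * gy
    gxy = w * gx * gy
    A = np.array([[gy2.sum(), -gxy.sum()], [-gxy.sum(), gx2.sum()]])
    bvec = np.array(
        [(gy2 * xm - gxy * ym).sum(), (gx2 * ym - gxy * xm).sum()]
    )
    try:
        sol = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise DetectionError("degenerate gradient structure") from exc
    return float(sol[0]), float(sol[1])


# ---------------------------------------------------------------------------
# profile extraction


def averaged_cross_section(
    image: np.ndarray,
    center: tuple[float, float],
    pixel_pitch_nm: float,
    n_angles: int = 16,
    r_max_nm: float | None = None,
    step_nm: float | None = None,
    background_annulus_nm: tuple[float, float] | None = None,
    psf_radius_nm: float = 250.0,
    interp_order: int = 3,
) -> CrossSectionProfile:
    """Mean of ``n_angles`` interpolated line profiles through ``center``.

    Angles are uniform over [0, pi).  Sampling uses cubic-spline interpolation
    by default: the image is band-limited by the optics, and linear
    interpolation of a camera-sampled doughnut systematically underestimates
    the dip.  The background is the median of an annulus at 3-4x the expected
    PSF radius (``psf_radius_nm``) and is subtracted, with the result clipped
    at zero.  A ``truncated`` flag is set when the requested profile extends
    beyond the image.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("center must lie inside the image")
    flags: list[str] = []

    edge_nm = min(cx, nx - 1 - cx, cy, ny - 1 - cy) * pixel_pitch_nm
    if r_max_nm is None:
        r_max_nm = edge_nm
    elif r_max_nm > edge_nm:
        flags.append("truncated")
        r_max_nm = edge_nm
    if step_nm is None:
        step_nm = pixel_pitch_nm / 4.0

    n_half = int(math.floor(r_max_nm / step_nm))
    r = np.arange(-n_half, n_half + 1) * step_nm

    angles = np.arange(n_angles) * math.pi / n_angles
    prof = np.zeros(r.shape)
    for ang in angles:
        xs = cx + (r / pixel_pitch_nm) * math.cos(ang)
        ys = cy + (r / pixel_pitch_nm) * math.sin(ang)
        prof += ndimage.map_coordinates(img, [ys, xs], order=interp_order, mode="nearest")
    prof /= n_angles

    if background_annulus_nm is None:
        background_annulus_nm = (3.0 * psf_radius_nm, 4.0 * psf_radius_nm)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(xx - cx, yy - cy) * pixel_pitch_nm
    mask = (rr >= background_annulus_nm[0]) & (rr <= background_annulus_nm[1])
    if mask.sum() < 16:
        # annulus does not fit: fall back to the image border
        mask = rr >= 0.8 * edge_nm
        flags.append("background_border")
    background = float(np.median(img[mask])) if mask.any() else float(np.median(img))

    net = np.clip(prof - background, 0.0, None)
    return CrossSectionProfile(r_nm=r, intensity=net, background=background, flags=flags)


# ---------------------------------------------------------------------------
# scalar descriptors


def _cross_left(r, y, level, i0, i1):
    """Linear-interpolated r where y crosses ``level`` between i0 and i0-1."""
    y0, y1 = y[i0], y[i1]
    if y1 == y0:
        return r[i0]
    t = (level - y0) / (y1 - y0)
    return r[i0] + t * (r[i1] - r[i0])


def outer_fwhm(profile: CrossSectionProfile) -> float:
    """Distance between the outermost half-maximum crossings (nm)."""
    y = profile.intensity
    r = profile.r_nm
    m = y.max()
    if m <= 0:
        raise ValueError("profile has no positive maximum")
    half = m / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size == 0 or above[0] == 0 or above[-1] == len(y) - 1:
        raise ValueError("half-maximum crossing outside profile support")
    i_l, i_r = above[0], above[-1]
    r_l = _cross_left(r, y, half, i_l, i_l - 1)
    r_r = _cross_left(r, y, half, i_r, i_r + 1)
    return float(r_r - r_l)


def depth(profile: CrossSectionProfile) -> float:
    """Normalized dip contrast ``(I_max - I_center)/I_max``, clipped to [0, 1]."""
    y = profile.intensity
    m = y.max()
    if m <= 0:
        raise ValueError("profile has no positive maximum")
    ic = y[profile.center_index]
    return float(np.clip((m - ic) / m, 0.0, 1.0))


def inner_fwhm(
    profile: CrossSectionProfile, dip_threshold: float = DIP_THRESHOLD_DEFAULT
) -> float:
    """Width of the central dip at half its depth (nm); nan when no dip.

    The dip level is ``I_center + (I_max - I_center)/2``; the width is
    measured between the crossings nearest ``r = 0`` on either side.
    """
    y = profile.intensity
    r = profile.r_nm
    m = y.max()
    if m <= 0:
        raise ValueError("profile has no positive maximum")
    ci = profile.center_index
    ic = y[ci]
    if (m - ic) / m < dip_threshold:
        return float("nan")
    level = ic + (m - ic) / 2.0

    # walk outward from the centre to the nearest crossing on each side
    left = None
    for i in range(ci - 1, -1, -1):
        if y[i] >= level:
            left = _cross_left(r, y, level, i + 1, i)
            break
    right = None
    for i in range(ci + 1, len(y)):
        if y[i] >= level:
            right = _cross_left(r, y, level, i - 1, i)
            break
    if left is None or right is None:
        profile.flags.append("one_sided_dip")
        return float("nan")
    return float(right - left)


def area(profile: CrossSectionProfile) -> float:
    """Equivalent width (nm): profile integral over its support / maximum.

    The support spans the outermost half-maximum crossings extended outward to
    the first zero samples, so the value is robust to far-field ripples while
    remaining invariant to intensity scaling.
    """
    y = profile.intensity
    r = profile.r_nm
    m = y.max()
    if m <= 0:
        raise ValueError("profile has no positive maximum")
    half = m / 2.0
    above = np.nonzero(y >= half)[0]
    lo, hi = above[0], above[-1]
    # extend to the first effectively-zero sample; the relative floor makes
    # the support endpoint robust to the sampling step
    floor = 2e-3 * m
    while lo > 0 and y[lo - 1] > floor:
        lo -= 1
    while hi < len(y) - 1 and y[hi + 1] > floor:
        hi += 1
    return float(np.trapezoid(y[lo : hi + 1], r[lo : hi + 1]) / m)


def extract_features(
    image: np.ndarray,
    pixel_pitch_nm: float,
    center: tuple[float, float] | None = None,
    n_angles: int = 16,
    dip_threshold: float = DIP_THRESHOLD_DEFAULT,
    psf_radius_nm: float = 250.0,
    r_max_nm: float | None = None,
) -> FeatureVector:
    """Full feature vector of a single-spot image (shared centre and profile)."""
    if center is None:
        center = locate_center(image)
    prof = averaged_cross_section(
        image,
        center,
        pixel_pitch_nm,
        n_angles=n_angles,
        psf_radius_nm=psf_radius_nm,
        r_max_nm=r_max_nm,
    )
    d = depth(prof)
    fv = FeatureVector(
        fwhm_nm=outer_fwhm(prof),
        ifwhm_nm=inner_fwhm(prof, dip_threshold),
        area_nm=area(prof),
        depth=d,
        flags=list(prof.flags),
    )
    return fv
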