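"""Analytic phase bookkeeping of emission self-interference above a mirror.

An emitter a distance ``dz`` above a mirror interferes with its own reflected
emission.  Along the optical axis the accumulated phase difference between the
direct and the reflected wave decomposes into three terms::

    delta_phi(dz) = phi_z(dz) + phi_refl + phi_gouy(dz)

* ``phi_z = 4*pi*n*dz/lambda`` — the round-trip propagation phase,
* ``phi_refl`` — the phase delay picked up on reflection at the mirror
  (argument of the normal-incidence Fresnel coefficient),
* ``phi_gouy = atan(2*dz/z_R)`` — the Gouy phase a diverging emission beam
  accrues relative to a plane wave, with Rayleigh range ``z_R``.

Even multiples of pi give constructive interference (bright, Gaussian-like
spot), odd multiples destructive interference (dark centre, doughnut PSF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import OpticsConfig
from .media import OpticalMedium

__all__ = [
    "PhaseBreakdown",
    "InterferenceClass",
    "fresnel_r_normal",
    "reflection_phase",
    "propagation_phase",
    "gouy_phase",
    "blur_phase",
    "total_phase",
    "classify_interference",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhaseBreakdown:
    """The three phase terms (radians) and their exact sum."""

    phi_z: float
    phi_refl: float
    phi_gouy: float

    @property
    def delta_phi(self) -> float:
        return self.phi_z + self.phi_refl + self.phi_gouy


@dataclass(frozen=True)
class InterferenceClass:
    """Interference character of a total phase difference.

    ``label`` is ``constructive`` near even multiples of pi, ``destructive``
    near odd multiples, ``mixed`` otherwise; ``order_j`` is the nearest integer
    multiple of pi.
    """

    label: str
    order_j: int


def fresnel_r_normal(
    medium: OpticalMedium, mirror: OpticalMedium, wavelength_nm: float
) -> complex:
    """Normal-incidence amplitude reflection coefficient of the mirror.

    ``r = (n - n_mirror) / (n + n_mirror)`` with complex indices evaluated at
    ``wavelength_nm``.  Raises :class:`~selfipsf.media.WavelengthRangeError`
    when either medium is not tabulated there.
    """
    n1 = medium.index(wavelength_nm)
    n2 = mirror.index(wavelength_nm)
    return (n1 - n2) / (n1 + n2)


def reflection_phase(r: complex) -> float:
    """Phase delay (radians, in ``[0, 2*pi)``) imparted by reflection.

    Quadrant-aware: ``-arg(r) mod 2*pi`` under the absorbing index convention,
    which equals the single-branch expression ``pi - atan(Im r / Re r)``
    whenever ``Re r < 0`` (the metallic-mirror case) and returns 0 for a
    positive-real coefficient, pi for a negative-real one.
    """
    if r == 0:
        raise ValueError("reflection phase undefined for r = 0")
    return (-math.atan2(r.imag, r.real)) % TWO_PI


def propagation_phase(delta_z_nm: float, n: float, wavelength_nm: float) -> float:
    """Round-trip propagation phase ``4*pi*n*dz/lambda`` (radians)."""
    if delta_z_nm < 0:
        raise ValueError("delta_z must be >= 0")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    return 4.0 * math.pi * n * delta_z_nm / wavelength_nm


def gouy_phase(delta_z_nm: float, z_rayleigh_nm: float) -> float:
    """Gouy phase ``atan(2*dz/z_R)`` (radians), bounded by pi/2."""
    if z_rayleigh_nm <= 0:
        raise ValueError("Rayleigh range must be > 0")
    return math.atan(2.0 * delta_z_nm / z_rayleigh_nm)


def blur_phase(emitter_separation_nm: float, n: float, wavelength_nm: float) -> float:
    """Average phase spread ``2*pi*R*n/lambda`` between emitters a distance
    ``R`` apart inside one particle; small values mean the ensemble does not
    wash out the interference."""
    if emitter_separation_nm < 0:
        raise ValueError("separation must be >= 0")
    return 2.0 * math.pi * emitter_separation_nm * n / wavelength_nm


def total_phase(delta_z_nm: float, optics: OpticsConfig) -> PhaseBreakdown:
    """Total axial phase difference for a spacing ``delta_z_nm``.

    Uses the ambient index of ``optics`` as the propagating medium of the
    simple single-medium model.
    """
    r = fresnel_r_normal(
        optics.ambient_medium(), optics.mirror_medium(), optics.wavelength_nm
    )
    return PhaseBreakdown(
        phi_z=propagation_phase(delta_z_nm, optics.medium_n, optics.wavelength_nm),
        phi_refl=reflection_phase(r),
        phi_gouy=gouy_phase(delta_z_nm, optics.z_rayleigh_nm),
    )


def classify_interference(
    delta_phi: float, tol: float = 0.3 * math.pi
) -> InterferenceClass:
    """Classify a total phase difference by its nearest multiple of pi.

    Within ``tol`` of an even multiple -> constructive; of an odd multiple ->
    destructive; otherwise mixed.  ``tol`` must lie in (0, pi/2).
    """
    if not 0 < tol < math.pi / 2:
        raise ValueError("tol must lie in (0, pi/2)")
    j = round(delta_phi / math.pi)
    if abs(delta_phi - j * math.pi) <= tol:
        label = "constructive" if j % 2 == 0 else "destructive"
    else:
        label = "mixed"
    return InterferenceClass(label=label, order_j=int(j))
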