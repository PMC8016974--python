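"""Planar substrate stacks and their angle-dependent reflection coefficients.

The geometry is an ambient half-space (where the emitter sits), zero or more
dielectric layers, and a mirror half-space below.  Reflection coefficients are
computed by the standard stratified-medium recursion; with no layers the
two-medium Fresnel coefficients are recovered exactly.

Sign conventions match the dipole-field decomposition used by the PSF engine:
for p polarization the basis is chosen so that a perfect conductor gives
``r_p = +1`` and ``r_s = -1`` (hence ``r_p(0) = -r_s(0)`` at normal
incidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import OpticsConfig
from .media import OpticalMedium

__all__ = ["SubstrateStack", "angular_reflection"]


@dataclass(frozen=True)
class SubstrateStack:
    """Mirror half-space, ordered layers above it, and the ambient medium.

    ``layers`` are listed top-down (adjacent to the ambient first) as
    ``(medium, thickness_nm)``; an empty list is a single interface.
    """

    ambient: OpticalMedium
    mirror: OpticalMedium
    layers: tuple[tuple[OpticalMedium, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for _, t in self.layers:
            if t < 0:
                raise ValueError("layer thickness must be >= 0")

    @classmethod
    def simple(cls, ambient_n: float, mirror: OpticalMedium) -> "SubstrateStack":
        """Single-interface stack: ambient directly on the mirror."""
        return cls(OpticalMedium.constant("ambient", ambient_n), mirror)

    @classmethod
    def from_config(cls, optics: OpticsConfig, layered: bool = False) -> "SubstrateStack":
        """Build from an :class:`~selfipsf.config.OpticsConfig`.

        ``layered=True`` inserts the spacer layer; the default is the simple
        single-medium model.
        """
        ambient = optics.ambient_medium()
        mirror = optics.mirror_medium()
        if layered and optics.spacer_thickness_nm > 0:
            spacer = OpticalMedium.constant("spacer", optics.spacer_n)
            return cls(ambient, mirror, ((spacer, optics.spacer_thickness_nm),))
        return cls(ambient, mirror)


def _interface_r(kz1, kz2, n1, n2, polarization: str):
    if polarization == "s":
        return (kz1 - kz2) / (kz1 + kz2)
    # p convention with r_p(normal) = (n2 - n1)/(n2 + n1)
    return (n2**2 * kz1 - n1**2 * kz2) / (n2**2 * kz1 + n1**2 * kz2)


def angular_reflection(
    theta,
    polarization: str,
    stack: SubstrateStack,
    wavelength_nm: float,
):
    """Complex reflection coefficient of the stack at ambient angle ``theta``.

    Parameters
    ----------
    theta
        Incidence angle(s) in radians, measured in the ambient medium;
        must satisfy ``0 <= theta < pi/2``.
    polarization
        ``"s"`` or ``"p"``.

    Returns a complex scalar or array matching ``theta``.
    """
    if polarization not in ("s", "p"):
        raise ValueError("polarization must be 's' or 'p'")
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th >= np.pi / 2):
        raise ValueError("theta must lie in [0, pi/2) in the ambient medium")

    k0 = 2.0 * np.pi / wavelength_nm
    n_amb = stack.ambient.index(wavelength_nm)
    kx = k0 * n_amb.real * np.sin(th)  # conserved transverse wavenumber

    media = [n_amb] + [m.index(wavelength_nm) for m, _ in stack.layers]
    media.append(stack.mirror.index(wavelength_nm))
    thicknesses = [t for _, t in stack.layers]

    kz = [np.sqrt((k0 * n) ** 2 - kx**2 + 0j) for n in media]
    # enforce decaying/outgoing branch: Im(kz) >= 0
    kz = [np.where(np.imag(z) < 0, -z, z) for z in kz]

    # recursion from the deepest interface upward
    r = _interface_r(kz[-2], kz[-1], media[-2], media[-1], polarization)
    for i in range(len(media) - 3, -1, -1):
        r01 = _interface_r(kz[i], kz[i + 1], media[i], media[i + 1], polarization)
        beta = kz[i + 1] * thicknesses[i]
        phase = np.exp(2j * beta)
        r = (r01 + r * phase) / (1.0 + r01 * r * phase)
    return r if r.shape else complex(r)
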