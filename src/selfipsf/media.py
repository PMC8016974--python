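"""Optical media with complex, possibly wavelength-tabulated refractive indices.

The absorbing convention is ``n_complex = n + i*k`` with ``k >= 0`` (time
dependence ``exp(-i*omega*t)``), so a lossy mirror has a positive imaginary
part.  Tabulated media are interpolated linearly in wavelength and refuse to
extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalMedium",
    "WavelengthRangeError",
    "silver",
    "SILVER_TABLE_ID",
]


class WavelengthRangeError(ValueError):
    """Requested wavelength lies outside a medium's tabulated range."""


@dataclass(frozen=True)
class OpticalMedium:
    """A homogeneous medium, dispersionless or tabulated versus wavelength.

    Parameters
    ----------
    name
        Text label, recorded in output metadata.
    wavelengths_nm
        Strictly increasing wavelengths of the table; a single entry makes the
        medium dispersionless.
    indices
        Complex refractive index at each tabulated wavelength.
    """

    name: str
    wavelengths_nm: tuple[float, ...]
    indices: tuple[complex, ...]

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != len(self.indices) or not self.indices:
            raise ValueError("table must have matching, non-empty columns")
        if any(b <= a for a, b in zip(self.wavelengths_nm, self.wavelengths_nm[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        for n in self.indices:
            n = complex(n)
            if n.real <= 0:
                raise ValueError(f"real part of refractive index must be > 0, got {n}")
            if n.imag < 0:
                raise ValueError(f"imaginary part must be >= 0 (absorbing convention), got {n}")

    @classmethod
    def constant(cls, name: str, n: complex) -> "OpticalMedium":
        """Dispersionless medium with index ``n`` at every wavelength."""
        return cls(name, (0.0,), (complex(n),))

    @property
    def dispersionless(self) -> bool:
        return len(self.indices) == 1

    def index(self, wavelength_nm: float) -> complex:
        """Complex refractive index at ``wavelength_nm`` (linear interpolation)."""
        if self.dispersionless:
            return self.indices[0]
        wl = np.asarray(self.wavelengths_nm)
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise WavelengthRangeError(
                f"{self.name}: {wavelength_nm} nm outside tabulated range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        re = np.interp(wavelength_nm, wl, [n.real for n in self.indices])
        im = np.interp(wavelength_nm, wl, [n.imag for n in self.indices])
        return complex(re, im)


# Compact silver n,k tabulation in the visible/near-IR, in the style of the
# classic thin-film measurements (Johnson--Christy), linearly interpolated.
# Adequate for reflection-phase modelling of a thick evaporated Ag mirror.
SILVER_TABLE_ID = "Ag-JC-style-bundled-v1"

_SILVER_NK: tuple[tuple[float, float, float], ...] = (
    # (wavelength nm, n, k)
    (380.0, 0.05, 1.73),
    (400.0, 0.05, 2.11),
    (425.0, 0.04, 2.28),
    (450.0, 0.05, 2.42),
    (460.0, 0.05, 2.52),
    (475.0, 0.05, 2.63),
    (500.0, 0.05, 2.87),
    (550.0, 0.06, 3.32),
    (600.0, 0.06, 3.75),
    (650.0, 0.07, 4.15),
    (700.0, 0.08, 4.52),
    (750.0, 0.09, 4.89),
    (800.0, 0.09, 5.24),
)


def silver() -> OpticalMedium:
    """Bundled silver-mirror tabulation (see ``SILVER_TABLE_ID``)."""
    return OpticalMedium(
        SILVER_TABLE_ID,
        tuple(w for w, _, _ in _SILVER_NK),
        tuple(complex(n, k) for _, n, k in _SILVER_NK),
    )
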