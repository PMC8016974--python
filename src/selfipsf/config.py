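"""Run configuration: optics, camera and analysis blocks, JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .media import OpticalMedium, silver

__all__ = ["OpticsConfig", "CameraConfig", "RunConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration."""


# Rayleigh range (nm) of the emission beam entering the Gouy term of the
# analytic phase model; calibrated once so a 154.9 nm mirror spacing accrues a
# Gouy shift of 0.23*pi.
Z_RAYLEIGH_DEFAULT_NM = 351.4


@dataclass
class OpticsConfig:
    """Optical configuration shared by the phase model and the PSF engine.

    Distances are nm.  ``medium_n`` is the ambient (immersion) index the
    simple single-medium model propagates in; ``spacer_n``/``spacer_thickness_nm``
    describe the optional dielectric layer of the layered substrate model.
    ``na_eff`` is the effective numerical aperture of the collection path
    (<= ``na``); ``focus_height_nm`` is the height of the fixed detection plane
    above the mirror surface, or ``None`` to focus at the particle itself.
    """

    wavelength_nm: float = 455.0
    medium_n: float = 1.5
    spacer_n: float = 1.46
    spacer_thickness_nm: float = 0.0
    mirror: str | complex = "Ag"
    z_rayleigh_nm: float = Z_RAYLEIGH_DEFAULT_NM
    na: float = 1.4
    na_eff: float = 1.2
    pixel_pitch_nm: float = 65.0
    field_px: int = 64
    focus_height_nm: float | None = 0.0

    def mirror_medium(self) -> OpticalMedium:
        if isinstance(self.mirror, str):
            if self.mirror.lower() in ("ag", "silver"):
                return silver()
            if self.mirror.lower() in ("none", "off"):
                # index-matched to the ambient -> zero reflection
                return OpticalMedium.constant("no-mirror", self.medium_n)
            if self.mirror.lower() in ("perfect", "pec"):
                return OpticalMedium.constant("perfect-mirror", 1e-6 + 1e8j)
            raise ConfigurationError(f"unknown mirror material {self.mirror!r}")
        return OpticalMedium.constant("custom-mirror", complex(self.mirror))

    def ambient_medium(self) -> OpticalMedium:
        return OpticalMedium.constant("ambient", self.medium_n)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if isinstance(d["mirror"], complex):
            d["mirror"] = [d["mirror"].real, d["mirror"].imag]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "OpticsConfig":
        d = dict(d)
        m = d.get("mirror", "Ag")
        if isinstance(m, (list, tuple)):
            d["mirror"] = complex(m[0], m[1])
        return cls(**d)


@dataclass
class CameraConfig:
    """Synthetic camera: counts = offset + gain * Poisson(expected photons)."""

    gain: float = 1.0
    offset: float = 100.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CameraConfig":
        return cls(**d)


@dataclass
class RunConfig:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    analysis: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "optics": self.optics.to_dict(),
            "camera": self.camera.to_dict(),
            "analysis": dict(self.analysis),
            "seed": self.seed,
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            optics=OpticsConfig.from_dict(d.get("optics", {})),
            camera=CameraConfig.from_dict(d.get("camera", {})),
            analysis=dict(d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
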