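"""Optical configuration shared by the forward models and solvers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

#: Default compensatory retardance of the liquid-crystal polarizer, in
#: radians (~3% of a wave).  Configurable; recorded in every output.
DEFAULT_CHI = 0.06 * math.pi


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging-path parameters.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in micrometres.
    na_detection : float
        Numerical aperture of the detection objective.
    na_illumination : float
        Numerical aperture of the condenser (partially coherent source).
    pixel_size : float
        Object-space pixel size in micrometres.
    z_step : float
        Axial step between acquired planes in micrometres.
    chi : float
        Compensatory retardance of the liquid-crystal polarizer in
        radians.  Must lie strictly inside (0, pi) so the instrument
        matrix has full column rank.
    medium_index : float
        Refractive index of the imaging medium (1.0 models an air path).
    """

    wavelength: float
    na_detection: float
    na_illumination: float
    pixel_size: float
    z_step: float
    chi: float = DEFAULT_CHI
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        for name in ("wavelength", "pixel_size", "z_step"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")
        if not (0 < self.na_illumination <= self.na_detection < self.medium_index):
            raise ValueError(
                "require 0 < na_illumination <= na_detection < medium_index, got "
                f"na_illumination={self.na_illumination}, "
                f"na_detection={self.na_detection}, medium_index={self.medium_index}"
            )
        if not (0 < self.chi < math.pi):
            raise ValueError(f"chi must lie in the open interval (0, pi), got {self.chi!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "OpticsConfig":
        return cls(**payload)
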