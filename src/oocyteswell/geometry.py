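"""Spherical geometry of the oocyte.

The swelling assay images the oocyte from above and records one diameter per
frame; volume and surface area are derived assuming spherical geometry.  The
relative-volume trace V/V0 that the permeability estimators consume is built
here, with V0 and S0 taken from the first (t = 0) diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import InsufficientDataError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .swell_model import BathCondition, DiameterTrace

__all__ = [
    "VolumeTrace",
    "sphere_volume",
    "sphere_surface",
    "sphere_diameter",
    "surface_from_volume",
    "trace_to_volume",
]


def sphere_volume(d):
    """Volume (cm^3) of a sphere of diameter ``d`` (cm): (pi/6) d^3.

    Accepts scalars or arrays; every diameter must be strictly positive.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = (np.pi / 6.0) * d**3
    return float(out) if out.ndim == 0 else out


def sphere_surface(d):
    """Surface area (cm^2) of a sphere of diameter ``d`` (cm): pi d^2."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = np.pi * d**2
    return float(out) if out.ndim == 0 else out


def sphere_diameter(v):
    """Diameter (cm) of a sphere of volume ``v`` (cm^3); inverse of sphere_volume."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be > 0")
    out = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def surface_from_volume(v):
    """Apparent sphere surface (cm^2) at volume ``v`` (cm^3): pi^(1/3) (6v)^(2/3)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be > 0")
    out = np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class VolumeTrace:
    """Relative-volume time series for one oocyte.

    ``rel_volume[0]`` is exactly 1 by construction: relative volume is the
    cube of the diameter ratio, which also makes it invariant to the unit
    (mm vs cm) the diameters were recorded in.
    """

    oocyte_id: str
    construct: str
    bath: "BathCondition"
    times: np.ndarray
    rel_volume: np.ndarray
    v0: float
    s0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rel_volume", np.asarray(self.rel_volume, dtype=float))
        if self.times.shape != self.rel_volume.shape:
            raise ValueError("times and rel_volume must have equal length")
        if self.v0 <= 0 or self.s0 <= 0:
            raise ValueError("v0 and s0 must be > 0")
        if self.rel_volume[0] != 1.0:
            raise ValueError("rel_volume[0] must be exactly 1")


def trace_to_volume(trace: "DiameterTrace") -> VolumeTrace:
    """Convert a diameter trace to a relative-volume trace.

    V0 and S0 come from the first diameter (the initial oocyte surface area
    is the one entering the estimators); rel_volume[i] = (d_i / d_0)^3.
    """
    if len(trace.times) < 3:
        raise InsufficientDataError(
            f"oocyte {trace.oocyte_id!r}: need >= 3 samples, got {len(trace.times)}"
        )
    d = np.asarray(trace.diameters, dtype=float)
    d0 = float(d[0])
    rel = (d / d0) ** 3
    rel[0] = 1.0  # exact by definition
    return VolumeTrace(
        oocyte_id=trace.oocyte_id,
        construct=trace.construct,
        bath=trace.bath,
        times=np.asarray(trace.times, dtype=float),
        rel_volume=rel,
        v0=sphere_volume(d0),
        s0=sphere_surface(d0),
    )
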