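"""Light forcing for a well-mixed surface layer.

Surface irradiance follows a solar-elevation model (declination + hour
angle) truncated at zero and normalised so that noon at the summer
solstice equals ``peak_noon_irradiance``; irradiance is therefore in
relative units.  Light decays with depth following Lambert-Beer's law,
with an attenuation coefficient composed of a background term (dissolved
substances) and algal self-shading.  Because the layer is instantly
mixed, producers experience the vertical average of the light profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightForcing",
    "AttenuationModel",
    "surface_irradiance",
    "attenuation_coefficient",
    "depth_averaged_irradiance",
]

#: axial tilt of the Earth, degrees
_OBLIQUITY = 23.44
#: days per year used by the seasonal cycle
_YEAR = 365.0


@dataclass(frozen=True)
class LightForcing:
    """Seasonal and diel surface-irradiance forcing.

    Parameters
    ----------
    latitude
        Degrees north.  Default is the Linnaeus Microbial Observatory
        site in the southern Baltic proper (56.93 N).
    peak_noon_irradiance
        Irradiance at solar noon on the summer solstice (relative
        units; the light-limitation factor is saturating, so only the
        shape matters).
    season_start, season_end
        Vegetative season window as continuous days since 1 January
        00:00 local solar time (day 89 = 30 March, day 274 = 1 October).
    """

    latitude: float = 56.93
    peak_noon_irradiance: float = 1.0
    season_start: float = 89.0
    season_end: float = 274.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude must be in [-90, 90], got {self.latitude}")
        if self.peak_noon_irradiance < 0:
            raise ValueError("peak_noon_irradiance must be nonnegative")
        if self.season_start >= self.season_end:
            raise ValueError("season_start must precede season_end")


@dataclass(frozen=True)
class AttenuationModel:
    """Linear light-attenuation model: k = k_s * W_PP + k_bg.

    ``k_s`` [m^2 (mg C)^-1] converts algal carbon ``W_PP`` [mg C m^-3]
    into self-shading; ``k_bg`` [m^-1] is background attenuation by
    dissolved organic and inorganic substances; ``layer_depth`` [m] is
    the mixed-layer depth.
    """

    k_s: float = 5e-5
    k_bg: float = 0.14
    layer_depth: float = 10.0

    def __post_init__(self) -> None:
        if self.k_s < 0:
            raise ValueError(f"k_s must be >= 0, got {self.k_s}")
        if self.k_bg <= 0:
            raise ValueError(f"k_bg must be > 0, got {self.k_bg}")
        if self.layer_depth <= 0:
            raise ValueError(f"layer_depth must be > 0, got {self.layer_depth}")


def _declination(day_of_year):
    """Solar declination [radians] for a continuous day of year."""
    return math.radians(-_OBLIQUITY) * np.cos(2.0 * math.pi * (day_of_year + 10.0) / _YEAR)


def _sin_elevation(latitude_deg, day_of_year, hour_angle):
    phi = math.radians(latitude_deg)
    dec = _declination(day_of_year)
    return math.sin(phi) * np.sin(dec) + math.cos(phi) * np.cos(dec) * np.cos(hour_angle)


def surface_irradiance(forcing: LightForcing, t):
    """Surface irradiance at continuous time ``t`` [days since 1 Jan, 00:00].

    Zero at night, maximal near solar noon, periodic in both the diel
    (24 h) and seasonal (365 d) cycle.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    day = np.floor(t) % _YEAR
    frac = t - np.floor(t)
    hour_angle = 2.0 * math.pi * (frac - 0.5)  # 0 at local solar noon
    sinel = _sin_elevation(forcing.latitude, day, hour_angle)
    # normalise to noon on the summer solstice (day 172)
    norm = _sin_elevation(forcing.latitude, 172.0, 0.0)
    out = forcing.peak_noon_irradiance * np.maximum(sinel, 0.0) / norm
    return float(out) if out.ndim == 0 else out


def attenuation_coefficient(model: AttenuationModel, W_PP: float) -> float:
    """Total attenuation k = k_s * W_PP + k_bg [m^-1].

    ``W_PP`` is the summed carbon biomass of the primary producers
    [mg C m^-3]; self-shading only ever adds to the background term.
    """
    if W_PP < 0:
        raise ValueError(f"algal biomass W_PP must be >= 0, got {W_PP}")
    return model.k_s * W_PP + model.k_bg


def depth_averaged_irradiance(I0: float, k: float, H: float) -> float:
    """Mean irradiance over a mixed layer of depth ``H`` under Lambert-Beer decay.

    Closed form I0 * (1 - exp(-kH)) / (kH); lies in (0, I0], decreasing
    in ``k``.  The transparent-water limit k*H -> 0 is handled by a
    series branch; nonpositive ``k`` is rejected.
    """
    if k <= 0:
        raise ValueError(f"attenuation coefficient k must be > 0, got {k}")
    if H <= 0:
        raise ValueError(f"layer depth H must be > 0, got {H}")
    if I0 < 0:
        raise ValueError(f"surface irradiance must be >= 0, got {I0}")
    kh = k * H
    if kh < 1e-8:
        return I0 * (1.0 - 0.5 * kh)
    return I0 * (1.0 - math.exp(-kh)) / kh
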