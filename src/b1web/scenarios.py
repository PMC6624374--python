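"""Scenario construction: the 3-factor environmental cube and sensitivity axes.

A scenario is one combination of (1) planktivorous fish abundance,
(2) nutrient level at the start of the vegetative season and (3)
background light attenuation by dissolved substances, together with the
B1 bioavailability and the B1-source-rate multiplier used for
sensitivity analyses.  Initial phosphate is tied to total inorganic
nitrogen through the Redfield ratio N:P = 16:1.  Dissolved
concentrations use 1 umol/l = 1 mmol m^-3 throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scenario",
    "make_scenario",
    "redfield_phosphorus",
    "scenario_grid",
    "sensitivity_axis",
    "default_scenario",
    "poor_reference_scenario",
    "rich_reference_scenario",
    "FISH_RANGE",
    "NUTRIENT_ENDPOINTS",
    "KBG_RANGE",
]

#: planktivorous fish abundance range [ind m^-3] (Baltic herring + sprat stocks)
FISH_RANGE = (0.004, 0.01)
#: (NO3, NH4) at the very-low and very-high nutrient endpoints [mmol m^-3]
NUTRIENT_ENDPOINTS = ((2.01, 0.93), (30.0, 7.0))
#: background attenuation range [m^-1]
KBG_RANGE = (0.04, 0.24)


def redfield_phosphorus(NO3_0: float, NH4_0: float) -> float:
    """Initial phosphate from total inorganic N via Redfield N:P = 16:1."""
    if NO3_0 < 0 or NH4_0 < 0:
        raise ValueError("initial nutrient concentrations must be >= 0")
    return (NO3_0 + NH4_0) / 16.0


@dataclass(frozen=True)
class Scenario:
    """One point of the environmental parameter cube."""

    fish_abundance: float          # ind m^-3
    NO3_0: float                   # mmol m^-3
    NH4_0: float                   # mmol m^-3
    PO4_0: float                   # mmol m^-3, Redfield-derived
    k_bg: float                    # m^-1
    bioavailability: float = 0.15
    b1_input_multiplier: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.fish_abundance <= 0:
            raise ValueError(f"fish_abundance must be > 0, got {self.fish_abundance}")
        if self.NO3_0 < 0 or self.NH4_0 < 0 or self.PO4_0 < 0:
            raise ValueError("initial nutrient concentrations must be >= 0")
        if self.k_bg <= 0:
            raise ValueError(f"k_bg must be > 0, got {self.k_bg}")
        if not 0.0 <= self.bioavailability <= 1.0:
            raise ValueError(
                f"bioavailability must be in [0, 1], got {self.bioavailability}")
        if self.b1_input_multiplier < 0:
            raise ValueError("b1_input_multiplier must be >= 0")

    @property
    def total_N(self) -> float:
        return self.NO3_0 + self.NH4_0


def make_scenario(fish_abundance: float, NO3_0: float, NH4_0: float,
                  k_bg: float, *, bioavailability: float = 0.15,
                  b1_input_multiplier: float = 1.0, label: str = "") -> Scenario:
    """Build a scenario with phosphate derived from the Redfield ratio."""
    return Scenario(
        fish_abundance=fish_abundance, NO3_0=NO3_0, NH4_0=NH4_0,
        PO4_0=redfield_phosphorus(NO3_0, NH4_0), k_bg=k_bg,
        bioavailability=bioavailability,
        b1_input_multiplier=b1_input_multiplier, label=label,
    )


def _label(i: int, fish: float, totN: float, k_bg: float) -> str:
    return f"s{i:03d}_f{fish:.4f}_N{totN:05.2f}_k{k_bg:.2f}"


def scenario_grid(n_fish: int, n_nutrient: int, n_kbg: int,
                  overrides: dict | None = None) -> list[Scenario]:
    """Cartesian grid of scenarios over the three environmental factors.

    Fish abundance and background attenuation are evenly spaced over
    their ranges; nutrient levels interpolate the (NO3, NH4) pair
    linearly between the very-low and very-high endpoints, so every
    level keeps the printed NO3:NH4 mix and the Redfield phosphate.
    ``overrides`` may set ``bioavailability`` and/or
    ``b1_input_multiplier`` on every scenario.  Labels are
    deterministic across calls.
    """
    for name, n in (("n_fish", n_fish), ("n_nutrient", n_nutrient), ("n_kbg", n_kbg)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    overrides = overrides or {}
    unknown = set(overrides) - {"bioavailability", "b1_input_multiplier"}
    if unknown:
        raise ValueError(f"unknown scenario overrides: {sorted(unknown)}")

    def levels(lo, hi, n):
        return [lo] if n == 1 else list(np.linspace(lo, hi, n))

    fish_levels = levels(*FISH_RANGE, n_fish)
    kbg_levels = levels(*KBG_RANGE, n_kbg)
    (no3_lo, nh4_lo), (no3_hi, nh4_hi) = NUTRIENT_ENDPOINTS
    fracs = levels(0.0, 1.0, n_nutrient)
    nutrient_levels = [
        (no3_lo + f * (no3_hi - no3_lo), nh4_lo + f * (nh4_hi - nh4_lo)) for f in fracs
    ]

    out = []
    i = 0
    for fish in fish_levels:
        for no3, nh4 in nutrient_levels:
            for k_bg in kbg_levels:
                out.append(make_scenario(
                    fish, no3, nh4, k_bg,
                    label=_label(i, fish, no3 + nh4, k_bg), **overrides))
                i += 1
    return out


def sensitivity_axis(base: Scenario, parameter: str, values) -> list[Scenario]:
    """Copies of ``base`` with one sensitivity parameter swept.

    ``parameter`` is ``"bioavailability"`` (studied range 5-20%) or
    ``"b1_input_multiplier"`` (B1 source rate relative to the metabolic
    rate).  ``base`` is not mutated.
    """
    if parameter not in ("bioavailability", "b1_input_multiplier"):
        raise ValueError(f"unknown sensitivity parameter {parameter!r}")
    out = []
    for i, v in enumerate(values):
        if parameter == "bioavailability" and not 0.0 < v <= 1.0:
            raise ValueError(f"bioavailability must be in (0, 1], got {v}")
        if parameter == "b1_input_multiplier" and v < 0:
            raise ValueError(f"b1_input_multiplier must be >= 0, got {v}")
        out.append(dataclasses.replace(
            base, **{parameter: v},
            label=f"{base.label or 'base'}_{parameter}{i}_{v:g}"))
    return out


def default_scenario() -> Scenario:
    """Mid-cube reference: intermediate fish, nutrients and attenuation."""
    (no3_lo, nh4_lo), (no3_hi, nh4_hi) = NUTRIENT_ENDPOINTS
    return make_scenario(
        0.007, 0.5 * (no3_lo + no3_hi), 0.5 * (nh4_lo + nh4_hi), 0.14,
        label="default_mid_cube")


def poor_reference_scenario() -> Scenario:
    """High fish, very high nutrients, intermediate attenuation.

    The corner of the cube the regime map associates with vitamin
    B1-poor planktivorous fish via a persistent picoalgae bloom.
    """
    return make_scenario(0.01, 30.0, 7.0, 0.14, label="reference_b1_poor")


def rich_reference_scenario() -> Scenario:
    """Low fish, intermediate nutrients, clear water.

    The corner associated with fluctuating plankton, microalgae blooms
    and vitamin B1-rich fish.
    """
    (no3_lo, nh4_lo), (no3_hi, nh4_hi) = NUTRIENT_ENDPOINTS
    return make_scenario(
        0.004, 0.5 * (no3_lo + no3_hi), 0.5 * (nh4_lo + nh4_hi), 0.04,
        label="reference_b1_rich")
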