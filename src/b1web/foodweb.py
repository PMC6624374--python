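"""Trophic groups and instantaneous process rates.

The food web is a size ladder — heterotrophic bacteria, three
primary-producer size classes (picoalgae, nanoalgae, microalgae), two
protozoan grazers (nanoflagellates, ciliates), mesozooplankton and a
planktivorous clupeid fish — in which every consumer feeds on the
groups one size level below its own:

    nanoflagellates  <- bacteria, picoalgae
    ciliates         <- nanoflagellates, nanoalgae
    mesozooplankton  <- ciliates, microalgae
    fish             <- mesozooplankton

Biomass is carried as carbon [umol C m^-3] with fixed Redfield
stoichiometry (C:N:P = 106:16:1), so nitrogen and phosphorus budgets
close exactly.  Each group additionally carries a vitamin B1 pool
[umol B1 m^-3]; the mass-specific content (quota = pool / biomass) is
bounded above by an empirically estimated maximum ``q_max`` per group.
Producers and bacteria replenish their quota toward ``q_max`` at their
metabolic rate; consumers acquire B1 only through feeding, absorbing a
bioavailable fraction ``b`` of the B1 in ingested prey and degrading
the rest, while their own pool turns over at their metabolic rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

__all__ = [
    "GROUPS",
    "PRODUCERS",
    "REDFIELD_N_PER_C",
    "REDFIELD_P_PER_C",
    "UMOL_C_TO_MG",
    "TrophicGroupSpec",
    "EcosystemState",
    "baltic_default_specs",
    "nutrient_limitation",
    "allometric_scale",
    "producer_growth_rate",
    "bacterial_growth_rate",
    "grazing_flux",
    "partition_ingestion",
    "IngestionPartition",
    "b1_source_flux",
    "b1_trophic_transfer",
    "b1_consumer_update",
    "b1_fish_update",
]

#: canonical group order, ascending size
GROUPS = (
    "bacteria",
    "picoalgae",
    "nanoalgae",
    "microalgae",
    "nanoflagellates",
    "ciliates",
    "mesozooplankton",
    "fish",
)
PRODUCERS = ("picoalgae", "nanoalgae", "microalgae")

#: Redfield molar ratios per mol biomass carbon
REDFIELD_N_PER_C = 16.0 / 106.0
REDFIELD_P_PER_C = 1.0 / 106.0
#: 1 umol C = 12.011 ug = 0.012011 mg (for self-shading, which is per mg C)
UMOL_C_TO_MG = 12.011e-3

_ROLES = ("producer", "heterotrophic_bacteria", "consumer", "fish")

# Empirically estimated maximal mass-specific B1 content [umol B1 (umol C)^-1]
MAX_B1_QUOTA = {
    "bacteria": 1.48e-7,
    "picoalgae": 1.48e-7,
    "nanoalgae": 1.18e-7,
    "microalgae": 1.18e-7,
    "nanoflagellates": 1.32e-7,
    "ciliates": 1.27e-7,
    "mesozooplankton": 1.28e-7,
    "fish": 1.04e-10,
}


@dataclass(frozen=True)
class TrophicGroupSpec:
    """Static parameters of one trophic group.

    ``cell_or_body_volume`` is the cell volume [um^3] for unicells and
    protozoans; for fish it holds the individual carbon mass
    [umol C ind^-1] instead.  Rate parameters that do not apply to a
    role (e.g. ``clearance`` for a producer) are zero.
    """

    name: str
    role: str
    cell_or_body_volume: float
    q_max: float
    prey: tuple = ()
    mu_max: float = 0.0          # maximal specific growth rate [d^-1]
    K_N: float = 0.0             # DIN half-saturation [mmol m^-3]
    K_P: float = 0.0             # DIP half-saturation [mmol m^-3]
    K_DOC: float = 0.0           # DOC half-saturation [mmol C m^-3], bacteria only
    K_I: float = 0.0             # light half-saturation [relative irradiance]
    clearance: float = 0.0       # [m^3 (umol C)^-1 d^-1], consumers/fish
    I_max: float = 0.0           # maximal specific ingestion [d^-1]
    gge: float = 0.0             # gross growth efficiency
    metabolic_rate: float = 0.0  # specific turnover [d^-1]
    basal_respiration: float = 0.0  # maintenance carbon loss [d^-1]

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if self.role == "fish" and self.basal_respiration != 0.0:
            raise ValueError(
                f"{self.name}: fish biomass is fixed; basal_respiration must be 0")
        if self.q_max <= 0:
            raise ValueError(f"{self.name}: q_max must be > 0")
        if self.cell_or_body_volume <= 0:
            raise ValueError(f"{self.name}: cell_or_body_volume must be > 0")
        for attr in ("mu_max", "K_N", "K_P", "K_DOC", "K_I", "clearance",
                     "I_max", "metabolic_rate", "basal_respiration"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        if self.role in ("consumer", "fish"):
            if not 0.0 < self.gge < 1.0:
                raise ValueError(f"{self.name}: gge must be in (0, 1)")
            if not self.prey:
                raise ValueError(f"{self.name}: consumer needs a prey list")
        if self.role == "heterotrophic_bacteria" and not 0.0 < self.gge < 1.0:
            raise ValueError(f"{self.name}: bacterial growth efficiency must be in (0, 1)")
        object.__setattr__(self, "prey", tuple(self.prey))


def allometric_scale(volume: float, reference_volume: float, exponent: float) -> float:
    """Dimensionless allometric multiplier (volume / reference_volume)**exponent.

    Applied with a negative exponent to ``mu_max`` (smaller cells grow
    and take up nutrients faster per unit carbon) and a positive one to
    ``K_I`` (larger cells absorb less light per unit volume, so they
    saturate at higher irradiance).
    """
    if volume <= 0 or reference_volume <= 0:
        raise ValueError("volumes must be > 0")
    return (volume / reference_volume) ** exponent


# Allometric bases for the default producer parameterization, all relative to
# a 1 um^3 reference cell (picoalgae).  Config-overridable.
_MU0 = 1.3          # d^-1 at 1 um^3
_MU_EXP = -0.10     # growth-rate exponent on cell volume
_KN0 = 0.30         # mmol N m^-3 at 1 um^3
_KN_EXP = 0.20      # affinity worsens with size
_KI0 = 0.02         # relative irradiance at 1 um^3
_KI_EXP = 1.0 / 3.0


def _producer(name: str, volume: float, met_frac: float = 1.0) -> TrophicGroupSpec:
    mu = _MU0 * allometric_scale(volume, 1.0, _MU_EXP)
    K_N = _KN0 * allometric_scale(volume, 1.0, _KN_EXP)
    K_I = _KI0 * allometric_scale(volume, 1.0, _KI_EXP)
    return TrophicGroupSpec(
        name=name, role="producer", cell_or_body_volume=volume,
        q_max=MAX_B1_QUOTA[name], mu_max=mu, K_N=K_N, K_P=K_N / 16.0,
        K_I=K_I, metabolic_rate=met_frac * mu, basal_respiration=0.03,
    )


def baltic_default_specs() -> dict[str, TrophicGroupSpec]:
    """Default parameter table for the Baltic-proper style food web.

    Maximal B1 quotas are the empirical per-group values; the remaining
    rate constants are the package's own parameterization (allometric
    producer ladder, protozoan-to-fish clearance/ingestion rates in
    literature ranges) and every entry can be overridden through the
    run configuration.
    """
    specs = {
        "bacteria": TrophicGroupSpec(
            name="bacteria", role="heterotrophic_bacteria",
            cell_or_body_volume=0.1, q_max=MAX_B1_QUOTA["bacteria"],
            mu_max=2.0, K_N=0.2, K_P=0.2 / 16.0, K_DOC=10.0,
            gge=0.3, metabolic_rate=2.0, basal_respiration=0.1,
        ),
        "picoalgae": _producer("picoalgae", 1.0),
        "nanoalgae": _producer("nanoalgae", 1e2),
        "microalgae": _producer("microalgae", 1e4),
        "nanoflagellates": TrophicGroupSpec(
            name="nanoflagellates", role="consumer", cell_or_body_volume=1e2,
            q_max=MAX_B1_QUOTA["nanoflagellates"],
            prey=("bacteria", "picoalgae"),
            clearance=5e-4, I_max=3.5, gge=0.3, metabolic_rate=0.3,
            basal_respiration=0.3,
        ),
        "ciliates": TrophicGroupSpec(
            name="ciliates", role="consumer", cell_or_body_volume=1e4,
            q_max=MAX_B1_QUOTA["ciliates"],
            prey=("nanoflagellates", "nanoalgae"),
            clearance=3e-4, I_max=2.5, gge=0.3, metabolic_rate=0.2,
            basal_respiration=0.2,
        ),
        "mesozooplankton": TrophicGroupSpec(
            name="mesozooplankton", role="consumer", cell_or_body_volume=1e7,
            q_max=MAX_B1_QUOTA["mesozooplankton"],
            prey=("ciliates", "microalgae"),
            clearance=3e-4, I_max=1.0, gge=0.3, metabolic_rate=0.1,
            basal_respiration=0.08,
        ),
        "fish": TrophicGroupSpec(
            name="fish", role="fish",
            cell_or_body_volume=1.5e5,  # umol C per individual, ~15 cm clupeid
            q_max=MAX_B1_QUOTA["fish"],
            prey=("mesozooplankton",),
            clearance=1e-4, I_max=0.03, gge=0.3, metabolic_rate=0.03,
        ),
    }
    return specs


@dataclass
class EcosystemState:
    """Time-varying pools of the enclosed mixed layer.

    Biomass and B1 pools are arrays aligned with ``groups``; dissolved
    pools are scalars [mmol m^-3] except DOC [mmol C m^-3].  Fish
    abundance [ind m^-3] is constant within a run.
    """

    groups: tuple
    biomass_C: np.ndarray    # [umol C m^-3]
    b1_pool: np.ndarray      # [umol B1 m^-3]
    NO3: float
    NH4: float
    PO4: float
    DOC: float
    fish_abundance: float
    day: float = 0.0

    def __post_init__(self) -> None:
        self.biomass_C = np.asarray(self.biomass_C, dtype=float)
        self.b1_pool = np.asarray(self.b1_pool, dtype=float)
        if self.biomass_C.shape != (len(self.groups),):
            raise ValueError("biomass_C must have one entry per group")
        if self.b1_pool.shape != (len(self.groups),):
            raise ValueError("b1_pool must have one entry per group")
        for name, value in (("NO3", self.NO3), ("NH4", self.NH4),
                            ("PO4", self.PO4), ("DOC", self.DOC)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if np.any(self.biomass_C < 0) or np.any(self.b1_pool < 0):
            raise ValueError("biomass and B1 pools must be >= 0")

    def index(self, group: str) -> int:
        return self.groups.index(group)

    @property
    def quota(self) -> np.ndarray:
        """Mass-specific B1 content per group [umol B1 (umol C)^-1]."""
        return self.b1_pool / self.biomass_C

    def total_N(self) -> float:
        """Dissolved plus biomass-bound nitrogen [mmol N m^-3]."""
        # biomass is in umol C; 1 umol = 1e-3 mmol
        return self.NO3 + self.NH4 + float(self.biomass_C.sum()) * REDFIELD_N_PER_C * 1e-3

    def total_P(self) -> float:
        """Dissolved plus biomass-bound phosphorus [mmol P m^-3]."""
        return self.PO4 + float(self.biomass_C.sum()) * REDFIELD_P_PER_C * 1e-3

    def copy(self) -> "EcosystemState":
        return EcosystemState(
            groups=self.groups, biomass_C=self.biomass_C.copy(),
            b1_pool=self.b1_pool.copy(), NO3=self.NO3, NH4=self.NH4,
            PO4=self.PO4, DOC=self.DOC, fish_abundance=self.fish_abundance,
            day=self.day,
        )


def nutrient_limitation(conc: float, K: float) -> float:
    """Monod limitation factor conc / (conc + K) in [0, 1]."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if K <= 0:
        raise ValueError(f"half-saturation must be > 0, got {K}")
    return conc / (conc + K)


def producer_growth_rate(spec: TrophicGroupSpec, mean_irradiance: float,
                         DIN: float, DIP: float) -> float:
    """Specific growth rate of a primary producer [d^-1].

    Liebig minimum of the Monod nitrogen and phosphorus factors,
    multiplied by a saturating light factor I / (I + K_I) evaluated at
    the depth-averaged irradiance; bounded by ``mu_max``.
    """
    if spec.role != "producer":
        raise ValueError(f"{spec.name} is not a producer")
    if mean_irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    f_N = nutrient_limitation(DIN, spec.K_N)
    f_P = nutrient_limitation(DIP, spec.K_P)
    f_I = mean_irradiance / (mean_irradiance + spec.K_I)
    return spec.mu_max * min(f_N, f_P) * f_I


def bacterial_growth_rate(spec: TrophicGroupSpec, DOC: float,
                          DIN: float, DIP: float) -> float:
    """Specific growth rate of heterotrophic bacteria [d^-1].

    Liebig minimum over DOC (carbon substrate) and the inorganic N and
    P needed to build Redfield biomass.
    """
    if spec.role != "heterotrophic_bacteria":
        raise ValueError(f"{spec.name} is not heterotrophic bacteria")
    f_DOC = nutrient_limitation(DOC, spec.K_DOC)
    f_N = nutrient_limitation(DIN, spec.K_N)
    f_P = nutrient_limitation(DIP, spec.K_P)
    return spec.mu_max * min(f_DOC, f_N, f_P)


def grazing_flux(pred_spec: TrophicGroupSpec, pred_biomass_C: float,
                 prey_biomass_C: Mapping[str, float]) -> dict[str, float]:
    """Carbon ingestion flux from each prey group [umol C m^-3 d^-1].

    Clearance-rate feeding with a hard cap: the per-prey encounter rate
    is ``clearance * prey_biomass`` [d^-1 per unit predator C]; if the
    summed encounter rate exceeds ``I_max`` the fluxes are scaled back
    proportionally, which yields a type-II (saturating) functional
    response with the plateau shared across prey in proportion to
    clearance * biomass.
    """
    if pred_spec.role not in ("consumer", "fish"):
        raise ValueError(f"{pred_spec.name} is not a consumer")
    if not pred_spec.prey:
        raise ValueError(f"{pred_spec.name} has an empty prey list")
    if pred_biomass_C < 0:
        raise ValueError("predator biomass must be >= 0")
    encounter = {}
    for prey in pred_spec.prey:
        b = prey_biomass_C[prey]
        if b < 0:
            raise ValueError(f"prey biomass for {prey} must be >= 0")
        encounter[prey] = pred_spec.clearance * b
    total = sum(encounter.values())
    scale = 1.0 if total <= pred_spec.I_max or total == 0.0 else pred_spec.I_max / total
    return {prey: pred_biomass_C * enc * scale for prey, enc in encounter.items()}


class IngestionPartition(NamedTuple):
    growth_C: float
    respired_C: float
    excreted_DOC: float
    excreted_DIN: float   # mmol N m^-3 d^-1
    excreted_DIP: float   # mmol P m^-3 d^-1


#: fraction of non-growth carbon losses excreted as DOC (rest respired)
DOC_LOSS_FRACTION = 0.2
#: fraction of gross primary production exuded as DOC
PRODUCER_EXUDATION = 0.1


def partition_ingestion(pred_spec: TrophicGroupSpec,
                        ingested_C: float) -> IngestionPartition:
    """Split ingested carbon into growth, respiration and excretion.

    ``growth_C = gge * ingested``; of the remainder a fixed fraction is
    excreted as DOC and the rest respired (leaves the modelled carbon
    budget as CO2).  All N and P of the non-grown ingested biomass is
    returned to the NH4 and PO4 pools, so element budgets close
    exactly.  For fish, somatic growth is immediately remineralized as
    well (constant population size), so growth_C is reported as zero
    and its carbon joins respiration, its N and P the dissolved pools;
    the B1 content of ingested prey is handled separately and is
    retained.
    """
    if ingested_C < 0:
        raise ValueError("ingested carbon must be >= 0")
    growth = pred_spec.gge * ingested_C
    losses = ingested_C - growth
    doc = DOC_LOSS_FRACTION * losses
    respired = losses - doc
    if pred_spec.role == "fish":
        respired += growth
        growth = 0.0
    # umol -> mmol for the dissolved pools
    din = (ingested_C - growth) * REDFIELD_N_PER_C * 1e-3
    dip = (ingested_C - growth) * REDFIELD_P_PER_C * 1e-3
    return IngestionPartition(growth, respired, doc, din, dip)


def b1_source_flux(spec: TrophicGroupSpec, biomass_C: float,
                   current_quota: float, b1_input_multiplier: float = 1.0) -> float:
    """B1 synthesis/uptake by a producer or bacterial group [umol B1 m^-3 d^-1].

    The quota relaxes toward ``q_max`` at a specific rate equal to the
    group's metabolic rate times an input multiplier (the sensitivity
    hook for faster/slower net B1 acquisition):
    flux = rate * (q_max - quota) * biomass.
    """
    if spec.role not in ("producer", "heterotrophic_bacteria"):
        raise ValueError(f"{spec.name} gains B1 only by feeding")
    if not 0.0 <= current_quota <= spec.q_max * (1 + 1e-12):
        raise ValueError(f"quota {current_quota} outside [0, q_max]")
    if biomass_C < 0 or b1_input_multiplier < 0:
        raise ValueError("biomass and multiplier must be >= 0")
    rate = spec.metabolic_rate * b1_input_multiplier
    return rate * max(spec.q_max - current_quota, 0.0) * biomass_C


def b1_trophic_transfer(ingested_C: float, prey_quota: float,
                        b: float) -> tuple[float, float]:
    """Absorbed and degraded B1 for one feeding flux.

    The B1 contained in the ingested biomass is ``prey_quota *
    ingested_C``; the consumer absorbs the bioavailable fraction ``b``
    and the rest is degraded.  Absorbed + degraded equals the B1
    removed from the prey pool exactly.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"bioavailability must be in [0, 1], got {b}")
    if ingested_C < 0 or prey_quota < 0:
        raise ValueError("ingested carbon and prey quota must be >= 0")
    total = prey_quota * ingested_C
    absorbed = b * total
    return absorbed, total - absorbed


def b1_consumer_update(spec: TrophicGroupSpec, biomass_C_after_growth: float,
                       absorbed_B1: float, old_pool: float,
                       dt: float = 1.0) -> tuple[float, float]:
    """One-step B1 pool update for a consumer: first-order turnover plus intake.

    pool' = old_pool * (1 - turnover * dt) + absorbed * dt, then capped
    so the quota does not exceed ``q_max``; the clipped overflow is
    returned so the mass-balance ledger can count it as degraded.
    Turnover equals the group's metabolic rate.
    """
    if absorbed_B1 < 0 or old_pool < 0 or biomass_C_after_growth < 0:
        raise ValueError("inputs must be >= 0")
    decay = max(1.0 - spec.metabolic_rate * dt, 0.0)
    pool = old_pool * decay + absorbed_B1 * dt
    cap = spec.q_max * biomass_C_after_growth
    overflow = max(pool - cap, 0.0)
    return pool - overflow, overflow


def b1_fish_update(spec: TrophicGroupSpec, state: EcosystemState,
                   absorbed_B1: float, dt: float) -> tuple[float, float]:
    """B1 pool and quota update for the fish population.

    Fish carbon biomass is fixed at abundance * individual carbon mass
    (balanced birth and death), so at a given total absorbed flux the
    steady-state quota absorbed/(turnover * biomass) is inversely
    proportional to abundance: the incoming vitamin is diluted among
    individuals when planktivorous fish are numerous.
    """
    if spec.role != "fish":
        raise ValueError(f"{spec.name} is not fish")
    if state.fish_abundance <= 0:
        raise ValueError("fish abundance must be > 0")
    biomass = state.fish_abundance * spec.cell_or_body_volume
    old_pool = float(state.b1_pool[state.index("fish")])
    pool, _overflow = b1_consumer_update(spec, biomass, absorbed_B1, old_pool, dt)
    return pool, pool / biomass


def validate_foodweb(specs: Mapping[str, TrophicGroupSpec]) -> None:
    """Check that every consumer's prey are present in the spec table."""
    for spec in specs.values():
        for prey in spec.prey:
            if prey not in specs:
                raise ValueError(f"{spec.name}: prey {prey!r} not in the food web")
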