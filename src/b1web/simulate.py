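"""Seasonal time integration of one scenario with mass-balance auditing.

The enclosed mixed layer is integrated with an explicit Euler scheme
over the vegetative season (30 March - 1 October).  Every flux is
evaluated from the state at the beginning of the step; proportional
flux limiting scales outgoing fluxes down whenever a pool would be
exhausted within the step, which preserves positivity and exact
element conservation simultaneously.  There is no nonconsumptive
mortality: biomass is lost only to grazing (and, for carbon, to
respiration and DOC excretion).

A ledger accumulates the carbon, nitrogen, phosphorus and vitamin B1
budgets so that closure can be asserted after a run: N and P totals
are constant (enclosed system), carbon satisfies
``delta(biomass + DOC) = primary production - respiration`` and B1
satisfies ``sources = delta(stocks) + degraded``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .foodweb import (
    EcosystemState,
    REDFIELD_N_PER_C,
    REDFIELD_P_PER_C,
    UMOL_C_TO_MG,
    TrophicGroupSpec,
    baltic_default_specs,
    validate_foodweb,
)
from .forcing import LightForcing, surface_irradiance
from .scenarios import Scenario, default_scenario

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationError",
    "step",
    "run_scenario",
    "run_reduced_foodchain",
]


class SimulationError(RuntimeError):
    """Numerical failure during integration (NaN or negative pool)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and initial-condition settings.

    Times are continuous days since 1 January (day 89 = 30 March,
    day 152 = 1 June, day 274 = 1 October).  April and May are within
    the simulated season but excluded from analysis, leaving time for
    the plankton and the fish B1 pool to spin up.
    """

    dt: float = 0.02                      # d; diel forcing needs sub-daily steps
    season_start: float = 89.0
    season_end: float = 274.0
    analysis_start: float = 152.0
    layer_depth: float = 10.0             # m
    k_s: float = 5e-5                     # m^2 (mg C)^-1 self-shading coefficient
    initial_biomass: float = 10.0         # umol C m^-3 seed per group
    initial_DOC: float = 5.0              # mmol C m^-3
    initial_quota_fraction: float = 0.01  # of q_max ("picomolar" start)
    extinction_floor: float = 1e-6        # umol C m^-3
    producer_exudation: float = 0.1       # fraction of gross production to DOC
    doc_loss_fraction: float = 0.2        # fraction of consumer losses to DOC

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 0.1:
            raise ValueError(f"dt must be in (0, 0.1], got {self.dt}")
        if not self.season_start < self.analysis_start < self.season_end:
            raise ValueError("need season_start < analysis_start < season_end")
        if self.layer_depth <= 0:
            raise ValueError("layer_depth must be > 0")
        if self.k_s < 0:
            raise ValueError("k_s must be >= 0")
        for attr in ("initial_biomass", "initial_DOC"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if not 0.0 < self.initial_quota_fraction <= 1.0:
            raise ValueError("initial_quota_fraction must be in (0, 1]")
        if not 0.0 <= self.producer_exudation < 1.0:
            raise ValueError("producer_exudation must be in [0, 1)")
        if not 0.0 <= self.doc_loss_fraction <= 1.0:
            raise ValueError("doc_loss_fraction must be in [0, 1]")


@dataclass
class SimulationResult:
    """Daily time series and closed budgets of one scenario run.

    Pools are midnight instantaneous values; ``light`` and ``k`` are
    means over the preceding day (NaN on the first record).  All series
    share the ``days`` axis.
    """

    scenario: Scenario
    config: SimulationConfig
    groups: tuple
    days: np.ndarray            # day-of-year of each record
    biomass: np.ndarray         # (n_days, n_groups) umol C m^-3
    quota: np.ndarray           # (n_days, n_groups) umol B1 (umol C)^-1
    NO3: np.ndarray
    NH4: np.ndarray
    PO4: np.ndarray
    DOC: np.ndarray
    light: np.ndarray           # daily-mean depth-averaged irradiance
    k: np.ndarray               # daily-mean attenuation [m^-1]
    ledger: dict

    def index(self, group: str) -> int:
        return self.groups.index(group)

    def group_biomass(self, group: str) -> np.ndarray:
        return self.biomass[:, self.index(group)]

    def group_quota(self, group: str) -> np.ndarray:
        return self.quota[:, self.index(group)]

    @property
    def fish_quota(self) -> np.ndarray:
        return self.group_quota("fish")

    @property
    def DIN(self) -> np.ndarray:
        return self.NO3 + self.NH4

    def analysis_mask(self) -> np.ndarray:
        """Records inside the analysis window (June 1 - season end)."""
        return self.days >= self.config.analysis_start

    def to_frame(self):
        """Tidy long-format table: (day, variable, group, value)."""
        import pandas as pd

        rows = []
        for j, g in enumerate(self.groups):
            rows.append(pd.DataFrame({
                "day": self.days, "variable": "biomass_C", "group": g,
                "value": self.biomass[:, j]}))
            rows.append(pd.DataFrame({
                "day": self.days, "variable": "b1_quota", "group": g,
                "value": self.quota[:, j]}))
        for name, series in (("NO3", self.NO3), ("NH4", self.NH4),
                             ("PO4", self.PO4), ("DOC", self.DOC),
                             ("light", self.light), ("k", self.k)):
            rows.append(pd.DataFrame({
                "day": self.days, "variable": name, "group": "",
                "value": series}))
        return pd.concat(rows, ignore_index=True)


class _Engine:
    """Precompiled parameter arrays for one food-web spec table."""

    def __init__(self, specs: Mapping[str, TrophicGroupSpec],
                 forcing: LightForcing, config: SimulationConfig,
                 scenario: Scenario):
        validate_foodweb(specs)
        self.groups = tuple(specs)
        self.specs = dict(specs)
        self.forcing = forcing
        self.config = config
        self.scenario = scenario
        idx = {g: i for i, g in enumerate(self.groups)}
        n = len(self.groups)

        roles = [specs[g].role for g in self.groups]
        self.prod = np.array([i for i, r in enumerate(roles) if r == "producer"],
                             dtype=int)
        bact = [i for i, r in enumerate(roles) if r == "heterotrophic_bacteria"]
        if len(bact) > 1:
            raise ValueError("at most one heterotrophic bacteria group supported")
        self.bact = bact[0] if bact else None
        self.fish = idx.get("fish")

        def arr(attr):
            return np.array([getattr(specs[g], attr) for g in self.groups])

        self.q_max = arr("q_max")
        self.met = arr("metabolic_rate")
        self.mu_max = arr("mu_max")
        self.K_N = arr("K_N")
        self.K_P = arr("K_P")
        self.K_I = arr("K_I")
        # maintenance respiration burns biomass carbon and remineralizes its
        # N and P (fish excluded: constant population, budget fully recycled)
        self.basal_rate = arr("basal_respiration")

        # consumers in group order; each entry (pred index, prey indices, ...)
        self.consumers = []
        for i, g in enumerate(self.groups):
            s = specs[g]
            if s.role in ("consumer", "fish"):
                prey_idx = np.array([idx[p] for p in s.prey], dtype=int)
                self.consumers.append(
                    (i, prey_idx, s.clearance, s.I_max, s.gge, s.role == "fish"))
        self.n = n

    def initial_state(self) -> EcosystemState:
        cfg, sc = self.config, self.scenario
        B = np.full(self.n, cfg.initial_biomass)
        if self.fish is not None:
            B[self.fish] = sc.fish_abundance * self.specs["fish"].cell_or_body_volume
        pool = cfg.initial_quota_fraction * self.q_max * B
        return EcosystemState(
            groups=self.groups, biomass_C=B, b1_pool=pool,
            NO3=sc.NO3_0, NH4=sc.NH4_0, PO4=sc.PO4_0, DOC=cfg.initial_DOC,
            fish_abundance=sc.fish_abundance, day=cfg.season_start,
        )

    def new_ledger(self, state: EcosystemState) -> dict:
        return {
            "N_initial": state.total_N(), "P_initial": state.total_P(),
            "C_initial": float(state.biomass_C.sum()) + state.DOC * 1e3,
            "B1_initial": float(state.b1_pool.sum()),
            "primary_production": 0.0, "respiration": 0.0,
            "b1_sources": 0.0, "b1_degraded_transfer": 0.0,
            "b1_degraded_turnover": 0.0, "b1_degraded_overflow": 0.0,
            "b1_absorbed": np.zeros(self.n),
            "b1_grazing_outflow": np.zeros(self.n),
        }

    def step(self, B, P, NO3, NH4, PO4, DOC, t, dt, ledger):
        """Advance pools by one Euler step; mutates B and P in place."""
        cfg, sc = self.config, self.scenario

        # --- light ---
        I0 = surface_irradiance(self.forcing, t)
        W_PP = UMOL_C_TO_MG * float(B[self.prod].sum())
        k = cfg.k_s * W_PP + sc.k_bg
        kh = k * cfg.layer_depth
        Iavg = I0 * (1.0 - math.exp(-kh)) / kh if kh > 1e-8 else I0

        DIN = NO3 + NH4

        # --- producer and bacterial gross growth (pre-limit) ---
        p = self.prod
        fN = DIN / (DIN + self.K_N[p])
        fP = PO4 / (PO4 + self.K_P[p])
        fI = Iavg / (Iavg + self.K_I[p])
        mu = self.mu_max[p] * np.minimum(fN, fP) * fI
        G = mu * B[p]                            # gross C fixation
        exud = cfg.producer_exudation * G        # DOC exudation
        NB = G - exud                            # net producer biomass growth

        if self.bact is not None:
            sb = self.specs[self.groups[self.bact]]
            f = min(DOC / (DOC + sb.K_DOC) if sb.K_DOC > 0 else 1.0,
                    DIN / (DIN + sb.K_N), PO4 / (PO4 + sb.K_P))
            Gb = sb.mu_max * f * B[self.bact]    # net bacterial growth
            bge = sb.gge
        else:
            Gb, bge = 0.0, 1.0

        # --- proportional limiting on dissolved resources ---
        growthC = float(NB.sum()) + Gb           # umol C needing N and P
        demandN = growthC * REDFIELD_N_PER_C * 1e-3   # mmol per day
        demandP = growthC * REDFIELD_P_PER_C * 1e-3
        demandDOC = (Gb / bge) * 1e-3
        sN = min(1.0, DIN / (demandN * dt)) if demandN > 0 else 1.0
        sP = min(1.0, PO4 / (demandP * dt)) if demandP > 0 else 1.0
        sDOC = min(1.0, DOC / (demandDOC * dt)) if demandDOC > 0 else 1.0
        s_prod = min(sN, sP)
        if s_prod < 1.0:
            G = G * s_prod
            exud = exud * s_prod
            NB = NB * s_prod
        s_bact = min(sN, sP, sDOC)
        Gb *= s_bact
        doc_uptake = Gb / bge
        resp_bact = doc_uptake - Gb

        # --- grazing fluxes (from pre-step biomasses) ---
        outflow = np.zeros(self.n)
        fluxes = []  # (pred i, prey_idx, per-prey flux array, gge, is_fish)
        for i, prey_idx, clearance, I_max, gge, is_fish in self.consumers:
            enc = clearance * B[prey_idx]
            tot = float(enc.sum())
            if tot > I_max:
                enc = enc * (I_max / tot)
            F = B[i] * enc
            outflow[prey_idx] += F
            fluxes.append((i, prey_idx, F, gge, is_fish))

        basal = self.basal_rate * B   # maintenance respiration

        # biomass may not be drawn below the extinction floor within a step;
        # grazing and basal respiration share the available stock
        avail = np.maximum(B - cfg.extinction_floor, 0.0)
        total_out = outflow + basal
        with np.errstate(divide="ignore", invalid="ignore"):
            fac = np.where(total_out * dt > avail,
                           avail / np.maximum(total_out * dt, 1e-300), 1.0)
        if fac.min() < 1.0:
            for _, prey_idx, F, _, _ in fluxes:
                F *= fac[prey_idx]
            outflow *= fac
            basal *= fac

        # --- ingestion partitioning ---
        growth_cons = np.zeros(self.n)
        excr_N = 0.0   # umol N equivalents as carbon-proportional bookkeeping
        doc_excr = 0.0
        resp_cons = 0.0
        for i, prey_idx, F, gge, is_fish in fluxes:
            I_tot = float(F.sum())
            grown = gge * I_tot
            losses = I_tot - grown
            doc_j = cfg.doc_loss_fraction * losses
            resp_j = losses - doc_j
            if is_fish:  # constant population: somatic growth remineralized
                resp_j += grown
                grown = 0.0
            growth_cons[i] = grown
            excr_N += I_tot - grown   # carbon units; converted below
            doc_excr += doc_j
            resp_cons += resp_j
        basal_tot = float(basal.sum())
        excr_N += basal_tot           # maintenance N/P remineralized
        resp_cons += basal_tot

        # --- vitamin B1 fluxes (pre-step quotas) ---
        q = P / B
        src = np.zeros(self.n)
        mult = sc.b1_input_multiplier
        rate = np.minimum(self.met * mult, 1.0 / dt)
        if self.bact is not None:
            i = self.bact
            src[i] = rate[i] * max(self.q_max[i] - q[i], 0.0) * B[i]
        src[p] = rate[p] * np.maximum(self.q_max[p] - q[p], 0.0) * B[p]

        b1_out = q * outflow                     # B1 leaving prey pools
        absorbed = np.zeros(self.n)
        b = sc.bioavailability
        for i, prey_idx, F, _, _ in fluxes:
            absorbed[i] = b * float((q[prey_idx] * F).sum())
        degraded_transfer = float(b1_out.sum()) - float(absorbed.sum())

        turnover = np.zeros(self.n)
        for i, _, _, _, _ in fluxes:
            turnover[i] = self.met[i] * P[i]

        # limit B1 outflows so no pool goes negative within the step
        b1_loss = b1_out + turnover
        with np.errstate(divide="ignore", invalid="ignore"):
            fac_b1 = np.where(b1_loss * dt > P,
                              P / np.maximum(b1_loss * dt, 1e-300), 1.0)
        if fac_b1.min() < 1.0:
            for i, prey_idx, F, _, _ in fluxes:
                absorbed[i] = b * float((q[prey_idx] * fac_b1[prey_idx] * F).sum())
            b1_out *= fac_b1
            turnover *= fac_b1
            degraded_transfer = float(b1_out.sum()) - float(absorbed.sum())

        # --- apply updates ---
        B[p] += NB * dt
        if self.bact is not None:
            B[self.bact] += Gb * dt
        B += growth_cons * dt
        B -= (outflow + basal) * dt
        np.maximum(B, cfg.extinction_floor, out=B)

        # after scaling, recompute the exact N/P draw from realized growth
        growthC = float(NB.sum()) + Gb
        drawN = growthC * REDFIELD_N_PER_C * 1e-3 * dt
        drawP = growthC * REDFIELD_P_PER_C * 1e-3 * dt
        nh4_draw = min(NH4, drawN)
        no3_draw = drawN - nh4_draw
        retN = excr_N * REDFIELD_N_PER_C * 1e-3 * dt
        retP = excr_N * REDFIELD_P_PER_C * 1e-3 * dt
        # max(..., 0) only absorbs fp rounding; the limiter keeps draws <= stock
        NH4 = max(NH4 - nh4_draw, 0.0) + retN
        NO3 = max(NO3 - no3_draw, 0.0)
        PO4 = max(PO4 - drawP, 0.0) + retP
        DOC = max(DOC + (float(exud.sum()) + doc_excr - doc_uptake) * 1e-3 * dt, 0.0)

        P += (src + absorbed - b1_out - turnover) * dt
        np.maximum(P, 0.0, out=P)
        cap = self.q_max * B
        over = np.maximum(P - cap, 0.0)
        P -= over

        # --- ledger ---
        ledger["primary_production"] += float(G.sum()) * dt
        ledger["respiration"] += (resp_bact + resp_cons) * dt
        ledger["b1_sources"] += float(src.sum()) * dt
        ledger["b1_degraded_transfer"] += degraded_transfer * dt
        ledger["b1_degraded_turnover"] += float(turnover.sum()) * dt
        ledger["b1_degraded_overflow"] += float(over.sum())
        ledger["b1_absorbed"] += absorbed * dt
        ledger["b1_grazing_outflow"] += b1_out * dt

        return NO3, NH4, PO4, DOC, Iavg, k

    def finalize_ledger(self, ledger, state: EcosystemState) -> dict:
        tiny = 1e-300
        n0, p0 = ledger["N_initial"], ledger["P_initial"]
        c0, b10 = ledger["C_initial"], ledger["B1_initial"]
        c1 = float(state.biomass_C.sum()) + state.DOC * 1e3
        b11 = float(state.b1_pool.sum())
        deg = (ledger["b1_degraded_transfer"] + ledger["b1_degraded_turnover"]
               + ledger["b1_degraded_overflow"])
        out = dict(ledger)
        out["b1_absorbed"] = {g: float(v) for g, v in
                              zip(self.groups, ledger["b1_absorbed"])}
        out["b1_grazing_outflow"] = {g: float(v) for g, v in
                                     zip(self.groups, ledger["b1_grazing_outflow"])}
        out["N_final"] = state.total_N()
        out["P_final"] = state.total_P()
        out["C_final"] = c1
        out["B1_final"] = b11
        out["N_residual_rel"] = (out["N_final"] - n0) / max(abs(n0), tiny)
        out["P_residual_rel"] = (out["P_final"] - p0) / max(abs(p0), tiny)
        net_c = ledger["primary_production"] - ledger["respiration"]
        out["C_residual_rel"] = ((c1 - c0) - net_c) / max(abs(c0) + abs(net_c), tiny)
        out["B1_residual_rel"] = ((ledger["b1_sources"] - (b11 - b10) - deg)
                                  / max(ledger["b1_sources"], tiny))
        return out


def _run(engine: _Engine) -> SimulationResult:
    cfg = engine.config
    steps_per_day = max(1, round(1.0 / cfg.dt))
    dt = 1.0 / steps_per_day
    n_days = int(round(cfg.season_end - cfg.season_start))

    state = engine.initial_state()
    ledger = engine.new_ledger(state)
    B = state.biomass_C
    P = state.b1_pool
    NO3, NH4, PO4, DOC = state.NO3, state.NH4, state.PO4, state.DOC

    n_rec = n_days + 1
    days = np.empty(n_rec)
    biomass = np.empty((n_rec, engine.n))
    quota = np.empty((n_rec, engine.n))
    no3_s = np.empty(n_rec)
    nh4_s = np.empty(n_rec)
    po4_s = np.empty(n_rec)
    doc_s = np.empty(n_rec)
    light_s = np.full(n_rec, np.nan)
    k_s_ = np.full(n_rec, np.nan)

    def record(row, t, light, kmean):
        days[row] = t
        biomass[row] = B
        quota[row] = P / B
        no3_s[row], nh4_s[row], po4_s[row], doc_s[row] = NO3, NH4, PO4, DOC
        light_s[row], k_s_[row] = light, kmean
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(P))
                and np.isfinite(NO3 + NH4 + PO4 + DOC)):
            raise SimulationError(
                f"non-finite pool at day {t:.1f} "
                f"(scenario {engine.scenario.label or 'unnamed'}); "
                f"ledger: {engine.finalize_ledger(ledger, state)}")

    record(0, cfg.season_start, np.nan, np.nan)
    t = cfg.season_start
    for d in range(n_days):
        lsum = 0.0
        ksum = 0.0
        for i in range(steps_per_day):
            NO3, NH4, PO4, DOC, Iavg, k = engine.step(
                B, P, NO3, NH4, PO4, DOC, t, dt, ledger)
            lsum += Iavg
            ksum += k
            t = cfg.season_start + d + (i + 1) * dt
        t = cfg.season_start + d + 1
        record(d + 1, t, lsum / steps_per_day, ksum / steps_per_day)

    state = EcosystemState(
        groups=engine.groups, biomass_C=B, b1_pool=P, NO3=NO3, NH4=NH4,
        PO4=PO4, DOC=DOC, fish_abundance=engine.scenario.fish_abundance,
        day=t)
    return SimulationResult(
        scenario=engine.scenario, config=cfg, groups=engine.groups,
        days=days, biomass=biomass, quota=quota, NO3=no3_s, NH4=nh4_s,
        PO4=po4_s, DOC=doc_s, light=light_s, k=k_s_,
        ledger=engine.finalize_ledger(ledger, state))


def run_scenario(scenario: Scenario | None = None,
                 specs: Mapping[str, TrophicGroupSpec] | None = None,
                 config: SimulationConfig | None = None,
                 forcing: LightForcing | None = None) -> SimulationResult:
    """Integrate one scenario over the vegetative season.

    All scenarios share identical initial conditions apart from the
    scenario factors themselves: every group is seeded at a small
    biomass, quotas start at a picomolar-scale fraction of their
    maxima, and dissolved pools come from the scenario.  The run is
    deterministic: identical inputs give identical outputs.
    """
    scenario = scenario or default_scenario()
    specs = specs or baltic_default_specs()
    config = config or SimulationConfig()
    forcing = forcing or LightForcing(
        season_start=config.season_start, season_end=config.season_end)
    return _run(_Engine(specs, forcing, config, scenario))


def step(state: EcosystemState, specs: Mapping[str, TrophicGroupSpec],
         forcing: LightForcing, config: SimulationConfig,
         scenario: Scenario) -> EcosystemState:
    """Advance an ecosystem state by one Euler step of ``config.dt``.

    Returns a new state; the input is not mutated.  The same flux
    ordering as the season integrator: light, autotrophic/bacterial
    growth with nutrient draw-down, grazing, ingestion partitioning and
    excretion, then the B1 source/transfer/turnover/cap updates.
    """
    engine = _Engine(specs, forcing, config, scenario)
    new = state.copy()
    ledger = engine.new_ledger(new)
    NO3, NH4, PO4, DOC, _, _ = engine.step(
        new.biomass_C, new.b1_pool, new.NO3, new.NH4, new.PO4, new.DOC,
        state.day, config.dt, ledger)
    new.NO3, new.NH4, new.PO4, new.DOC = NO3, NH4, PO4, DOC
    new.day = state.day + config.dt
    if not (np.all(np.isfinite(new.biomass_C)) and np.all(np.isfinite(new.b1_pool))):
        raise SimulationError(
            f"non-finite pool after step; ledger: {engine.finalize_ledger(ledger, new)}")
    return new


def run_reduced_foodchain(chain_specs: Sequence[TrophicGroupSpec],
                          config: SimulationConfig | None = None,
                          scenario: Scenario | None = None) -> SimulationResult:
    """Run the engine on a minimal 1-3 level food chain.

    Intended for analytic checking (nutrient-budget plateaus,
    predator-prey lag, B1 transfer bounds) on webs small enough to
    reason about in closed form.
    """
    if not 1 <= len(chain_specs) <= 3:
        raise ValueError("reduced food chain must have 1-3 groups")
    specs = {s.name: s for s in chain_specs}
    scenario = scenario or default_scenario()
    config = config or SimulationConfig()
    forcing = LightForcing(season_start=config.season_start,
                           season_end=config.season_end)
    return _run(_Engine(specs, forcing, config, scenario))
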