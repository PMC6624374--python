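"""Process rates, B1 bookkeeping and the default food-web wiring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from b1web import (EcosystemState, TrophicGroupSpec, allometric_scale,
                   b1_consumer_update, b1_fish_update, b1_source_flux,
                   b1_trophic_transfer, bacterial_growth_rate,
                   baltic_default_specs, grazing_flux, nutrient_limitation,
                   partition_ingestion, producer_growth_rate)
from b1web.foodweb import GROUPS, MAX_B1_QUOTA, REDFIELD_N_PER_C


@pytest.fixture(scope="module")
def specs():
    return baltic_default_specs()


# --- static table -----------------------------------------------------------

def test_default_quota_maxima_match_empirical_values(specs):
    expected = {
        "bacteria": 1.48e-7, "picoalgae": 1.48e-7, "nanoalgae": 1.18e-7,
        "microalgae": 1.18e-7, "nanoflagellates": 1.32e-7,
        "ciliates": 1.27e-7, "mesozooplankton": 1.28e-7, "fish": 1.04e-10,
    }
    for name, q in expected.items():
        assert specs[name].q_max == q


def test_foodweb_wiring_is_the_size_ladder(specs):
    assert set(specs["nanoflagellates"].prey) == {"bacteria", "picoalgae"}
    assert set(specs["ciliates"].prey) == {"nanoflagellates", "nanoalgae"}
    assert set(specs["mesozooplankton"].prey) == {"ciliates", "microalgae"}
    assert set(specs["fish"].prey) == {"mesozooplankton"}
    assert tuple(specs) == GROUPS


def test_spec_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        TrophicGroupSpec(name="x", role="producer", cell_or_body_volume=1.0,
                         q_max=0.0)
    with pytest.raises(ValueError):
        TrophicGroupSpec(name="x", role="consumer", cell_or_body_volume=1.0,
                         q_max=1e-7, gge=0.3, prey=())
    with pytest.raises(ValueError):
        TrophicGroupSpec(name="x", role="fish", cell_or_body_volume=1.0,
                         q_max=1e-10, gge=0.3, prey=("y",),
                         basal_respiration=0.1)


# --- limitation and growth --------------------------------------------------

@pytest.mark.parametrize("conc, K, expected", [
    (0.0, 1.0, 0.0),
    (2.5, 2.5, 0.5),
    (7.5, 2.5, 0.75),
])
def test_monod_limitation(conc, K, expected):
    assert nutrient_limitation(conc, K) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("volume, ref, exp, expected", [
    (123.0, 123.0, -0.25, 1.0),
    (16.0, 1.0, -0.25, 0.5),
    (7.7, 1.0, 0.0, 1.0),
])
def test_allometric_scale(volume, ref, exp, expected):
    assert allometric_scale(volume, ref, exp) == pytest.approx(expected, rel=1e-12)


def test_producer_growth_liebig_and_light():
    spec = TrophicGroupSpec(name="p", role="producer", cell_or_body_volume=1.0,
                            q_max=1e-7, mu_max=1.0, K_N=1.0, K_P=1.0, K_I=1.0)
    assert producer_growth_rate(spec, 0.0, 100.0, 100.0) == 0.0
    assert producer_growth_rate(spec, 1e6, 0.0, 100.0) == 0.0
    # f_N = 0.8, f_P = 0.5, f_I = 0.5 -> min rule gives 0.25 / d
    assert producer_growth_rate(spec, 1.0, 4.0, 1.0) == pytest.approx(0.25, rel=1e-12)


def test_producer_growth_rejects_non_producer(specs):
    with pytest.raises(ValueError):
        producer_growth_rate(specs["fish"], 1.0, 1.0, 1.0)


def test_bacterial_growth_min_rule():
    spec = TrophicGroupSpec(name="b", role="heterotrophic_bacteria",
                            cell_or_body_volume=0.1, q_max=1e-7, mu_max=2.0,
                            K_N=1.0, K_P=1.0, K_DOC=1.0, gge=0.3)
    assert bacterial_growth_rate(spec, 0.0, 10.0, 10.0) == 0.0
    assert bacterial_growth_rate(spec, 1e9, 1e9, 1e9) == pytest.approx(2.0, rel=1e-6)
    # f_DOC = 0.6, f_N = 0.9, f_P = 0.8 -> 2 * 0.6 = 1.2 / d
    assert bacterial_growth_rate(spec, 1.5, 9.0, 4.0) == pytest.approx(1.2, rel=1e-12)
    with pytest.raises(ValueError):
        bacterial_growth_rate(baltic_default_specs()["picoalgae"], 1, 1, 1)


# --- grazing ----------------------------------------------------------------

def test_grazing_zero_prey(specs):
    flux = grazing_flux(specs["fish"], 100.0, {"mesozooplankton": 0.0})
    assert flux == {"mesozooplankton": 0.0}


def test_grazing_linear_regime_matches_clearance_law(specs):
    """Far below satiation the flux is clearance * prey * predator."""
    pred = specs["mesozooplankton"]
    prey = {"ciliates": 3.0, "microalgae": 5.0}
    flux = grazing_flux(pred, 7.0, prey)
    for name, B in prey.items():
        assert flux[name] == pytest.approx(pred.clearance * B * 7.0, rel=1e-12)


def test_grazing_saturates_at_I_max(specs):
    pred = specs["nanoflagellates"]
    flux = grazing_flux(pred, 2.0, {"bacteria": 1e9, "picoalgae": 1e9})
    assert sum(flux.values()) == pytest.approx(pred.I_max * 2.0, rel=1e-12)


def test_grazing_cap_shares_proportionally(specs):
    pred = specs["ciliates"]
    flux = grazing_flux(pred, 1.0, {"nanoflagellates": 3e8, "nanoalgae": 1e8})
    assert flux["nanoflagellates"] == pytest.approx(3 * flux["nanoalgae"], rel=1e-12)


def test_grazing_rejects_empty_prey_list():
    with pytest.raises(ValueError):
        TrophicGroupSpec(name="x", role="consumer", cell_or_body_volume=1.0,
                         q_max=1e-7, gge=0.3, prey=())


# --- ingestion partitioning -------------------------------------------------

def test_partition_zero_ingestion(specs):
    part = partition_ingestion(specs["mesozooplankton"], 0.0)
    assert all(v == 0.0 for v in part)


def test_partition_split_arithmetic(specs):
    # gge = 0.3, DOC fraction of losses = 0.2 -> 100 = 30 + 14 + 56
    part = partition_ingestion(specs["mesozooplankton"], 100.0)
    assert part.growth_C == pytest.approx(30.0)
    assert part.excreted_DOC == pytest.approx(14.0)
    assert part.respired_C == pytest.approx(56.0)


def test_partition_conserves_nitrogen(specs):
    part = partition_ingestion(specs["ciliates"], 37.5)
    ingested_N = 37.5 * REDFIELD_N_PER_C * 1e-3
    growth_N = part.growth_C * REDFIELD_N_PER_C * 1e-3
    assert ingested_N == pytest.approx(growth_N + part.excreted_DIN, rel=1e-12)


def test_partition_fish_growth_is_remineralized(specs):
    part = partition_ingestion(specs["fish"], 100.0)
    assert part.growth_C == 0.0
    assert part.respired_C + part.excreted_DOC == pytest.approx(100.0)
    assert part.excreted_DIN == pytest.approx(100.0 * REDFIELD_N_PER_C * 1e-3)


# --- vitamin B1 fluxes ------------------------------------------------------

def test_b1_source_saturated_quota_gives_zero(specs):
    spec = specs["picoalgae"]
    assert b1_source_flux(spec, 100.0, spec.q_max, 1.0) == 0.0


def test_b1_source_full_deficit():
    spec = TrophicGroupSpec(name="p", role="producer", cell_or_body_volume=1.0,
                            q_max=1e-7, metabolic_rate=1.0)
    assert b1_source_flux(spec, 1.0, 0.0, 1.0) == pytest.approx(1e-7)


def test_b1_source_linear_in_multiplier(specs):
    spec = specs["picoalgae"]
    base = b1_source_flux(spec, 10.0, 0.5 * spec.q_max, 1.0)
    for mult in (0.1, 10.0):
        assert b1_source_flux(spec, 10.0, 0.5 * spec.q_max, mult) == \
            pytest.approx(mult * base, rel=1e-12)


def test_b1_source_rejects_consumers(specs):
    with pytest.raises(ValueError):
        b1_source_flux(specs["fish"], 1.0, 0.0, 1.0)


def test_b1_transfer_arithmetic():
    absorbed, degraded = b1_trophic_transfer(1000.0, 1.28e-7, 0.15)
    assert absorbed == pytest.approx(1.92e-5, rel=1e-12)
    assert degraded == pytest.approx(1.088e-4, rel=1e-12)
    assert absorbed + degraded == pytest.approx(1.28e-7 * 1000.0, rel=1e-12)


@pytest.mark.parametrize("b, expect_absorbed", [(0.0, 0.0), (1.0, 1.28e-4)])
def test_b1_transfer_extremes(b, expect_absorbed):
    absorbed, degraded = b1_trophic_transfer(1000.0, 1.28e-7, b)
    assert absorbed == pytest.approx(expect_absorbed, abs=1e-18)
    assert absorbed + degraded == pytest.approx(1.28e-4, rel=1e-12)


def test_b1_transfer_rejects_bad_bioavailability():
    with pytest.raises(ValueError):
        b1_trophic_transfer(1.0, 1e-7, 1.5)


def test_b1_consumer_update_decay_and_cap(specs):
    spec = TrophicGroupSpec(name="z", role="consumer", cell_or_body_volume=1.0,
                            q_max=1e-6, prey=("y",), gge=0.3,
                            metabolic_rate=0.1)
    # no turnover, no intake -> unchanged
    frozen = TrophicGroupSpec(name="z0", role="consumer", cell_or_body_volume=1.0,
                              q_max=1e6, prey=("y",), gge=0.3, metabolic_rate=0.0)
    pool, over = b1_consumer_update(frozen, 1.0, 0.0, 10.0, dt=1.0)
    assert pool == 10.0 and over == 0.0
    # first-order decay: 10 * (1 - 0.1) = 9
    pool, over = b1_consumer_update(spec, 1e12, 0.0, 10.0, dt=1.0)
    assert pool == pytest.approx(9.0) and over == 0.0
    # absorbing far beyond the cap leaves quota exactly at q_max
    pool, over = b1_consumer_update(spec, 2.0, 1e-3, 0.0, dt=1.0)
    assert pool == pytest.approx(spec.q_max * 2.0)
    assert over == pytest.approx(1e-3 - spec.q_max * 2.0)


@given(st.lists(st.tuples(st.floats(0.0, 1e-9), st.floats(0.01, 0.5)),
                min_size=1, max_size=50))
def test_quota_stays_bounded_under_random_flux_sequences(seq):
    """Consumer quota remains in [0, q_max] for any intake sequence."""
    spec = baltic_default_specs()["mesozooplankton"]
    biomass = 5.0
    pool = 0.5 * spec.q_max * biomass
    for absorbed, dt in seq:
        pool, _ = b1_consumer_update(spec, biomass, absorbed, pool, dt=dt)
        assert 0.0 <= pool <= spec.q_max * biomass * (1 + 1e-12)


def _steady_fish_quota(specs, abundance, absorbed_per_day, n_days=3000):
    state = EcosystemState(
        groups=("fish",), biomass_C=[abundance * specs["fish"].cell_or_body_volume],
        b1_pool=[0.0], NO3=1.0, NH4=1.0, PO4=1.0, DOC=1.0,
        fish_abundance=abundance)
    quota = 0.0
    for _ in range(n_days):
        pool, quota = b1_fish_update(specs["fish"], state, absorbed_per_day, 1.0)
        state.b1_pool[0] = pool
    return quota


def test_fish_quota_dilutes_with_abundance(specs):
    """At fixed absorbed flux the steady-state quota scales as 1/abundance."""
    flux = 1e-9  # umol B1 m^-3 d^-1, small enough to stay below the cap
    q1 = _steady_fish_quota(specs, 0.004, flux)
    q2 = _steady_fish_quota(specs, 0.008, flux)
    assert q1 == pytest.approx(2.0 * q2, rel=1e-6)


def test_fish_quota_never_exceeds_cap(specs):
    q = _steady_fish_quota(specs, 0.004, 1e-3, n_days=500)
    assert q <= 1.04e-10 * (1 + 1e-12)


def test_fish_update_requires_positive_abundance(specs):
    state = EcosystemState(groups=("fish",), biomass_C=[1.0], b1_pool=[0.0],
                           NO3=0, NH4=0, PO4=0, DOC=0, fish_abundance=0.0)
    with pytest.raises(ValueError):
        b1_fish_update(specs["fish"], state, 0.0, 1.0)


# --- state invariants -------------------------------------------------------

def test_state_totals_and_validation():
    state = EcosystemState(
        groups=("a", "b"), biomass_C=[106.0, 106.0], b1_pool=[0.0, 0.0],
        NO3=1.0, NH4=0.5, PO4=0.25, DOC=2.0, fish_abundance=0.005)
    # 212 umol C carries 32 umol N = 0.032 mmol and 2 umol P = 0.002 mmol
    assert state.total_N() == pytest.approx(1.532, rel=1e-12)
    assert state.total_P() == pytest.approx(0.252, rel=1e-12)
    with pytest.raises(ValueError):
        EcosystemState(groups=("a",), biomass_C=[-1.0], b1_pool=[0.0],
                       NO3=0, NH4=0, PO4=0, DOC=0, fish_abundance=0.005)
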