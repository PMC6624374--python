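"""Scenario classification, summary statistics and the trophic decay chain.

A scenario is classified by the fraction of analysis-window days (June
1 to season end) on which the mass-specific vitamin B1 content of
planktivorous fish drops below the mean level recorded in Baltic
clupeids, 6.41e-11 umol B1 per umol C.  Fish are *B1-poor* when that
fraction exceeds 30% of the window, *B1-rich* when more than 70% of
days lie above the threshold, and *intermediate* otherwise.  All
comparisons are strict; boundary equalities fall to the weaker claim
(intermediate).

The decay chain is the analytic backbone of the trophic-transfer
arithmetic: with bioavailability ``b`` per feeding step, a pool of a
compound entering the food chain survives ``b**n`` after ``n``
consumer levels.  From picoalgae the route to fish crosses four levels
(nanoflagellates, ciliates, mesozooplankton, fish); from microalgae,
two (mesozooplankton, fish).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import SimulationResult

__all__ = [
    "ClassificationRule",
    "ScenarioClassification",
    "SummaryStats",
    "DecayChainResult",
    "CONSUMER_LEVELS_TO_FISH",
    "classify",
    "classify_series",
    "summarize",
    "decay_chain",
    "cube_report",
]

#: number of consumer levels a B1 pool crosses from each entry group to fish
CONSUMER_LEVELS_TO_FISH = {
    "bacteria": 4,
    "picoalgae": 4,
    "nanoalgae": 3,
    "microalgae": 2,
}


@dataclass(frozen=True)
class ClassificationRule:
    """Threshold and window fractions for fish B1 status."""

    quota_threshold: float = 6.41e-11   # umol B1 (umol C)^-1
    poor_fraction: float = 0.30
    rich_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.quota_threshold <= 0:
            raise ValueError("quota_threshold must be > 0")
        for name in ("poor_fraction", "rich_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class ScenarioClassification:
    scenario_label: str
    fraction_days_below: float
    label: str                       # b1_poor | b1_rich | intermediate
    window: tuple                    # (analysis_start, season_end)
    n_days: int
    fish_abundance: float = math.nan
    total_N: float = math.nan
    k_bg: float = math.nan


def classify_series(days: np.ndarray, fish_quota: np.ndarray,
                    rule: ClassificationRule,
                    analysis_start: float, season_end: float,
                    *, scenario_label: str = "", fish_abundance: float = math.nan,
                    total_N: float = math.nan, k_bg: float = math.nan
                    ) -> ScenarioClassification:
    """Classify a daily fish-quota series over the analysis window."""
    days = np.asarray(days, dtype=float)
    fish_quota = np.asarray(fish_quota, dtype=float)
    if days.shape != fish_quota.shape:
        raise ValueError("days and fish_quota must have equal length")
    mask = (days >= analysis_start) & (days <= season_end)
    n = int(mask.sum())
    if n == 0 or days[mask].min() > analysis_start or days[mask].max() < season_end - 1:
        raise ValueError(
            f"series does not cover the analysis window "
            f"[{analysis_start}, {season_end}]")
    frac = float((fish_quota[mask] < rule.quota_threshold).mean())
    if frac > rule.poor_fraction:
        label = "b1_poor"   # takes precedence, guarded against odd rules
    elif (1.0 - frac) > rule.rich_fraction:
        label = "b1_rich"
    else:
        label = "intermediate"
    return ScenarioClassification(
        scenario_label=scenario_label, fraction_days_below=frac, label=label,
        window=(analysis_start, season_end), n_days=n,
        fish_abundance=fish_abundance, total_N=total_N, k_bg=k_bg)


def classify(result: SimulationResult,
             rule: ClassificationRule | None = None) -> ScenarioClassification:
    """Classify one simulation by the fish B1 status over its analysis window."""
    rule = rule or ClassificationRule()
    sc = result.scenario
    return classify_series(
        result.days, result.fish_quota, rule,
        result.config.analysis_start, result.config.season_end,
        scenario_label=sc.label, fish_abundance=sc.fish_abundance,
        total_N=sc.total_N, k_bg=sc.k_bg)


@dataclass(frozen=True)
class SummaryStats:
    """Window statistics of one run (analysis window, daily values).

    CVs use the population standard deviation; a zero-mean series
    yields NaN rather than infinity.  ``picoalgae_biomass_fraction`` is
    the window mean of picoalgae carbon over total producer carbon.
    """

    scenario_label: str
    mean_mesozoo_biomass: float
    cv_ciliates: float
    cv_microalgae: float
    cv_picoalgae: float
    cv_mesozoo: float
    picoalgae_biomass_fraction: float
    median_depth_avg_light: float
    median_DIN: float
    median_DIP: float


def _cv(x: np.ndarray) -> float:
    m = float(np.mean(x))
    if m == 0.0:
        return math.nan
    return float(np.std(x)) / m


def summarize(result: SimulationResult) -> SummaryStats:
    """Biotic and abiotic correlates of one run over its analysis window."""
    mask = result.analysis_mask()
    if not mask.any():
        raise ValueError("result does not cover the analysis window")
    pico = result.group_biomass("picoalgae")[mask]
    nano = result.group_biomass("nanoalgae")[mask]
    micro = result.group_biomass("microalgae")[mask]
    cil = result.group_biomass("ciliates")[mask]
    meso = result.group_biomass("mesozooplankton")[mask]
    producers = pico + nano + micro
    return SummaryStats(
        scenario_label=result.scenario.label,
        mean_mesozoo_biomass=float(np.mean(meso)),
        cv_ciliates=_cv(cil),
        cv_microalgae=_cv(micro),
        cv_picoalgae=_cv(pico),
        cv_mesozoo=_cv(meso),
        picoalgae_biomass_fraction=float(np.mean(pico / producers)),
        median_depth_avg_light=float(np.nanmedian(result.light[mask])),
        median_DIN=float(np.median(result.DIN[mask])),
        median_DIP=float(np.median(result.PO4[mask])),
    )


@dataclass(frozen=True)
class DecayChainResult:
    """Analytic survival of a compound pool across ``n`` consumer levels."""

    b: float
    n: int
    surviving_fraction: float
    fold_reduction: float


def decay_chain(b: float, n: int) -> DecayChainResult:
    """Fraction of a compound pool surviving ``n`` feeding transfers.

    With bioavailability ``b`` per transfer, the pool decays as b**n
    (a negative exponential in the number of consumer levels); the
    fold reduction is its reciprocal.  b = 0 with n > 0 leaves the
    fold reduction undefined (NaN).
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"bioavailability must be in [0, 1], got {b}")
    if not (isinstance(n, (int, np.integer)) and n >= 0):
        raise ValueError(f"n must be a nonnegative integer, got {n!r}")
    surviving = b ** n
    fold = math.nan if surviving == 0.0 else 1.0 / surviving
    return DecayChainResult(b=b, n=int(n), surviving_fraction=surviving,
                            fold_reduction=fold)


def cube_report(classifications, summaries):
    """Long-format table of the scenario cube: one row per scenario.

    Keyed by (fish abundance, total N, k_bg) with the classification
    label, the fraction of B1-poor days and all summary columns.  A
    soft diagnostic column ``flag_high_pico_fraction`` marks B1-poor
    rows whose picoalgae biomass fraction exceeds the grid median (the
    pattern expected of the poor regime); it is a report flag, not a
    validity check.  Duplicate scenario labels are rejected.
    """
    import pandas as pd

    classifications = list(classifications)
    summaries = list(summaries)
    if len(classifications) != len(summaries):
        raise ValueError("one summary per classification required")
    labels = [c.scenario_label for c in classifications]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario ids in cube report")
    rows = []
    for c, s in zip(classifications, summaries):
        if s.scenario_label != c.scenario_label:
            raise ValueError(
                f"classification/summary mismatch: {c.scenario_label!r} "
                f"vs {s.scenario_label!r}")
        rows.append({
            "scenario": c.scenario_label,
            "fish_abundance": c.fish_abundance,
            "total_N": c.total_N,
            "k_bg": c.k_bg,
            "label": c.label,
            "fraction_days_below": c.fraction_days_below,
            "mean_mesozoo_biomass": s.mean_mesozoo_biomass,
            "cv_ciliates": s.cv_ciliates,
            "cv_microalgae": s.cv_microalgae,
            "cv_picoalgae": s.cv_picoalgae,
            "cv_mesozoo": s.cv_mesozoo,
            "picoalgae_biomass_fraction": s.picoalgae_biomass_fraction,
            "median_depth_avg_light": s.median_depth_avg_light,
            "median_DIN": s.median_DIN,
            "median_DIP": s.median_DIP,
        })
    df = pd.DataFrame(rows)
    if len(df):
        med = df["picoalgae_biomass_fraction"].median()
        df["flag_high_pico_fraction"] = (
            (df["label"] == "b1_poor")
            & (df["picoalgae_biomass_fraction"] > med))
    else:
        df = pd.DataFrame(columns=list(df.columns) + ["flag_high_pico_fraction"])
    return df
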