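# Methods

## Scope and state variables

`b1web` integrates an enclosed, instantly mixed 10 m water column over
one vegetative season (30 March – 1 October, continuous days since
1 January, day 89–274). The state comprises, per trophic group, a
carbon biomass pool [µmol C m⁻³] and a vitamin B1 pool [µmol B1 m⁻³],
plus dissolved NO₃, NH₄, PO₄ [mmol m⁻³] and DOC [mmol C m⁻³]. Eight
groups form a strict size ladder — bacteria, picoalgae, nanoalgae,
microalgae, nanoflagellates, ciliates, mesozooplankton, planktivorous
fish — with each consumer feeding on the group(s) one size level
below: nanoflagellates ← {bacteria, picoalgae}, ciliates ←
{nanoflagellates, nanoalgae}, mesozooplankton ← {ciliates,
microalgae}, fish ← {mesozooplankton}.

Biomass stoichiometry is fixed at Redfield C:N:P = 106:16:1. That
choice (no internal nutrient quotas) makes nitrogen and phosphorus
conservation exact by construction, which the integrator verifies: a
full-season run closes the N, P, C and B1 budgets to ≲10⁻¹⁴ relative.

The fish population has balanced birth and death: its carbon biomass
is `abundance × individual mass` (1.5×10⁵ µmol C ≈ 1.8 g C, a ~15 cm
clupeid) and never changes. Fish somatic growth carbon is
remineralized immediately; the vitamin content of ingested prey is
retained, which makes the fish a pure B1 integrator and produces the
dilution effect: at a fixed bioavailable B1 flux, the steady-state
quota `flux / (turnover × biomass)` is inversely proportional to
abundance.

## Light

Surface irradiance is a solar-elevation model: declination
δ = −23.44° cos(2π(d+10)/365), hour angle from local solar time,
irradiance ∝ max(sin(elevation), 0), normalized so summer-solstice
noon equals 1 at the default site (56.93°N). Only the *shape* matters:
irradiance enters growth through a saturating factor, so it is kept in
relative units.

Attenuation is `k = k_s·W_PP + k_bg` with `W_PP` the summed producer
carbon in mg C m⁻³, `k_s = 5×10⁻⁵ m² (mg C)⁻¹` (a dense
2000 mg C m⁻³ bloom adds ≈ 0.1 m⁻¹, comparable to the background
range) and `k_bg` the scenario's background attenuation. Producers see
the Lambert–Beer vertical average `I₀(1−e^{−kH})/(kH)` of the layer —
consistent with instantaneous mixing, cheap, and analytically
checkable against quadrature (the tests require 10⁻⁸ relative
agreement).

## Process rates

**Producers**: µ = µ_max(V) · min(f_N, f_P) · f_I with Monod factors
f_X = X/(X+K_X) and Liebig's minimum across N and P. Allometry in cell
volume V (µm³) relative to a 1 µm³ reference: µ_max ∝ V^(−0.10),
K_N ∝ V^(+0.20) (small cells are better competitors at low nutrients),
K_I ∝ V^(+1/3) (large cells absorb less light per unit volume, so high
background attenuation penalizes microalgae most). A steeper, purely
metabolic µ_max exponent (−0.25) was tried first and rejected: across
four orders of magnitude in volume it makes microalgae categorically
nonviable against grazing, whereas observed phytoplankton growth
allometry over this range is nearly flat to unimodal. 10% of gross
production is exuded as DOC. NH₄ is drawn before NO₃; excretion
returns N as NH₄.

**Bacteria**: µ = µ_max · min(f_DOC, f_N, f_P); DOC supplies carbon at
growth efficiency 0.3 (the remainder respired), N and P are taken
inorganically at Redfield proportions.

**Consumers**: clearance-rate feeding. Per prey, the encounter rate is
`clearance × prey biomass` [d⁻¹ per unit predator C]; if the summed
encounter rate exceeds `I_max` all fluxes scale back proportionally —
a type-II response whose plateau is shared across prey in proportion
to clearance × biomass. Ingestion splits into growth (gge = 0.3), DOC
excretion (20% of the losses) and respiration; all N and P of
non-grown ingesta return to NH₄ and PO₄.

**Maintenance respiration.** Producers, bacteria and zooplankton
additionally respire biomass at a basal rate (N and P remineralized).
Biomass is therefore the balance of growth, respiration and predation
— there is still no other nonconsumptive mortality. The term is
load-bearing: without it, a group whose predator has collapsed is
immortal and ratchets every regenerated nutrient atom into its own
biomass over the season. In practice that artifact made ungrazed
microalgae dominate exactly the scenarios that should be
picoalgae-skewed.

**Vitamin B1.** Producers and bacteria relax their quota toward the
group maximum at `metabolic_rate × multiplier`:
`flux = rate · (q_max − quota) · biomass` (the multiplier is the
sensitivity hook for faster/slower net B1 acquisition — covering, for
example, communities dominated by auxotrophs that take the vitamin up
from water rather than synthesizing it). Feeding moves
`prey_quota × ingested_C` of B1 out of the prey pool; the consumer
absorbs the bioavailable fraction `b` (default 0.15, studied range
5–20%) and the rest is degraded. Consumer pools turn over at the
metabolic rate, and every quota is capped at its empirical maximum
(overflow counted as degraded). The B1 ledger —
sources = Δstocks + transfer losses + turnover + cap overflow — closes
to machine precision.

Explicit dissolved-B1 pools, auxotrophy dynamics, thiaminase
enzymology, mixotrophy and temperature dependence are out of scope.

## Integration

Explicit Euler at dt = 0.02 d (50 steps per day; sub-daily steps are
required by the diel light cycle). All fluxes are evaluated from the
state at the start of the step; proportional flux limiting scales the
outgoing fluxes of any pool that would be exhausted within the step,
which preserves positivity and exact conservation simultaneously.
Biomass may not be grazed or respired below an extinction floor of
10⁻⁶ µmol C m⁻³, so populations can crash deeply but never to zero.
Pools are recorded as midnight instantaneous values; light and k as
daily means (removing diel aliasing from the CV statistics). Runs are
deterministic: the package contains no random number draws.

Initial conditions, shared by all scenarios: every group seeded at
10 µmol C m⁻³ (fish biomass from abundance), DOC 5 mmol m⁻³, quotas at
1% of their maxima (picomolar scale). Smaller seeds (≲1 µmol C m⁻³)
were rejected because they starve mesozooplankton to the floor during
April regardless of scenario — a spin-up artifact that erases the very
contrasts the scenario cube is meant to expose. April–May remain
excluded from all statistics (analysis window 1 June – 1 October).

## Classification and summaries

A scenario is *B1-poor* when the fish quota is below
6.41×10⁻¹¹ µmol B1 (µmol C)⁻¹ (the mean level recorded in Baltic
clupeids; comparisons strict) on more than 30% of analysis-window
days, *B1-rich* when more than 70% of days sit above the threshold,
*intermediate* otherwise — boundary equalities fall to the weaker
claim. Summary statistics over the window: mean mesozooplankton
biomass; CVs (population SD / mean; NaN for a zero-mean series) of
ciliate, microalgae, picoalgae and mesozooplankton biomass; the mean
daily picoalgae share of producer carbon; medians of depth-averaged
light, DIN and DIP.

The analytic decay chain `b^n` uses n = 4 consumer levels from
picoalgae or bacteria to fish (nanoflagellates, ciliates,
mesozooplankton, fish), n = 3 from nanoalgae, n = 2 from microalgae.
The printed attenuation factors (≈6.7-fold per level, ≈2000-fold and
0.5‰ from picoalgae, ≈2% from microalgae, 10⁴-fold at b = 0.10) all
require n = 4 for the picoalgae route; a verbal count of "three
consumer levels" circulates for that route but is inconsistent with
those numbers, so four is used throughout.

## Parameter defaults and calibration

Quota maxima [µmol B1 (µmol C)⁻¹] are empirical: bacteria and
picoalgae 1.48×10⁻⁷, nanoalgae and microalgae 1.18×10⁻⁷,
nanoflagellates 1.32×10⁻⁷, ciliates 1.27×10⁻⁷, mesozooplankton
1.28×10⁻⁷, fish 1.04×10⁻¹⁰.

The rate constants are the package's own parameterization, chosen once
within literature ranges so that the default food web reproduces the
qualitative regime structure the model is meant to express, and all
overridable through the run configuration:

| group | µ_max or I_max [d⁻¹] | K_N [mmol m⁻³] | K_I [rel] | clearance [m³ (µmol C)⁻¹ d⁻¹] | metabolic [d⁻¹] | basal [d⁻¹] |
|---|---|---|---|---|---|---|
| bacteria | 2.0 | 0.20 (K_DOC 10) | — | — | 2.0 | 0.10 |
| picoalgae | 1.30 | 0.30 | 0.020 | — | 1.30 | 0.03 |
| nanoalgae | 0.82 | 0.75 | 0.093 | — | 0.82 | 0.03 |
| microalgae | 0.52 | 1.89 | 0.431 | — | 0.52 | 0.03 |
| nanoflagellates | 3.5 | — | — | 5×10⁻⁴ | 0.30 | 0.30 |
| ciliates | 2.5 | — | — | 3×10⁻⁴ | 0.20 | 0.20 |
| mesozooplankton | 1.0 | — | — | 3×10⁻⁴ | 0.10 | 0.08 |
| fish | 0.03 | — | — | 1×10⁻⁴ | 0.03 | 0 |

gge = 0.3 for all heterotrophs. The B1 turnover of each group equals
its metabolic rate (one fewer free parameter, consistent with constant
specific turnover); producer "metabolic" rates are set to µ_max so the
B1 source keeps pace with growth dilution. Fish clearance ×
high-abundance biomass gives a mesozooplankton mortality of
0.06–0.15 d⁻¹, bracketing the mesozooplankton's maximal net growth
(0.22 d⁻¹) so the fish axis genuinely tips its persistence.

What the calibrated defaults verifiably produce (asserted by the
acceptance tests on a 3×5×5 cube): B1-poor scenarios in the
{high fish, high nutrients, intermediate attenuation} corner and under
the strongest background attenuation at low-to-mid nutrients; a
B1-rich outcome at {low fish, mid nutrients, clear water}; B1-poor
scenarios averaging a higher picoalgae biomass fraction and a lower
mean mesozooplankton biomass than B1-rich ones; and classification of
both reference scenarios invariant to the B1 source-rate multiplier in
{0.1, 10}. In the poor regime at high nutrient input, this
implementation holds median DIN well above zero (the regime is
grazing-controlled rather than drawdown-controlled), so low dissolved
nutrients should not be read as a signature of the poor state here.

## What the scenario machinery emulates — and what it does not

Scenarios are synthetic by design: the cube endpoints (fish
0.004–0.01 ind m⁻³; NO₃/NH₄ from 2.01/0.93 to 30/7 µmol l⁻¹ with
Redfield phosphate; k_bg 0.04–0.24 m⁻¹) span conditions reported for
the southern Baltic proper, with intermediate levels interpolated
linearly. The `fixture_quota_series` generator produces step-shaped
daily quota series with an exact below-threshold day count — useful
for testing the classifier, with no pretense of resembling simulated
dynamics. Passing tests therefore demonstrate internal consistency and
the stated regime structure under these idealized conditions; they do
not validate the model against field time series, seasonal
stratification, temperature effects, species succession within size
classes, or inedible filamentous cyanobacteria, none of which are
represented.

## Numerical behaviour and known limitations

* **Phase sensitivity.** The calibrated web is a relaxation
  oscillator: populations boom and crash over several orders of
  magnitude, as the fluctuating regimes require. Instantaneous
  end-of-season biomasses are therefore phase-sensitive: halving dt
  shifts cycle timing slightly, and a group near a trough can differ
  by large factors between dt = 0.02 and dt = 0.01 even though the
  attractor is unchanged. Robust outputs are the conserved totals
  (exact at any dt) and the window statistics; the classification
  labels and below-threshold fractions of the default and both
  reference scenarios are unchanged under dt halving. Instantaneous
  per-group state at a fixed date should not be treated as
  dt-converged.
* **Euler with flux limiting** trades accuracy for exact positivity
  and conservation; rates up to ~5 d⁻¹ at dt = 0.02 give per-step
  relative errors of order 10⁻³, acceptable for seasonal statistics
  but visible in cycle phase (above).
* The producer allometry, protozoan rates and the DOC split live in
  ranges, not point estimates; conclusions that depend on exact
  boundary positions in the scenario cube should be checked against
  parameter overrides.
* One bacteria group at most; the engine supports arbitrary subsets of
  the ladder (used by the reduced-foodchain test harness).
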