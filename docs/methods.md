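# Methods

## Model structure and assumptions

The community is deliberately minimal: three phytoplankton guilds
(dinoflagellate hosts, diatoms, nanophytoplankton) compete for a single
nutrient (nitrate), one parasite with an explicit free-living stage
infects the hosts, and two micrograzer guilds partition the prey spectrum
— microciliates eat dinoflagellates (healthy and infected) and diatoms,
rotifers eat nanophytoplankton and dinospores. Mesozooplankton are
excluded (their generation times are too long to respond within a 30-day
bloom window), there is no nutrient recycling, no mixotrophy or
allelopathy, and no spatial structure. Infected hosts neither divide nor
take up nitrogen; infection is fatal and lasts `h` days on average, after
which `epsilon` dinospores are released per host.

Key functional forms:

* **Nutrient limitation** — Michaelis–Menten–Monod, `f_x = N/(K_x+N)`,
  per guild `x ∈ {h, d, a}`.
* **Infection** — Holling type-II attack per dinospore,
  `phi(H) = aH/(1+ahH)`, saturating at `1/h` when hosts are abundant;
  dinospores are consumed by attachment (term `-phi P` in the dinospore
  equation).
* **Grazing** — saturating functional responses for ingestion; numerical
  responses with prey thresholds (`x_c`, `x_r`) below which grazer
  populations decline. Grazing pressure on a prey pool is partitioned in
  proportion to that prey's share of the total (`H/(H+I+D)` etc.), with
  the quotient defined as 0 at zero total prey.
* **Temperature** — all rates are taken as valid at 20 °C; the only
  runtime temperature dependence is the rotifer-ingestion multiplier
  `0.94/(1+219000·T^−4.35)·24` (hourly → daily conversion included),
  ≈ 15.25 at 20 °C.

## Parameters

All defaults ship in `ParameterSet` / `table1_defaults()`; they are
literature-derived constants for a *Prorocentrum triestinum* /
*Amoebophrya* system with grazer parameters from cultured ciliates and
brachionid rotifers. The ones that matter most in practice:

| symbol | meaning | default | unit |
|---|---|---|---|
| `r_h, r_d, r_a` | maximal growth rates | 0.7, 1.5, 0.7 | d⁻¹ |
| `K_h, K_d, K_a` | N half-saturations | 2.3, 1.2, 0.5 | μM |
| `Q_h, Q_d, Q_a` | N cell quotas | 7.12e-7, 6.12e-7, 4.33e-9 | μM cell⁻¹ |
| `epsilon` | dinospores per killed host | 150 | — |
| `m` | dinospore mortality | 0.26 | d⁻¹ |
| `a` | dinospore search rate | 1.34e-8 | L cell⁻¹ d⁻¹ |
| `h` | handling/maturation time | 2.46 | d |
| `x_c, x_r` | grazer prey thresholds | 7.24e5, 2.52e6 | prey L⁻¹ |

`h` deserves a note: the source table prints its unit as d⁻¹, but the
Holling denominator `1+ahH` and the maturation fluxes `I/h`, `ε·I/h` are
dimensionally consistent only if `h` is a time, and the stated biology
(intracellular maturation of 2–3 days) matches `h = 2.46 d`. It is
implemented as a time.

Two further printing defects in the source equations are corrected by
default and kept available as switches (`ModelOptions`):

* the nitrate equation as printed multiplies diatom and nanophytoplankton
  uptake by the *dinoflagellate* abundance; the default uses each guild's
  own abundance (`strict_nitrate_uptake=True` restores the printed form);
* the rotifer equation as printed reads `dR/dt = r_r·C`; the default uses
  `r_r·R` (`strict_rotifer_growth=True` restores the printed form).

## Numerical choices

* **Integration** — LSODA (stiffness-switching) with `rtol = 1e-8` and
  per-variable `atol = rtol·max(|y0|, 1)`; state variables span eight
  orders of magnitude, so uniform absolute tolerances would either choke
  the stepper or lose the small pools. The right-hand side evaluates all
  responses on `max(y, 0)` and outputs are clamped non-negative, so the
  tiny negative excursions adaptive steppers produce cannot flip signs in
  partition quotients. The test suite verifies agreement with an
  independently coded fixed-step RK4 integrator at `dt = 1e-3 d` to
  better than 1e-3 (relative to each state's maximum) on the scenario
  fixtures.
* **Output grid** — 0.1 d over 30 d; peak-day identification is not
  grid-limited at daily resolution, and halving the step changes neither
  peak days nor integrated loss shares (< 0.5 pp).
* **Peak times** — earliest attainment of a series' maximum, with values
  within 1e-8 (relative) of the maximum treated as ties. On saturating
  prevalence curves the bitwise argmax wanders along a plateau that is
  flat to 1e-14; resolving ties at the accuracy the integrator actually
  delivers makes the reported peak day well-conditioned.
* **Flux attribution** — every equation's right-hand side is assembled
  from named signed terms, and the public RHS sums exactly those terms,
  so the decomposition is exact by construction (asserted bitwise in
  tests). Loss terms are re-evaluated along the stored trajectory and
  integrated by the trapezoid rule; the demise window runs from a
  variable's earliest peak to the end of the run. The dinospore
  "mortality" denominator includes all three loss terms (attachment,
  background mortality, rotifer grazing) by default; a restricted
  denominator is available via the `terms` argument.
* **Sensitivity analysis** — Saltelli cross-sampling (scrambled Sobol'
  sequence base points, `n(k+2)` runs) with the Saltelli-2010/Jansen
  estimators for S1/ST and a seeded 200-rep bootstrap for confidence
  half-widths, all implemented in `sensitivity.py` and validated against
  the analytic Ishigami and linear-additive benchmarks as well as
  SciPy's independent estimator. Ranges default to ±50% around nominal
  for all 23 biological constants; base-row pairs violating the domain
  constraints `K_rc > x_c`, `K_rr > x_r` (possible only for the rotifer
  pair at ±50%) are redrawn. The analysed scalar is the time-averaged
  abundance of H, I and P over the 30-d full-community run (robust to
  peak-timing shifts); final and maximal values are available via
  `statistic=`. Default `n_base = 512`; the packaged experiment drivers
  use 128 (≈ 3,200 model runs per condition, under a minute).

## What the experiment generators emulate

`scenarios.py` encodes the study designs themselves — community subsets
at two nitrate levels, a 6×8×2 nitrate × competitor factorial, removal
designs, and host-free rotifer-grazing assays (nanophytoplankton frozen
to suppress prey growth, dinospore release absent because hosts are
absent, background dinospore mortality retained). These are idealized
closed batch systems: no immigration, mixing, light limitation, or
observation error. Passing tests therefore demonstrate internal
consistency of the model and analyses, not fidelity to any field system.

The stated dinospore:host wording for the grid experiments ("2:1") is
inconsistent with its own parenthetical number (125,000 dinospores/L
against 250,000 hosts/L); the explicit number is used.

## Agreement with the published values, and its limits

A pre-implementation variant study (every textually defensible reading of
the defective equations, the `h` unit, and fixed-versus-dynamic nitrate)
found that **no single model variant reproduces all six published anchor
numbers**; different subsets emerge under different readings, which
suggests the original Matlab runs were not all performed with one
consistent equation set. Under this package's default (corrected)
equations:

* scenario-1 prevalence peaks on day 10 (reported: 9) under eutrophic
  forcing, but day 25 (reported: 17) under oligotrophic forcing;
* the full-community maximal prevalence is ≈ 6% oligotrophic (reported
  ≈ 10%) but ≈ 54% eutrophic (reported ≈ 99%);
* rotifers account for ≈ 27% of demise-phase dinospore losses with
  sparse competitors (reported 28%) but ≈ 11% with dense competitors
  (reported ≈ 84%).

The high-competitor discrepancies trace to nitrate dynamics: with the
corrected uptake equation, 36 μM nitrate is exhausted within days, the
nanophytoplankton crash, and the rotifer bloom collapses before the
dinospore demise. Freezing nitrate (the `frozen={"N"}` hook) or using the
printed uptake equation keeps the competitor pool growing and recovers
the published 84%/99%-type values — evidence that the original runs
effectively lacked self-limiting nutrient drawdown for those experiments.
The defaults were **not** switched to chase those numbers; the
discrepancies are reported as-is and the switches make every alternative
reproducible.

Sensitivity rankings share this caveat: under the default model the
diatom half-saturation `K_d` and diatom growth rate `r_d` vie for the top
rank for hosts under oligotrophic forcing (their separation is within
Monte-Carlo noise at `n_base = 128`), while several other published
rankings (e.g. `epsilon` first for infected hosts) appear at second
rather than first rank. The original analysis's parameter ranges and
output scalar were not published; ±50% uniform ranges and time-averaged
outputs are this package's documented choice.

## Known limitations

* Explicit (non-stiff) fixed-step integration of the full community is
  only used as a test oracle; production runs need the stiff-capable
  solver once grazer populations explode.
* Exponential grazer growth is unchecked by anything except prey
  depletion; 30-day horizons keep this within floating-point range, much
  longer horizons may not be meaningful.
* The removal-effect intensity is undefined when removing a member
  eliminates the affected variable itself (e.g. hosts removed, host
  maximum); the experiment drivers report these cells as null.
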