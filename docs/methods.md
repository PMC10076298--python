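# Methods

This note documents the model implemented by `landsys`, the choices made
where the design was genuinely open, what the synthetic data emulate, and
the package's known limitations.

## Allocation model

The simulator balances aggregated demands for land-system *services*
against spatially explicit supply. A land system *j* supplies `S[j,d]` units
of service *d* per unit area (here: km² of cover type *d* per km², so rows
of the capability matrix over area services sum to 1). Supply of *d* is
`Σ_c S[T(c),d] · cell_area` over non-nodata cells.

Within a time step, iterations proceed synchronously: every cell is
re-decided from the frozen previous-iteration state, so visiting order is
irrelevant. A cell adopts the type with the largest transition potential
(suitability + incumbent resistance + competitive advantage) unless it is
in the restricted mask, has not yet dwelt its type's minimum number of time
steps, or the conversion from its previous-iteration type to the argmax
type is disallowed — in the last case it keeps its previous-iteration type
rather than falling back to the best allowed alternative. The allowance
matrix argument is the *previous-iteration* type: using the current
iteration's result would be acausal. Argmax ties break to the lowest type
id, which makes runs reproducible.

The competitive advantage uses only the *sign* of conversion-order
differences, weighted by the accumulated gap variable `diff`. `diff` starts
at 0, and each iteration subtracts the relative gap divided by
`Speed_i · R_i`; `Speed` starts at 0.05 and grows by 0.0002 per iteration,
and `R_i` is one fresh uniform integer in [322, 365] per iteration, shared
by all services. Services with zero demand keep `diff = 0` and are excluded
from convergence (division guard). Convergence requires the mean *absolute*
relative gap below 0.5 % and every service's absolute gap below 1 %;
absolute values are used deliberately, since a signed mean would let
oversupplied runs converge spuriously. The iteration cap is 20 000; hitting
it returns a flagged result, never an exception.

Two structural failure modes are detected and reported rather than patched:

* **Stagnation.** If all systems share the same conversion order for every
  service (e.g. a one-class classification), the competitive advantage is
  identically zero and no amount of iterating can move supply; the step
  returns immediately with a `stagnated` flag. The class-number sweep
  records such runs as missing.
* **Freezing at the cap.** With few classes, many systems tie, whole strata
  become immobile (within a tied group only resistance and suitability
  matter, and resistance favours incumbents), and the remaining gap can
  stay just outside tolerance while `diff` grows without changing any
  argmax. The run then reports `converged=False` with the trace showing
  where supply stopped moving.

## Conversion orders by adaptive natural breaks

A capability column is classified into contiguous classes of its sorted
values. The general algorithm enumerates every placement of K−1 breaks
between unequal neighbours and keeps the partition maximising
`GVF = 1 − SDCM/SDAM` (equivalently minimising the within-class sum of
squares); enumerations beyond 500 000 candidates are solved by an
equivalent dynamic program with identical tie rules. The adaptive variant
raises K from 2 until the best GVF strictly exceeds the threshold
(default 0.8); values in the κ-th class (classes ordered by mean) get order
κ−1. Termination is guaranteed: at K = number of distinct values the GVF
is exactly 1.

Open points the source material leaves unstated, decided here:

* Breaks are never placed between equal values, so tied capabilities always
  share an order — required for a well-defined ordinal output.
* Ties in GVF resolve to the partition with the fewest values in the top
  class, then the lexicographically smallest break vector. "Tie" means
  SDCMs within 1e-9 relative to SDAM, so the outcome does not depend on
  float summation order; the strict `>` threshold comparison carries the
  same 1e-12 guard (a best partition whose GVF is *exactly* the threshold
  does not stop the search).
* The automatic method assigns order 0 (not −1) to zero-capability systems,
  following the literal κ−1 mapping; a flag restores −1 semantics. The
  rank benchmark maps zeros to −1 and uses competition ranking ("1224")
  for ties.
* The benchmark's rank runs over land systems within a fixed service
  column, matching its stated intent ("relative order of the land systems'
  contribution" to one demand).

## Taxonomy, capabilities, demand

The fine-resolution (micro) cover map is aggregated in square blocks
(default 33×33; 30 m cells become 990 m macro cells). Trailing partial
blocks are dropped rather than padded so fractions stay exact; the macro
header records the true cellsize instead of resampling to a rounder one.
Each macro cell takes its dominant cover type (ties to the lowest type id)
at one of three density levels; the two thresholds per cover type are the
natural-breaks class bounds (K = 3) of the dominant-cell fraction values,
computed over that type's dominant cells only. A cover type with fewer than
three distinct fraction values collapses to fewer levels and is recorded —
on real data a density level can be entirely absent. The legend enumerates
every (cover, level) combination the thresholds define, so a second date
classifies into the same legend; systems absent at the first date get
zero capability rows, flagged.

`S[j,d]` comes from overlaying the macro map on the micro map:
`Λ_{j,d}/Λ_j`, areas counted over non-nodata micro cells. Demand for
service *d* in a year is the total micro area of cover *d* that year; by
construction the initial map's supply equals the same-date demand exactly
on block-divisible rasters (verified to ~1e-16 in the acceptance run).

## Suitability, resistance, allowance

Suitability per system is plain maximum-likelihood logistic regression,
fitted by iteratively reweighted least squares on internally standardized
factors (convergence when the largest coefficient change is below 1e-8, cap
100 iterations), coefficients transformed back to the original scale.
Complete separation is handled by capping |β| at 30 on the standardized
scale and flagging non-convergence — closest to plain ML, no penalty term.
Fits are skipped when either outcome class has fewer than 30 sampled cells
(rare systems; their suitability surface falls back to the observed
prevalence so the allocation still has a value for them). Collinearity
pruning uses |SRCC| although the source rule is stated one-sided — a strong
negative correlation is equally collinear; from the worst pair the member
with the larger correlation sum is dropped, ties by factor name, making the
result independent of input order. Spatial sampling keeps cells whose row
and column are both ≡ 0 mod (interval+1), anchored at (0,0).

Resistance is per-type historical persistence, in [0,1] by construction;
types absent at the first date get 0 with a warning. The allowance matrix
permits a→b only where that conversion exceeded 1 % of the study area
between the dates; the diagonal is always 1 (a system may always remain
itself) — the historical-noise rule is read as applying to off-diagonal
conversions only.

ROC AUC uses the rank (Mann–Whitney) formulation with midranks, identical
to trapezoidal integration of the ROC curve, and is undefined (None) for
one-class inputs.

## Synthetic data: what it emulates, what it does not

The fixture generator emulates the *structure* of a fine-resolution cover
product: a categorical raster with spatial autocorrelation (smoothed
uniform noise thresholded at its quantiles — dependency-free and exactly
reproducible), a second date with per-type persistence (Bernoulli keeps;
failures resample uniformly among other types), and continuous factor
surfaces with known logistic coefficients and closed-form probability
grids. Each generator draws from its own RNG stream keyed off the master
seed, so adding a generator never perturbs the others.

Default conditions: 4 cover types, 33×33 aggregation, persistence grading
from 0.95 to 0.75 across types — mostly persistent landscapes where some
covers decline and others expand, so demands genuinely shift between the
dates (spatially uniform change would leave aggregate demands unchanged
and make the allocation trivial). In the assembled study, factor surfaces
mix unit-variance noise (weight 0.5) with the first date's cover-fraction
surfaces, because real driving factors carry information about landscape
composition; with pure noise every regression would be uninformative
(AUC ≈ 0.5), which real studies do not show.

What passing tests on these fixtures do *not* show: real landscapes have
directional, spatially clustered change, far more systems (around 30), and
capability columns with pronounced clusters. On the smooth synthetic
capabilities the rank benchmark discriminates finely and tends to converge
faster than the adaptive orders, whose coarse classes tie many systems —
the opposite of what strongly clustered real capabilities can produce. The
class-number sweep's qualitative behaviour (K = 1 unusable; Kappa and
total disagreement strongly rank-anticorrelated across K) does transfer.

## Problem sizes

Tests run on micro rasters up to 660×660 (20×20 macro) and the acceptance
script on 1320×1320 (40×40 macro) with 10 000-observation recovery
experiments — sizes chosen so the full suite completes in about a minute
while every macro map still contains both fitted and skipped regressions.
The simulation engine is vectorised over cells; a 20 000-iteration,
1 600-cell, 12-system step takes a few seconds.

## Limitations

Single region, static factors, no neighbourhood interaction terms, no
multi-resolution map comparison, ESRI ASCII/CSV formats only. The
suitability stage offers no spatial cross-validation or alternative
regressors. Whether the cell update should be synchronous or sequential is
not documented for the original implementation; synchronous was chosen for
order-independence and is the only mode.
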