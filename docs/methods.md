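# Methods

## Model

A root's epidermal cell-length profile is the series of cell lengths
`x_1..x_T` (μm) ordered by the cells' axial positions `p_1 ≤ … ≤ p_T` (μm,
centre-of-cell coordinates with the root cap junction at the origin). Cells
from several files are merged and sorted by projected position, never by
within-file index; tied positions are kept in input order.

The heteroscedastic piecewise Gaussian linear model assumes `J` contiguous
zones delimited by change points `τ_1 < … < τ_{J−1}` (each the index of the
first cell of the shootward zone), and within zone `j`

    E(x_t) = α_j + β_j p_t,   Var(x_t) = σ_j²    for τ_j ≤ t < τ_{j+1}.

Within-zone parameters are profiled by maximum likelihood: OLS for
`(α_j, β_j)` and `σ̂_j² = RSS_j / n_j`, giving the segment log-likelihood
`−(n_j/2)(log(2π σ̂_j²) + 1)`. The change-in-the-variance model used for
residual series keeps a single global mean (fixed at the series average —
for OLS residuals it is numerically zero) and profiles only the per-segment
variance; it shares all machinery below through its own segment-cost matrix.

The reported limit position of change point `τ_j` is the position of the
first cell of the shootward zone, so a maximum-a-posteriori limit can sit at
an endpoint of its credible interval.

## Algorithms and numerics

* Segment costs for every feasible cell range `u..v` are computed from
  running sums of `p, p², x, x², px` in `O(T²)`; dynamic programming over
  them is `O(J·T²)`. Segments shorter than the minimum length are `−inf`.
* The `N` most probable segmentations come from an N-best extension of the
  dynamic program (each DP state keeps its `N` best values with
  backpointers). Ties anywhere are broken toward the lexicographically
  smallest change-point vector, making every output deterministic.
* Sums over the whole segmentation space (evidence, change-point posteriors,
  per-cell zone-occupancy profiles) use forward–backward recursions in
  log-sum-exp arithmetic with a uniform prior over feasible segmentations;
  the max-type "segmentation probability profiles" use the Viterbi analogue.
  Zone occupancy is obtained as differences of change-point posterior CDFs,
  which telescopes to unit row sums by construction.
* Change-point credible intervals (default coverage 0.95) are the smallest
  contiguous index interval around the optimal change point reaching the
  coverage, grown greedily toward the side with more mass, ties rootward.
  The interval therefore always contains the optimal change point.
* A variance floor of 1e−6 μm² inside segment costs keeps log-likelihoods
  finite on collinear stretches; fits at the floor are flagged degenerate
  and excluded from t-tests and confidence intervals.
* Minimum segment length defaults to 4 cells (3 are needed for a positive
  residual variance; 4 adds stability).
* Slopes are fitted in μm per μm and reported ×1000 (μm of cell length per
  mm of axis), the convention of the cohort tables.

## Selection of the number of zones

The slope heuristic fits `ℓ(J)` (optimal log-likelihood) for `J = 1..J_max`
and estimates the penalty slope `ŝ` as the OLS slope of `ℓ(J)` on the model
dimension `D(J)` over the upper half of the grid (at least 3 points; with
fewer, all `J ≥ 2`), floored at zero. The criterion is
`C(J) = ℓ(J) − 2 ŝ D(J)`; model weights are the softmax of `C`; the selected
`J*` maximizes `C` with a smallest-`J` tie-break. Dimensions are `4J − 1`
for the linear family (line + variance per zone + change points) and `2J`
for the variance family.

`J_max` defaults to 5 for the linear family. For the variance model fitted
to the residuals of a `J`-zone linear fit, the grid extends to `J + 2`: an
algebraic property of the recipe is that with fewer than 3 upper-half points
the fallback regression over all `J ≥ 2` makes `C(3) − C(2) = −(ℓ(4) − ℓ(3))
≤ 0`, so a 4-model grid can never return three variance zones; a grid two
beyond the linear model's count always estimates the penalty from models
past the one of interest. Standalone variance fits default to `J_max = 4`.

The exact weight construction of the original slope-heuristic formulation
is not reproduced here; per-root model weights from this package are
therefore comparable in behaviour (models within about one zone of the
optimum receive non-negligible weight) but not numerically identical to
published per-root values.

## Biological labeling and the retained segmentation

Segments are labeled by the expected succession DZ → (TZ) → EZ → MZ:
a single segment is MZ; with two segments the first is EZ when its slope is
significantly positive (two-sided t-test, level 0.05) and at least
20 μm/mm, else DZ (diagnosis "merged", since EZ and MZ are presumably
merged); three segments are DZ/EZ/MZ with diagnosis "EZ-missing" when the
middle slope is not significantly positive; four segments are DZ/TZ/EZ/MZ
when both leading segments have short cells. The 20 μm/mm threshold only
disambiguates 2-segment fits (published EZ slopes are 9.8–201.8 μm/mm, DZ
slopes −22.1 to 27.9).

The retained segmentation follows a fixed, deterministic strategy:
(1) optimal segmentation at the selected `J`, labeled; (2) on a merged
diagnosis, well-supported segmentations with one more zone (posterior within
a factor 10 of the optimum's, among the top 10) are screened and the best
consistent one retained; (3) if any jump of the piecewise function at a
limit exceeds twice the smaller adjacent residual sd, well-supported
alternatives at the same `J` are screened for one that passes; (4) failing
all, the optimal segmentation is kept and the problem reported. Provenance
(optimal / alternative rank k / J+1 model rank k) is always recorded, and a
CLI override (`--force-j/--force-rank`) reproduces expert choices. The
first-root-hair position is never used in selection — it is only compared
with the retained EZ-MZ limit afterwards (a match means the hair lies in EZ
or inside the limit's credible interval, endpoints included).

Approximate continuity at a limit is assessed by overlap (closed intervals)
of the rootward and shootward OLS confidence intervals for the mean cell
length at the limit position, `ŷ ± t_{n−2} s √(1/n + (x₀−p̄)²/S_pp)` with
`s² = RSS/(n−2)`, default level 0.95.

## Synthetic profiles

The generator emulates the measurement process: within each of `n_files`
(default 3) epidermal files, cells tile the axis from 0; the next cell's
expected length is the current zone's line evaluated at the rootward edge,
the realised length is Gaussian with the zone's sd truncated at a floor
(0.5 μm), the recorded position is the cell centre, and files are merged by
position. A first-root-hair position is placed at the EZ-MZ limit plus a
configurable offset (default +100 μm). Ground truth (limits, per-zone
parameters, per-cell zones by centre) is returned alongside.

Design consequences worth knowing: (i) evaluating the mean at the cell's
rootward edge rather than its centre shrinks the realised slope slightly
(by a factor `1/(1 + β/2)`; ≈3% at 60 μm/mm), negligible against tabled
noise; (ii) cells straddling a zone boundary are drawn from the rootward
zone's line, so at very low noise the change point is defined up to that
straddling cell; (iii) files are generated independently — real inter-file
correlation of cell lengths is not emulated; (iv) contiguous tiling means
cell density is tied to cell length exactly, whereas real profiles have
missing cells. Passing recovery tests on these profiles therefore shows the
machinery recovers the generating zonation under the stated noise model,
not that every property of measured profiles is captured.

Preset parameter sets mirror the published tables: a vigorous 3-zone root
(DZ to 855 μm, flat ≈6 μm cells, sd 1.3; EZ to 1494 μm, slope 59.5 μm/mm,
sd 5.5; MZ slope 49.6, sd 18.2), a single-regime root, and an arrested
C-type root (single MZ-like zone, mild positive trend, sd ≈13).

## Problem sizes used in tests and the acceptance script

Exhaustive-enumeration equivalence is checked on 200 randomized series with
`T ≤ 12` and `J ≤ 3` (tolerance 1e−9). Recovery rates use 50 seeded
replicates: three-zone profiles at the vigorous-root preset (zone-number
selection and limits within ±3 local mean cell lengths — the mean cell
length at each limit — in ≥ 90% of runs) and two-block Gaussian series of
40 + 40 points with sd 1 then 10 (two segments with the break within ±3
indices in ≥ 90%). Cohort-level numbers are recomputed from the packaged
tables and are deterministic.

## Known limitations

* Per-root fits of the original cohort cannot be reproduced because the raw
  series were not deposited; the packaged tables carry the published
  per-root results instead.
* The co-localization rule counts a limit as unsupported when the variance
  model selects fewer zones than the linear model (no counterpart limit);
  on the packaged tables this yields 53 of 59 co-localized limits.
* The labeling ontology stops at four segments (DZ/TZ/EZ/MZ); more change
  points than that raise an error rather than guessing labels.
* PCA requires complete cases; roots lacking diameters are dropped from it
  (the packaged tables print no diameters, so the published PCA axes are
  not reproducible from fixtures).
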