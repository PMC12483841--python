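# Methods

This note documents the models and procedures `sageplan` implements, the
defaults it ships, the numerical choices behind them, and what the synthetic
landscapes do and do not establish about real data.

## Planning units and classification

Planning units are individual raster cells (default 30 m) on a shared
north-up grid; all layers in one analysis must agree in shape, cell size and
origin (alignment is enforced, never repaired, and no reprojection is
attempted).  Cell membership in polygons and buffers is decided by
cell-center containment: unambiguous, cheap, and consistent between zonal
statistics, conservation-area masks and lek buffers.

**Degraded** cells are flagged from two signed change fields, Δh = historic −
current and Δp = potential − current cover (gains count as negative losses —
the statistics are of *change*, not loss).  With the mean and SD of each
field over all non-nodata cells, a cell is degraded when Δh or Δp exceeds
its mean + 2 SD, or when both sit in their own 1–2 SD band.  Zero variance
in both fields is an error (no classification is possible).  **Intact**
cells are non-degraded cells with current cover ≥ 15% (inclusive), the
conventional minimum for sage-grouse use; the two masks are disjoint by
construction.

Unit bookkeeping uses rook (4-neighbor) adjacency: boundary length is an
edge property and diagonal neighbors share no edge.  Every unit satisfies
4·cell_size = Σ(shared edges) + study-edge length, which lets the boundary
penalty price exposed perimeter exactly.

**Ecological potential.** Degraded cells carry no useful current species
signal, so their restored value is imputed as the zonal mean of the
(rescaled) feature over intact cells in the same management cluster.
Clusters without intact cells leave their degraded cells undefined; those
units contribute zero to that feature's totals and capture.  In merged
pools (restoration problems that also contain intact cells), intact units
keep their direct feature values and only degraded units take the imputed
ones.

## Layer transforms

All feature layers are rescaled linearly to [0, 1] before optimization (a
constant layer maps to zeros rather than failing).  Cost layers that should
*attract* selection are transposed order-reversingly, v′ = −v + v_max + 1,
so the maximum maps to exactly 1 and a minimum-set objective prefers
high-valued cells; v_max is taken over the candidate units only, since cost
outside the pool never enters the objective.  Signed layers (connectivity
loss ≤ 0) are shifted order-preservingly, v′ = v + |v_min| + 1, applied
verbatim even to all-positive inputs — reproducibility of the stated
formula over cleverness.  CV at non-positive means is undefined and becomes
nodata.

## Circuit-theory connectivity

Connectivity is modeled as current in a resistor network: cells with
positive conductance (here, percent sagebrush cover) are nodes, rook
neighbors are joined with edge conductance equal to the arithmetic mean of
the two cells (the standard raster discretization; 8-neighbor graphs are
available behind a config switch).  For each source a window of the
configured radius is cut out (truncated at the study edge — no data exists
outside), a unit current is injected at the source, the other sources in
the window (or the other lek points) are grounded, and the Kirchhoff node
equations are solved with a sparse LU factorization.  Per-cell throughflow
is half the sum of absolute edge currents plus half the absolute
injected/absorbed current, so a series chain carries exactly the injected
current everywhere.  Windows whose source has no positive-conductance path
to any ground carry zero current (logged, not fatal).  Cumulative maps are
sums over windows and therefore invariant to visiting order; a uniform
conductance rescaling leaves them unchanged (unit injection).

The `stride` parameter thins cover-based window centers to every
`stride`-th grid row/column; it changes only how densely windows are
seeded, not the physics of any window, and `stride=1` reproduces the dense
scheme.  The lek map applies a focal (circular) mean at the window radius
to the cumulative surface — interpreting the final product as mean current
over the moving window — and then zeroes a 1-km buffer around each lek,
whose near-source currents would otherwise dominate prioritization.  The
loss layer is min(now − then, 0): apparent gains can come from mere current
redirection and are clamped.

Defaults: 30-km radius and a 15% cover source threshold (annual-home-range
scale and the intact-habitat definition).  The desk-scale catalog runs use
a 600-m radius with stride 4 — on the bundled 3-km-wide landscapes a 30-km
window would degenerate to a single global solve; the chosen window spans a
fifth of the map, which preserves the moving-window character at a size the
test suite can afford.

## The minimum-set solver

Objective and constraints are given in the README.  Numerical choices:

* The boundary term Σ p*ᵢxᵢ − 2Σ Lᵢⱼxᵢxⱼ is linearized with continuous
  yᵢⱼ ∈ [0, 1], yᵢⱼ ≤ xᵢ, yᵢⱼ ≤ xⱼ; since the y coefficient −2bL is
  negative for b > 0, y reaches min(xᵢ, xⱼ) at any optimum and the
  linearization is exact.  With b = 0 no y variables are created.
* `gap` is the MILP *relative optimality gap* (default 0.01).  The source
  workflow glosses it as allowed deviation from targets, but in the solver
  ecosystem it bounds the objective, and targets stay hard constraints in
  every backend here.
* A relative target on a zero-total feature resolves to t = 0 (vacuous,
  warned) rather than infeasible: 0.2 × 0 = 0.
* Infeasibility names the violated features (target exceeds what the whole
  pool provides, including the empty-pool case from aggressive masking).
* The exhaustive backend (n ≤ 22) is the test oracle; ties break to the
  lexicographically smallest selected set for determinism.  The greedy
  backend is a weighted set-cover heuristic used as a fast feasible
  fallback and a sanity bound (its objective can never beat the optimum).
* The nominal boundary penalty 1e-5 (anti-fragmentation device for weakly
  constrained problems) is an ordinary b value, not a special mode.

Boundary-penalty calibration solves the b = 0 problem and a sorted
candidate list, then returns the largest b whose pure-cost inflation over
the b = 0 optimum stays within a tolerance, reporting cost inflation, clump
counts and exposed boundary per candidate.  The acceptance rule is a
declared substitute for the source workflow's unspecified "aligned with
problem objectives" judgment.

## Problem catalog

The nine stock configurations (see `data/catalog_defaults.yaml`, diffed
against the in-code catalog by the test suite): protection problems on
intact units with uniform cost (1a, nominal penalty 1e-5 on the all-species
run only), transposed sagebrush connectivity (1b), transposed future cover
(1c) and untransposed spring soil moisture (1d, nominal penalty, optional
future-cover masks at 5/10/15% — minimizing an untransposed moisture cost
deliberately prioritizes low-moisture, low-resilience sites); restoration
problems on degraded units with transposed soil moisture cost and
ecological-potential features (2a merges in the intact units and locks
them, b = 0.1 all-species and 0.015 for single-species runs, the midpoint
of the calibrated 0.006–0.024 band; 2b is the uncertainty variant);
conservation-design problems masked to core/growth-opportunity areas (3a
transposed lek connectivity; 3b, b = 2.5 and 3c with shifted
connectivity-loss cost, b = 1.5, both locking in 3a's selected sites).
Because intact and degraded pools are disjoint, 3b/3c merge 3a's selected
cells into their pools before locking them — the same merge-and-lock device
2a uses.  Single-species runs target one species at 0.2 and set all other
targets to 0.

Areas are reported in hectares (cell_size²/10⁴).  Summary tables give
median, quartiles, min and max of each layer over selected units, and
capture proportions for all features, targeted or not — the ingredient of
the umbrella-species cross-capture matrix.

## Uncertainty sweep

The sweep freezes absolute targets t_k = 0.2·Σf_k from the unpenalized
layers, then for each weight w ∈ {0.0, 0.1, …, 0.8} (nine iterations)
solves with utility layers cost + w·CV and max(0, feature − w·u_k), with no
boundary penalty and no locked-in units (both would need per-iteration
recalibration and break comparability).  Selection counts over feasible
iterations classify units as low (≥ 7), medium (4–6) or high (1–3)
sensitivity, with never-selected units kept as a separate class because the
classification compares selected sites only.  Infeasible iterations are
recorded, flagged and excluded from counts.

One scale decision matters here.  The cost penalty adds w × CV directly
(cost and its CV ratio are commensurate).  For features, the dimensionless
CV ratio is first converted to a standard-deviation surface on the
feature's own optimization scale, u_k = CV × value, before the subtraction.
Subtracting the raw ratio from 0–1-rescaled features lets a moderate CV
(≈0.3) exceed typical feature values outright once w ≥ 0.2 — strongly
right-skewed density layers, whose rescaled mass sits near zero, lose
almost their entire total to clamping, nearly every iteration goes
infeasible, and the sensitivity map degenerates to a single class.  The
sd-scaled penalty keeps the formula's intent (an uncertainty-discounted
lower bound on the feature) while keeping the nine iterations comparable.

## Synthetic landscapes

The generator emulates, per seed and bit-reproducibly: spatially
autocorrelated percent-cover fields (Gaussian-smoothed white noise — simple,
seedable, and sufficient for patch structure) with an ecological-potential
offset above historic cover; patchy degradation covering a configurable
fraction of cells (default 0.2) at a configurable depth (default 12%
cover); a future-cover surface attenuated by a smooth trend so the 5/10/15%
mask thresholds partition the map nontrivially; species layers with the
field's characteristic distribution-shape contrast — non-negative,
right-skewed density-like layers (lognormal noise around a cover response;
one species prefers open, low-cover shrubland) and left-skewed
probability-like layers in [0, 1]; CV surfaces for all but one species (so
the sweep's exclude-no-CV rule is exercised); rectangular management
clusters tiling the grid; two conservation-area rectangles covering about
half the map; and lek points sampled preferentially from high-cover cells.
A cluster-constant lek-abundance index (with CV) stands in for the
cluster-scale abundance product used by restoration problems.

Default scale is 100 × 100 cells at 30 m — large enough to exercise
windows, masks and the MILP, small enough that the full catalog solves in
well under a minute.  What the generator does *not* emulate: real spatial
covariance structure, climate or vegetation process realism, observation
error correlated across species, or the geography of any particular region.
Passing tests therefore demonstrate that the workflow's logic and
optimization behave as specified under controlled conditions, not that any
particular real landscape would yield similar selections.

## Known limitations

* Single-band GeoTIFF and square cells only; inputs must be pre-aligned.
* The omnidirectional scheme grounds the window's other sources against a
  unit injection at the center; block-aggregated source strengths and
  alternative normalizations of production tools are out of scope, as are
  pairwise (all-to-all) modes and least-cost-path alternatives.
* The focal-mean interpretation of the final lek map is one reading of
  "mean values over the moving window"; the cumulative map is also exposed
  for users who prefer it raw.
* Exhaustive enumeration is capped at 22 units; beyond that only MILP and
  greedy backends apply.
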