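# Methods

## Data model

All spatial stages operate on `CategoricalRaster`: a 2-D integer class grid
with square cells (side `cell_size_m` metres), a nodata code, an upper-left
origin and an opaque CRS tag. Rasters are row-major with the row index
increasing southward; indices are 0-based. Multi-raster operations require
exact alignment (same shape, cell size, origin, CRS tag) — there is no
reprojection or resampling. Non-square cells are rejected so the cell area
`A = cell_size² / 10⁴` ha is unambiguous. Nodata is propagated, never
imputed; every count, fraction and total excludes nodata cells.

Two formats are read and written: ESRI ASCII grid (human-readable; used for
all test fixtures) and single-band integer TIFF with a JSON sidecar
(`<name>.tif.aux.json`) carrying cell size, origin, nodata and CRS tag.
Cell size is raster metadata, never a package constant.

## Reclassification

The shipped 44→7 map assigns the CLC level-3 grid codes 1–44 (standard
order) to Settlement (the 11 artificial classes), Crop land (9 agricultural
classes), Forest land (agro-forestry + the three forest classes), Grassland
(natural grassland, moors/heathland, sclerophyllous, transitional
woodland-shrub, pastures, sparsely vegetated), Wetland (5 classes), Water
body (5 classes) and Other land (beaches/dunes, bare rocks, burnt areas,
glaciers). Target codes are fixed 1–7 so matrices and tables are comparable
across runs. Unmapped codes either abort (`policy="error"`, the default) or
become nodata with a logged count. Under the error policy reclassification
preserves the number of valid cells, hence total area.

## Transition estimation

`cross_tabulate` counts joint class occurrences of two aligned maps
(excluding cells nodata in either); `to_probabilities` row-normalises, with
empty rows becoming identity rows so that matrix products remain defined —
a class with no population is treated as persistent should it reappear.
Averaging across periods is an unweighted arithmetic mean (the mean of
row-stochastic matrices is row-stochastic exactly). Matrices are stored at
full precision; the shipped averaged Calabria matrix is printed at 4
decimals upstream, so `default_transition_matrix()` renormalises its rows
(raw row sums deviate from 1 by up to 1.5e-3) while
`raw_default_matrix_frame()` preserves the verbatim values.

## CA–Markov prediction

Markov quantity targets are `n' = nᵀP`, rounded to integers by largest
remainder so the valid-cell total is conserved exactly. The cellular
automaton allocates those quantities: the suitability of cell *x* for class
*c* is `P[current(x), c] · (ε + f_c(x))`, where `f_c` is the fraction of
class *c* in the `filter_size × filter_size` window (default 5×5),
edge-truncated and computed over the valid cells actually present, and
ε = 0.01 keeps transitions into locally absent classes possible. Quotas are
interpolated linearly across `iterations` CA passes (default 6, one per
future year); the full Markov step is applied once, not compounded.

Within a pass, allocation is two-stage: (1) persistence claims are honoured
first, in descending persistence suitability, up to each class's quota;
(2) displaced cells are then assigned greedily by descending suitability
under the remaining budgets. Ties break deterministically (persistence,
then row-major index, then class code) by default; `tie_break="random"`
shuffles among exact ties under the seed. The design was open — the
proprietary multi-objective allocator used by desktop GIS packages is not
published — and the two-stage form was chosen because it uses exactly the
two ingredients the method names (transition probabilities and neighbourhood
contiguity) while making three invariants structural: an identity matrix is
a fixpoint, an absorbing class never loses cells, and per-class output
counts equal the rounded Markov targets exactly after the final pass.
Replicating any particular desktop implementation bit-for-bit is a
non-goal.

## Validation

With `p_ij` the simulated×reference proportions, `M = Σ p_ii`,
`N(n) = 1/J_chance`, `N(m) = Σ c_j r_j` and `P(m) = Σ min(c_j, r_j)`, the
agreement decomposes (single stratum) into chance = `min(N(n), N(m), M)`,
quantity = `max(0, min(N(m), M) − chance)`, gridcell = `max(0, M − N(m))`,
plus disagreements `P(m) − M` (location) and `1 − P(m)` (quantity); the
seven components always sum to 1. Kappas:
`Kno = (M − N(n))/(1 − N(n))`, `Kstd = (M − N(m))/(1 − N(m))`,
`Kloc = (M − N(m))/(P(m) − N(m))`; with one stratum `Klocstrata = Kloc`.
Degenerate denominators yield NaN rather than a number.

Two deliberate choices:

- `J_chance` defaults to **8**, not 7: the reference validation reports
  chance agreement of exactly 1/8, i.e. the tool that produced them counts
  a background/nodata category. It is a plain argument everywhere.
- The clamped components are invertible back to `M`, `N(m)`, `P(m)` only
  when observed agreement beats the chance and quantity baselines
  (`M ≥ N(m)` and `M ≥ N(n)`), which holds in any usable validation run;
  the oracle-equivalence tests therefore use correlated map pairs, the
  regime the statistics are designed for.

## Carbon pools

Forest pools scale from growing stock (default 225.4 m³/ha, the regional
inventory figure): `BAG = GS·BEF·WBD`, `CAG = BAG·CF`, `CBG = BAG·R·CF`,
`CDOM = CAG·(AMR + litter_fraction)`. The below-ground relation uses the
root-to-shoot ratio R explicitly; a published variant that omits R from the
formula while defining R as "the factor converting above-ground to
below-ground biomass" is treated as a typo. Litter-carbon regressions in
the inventory literature have unpublished coefficients, so litter enters as
a configurable fraction of CAG, default 0 — with the consequence that the
equation route gives forest `CDOM ≈ 1.46` Mg/ha where the shipped
assessment table carries 9, and forest `CAG ≈ 82.3` where the table carries
93. The shipped 7-class pool table is the authoritative assessment input
(it is what the multi-year ledger reproduces); the equation-based
constructors exist for methodology reuse on other regions and are not
forced to match it, since the averaging order and litter placement behind
the published table are not recoverable.

Grassland uses IPCC defaults (`BAG` 2.7 Mg d.m./ha, root-to-shoot 4.0,
carbon fraction 0.5); crop and wetland densities are unweighted means of
the shipped per-type tables (rounding those means to integers reproduces
the corresponding rows of the pool table).

## Assessment and valuation

Cell storage is `A · (CAG+CBG+CSOIL+CDOM)` of the cell's class; the map
total equals the class-aggregate route `Σ area_km2 · 100 · density` to
1e-9 relative (both are exact sums — this two-route identity is tested).
Sequestration is the signed difference between assessment years; CO₂
equivalence uses 44/12 exactly. Valuation follows the discounted
per-year-spread formula with defaults V = 200 EUR/Mg C, r = 3 %/yr,
c = 0 %/yr. Because published period values in this domain are sometimes
quoted without the discount factor (the reference ledger's period values
equal ≈ V·s × 0.999, matching neither r = 3 nor r = 0 exactly), the ledger
reports both the discounted and the undiscounted `V·s` value per period;
no attempt is made to force agreement with that column. Monetary amounts
are carried at full precision; million-EUR 2-dp rounding happens only at
presentation.

Two internal inconsistencies of the reference ledger are asserted at face
value in the acceptance tests and fail there by design: its last-period
variation is not the difference of its own stored-carbon column (off by
≈294 kMg — evidently computed from a map-level total that the printed area
table does not reproduce), and one CO₂ entry deviates from 44/12 × the
printed variation by 3.56e-4 relative, just above the 3e-4 drift the other
rows show from upstream rounding.

## Synthetic landscapes

`generate_initial` draws `n_patch_seeds` seed cells (the first J get one
class each, so every class is present) and labels every cell by its nearest
seed (ties: lowest class code) — a tessellation chosen over noise
thresholding because it guarantees class presence and a controllable patch
count with no extra dependencies. `evolve_markov` draws each cell's next
class from its matrix row; with probability `spatial_mixing` the row is
first re-weighted by the classes present in the 3×3 neighbourhood
(renormalised, falling back to the plain row when there is no overlap),
which clusters change without creating transitions the matrix forbids. One
integer seed feeds a named stream per operation, so sub-results are
independently reproducible.

Defaults mirror the study conditions the package targets: 7 classes, the
shipped averaged transition matrix, 4 dates at 6-year steps, a 200×200 grid
(40 000 cells keeps every class populated enough that, at
`spatial_mixing = 0`, cross-tabulation recovers the true matrix to max
absolute entry error ≤ 0.02), 49 patch seeds, mixing 0.25. What the
generator does **not** emulate: real geomorphology, class-adjacency
structure (coasts, altitude zonation), minimum-mapping-unit generalisation,
or classification error between dates. Passing tests therefore demonstrate
the estimators' and allocator's correctness and internal consistency, not
the predictive skill of CA–Markov on real CORINE data.

## Numerical and testing notes

- Row-stochasticity is enforced at 1e-9; component sums at 1e-9 when
  computed (1e-3 when constructed from 4-dp printed inputs).
- Largest-remainder rounding breaks remainder ties toward the lowest index.
- Test problem sizes: unit tests use grids ≤ 30×30; the parameter-recovery
  check uses one 200×200 series (≈0.3 s); the whole suite runs in a few
  seconds.
- Reference-table reproduction tolerances follow the precision of the
  printed sources: 1e-4 relative for stored carbon (2-dp area rounding
  propagates to ~2e-5), 0.005 absolute on 2-dp monetary values, 1e-3
  absolute on 4-dp kappas, 3e-4 relative on CO₂ equivalents.
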