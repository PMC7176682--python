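# Methods

## Model overview

landflow maps structural landscape connectivity as electrical current
density on a resistance raster and quantifies how sensitive the
resulting map is to the main modelling decisions. The chain is:

1. per-category binary footprint layers × expert h values → degree of
   human modification H (fuzzy algebraic sum);
2. H + percent slope + water mask → resistance R (scaling function,
   slope penalty s/4, additive water penalty);
3. R → cumulative current density (random boundary-node pairs,
   Laplacian solves, correlation-based convergence, buffer clipping);
4. map ensemble from a 2×2×2 factorial design → z-scores,
   correlation/agreement matrices, dissimilarities, db-RDA variance
   partitioning.

The model is species-agnostic by construction: resistance encodes
human modification, not the movement ecology of any taxon, so current
density reads as relative intensity of potential ecological flow.

## Human modification

For a cell touched by footprint categories with values h₁…h_k the
index is H = 1 − ∏(1 − h_j); an untouched cell has H = 0. The fuzzy
algebraic sum is bounded below by max(h_j) and above by min(1, Σh_j),
is permutation-invariant, monotone in every argument, and has 1 as an
absorbing value — all asserted as property tests.

Index variants: H_F uses the physical-footprint values, H_U the
intensity-of-use values, H_FU their mean. The mean is taken **per
category before the fuzzy sum**. The alternative — averaging the
finished H_F and H_U surfaces — is exposed as
`modification_surface(..., fu_mode="surface")`; the two coincide
exactly wherever at most one footprint is present and differ only
through the nonlinearity of the product on multi-footprint cells.
The per-category reading was chosen because the index is defined
category-wise in the catalog.

Region dependence is cell-wise: a footprint spanning both the forest-
and the agriculture-dominated region takes the region-specific h of
each cell.

## Resistance

R = f(H) + s/4 + w_res·w with

* f high contrast = (H+1)¹⁰ — strong separation of heavily modified
  cells: f(0.5) = 57.665, f(1) = 1024;
* f low contrast = 1 + 1000·H — preserves proportionality:
  f(0.5) = 501, f(1) = 1001.

Both have f(0) = 1, so R ≥ 1 everywhere (validated by the
`ResistanceRaster` invariant). A slope of 100% adds 25. The water
penalty is additive on top of f(H) even when a water cell also
carries footprints, so the technical maximum under the high-contrast
scaling with w_res = 1000 is 1024 + 1000 = 2024 at zero slope. The
main map uses w_res = (1.5)¹⁰ = 57.665 (an intermediate modification
of 0.5); the constant is kept at full precision internally and prints
as 57.7. The factorial design varies w_res over {0, 1000} only; the
slope term is never varied.

Aggregation to the analysis resolution is the arithmetic block mean;
trailing partial blocks average the cells available, and a coarse
cell is NoData only when the whole block is. Mean aggregation
conserves the global mean when the factor divides the grid — a
regression test guards this. Masks (study area) aggregate by block
majority (≥ 50% inside).

## Circuit solver

Edge conductance between neighbours i, j is 1/((R_i + R_j)/2): each
cell contributes half of its resistance to every crossing (half-cell
series convention), so a 1×n chain has the closed-form end-to-end
resistance Σ mean(R_i, R_{i+1}). The mean-of-conductances
alternative is available (`convention="mean_conductance"`). The
default neighbourhood is 8, diagonals divided by √2 for the longer
centre distance; 4-neighbourhood is used in several oracle tests.

Solves ground a fixed reference node and reuse one sparse LU
factorization of the reduced Laplacian for every pair — per-cell
currents are invariant to the grounding choice, and the shared
factorization is what makes 50-node ensembles cheap. Per-cell current
density is half the sum of absolute incident edge currents, with the
two terminals set to the injected magnitude (1), so every cell of a
uniform chain reads exactly 1. Correctness is pinned by: Kirchhoff
residuals < 1e-8, agreement with a dense symmetric-pseudo-inverse
oracle to 1e-8 on random grids (5×5–12×12, 20 seeds), reciprocity and
resistance-scale invariance to 1e-10, and a monotone barrier check.

Boundary nodes are placed at equal arc-length intervals along the
outermost ring of the buffered extent, from a seeded random offset,
snapped to the nearest distinct valid cell. Accumulation samples
unordered pairs without replacement in seeded random order and stops
when the Pearson correlation between the cumulative map before and
after the latest batch (default batch 1, first check after 10 pairs)
reaches the threshold, default 0.999. This is our reading of the
"correlation function = 0.999" convergence rule of omnidirectional
connectivity tools; what exactly those tools correlate is not
published, so no claim of bit-identical behaviour is made. Per-pair
solves are accumulated raw (no per-pair normalization): the
downstream z-scoring absorbs any global scale.

Water cells are ordinary high-resistance cells and are never removed
from the graph; only cells outside the buffered extent are absent. A
disconnected raster is an error, not a warning.

## Map comparison and variance partitioning

z-scores use the population standard deviation (divide by n; at
raster scale the distinction from n−1 is negligible) over valid —
i.e. clipped — cells only. Classification uses z ≥ cutoff at all
three cutoffs {0, 1, 2}; ties count as important. Nestedness of the
three classifications is asserted.

Agreement between two classified maps is the fraction of valid cells
classified identically. Similarities convert to dissimilarities as
D = 1 − m by default, with sqrt(1 − m) as an option.

Variance partitioning follows vegan's `varpart` logic: principal
coordinates of the Gower-centred −D²/2 matrix (axes with positive
eigenvalues retained; Lingoes and Cailliez corrections available),
RDA R² of the coordinate cloud on every subset of the dummy-coded
factors, Ezekiel adjustment R²_adj = 1 − (1 − R²)(n−1)/(n−p−1),
unique fractions by inclusion–exclusion, unexplained = 100% minus the
sum of unique fractions. Negative adjusted fractions — and, for
near-deterministic designs at n = 8, fractions above 100% — are
reported as-is, as vegan does. The implementation is verified against
`vegan::varpart` outputs frozen into the test suite, and against
classical RDA on raw Euclidean configurations (PCoA round-trip
identity).

**Distance scale for the reference reanalysis.** The packaged 8×8
correlation matrix between the Alberta factorial maps is reanalysed
with the *metric* form: since the maps are z-scored, the cell-space
Euclidean distance between maps a and b is exactly √(2n(1 − r_ab)),
so db-RDA on √(1 − r) is identical to a classical RDA on the maps
themselves and every eigenvalue is non-negative. Running the same
partitioning on 1 − r directly embeds with large negative eigenvalues
and, under the adjusted inclusion–exclusion arithmetic, yields
fractions summing far above 100%. With the metric form the
partitioning gives water 48.4%, scaling 28.9%, H index 14.6%,
unexplained 8.2% — the same ranking as the originally reported
42.4/28.4/12.5/16.7, with the water and unexplained fractions
differing by more than rounding of the printed two-decimal
correlations can explain (a ±0.005 perturbation study moves each
fraction by < 0.6 points). The original fractions were evidently
derived from the unrounded map data or an unstated dissimilarity
variant; the package reports what its documented pipeline computes
rather than tuning toward the printed values.

## Synthetic landscapes

The generator emulates the structure, not the semantics, of a
human-footprint inventory at fine resolution:

* patch categories: gaussian-smoothed white noise thresholded at the
  coverage quantile, giving spatially autocorrelated blobs with
  near-exact expected coverage; an `overlap` parameter mixes a shared
  field into every category so footprints co-occur (co-occurrence
  rates are not published, so they are a knob, default 0.3);
* one category of one-cell-wide polylines spanning the grid (the
  roads analogue; individual lines never fill a 2×2 block, though
  crossings may);
* contiguous water patches (thresholded smooth noise, default 5%
  cover) and a smooth slope field rescaled to [0, max_slope], default
  max 40% — only the range matters to the resistance formula;
* a wavy-boundary two-region mask (forest north, agriculture south)
  and a centred rectangular study area inside a buffer ring of width
  ≥ 20% of the study width (default 1/3).

Catalog h values are uniform on [0, 1] per category × region.
Everything is driven by `numpy.random.default_rng(seed)`; identical
configs give bit-identical bundles.

What passing tests on these landscapes shows: the pipeline's
mechanics — combination rules, solver correctness, convergence,
partition arithmetic — behave as specified. What it does not show:
realistic Alberta-scale effect sizes; which factor dominates the
uncertainty partition on synthetic data depends on the drawn catalog
and landscape, not on the geography the original ranking reflects.

## Problem sizes and defaults

Defaults are chosen so a full ensemble runs on a laptop core: fine
grid 300×300 (study 180×180 plus a 1/3 buffer), aggregation factor 3
(so the analysis grid is 100×100, mirroring the 10 m → 100 m workflow
with a smaller factor), 20 boundary nodes, convergence 0.999. At
these sizes each factorial map converges after roughly 50 of the 190
possible pairs and the nine-map ensemble completes in seconds. The
node count is configurable up to the perimeter size (the original
workflow used 50).

## Known limitations

* No geodesic/projected CRS handling: grids are abstract row-major
  rasters with square cells (ESRI ASCII grid I/O only).
* db-RDA significance testing (permutation tests) is out of scope;
  fractions are reported without p-values, and interactions between
  factors are not modelled.
* The convergence rule is a faithful reimplementation of a published
  description, not a bit-compatible port of any existing solver.
* Current density is omnidirectional (boundary-pair) only; no
  patch-to-patch or least-cost-path variants.
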