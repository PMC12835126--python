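# Methods

## Model and assumptions

The dual observer model treats spike-sorting yield as a coverage problem:
every electrode observes a sphere of radius *R*, tissue seen by exactly
one electrode contributes units at density *p*<sub>single</sub>, tissue
seen by two or more contributes at density
*p*<sub>double</sub> = 2*G* *p*<sub>single</sub>, and the two
contributions are disjoint. The assumptions this buys and their limits:

- observation volumes are isotropic spheres of a single radius; real
  extracellular amplitude decay is anisotropic and neuron-dependent;
- coverage by *three or more* electrodes is not distinguished from
  coverage by two — the gain saturates at the second observer;
- *p*<sub>single</sub> and *G* are homogeneous across the sampled tissue.

For evenly spaced collinear arrays the coverage volumes have closed
forms built from the equal-sphere lens
*V*₂(*R*, *D*) = (π/3)(4*R*³ − 3*R*²*D* + *D*³/4):

- *V*<sub>double</sub> = (*M*−1) *V*₂(*R*, *D*) − (*M*−2) *V*₂(*R*, 2*D*)
- *V*<sub>total</sub> = *M* *V*₁(*R*) − (*M*−1) *V*₂(*R*, *D*)
- *V*<sub>single</sub> = *V*<sub>total</sub> − *V*<sub>double</sub>

with lens terms clipped to zero once the sphere pair separates. All
higher-order inclusion–exclusion terms cancel for collinear equal
spheres because a triple intersection A∩B∩C coincides with the
second-neighbour intersection A∩C. The package defines
*V*<sub>single</sub> as "covered by **exactly** one sphere" throughout;
with that convention the three formulas above, the linear-array
efficiency

E(R,D) = 1 + 2(G−1)·(M−1)/M·V₂(R,D)/V₁ − (2G−1)·(M−2)/M·V₂(R,2D)/V₁,

the closed-form optimum D_opt = R·√[(4MG−12G+4)/(7MG−3M−15G+7)] and the
tabulated per-channel yields form one mutually consistent set (the
optimum is the stationary point of E, verified here by a brute-force
argmax oracle over dense spacing grids). The test suite additionally
checks the closed forms against an independent concentric-disc slice
integration oracle, which confirms the cancellation claim in all overlap
regimes up to M = 64 and R/D = 25.

Degenerate inputs: M = 1 and M = 2 are supported by the volume formulas
(the absent neighbour terms vanish); the closed-form optimum requires
M > 3 and raises otherwise, directing the caller to a numeric search.
For G ≤ 1 there is no interior optimum — efficiency is ≤ 1 wherever
spheres overlap and exactly 1 for D ≥ 2R — so the optimum is reported as
the boundary value D = R with a `boundary_g_le_1` flag, rendered as
"≥ R μm" in reports (any spacing above it performs alike; smaller
spacings only waste coverage).

## Parameters and units

| parameter | meaning | units | default |
|---|---|---|---|
| R (`r_obs`) | observation radius | μm | fitted (grid 1–200, step 1) |
| G (`g`) | gain factor p_double/(2 p_single) | — | fitted (grid 0.01–4, step 0.01) |
| p_single | sortable-unit density | per mm³ | fitted (least-squares scale) |
| D | inter-electrode distance (nearest-neighbour for zig-zags) | μm | layout-derived |

Lengths are μm and volumes μm³ internally; densities cross the API
boundary per mm³ (factor 10⁹).

The approximation E_opt ≈ 0.76 G + 0.16 is used for tabulated
"optimal efficiency" and "optimal units/channel :=
p_single · V₁(R) · E_opt" figures — it is the convention those summary
tables are defined by, and it makes the per-channel figure independent
of M. The exact efficiency at D_opt is always reported alongside (for
example 1.43 vs 1.41 at G = 1.64); the difference is a known property of
the approximation, not a numerical error.

## Monte-Carlo volume estimation

For layouts without a closed form (zig-zag geometries), volumes are
estimated from uniform points in the electrode bounding box expanded by
max(200 μm, R) on every axis, so each observation sphere lies wholly
inside the box for any radius in the fitting grid. A point's coverage
count comes from its nearest and second-nearest electrode distances
(`scipy.spatial.cKDTree`); V_total and V_double are the box volume times
the fractions with d₁ ≤ R and d₂ ≤ R, with binomial standard errors.
The estimator is deterministic given (seed, n_points, layout, R) and
uses `numpy.random.default_rng`.

One point cloud per layout serves every radius up to the box margin: the
sorted (d₁, d₂) arrays are binary-searched per radius. This is
arithmetically identical to re-using the same draw radius by radius, and
has two consequences exploited by the fitter: the ~200 radii of the grid
cost one sampling pass, and the similarity surface over (R, G) is not
tilted by independent sampling noise between cells. Profiles are cached
per (layout, settings) within a process.

Dispatch (`hybrid_volumes`): exact independent-sphere result when
R ≤ D_nn/2 (no intersections exist), exact closed form for strictly
linear equidistant layouts, Monte-Carlo otherwise; the branch taken is
recorded on the result.

## Fitting

Medians of units-per-channel over recordings (midpoint convention for
even counts) are taken per configuration, ordered by effective pitch.
For each grid cell the predicted pattern at unit density is
(V_single + 2G V_double)/(M·10⁹) per configuration; the cell maximizing
cosine similarity with the median vector wins, ties broken toward
smaller R then smaller G (determinism; ties are counted in the
diagnostics). p_single is then (y·m̂)/(m̂·m̂), the projection of the data
onto the winning pattern — the scale minimizing squared error, which
reproduces noise-free truth exactly. At least three configurations are
required (three free parameters); all-zero medians are rejected because
cosine similarity is undefined.

Grid-cell coupling: when the data come from parameters between grid
cells, R snaps to the nearer 1 μm cell and the best G at that cell
shifts correspondingly — recovery is within one grid step in R and about
two steps in G on noise-free data.

## Synthetic data generator

The generator emulates a campaign of spike-sorted recordings over a
downsampling series of one probe: per configuration the model expectation
N/M, per recording either multiplicative lognormal noise
(N/M)·exp(ε), ε ~ N(0, σ²) with σ = 0.2 by default — chosen as a
realistic inter-recording coefficient of variation for repeated
penetrations of one region, and configurable — or Poisson counts
Poisson(N)/M for sparse configurations where units are small integers.
Defaults mirror the study conditions: six recordings per configuration,
the rodent series (256/128/64/32/16 channels at 8.5/12/24/48/96 μm) or
human series (192/96/64/48/38/19 channels at 25.6/40/62.1/80/101.3/200
μm).

What the generator does **not** emulate: correlations between
configurations derived from the same underlying recording (real
downsampled datasets share noise), sorter-specific failure modes,
defective electrodes (~a few % on real probes), and within-recording
drift. Passing recovery tests therefore demonstrate the estimator's
statistical behaviour under the model's own noise assumptions, not
robustness to every artefact of real recordings.

## Probe presets and downsampling

The rodent preset (256 electrodes, two zig-zag columns, 6 μm row advance,
6 μm column offset → 8.5 μm nearest-neighbour pitch) is
reverse-engineered from the published pitch and the probe description
(two columns, 12 μm per-column pitch); the human preset (192 electrodes,
20 μm row advance, 16 μm column offset → 25.6 μm pitch) from the
Neuropixels column-pair geometry. Both are overridable via layout JSON.
Downsampling keeps every k-th electrode in shank order; the series
helpers use offset = M mod k, which reproduces all published channel
counts (including 38 of 192 at k = 5 and 19 at k = 10). Shifted-
configuration enumeration returns all k offset variants, which share the
pitch up to boundary effects.

## Problem sizes and numerical choices

- Grid fits tabulate volumes once per configuration (analytic for linear
  members; one seeded profile for the zig-zag member) and evaluate all
  200×400 cells vectorized.
- Recovery studies in the test suite use 10⁶-point Monte-Carlo profiles:
  at that size the volume standard errors are far below the σ = 0.2
  recording noise being studied. Oracle-equivalence validation uses the
  full 10⁷ points.
- Lens and coverage volumes clamp sub-femtolitre negative round-off
  (three-term cancellation near sphere tangency) to zero.
- Monte-Carlo agreement tests compare against 3 standard errors computed
  at the *true* hit probability, which remains valid for cells with
  expected hit counts below one.

## Known limitations

- Only single-shank geometries are treated; multi-shank probes reduce to
  this case when inter-shank distance exceeds 2R.
- No uncertainty quantification on fitted parameters (no bootstrap CIs);
  the grid-cell resolution (1 μm, 0.01) is the reporting granularity.
- 2-D grid layout optimization (square/hexagonal) is out of scope.
- The closed-form optimum assumes M > 3; small arrays need the numeric
  curve search.
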