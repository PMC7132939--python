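# Methods

`mvbkit` quantifies membrane-bound organelles — multivesicular bodies
(MVBs) in the motivating use case — that have been segmented from FIB-SEM
stacks of cortical neuropil. The pipeline takes labeled voxel rasters or
object catalogs and produces densities, volume fractions, compartment
statistics, size-distribution fits and spatial-randomness verdicts. Because
raw volume-EM segmentations are rarely shareable, every estimator is
validated by parameter recovery against a synthetic generator with known
ground truth.

## The synthetic generator (what it emulates, what it does not)

A generated experiment mimics the sampling design of a FIB-SEM study of
juvenile rat somatosensory cortex: 29 stacks spread over cortical layers
I–VI (3/4/10/5/3/4 stacks per layer), each stack an axis-aligned box whose
volume is drawn uniformly from 167.39–444.11 μm³ (the printed range of the
study's counting frames; their mean is 277.23 μm³). Within each stack:

- **Positions** follow either complete spatial randomness (CSR, a
  homogeneous Poisson process) at intensity λ = 0.21 objects/μm³ — the
  study's reported mean density — or a Thomas cluster process as the
  clustered alternative. Thomas parents are Poisson with rate κ in a window
  expanded by 4·`cluster_sd` per face (so clusters centred just outside
  still contribute offspring, the standard edge-bias fix); each parent gets
  a Poisson(μ_c) number of offspring scattered isotropically with Gaussian
  sd `cluster_sd`, and only offspring inside the window are kept. The
  "tight cluster" condition used throughout the tests is κ = 0.021 μm⁻³,
  μ_c = 10, cluster_sd = 0.25 μm: it keeps the effective intensity
  κ·μ_c = 0.21 μm⁻³ equal to the CSR condition while making cluster spread
  an order of magnitude smaller than the window side, so it exercises the
  classifier rather than straddling its decision boundary.
- **Volumes** are log-normal with natural-log-scale parameters
  μ = −5.1375, σ = 0.9173 (μm³), the study's best-fit size distribution;
  the implied mean exp(μ + σ²/2) ≈ 8.9 × 10⁻³ μm³ agrees with the reported
  mean MVB volume to within 2%.
- **Compartments** (dendrite, excitatory axon, inhibitory axon,
  nonsynaptic process) are i.i.d. multinomial with probabilities
  0.3914 / 0.1587 / 0.0229 / 0.4270, the pooled layer I–VI percentages.
- **Morphology flags** (docked on a mitochondrion, tubular protrusions,
  clathrin coat) are independent Bernoulli with rates 0.1816 / 0.0666 /
  0.1974.

One global seed drives a `numpy` `SeedSequence` that spawns one substream
per stack, so multi-stack experiments are reproducible and individual
stacks are independent.

The voxel phantom renders each object as a sphere in physical space
(an ellipsoid in index space under anisotropic voxels), adds a cylindrical
protrusion of radius 0.25·r and length 1.5·r along +x when the tubule flag
is set, and resolves overlaps deterministically in favour of the lower
object ID. Default phantom geometry is desk-scale (≤ a few hundred voxels
per side) rather than acquisition-scale; all estimators take geometry as a
parameter, so nothing depends on that choice. Objects whose bounding sphere
crosses the raster edge are clipped there; only an object whose diameter
exceeds the raster extent is an error.

What the generator deliberately does **not** emulate: electron-optics
noise, membrane appearance, intraluminal vesicles, synapses, registration
artefacts, or any spatial structure in compartment geometry (the optional
background partition is a seeded nearest-seed tessellation, pure plumbing
for exercising the Cavalieri stage). Consequently, passing recovery tests
demonstrates that the estimators are correct and unbiased under the assumed
sampling model — not that segmentation or compartment classification of
real micrographs is accurate.

## Morphometry and shrinkage

Object volume is voxel count × voxel volume; the centroid is the unweighted
mean of voxel-center positions (label rasters carry no intensity to weight
by), mapped to physical μm as origin + (index + ½)·voxel size. Discretization
error of the sphere phantom shrinks monotonically with voxel size
(≈17% at 80 nm to ≈6% at 20 nm for the default size distribution, dominated
by the many sub-voxel-scale small objects).

Tissue shrinkage from osmication/embedding is corrected by dividing
measurements by after/before factors — linear 0.90, area 0.81 ≈ 0.90²,
volume 0.73 ≈ 0.90³ — applied coherently to object volumes and to
counting-frame dimensions so densities are corrected once, not twice.

## Stereology

**Counting frame.** Density uses the unbiased 3D brick: inclusion faces
meet at the low corner, the opposite faces are exclusion planes, and an
object is counted iff its unique counting point (the centroid, the only
point the catalog carries) lies in the half-open box [lo, hi). Boundary
cases follow the brick rule exactly: on an inclusion face counts, on an
exclusion plane does not. Monte-Carlo tests confirm E[count] = λV under
CSR.

**Aggregation.** The headline "mean density across layers" is the
unweighted mean of the six layer means (each layer mean being the
unweighted mean of its stacks); equal-weight pooling over stacks is
available by flag (`aggregation="pooled_stacks"`). The two differ whenever
layers contribute unequal stack counts, and the layer-mean convention is
the default because it matches how per-layer tables are reported.

**Cavalieri.** Volume fractions are estimated by point counting: a square
grid (default spacing 632 nm, associated area spacing² = 399 424 nm² — we
expose spacing as the primitive and compute the area rather than quoting a
rounded constant) on every 40th section (Δz = 800 nm at 20 nm sections).
The fraction is grid points hitting the target labels over grid points in
the reference area. The grid origin is fixed at half a spacing for
reproducibility; passing a seed randomizes it uniformly within one grid
cell, which is the unbiased variant used in the calibration tests
(estimate within 3 sem of the analytic fraction of a rendered sphere over
200 random origins).

## Spatial statistics

All three classical summary functions are implemented for points in a 3D
box window, with estimators chosen so a brute-force double loop reproduces
them to floating-point accuracy:

- **G** (nearest-neighbour distance CDF) and **F** (empty-space function)
  use the reduced-sample (border) correction: a point or test site
  contributes at distance r only if its distance to the window boundary is
  at least r. F's test locations default to a deterministic 32³ lattice of
  cell centers. Note the reduced-sample estimator is *not* guaranteed
  monotone in r (its denominator shrinks with r); the theoretical curves
  and the uncorrected empirical CDFs are.
- **K** (Ripley's reduced second moment) uses the translation correction
  e_ij = V / Π_a(L_a − |Δ_a|), so K̂(r) = V/(n(n−1)) Σ_{i≠j} 1[d_ij ≤ r]
  e_ij.

Under CSR, G(r) = F(r) = 1 − exp(−λ·(4/3)πr³) and K(r) = (4/3)πr³; the test
suite checks both closed forms by averaging ≥200 simulations. The default
distance grid is 64 points from 0 to one quarter of the shortest window
side, a standard guard against edge-dominated estimates.

**Envelope test.** A pattern is classified against `nsim = 100` CSR
simulations conditioned on the observed count (a binomial process — this
removes count variance from the envelope; a Poisson-count variant is one
flag away in the generator). The default band is **global
(simultaneous)**: simulation mean ± the largest whole-curve deviation among
the simulations, giving a controlled family-wise false-alarm rate of about
1/(nsim+1) per function (≈3% over G, F and K jointly — measured 7% "not
random" on CSR). The classical pointwise min/max band is available via
`envelope_type="pointwise"`, but scanned over 64 grid points and three
functions its joint false-alarm rate is large — measured ≈48% on CSR — so
it is unsuitable as an automatic classifier; this is why the global band is
the default even though pointwise bands are the older convention. The
verdict is *random* when every selected function stays within its band;
breaches only in the clustered direction (G above, F below, K above) give
*clustered*; only the opposite signature gives *regular*; anything else is
*mixed*. Patterns with fewer than 25 points are refused, mirroring the
common practice of excluding small samples.

## Statistics

The log-normal size fit is maximum likelihood on natural logs: μ̂ is the
mean of ln v and σ̂ uses divisor n (the MLE); a moment-matching alternative
is provided. The goodness summary is a KS statistic of the logs against
Normal(μ̂, σ̂); because parameters are estimated from the same data its
p-value is a screening diagnostic, not an exact test. Concentration ratios
divide the percentage of objects in a compartment by the compartment's
volume fraction of the neuropil (fixed reference constants: dendrites
38.50%, axons 22.81%, nonsynaptic 38.69%); ratios above 1 mean enrichment.
χ² is provided in goodness-of-fit form (expected = total × volume fraction,
df = c − 1) and r×c independence form. Group comparisons are Mann–Whitney
(two groups) and Kruskal–Wallis with a hand-implemented Dunn post-hoc
(pooled mid-ranks, tie-corrected variance, Holm adjustment by default —
Bonferroni and unadjusted available). Type-I error of χ² and KW is verified
at α = 0.05 over 2000 null replicates.

Percentages in written reports are rounded to two decimals; internal
arithmetic is full precision. Per-layer densities weight stacks equally;
size summaries pool objects within a cell of the table. Both conventions
are flaggable because published tables rarely state which was used.

## Numerical and degenerate-input choices

- Reduced-sample CDFs return NaN where the denominator is empty (r larger
  than every point's boundary distance); envelope logic ignores NaN bins.
- All-equal volumes fit with σ = 0 and a degenerate (perfect) goodness
  summary; fits require n ≥ 3 and strictly positive volumes.
- Rendering assigns at least the voxel containing the centroid, so
  sub-voxel objects are never silently dropped.
- Cavalieri refuses grids finer than the voxel size and sampling schemes
  that produce zero points.
- Empty label stacks measure to an empty list, not an error; an empty
  catalog renders to a pure-background raster.

## Problem sizes in the shipped tests

The test suite and the acceptance script use desk-scale problem sizes
chosen as the package's own defaults: 10⁵ draws for distribution-recovery
checks, 29 simulated stacks for density recovery, 100–1000 replicates for
Monte-Carlo calibration, 100-seed × 100-simulation envelope calibration,
and ≤128³-voxel phantoms. These are the sizes at which the quoted
tolerances (e.g. ±0.01 on fitted μ and σ, ±0.02 on recovered density) are
statistically meaningful.

## Known limitations

- Compartment classification, docking, tubules and clathrin arrive as
  catalog flags; nothing is detected from images.
- Only homogeneous processes: no inhomogeneous-intensity spatial variants,
  no pair-correlation function, no cross-type statistics.
- The envelope verdict taxonomy formalizes a narrative convention; with
  pointwise bands it reproduces that convention's high false-alarm rate,
  which should be kept in mind when comparing against published counts of
  "random" vs "clustered" samples.
- Windows are axis-aligned boxes; irregular sampling windows are out of
  scope.
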