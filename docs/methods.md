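# Methods

## Scope and model of the measurement

`vsaxs` treats a single-particle scattering experiment as repeated
snapshots of one particle shape at fresh, uniformly random orientations.
Under that assumption the expectation of any detector pixel's counts equals
the spherical average of the particle's intensity at that pixel's |q|, so
the sum of many azimuthally integrated patterns converges to the 1D SAXS
profile of the particle. Everything downstream (Guinier analysis, shape
retrieval) then operates on that virtual SAXS profile exactly as it would
on a solution-scattering measurement. Monodispersity is the essential
sample requirement; patterns from several well-separated identical
particles still satisfy it, whereas aggregates and droplets enter as
false positives.

## Detector geometry and momentum transfer

A flat detector at distance D (mm) with pixel pitch p (mm) and fractional
beam center (cx, cy); pixel centers at integer 0-based coordinates. The
momentum transfer of a pixel is q = k(ŝ − ẑ), k = 2π/λ, giving
|q| = 2k sin(α/2) with α = atan(r/D) the full scattering angle; the
out-of-plane component k(cos α − 1) carries the Ewald curvature. The
**flat region** used for center refinement is defined by a fractional
departure of the Ewald sphere from its tangent plane, 1 − cos α ≤ 1%,
equivalent to a half-angle cutoff arccos(0.99)/2 ≈ 0.0707 rad.

Default synthetic study conditions (chosen once; all lengths in nm,
q in nm⁻¹): λ = 0.2, D = 4000 mm, 128 px of 0.5 mm (or the equivalent
64 px of 1 mm where scale allows), beam center mid-detector. The edge then
sits at q ≈ 0.25 nm⁻¹, resolving the particle sizes used in the case-study
analogs (68–364 nm). Incident fluence is constant across shots by default
(`fluence_scale`, the expected photon count at forward scattering, is
per-shot configurable); the noisy-centering studies use a fluence giving
≥ 10⁵ flat-region counts per pattern.

## Bead models and their profiles

Shapes are filled on a cubic lattice (spacing s, bead radius s/2) and then
**rescaled so the enclosed volume n·s³ equals the analytic solid volume**
(sphere, ellipsoid, cube, dumbbell with its lens overlap). This removes
the leading-order size bias of the discretization — without it the
effective radius is off by ~0.1% of a spacing, which shifts the profile
minima and produces several-percent errors in the side lobes.

The 1D profile of a bead model is the Debye sum over pairwise distances,
multiplied by the squared uniform-sphere amplitude of one bead,
Φ_b(q) = 3(sin x − x cos x)/x³, x = q·r_b. The simulator applies the same
Φ_b² to its coherent bead sums, so the two routes to a profile (pattern
averaging and the Debye formula) describe the same object. For models above
2000 beads the pair sum uses a blocked pair-distance histogram (1000–4000
bins) carrying the weighted mean distance per bin; on the models used here
it is indistinguishable from the exact sum (≲10⁻⁴ relative) at an order of
magnitude less time and bounded memory.

Two independent oracles guard the profile code: the closed-form solid
sphere (agreement within 1% up to qR = 8 away from the analytic nulls,
where a relative comparison is ill-conditioned for any discretization —
the null positions themselves are checked via the first minimum at
qR = 4.4934), and a brute-force spherical average of |F(q)|² over
Fibonacci-distributed directions (within 1% of the Debye sum).

## Guinier analysis

Rg comes from a fit of ln I against q² restricted iteratively to
q·Rg ≤ 1.3. The fit includes a q⁴ correction term (ln I = a + bq² + cq⁴,
Rg = √(−3b)): a straight line at this cutoff carries a ≈ +1% truncation
bias for a solid sphere, which the quartic term removes (< 0.1% across the
grids tested) while staying exact for a pure Gaussian profile.

## Center refinement

The Friedel-pair score at a trial center is the mean over flat-region
pixel pairs (p, p′ = reflection through the center, nearest-pixel rounding)
of (I(p) − I(p′))²/max(I(p) + I(p′), 1) — the denominator is the Poisson
variance of the difference, floored at one count, which keeps bright pixels
from dominating and makes the expected score scale-free. A single-pass
integer grid search (default ±5 px) minimizes it; ties break toward the
initial guess, then lexicographically. An optional second pass at a quarter
step refines sub-pixel centers. Refinement is per pattern by default (the
simulator's center jitter is per shot); refining once per run is a matter
of passing the same result to every integration.

## Profiles and merging

Azimuthal integration assigns each unmasked pixel to the half-open q bin
containing its |q| and reports the per-bin **mean** (the standard estimator
of the azimuthally averaged intensity; comparisons downstream are
scale-free, so mean vs sum is a convention). σ is the Poisson error of the
mean. Merging accumulates pooled photon and pixel totals per bin and
reports n_patterns × pooled mean: N copies of a profile sum to N× that
profile, the operation is associative, and it reduces to plain summation
when every pattern covers every bin. No per-shot normalization is applied
before summation. Convergence is traced by the Pearson correlation of the
cumulative profile against the full-set merge (any reference profile can
be substituted), and by randomly splitting the set into halves and
correlating the two merges.

## Shape database and retrieval

Every model is recentered, scaled to unit bounding radius (max centroid
distance plus bead radius — one of several defensible "radius" conventions;
users matching an external r₀ should note it), and stored as I_ref(s) on an
equally spaced s = q·R grid (default 512 points to s_max = 50), normalized
to I_ref(0) = 1. Scaling a model to radius r is then the argument rescaling
I(q; r) = I_ref(q·r), interpolated linearly in log intensity to preserve
deep minima (linear across non-positive values). The chi score uses
experimental σ weighting when available and relative residuals
(σᵢ = I_e(qᵢ)) otherwise; both are explicit options.

The radius search is a golden-section minimization over
[0.8 r₀, 1.25 r₀] (symmetric on a log scale, so over- and under-estimates
of r₀ are treated equally) with tolerance 0.01 r₀ — 8 iterations by the
golden-ratio contraction. The default `global` mode minimizes
J(r) = min over models of χ(r), then refines the top candidates with
independent per-model searches before the final ranking; `per_model` mode
runs the independent searches from the start. K = 10 models are returned,
rendered as voxel maps at their fitted radii.

Top-set maps are clustered by the Jaccard overlap of their supports after
centroid + principal-axes alignment (axes ordered by variance, sign fixed
by the third central moment, right-handedness enforced), single linkage at
overlap ≥ 0.75. Class averages are voxel-wise means on a common grid after
the same deterministic alignment. When r₀ is not supplied it is estimated
as √(5/3)·Rg from a Guinier fit (the sphere-equivalent radius) and logged.

## Synthetic data: what it does and does not emulate

The simulator reproduces the statistical structure the pipeline relies on:
uniform SO(3) orientations (seeded Shoemake sampling; a Halton-based
quasi-uniform set exists for convergence studies), Ewald-sphere sampling
with curvature, Poisson counting noise, per-shot beam-center jitter, and
false positives drawn from a different (droplet-like) model at a set rate.
It does **not** emulate detector panel gaps and gain structure, polarization
and solid-angle corrections, jet/background scattering, fluence variation
across shots, multi-particle hits, or orientation preference — so passing
tests demonstrate the pipeline's correctness under its stated assumptions,
not robustness to every instrument systematic. Outlier rejection is
deliberately not applied anywhere; the convergence trace and split-half
tools only expose the information.

Case-study analogs used by the tests and the acceptance script: a
135 × 68 nm prolate particle (500 noisy patterns, recovered axes within
10%) and a touching-spheres dumbbell with 91 nm lobes (500 noisy patterns,
lobe radius recovered within 3%; the lobe radius of a retrieved model is
estimated as √(5/3)·Rg of one lobe's beads, which is robust to lattice
discretization where the raw extent is biased low). Problem sizes (64–128 px
detectors, 500–600 patterns, ~500–2000-bead models) were chosen as the
smallest that leave comfortable margins on those recovery tolerances.

## Numerical choices

- Coherent sums use single-precision trigonometry (phase quantization
  ~10⁻⁶ rad); noiseless patterns are centrosymmetric only to that level,
  ~6 orders below the symmetry breaking of a 1 px center error.
- Monte-Carlo orientation averaging converges as ~1/√n; at 500 random
  orientations the merged profile of the prolate matches its Debye curve
  to ~3% near the first minimum, at 2000 quasi-uniform orientations to
  < 2% (the level the orientation-averaging tests assert). Comparisons use
  the within-bin pixel mean of the reference curve, which separates
  orientation convergence from the pixel-discretization bias of comparing
  at bin centers.
- Golden-section iteration counts follow ceil(log(tol/width)/log 0.618)
  exactly; the final radius is the midpoint of the terminal bracket.
- Degenerate inputs raise typed errors (`vsaxs.errors`): fewer than 50
  Friedel pairs, empty integration masks, mismatched q grids, all-zero
  model profiles, queries entirely outside the database s range.

## Known limitations

- The Debye route ignores solvent contrast and hydration shells; profiles
  are vacuum shapes, appropriate for the large nanoparticles studied.
- Bounding-sphere radius inflates r₀ for very anisometric shapes (the
  bracket ±25% absorbs moderate mismatch; extreme aspect ratios may need a
  user-supplied bracket).
- Real-space clustering at a fixed 0.75 overlap is scale-free but
  resolution-dependent; maps are rendered at r/20 voxels for comparability.
- The database search is exhaustive per radius evaluation (fine for
  thousands of models; no indexing/pruning is attempted).
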