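# vsaxs

Virtual small-angle X-ray scattering (SAXS) analysis for single-particle
diffraction experiments, with fast shape retrieval from a size-rescalable
model database.

## The problem

An X-ray free-electron laser records thousands of 2D scattering patterns,
each from one particle at an unknown orientation. Full 3D reconstruction
(orientation recovery plus phase retrieval) is slow; but if the orientations
are uniformly random, simply **summing azimuthally integrated patterns**
yields the spherically averaged 1D profile I(q) — the same observable a
solution SAXS experiment measures. That "virtual SAXS profile" can be
analysed with mature SAXS methods in near real time during a beamtime,
giving immediate low-resolution 3D model feedback.

`vsaxs` implements the whole chain:

1. **Simulation** of realistic pattern stacks (monodisperse bead-model
   particles, uniform orientations, Ewald-sphere sampling, Poisson noise,
   beam-center jitter, controllable false-positive contamination).
2. **Beam-center refinement** per pattern, by a grid search minimizing the
   intensity difference of Friedel pairs I(q) = I(−q) inside the flat
   region of the Ewald sphere (1 − cos α ≤ 1%, i.e. half-angle ≲ 0.07 rad).
3. **Azimuthal integration and merging** into the virtual SAXS profile,
   with convergence monitored by the Pearson correlation of the cumulative
   profile against the full-set reference, and by split-half consistency.
4. **Shape retrieval**: a database of shapes stored as dimensionless
   profiles I_ref(s), s = q·R, computed at unit bounding radius via the
   Debye formula

       I(q) = Φ_b(q)² Σᵢⱼ wᵢwⱼ sin(q rᵢⱼ)/(q rᵢⱼ),

   so that resizing a model to radius r is a pure argument rescaling
   I(q; r) = I_ref(q·r). Agreement with the experimental profile is the
   reduced chi score

       χ = sqrt( (1/N) Σ ((I_e − c·I_m)/σ)² ),

   with the scale factor c solved by least squares in closed form. The
   radius is optimized by golden-section search over [0.8 r₀, 1.25 r₀]
   (8 iterations at the default 0.01 r₀ tolerance); the ten best models are
   exported as CCP4 maps, clustered by real-space overlap, and averaged
   per class.

## Worked example

```sh
vsaxs simulate --shape dumbbell --params radius=91,separation=182,spacing=16 \
      --n-patterns 300 --fluence 5000 --n-px 64 --seed 7 --out patterns.h5
vsaxs build-db --preset --out shapedb.h5
vsaxs pipeline patterns.h5 --db shapedb.h5 --r0 185 --out-dir run/
```

The last command refines centers, merges the 300 patterns, searches the
built-in 12-shape database and prints

```
wrote centers for 300 patterns to run/centers.csv
merged 300 patterns into run/profile.dat
rank-1: dumbbell_d2R  chi=31.73  r=189.4 nm; 8 model class(es)
```

meaning the touching-spheres dumbbell is the best match at a fitted
bounding radius of 189.4 nm — a lobe sphere radius of ≈92 nm, within about
1% of the 91 nm the particles were simulated with. `run/` contains the merged profile
(`profile.dat`), the convergence trace (`trace.csv`), the ranking with
per-model chi, scale and radius (`rank.csv`), a `.fit` curve per model, and
CCP4 maps for the ten retrieved models and their classes.

The same works from Python:

```python
import numpy as np
from vsaxs import simulate, profiles, shapedb, retrieve

geo = simulate.DetectorGeometry(wavelength_nm=0.2, distance_mm=4000,
                                pixel_mm=1.0, n_fast=64, n_slow=64,
                                beam_center=(31.5, 31.5))
model = simulate.make_shape("dumbbell", radius=91, separation=182, spacing=16)
pats, _ = simulate.simulate_dataset(model, geo, 300, 5000.0, seed=7)
bins = profiles.default_q_bins(geo, 150)
merged = profiles.accumulate([profiles.azimuthal_integrate(p, q_bins=bins)
                              for p in pats])
db = shapedb.build_database(shapedb.default_shape_set())
result = retrieve.search(db, merged, r0=185.0)
print(result.ranked[0].model_id, result.ranked[0].r)
# dumbbell_d2R 188.57...
```

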