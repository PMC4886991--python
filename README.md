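# stillgrid

Per-image optimisation of spot-finding parameters for serial still
crystallography, with Ewald-proximal-volume (EPV) result selection and
unit-cell clustering.

## The problem

In serial crystallography — XFEL experiments and zero-rotation synchrotron
collection alike — every exposure comes from a different crystal (or
crystal volume). Crystal size, quality, mosaic structure and orientation
vary shot to shot, so the recorded stills differ wildly in spot size,
intensity and background, and a large fraction of frames are blank.
Indexing and integration are highly sensitive to the two thresholds used
for candidate Bragg-peak detection: the minimum peak height (background-
subtracted intensity over the background standard deviation, in σ units)
and the minimum spot area (connected pixels). No single threshold pair
works across a heterogeneous set, and frames that fail to index are lost
from the merged data set.

stillgrid addresses this with a per-image grid search: every pairwise
combination of the two thresholds, built from user-supplied medians and
spreads in unit steps, is run through the full pipeline — spot finding,
target-cell indexing, lattice/beam-centre refinement, mosaic-parameter
estimation, reflection prediction and summation integration — and each
completed result is retained.

## Selecting the best result: the Ewald proximal volume

A still records a reflection only while its reciprocal-lattice point
overlaps the Ewald sphere. Mosaic structure gives each point a finite
full-width diameter

    w(d) = 2/D + η/d,

where *D* is the effective mosaic block size (Å), η the effective
full-width mosaic rotational spread (rad), and *d* the resolution of the
reflection. The EPV is the volume of the shell of half-thickness *w*/2
around the Ewald sphere, out to the scattering angle of the resolution
limit *d*<sub>L</sub>. In spherical coordinates centred on the sphere
centre (radius *r*, polar angle τ = 2θ, azimuth κ) it is

    EPV = 2π/3 ∫₀^τL sin τ [ (1/λ + w/2)³ − (1/λ − w/2)³ ] dτ,
    τL = 2 arcsin(λ / 2 d_L),   d(τ) = λ / (2 sin(τ/2)),

evaluated by Gauss–Legendre quadrature. Multiplying by the primitive cell
volume gives the spot count an ideal, background-free detector would see:
N_spot = EPV · V_cell. A small EPV means a sharply determined crystal
model; one large enough to hold the observed reflections means the model
explains the data. The best result per image is chosen in two steps:

1. keep the 25% of integration results with the smallest EPV;
2. of those, return the one with the most strong integrated reflections
   (I/σ(I) > 5 by default).

Afterwards, accepted images are grouped by Niggli-reduced unit cell with
average-linkage hierarchical clustering, the dominant cluster (most
members) is marked, and run summaries (stage counts, selected-parameter
heat map, beam-centre scatter, limiting-resolution histogram, a
downstream-merging parameter stub with the lowest-symmetry Laue class) are
written.

Because real serial data sets are huge and proprietary, the package ships
a synthetic still generator with full ground truth (cell, orientation,
mosaic parameters, per-reflection intensities) so that every stage is
testable end to end.

## Worked example

```python
import stillgrid as sg

cell = (79.0, 79.0, 38.0, 90.0, 90.0, 90.0)     # tetragonal-lysozyme-like
det = sg.default_geometry()                      # 256x256 px, 50 mm

# one synthetic still with known mosaic structure
truth = sg.random_crystal(cell, D_range=(500, 500),
                          eta_range=(0.002, 0.002), rng_seed=7)
frame, manifest = sg.render_still(truth, det, background_mean=50.0,
                                  d_min=3.5, rng_seed=7)

epv = sg.compute_epv(D=500.0, eta=0.002, wavelength=1.3, d_L=3.5)
print(sg.expected_spot_count(epv, cell))

grid = sg.build_grid(sg.GridSpec(4, 2, 4, 2))    # heights 2..6, areas 2..6
best, results, log = sg.process_image_gridsearch(frame, grid, cell,
                                                 sg.ProcessOptions())
```

Output for this frame:

```
rendered reflections on detector: 272
EPV = 1.124e-03 A^-3, expected N_spot = 266.5
grid: 25 parameter pairs, 25 completed
best grid point (min_height, min_area) = (4.0, 6)
EPV of best model = 7.161e-04 A^-3, strong reflections (I/sigI > 5): 168
refined cell: 78.96 79.02 38.01 90.00 90.00 90.00
mosaic: D = 716 A, eta = 0.0000 rad
```

The generator placed 272 reflections on the detector, in line with the
expected count EPV·V_cell ≈ 266 for these mosaic parameters. The grid
search completed at all 25 threshold pairs; the selected result sits in
the smallest-EPV quarter with the most strong reflections, and its refined
cell reproduces the ground truth to ≈0.05%. The covering mosaic estimate
(D = 716 Å, η = 0) is wider/sharper than the generating values in the way
one-sided coverage estimates are — see `docs/methods.md`.

The same pipeline is available from the shell:

```
stillgrid generate --n 50 --blank-fraction 0.5 \
    --population 79,79,38,90,90,90,1.0 --seed 1 --out frames/
stillgrid process --input-dir frames/ --config run.cfg --out-dir run/
stillgrid cluster --run-dir run/ --threshold 5.0
```

where `run.cfg` is key=value text (`target_cell = 79 79 38 90 90 90`,
`height_median = 4`, `height_spread = 2`, ...).

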