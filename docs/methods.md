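# Methods

This note documents the models, numerical choices and limitations behind
stillgrid: what is computed, under which assumptions, and what the test
suite does and does not demonstrate about real data.

## Geometry and conventions

The lab frame puts the crystal at the origin with the incident beam along
+z and a flat detector normal to the beam at `distance` mm. Pixels are
addressed `(slow, fast)`, 0-based, centres at integer coordinates; `fast`
maps to +x and `slow` to +y. The Ewald sphere has radius 1/λ centred at
(0, 0, −1/λ); a reciprocal node `q = R·B·h` (with `B` the reciprocal basis
of the cell, columns a*, b*, c*, and `R` the crystal orientation)
diffracts when its signed sphere offset δ = |q + ẑ/λ| − 1/λ is small.
Cells are handled by gemmi (orthogonalization, volume, Niggli reduction).

## Spot-width model and the Ewald proximal volume

Reciprocal nodes carry a full-width diameter

    w(d) = 2/D + η/d

combining the block-size term (α ≃ 2/D, the diameter of the origin
reflection) with the rotational-spread term, the arc η swept at radius
1/d. The EPV integrates the shell |δ| ≤ w/2 over azimuth (closed form,
2π), radius (closed form, difference of cubes over 3) and polar angle τ
(Gauss–Legendre, default 256 nodes). The integrand is smooth, so 128
nodes already agree with 256 to better than 1e−6 relative; the node/weight
pairs are cached. τ runs from 0 (no inner resolution cut by default — an
optional low-resolution cut `d_max` exists on the prediction side) to
τ_L = 2 arcsin(λ/2d_L). The expected spot count is N = EPV · V_cell,
with one lattice node per reciprocal-cell volume 1/V_cell; cells are
taken in the primitive setting as given.

The unit tests check the quadrature against an independent Monte-Carlo
rejection volume (uniform sampling of the bounding shell-cone via the
r³/cos τ change of variables), and the generator/predictor spot counts
against N over ≥200 random orientations; both agree to ≲1%.

## Synthetic still generation

The generator emulates the variability that motivates per-image parameter
optimisation, with full ground truth:

- **Crystal**: orientation Haar-uniform on SO(3) (Shoemake's quaternion
  method); D and η uniform in configurable intervals. Defaults
  (D ∈ [300, 1000] Å, η ∈ [0.0005, 0.004] rad) span sharp to visibly
  mosaic stills.
- **Reflections**: every node with d ≥ d_min and |δ| ≤ w(d)/2; recorded
  intensity is the full intensity (lognormal across reflections) times a
  partiality factor exp(−δ²/2σ_r²) with FWHM equal to w — the literature
  specifies no partiality profile for this geometry, so a smooth monotone
  falloff tied to the same w as prediction keeps the two sides consistent.
- **Detector**: isotropic 2-D Gaussian spot footprints (σ_px per image,
  default range 0.9–2.8 px, from sharp cores to diffuse blobs), flat
  background (30–150 counts), Poisson noise on background + signal, gain
  1 count/photon, values clipped to the unsigned-16-bit range. Read
  noise, SASE spectra, polarization, absorption and panel gaps are out of
  scope.
- **Data sets**: a population mixture of cells (weights summing to 1)
  with relative length jitter (sd 0.2%), a blank fraction, and per-image
  seeds derived as `SeedSequence([master_seed, image_index])`, making
  re-runs byte-identical.
- **Default study geometry**: 256×256 px of 0.172 mm at 50 mm and
  λ = 1.3 Å, which places the d_L = 3.5 Å ring at ~114 px — a deliberately
  small detector that keeps a full pipeline run on one frame around a
  second.

Passing tests on these frames show the pipeline recovers models it can
represent exactly; they do not probe detector artefacts, non-Gaussian
profiles, ice rings or spectral bandwidth.

## Image pre-processing

Frames are stored in a 512-byte-header SMV dialect (beam centre in mm in
the header, pixels in memory; masks as `.mask` sidecars). Recentering
pads (never crops) the raster so the beam centre lands on the geometric
centre within half a pixel; padded pixels are zero and masked. The
beam-stop mask is a disc plus a rectangular support arm. Triage runs the
spot finder once at a single cheap parameter point (by default the
grid-search median) and discards frames with fewer than `min_spots`
(default 10) candidates; `min_spots = 0` bypasses triage.

## Spot finding

Background is a per-tile (32 px) median with sigma from 1.4826·MAD,
broadcast to pixel resolution — robust to sparse bright peaks, adequate
for smooth scatter backgrounds. Sigma is floored at one count: rasters
are integer, so sub-count thresholds are not meaningful on noise-free
backgrounds. A spot is a maximal 8-connected component above
`background + min_height·σ` with at least `min_area` pixels; centroids
are intensity-weighted, σ(I) is counting statistics
(√(Σcounts + Σσ_bg²)), and the list is sorted by summed intensity. The
background is estimated once per frame and shared by all grid points —
the two searched parameters do not interact with it.

## Indexing (known cell, unknown orientation)

Unknown-cell autoindexing is out of scope; the grid search needs only a
target-cell orientation search. Observed spots are back-projected onto
the Ewald sphere; the search looks for the rotation placing the most
observations on lattice nodes:

1. **Pre-filter**: components with area > 1.4× the per-frame median are
   overlapping reflections (within one still the footprint is constant up
   to the log of the amplitude) and are excluded; the brightest 40
   survivors are used.
2. **Coarse stage**: 80 000 quasi-uniform rotations (super-Fibonacci
   spiral on the quaternion sphere). Three batched, soft-weighted Kabsch
   sweeps (weights 1/(1+(e/tol')²), tol' = 2.5× the strict tolerance)
   with a per-candidate beam-centre update pull every candidate to its
   nearest joint optimum — this widens the scoring basin from ~1° to the
   covering radius of the grid, and tolerates a few pixels of beam-centre
   error.
3. **Polish**: the top 300 candidates are refined by iterated
   nearest-node assignment + Kabsch, in two variants (joint
   rotation+beam, and rotation-only from the nominal beam), keeping the
   solution indexing the most spots; the loop exits early once 90% of
   spots index.
4. **Acceptance**: success requires max(50% of spots, 10 spots) within
   2× the strict tolerance (strict = 0.15× the shortest reciprocal cell
   edge). The factor 2 admits wide-mosaic crystals whose genuine
   reflections sit up to w/2 off the sphere; a random rotation hits only
   ~5% of spots at that radius. The absolute floor keeps sparse frames
   from being "solved" by an aliased orientation.
5. **Escalation**: if nothing passes, one retry with a doubled rotation
   grid; `index_still` additionally retries when the subsequent
   refinement rejects the solution, and reports failure otherwise.

Within one image's grid search the crystal does not change, so the coarse
search runs at most three times (bootstrapped at the grid's middle point)
and every other grid point starts from the cached orientation with a
local polish only.

## Refinement

Bounded trust-region least squares (soft-L1 loss, f_scale 0.5 px) on
observed-minus-predicted spot positions over 8 parameters: a rotation
perturbation (3), relative scales of a, b, c (3) and a beam-centre shift
(2); cell angles stay at target (stills barely constrain them). Two
rounds with reassignment: the first at the relaxed tolerance (absorbing
beam error), the second strictly. A weak prior (sd 0.5% per axis) pins
the cell scale along the beam direction, which a single still does not
constrain. Guards: if the refit increases the rmsd, or indexes fewer
spots strictly than the input model (a symptom of jumping to a
pseudo-solution on an aliased lattice), the input model is returned
flagged unrefined.

## Mosaic-parameter estimation

A coverage criterion on a 2-D scan: for each η on a linear grid (81
values up to 0.02 rad) the smallest block-size term covering every
retained spot is 2/D = max_i(2|δ_i| − η/d_i); among the covering pairs
the one with the smallest EPV is returned (the natural total order for
"smallest pair", and exactly the quantity the selection step minimises).
Assignments use 3× the strict tolerance — a node a full half-width off
the sphere back-projects that far — and the worst 2% of coverage
constraints are trimmed against stray assignments. The criterion is
one-sided: detected spots rarely sit exactly at |δ| = w/2, so estimates
are biased small, and the (1/D, η) split along the feasible-region
boundary is only weakly determined on sparse frames (the width at high
resolution, which dominates the EPV, is determined much better than the
individual parameters). If no scanned pair covers, boundary values are
returned flagged saturated.

## Integration and filtering

Prediction enumerates all nodes with d ≥ d_L and |δ| ≤ w/2 under the
refined model. Integration is plain summation in a circular mask (radius
3 px default) with local-background subtraction; predictions off the
detector or touching masked pixels are dropped and tallied; reflections
further than w/4 from the sphere are flagged partial. The optional
Bravais filter Niggli-reduces the result's cell and checks the angle
pattern of the required lattice family (1° default) and, given a target
cell, sorted edge lengths within 5% relative.

## Selection and analytics

The two-step heuristic keeps ceil(25%·N) smallest-EPV results (ties:
more reflections, then grid order) and returns the one with the most
strong reflections, I/σ strictly above 5 (ties: smaller EPV, then grid
order) — every tie chain ends at the unique grid index, so the selection
is invariant under input permutation, which a 100-shuffle test verifies.

Cell clustering uses a documented simplification of the
Andrews–Bernstein metric: Euclidean distance on Niggli-reduced edge
lengths plus angle differences scaled by 0.5 Å/degree, with average
linkage cut at 5.0 distance units by default — chosen so 0.5% length
noise stays together while a doubled axis separates by hundreds of units.
The full G6/NCDist metric is a noted upgrade path. The per-image
limiting resolution reported in summaries is the highest-resolution
integrated reflection. The downstream-parameter stub lists the dominant
cluster's images, centroid cell and the lowest-symmetry Laue class of the
assigned Bravais lattice (e.g. P4/m rather than P4/mmm for tP): scaling
can merge upwards later, but over-merged symmetry cannot be undone.

## Problem sizes in the test suite

The suite runs everything at desk scale, as the package's own choice of
study conditions: EPV Monte-Carlo cross-checks at 10⁷ samples; spot-count
consistency over 200 orientations; parameter recovery on 50 noiseless
stills (with a 2 px beam-centre error injected); the grid-search
comparison on 50 heterogeneous frames with a 5×5 grid (heights 4±2,
areas 4±2) against the single median point — the canonical 15×21 grid
shape is verified exactly and separately; clustering on a 30-frame 60/40
two-form mixture; triage on an 80-frame, 90%-blank run.

## Known limitations

- Target-cell indexing only; no basis-vector autoindexing.
- The (1/D, η) decomposition is weakly identified per still (see above);
  EPV ranking, which is what selection needs, is much more stable.
- Cells from one still are poorly constrained along the beam; the weak
  target prior means per-image cells are partially regularised towards
  the target and clustering separability rests on in-plane axes.
- The simplified cell metric is not invariant under all lattice-character
  boundary cases the way NCDist is; for strongly sheared monoclinic or
  triclinic mixtures the threshold needs tuning.
- Integration uses fixed circular masks, not profile fitting; strongly
  elongated spots lose signal.
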