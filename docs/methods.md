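# Methods

`cortex3d` implements the computational pipeline for quantifying pyramidal
neurons in serial semi-thin sections of cortex: image plumbing (biopsy
planning, section detection, rigid stack alignment), segmentation and its
validation, 3D reconstruction with voxel morphometrics, pyramidal /
non-pyramidal classification, 2D stereology (nucleator), and spatial
statistics for columnar organization. A seeded synthetic-scene generator
stands in for the microscope so that every stage can be verified against
exact ground truth.

## Coordinates and units

`x` is the in-plane axis pointing toward the pial surface, `y` the
orthogonal in-plane axis, `z` the sectioning axis. All public coordinates,
spacings and measurements are in micrometres; voxel arrays are indexed
`[z, y, x]`. The default voxel is 0.272 × 0.272 × 0.8 μm — in-plane pixels
at the resolution of a ×20 slide scanner, axial spacing equal to the
section sampling interval.

## Synthetic scenes

**Point process.** Cell centroids follow a Poisson cylinder-cluster
process: minicolumn axes are a Poisson process in the y–z plane (simulated
on a window dilated by 4σ so edge columns contribute), each column carries
a Poisson number of cells spread uniformly over the whole x-extent and
displaced radially by an isotropic Gaussian of scale σ_r. A hardcore
minimum separation is enforced by dependent thinning in insertion order —
somata cannot overlap their centres. CSR patterns (binomial or Poisson) use
the same window conventions.

**Defaults as study conditions.** The defaults target the layer-III
marginals of a three-subject human study: pyramidal number density
28,155 mm⁻³ *after* thinning (column intensity 2.18 × 10⁻³ μm⁻², 3.2
cells/column over a 150 × 150 × 96 μm window, hardcore 12 μm, calibrated
over 150 simulations); log-normal pyramidal volumes with mean 795 μm³ and
σ_log = 0.9 (matching the reported within-subject spread); folded-normal
orientation angles about the pial axis with scale 36.4°, giving a mean
folded angle of ≈29°; 25% of somata emitted as small round (glial-like)
cells with log-normal volumes of mean 70 μm³.

**Shapes and the sphericity caveat.** Somata are prolate spheroids whose
aspect is solved (Brent's method on the closed-form spheroid surface area)
so the analytic sphericity matches a target of 0.85 ± 0.04. The study's
*measured* sphericity of ≈0.35 is unreachable for smooth ellipsoids at
somatic volumes — a 795 μm³ spheroid would need to be ~80 μm long to reach
ψ = 0.35; real cells get there through surface irregularity, which the
generator deliberately does not model. Consequently scene sphericities
(analytic ≈0.85, measured ≈0.75 after anisotropic voxelization) are
internally consistent but do not reproduce the real-tissue value, and
nothing downstream depends on them except the classifier's shape contrast.

**Rendering.** A voxel belongs to the nearest cell whose ellipsoid contains
its centre (ties to the lower id); overlap beyond a configurable fraction
is recorded as a scene warning. The intensity stack is two-valued (light
background 200, dark cells 80), blurred with a Gaussian PSF (σ = 0.4 μm)
and degraded with additive Gaussian noise (σ = 6), then quantized to
16-bit. Fixed seeds make scenes bit-identical.

**What passing tests do and do not show.** The generator reproduces
contrast, anisotropy, crowding and columnarity, but not dendrites, staining
gradients, wrinkles, section loss or registration error. Pipeline accuracy
on these scenes demonstrates correctness of the measurement chain, not
robustness to real histological artifacts — which is why mask ingestion
from any external segmenter is first-class.

## Segmentation and validation

The reference segmenter is classical: Gaussian smoothing (0.5 μm), global
Otsu threshold keeping dark voxels, in-plane binary opening, per-section
hole filling. A minimum contrast of 20 intensity units between the Otsu
classes guards against thresholding a unimodal (object-free) stack. This
is adequate only because synthetic contrast is controlled; on real tissue
a trained segmenter should supply the masks.

Pixelwise validation uses sensitivity TP/(TP+FN), precision TP/(TP+FP) and
their harmonic mean F1; reported values are rounded half-up to two
decimals. Objectwise validation matches 3D objects by centroid
containment: a reference centroid (rounded to its voxel) must fall inside
a predicted cell profile in the same section. Objects whose centroid lies
in the first/last three sections are excluded from the tally, since edge
objects have poorly estimated centroids.

## 3D reconstruction and morphometry

Connected components use 26-connectivity; components under 8 voxels are
artifacts; a validation mode drops objects spanning fewer than 4
consecutive sections (height < ~3 μm). Volume is voxel count × voxel
volume and centroids are voxel-centre means — exact given the labeling.
Surface area comes from a marching-cubes isosurface at level 0.5 on the
physically scaled grid, after smoothing the binary volume with a Gaussian
of 0.7 voxels: unsmoothed marching cubes inherits the voxel staircase,
inflating area by ~8% and depressing sphericity of a digitized ball to
0.92. With smoothing the ball measures ψ ≈ 0.99; the cost is rounded
corners on polyhedral objects (a cube reads ~0.86 instead of 0.806), which
is irrelevant for smooth somata and is the "mesh tolerance" used in tests.

The maximum Feret diameter is the largest pairwise distance over convex-
hull vertices of boundary-voxel centres (3D) or of per-section contour
polygons (2D), in physical μm. The orientation vector is the unit vector
along the 3D Feret axis; its angle to the pial axis is folded to [0°, 90°]
via |cos θ| because a caliper axis has no sign.

## Classification

The layer-III window is the interval between the two dominant peaks (layers
II and IV) of a Gaussian-kernel density of centroid x-coordinates, shrunk
by 10% of the inter-peak distance per side; a prominence floor of 25% of
the density maximum keeps sampling wiggles of a flat profile from posing as
layers, and failure falls back to manual bounds.

Pyramidal vs non-pyramidal: a 2-component full-covariance Gaussian mixture
(regularization 10⁻⁶) over raw (volume, sphericity), fitted only on cells
below the dataset-mean volume so that large pyramids do not dominate the
fit. Two numerical choices matter:

* **Initialization.** k-means initialization on raw features is dominated
  by the volume scale and reliably converges to a spurious volume-split
  local optimum; seeded `random_from_data` starts with 10 restarts find
  the higher-likelihood size/shape split (log-likelihood −194 vs −214 on a
  representative scene).
* **Degenerate subset.** When the below-mean subset has no two-component
  structure (BIC prefers one component), a forced hard split would label
  half of one tight cluster arbitrarily; instead the whole subset is taken
  as the non-pyramidal cluster. With real mixtures of small pyramids and
  glia the two-component fit wins and the rule is inactive.

The component with the lower mean volume (ties: lower mean sphericity) is
non-pyramidal; all above-mean cells are pyramidal. Oversized objects
(merged cells, vessels) are then flagged as outliers when their log maximum
Feret diameter (2D or 3D) exceeds the pyramidal mean + 3 SD — upper tail
only, population SD.

## Nucleator

Rays leave the profile centroid at a uniform-random start angle with
360°/n spacing (n = 5) and stop at the first boundary crossing, solved by
exact ray–segment intersection on the μm-coordinate polygon. The printed
estimator is used verbatim: Volume = (4/3)π l̄³ with the *cube of the
mean* length (Diameter = 2 l̄); classical nucleator theory integrates the
mean of cubed lengths and is available via `classical=True`. Two sampling
variants: rays on the largest profile only, or pooled over all profiles
(which underestimates, since off-equator profiles are smaller). The 3D
comparison value is the sphere-equivalent diameter (6V/π)^{1/3}.

## Cylindrical K-function and global envelopes

K̂_u(r, t) uses the translation edge correction — exact for box windows as
a product of 1D side overlaps — and the unbiased-under-CSR intensity-square
estimator n(n−1)/|W|². Pair contributions are accumulated once into an
(r, t) bin grid by a compiled kernel and cumulatively summed, so a 64 × 64
grid costs one O(n²) pass. Under CSR, K_u(r, t) = 2πr²t for every u.

The CSR null is a binomial process conditioned on the observed count
(Poisson optional). The extreme-rank-length (ERL) global envelope test
ranks the observed surface among `nsim` simulated ones by two-sided
pointwise ranks; ties between curves are refined by comparing ascending-
sorted rank vectors lexicographically. The 95% envelope is the pointwise
hull after discarding the ⌊α(nsim+1)⌋ most extreme curves, the p-value is
the conservative ERL rank fraction (a liberal/conservative interval is
reported), and each (r, t) cell is classified above/inside/below. Grids
default to 64 values on r ∈ [0, 25] μm and t ∈ [0, 80] μm (or fixed
t = 80); tests and the acceptance script use coarser grids (16–32 values)
and nsim = 199 — the ERL level is exact by exchangeability at any nsim, so
these sizes trade only resolution, not validity, for desk-scale runtimes.
2000–4000 simulations remain available by argument.

## Aggregation

Cross-subject summaries report the mean, the *population* SD (divisor n)
and CV = SD/mean. The population-SD convention is forced by the published
summary rows: the sample SD of the three subject volume means {867, 709,
808} is 79.8, while the printed value (65) is the population SD.

## Problem sizes in tests and the acceptance script

Scenes are 150 × 150 × 96 μm (≈80 cells, ≈3.7 × 10⁷ voxels); end-to-end
recovery uses 10–12 seeded scenes. Envelope calibration uses 300–500
replicates at n = 64 with nsim = 199; power uses 30–50 replicates of a
strong columnar fixture (σ_r = 5 μm, 20 cells/column, n ≈ 500). These
sizes are the package's chosen trade-off between Monte-Carlo resolution
and a practical desk run; all are arguments, not constants.

## Known limitations

* Touching cells are not split (no watershed); merged neighbours inside
  dense columns cost the end-to-end pipeline ~5% of cells, so recovered
  density is a slight underestimate.
* The rigid aligner optimizes Mattes mutual information with a
  multiresolution regular-step gradient descent; evolutionary optimizers
  with small initial radii stalled under physical-shift parameter scaling,
  so the implementation keeps the metric and the accuracy contract
  (0.2° / 1 px recovery) rather than a specific optimizer.
* Objectwise centroid matching tests membership in the centroid's own
  section profile; sub-voxel centroids are rounded to the nearest voxel.
* The homogeneity of point patterns is assumed, not tested; projection
  histograms are a diagnostic left to the user.
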