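# Methods

## Model and assumptions

Deformation tracking treats strain estimation as a sequence of 2D
deformable registrations. The end-diastolic frame is the undeformed
reference configuration; for every other frame `t` a displacement field
`u_t(X)` on reference coordinates is estimated such that
`I_t(X + u_t(X)) ≈ I_ref(X)`. This backward-sampling convention makes
`X + u_t(X)` the position at time `t` of the material point that sat at
`X` at end-diastole, so the fields are directly Lagrangian and the strain
follows from continuum mechanics without composing frame-to-frame
transforms (which would accumulate error):

- deformation gradient `F = I + ∂u/∂X` (dimensionless; derivatives taken
  in physical mm),
- Green–Lagrange strain `E = (FᵀF − I)/2`, symmetric, exactly zero for
  rigid motions and frame-indifferent,
- circumferential strain `Ecc = e_cᵀ E e_c` with `e_c` the local unit
  tangent of the LV-centered polar frame.

Assumptions: a single mid-ventricular short-axis slice with negligible
through-plane motion; a mask drawn once on the reference frame (Lagrangian
tracking makes per-frame masks unnecessary); intensity approximately
conserved along the motion (SSD similarity), which holds within a
normalized b-SSFP cine series.

`∂u/∂X` is evaluated analytically from the b-spline basis derivatives, not
by finite-differencing the dense field; a finite-difference evaluation
exists in the test suite purely as an oracle.

## Displacement model and optimization

`u` is a uniform cubic b-spline lattice in physical coordinates. The
lattice extends two control points beyond every image border so the
4-support tensor-product basis covers all pixels; constant and affine
fields are represented exactly (linear precision), which the partition-of-
unity and affine tests pin down.

The objective is mean SSD (per-pixel, so the regularization weight is
resolution independent) plus `λ ×` the bending energy — the image-domain
mean of the squared second derivatives of `u`. Bending energy is the
standard choice for b-spline registration; it is affine invariant and so
does not penalize bulk contraction or rotation. Frames are jointly
rescaled to [0, 1] by the series min/max before optimization so `λ` and
tolerances transfer across scanners.

Optimization is L-BFGS-B with the analytic gradient (verified against
central differences to ~1e−7 relative) over a Gaussian image pyramid with
downsampling factor 2 per level; the control spacing doubles with each
coarser level and solutions are transferred by sampling the coarse field
at the new control points and spline-prefiltering. Frames are processed
marching outward from the reference with warm starts from the temporally
adjacent solution. There is no randomized initialization anywhere: two
runs on identical inputs are bit-identical.

Inside the optimizer, out-of-frame samples use clamped edge extension
rather than a constant fill. A constant fill makes the objective
discontinuous the moment a border pixel crosses the frame edge, which
stalls quasi-Newton line searches; clamping keeps the objective continuous
while the public `warp_image` retains constant-fill semantics for exports.

### Defaults (and why)

| parameter | default | rationale |
|---|---|---|
| control spacing | 8 mm (finest level) | smooth over a ~10 mm wall yet able to express transmural gradients; sweeps from 3–12 mm changed peak-Ecc recovery by <0.005 strain |
| λ (bending weight) | 0.01 | with [0,1] intensities keeps the two objective terms within about two orders of magnitude on the phantom; recovery is insensitive over 0.001–0.1 |
| pyramid levels | 3 | 64-px images bottom out at 16 px, enough context for ~4 mm motions |
| iterations / level | 100 | L-BFGS typically converges in 30–60 |
| convergence | relative objective decrease < 1e−6 | scaled by the initial objective at each level |
| interpolation | cubic b-spline (mirror boundary) | smooth analytic image gradients for the optimizer; linear available |
| SSD support | full frame | blood-pool texture is unreliable but dark and low-weight; a mask-restricted mode exists and was tested (slightly worse Jacobian accuracy on the phantom, since the wall edge then constrains the field only one-sidedly) |

The LV center is the mask centroid (overridable). Segment arcs are 60°,
centered on `angular_offset + 60k`, closed on the lower bound; the offset
is a required anatomical input on clinical data (RV insertion) and 0 for
the phantom (anterior centered at image-up). Segment means are plain pixel
means over the transmural mask; the global mean is the pixel-count-
weighted mean of the segment means by construction. Peak strain is the
most negative value over the cycle — no systole detection. Pixels closer
than 1 nm to the center have no polar frame and would raise.

## The phantom: what it emulates, and what it does not

The synthetic dataset is a thick-walled annulus in 2D incompressible
contraction, `r(R, t) = sqrt(R² − R_endo² + r_endo(t)²)` with
`r_endo(t) = R_endo(1 − c(t))` and a `sin²` temporal profile, optionally
with a rigid rotation ("torsion"). This yields closed forms for
everything the method must measure: `λ_θ = r/R`, `Ecc = (λ_θ² − 1)/2`
with its transmural gradient (−18% at the endocardium vs −8% at the
epicardium at 20% contraction; transmural mean ≈ −11.6%), and det F = 1
exactly. The default geometry (64 px at 1.4 mm, 20 mm/30 mm radii, 20
frames, 20% peak endocardial contraction, 3 mm speckle correlation, 2%
additive noise) matches the scale of a mid-LV b-SSFP slice.

The wall texture is a random-phase sum of 128 cosines — an analytic
function of the *reference* coordinate — so frames are rendered by exact
advection through the inverse motion with no resampling error. Texture is
load-bearing: a flat annulus makes circumferential motion unobservable to
SSD (aperture problem). Rendering emulates an idealized band-limited
acquisition: each pixel averages a 3×3 subpixel grid of the advected
pattern (partial volume) and the image is blurred with a 2 mm-FWHM
Gaussian PSF before noise is added. Point sampling instead of this
produces aliasing (speckle near Nyquist, a one-pixel wall edge) that
intensity registration partly "tracks", tripling the displacement error;
no real scanner produces such images.

Not emulated: through-plane motion, papillary muscles, SSFP banding or any
k-space physics, coil shading, and realistic noise correlation. Passing on
the phantom therefore demonstrates correct mechanics and registration
behaviour under known ground truth — not clinical accuracy.

## Agreement statistics

Bland–Altman bias is the mean of paired differences, SD uses the n−1
denominator, limits of agreement are bias ± 1.96 SD. The ICC is ICC(2,1):
two-way random effects, absolute agreement, single measurement, computed
from the mean squares of the subject × rater table — the conventional
form for intra-/inter-observer repeats of a single reading. It matches
pingouin's ICC(A,1) to machine precision in the tests. Note that at
finite n, ICC(2,1) on columns with equal means and variances equals
`r / (1 − (1 − r)/n)`, not Pearson's r; the two coincide only as n grows
or at r = 1.

## Numerical choices and degenerate inputs

- All coordinates are (row, col) in mm, pixel (0,0) center at the origin;
  anisotropic spacing is honoured throughout.
- Cine intensities are never rescaled on load beyond DICOM
  slope/intercept; DICOM frames order by TriggerTime, falling back to
  InstanceNumber; any geometry mismatch in a series is a hard error, as is
  a non-positive spacing in a NIfTI header (validated on the raw header,
  since nibabel silently repairs it).
- A segment with no pixels is reported absent (NaN / null), never as zero
  strain. An empty mask, empty SSD support, < 2 frames, or a non-finite
  objective during optimization raise immediately, the latter naming the
  likely misconfiguration.
- Strain tables round-trip through CSV at 6 decimals; identical runs
  produce byte-identical CSVs.
- The run report echoes every resolved parameter needed to reproduce the
  run, the per-frame final objectives, and the fraction of mask pixels
  with det F > 0 (a warning is emitted below 99%).

## Problem sizes

The test-suite and acceptance-script phantoms use the default 64×64 /
20-frame geometry; a full tracking run takes roughly 10–25 s on one CPU,
the whole validation a few minutes. The CLI and determinism tests use a
32×32 / 4-frame miniature of the same annulus.

## Known limitations

- **Jacobian accuracy at the mask boundary.** On the contracting phantom
  the recovered fields keep |det F − 1| ≤ 0.05 for ~96% of *interior*
  myocardial pixels but only ~84% of all mask pixels: the one-pixel
  endocardial/epicardial boundary rings carry a systematic bias. The true
  motion has a derivative kink at the wall edge (incompressible wall,
  unconstrained cavity/background), which a globally smooth b-spline with
  a whole-image bending penalty cannot represent; the derivative at the
  edge is estimated one-sidedly and smoothed. Sweeps over control spacing
  (3–12 mm), λ (0.001–1), pyramid depth, and mask-restricted SSD all
  plateau at 84–86%. Global and segmental Ecc are unaffected (recovery
  error ≤ 0.002 strain) because the circumferential gradient is
  well-constrained by the speckle; only the transmural (radial) derivative
  at the boundary is biased. Strain at boundary pixels should be read with
  this in mind.
- Only mid-LV circumferential strain is produced: no longitudinal or
  radial outputs, no 3D, no torsion quantification.
- Segmental values depend on the anatomical anchor angle, which the
  package cannot infer from images.
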