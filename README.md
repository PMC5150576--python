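# cinestrain

Pixel-wise myocardial strain from short-axis cine MRI by **deformation
tracking**: intensity-based deformable registration of every cine frame to
the end-diastolic reference frame with a cubic b-spline free-form
deformation, followed by continuum-mechanics strain evaluation on the
myocardial mask.

It is aimed at cardiac imaging researchers who want circumferential strain
from routinely acquired balanced-SSFP cine stacks — without a bespoke
strain sequence — together with the synthetic phantoms and agreement
statistics needed to validate and reproduce such measurements.

## Method

Each target frame is warped onto the reference frame by minimizing

```
J(c) = (1/N) Σ_X [ I_ref(X) − I_t(X + u(X)) ]²  +  λ · B(u)
```

where the displacement field is a uniform cubic b-spline lattice

```
u(X) = Σ_ij c_ij B₃((x−o₁)/s − i) B₃((y−o₂)/s − j)
```

and `B(u)` is the thin-plate bending energy (mean squared second
derivatives of `u`; zero for any affine motion). Optimization is
limited-memory quasi-Newton with the analytic gradient over a 3-level
image pyramid, warm-started frame-to-frame; every field lives on reference
(Lagrangian) coordinates.

From the tracked field, at every myocardial pixel `X`:

```
F = I + ∂u/∂X            (deformation gradient, analytic b-spline derivatives)
E = (FᵀF − I)/2          (Green–Lagrange strain; zero for rigid motions)
Ecc = e_cᵀ E e_c         (circumferential component in the LV polar frame)
```

Ecc is averaged over the mask (global) and over six 60° segments
(anterior, antero-septal, infero-septal, inferior, infero-lateral,
antero-lateral); the peak is the most negative value across the cycle.
Reproducibility of paired measurements is summarized by Bland–Altman bias
and 95% limits of agreement, ICC(2,1) (two-way random effects, absolute
agreement, single measurement), and Pearson's r.

## Worked example

Render a contracting incompressible annulus phantom (64×64, 1.4 mm pixels,
10 mm wall, 20 frames, 20% peak endocardial contraction, speckle texture,
2% noise) and track it:

```bash
cinestrain phantom --out phantom-data --seed 3
cinestrain strain phantom-data/cine.nii.gz phantom-data/mask.nii.gz --out-dir run
```

`run/strain.csv` holds one row per frame (global Ecc then the six
segments, in percent) and `run/report.json` the resolved configuration and
summary. For this phantom the analytic transmural-mean peak Ecc is
−11.64%, and the run prints:

```
peak_global_Ecc_pct: -11.73
segments: anterior -11.87, antero-septal -12.36, infero-septal -11.70,
          inferior -12.20, infero-lateral -12.49, antero-lateral -12.00
```

i.e. the pipeline recovers the global peak within ~0.1% strain of ground
truth on a noisy phantom, in ~10 s on one CPU. Agreement statistics for
paired re-reads come from a two-column CSV:

```bash
cinestrain agreement reads.csv --plot ba.png
```

which reports bias, SD of differences, 95% limits of agreement, ICC(2,1)
and Pearson's r as JSON.

On clinical images the segment anchor (`--angular-offset`, degrees from
image-up) must be set from the RV insertion point; segmental — not
global — values depend on it.

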