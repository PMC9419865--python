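# epimech

Quantitative analysis of epithelial cell sheets grown on nanofibrous
culture substrates — and of the substrates themselves.

Engineered cell-culture inserts carrying a free-hanging electrospun
nanofiber membrane give keratinocytes and other epithelial cells a soft,
rough, ECM-like microenvironment, in contrast to flat, stiff tissue
culture polystyrene (TCPS). Assessing whether cells on such a membrane
really adopt a more tissue-like phenotype requires four quantitative
readouts, and `epimech` implements all of them as a tested pipeline:

1. **Cellular nanomechanics from AFM force curves.** Nanoindentation of
   live cells with a colloidal probe (sphere radius *R*) is modelled as
   adhesive elastic contact (JKR theory) plus a membrane-spring term.
   With reduced modulus *E\** = *E*/(1 − ν²) and contact radius *a*, the
   loading branch is

   *F*(*a*) = 4*E\**a³/(3*R*) − √(8π*w E\* a*³),
   δ(*a*) = *a*²/*R* − √(2π*w a*/*E\**),

   where *w* is the work of adhesion (pull-off force −(3/2)π*wR*). The
   measured force adds a membrane contribution *K*<sub>m</sub>·δ and a
   linear baseline. The fit recovers the Young's modulus *E*, membrane
   stiffness *K*<sub>m</sub>, their dimensionless ratio
   β = *K*<sub>m</sub>/(*E R*), the contact point, and adhesion
   energetics from the retract segment.
2. **Nanofiber membrane morphometry.** Fiber-diameter distribution
   (skeleton + Euclidean distance transform), projected pore sizes
   (background connected components), orientation randomness (annular
   integration of the 2D FFT power spectrum, doubled-angle resultant
   *S* ∈ [0, 1]), and RMS roughness R<sub>q</sub> after plane removal.
3. **Cell and nucleus morphometrics.** Two-channel (DAPI / F-actin)
   segmentation by seeded watershed; per-cell area, eccentricity,
   circularity 4π*A*/*P*², nuclear-to-cell area ratio, internuclear
   spacing, cell height from topography or z-stacks, and per-cell
   junction-protein intensity fold changes with bootstrap CIs.
4. **Scratch-wound kinetics.** Texture-variance wound segmentation,
   wound-area fraction vs *t* = 0, closure time, and per-front migration
   velocity.

Every input modality has a synthetic generator with exact per-object
ground truth (`epimech.synthetic`), so the whole pipeline is testable
end-to-end without any instrument data.

## Worked example

Fit the contact model to a synthetic junction indentation curve
(*E* = 30.73 Pa, β = 1.37, probe radius 2.6 µm, light force noise):

```python
from epimech import synthetic, ContactModel
from epimech.datatypes import ContactModelParams

params = ContactModelParams(E=30.73, R=2.6e-6, w=1e-5,
                            K_m=1.37 * 30.73 * 2.6e-6, z0=1.0)
curve, truth = synthetic.gen_force_curve(params, z_range=1.4, n_points=500,
                                         noise_sd=5e-4, seed=42,
                                         region="junction", substrate_label="NCCI")
res = ContactModel(curve).fit()
print(res.summary())
```

```
Contact-model fit (JKR + membrane spring)
=============================================
  sample           sim-42
  region/substrate junction/NCCI
  converged        True
  E       (Pa)     31.2117
  w       (J/m^2)  9.97648e-06
  K_m     (N/m)    0.00010854
  beta = K_m/(E R) 1.33752
  z0      (um)     1.0016
  baseline (nN)    -3.892e-05 + 7.067e-05 z
  rmse    (nN)     0.0004791
  max indent (um)  0.3984
  w_pulloff (J/m^2) 3.88941e-06
  hysteresis (J)    9.90691e-17
```

The fitted modulus (31.2 Pa) and membrane-to-bulk ratio (1.34) recover
the generating values (30.73 Pa, 1.37) to within the noise; `rmse` is at
the injected noise floor and `z0` is found within 2 nm of the true
contact point. On a noise-free curve the same call returns the generator
parameters to machine precision.

The other stages follow the same pattern — generate (or load), analyse,
summarise:

```python
from epimech import synthetic
from epimech.fibers import segment_fibers, fiber_diameters

img, truth = synthetic.gen_fiber_image(n_fibers=100, diameter_mean=622,
                                       diameter_sd=31, pixel_size=50,
                                       image_size=1024, seed=21)
d = fiber_diameters(segment_fibers(img), pixel_size=50)
print(f"{d['mean_nm']:.0f} nm from {d['n_fibril_pixels']} skeleton samples")
# 610 nm from 14262 skeleton samples
```

A CLI mirrors the library (`epimech simulate | fit-afm | fibers | cells |
wound | stats | run | report`); `epimech run` executes the full synthetic
end-to-end pipeline and writes per-stage CSV/JSON outputs plus a
consolidated report that is byte-identical across runs with the same
config and seed.

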