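# cardiohomog

Image-based estimation of cardiac tissue composition and extracellular
conductivity tensors from 3D confocal-style volumes.

## The problem

Bidomain and multidomain simulations of cardiac electrical conduction
need extracellular conductivity tensors σ_e, but direct electrode
measurements at the sub-millimetre scale are essentially unavailable —
especially for diseased tissue such as the infarct border zone.  An
alternative is to *compute* them from microscopy: segment a 3D
confocal stack of labelled myocardium (wheat germ agglutinin for
matrix/glycocalyx, DAPI for nuclei, Cx43, α-SMA and vimentin for cell
typing) into tissue domains, treat the extracellular space as the only
conductive phase, and homogenize.

`cardiohomog` implements that pipeline for voxelized volumes:

* **phantom** — a synthetic tissue generator (myocyte rods in a
  staggered brick-wall packing, laminae separated by interlaminar
  clefts, capillaries, fibroblasts/myofibroblasts) with steerable
  volume-fraction targets and a pseudo-confocal five-channel renderer
  (PSF blur, depth attenuation, noise).  Because no real image data are
  bundled, every downstream stage is exercised and validated on these
  phantoms.
* **preprocess** — Gaussian/mean denoising, depth-attenuation
  correction g(z) = exp(−r·z)·(1 + a·z), Richardson–Lucy deconvolution,
  scar-distance intensity profiles.
* **segment** — watershed myocyte instances on the WGA channel,
  capillary tubes, nucleus-anchored fibroblast/myofibroblast
  classification (vimentin±/α-SMA±, not vessel-proximal), extracellular
  residual, low-WGA interlaminar cleft detection, and the
  WGA `mode + 1·SD` interface refinement of the conductive mask.
* **metrics** — volume fractions per domain and the fibrosis degree

      F = (V_e − V_cleft + V_fibro + V_myofibro)_region
        − (V_e − V_cleft + V_fibro + V_myofibro)_control

* **conduct** — the homogenization core: conductive mask = extracellular
  ∪ cleft ∪ interface addition at σ_bulk = 2 S/m; ±1 V Dirichlet
  electrodes, no-flux Neumann elsewhere; 7-point finite-difference
  Laplace solve (conjugate gradients, relative residual < 1e-10);
  σ_e,x = J_e,x / E_e,x for x ∈ {l, t, n} (longitudinal = fiber,
  transverse = in cleft plane, normal = cleft normal); PCA-based axis
  alignment; rectangular-block analytic verification.
* **stats** — unpaired two-tailed t-tests with Holm–Bonferroni
  correction, simple/multiple OLS regression with R², and the
  composition-vs-conductivity regression study.

## Worked example

Generate an infarct border-zone phantom, segment its rendered channel
stack, and compute composition and conductivities:

```python
from cardiohomog.phantom import PhantomSpec, REGION1_FRACTIONS, \
    generate_labels, render_channels
from cardiohomog.segment import SegmentationParams, segment_volume
from cardiohomog.metrics import VolumeFractions, volume_fractions, fibrosis_degree
from cardiohomog.conduct import conductivity_tensor

spec = PhantomSpec(grid_shape=(96, 96, 128), voxel_size=400.0,
                   target_fractions=REGION1_FRACTIONS, seed=1)
truth = generate_labels(spec)
stack = render_channels(truth, seed=1)
seg = segment_volume(stack, SegmentationParams(voxel_size=400.0,
                                               min_myocyte_volume=200.0))
vf = volume_fractions(seg)
print(vf.as_dict())
control = VolumeFractions(V_myo=65.03, V_e=24.68, V_cleft=3.95,
                          V_vessel=7.71, V_fibro=2.48, V_myofibro=0.09)
print(fibrosis_degree(vf, control).degree)
t = conductivity_tensor(seg, rtol=1e-10)
print(t.sigma_l, t.sigma_t, t.sigma_n)
```

prints (values from this exact configuration):

```
{'V_myo': 46.92, 'V_e': 40.43, 'V_cleft': 5.26, 'V_vessel': 3.67,
 'V_fibro': 4.96, 'V_myofibro': 4.01}
20.85
0.785 0.384 0.357
```

The segmentation recovers the generator's border-zone composition
(myocytes ≈ 47 %, extracellular ≈ 40 % of which ≈ 5 points are
interlaminar cleft), the fibrosis degree relative to the control
reference is ≈ 21 percentage points, and the homogenized tensor is
anisotropic with σ_l > σ_t ≥ σ_n — the normal component is smallest
because current crossing the laminae must thread the staggered
interstitial network, while the in-plane clefts boost the longitudinal
and transverse components.

A command-line interface mirrors the library
(`cardiohomog phantom|preprocess|segment|metrics|tensor|verify|run`),
e.g. `cardiohomog run --config pipeline.yaml --out results/` for the
end-to-end phantom → statistics pipeline with a reproducibility
manifest.

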