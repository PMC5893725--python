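# Methods

This note records the models, numerical choices and design decisions
behind `cardiohomog`, and what the synthetic phantoms do and do not
establish about real tissue.

## Homogenization model

The extracellular space is modelled as the sole conductive phase with a
uniform bulk conductivity σ_bulk = 2 S/m; myocytes, vessels,
fibroblasts and myofibroblasts are perfect insulators at this scale
(their membranes, and for capillaries the endothelial wall, bar
extracellular current).  On a voxel grid the conductive set is
extracellular ∪ interlaminar cleft ∪ the WGA-derived interface
addition, and the steady-state potential obeys ∇·(σ∇φ) = 0.

**Discretization.** Cell-centred 7-point finite differences with face
conductivities equal to the harmonic mean of the two adjacent voxel
conductivities.  With a binary medium this makes every
conductive/non-conductive face a zero-flux internal boundary without
explicit bookkeeping, and the exterior surfaces carry no-flux Neumann
conditions by construction (absent neighbours contribute no term).

**Electrodes.** Conductive voxels in the first and last slice along the
field direction are fixed at +1 V and −1 V.  The electrode separation is
(slices − 1)·voxel_size, which makes a uniform fully conductive model
return exactly σ_bulk — the identity the acceptance script recomputes.
Conductive components that do not touch both electrode faces carry no
steady current; they are removed before assembly (they would only
degrade conditioning).  If no component touches both faces the model
does not percolate and the conductivity is reported as exactly zero
with an explicit flag.

**Solver.** The reduced system over interior unknowns is symmetric
positive definite and is solved by conjugate gradients from a linear
interpolation between the electrode potentials (exact for prismatic
geometries, a good start otherwise), to a relative residual of the
original system below 1e-10 (configurable).  Any preconditioned Krylov
or multigrid solver reaching that residual would be interchangeable;
plain CG is adequate at the grid sizes used here (up to ~10⁶ voxels).

**Averaging.** For every plane of faces perpendicular to the field, the
total face current is divided by the *total* plane area (conductive and
non-conductive alike); σ_x = J_mean / E with E = 2 V / separation.  The
full-area convention makes the closed forms exact: a uniform model
returns σ_bulk, a prismatic slab of cross-section fraction f returns
f·σ_bulk, and disjoint spanning blocks add their fractions — the basis
of the rectangular-block verification, which reproduces the analytic
values to ≲1e-8 at solver rtol 1e-10.  Discrete conservation (equal
current through every plane, to 1e-6 relative) is checked on every
evaluation.

**Alignment.** Before homogenization, the fiber axis is estimated as
the mean first principal axis of the 10 largest myocyte instances and
the cleft-plane normal as the smallest principal axis of the largest
cleft; if either deviates from the (y, z) reference axes by more than
5°, the volume is rigidly rotated (nearest-neighbour resampling for
labels) and cropped to the largest interior box free of undefined
voxels (greedy face-trimming).

## Segmentation

All thresholds are histogram-derived so the chain has no
intensity-scale magic numbers:

* A three-class multi-Otsu split of the WGA histogram separates dark
  structure interiors (myocytes, clefts, lumina, cell bodies), an
  intermediate interface class (membrane-adjacent signal, vessel
  walls), and the bright extracellular matrix/glycocalyx.  Watershed
  seeds are connected cores of the dark class after a 0.4 μm distance-
  transform erosion; instances grow through the interface class but
  never into the matrix.
* Myocyte instances must exceed a minimum volume (500 μm³ by default;
  a few hundred μm³ on small test windows) **and** a minimum local
  half-thickness (3 μm).  The thickness criterion is what separates
  myocytes from planar clefts (~1–3 μm half-thickness) and capillary
  lumina; rejected candidates fall back into the extracellular
  residual, as do all unclaimed voxels.
* Capillaries are elongated dark tubes: half-thickness ≤ 1.6 × the
  nominal capillary radius, limited and roughly isotropic cross-section
  (a flat ribbon with min/max cross extent < 0.4 is not a lumen — this
  rejects cleft–corridor junction strips at coarse voxel sizes), length
  ≥ max(12 μm, 2.5 × cross extent), and — when the vimentin channel is
  available — not vimentin-positive throughout (an elongated fibroblast
  body is; a lumen is vimentin-dim).  An optional dilation absorbs the
  wall; the default detection already includes wall voxels below the
  matrix threshold.
* Fibroblast/myofibroblast classification anchors on DAPI nuclei
  (mode + k·SD threshold, k = 1, minimum 4 μm³), excluding nuclei
  inside myocytes or within 2 μm of a vessel ("proximal" is not
  quantified in the field's usage; 2 μm covers a pericyte/endothelial
  layer).  Each surviving nucleus claims its surrounding
  vimentin-positive connected region; a region with ≥10 % α-SMA-positive
  voxels is a myofibroblast, otherwise a fibroblast.
* Clefts are connected extracellular components with WGA below the
  extracellular-space histogram mode, at least 50 μm³, grown by one
  voxel inside the residual to re-attach the WGA-bright glycocalyx
  shell that lines the adjacent myocyte surfaces (the physical cleft
  includes its bounding shell; without this step the detected slab is
  systematically two voxels thinner than the true one).
* The conductivity interface addition thresholds WGA at
  mode + 1·SD (256-bin histogram over the observed range) inside the
  myocyte mask, re-admitting membrane-adjacent and t-tubule signal to
  the conductive phase.

## Synthetic phantoms

The generator emulates the geometry the analysis assumes, not confocal
optics:

* **Myocytes** are rectangular rods along y, 14 μm tall and nominally
  20 μm wide, staggered half a lattice period per layer (brick-wall
  packing — the voxel analogue of hexagonal rod packing).  The lattice
  period (width + interstitial) is fixed; volume-fraction steering
  shrinks the brick width about fixed centres by bisection against
  direct voxel counts.  A quarter-voxel lattice offset staggers the two
  brick edges across voxel centres, halving the steering quantization
  on coarse grids.
* **Laminae and clefts.** Every `layers_per_lamina` ∈ {3,4,5} layers, a
  planar cleft slab normal to z is carved at spacing
  n·14 + (n−1)·3 μm — 48, 65, 82 μm — with one plane anchored at the
  window centre so small windows contain a cleft.  The slab thickness
  is set from the cleft target and the number of planes in the window.
* **Capillaries** are cylinders along y covering 80 % of the window
  length with a random offset.  Finite segments matter: rods crossing
  the whole window would dam the interstitial sheets and artificially
  zero the normal conductivity.  Radius and count are solved from the
  vessel fraction target.  Placement prefers interstitial corridor
  centrelines and avoids cleft slabs.
* **Fibroblasts/myofibroblasts** are ellipsoids (semi-axes 2.5, 5, 2 μm,
  rescaled to hit the target with an integer cell count) with a DAPI
  nucleus core, placed in corridors ≥ 4 μm clear of vessel surfaces so
  their nuclei are unambiguously non-vessel-associated; different cell
  types keep a clear mutual gap so marker classification sees distinct
  bodies, and shortfalls from carving overlap are topped up with extra
  cells and a re-steer.  Steering is verified against a ±2 percentage-
  point tolerance; infeasible targets raise an error carrying the
  achieved-vs-target table.
* **Rendering** assigns a documented intensity level per domain and
  channel, then overlays the structured signals: a 1-voxel WGA-bright
  glycocalyx shell on every myocyte surface with a 1-voxel interface
  bleed just inside it, vessel walls (WGA/α-SMA/vimentin) with
  perivascular vimentin and wall nuclei, nucleus spheres, and Cx43
  puncta.  Optional anisotropic Gaussian PSF blur (z wider than x,y),
  exponential depth attenuation and additive/shot noise complete the
  forward model.  Everything is deterministic per seed.

**What phantom results do and do not show.**  Noiseless, blur-free
round trips (generation → rendering → segmentation → measurement,
recovering all fractions within ±2 points and all domains at Jaccard
≥ 0.9 at 200 nm voxels) validate the *logic* of the chain — thresholds,
shape criteria, bookkeeping — under geometry that satisfies the
pipeline's assumptions exactly.  They do not demonstrate robustness to
real confocal physics: irregular myocyte cross-sections, variable
staining, anisotropic blur interacting with thin clefts, or manual
corrections.  The preprocessing operators are validated separately
against closed forms (sampled Gaussian response, exact attenuation
inverses, Richardson–Lucy error decrease on blurred fixtures).

## Phantom ensembles and regression properties

The conduction ensemble spans V_e ≈ 20–45 % with cells and vessels
absent.  The non-cleft extracellular fraction rises linearly across the
ensemble while the cleft fraction follows a jittered-but-monotone ramp
(2–6 %).  Because the lattice is fixed and both extracellular
parameters only grow, consecutive phantoms have nested conductive
sets, so the monotone increase of every σ component with V_e is a
theorem of the variational formulation rather than a sampled
observation; the jitter decorrelates V_cleft from V_e − V_cleft enough
that V_e out-predicts V_cleft alone in the regression comparison.  In
this geometry every extracellular structure is prismatic along the
fiber axis, so σ_l equals the Wiener bound 2·(conductive fraction)
exactly — real tissue falls below it; the transverse and normal
components are bottlenecked by the bed joints/clefts and the staggered
corridor network respectively, reproducing the σ_l > σ_t > σ_n ordering.

## Statistics

Group comparisons use unpaired two-tailed t-tests (Student's pooled
variance by default, Welch optional) under Holm–Bonferroni step-down
correction at α = 0.05; the comparison family is caller-defined since
region-vs-control and region-pair contrasts may both be of interest.
Degenerate zero-variance samples return p = 1 (equal means) or p → 0
(unequal), flagged by an infinite statistic.  Regressions are ordinary
least squares; R² = 1 − SS_res/SS_tot, with the convention R² = 0 for a
constant response.  Group-level fibrosis is computed per sample and
then averaged (mean ± SD); evaluating the fibrosis formula directly on
group-mean fractions gives slightly different values (21.12 vs 21.21
points for the border zone against the bundled reference profiles) —
the difference is purely the order of averaging, and both evaluations
are provided.

## Numerical and testing choices

* Problem sizes: round-trip validation uses 160×128×256 voxels at
  200 nm (32×25.6×51.2 μm, one cleft plane); the conduction ensemble
  uses 72×64×120 voxels at 400 nm; oracle-equivalence checks solve
  dense systems up to 16³.  These sizes keep the full suite to a few
  minutes while leaving every mechanism (staggered packing, clefts,
  vessels, cells) represented.
* Gaussian filtering uses a truncation radius of 6σ so the discrete
  kernel matches the sampled normalized Gaussian to <1e-6.
* Richardson–Lucy uses reflective padding with FFT convolution: no edge
  ringing on thin stacks and total-intensity conservation to ~0.1 %.
* The attenuation model g(z) = exp(−r·z)(1 + a·z) composes depth decay
  and the linear laser ramp multiplicatively; a per-slice fitted gain
  (normalized mean slice intensity) is the model-free fallback, and
  channels with no signal in the reference slice are passed through
  with a warning.
* TIFF volumes always travel with a JSON sidecar (voxel size, axis
  convention, label dictionary); reading without one is refused rather
  than guessed.

## Known limitations

* Brick-wall myocytes have flat faces and right angles; watershed
  behaviour on rounded, irregular cross-sections is not exercised.
* The cleft model is strictly planar and axis-aligned before rotation;
  undulating or branching clefts are out of scope.
* σ_l attains the Wiener bound in phantoms (perfect prisms), so
  phantom conductivities are upper bounds relative to real tissue at
  the same V_e.
* Intracellular conductivities are not computed; the model treats all
  cells as insulators and says nothing about gap-junctional coupling.
* Segmentation parameters default to values tuned for the rendering
  model's intensity classes; real data would require revisiting the
  histogram-based thresholds (they are all exposed in
  `SegmentationParams`).
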