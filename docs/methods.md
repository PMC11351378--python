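# Methods

## The constitutive model

The bundle is an ensemble of `N0` linear-elastic fibers that engage
progressively under stretch.  Three ingredients define the stress:

1. **Recruitment.**  The stretch `ξ` at which a fiber becomes taut follows
   a Weibull density `R(ξ)` with shape `β` (dimensionless), scale `δ`
   (stretch units) and onset `γ` (default 1: nothing carries load below the
   rest length).  `β < 1` gives a monotone-decreasing recruitment rate,
   `β = 1` a constant rate, `β > 1` a rate that rises to an interior
   maximum and falls — the shape regimes have direct physical readings and
   are asserted in the test suite.
2. **Orientation.**  A fiber at inclination `θ` to the loading axis is
   stretched along its own axis by `λ cos θ` and contributes the projected
   component of its force; azimuthal symmetry is assumed (`φ` uniform).
   `P(θ, ξ)` is the orientation density over the hemisphere, normalised
   with the solid-angle factor: `∫₀^{2π}∫₀^{π/2} P sinθ dθ dφ = 1`.  Its
   dependence on the recruitment stretch expresses reorientation under
   load.
3. **Volume weighting.**  Each orientation's contribution is weighted by
   the volume fraction `ν(ξ, θ)` of fibers at that orientation (fiber
   cross-section over bundle cross-section equals fiber volume over bundle
   volume, with the current bundle volume `V_tot = A_tot · L0 · λ`).

The stress integral (engineering stress, MPa) is

    σ(λ) = 2π N0 E_f ∫₀^{π/2} ∫_{max(1,γ)}^{λcosθ}
           R(ξ) P(θ,ξ) (λcosθ − ξ) ν(ξ,θ) cos²θ sinθ dξ dθ,

with the inner integral empty whenever `λ cos θ ≤ max(1, γ)`.  Two
consequences are tested explicitly: `σ(1) = 0` exactly for any admissible
inputs, and `σ` is linear in both `E_f` and `N0`, so only their product is
identifiable.  `N0` is therefore fixed at 1 and the fitted `E_f` reported
as an effective fiber modulus.

### Quadrature

The double integral is evaluated by composite trapezoid rules on uniform
grids, by default 181 θ-nodes × 401 ξ-nodes.  On the seven-level strain
grid this changes `σ(1.08)` by less than 0.1 % when both steps are halved,
for both published parameter sets; the convergence check is part of the
suite.  All parameter-independent factors (`P`, `ν`, the lever arm, the
geometric weights) are precomputed once per stretch grid
(`model.QuadraturePlan`), so a parameter evaluation during fitting is a
single vectorised pass over the Weibull density (~1.5 ms); this is what
makes multi-start fitting cheap.  For `β < 1` the density has an integrable
singularity at `ξ → γ⁺`; the lower quadrature node of each inner panel is
shifted a quarter-step into the support (an open rule at the edge), which
keeps the integral finite and convergent at order `h^β` near the edge.

As `δ → 0` the model approaches the fully recruited limit
`σ → N0 E_f ν ∫ (λcosθ − 1)₊ cos²θ sinθ dθ`.  The approach is first order
in `δ`: the mean recruitment offset `δ·Γ(1+1/β)` (at least `0.886·δ`, for
any `β`) is lost from every fiber's stretch, so at `δ = 10⁻³` the relative
gap is still ~17 % at 1 % strain and ~2 % at 8 % strain.  The suite
verifies the linear convergence and the limit itself at `δ ≲ 2×10⁻⁵`.

### Empirical distributions

`P` is a per-strain histogram of fiber inclinations on 9 equal-width bins
over [0°, 90°] (the bin count is configurable), weighted so the discrete
solid-angle normalisation holds exactly by construction.  `ν` is the
per-bin fiber volume divided by `V_tot`.  Inside the stress integral both
are bin-constant in `θ` and piecewise-linear in `ξ` between measured
strain levels, with constant extrapolation outside the measured range —
the measurements say nothing beyond the scanned window, so no trend is
invented.  Skewness uses the moment coefficient `g1 = m3/m2^{3/2}` (the
common default of image-analysis software; the bias-adjusted `G1` is
available via a flag), and the across-strain count variability is a CV
with the sample standard deviation (ddof = 1).

## Fitting

The cost is the unweighted mean squared deviation between the model and
the measured stresses.  The optimiser is a seeded multi-start (default 16
starts): each start runs a bounded Nelder–Mead simplex in log-parameter
space, then a bounded trust-region least-squares polish with numeric
Jacobian; the best final cost wins and every start's trajectory is
reported.  The polish stage exists because the simplex alone needs very
tight tolerances (and an order of magnitude more time) to localise the
minimum of this shallow cost surface to the precision that noiseless
parameter recovery demands.  Default bounds: `E_f ∈ [10⁻³, 10⁴]` MPa
(spanning the two orders of magnitude separating healthy from degraded
fiber moduli), `β ∈ [0.1, 20]`, `δ ∈ [10⁻³, 2]`.  `γ` and `N0` stay fixed
during fitting.

**Identifiability.**  Noiseless curves pin all three parameters: recovery
from perturbed starts returns the generating values to ~10⁻¹² relative
error, and from ≥ 80 % of random starts within decade-wide bounds.  Under
realistic noise the picture changes qualitatively: with 1 % multiplicative
noise on the seven-point grid, the first-order (Fisher) standard
deviations of the log-parameters at the healthy-sample truth are ≈ 1.1 for
`E_f`, ≈ 0.6 for `δ`, and ≈ 0.006 for `β`.  The curve determines the
recruitment shape sharply but leaves a long flat valley in the
modulus–scale plane; fits along that valley are all excellent (`R²`
≈ 0.9999).  The test suite therefore asserts shape recovery and
goodness-of-fit under noise, not modulus recovery, and fitted `E_f` values
from sparse noisy curves should be interpreted with this degeneracy in
mind.

## Segmentation chain

Volumes are cropped to a region of interest along the loading axis
(protocol: 4 mm starting 1 mm above the fixed clamp), binarised with
Niblack local thresholding, separated into instances, and measured.

* **Niblack.**  Foreground iff intensity > local mean + `k` × local SD over
  a cubic window (half-width 15 voxels by default, exceeding the ~12-voxel
  fiber diameter; windows are clipped at the borders, statistics use only
  in-volume voxels).  `k` defaults to 0.2 but is strongly
  contrast-dependent: in a homogeneous noisy matrix the expected
  false-positive fraction is `Φ(−k)` regardless of the noise level, and at
  26-connectivity anything above ~10 % percolates into a single component.
  The phantom analyses use `k = 1.5` plus removal of components below a
  fiber-scale voxel count (`remove_speckle`), which keeps false foreground
  below the percolation threshold while retaining ~100 % of fiber voxels.
* **Separation.**  Euclidean distance transform of the foreground;
  H-maxima suppression (depth `h`, default 2 voxels) of the — optionally
  Gaussian-smoothed (σ = 1 voxel by default, stabilising the ridge of
  noisy-boundary cylinders) — relief yields markers; marker-controlled
  watershed of the negated distance map, restricted to the foreground at
  26-connectivity, labels every foreground voxel.  Components whose relief
  is entirely shallower than `h` become their own markers, so labelling is
  total for any `h`.
* **Metrics.**  Volume = voxel count × voxel size³; orientation = principal
  eigenvector of the second central moment tensor of the object's voxel
  coordinates, with `θ` folded into [0°, 90°] (axes are undirected) and the
  transverse azimuth `φ` into [0°, 180°); mean cross-sectional area = mean
  over occupied transverse slices.  Objects with < 3 voxels or a
  (near-)isotropic moment tensor are flagged degenerate.
* **Artifact rule.**  Objects collapsed onto the transverse plane
  (`θ = 90°` *and* `φ = 0°` within a 1° tolerance — both conditions
  required), non-positive volumes and degenerate objects are excluded; the
  surviving fiber fraction is reported.

On a ground-truth phantom with 20 non-overlapping fibers at 256³ this
chain matches every fiber one-to-one with inclination errors well under a
degree, and per-object voxel counts conserve the foreground exactly.

## Synthetic data: what it emulates, and what it does not

The phantom generator reproduces the imaging conditions the pipeline is
designed for: 9 µm voxels, 0–255 gray levels, background near 0, a
non-fibrous matrix only somewhat dimmer than the fibers (defaults 150 vs
200, noise SD 5), fiber radii 0.035–0.055 mm around the ~111 µm average
fiber thickness, orientations concentrated near the loading axis, and a
matrix cylinder containing the fibers (bundles are fibers *in* matrix, so
placement is confined to it).  For segmentation benchmarks the matrix is
widened to fill the transverse field of view, emulating an ROI cropped
inside the specimen — windows straddling a sharp specimen/air boundary
otherwise inflate the local threshold above the fiber intensity, a
real artifact the original protocol avoided the same way (by cropping
centrally).

Not emulated: X-ray physics (beam hardening, contrast-agent diffusion
gradients, clamp metal artifacts), fiber crimp and curvature (fibers are
straight cylinders), sub-fiber hierarchy, and viscoelasticity (the
protocol handles relaxation experimentally by waiting between strain
steps).  Passing phantom tests therefore demonstrates correctness of the
algorithms under the stated contrast/noise model, not robustness to every
acquisition artifact of real micro-CT.

Strain series are generated by incompressible affine reorientation,
`tan θ' = tan θ / λ^{3/2}`, applied to a base population — the standard
parameter-free kinematic stand-in for the alignment trend observed in
loaded fibrous tissue.  Real reorientation data would be needed to
calibrate anything richer; the exponent is a model choice, not a measured
quantity.  Load curves are forward-model evaluations with optional
additive (MPa) and multiplicative (fractional) Gaussian noise; with both
zero they reproduce `sigma_curve` bit-for-bit.

Every generator is deterministic under a fixed seed, and the pipeline
propagates one top-level seed to all stochastic stages, making full runs
byte-identical.

## Default parameters at a glance

| parameter | default | units | rationale |
|---|---|---|---|
| strain grid | 1.00…1.08 (7 levels) | — | the tensioning protocol's ε = 0–8 % |
| `γ` | 1 | stretch | no recruitment below rest length |
| `N0` | 1 | — | only `N0·E_f` identifiable |
| θ-nodes × ξ-nodes | 181 × 401 | — | < 0.1 % change on halving steps |
| θ-bins | 9 over [0°, 90°] | — | granularity of per-strain histograms |
| Niblack window radius | 15 | voxels | exceeds the fiber diameter |
| Niblack `k` | 0.2 | — | contrast-dependent; 1.5 for the phantom regime |
| H-maxima depth `h` | 2 | voxels | below fiber radii, above ridge noise |
| distance-map smoothing | 1 | voxels | stabilises cylinder ridges |
| artifact angle tolerance | 1 | degrees | exact equality is meaningless on estimates |
| voxel size | 0.009 | mm | imaging protocol |
| fit starts | 16 | — | non-convex, shallow cost surface |

## Known limitations

* The modulus–scale degeneracy under noise (above) is intrinsic to fitting
  three parameters to a short toe-region curve; richer strain grids or
  independent `δ` constraints would be needed to break it.
* Orientation estimation by the moment tensor assumes roughly straight,
  elongated objects; strongly curved or branching fibers bias `θ`.
* The histogram representation of `P` and `ν` (no kernel or spherical
  harmonics smoothing) matches the measurement granularity but makes the
  stress integral piecewise in `θ`.
* Problem sizes in the test suite (phantoms up to 256³, 20 noisy fit
  replicates) are chosen to exercise every claim at desk scale; the
  algorithms themselves are resolution-agnostic.
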