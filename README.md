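# ligafib

Structure–function analysis of fibrous ligament tissue: segment individual
collagen fibers from 3-D tomographic volumes, turn the segmented populations
into orientation and volume-fraction distributions, and fit a probabilistic
fiber-recruitment constitutive model to tensile stress–strain data.

The package is aimed at researchers working on the biomechanics of dense
fibrous tissues (ligaments, tendons, engineered grafts) who image specimens
with contrast-enhanced micro-CT under stepwise tension and want to connect
the observed microstructure to the macroscopic toe-region mechanics.

## The model

A bundle of `N0` fibers is stretched to the ratio `λ = L/L0`.  Each fiber
becomes load-bearing (is *recruited*) at its own stretch `ξ`, distributed as
a Weibull density with shape `β`, scale `δ` and onset `γ` (= 1 at rest
length):

    R(ξ) = (β/δ) ((ξ−γ)/δ)^(β−1) exp(−((ξ−γ)/δ)^β),   ξ > γ.

A fiber inclined at `θ` to the loading axis feels the axial stretch
`λ cos θ`.  With a linear fiber stress law of modulus `E_f`, the engineering
stress of the bundle is

    σ(λ) = 2π N0 E_f ∫₀^{π/2} ∫₁^{λcosθ} R(ξ) P(θ,ξ) (λcosθ − ξ)
            ν(ξ,θ) cos²θ sinθ dξ dθ,

where `P(θ,ξ)` is the orientation density over the hemisphere (normalised
with the `sin θ` solid-angle factor) and `ν(ξ,θ)` the fiber volume fraction;
both are measured per strain level from the segmented volumes.  `β < 1`
means most fibers engage immediately; `β > 1` means recruitment ramps up to
an interior maximum — the classical toe-region picture.  Only the product
`N0·E_f` is identifiable, so `N0` is fixed at 1 and `E_f` is an effective
fiber modulus.

Fitting minimises the mean squared deviation between model and measured
curve over `(E_f, β, δ)` with a seeded multi-start optimiser (bounded
simplex plus a bounded least-squares polish per start).

Because no raw micro-CT or load-cell data are published for this kind of
protocol, the `synthetic` module generates every input with known ground
truth: voxelised cylindrical-fiber phantoms (9 µm voxels, 0–255 gray
levels, a non-fibrous matrix only slightly dimmer than the fibers),
per-strain fiber tables evolved with incompressible affine reorientation
(`tan θ' = tan θ / λ^{3/2}`), and forward-model load curves with optional
noise.

## Worked example

Generate a noiseless stress–strain curve from the recruitment model with
`E_f = 100.0017` MPa, `β = 2.0143`, `δ = 0.2450` (uniform orientation
density, unit volume fraction) on the protocol's strain grid
ε = 0, 1, 2, 3, 4, 6, 8 %, and fit it back:

```python
from ligafib import DEFAULT_LAMBDA_GRID, ModelParams, sigma_curve

params = ModelParams(E_f=100.0017, beta=2.0143, delta=0.2450)
curve = sigma_curve(DEFAULT_LAMBDA_GRID, params)
for lam, s in zip(curve.lam, curve.stress):
    print(f"{lam:.2f}  {s:.6f}")
```

```
1.00  0.000000
1.01  0.000001
1.02  0.000021
1.03  0.000103
1.04  0.000323
1.06  0.001593
1.08  0.004884
```

The stress is zero at rest and rises steeply as fibers are recruited — the
toe region.  The same experiment from the shell:

```sh
$ ligafib recover --ef 100.0017 --beta 2.0143 --delta 0.2450 --n-starts 4 --seed 1
E_f: relative error 5.434e-13
beta: relative error 1.102e-14
delta: relative error 2.953e-13
R^2 = 1.00000
```

All three parameters are recovered to machine precision from the noiseless
curve.  With 1 % multiplicative noise (`--rel-noise 0.01`) the fit still
reaches `R² = 1.00000`, but `E_f` and `δ` wander far from the generating
values while `β` stays within ~1 %: the seven-point curve determines the
shape of recruitment well, yet wide combinations of modulus and scale
interpolate the data equally well — an intrinsic property of this model
worth keeping in mind when interpreting fitted moduli.

The full pipeline (phantom → segmentation → distributions → forward model →
fit) runs from a YAML configuration:

```sh
ligafib config --show-defaults > demo.yaml
ligafib run --config demo.yaml --out demo_run
```

which writes per-stage outputs (TIFF volumes, per-object CSV tables,
per-strain `P`/`ν` histograms, the model curve and the fit report) plus a
`manifest.json` recording seeds, outputs and timings.

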