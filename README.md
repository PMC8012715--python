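# aucplex

Solution-biophysics analysis of protein–DNA assembly by sedimentation
velocity, written around a concrete question: how many repressor dimers bind
a triple-repeat DNA operator, and how cooperatively?  The package targets
the workflow used to characterize the *E. coli* sialic-acid repressor NanR
binding its (GGTATA)₃-repeat operator — a dimeric ~59 kDa protein, a
~21.5 kDa 35-bp duplex, and a ladder of 1:1, 2:1 and 3:1 dimer:duplex
hetero-complexes up to ~198.5 kDa — but every piece is generic for
two-component protein/nucleic-acid systems.

It is aimed at analytical-ultracentrifugation practitioners and method
developers who want a scriptable, testable version of this analysis chain:

- **Synthetic data generation** — mass-action binding ladders equilibrated
  at t = 0, sedimented in sector geometry by a conservative Crank–Nicolson
  finite-volume Lamm solver (Scharfetter–Gummel advection, reflective ends),
  composed into single-wavelength fluorescence titrations or 220–300 nm
  multiwavelength absorbance datasets with seeded Gaussian and systematic
  (time- and radially-invariant) noise.
- **Spectra** — protein ε₂₈₀ by the Trp/Tyr composition rule
  (ε₂₈₀ = 5500·n_W + 1490·n_Y), DNA duplex ε₂₆₀ by the nearest-neighbor
  method with hypochromicity correction, duplex masses, dilution-series
  profile fitting, and the vector-angle separability diagnostic.
- **Hydrodynamics** — the Svedberg relation M = sRT/(D(1 − v̄ρ)), the
  Stokes–Einstein s↔D closure through f/f₀, and weight-averaged partial
  specific volumes v̄ = (M₁v̄₁ + M₂v̄₂)/(M₁ + M₂) for hetero-complexes.
- **Distribution inversion** — c(s)-style non-negative least squares over
  precomputed Lamm kernels, a simplified two-dimensional (s, f/f₀) grid
  analysis, algebraic elimination of ti/ri systematic noise, and
  residual-resampling Monte Carlo.
- **Multiwavelength deconvolution** — pointwise NNLS across wavelengths into
  molar protein and DNA concentration fields, per-component molar
  s-distributions, and stoichiometry (monomers per duplex) from co-migrating
  peak integrals.
- **Binding analysis** — isotherms from free/bound c(s) window integrals
  (2–3.5 S vs 3.5–12 S) or gel-shift densitometry tables, Hill fits
  θ = [L]ⁿ/(K_Dⁿ + [L]ⁿ), AIC comparison against the non-cooperative n = 1
  model with Akaike weights, and studentized bootstrap uncertainties.

## Worked example

The `pipeline` subcommand runs the whole chain on synthetic data — simulate
a multiwavelength run of the binding ladder, deconvolute it, integrate
stoichiometries, then simulate an 11-point fluorescence titration and fit
binding models:

```sh
aucplex pipeline --seed 7 --out demo/
```

`demo/report.json` from that exact command contains (abridged):

```
"spectra":        eps280_protein 13980.0, eps260_duplex 557193.0,
                  duplex_mass_Da 21494.2, vector_angle_deg 54.1
"stoichiometry":  complex3 (7.5-9.25 S): molar_ratio 5.92 -> 3 dimers,
                  vbar_avg 0.7101 mL/g, complex_mass_calc 198500 Da
"binding":        K_D 8.97e-08 M, hill_n 1.71,
                  akaike_weights_percent: hill 99.7 / noncooperative 0.3
```

Reading: the protein and DNA extinction spectra are separable (54°), the
co-migrating 7.5–9.25 S peak carries ≈ 6 protein monomers per duplex —
three dimers, a calculated 198.5 kDa complex — and the titration isotherm
is strongly cooperative (n ≈ 1.7, Hill model preferred at 99.7% Akaike
weight).  The fitted half-saturation (~90 nM total dimer) is an apparent
value: at 80 nM labeled duplex the titration is partly stoichiometric, so
ligand depletion is absorbed into K_D, exactly as in the corresponding
bench experiment.

The same stages are available piecemeal (`simulate`, `extinction`, `cs`,
`deconvolute`, `stoich`, `isotherm`) and as library calls; see the module
docstrings in `src/aucplex/`.

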