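# Methods

This note documents the models, numerical choices and limitations behind
`aucplex`.  Symbols: s (sedimentation coefficient, 1 S = 10⁻¹³ s), D
(diffusion coefficient, cm²/s), M (molar mass, Da), v̄ (partial specific
volume, mL/g), ρ and η (buffer density and viscosity), ω (rotor angular
velocity), f/f₀ (frictional ratio), θ (fraction of DNA bound), [L] (total
titrant concentration), K_D (half-saturation constant), n (Hill
coefficient).

## Binding ladder

The generator's chemical model is a DNA duplex O binding up to three
protein dimers P in stepwise equilibria with association constants K₁, K₂,
K₃ (M⁻¹):

    O + P ⇌ OP,  OP + P ⇌ OP₂,  OP₂ + P ⇌ OP₃.

Species concentrations follow from two mass balances; the solver reduces
them to a single monotone equation in the free-dimer concentration p and
brackets the root on [0, P_tot] (Brent's method, relative tolerance 1e−15;
mass balance audited to 1e−9 after solving).  Defaults K₁ = 1×10⁷,
K₂ = 4×10⁷, K₃ = 1.6×10⁸ M⁻¹: the increasing steps encode positive
cooperativity and place the occupancy transition inside the default
11-point, two-fold titration window (794 → 0.78 nM dimer against 80 nM
duplex).  Note that at 80 nM operator the titration is partly
stoichiometric — filling three dimer sites on half the duplex already
consumes ~120 nM dimer — so the *apparent* half-saturation of the
occupancy curve sits near 90 nM total dimer for any nanomolar-scale
stepwise constants.  Apparent constants from this design absorb ligand
depletion by construction; the package fits them as such and makes no
attempt to de-convolve depletion.

The ladder is equilibrated once at t = 0 and the species then sediment as
non-interconverting ideal species.  This is deliberate: the analysis layer
treats discrete co-migrating complexes, and reaction–diffusion–sedimentation
coupling (re-equilibration on the timescale of sedimentation) is out of
scope.  Consequences: synthetic boundaries are superpositions of
fixed-composition species, with none of the reaction-boundary broadening a
fast-exchanging real system would show.

## Fixture species

The packaged species table (s in S, M in kDa, v̄ in mL/g, at 20 °C
water-like conditions):

| species  | s    | M     | v̄      | composition |
|----------|------|-------|--------|-------------|
| dna      | 3.00 | 21.5  | 0.55   | 1 duplex    |
| dimer    | 3.70 | 59    | 0.7295 | 2 monomers  |
| complex1 | 4.50 | 80.5  | 0.6816 | 2 + duplex  |
| complex2 | 6.60 | 139.5 | 0.7018 | 4 + duplex  |
| complex3 | 8.31 | 198.5 | 0.7101 | 6 + duplex  |

Complex v̄ is the mass-weighted average of the protein and DNA parts; D is
derived from the Svedberg relation, which makes the table internally
consistent (inverting any fixture species recovers its mass exactly).  The
complex1/complex2 s values are the midpoints of their reporting windows
(4.0–5.0 and 6–7.25 S); implied f/f₀ values land at 1.6–1.8, i.e. extended
DNA-bearing particles, which is hydrodynamically sensible.

## Lamm solver

The sector-cell transport PDE

    ∂c/∂t = (1/r) ∂/∂r [ r (D ∂c/∂r − s ω² r c) ]

is discretized by a finite-volume scheme on a uniform radial grid (default
step 0.0026 cm ⇒ ~500 cells over the 5.9–7.2 cm column), with fluxes
through cell faces and zero flux through meniscus and bottom.  The
sector-weighted total ∫c·r dr is therefore conserved to solver roundoff
(measured ~1e−15 relative).  Face fluxes use Scharfetter–Gummel exponential
fitting, J = (D/Δr)[B(−Pe)c_L − B(Pe)c_R] with B(x) = x/(eˣ−1) and cell
Péclet number Pe = sω²rΔr/D; this degrades gracefully to upwinding as
D → 0, keeping steep low-diffusion boundaries positive.  Time stepping is
Crank–Nicolson with uniform sub-steps per scan interval chosen so the
advective Courant number stays ≤ 0.5; each interval factors one tridiagonal
system.  In the low-diffusion limit the simulated boundary midpoint tracks
the analytic trajectory r_m·exp(sω²t) to better than 0.1%.

## Distribution inversion

`cs_inversion` fits scans to a non-negative superposition of unit-loading
Lamm solutions on a log-spaced s-grid (default 100 points over 0.5–15 S;
log spacing matches how boundary resolution scales with s).  The s → D
closure uses one shared frictional ratio: M(s) from
M^{2/3} = sN_A·6πη(f/f₀)(3v̄/4πN_A)^{1/3}/(1−v̄ρ), then D from the Svedberg
relation.  f/f₀ defaults to 1.25 and can be optimized by bounded scalar
search on residual RMSD.  For labeled-DNA titration data the package-level
analyses fix f/f₀ = 1.6 instead, the value class of the DNA-bearing fixture
species; a protein-like 1.25 over-diffuses the kernels and systematically
leaks bound signal across the 3.5 S window boundary.

Two numerical choices matter:

- **Radial fitting window.**  By default the fit excludes radii within
  0.05 cm of the meniscus and 0.15 cm of the bottom.  With reflective ends
  the back-diffusion layer at the bottom reaches tens of times the loading
  concentration and would otherwise dominate the least squares; the same
  truncation is standard practice on real data.
- **Systematic noise.**  Time-invariant (per-radius) and radially invariant
  (per-scan) offsets enter the model as unconstrained indicator columns of
  the augmented design matrix.  Because that block is unconstrained it is
  eliminated exactly by block elimination — an orthogonal projection
  (two-way centering) applied to both data and kernels — after which the
  species weights solve a plain NNLS; the noise vectors are recovered
  algebraically from the residuals.  When both are fitted the shared
  constant is assigned to the ti vector (ri reported mean-free).

Plain sparse NNLS is the default (2DSA-like); an optional second-difference
smoothness penalty gives c(s)-like regularized output.  NNLS weights are
converted to amplitude densities per Svedberg by dividing by trapezoid
quadrature weights, so window integrals are exact piecewise-linear
integrals and sub-ranges partition the total.  `grid_2dsa` applies the same
machinery to a 2-D (s, f/f₀) kernel dictionary, with an optional one-pass
refinement that subdivides around occupied cells.  Grid bounds and
regularization levels are package conventions, flagged as such in fit
reports.  Monte Carlo uncertainty is residual resampling: replicate
datasets are best-fit model plus residuals resampled with replacement,
refit with identical settings (seeded).

## Multiwavelength deconvolution

Species spectra are composition-linear: ε_k(λ) = n_monomers·ε_prot(λ) +
n_duplex·ε_dna(λ), with the protein basis per monomer so that integrated
molar ratios read directly as monomers per duplex.  Deconvolution solves,
at every (r, t) point, A(λ) = l·Σ_k ε_k(λ)c_k with c_k ≥ 0.  The
implementation solves the unconstrained least squares for all points in one
BLAS call and re-solves only the points with negative coefficients by NNLS
(identical solution where the unconstrained optimum is feasible).  This
pointwise-in-(r,t) route is exactly equivalent to per-wavelength-model
decomposition in the noise-free limit and far simpler; decomposing
iteratively refined per-wavelength models is a non-goal.  Separability is
gated on the vector angle between basis profiles (default minimum 10°; the
synthetic Gaussian-band protein/DNA bases sit at ~54°, comparable to
measured protein/DNA spectra).  Stoichiometry over a window [s₁, s₂] is
∫protein/∫dna of the molar component distributions; the inferred dimer
count is round(ratio/2) with the residual reported, and the calculated
complex mass is dimers·2·monomer mass + duplex mass with the
weight-averaged v̄.

## Binding analysis

θ per titration point is ∫bound/(∫bound + ∫free) with default windows
2–3.5 S (free duplex) and 3.5–12 S (complex-shifted).  The Hill model is
fitted in the canonical half-saturation form θ = [L]ⁿ/(K_Dⁿ + [L]ⁿ), K_D in
molar units; the variant with the denominator constant taken literally as
K_D + [L]ⁿ (units Mⁿ) is available via `literal_kd=True` but is
dimensionally awkward and not the default.  [L] is the *total* titrant
concentration, so fitted constants are apparent (see above).  Fitting is
multi-start nonlinear least squares on log-parameters (8 log-spaced K
starts × n starts at 1 and 2).  Model comparison uses the least-squares
AIC, N·ln(SS/N) + 2k with k counting the variance parameter (k = 3 free-n,
k = 2 fixed-n), and Akaike weights exp(−Δᵢ/2)/Σexp(−Δⱼ/2) reported in
percent; AICc is not used, matching the reporting convention of percentage
weights.  Whether a published "AIC value of 99%" is an Akaike weight is not
always stated; this package computes Akaike weights.

Parameter uncertainties use a **studentized residual-resampling bootstrap**:
residuals are inflated by √(N/(N−p)) to restore the variance absorbed by
the p fitted parameters, resampled with replacement onto the fitted curve,
and each replicate's log-parameter deviation is studentized by its own
linearization SE; intervals are bootstrap-t.  Plain percentile intervals
were measured (by simulation at the 11-point design with 3% θ noise) to
cover only ~75–80% at nominal 95% — the small N and the clipping of
near-zero θ values make residuals heteroscedastic — while the studentized
interval covers ~94%.  Reported SDs are of the raw replicate draws.

## Synthetic-data realism

The generator emulates: sector-geometry transport of a discrete complex
ladder, distinct protein/DNA extinction spectra over 220–300 nm (2 nm
steps, 41 channels), duplex-only fluorescence signal (label on the DNA; a
free label or free protein contributes nothing), per-datum Gaussian noise,
and optional ti/ri systematic offsets.  Everything stochastic flows from
one integer seed (per-titration-point streams are spawned from it;
generation is bit-reproducible).  It does **not** emulate: reaction-coupled
sedimentation, fluorescence inner-filter and PMT-gain effects, interference
optics, buffer-gradient (dynamic density) effects, radial calibration
error, or meniscus-position uncertainty.  Passing closed-loop tests
therefore demonstrates the correctness and conditioning of the analysis
chain on data obeying its own transport model, not robustness to every
instrument artifact of real AUC data.

Problem sizes used in the shipped tests (10–25 scans, 260–430 radial
points, 60–150 s-grid points, 100-replicate fit sweeps, 200-replicate
coverage runs) were chosen as the smallest that leave the measured
quantities comfortably inside their tolerances; kernel dictionaries are
memoized across identical scan schedules.

## Sequence stand-ins

The repository's FASTA files are synthetic stand-ins, named `*_synthetic`:
a 263-residue protein with exactly 2 Trp + 2 Tyr and average monomer mass
29,481.6 Da (homodimer 58.96 kDa), and a 35-bp operator duplex containing
three GGTATA repeats with AT-rich spacer/flank bases.  Composition-level
quantities computed from them (ε₂₈₀ = 13,980 M⁻¹cm⁻¹, duplex
ε₂₆₀ ≈ 5.57×10⁵ M⁻¹cm⁻¹, duplex mass 21.49 kDa, dimer mass 59 kDa) match
the NanR/(GGTATA)₃ system; residue order and exact flanking bases do not.
Nearest-neighbor ε₂₆₀ values are table-dependent at the few-percent level
(the shipped table is the classic Cantor–Warshaw–Tinoco set); DNA masses
use average residue masses with a 5′-OH, no-terminal-phosphate,
unlabeled-duplex convention.

## Known limitations

- The common-f/f₀ c(s) closure cannot represent mixtures whose species have
  strongly different v̄ or shape exactly; window integrals of such mixtures
  carry few-percent biases (the 2-D grid analysis relaxes this).
- `grid_2dsa` is a single-pass NNLS with at most one refinement sweep, not
  the full iterative multi-stage 2DSA with stochastic grid refinement.
- The EMSA path validates and fits externally produced densitometry tables;
  gel image processing is out of scope.
- s-values are handled at experimental conditions; the s20,w
  standardization hook is an identity by default.
- Buffer density and viscosity are configuration inputs; no
  composition-based estimation is included.
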