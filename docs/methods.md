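# Methods

`nrpore` analyses specular neutron reflectometry (NR) of supported lipid
bilayers that mimic the mitochondrial outer membrane, before, during and
after their perforation by the apoptotic protein Bax.  This note records the
models, the numerical choices, and what the synthetic data used for
validation do and do not establish.

## Scattering length densities

The contrast quantity NR senses is the coherent scattering length density
ρ = Σᵢ bᵢ / V (Å⁻²).  Solvent SLD is the linear mix of the pure H₂O
(−0.56 × 10⁻⁶ Å⁻²) and D₂O (+6.38 × 10⁻⁶ Å⁻²) endpoints, computed from
atomic scattering lengths with a 30 Å³ water molecular volume; buffer salts
are ignored as dilute.  Silicon-matched water is the 38 % D₂O mixture whose
SLD equals bulk silicon (2.07 × 10⁻⁶ Å⁻²).

Materials carry a fixed (non-labile) scattering length, a labile-hydrogen
count that follows the solvent isotope, and a molecular volume:

- **Lipids.** POPC and tetraoleoyl-cardiolipin (TOCL) are split into
  headgroup and hydrocarbon-tail fragments with volumes from standard
  lipidomics tables (POPC 331/925 Å³, TOCL 530/1864 Å³), shipped as an
  overridable YAML table.  Membrane lipid at cardiolipin mole fraction
  x_CL is the mole-weighted pseudo-material.  The original analysis does
  not print its volume table; these values are configuration, not ground
  truth, and the same table is used for synthetic-data generation and
  fitting, so recovery tests are internally consistent.
- **Protein.** Bax SLDs are computed from the human Bax sequence (UniProt
  Q07812): per-residue atomic composition for scattering lengths, volume
  from the 1.21 Å³/Da protein specific volume, labile hydrogens counted
  Jacrot-style (backbone amides + side-chain OH/NH/SH) with a default
  exchange completeness of 0.9.  d-Bax carries 90 % deuteration of
  non-labile hydrogens.  This puts d-Bax at 7.3 × 10⁻⁶ Å⁻² in D₂O — a
  ~72 % reduction of contrast relative to h-Bax, i.e. "nearly invisible"
  in the qualitative sense, though not an exact match.

## Structure model

The interface is an ordered slab stack: silicon half-space, native oxide
(12 Å), a thin water gap (default 4 Å, standard in supported-bilayer
models), inner headgroups, tails, outer headgroups, and — after protein
interaction — a three-layer surface protein–lipid complex, then bulk
solvent.  Each layer holds volume fractions of named materials with solvent
as the implicit remainder; partial complex coverage is expressed through
the solvent fraction rather than a separate coverage parameter.  The
complex is by default constrained symmetric (wing layers share thickness
and composition).  z = 0 sits at the Si/SiO₂ interface, positive toward
solution; interfaces are error-function smoothed with per-interface
roughness (substrate default 3 Å, the polish specification of such
substrates).

Consistency is enforced by construction: the SLD depth profile is the
pointwise volume-fraction mixture of slab SLDs using the same interface
weights as the component profiles, so fractions sum to one at every z and
ρ(z) ≡ Σ φ(z)·ρ exactly.

Derived quantities: area per molecule APM = 2·V̄_tails/(t·φ_lipid) (two
leaflets), and per-region inventories Γ = Σ thickness × fraction (Å³/Å²).

## Reflectivity

Reflectivity is computed with the Abelès characteristic-matrix formalism
(verified against an independently coded Parratt recursion to < 10⁻¹⁰
relative on random stacks), with roughness as Névot–Croce attenuation of
the interface Fresnel coefficients — the standard choice for erf profiles.
Instrument resolution is Gaussian in Q with dQ/Q = 4 % interpreted as FWHM
(σ = dQ/2.355), the common time-of-flight convention; per-point dQ columns
override the global value.  In the fitting path the model is evaluated
exactly at 17 Gauss–Legendre nodes spanning ±4σ per data point (relative
accuracy ~10⁻² only in the immediate vicinity of the critical edge, where
the curve varies by orders of magnitude across the kernel, and ≪10⁻³
elsewhere; generation and fitting share the identical rule, so recovery is
unbiased).  The array-based `smear_resolution` uses an 801-node Simpson
kernel for near-exact convolution of sampled curves.

## Co-refinement and uncertainty

One contrast-independent structure must reproduce all curves; only
material SLDs, scale factors and flat backgrounds differ per contrast
(scale bounds [0.8, 1.2], background bounds [10⁻⁷, 10⁻⁵], defaults 1.0 and
10⁻⁶).  The objective is χ² = Σ ((R_model − R)/dR)².  Optimization is
bounded differential evolution (popsize 15) polished locally, followed by
an `emcee` ensemble sampler started in a tight ball around the optimum:
default max(2·n+2, 16) walkers (a minimum the stretch move needs to mix),
5000 steps, 30 % burn-in, all seeded.  Uncertainties are central 65 %
credible intervals, the reporting convention for these structures.
Volume-fraction validity (layer sums ≤ 1) is enforced by rejection —
invalid vectors get zero posterior mass — rather than a simplex
reparametrization; with at most two free fractions per layer the rejection
region is small and the sampler never stalls on it.  A posterior whose 65 %
interval spans most of a prior bound flags the result non-identifiable
instead of raising.

Time-resolved curves are fitted with a single scale-ratio coefficient α
between the before-interaction structure (α = 0) and the equilibrium
structure (α = 1): volume fractions mix linearly layer by layer and
thicknesses interpolate linearly.  A bare-bilayer endpoint is aligned to
the complex topology with zero-occupancy cluster layers.

## Kinetics

Protein accumulation is modelled as rising biexponential saturation,
y(t) = baseline + A_f(1−e^{−t/τ_f}) + A_s(1−e^{−t/τ_s}), fitted by
weighted least squares with multi-start initialization over a τ grid and
covariance-based errors; τ_fast < τ_slow is enforced by relabeling, an
amplitude collapsing below 1 % of the total flags the fit degenerate, and
a baseline term is included (default 0).  FTIR amide I band areas
(1600–1700 cm⁻¹) are trapezoidal integrals above a linear baseline between
window endpoints, hence offset-invariant.  Coarse NR traces are fitted
with the single slow exponential, since 40–60-min bins cannot resolve a
10-min process.  NR/FTIR agreement is reported as the Pearson correlation
of min-max-normalized overlays (FTIR averaged over each NR collection
window) and the ratio of slow time constants.

## Poration bookkeeping

From before/after structures: tail lipid coverage change (volume %),
bilayer thinning (Å), cluster lipid/protein inventories (Å³/Å²), and the
mass-balance ratio = (tail lipid loss + outer-headgroup lipid loss) ÷
(total cluster lipid inventory).  The inner headgroups are assumed
undisturbed.  On the printed central values of the 10 mol % system this
accounting gives ≈ 1.2; counting tail loss alone gives ≈ 1.08 — "balanced"
at the ~20 % level, consistent with lipid extraction rather than
dissolution, and the accounting convention is declared rather than claimed
to be the original one.  Intervals are propagated by joint resampling of
the two posterior chains (300 draws, seeded).  The cardiolipin trend test
reports strict monotonicity of lipid removal versus x_CL and its linear
slope (≈ 1 volume % per mol % across the 5/10/15 % systems).

## Synthetic data

No raw curves are deposited with the original study, so validation runs on
synthetic data generated from the printed structures.  The fixture catalog
carries the full 10 mol % CL structure before (tails 29.8 Å at 98 % lipid)
and after Bax (tails 27.6 Å at 86 % lipid + 5 % protein; complex
23.4/29.7/23.4 Å with 12/30/12 % protein and 17 % core lipid); the 5 and
15 mol % entries use the published tail coverages and core protein
contents with the 10 mol % geometry, flagged as supplementary-derived
defaults.  Reflectivity is simulated on a 120-point log-spaced Q grid over
0.01–0.3 Å⁻¹ (reading the instrument section's "Å⁻²" as a typo for Å⁻¹),
smeared at 4 % dQ/Q, with heteroscedastic noise σ = 0.02·R + 10⁻⁷ and
dR = σ.  Kinetic traces use a 0.6/0.4 fast/slow amplitude split (no
amplitudes are printed; a fast-dominant split matches the visual shape of
the published traces) with 2 % multiplicative noise on the 80-s FTIR
schedule and 5 % on 50-min NR bins timestamped at bin midpoints.

What this establishes: that the estimators recover the structures and
rates that generated the data, at realistic noise, resolution and sampling
— i.e. the pipeline is correct and calibrated.  What it does not
establish: robustness to model misspecification present in real samples
(in-plane inhomogeneity beyond a solvent fraction, background shape,
imperfect deuteration, correlated residuals), since generator and fitter
share the slab family and materials table.

## Problem sizes and determinism

Validation runs use chain lengths that resolve these well-conditioned
synthetic posteriors: 600 MCMC steps (×16–18 walkers) for the single
before/after co-refinements, 250 steps per replicate for the 20-replicate
calibration study, and differential-evolution budgets of 15–40
generations; production analyses of real data should use the 5000-step
default.  Every stochastic stage (data generation, optimizer, sampler,
chain resampling) is seeded, and pipeline outputs are byte-identical given
(config, seed).

## Known limitations

- The z-profile is the only resolved dimension; pore radius, number and
  lateral arrangement are outside the model.
- Scale factors and backgrounds default to fixed values in the packaged
  experiments; freeing them per contrast is supported but widens
  posteriors.
- The labile-hydrogen table treats ionizable side chains Jacrot-style;
  at pH 7 the carboxyl count is an approximation worth ~2 % of a
  protein's SLD.
- The balance ratio depends on the declared accounting of headgroup lipid;
  alternatives shift it by ~0.1.
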