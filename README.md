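# nrpore

Structural and kinetic analysis of protein-porated supported lipid
bilayers by multi-contrast specular neutron reflectometry (NR).

## The problem

The apoptotic protein Bax perforates mitochondrial-outer-membrane (MOM)
mimics — supported POPC/cardiolipin bilayers on silicon — and deposits the
extracted lipid in protein–lipid clusters on the membrane surface.
Resolving that process requires (i) forward-modelling specular
reflectivity R(Q) of a layered interface, (ii) fitting *one*
contrast-independent structure simultaneously to curves measured in
several H₂O/D₂O solvent contrasts and protein isotope forms, (iii)
propagating uncertainty with MCMC, and (iv) turning before/after
structures into lipid bookkeeping, alongside two-phase adsorption
kinetics from ATR-FTIR band areas and time-resolved NR.  `nrpore`
implements that pipeline for anyone analysing contrast-variation NR of
supported membranes and protein–membrane interactions.

## The model

The interface is a slab stack — Si | SiO₂ | water gap | headgroups |
tails | headgroups | optional three-layer surface complex | solvent —
where each layer carries volume fractions φ of named materials (solvent
is the remainder).  Under solvent contrast *c* a layer's scattering
length density is

    ρ_layer = Σ_i φ_i ρ_i(c),    ρ_i = [b_fix + n_exch(x b_D + (1−x) b_H)] / V,

with x the D₂O fraction.  Reflectivity is computed with the Abelès
characteristic-matrix formalism with Névot–Croce roughness and Gaussian
dQ/Q = 4 % resolution smearing, and co-refined against all contrasts by
differential evolution followed by an `emcee` ensemble sampler; reported
uncertainties are central 65 % credible intervals.  Adsorption kinetics
follow a rising biexponential y(t) = A_f(1−e^{−t/τ_f}) + A_s(1−e^{−t/τ_s}).

Because no raw curves are deposited with the study the package
re-implements, a synthetic-data module generates every input from the
published fitted structures (5/10/15 mol % cardiolipin, before and after
Bax) with realistic noise, resolution and sampling schedules; all tests
and the acceptance script run end-to-end on those.

## Worked example

Co-refine synthetic three-contrast data from the intact 90:10 POPC:TOCL
bilayer (`examples/03_corefinement.py`):

```text
co-refined bilayer structure (posterior median [65% CI]):
  tails.thickness              29.805  [29.775, 29.837]
  tails.frac.lipid_tail         0.979  [0.978, 0.980]
  head_out.frac.lipid_head      0.833  [0.828, 0.838]
  tails.roughness               2.908  [2.814, 3.003]
  chi-square at optimum: 351.3 over 360 points
```

The generating structure (tails 29.8 Å at 98 % lipid, headgroups 83 %
hydrated to 17 %) is recovered within tight intervals, and χ² ≈ n says
the noise model is consistent.  The other example scripts cover SLD
arithmetic (`01`), forward modelling (`02`), kinetics on FTIR vs NR
sampling (`04`), the poration mass balance and cardiolipin trend (`05`,
which prints the 8 → 12 → 18 volume % lipid-removal series), and the
one-parameter scale-ratio fit of time-resolved data (`06`).

A thin CLI chains the same stages from YAML configs:
`nrpore simulate|fit|kinetics|balance|report -c run.yaml -o out/`.

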