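"""Multi-contrast co-refinement with MCMC uncertainty.

Simulates the three-contrast characterisation of the intact 90:10
POPC:TOCL bilayer (D2O / silicon-matched water / H2O, 4% dQ/Q, realistic
counting noise), then fits one shared structure to all three curves and
prints the posterior medians with 65% credible intervals.  The recovered
values should bracket the generator's: tail thickness 29.8 Å at 98% lipid.
A run takes a minute or two.
"""

from nrpore.experiments import BEFORE_FREE_PARAMS, before_bilayer_experiment

result = before_bilayer_experiment(seed=0, n_steps=400)

print("co-refined bilayer structure (posterior median [65% CI]):")
for name in BEFORE_FREE_PARAMS:
    lo, hi = result.ci65[name]
    print(f"  {name:26s} {result.median_params[name]:8.3f}  [{lo:.3f}, {hi:.3f}]")
print(f"  chi-square at optimum: {result.chi2:.1f} over 360 points")
print("\nThe tail thickness and coverage land on the generating structure;")
print("interval widths show what three contrasts pin down simultaneously.")
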