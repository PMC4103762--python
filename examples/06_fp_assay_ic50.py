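"""Analyze a fluorescence-polarization competition assay.

Simulates a 12-point 2-fold titration (100 µM down to ~49 nM) of a compound
with true IC50 = 37 µM, computes per-well mP and percent inhibition against
the DMSO / free-peptide controls, and fits the four-parameter logistic.
Also runs a 93-compound single-dose screen with 28 designed actives.
"""

from polopharm import fixtures as fx
from polopharm import fit_ic50, percent_inhibition, screen_summary

plate, _ = fx.make_fp_plate([("compoundA", 37e-6, 1.0)], noise=0.02, seed=11)
table = percent_inhibition(plate)
print(table.head(4).to_string(index=False))

fit = fit_ic50(
    table.concentration.to_numpy(), table.percent_inhibition.to_numpy(),
    fix_bottom=0.0, fix_top=100.0,  # %inh is control-normalized
)
print(f"\nfitted IC50 = {fit.ic50 * 1e6:.1f} µM (truth 37 µM), "
      f"hill = {fit.hill:.2f}, converged = {fit.converged}")

screen, truth = fx.make_screen_plate(n_compounds=93, n_hits=28, seed=11)
summary = screen_summary(screen, threshold=50.0)
print(f"\nsingle-dose screen: {int(summary.hit.sum())}/{len(summary)} compounds "
      f">50% inhibition (designed: {truth['n_hits']})")
print(summary.head(3).to_string(index=False))
# mP = (I_par − I_perp)/(I_par + I_perp) × 0.998 × 1000; %inh interpolates a
# compound's mP between the DMSO (0%) and free-peptide (100%) controls.
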