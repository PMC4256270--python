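"""mtSSB:mtDNA stoichiometry: is there enough protein to coat the genome?

First reproduces the per-cell arithmetic from measured means and standard
deviations, then runs the full synthetic quantitative-western pipeline
(standard curve fit, band interpolation, Avogadro conversion) and shows it
recovers the generating truth.
"""

from mtssb import MeanSd, fit_standard_curve, molecules_per_cell, ssb_per_mtdna
from mtssb.stoichiometry import summarize
from mtssb.synthetic import SimulationSpec, simulate_western

# Measured per-cell counts: mtSSB by quantitative immunoblot, mtDNA by qPCR.
ssb = MeanSd(1.08e7, 0.45e7)
mtdna = MeanSd(5.07e3, 0.06e3)
report = summarize(ssb, mtdna)
ratio = report.ratio
print("per-cell stoichiometry (mean +/- sd, independence-propagated):")
print(f"  mtSSB molecules per cell : {ssb.mean:.2e} +/- {ssb.sd:.2e}")
print(f"  mtDNA molecules per cell : {mtdna.mean:.2e} +/- {mtdna.sd:.2e}")
print(f"  mtSSB per mtDNA          : {ratio.mean:.2e} +/- {ratio.sd:.2e}")
print(f"  tetramers per mtDNA      : {report.tetramers_per_mtdna} "
      f"(>= 500: each tetramer binds 59 nt)")
print(f"  coatable ssDNA           : {report.coverable_nt} nt vs 16,569 nt genome "
      f"-> sufficient: {report.sufficient}")

# Synthetic western round trip: generate noisy lanes, fit, interpolate.
spec = SimulationSpec(true_molecules_per_cell=1.08e7, n_replicates=3,
                      intensity_cv=0.02, seed=20141204)
table = simulate_western(spec)
standards = table[table.lane_type == "standard"].groupby("amount_ng").intensity.mean()
curve = fit_standard_curve(standards.index, standards.to_numpy())
samples = table[table.lane_type == "sample"]
recovered = molecules_per_cell(samples.intensity.to_numpy(), curve,
                               n_cells=float(samples.n_cells.iloc[0]))
print(f"\nsynthetic western (2% band noise, truth {spec.true_molecules_per_cell:.2e}):")
print(f"  calibration r^2          : {curve.r_squared:.4f}")
print(f"  recovered per cell       : {recovered.mean:.3e} +/- {recovered.sd:.1e}")
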