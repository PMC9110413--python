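"""Assign phosphate counts to a deconvolved native mass spectrum by MCMC.

Builds a synthetic deconvolved spectrum for a hyperphosphorylated protein
(mixture of states around 10 phosphates with small-ion adducts on the
80 Da / 23 Da ladder, base mass 39.9 kDa), then samples the posterior over
(phosphate, adduct) counts and summarizes the extent of phosphorylation.
"""

from tauagg import ms, synth

# direct peak arithmetic first: the highest-peak worked examples
for peak_kda in (40.7, 41.4):
    count, tie = ms.phosphate_count_from_peak(peak_kda, base_mass_kda=39.9)
    print(f"peak at {peak_kda} kDa -> {count} phosphate groups"
          + (" (tie flagged)" if tie else ""))

spectrum = synth.gen_spectrum(
    39_900.0,
    {(10, 0): 0.45, (10, 1): 0.25, (11, 0): 0.20, (9, 1): 0.10},
    peak_fwhm_da=8.0, noise_sd=0.0005, seed=0)

grid = ms.StateGrid(max_phos=26, max_adduct=6)
posterior = ms.run_assignment(spectrum, grid, chains=16, steps=3000,
                              burn_in=800, thin=20, seed=0)
summary = ms.summarize_extent(posterior)
print(f"\nposterior over phosphate count: mode {summary['mode_p']}, "
      f"mean {summary['mean_p']:.2f} +/- {summary['sd_p']:.2f}")
print(summary["marginal"].query("weight > 0.01").to_string(index=False))
print("\nThe mode matches the dominant simulated state (10 phosphates);")
print("the s.d. quantifies the adduct-induced assignment uncertainty.")
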