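"""Inhibitor viability assays: normalization, 4PL fits, patient comparison.

Simulates 9-point dilution plates in quadruplicate for several patient
samples, normalizes to untreated controls, fits the variable-slope 4PL
model per sample/compound, and compares samples per concentration with
Kruskal-Wallis + Dunn-Bonferroni.
"""

import gliomaprot as gp

config = gp.SimConfig(seed=13, n_proteins=10, dose_noise_sd=0.05)
plate, true_params = gp.simulate_dose_response(
    config, samples=("GB1", "GB2", "GB3"), compounds=("inhibitorA",)
)
norm = gp.normalize_viability(plate)
fits = gp.fit_plate(norm)

merged = fits.join(true_params.set_index(["sample", "compound"]), rsuffix="_true")
print(merged[["log_ic50", "log_ic50_true", "hill", "hill_true", "sse"]]
      .round(3).to_string())

comparisons = gp.compare_samples(norm)
sig = comparisons[comparisons["significant"]]
print(f"\n{len(sig)} of {len(comparisons)} pairwise comparisons significant "
      "(Dunn z, Bonferroni p < 0.05)")
# Fitted logIC50 values sit close to the generating truth; pairwise
# differences reflect the distinct planted IC50 per patient sample.
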