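"""Score spike-in detection and abundance accuracy across a cohort.

Runs the full single-cohort evaluation: merges inferred strains, labels
each sample's detection outcome (TP/TN/FP/FN at the benchmark's 10%
presence, 1% false-positive and 5% false-negative bounds), and reports
the per-depth RMSE between true and inferred spike-in abundance.
"""

from strainbench import cohort_simulator as sim
from strainbench.deconvolution import FitConfig, fit_mixture
from strainbench.pipeline import evaluate_cohort

design = sim.build_cohort_design(
    n_participants=5, samples_per_participant=4, n_sites=500, seed=3
)
cohort = sim.simulate_cohort(design)
result = fit_mixture(
    cohort.metagenotypes,
    FitConfig(n_strains=3 * len(cohort.genotypes), rng_seed=1),
)
ev = evaluate_cohort(cohort, result)

print(f"sLBP genotype similarity after merging: {ev.lbp_similarity:.3f}")
print("\nRMSE of sLBP abundance by sequencing depth:")
for depth, rmse in sorted(ev.rmse_by_depth.items()):
    print(f"  {depth:>3}x  {rmse:.4f}")
print("\ndetection outcomes:")
print(ev.detection["label"].value_counts().to_string())
print(f"\nfalse-positive rate (true 0%):  {ev.fp_rate}")
print(f"false-negative rate (true 10%): {ev.fn_rate}")
# RMSE below 0.02 at every depth and an empty FP/FN tally indicate the
# engine quantifies the spike-in accurately across the coverage range.
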