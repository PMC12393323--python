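"""Simulate a scaled LBP-trial cohort and inspect its ground truth.

Builds a cohort of 5 participants x 4 samples over 500 SNV sites: each
participant carries 1-4 private endogenous strains, every sample gets a
random sequencing depth (5-30x) and a spiked-in LBP strain at a random
level (0-100% in 10% steps).
"""

from strainbench import cohort_simulator as sim

design = sim.build_cohort_design(
    n_participants=5, samples_per_participant=4, n_sites=500, seed=3
)
cohort = sim.simulate_cohort(design)

print(f"strains (incl. sLBP): {len(cohort.genotypes)}")
print(f"samples: {len(cohort.metagenotypes)}")
print()
print(cohort.sample_table().head(8).to_string(index=False))
print()
sid = "P000_T0"
comp = cohort.compositions[sid]
print(f"true composition of {sid}:")
for strain, frac in sorted(comp.abundances.items()):
    print(f"  {strain:10s} {frac:.3f}")
mg = cohort.metagenotypes[sid]
print(f"\nmetagenotype of {sid}: {mg.n_sites} sites at {mg.depth[0]}x;")
print(f"first 10 alt counts: {mg.alt_count[:10].tolist()}")
# Each line above is a known ("true") quantity the evaluation modules can
# later compare against an inference.
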