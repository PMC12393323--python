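"""Select core biallelic SNV sites from a genome panel allele matrix.

Emulates building a species SNV database from a reference genome panel:
keep sites callable in >=95% of genomes whose minor allele appears in at
least 2 genomes, discarding monoallelic, rare-allele, gappy and
multi-allelic positions.
"""

import numpy as np
import pandas as pd

from strainbench.core_snv import core_presence_cutoff, select_core_biallelic_sites

rng = np.random.default_rng(0)
n_genomes, n_sites = 137, 40
freq = rng.uniform(0.0, 0.5, size=n_sites)
alleles = (rng.random((n_genomes, n_sites)) < freq[None, :]).astype(float)
missing = rng.random((n_genomes, n_sites)) < 0.03
alleles[missing] = np.nan
matrix = pd.DataFrame(
    alleles,
    index=[f"genome_{i:03d}" for i in range(n_genomes)],
    columns=[f"site_{j:03d}" for j in range(n_sites)],
)

cutoff = core_presence_cutoff(n_genomes, 0.95)
kept = select_core_biallelic_sites(matrix, core_fraction=0.95, min_allele_genomes=2)
print(f"panel: {n_genomes} genomes x {n_sites} candidate sites")
print(f"core-presence cutoff: {cutoff}/{n_genomes} callable genomes")
print(f"retained {len(kept)} core biallelic SNV sites: {kept}")
# With 137 genomes the 95% rule gives a 131-genome cutoff; dropped sites
# are those with too many missing calls or a minor allele in <2 genomes.
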