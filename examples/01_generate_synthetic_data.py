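"""Generate a synthetic urban landscape and an island-model SNP dataset.

Builds a categorical landcover raster (gardens, buildings, impervious cover,
parks, a street and a railway), then simulates 4 populations x 8 diploid
individuals at 500 biallelic SNPs with a target Fst of 0.10, degrades the
genotypes with sequencing annotations, and writes a VCF.
"""

from pathlib import Path

import numpy as np

from uhedge.genotype_io import write_vcf
from uhedge.synthetic_data import (
    default_landscape_spec,
    degrade_to_vcf_records,
    generate_landscape,
    simulate_island_genotypes,
)
from uhedge.resistance import write_landcover

out = Path("scratch_example_outputs")
out.mkdir(exist_ok=True)

lc = generate_landscape(default_landscape_spec(32, 32), seed=1)
write_landcover(lc, out / "landscape.asc")
classes, counts = np.unique(lc.codes, return_counts=True)
print("landscape 32x32 at 5 m resolution; class shares:")
for code, n in zip(classes, counts):
    print(f"  {lc.legend[code]:<22s} {n / lc.codes.size:.2f}")

gm, pops = simulate_island_genotypes(
    n_pops=4, n_per_pop=8, n_loci=500, fst_target=0.10, seed=1
)
samples, records = degrade_to_vcf_records(gm, missing_rate=0.05, seed=2)
write_vcf(samples, records, out / "genotypes.vcf")
print(f"\nwrote {gm.n_samples} individuals x {gm.n_loci} SNPs to {out / 'genotypes.vcf'}")
print("each genotype carries a read depth, each site a quality and mapping")
print("quality, so the filter chain (see example 02) has realistic inputs.")
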