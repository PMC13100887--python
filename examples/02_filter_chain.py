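"""Apply the post-calling SNP filter chain and inspect the per-step report.

Genotype calls below the depth floor are masked to missing first; site-level
rules (quality, mean depth, mapping quality, minor allele count, call rate,
biallelic-only, one SNP per capture locus) then act on the masked matrix.
"""

from uhedge.genotype_io import FilterConfig, apply_filter_chain, remove_high_missing_individuals
from uhedge.synthetic_data import degrade_to_vcf_records, simulate_island_genotypes

gm, _ = simulate_island_genotypes(4, 10, 800, 0.10, seed=3)
samples, records = degrade_to_vcf_records(gm, missing_rate=0.05, seed=4)

gm_f, report = apply_filter_chain(samples, records, FilterConfig())
print("rule                    in    out")
for rule, n_in, n_out in report.steps:
    print(f"{rule:<22s} {n_in:>4d} {n_out:>6d}")

gm_f, removed = remove_high_missing_individuals(gm_f, 0.20)
print(f"\nindividuals removed for >20% missingness: {removed or 'none'}")
print(f"final matrix: {gm_f.n_samples} individuals x {gm_f.n_loci} SNPs")
print("sites lost to the MAC rule are rare variants the island model drew at")
print("low frequency; the call-rate rule removes sites hit by the simulated")
print("5% random missingness.")
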