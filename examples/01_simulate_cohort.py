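"""Simulate a family cohort with known genetic-nurture ground truth.

Builds founder couples, offspring via meiosis with recombination, masks one
parent in ~83% of families (pairs vs trios), and generates substance-use
phenotypes under the calibrated generative model.  Optionally writes the
cohort to disk in the text formats the pipeline consumes (phased VCF,
pedigree TSV, phenotype TSV).
"""

from hapnurture import GenerativeParams, simulate_cohort

params = GenerativeParams(n_families=500, n_markers=1000, n_chromosomes=2, seed=1)
cohort = simulate_cohort(params)

ped = cohort.pedigree
off = ped[ped.role == "offspring"]
n_trio = ped[ped.role.isin(["mother", "father"])].groupby("family_id").genotyped.sum().eq(2).sum()
print(f"families: {params.n_families}, offspring: {len(off)}")
print(f"trios: {n_trio}, pairs: {params.n_families - n_trio} "
      "(one parent's genotypes withheld)")

base = cohort.phenotypes.query("wave == 1")
print(f"smoking initiation prevalence: {base.smoking_initiation.mean():.3f} "
      "(generative target 0.414)")
print(f"mean CPD among offspring: {base.cpd.mean():.2f} "
      f"(scale calibrated to mean {params.mean_cpd})")
xo = cohort.truth.crossover_counts(cohort.variant_map)
print(f"mean crossovers per gamete and chromosome: {xo.n_crossovers.mean():.3f} "
      f"(Poisson rate {params.crossover_rate})")

# Uncomment to write the cohort as text files:
# from hapnurture import io
# io.write_vcf("cohort.vcf", cohort.haplotypes, cohort.variant_map)
# io.write_pedigree("pedigree.tsv", cohort.pedigree)
# io.write_phenotypes("phenotypes.tsv", cohort.phenotypes)
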