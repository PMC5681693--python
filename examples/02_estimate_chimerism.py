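"""Estimate percent donor chimerism from simulated amplicon reads.

Simulates deep amplicon sequencing of a 60% donor / 40% recipient cell
mixture at three informative SNPs, tallies SNP-position bases by exact
anchor matching, applies the zygosity-corrected formulas and aggregates
across SNPs (mean +/- SEM).
"""

from chimerseq import (
    MixtureSimConfig,
    aggregate,
    count_bases,
    estimate_chimerism,
    select_informative_snps,
    simulate_genotype_pair,
    simulate_mixture_reads,
)

TRUE_CHIMERISM = 60.0

donor, recipient, panel = simulate_genotype_pair(n_loci=6, maf=0.5, seed=7)
informative = select_informative_snps(panel, donor, recipient)[:3]
loci = [s.locus for s in informative]

config = MixtureSimConfig(
    true_chimerism_percent=TRUE_CHIMERISM, depth_per_locus=5000,
    error_rate=0.002, seed=11,
)
reads, truth = simulate_mixture_reads(config, loci, donor, recipient)
counts = count_bases(reads, loci, sample_id="wb_d28")

estimates = []
for count, snp in zip(counts, informative):
    est = estimate_chimerism(count, snp)
    estimates.append(est)
    print(
        f"{est.locus_id}  {est.configuration.name:26s} "
        f"{est.percent:6.2f}%  [95% CI {est.ci_low:5.2f}-{est.ci_high:6.2f}]  "
        f"({est.effective_reads} reads)"
    )

agg = aggregate(estimates)
print(f"\naggregate: {agg.mean_percent:.2f}% donor chimerism "
      f"+/- {agg.sem_percent:.2f} (SEM over {agg.n_snps} SNPs)")
print(f"simulated truth: {TRUE_CHIMERISM:.1f}% "
      f"(realized donor-read fraction varies binomially per locus)")

# Each per-SNP estimate should land within ~1-2 points of 60%; the
# cross-SNP SEM quantifies their spread.
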