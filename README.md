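# revecol

Reverse-ecology analysis of closely related, co-existing bacterial
populations — the situation found for dominant rumen-epithelial
Campylobacteraceae, where one abundant lineage resolves into two clonal
populations on an ongoing speciation trajectory.

Given isolate genomes, metagenomic/metatranscriptomic reads and per-sample
covariates (e.g. SCFA concentrations), the toolkit

1. **demarcates populations** from pairwise genome relatedness: a
   transparent fragment-based ANI estimator (1 kb fragments, 70% fragment
   identity floor), complete-linkage clustering of `100 − ANI`, and the
   microdiversity criterion — candidate populations are clusters below
   species-level differentiation (<95% ANI between) with very low within
   divergence (mean < 0.4%);
2. **partitions the pangenome** into core / flexible / population-specific
   genes with the double 70% identity / 70% coverage presence rule, plus
   per-gene identity profiles and NG86 dN/dS with Jukes–Cantor correction;
3. **detects sweeps**: competitive read assignment (ties discarded), a
   native depth/allele-frequency SNP caller, SNP density in 1 kb windows,
   and the largest SNP-free region — the signature of a recently imported
   allele spreading by a gene-specific sweep — with windowed cross-population
   identity over the region;
4. **quantifies divergence** in 2.5 kb windows (raw p or JC69,
   `d = −(3/4)·ln(1 − (4/3)p)`), averaged within and between populations,
   and builds neighbor-joining gene/segment trees that expose gene-conversion
   (segment-tree discordance);
5. runs **identity-gated differential expression**: orthologue pairs with
   global identity in (80%, 97.5%] (separable under competitive mapping yet
   still orthologous) tested with a native negative-binomial Wald test —
   median-of-ratios size factors, trend-shrunken method-of-moments
   dispersion, two-sided Wald p, Benjamini–Hochberg adjustment
   (significance at adjusted p < 1e-5);
6. computes **abundance statistics**: reads-per-kilobase with the
   completeness >50% / contamination <10% genome-quality gate, paired fold
   changes (mean ± sd), and two-tailed Pearson correlations between
   population abundances and covariates (p < 0.05).

Everything is driven by a first-class synthetic-data generator
(`revecol.simgen`) that plants the evolutionary events this analysis is
meant to infer — two clonal populations at ~0.034 substitutions/site
between and <0.004 within, ~90% shared core genes, population-specific gene
blocks, an identical imported (SNP-free) segment, a duplicated two-variant
gene with a homogenized 3′ tail, NB transcript counts with planted
population-biased genes, and covariates coupled to population abundance —
and emits machine-readable ground truth for every event.

## Worked example

```python
from revecol import (SimConfig, simulate_populations, simulate_reads,
                     ani_matrix, cluster_genomes, demarcate_populations,
                     competitive_assign, call_snps, largest_snp_free_region)

cfg = SimConfig(seed=42)                     # 500 kb genomes, 5+8, all events planted
community = simulate_populations(cfg)

ani = ani_matrix(community.genomes)
pops = demarcate_populations(cluster_genomes(ani), ani)
print(pops.populations.to_string(index=False))
print(f"between-population ANI: {pops.between_ani.mean_ani.iloc[0]:.2f}%")

reads = simulate_reads(community)            # 50x, 150 bp, error-free
ref_a, ref_b = community.reference("A"), community.reference("B")
assign = competitive_assign(reads, {ref_a: community.genomes[ref_a],
                                    ref_b: community.genomes[ref_b]})
snps = call_snps(assign, reads, ref_a, community.genomes[ref_a])
region, _ = largest_snp_free_region(snps.table, len(community.genomes[ref_a]),
                                    coverage_mask=snps.coverage >= 10)
print(f"SNPs called on {ref_a}: {len(snps.table)}")
print(f"largest SNP-free region: [{region.start}, {region.end}) = {region.length} bp")
```

prints

```
population  n_members  mean_within_divergence
        P1          8                0.003190
        P2          5                0.003113
between-population ANI: 96.36%
SNPs called on A01: 4034
largest SNP-free region: [144682, 152912) = 8230 bp
```

The two planted populations are recovered with their within-population
divergence (~0.003 substitutions/site, i.e. clonal) and their between-ANI
near 96.6% (the imported segment planted in this full scenario pulls the
estimate down by ~0.2 points — it is genuinely divergent sequence). The
largest SNP-free interval on the population-A reference spans the planted
8 kb import ([144873, 152873) in this run): within population A the region
is identical in every genome, so competitive mapping finds zero
polymorphism there against a background SNP every ~130 bp.

The same steps are exposed on the command line:

```bash
revecol simulate --seed 42 --out sim/
revecol ani --fasta sim/genomes.fasta --out ani/
revecol run --seed 42 --out run/        # full pipeline with manifest
```

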