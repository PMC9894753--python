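# Methods

## The simulated community

`simgen` generates the scenario the analysis modules are meant to invert: a
single ancestral genome gives rise to two clonal populations, A and B,
which a reverse-ecology workflow must demarcate, characterise and contrast.
All substitutions are planted uniformly at random with independent sites
and no indels, so expected distances are exact functions of the planted
counts and every downstream oracle can be computed in closed form. Gene
gain and loss is realised as deletion of whole gene spans; all genomes
therefore stay colinear on the ancestral coordinate system, and the
simulator can emit a gap-free alignment over the columns shared by all
genomes (`SimulatedCommunity.core_alignment`).

Distances are parameterised the way estimators see them: `d_between`
(default **0.034** substitutions/site) is the expected *genome-to-genome*
raw distance across populations and `d_within` (default **0.003**) the
expected pairwise distance within a population. The stem between the two
population ancestors therefore carries `d_between − d_within` substitutions
per site and each genome another `d_within / 2` private ones. Site
collisions between branches are possible but contribute O(d²) ≈ 1e-4
absolute, far below every tolerance used.

Planted events, with defaults:

| event | default | note |
|---|---|---|
| genomes | 5 (A) + 8 (B), 500 kb | unequal sampling of the two populations |
| genes | 1,500, mean 280 bp (multiple of 3), ~50 bp intergenic | see below |
| core fraction | 0.90 | genes present in all genomes |
| population-specific genes | 40 (A) + 45 (B), planted in blocks of 5 | fixed in one population, absent from the other |
| other flexible genes | remainder; each missing from 2–4 random genomes | never re-creating a population-specific pattern |
| imported segment | 8 kb at 0.15 divergence vs B, identical in all A genomes | overwritten after within-population mutation, so it is SNP-free within A by construction |
| duplicated gene | two 1,500 bp copies at 0.10 divergence; last 500 bp of the second copy overwritten by the first in every B genome | produces 5′/3′ segment-tree discordance |
| reads | 150 bp, 50× per genome, error-free, uniform strands | per-base error rate is configurable |
| transcript counts | NB with dispersion 0.05, log-normal baselines (µ≈90), log-normal size factors | planted ±`de_log2fc` on `n_de_genes` core genes, n=6 samples per population |
| covariates | n=94 samples; covariate 1 rises and covariate 2 falls with log population-A abundance, Gaussian noise | acetate/propionate-like |

Gene geometry is not something the source data pin down; 1,500 genes of
~280 bp were chosen so that a full annotated gene complement fits on the
500 kb genomes used throughout the recovery experiments, keeping every
experiment at desk scale. Genome length, gene count and all event sizes are
configuration fields.

One top-level seed controls everything; the generator fans it out into
fixed streams (genomes=0, reads=1, counts=2, covariates=3) so stages can be
re-run in isolation and are byte-reproducible.

What the generator does **not** emulate: indels and rearrangements inside
homologous sequence, recombination outside the planted events, GC/codon
bias, coverage biases, sequencing error structure beyond uniform
substitutions, and overdispersion of abundances across animals. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to assembly artefacts or
alignment ambiguity in real data.

## Fragment ANI and demarcation

`compute_ani` tiles the query genome into non-overlapping 1 kb fragments
(trailing partial fragment dropped), places each fragment at its best
k-mer-seeded (k=15) location in the target on either strand, and scores the
diagonal ungapped; ANI is the mean identity of fragments at ≥70% identity,
and the retained fraction is reported alongside (no cutoff is applied to
it). Identity is deliberately a *substitution* measure: fragments that are
only part-homologous at their placement — those spanning a gene
presence/absence junction or a rearrangement breakpoint — are detected by a
non-homology run test (any 100 bp window with ≤45 matches, essentially
impossible under substitution divergence at any retainable identity) and
excluded from retention. Gap-tolerant rescue was rejected: a
minimum-edit-distance path may prefer to misalign a short flank rather than
open the true gene-sized gap, which systematically drags fragment identity
toward gene content. The two directional values are averaged for the
symmetric matrix and both are retained.

Clustering is complete linkage on `100 − ANI` with a flat cut (default 5,
i.e. 95% ANI). Demarcation re-cuts the dendrogram at twice
`100 × within_divergence_max`: complete linkage bounds the *maximum*
pairwise distance while the criterion is stated on the *mean*, and
individual pairs scatter around the mean; each resulting cluster must then
pass mean within divergence ≤ 0.004 and ≥2 members. Singletons are flagged,
never merged.

## Pangenome

Gene presence uses each gene's best hit per genome (k-mer seeded, edlib
refinement for small indels) gated at ≥70% identity **and** ≥70% query
coverage. Classes: *core* = present in every genome; *flexible* = missing
from ≥2 genomes; *population-specific* = flexible genes present in all
genomes of one population and absent from all of the other. Genes missing
from exactly one genome sit between the published definitions and are
reported separately as *near_core*, excluded from both headline counts. The
headline core fraction is computed over the non-redundant union catalog of
the two reference genomes (primary reference genes plus secondary-reference
genes not in it, orthology marked by shared locus tags), since either
reference alone lacks the other population's specific genes.

dN/dS follows Nei–Gojobori (1986) with the conventions of the reference
implementation in Biopython's codon-alignment module, against which it is
tested to 1e-9: each codon position contributes sites in thirds, changes to
stop codons count as nonsynonymous, pathway differences are averaged over
all mutational orderings with equal weight, and pN/pS receive the
Jukes–Cantor correction. Codon pairs where either codon is a stop are
excluded from sites and differences (the simulated genes are random
sequence, not ORFs). The ratio is undefined (reported NA) when dS = 0 or a
proportion saturates (p ≥ 3/4). Per-gene ratios are reported as a
distribution; only orthologue pairs with identical alignment length and
intact frame are computed.

## Sweep scan

Competitive assignment scores each read against every reference (both
strands) as matches − mismatches on the best seeded diagonal; the
highest-scoring reference wins, reads whose best identity falls below 80%
are reported unassigned, and exact ties are *discarded* rather than placed
randomly — random placement would manufacture false intra-population
polymorphism and shorten SNP-free regions, so discarding is the
conservative choice for sweep detection.

The SNP caller is native and parameter-explicit because the corresponding
filter settings in standard toolchains vary: a site is a SNP when assigned
depth ≥10 and (polymorphism mode, the default for intra-population scans)
the minor-allele fraction lies in [0.1, 0.9]. Thresholds are declared in
the VCF header. SNP density is reported per 1 kb window (final partial
window normalised by true width). The largest SNP-free region is the
longest run of positions free of SNPs and, optionally, of positions below
the depth floor, so uncovered stretches cannot masquerade as SNP-free; ties
break leftmost and the full ranked gap list is returned. The
cross-population identity track aligns the detected region to the other
reference, computes identity per 1 kb window, smooths with a centred moving
average (default 3 windows — the span is a parameter because no standard
value exists) and flags windows more than 5 points below the genome-wide
mean as breakpoints.

## Windowed divergence and trees

Window distances are direct pairwise model distances (raw p over non-gap
columns, or JC69) per fixed window (default 2.5 kb; a window larger than
the alignment spans all of it), not patristic distances from per-window
trees — the quantities of interest are the averaged within/between
distances, for which direct computation is exact and self-contained. JC69
is undefined at p ≥ 3/4 (NA with warning).

A note on stability: with substitutions planted uniformly, the
between-population count in a 2.5 kb window is approximately Poisson with
mean ~85, so the coefficient of variation of the between-population window
track cannot fall below ~10.4% regardless of implementation; measured
values are 10.4–11.3% across seeds. A stability bound below that floor is
not attainable under this model, and the corresponding check is left
failing rather than loosened.

Trees are neighbor joining on JC69 distances with deterministic
tie-breaking (first minimal Q pair in current index order) and negative
branch-length estimates clamped to zero; topology agrees with scikit-bio's
NJ on additive matrices. ML inference is deliberately out of scope: the
claims made on gene/segment trees are about topology classes (which variant
pairs are sisters), which distance NJ resolves.

## Differential expression

Orthologue pairs are reciprocal best hits; the gate keeps pairs with global
alignment identity (edit distance over the shorter gene) in (80%, 97.5%] —
distinguishable under competitive mapping yet orthologous — and retains
excluded pairs with their reason. The NB test: size factors by
median-of-ratios; per-gene dispersion by method-of-moments on normalised
counts pooled within groups, shrunk in log space (weight 0.5) toward an
`a₀ + a₁/µ` trend fitted across genes; log2 fold change with a 0.5
pseudocount; delta-method SE; two-sided Wald p against the standard normal
(the trend-shrunken dispersion pools information across genes, as standard
NB-Wald DE practice does); BH across tested pairs; all-zero pairs excluded
with status. On the planted design (|log2FC|=3, n=6/side, dispersion 0.05)
the suite measures sensitivity ≥0.8 at adjusted p < 1e-5 and a null
BH-rejection fraction ≪ 0.05. This is a simplified stand-in for full GLM
machinery: no fold-change shrinkage, no outlier refitting, single-factor
designs only — its decision surface (log2FC, adjusted p), not another
tool's exact numbers, is the tested contract.

## Abundance statistics

Reads-per-kilobase applies the conventional genome-quality gate
(completeness >50%, contamination <10%) before ranking units by median RPK.
Fold changes are per-replicate treatment/control ratios summarised as
mean ± sd; zero-control replicates are excluded with a warning. Correlations
are plain Pearson with two-tailed p from the t transform (n−2 df),
significance at p < 0.05 and *no* multiplicity correction by default,
mirroring how small correlation panels are conventionally reported (a BH
option exists). The n=94 design repeatedly samples the same eight animals;
plain Pearson ignores that pseudoreplication, and this caveat is inherited
deliberately.

## Numerical conventions

Coordinates are 0-based half-open internally; GFF3 and VCF output are
1-based (BED output 0-based half-open). Bases are encoded A,C,G,T → 0..3
(gap/N = 4) and all genome-scale operations are vectorised numpy on these
arrays. Ties everywhere break to the leftmost/lowest index. The problem
sizes used by the recovery experiments — 500 kb genomes, 13 genomes, 50×
reads, 10 demarcation replicates, 3 read-mapping replicates in the
acceptance script — were chosen as the smallest sizes at which the planted
parameters are estimated with sampling error well inside the tested
tolerances.

## Known limitations

* The aligners are k-mer-seeded and ungapped at their core (edlib handles
  small indels); there is no full gapped read mapper, no indel calling and
  no haplotype phasing.
* ANI is a substitution-identity estimator; genomes whose homology is
  dominated by large indels or repeats will show reduced aligned fractions
  rather than adjusted identities.
* The NB test handles exactly two groups and unpaired samples.
* Population demarcation assumes clonal (microdiverse) clusters; highly
  recombining populations with continuous identity gradients will not
  produce clean candidates, and the identity-distribution check
  (`identity_distribution`) is the intended diagnostic for such structure.
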