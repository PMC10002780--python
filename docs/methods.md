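# Methods

## Study design and statistical model

`hybridase` analyzes reciprocal F1 hybrid crosses of inbred parents. Each
cross × tissue unit carries an expected maternal:paternal read ratio r:
1:1 in the diploid embryo and 2:1 in the triploid endosperm, whose two
maternal genome copies double the maternal expectation under unbiased
expression. For a gene with summed allele counts (m, p), deviation from the
expectation is tested with a one-degree-of-freedom chi-square
goodness-of-fit statistic

    X² = (m − E_m)²/E_m + (p − E_p)²/E_p,
    E_m = (m+p)·r/(r+1),  E_p = (m+p)/(r+1)

without continuity correction, and the p-value is the χ²₁ upper tail.
Genes with m + p < 20 informative reads are not tested (`non_analyzed`).
P-values are converted to q-values by Benjamini–Hochberg within each
cross × tissue family; BH was chosen because the source analysis reports
q-values without naming a procedure and BH is the field default.

Fold tiers grade effect size on the raw counts: tier t ∈ {2, 5, 9} requires
max(m,p) ≥ t·min(m,p), boundaries inclusive; a zero on the low side with
reads on the high side is monoallelic expression and takes the top tier.
Tiers are computed on raw counts even in endosperm (following the source
procedure literally); note that under 2:1 dosage a paternal-preferring
allele with a 19:1 expression bias sits at an expected 9.5-fold raw ratio,
right at the tier-9 boundary, so tier-9 detection in endosperm is
intrinsically harder for paternal-preferring genes. A
dosage-corrected alternative can be obtained by pre-dividing the maternal
count by r before tiering; the default caller does not do this.

### Reciprocal reconciliation

A gene is a genotype-dependent ASEG only when both reciprocal crosses are
individually biased (q < 0.05 and tier ≥ 9 by default) toward the **same
parental genotype**. With two parents, the only other both-biased outcome
is bias toward the same parent-of-origin; such genes are flagged
`imprinted_like` and excluded from the genotype-dependent set. The pair
inherits the worse q-value and the lower tier of its two crosses. The
call-status vocabulary is therefore `non_analyzed` (either cross
unanalyzable), `non_biased`, `biased`, and `imprinted_like`; the fourth
value makes the imprinting exclusion visible instead of folding it into
`non_biased`. Requiring significance in both reciprocals (rather than
pooling reads across them) is the stricter of the two defensible readings
and guarantees the genotype-dependence of every call.

### Clusters

A cluster is a maximal chain of consecutive ASEGs on one chromosome in
which every adjacent start-to-start gap is ≤ 1 Mb (inclusive), with ≥ 2
members; a `max_span` option additionally caps the total span for the
stricter reading of "within a 1 Mb region". Mean inter-ASEG distance is the
mean of within-chromosome adjacent start-to-start gaps pooled over
chromosomes. Enrichment against chance uses a label-permutation test as the
primary statistic: ASEG labels are shuffled over the analyzable-gene
universe and the cluster count recomputed; when the number of distinct
arrangements C(n,k) ≤ 50,000 all arrangements are enumerated and the
p-value is exact, otherwise Monte Carlo with an add-one correction,
p = (1 + #{count ≥ observed}) / (n_perm + 1). A one-sided Fisher exact test
on {in observed cluster span, outside} × {ASEG, non-ASEG} is reported as a
secondary statistic, since the original 2×2 construction is not
recoverable.

### Consistency tables

For a reference set of ASEGs (one hybrid/tissue/preferred genotype), each
gene is classified in a second call set as biased-same-direction (same
preferred genotype), biased-opposite, non-biased, or non-analyzed (absent
or unanalyzable). "Consistent" requires the same preferred genotype, not
merely any bias. Display percentages use truncation to one decimal,
floor(n/d·1000)/10 — the convention that reproduces the published printed
values (223/414 → 53.8, not 53.9). The three-hybrid overlap reports Venn
region counts over gene identity and the all-hybrid-consistent share both
relative to the union and to each hybrid's own set.

### Allelic methylation (gDMRs)

Methylation level is C/(C+T). Sites need ≥ 5 reads per allele record.
Each chromosome is tiled with 200-bp windows sliding by 20 bp; a window is
analyzable when **each allele** has more than five qualifying context sites
in it (the per-allele reading of the site filter — stricter than filtering
the union). Allelic bias per window is a two-sided Fisher exact test on the
pooled 2×2 table [[meth_A, unmeth_A], [meth_B, unmeth_B]], computed by
hypergeometric enumeration (tables no more probable than the observed one).
Window q-values are BH per context. Candidates need q < 0.01, an allelic
level difference > 0.30, and a hyper-allele level > 0.40; the 40% floor is
stated for CG in the source and applied to CHG as well by default
(configurable). Candidates are refined by scoring 50-bp sub-windows (step
20, ≥ 1 qualifying site per allele, BH over all sub-windows, same three
criteria); the union of passing sub-windows is merged within 200 bp per
chromosome × hyper-allele, and each merged region's levels are re-pooled
over its sites. CHH regions are never called.

Metagene profiles split each gene into 60 body bins plus 20 bins per
2,000-bp flank (flank length is a package choice; the source does not state
one). Bin assignment is proportional to coordinates (genes shorter than 60
bp simply use coarse fractional bins), the bin order is reversed for
minus-strand genes, and the profile level per bin is the pooled
ΣC / Σ(C+T) over all genes in the set. An ASEG overlaps a gDMR when the
region intersects the 1-based inclusive gene span by ≥ 1 bp.

## The synthetic-data generator

The generator emulates the *data layout* of the emulated study, not its
biology: three inbred parents (B73, Mo17, CAU5), three reciprocal hybrid
pairs, embryo and endosperm. Defaults are the study conditions used
throughout the tests: 2,000 genes on two 5-Mb chromosomes, Poisson(3)
candidate SNPs per gene with independently drawn parental bases (so ~3/4 of
candidate sites are informative for a given pair), Poisson(100) reads per
gene per cross, 5% planted ASEGs with bias strength 0.95, 2% imprinted-like
genes, and beta-binomial allelic sampling with rho = 0.005 — mild
overdispersion of the order seen in pooled-replicate allele-count data
(rho = 0 recovers pure binomial sampling).

The maternal read probability composes the dosage prior d = r/(r+1) with
the allelic weight w of the preferred allele (w = bias_strength):
p_m = d·w_m / (d·w_m + (1−d)·w_p). Dosage is applied before bias, so
neutral endosperm genes have exactly p_m = 2/3. ASE genes attach the bias
to a genotype (and behave neutrally in hybrid pairs that do not carry their
preferred parent); imprinted-like genes attach it to the maternal or
paternal role. Gene-level counts are split multinomially across the gene's
informative SNPs, which is irrelevant downstream because calling sums them
again.

The methylome is simulated for one hybrid pair over a configurable
sub-region of each chromosome: cytosine sites every 25 bp, CG/CHG contexts
alternating in 500-bp blocks (CG-island-like, so 200-bp windows contain
~8 same-context sites and pass the > 5-site filter), a per-site background
level drawn uniformly on [0.05, 0.95] and **shared by both alleles**, and
Poisson(30) reads per site per allele. Planted gDMRs are non-overlapping
intervals (default 50 regions of 300 bp, alternating contexts) where the
hyper-allele methylates at 0.9 and the other at 0.1.

What the generator does **not** model: mapping bias and alignment
artifacts, read-level correlation between SNPs of one gene (each read is
counted once per gene here, whereas per-SNP summation can count one
fragment several times in real data), per-replicate variance (counts are
pooled), bimodal CG methylation landscapes, and sequence-driven SNP/site
density. Passing recovery tests therefore demonstrates correctness of the
calling chain under the stated sampling model, not performance on real
maize libraries.

## Verification and problem sizes

- Oracle agreement: the chi-square tail is checked against the closed form
  erfc(√(x/2)) on 1,000 random count pairs (≤ 1e-10); the Fisher p against
  exact rational hypergeometric enumeration for tables with n ≤ 40
  (≤ 1e-12); the cluster permutation p against exhaustive label enumeration
  on a 10-gene universe (exact equality).
- ASEG recovery runs at the default study conditions with rho = 0 (the
  generator's binomial calibration regime) on one hybrid pair, embryo
  tissue: sensitivity ≥ 0.9 and false-positive rate ≤ 0.01 are measured
  over planted/neutral genes analyzable in both reciprocals — genes that
  draw no informative SNP are undetectable by any allele-counting method
  and are excluded from the denominator. All planted imprinted-like genes
  must be absent from the genotype-dependent set.
- gDMR recovery uses 50 planted regions (levels 0.9 vs 0.1, depth 30,
  ~8 sites per 200 bp): precision and recall ≥ 0.9, matching calls to
  planted regions by overlap + context + hyper-allele. The all-null
  methylome (equal allele levels) must yield zero gDMRs in ≥ 95% of 20
  independent seeds; the > 30% level-difference criterion makes null calls
  essentially impossible at these depths, so the binding check is the FDR
  chain itself.
- Determinism: identical config + seed reproduces every output table
  byte-for-byte, including a full pipeline run.

Problem sizes (2,000-gene expression sims, 100–150-kb methylomes, 20 null
seeds, 2,000 permutations) were chosen so the full suite and the
acceptance script each complete in about a minute while keeping every
Monte-Carlo margin comfortable.

## Numerical and degenerate-input choices

- Ties in fold direction (m = p) can never be called biased because the
  tier is 0.
- All-zero Fisher tables return p = 1 with a log notice.
- Unsorted cluster input is sorted internally and logged; SNPs in
  overlapping genes count toward every containing gene (logged); SNPs
  outside genes are dropped (logged).
- Interval merging treats gap = next.start − current.end and merges when
  gap ≤ 200 bp; it is idempotent and order-independent.
- Coordinates are 1-based inclusive everywhere in memory and on disk
  (VCF/GFF3/TSV); only the BED export converts to 0-based half-open.

## Known limitations

- The reciprocal-reconciliation rule (significance in both crosses) is
  conservative; pooling reads across reciprocals would gain power at the
  cost of admitting single-cross artifacts.
- Per-SNP summation can multiply-count fragments spanning several SNPs in
  real data; kept deliberately to match the source procedure.
- The Fisher 2×2 for cluster enrichment is one defensible construction of
  an under-specified test; the permutation p is the primary statistic.
- CHG gDMRs reuse the CG 40% hyper-level floor unless overridden.
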