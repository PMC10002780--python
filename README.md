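# hybridase

Genotype-dependent allele-specific expression (ASE) and allelic DNA
methylation calling for reciprocal F1 hybrid crosses, modeled on maize
kernel tissues.

## The problem

In an F1 hybrid, SNPs between the two inbred parents let RNA-seq reads be
assigned to the maternal or paternal allele. A gene whose two alleles are
expressed at significantly unequal levels shows allele-specific expression.
Reciprocal crosses (A×B and B×A) separate two very different causes:

- **genotype-dependent ASE** — the same parental *genotype* is preferred in
  both cross directions (a cis-regulatory difference between the parental
  alleles);
- **imprinting** — the same *parent-of-origin* is preferred in both
  directions.

Ploidy matters: the embryo is diploid, so unbiased expression gives a 1:1
maternal:paternal read ratio, while the triploid endosperm (two maternal
genome copies) gives 2:1.

`hybridase` implements the full calling chain for this design:

1. **Informative SNPs** — sites where both parents are homozygous for
   different alleles (from a two-sample VCF).
2. **Per-gene allele counts** — per-SNP maternal/paternal reads summed over
   each gene's SNPs; genes with < 20 informative reads are non-analyzed.
3. **Ratio-deviation test** — for gene counts (m, p) and expected
   maternal:paternal ratio r, a 1-df chi-square goodness-of-fit test with
   expected counts (m+p)·r/(r+1) and (m+p)/(r+1); Benjamini–Hochberg
   q-values per cross × tissue.
4. **Fold tiers** — biased genes are graded by max(m,p) ≥ t·min(m,p) for
   t ∈ {2, 5, 9}; the default caller requires the 9-fold tier and q < 0.05.
5. **Reciprocal reconciliation** — genotype-dependent ASEGs must be biased
   toward the same genotype in both reciprocals; same-parent-of-origin bias
   is flagged `imprinted_like` and excluded.
6. **Genomic clusters** — chains of consecutive ASEGs with ≤ 1 Mb
   start-to-start gaps, with permutation and Fisher enrichment tests.
7. **Consistency tables** — cross-tissue and cross-hybrid tabulation of each
   ASEG set (biased same direction / biased opposite / non-biased /
   non-analyzed), with display percentages truncated to one decimal.
8. **gDMRs** — genotype-dependent differentially methylated regions from
   allele-resolved bisulfite counts: ≥ 5 reads per site, 200-bp windows
   sliding by 20 bp with > 5 context sites per allele, two-sided Fisher
   exact test per window, BH FDR < 0.01, allelic level difference > 30%,
   hyper-allele level > 40%, 50-bp refinement, and merging within 200 bp.
   Plus 20/60/20-bin metagene methylation profiles and ASEG × gDMR overlap.

A fully seeded synthetic-data generator (`hybridase.simulate`) emulates the
study design — three reciprocal hybrid pairs of B73/Mo17/CAU5, both kernel
tissues, beta-binomial allelic sampling, planted ASEGs/imprinted-like genes
and planted gDMRs — and emits the truth labels needed to score recovery.

## Worked example

```python
from hybridase.simulate import SimConfig, simulate
from hybridase.aseg import call_hybrid
from hybridase.methylation import call_gdmrs

cfg = SimConfig(n_genes=300, chrom_length=800_000,
                methyl_region_length=40_000, planted_gdmr_count=10, seed=5)
res = simulate(cfg)

calls = call_hybrid(res.ase_counts, res.genes, "BC/CB", "embryo")
print(calls["status"].value_counts().to_string())

gd, windows = call_gdmrs(res.methyl_sites, "CG")
print(f"{len(windows)} analyzable CG windows, {len(gd)} CG gDMRs")
```

prints

```
status
non_biased        260
non_analyzed       27
biased              9
imprinted_like      4
1670 analyzable CG windows, 5 CG gDMRs
```

Of 300 simulated genes, 27 lack sufficient informative reads, 9 are called
genotype-dependent ASEGs (all 9 are planted ASE genes of this hybrid pair —
checked against `res.truth`), and 4 genes biased toward the same
parent-of-origin in both reciprocals are excluded as imprinted-like. The
five CG gDMRs are the five planted CG regions; e.g. the first call spans
chr1:1581–1930 with allelic levels 0.92 vs 0.10 (q ≈ 3e-24) and CAU5 as the
hyper-methylated allele.

The same analyses are available from the shell:

```bash
hybridase simulate --out fixtures --seed 5
hybridase call --counts fixtures/counts.tsv --gff fixtures/genes.gff3 \
          --hybrid BC/CB --tissue embryo
hybridase gdmr --meth fixtures/methylation.tsv --context CG
hybridase run --config pipeline.yaml   # whole pipeline from one config
```

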