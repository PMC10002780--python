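"""Informative-SNP selection and per-gene allele-count aggregation.

Hybrid reads can only be assigned to a parent at sites where the two inbred
parents are homozygous for different alleles.  Per-SNP allele counts are then
summed over each gene's SNPs into a single maternal/paternal pair per
cross x tissue, and genes with fewer than ``min_total`` informative reads are
flagged non-analyzed.  Pooling replicates before testing is assumed upstream.
"""

from __future__ import annotations

import logging

import pandas as pd

from .design import CrossDesign
from .io import read_vcf_genotypes

log = logging.getLogger(__name__)

#: Minimum summed allele-informative reads for a gene to be testable.
MIN_GENE_READS = 20


def select_informative_snps(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Retain sites where both parents are homozygous for different bases.

    ``genotypes`` is the output of :func:`hybridase.io.read_vcf_genotypes`:
    chrom, pos, and one column of called base pairs per parental sample.
    Heterozygous or missing calls are dropped.  Returns
    chrom, pos, parentA_allele, parentB_allele with sample names recorded in
    ``frame.attrs['samples']``.
    """
    sample_a, sample_b = genotypes.attrs.get(
        "samples", list(genotypes.columns[-2:]))
    rows = []
    for rec in genotypes.itertuples(index=False):
        call_a = getattr(rec, sample_a)
        call_b = getattr(rec, sample_b)
        if call_a is None or call_b is None:
            continue
        if len(set(call_a)) != 1 or len(set(call_b)) != 1:
            continue  # heterozygous in a parent: uninformative
        a, b = call_a[0], call_b[0]
        if a != b:
            rows.append((rec.chrom, rec.pos, a, b))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "parentA_allele",
                                      "parentB_allele"])
    out.attrs["samples"] = [sample_a, sample_b]
    return out


def informative_snps_from_vcf(path) -> pd.DataFrame:
    """Convenience: read a two-sample VCF and select informative sites."""
    return select_informative_snps(read_vcf_genotypes(path))


def assign_snps_to_genes(snps: pd.DataFrame,
                         genes: pd.DataFrame) -> pd.DataFrame:
    """Assign SNPs to genes by coordinate containment in the gene span.

    A SNP inside two overlapping genes contributes to both (logged); SNPs
    outside every gene are dropped (logged).
    """
    merged = snps.merge(genes, on="chrom", suffixes=("", "_gene"))
    hit = merged[(merged["pos"] >= merged["start"])
                 & (merged["pos"] <= merged["end"])]
    n_orphan = len(snps) - hit.drop_duplicates(["chrom", "pos"]).shape[0]
    if n_orphan:
        log.info("%d SNPs fall outside every gene and are not counted",
                 n_orphan)
    dup = hit.duplicated(["chrom", "pos"], keep=False).sum()
    if dup:
        log.info("%d SNP assignments involve overlapping genes", dup)
    return hit[["chrom", "pos", "gene_id"]]


def aggregate_gene_counts(per_snp: pd.DataFrame, genes: pd.DataFrame,
                          design: CrossDesign,
                          informative: pd.DataFrame | None = None,
                          ) -> pd.DataFrame:
    """Sum per-SNP maternal/paternal reads into per-gene totals.

    ``per_snp`` must carry gene_id, cross, tissue, snp_pos, maternal_reads,
    paternal_reads.  Only rows for this design's cross and tissue are used;
    when ``informative`` (chrom, pos) is given, counts at other positions are
    discarded.  Every gene in ``genes`` is emitted, with zero counts and
    ``n_snps=0`` when it has no informative covered SNP.
    """
    sub = per_snp[(per_snp["cross"] == design.cross)
                  & (per_snp["tissue"] == design.tissue)]
    if (sub[["maternal_reads", "paternal_reads"]] < 0).any().any():
        raise ValueError("negative allele counts in input")
    if informative is not None:
        sub = sub.merge(genes[["gene_id", "chrom"]], on="gene_id")
        keep = informative[["chrom", "pos"]].rename(columns={"pos": "snp_pos"})
        sub = sub.merge(keep, on=["chrom", "snp_pos"])
    grouped = sub.groupby("gene_id").agg(
        maternal=("maternal_reads", "sum"),
        paternal=("paternal_reads", "sum"),
        n_snps=("snp_pos", "nunique"))
    out = genes[["gene_id"]].merge(grouped, on="gene_id", how="left")
    out[["maternal", "paternal", "n_snps"]] = (
        out[["maternal", "paternal", "n_snps"]].fillna(0).astype(int))
    out.insert(1, "cross", design.cross)
    out.insert(2, "tissue", design.tissue)
    out["status"] = flag_analyzable(out["maternal"], out["paternal"])
    return out


def flag_analyzable(maternal, paternal,
                    min_total: int = MIN_GENE_READS):
    """'analyzable' when maternal+paternal >= min_total, else 'non_analyzed'."""
    import numpy as np

    scalar = np.isscalar(maternal) and np.isscalar(paternal)
    m = pd.Series([maternal]) if scalar else pd.Series(maternal)
    p = pd.Series([paternal]) if scalar else pd.Series(paternal)
    if (m < 0).any() or (p < 0).any():
        raise ValueError("allele counts must be non-negative")
    total = m + p
    out = pd.Series("non_analyzed", index=total.index, dtype=object)
    out[total >= min_total] = "analyzable"
    return out.iloc[0] if scalar else out
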