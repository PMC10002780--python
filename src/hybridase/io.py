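"""Readers and writers for the plain-text interchange formats.

VCF and GFF3 are 1-based inclusive on disk.  Internally every table keeps
1-based coordinates as well; the only 0-based half-open output is the BED
export of gDMR calls, converted at write time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam


class ParseError(ValueError):
    """Raised when an input record cannot be interpreted."""


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hybridase-simulate
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_a}\t{sample_b}
"""


def write_vcf(snps: pd.DataFrame, parent_a: str, parent_b: str, path) -> None:
    """Write homozygous-different SNPs of one parent pair as VCFv4.2.

    `snps` carries one base column per parent; sites where the two requested
    parents share a base are uninformative for this pair and are skipped.
    REF is parent A's base (the reference-line convention), ALT parent B's.
    """
    informative = snps[snps[parent_a] != snps[parent_b]]
    informative = informative.sort_values(["chrom", "pos"])
    contigs = "".join(f"##contig=<ID={c}>\n"
                      for c in sorted(informative["chrom"].unique()))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample_a=parent_a,
                                    sample_b=parent_b))
        for rec in informative.itertuples():
            ref, alt = getattr(rec, parent_a), getattr(rec, parent_b)
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"GT\t0/0\t1/1\n")


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read a two-sample VCF into per-site resolved genotype calls.

    Returns one row per record: chrom, pos, and for each sample the pair of
    called bases (``None`` where the call is missing).  Filtering to
    informative sites is done downstream.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ParseError(f"{path}: expected 2 parental samples, "
                             f"found {len(samples)}")
        for rec in vcf:
            site = {"chrom": rec.chrom, "pos": rec.pos}
            for name in samples:
                call = rec.samples[name]
                alleles = call.alleles  # resolved bases or None
                if alleles is None or any(a is None for a in alleles):
                    site[name] = None
                else:
                    site[name] = tuple(alleles)
            rows.append(site)
    frame = pd.DataFrame(rows, columns=["chrom", "pos", *samples])
    frame.attrs["samples"] = samples
    return frame


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene spans as GFF3 with stable ``ID=`` attributes."""
    genes = genes.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\thybridase\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n")


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 into a gene-model table."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand))
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
    return frame.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------- TSV

_REQUIRED = {
    "counts": ["gene_id", "cross", "tissue", "snp_pos", "maternal_reads",
               "paternal_reads"],
    "methylation": ["chrom", "pos", "strand", "context", "allele",
                    "count_methylated", "count_total"],
    "calls": ["gene_id", "hybrid", "tissue", "status", "q_value",
              "fold_tier", "preferred_genotype"],
}


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    """Read a TSV, optionally validating a known schema."""
    frame = pd.read_csv(path, sep="\t")
    if kind is not None:
        missing = set(_REQUIRED[kind]) - set(frame.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for rec in intervals.itertuples():
            name = getattr(rec, "name", None) or getattr(
                rec, "hyper_allele", ".")
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{name}\n")
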