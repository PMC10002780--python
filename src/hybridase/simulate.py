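"""Synthetic allele-resolved data for reciprocal maize-like hybrid crosses.

The generator emulates the data layout of a kernel ASE study: three inbred
parents crossed into reciprocal F1 hybrids, embryo (1:1 maternal:paternal
dosage) and endosperm (2:1) sampled, RNA reads assigned to parental alleles at
informative SNPs, and allele-resolved bisulfite counts over a genomic region
with planted genotype-dependent differentially methylated regions (gDMRs).

Planted truth labels are emitted alongside every table so that callers can be
scored for recovery.  All sampling is driven by a single integer seed and is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_HYBRIDS, TISSUES, hybrid_designs, parse_hybrid

_BASES = np.array(["A", "C", "G", "T"])

# fixed spawn keys so each stage has an independent, reproducible stream
_K_ANNOT, _K_TRUTH, _K_COUNTS, _K_METH = 0, 1, 2, 3


class SimError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults describe the emulated study: three reciprocal hybrid pairs of
    B73/Mo17/CAU5, both kernel tissues, ~100x allele-informative coverage per
    gene, 5% genotype-dependent ASE genes at 0.95 allelic bias, 2% imprinted-
    like genes, and mildly overdispersed allelic sampling.
    """

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 2_000
    snps_per_gene_mean: float = 3.0
    depth_mean: float = 100.0
    dispersion: float = 0.005  # beta-binomial rho; 0 = pure binomial
    frac_aseg: float = 0.05
    frac_imprinted: float = 0.02
    bias_strength: float = 0.95
    parents: tuple[str, ...] = ("B73", "Mo17", "CAU5")
    hybrids: tuple[str, ...] = DEFAULT_HYBRIDS
    tissues: tuple[str, ...] = TISSUES
    # methylome arm (simulated for one hybrid pair over a sub-region)
    methyl_hybrid: str = "MC/CM"
    methyl_region_length: int = 150_000
    methyl_site_spacing: int = 25
    methyl_depth_mean: float = 30.0
    planted_gdmr_count: int = 50
    planted_gdmr_width: int = 300
    gdmr_hyper_level: float = 0.9
    gdmr_hypo_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_aseg + self.frac_imprinted > 1:
            raise SimError("frac_aseg + frac_imprinted must be <= 1")
        if not 0.5 <= self.bias_strength <= 1.0:
            raise SimError("bias_strength must be in [0.5, 1.0]")
        if not 0 <= self.dispersion < 1:
            raise SimError("dispersion (rho) must be in [0, 1)")
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "methyl_site_spacing"):
            if getattr(self, name) <= 0:
                raise SimError(f"{name} must be positive")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthSet:
    """Planted per-gene labels and planted gDMR intervals."""

    genes: pd.DataFrame  # gene_id, label, preferred_parent
    gdmrs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "context", "hyper_allele"]))

    def labels_for(self, parents: frozenset[str]) -> pd.Series:
        """Per-gene effective label within one hybrid pair.

        An ASE gene whose preferred parent is not part of the pair behaves
        neutrally in that pair.
        """
        lab = self.genes.set_index("gene_id")["label"].copy()
        pref = self.genes.set_index("gene_id")["preferred_parent"]
        outside = lab.str.startswith("aseg") & ~pref.isin(list(parents))
        lab[outside] = "neutral"
        return lab


def _rng(cfg: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed,
                                                        spawn_key=(key,)))


def gen_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping genes and informative SNP candidates.

    Returns ``(genes, snps)``: genes with 1-based inclusive spans and strand,
    SNPs with one base column per parent (parents may coincide at a site, in
    which case the site is uninformative for that pair).
    """
    rng = _rng(cfg, _K_ANNOT)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    gene_rows, snp_rows = [], []
    gid = 0
    for chrom, n_c in zip(cfg.chromosomes, per_chrom):
        if n_c == 0:
            continue
        slot = cfg.chrom_length // n_c
        if slot < 400:
            raise SimError(
                f"n_genes too large: {n_c} genes on {cfg.chrom_length} bp "
                f"leaves {slot} bp per gene")
        for j in range(int(n_c)):
            gid += 1
            max_len = min(3000, slot - 100)
            length = int(rng.integers(300, max_len + 1))
            start = int(j * slot + rng.integers(1, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid:05d}"
            gene_rows.append((gene_id, chrom, start, start + length - 1,
                              strand))
            n_snp = int(rng.poisson(cfg.snps_per_gene_mean))
            n_snp = min(n_snp, length)
            if n_snp:
                pos = np.sort(rng.choice(np.arange(start, start + length),
                                         size=n_snp, replace=False))
                bases = rng.integers(0, 4, size=(n_snp, len(cfg.parents)))
                for k, p in enumerate(pos):
                    snp_rows.append((chrom, int(p), gene_id,
                                     *(_BASES[b] for b in bases[k])))
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end",
                                  "strand"])
    snps = pd.DataFrame(snp_rows,
                        columns=["chrom", "pos", "gene_id", *cfg.parents])
    return genes, snps


def assign_truth(cfg: SimConfig, genes: pd.DataFrame) -> TruthSet:
    """Assign neutral / ASE / imprinted-like labels to genes."""
    rng = _rng(cfg, _K_TRUTH)
    n = len(genes)
    n_aseg = int(round(cfg.frac_aseg * n))
    n_imp = int(round(cfg.frac_imprinted * n))
    idx = rng.permutation(n)
    labels = np.array(["neutral"] * n, dtype=object)
    pref = np.array([""] * n, dtype=object)
    aseg_idx = idx[:n_aseg]
    labels[aseg_idx] = "aseg"
    pref[aseg_idx] = rng.choice(cfg.parents, size=n_aseg)
    imp_idx = idx[n_aseg:n_aseg + n_imp]
    role = rng.choice(["maternal", "paternal"], size=n_imp)
    labels[imp_idx] = np.char.add("imprinted_", role.astype(str))
    truth = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                          "label": labels, "preferred_parent": pref})
    return TruthSet(genes=truth)


def _maternal_prob(label: str, pref: str, design, bias: float) -> float:
    """Expected maternal read fraction: dosage prior times allelic bias."""
    d = design.expected_ratio / (design.expected_ratio + 1.0)
    if label == "neutral":
        return d
    if label == "aseg":
        w_m = bias if pref == design.maternal else 1.0 - bias
    elif label == "imprinted_maternal":
        w_m = bias
    elif label == "imprinted_paternal":
        w_m = 1.0 - bias
    else:
        raise SimError(f"unknown truth label {label!r}")
    w_p = 1.0 - w_m
    return d * w_m / (d * w_m + (1.0 - d) * w_p)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, p: np.ndarray,
                   rho: float) -> np.ndarray:
    """Vector of allele counts with beta-binomial overdispersion rho."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n)
    if rho <= 0:
        return rng.binomial(n, p)
    nu = 1.0 / rho - 1.0
    a, b = np.clip(p * nu, 1e-9, None), np.clip((1.0 - p) * nu, 1e-9, None)
    pp = rng.beta(a, b)
    pp[p <= 0.0] = 0.0
    pp[p >= 1.0] = 1.0
    return rng.binomial(n, pp)


def simulate_ase_counts(cfg: SimConfig, truth: TruthSet,
                        snps: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP allele-resolved read counts for every cross x tissue.

    Gene-level depth is Poisson around ``depth_mean``; the maternal count is
    beta-binomial with the configured dispersion around the expected maternal
    fraction (dosage prior x allelic bias); per-gene counts are then split
    multinomially across the gene's informative SNPs.
    """
    rng = _rng(cfg, _K_COUNTS)
    rows = []
    lab_all = truth.genes.set_index("gene_id")
    for hybrid in cfg.hybrids:
        for tissue in cfg.tissues:
            fwd, rev = hybrid_designs(hybrid, tissue)
            informative = snps[snps[fwd.maternal] != snps[fwd.paternal]]
            lab = truth.labels_for(fwd.parents)
            for design in (fwd, rev):
                for gene_id, grp in informative.groupby("gene_id", sort=True):
                    label = lab[gene_id]
                    pref = lab_all.loc[gene_id, "preferred_parent"]
                    p_m = _maternal_prob(label, pref, design,
                                         cfg.bias_strength)
                    depth = int(rng.poisson(cfg.depth_mean))
                    if depth == 0:
                        continue
                    mat = int(_beta_binomial(rng, np.array([depth]),
                                             np.array([p_m]),
                                             cfg.dispersion)[0])
                    pat = depth - mat
                    k = len(grp)
                    probs = np.full(k, 1.0 / k)
                    mat_split = rng.multinomial(mat, probs)
                    pat_split = rng.multinomial(pat, probs)
                    for (pos, m, p) in zip(grp["pos"], mat_split, pat_split):
                        rows.append((gene_id, design.cross, tissue, int(pos),
                                     int(m), int(p)))
    return pd.DataFrame(rows, columns=["gene_id", "cross", "tissue",
                                       "snp_pos", "maternal_reads",
                                       "paternal_reads"])


def _plant_gdmrs(cfg: SimConfig, rng: np.random.Generator,
                 alleles: tuple[str, str]) -> pd.DataFrame:
    """Non-overlapping planted gDMR intervals in CG and CHG contexts."""
    total = cfg.planted_gdmr_count
    if total == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "hyper_allele"])
    per_chrom = np.full(cfg.n_chromosomes, total // cfg.n_chromosomes)
    per_chrom[: total % cfg.n_chromosomes] += 1
    rows = []
    i = 0
    for chrom, n_c in zip(cfg.chromosomes, per_chrom):
        if n_c == 0:
            continue
        slot = cfg.methyl_region_length // int(n_c)
        # keep >=600 bp between regions so merged calls stay separable
        if slot < cfg.planted_gdmr_width + 600:
            raise SimError("planted gDMRs do not fit the methylated region")
        for j in range(int(n_c)):
            start = int(j * slot + rng.integers(1, slot
                                                - cfg.planted_gdmr_width
                                                - 400))
            rows.append((chrom, start, start + cfg.planted_gdmr_width - 1,
                         "CG" if i % 2 == 0 else "CHG",
                         alleles[int(rng.integers(0, 2))]))
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "hyper_allele"])


def simulate_methylome(cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Allele-resolved cytosine table with planted gDMRs.

    Background methylation is drawn per site and shared by both alleles;
    inside a planted gDMR the hyper-allele methylates at
    ``gdmr_hyper_level`` and the other allele at ``gdmr_hypo_level``.
    Updates ``truth.gdmrs`` in place with the planted intervals.
    """
    rng = _rng(cfg, _K_METH)
    fwd, _ = hybrid_designs(cfg.methyl_hybrid, "endosperm")
    alleles = (fwd.maternal, fwd.paternal)
    gdmrs = _plant_gdmrs(cfg, rng, alleles)
    truth.gdmrs = gdmrs
    rows = []
    for chrom in cfg.chromosomes:
        pos = np.arange(cfg.methyl_site_spacing, cfg.methyl_region_length + 1,
                        cfg.methyl_site_spacing)
        # contexts alternate in 500-bp blocks (CG-island-like) so that
        # 200-bp windows inside a block have enough same-context sites
        context = np.where((pos // 500) % 2 == 0, "CG", "CHG").astype(object)
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        base_level = rng.uniform(0.05, 0.95, size=len(pos))
        level = {a: base_level.copy() for a in alleles}
        regions = gdmrs[gdmrs["chrom"] == chrom]
        for reg in regions.itertuples():
            inside = (pos >= reg.start) & (pos <= reg.end)
            context[inside] = reg.context
            hypo = alleles[0] if reg.hyper_allele == alleles[1] else alleles[1]
            level[reg.hyper_allele][inside] = cfg.gdmr_hyper_level
            level[hypo][inside] = cfg.gdmr_hypo_level
        for allele in alleles:
            total = rng.poisson(cfg.methyl_depth_mean, size=len(pos))
            meth = rng.binomial(total, level[allele])
            for i in range(len(pos)):
                rows.append((chrom, int(pos[i]), strand[i], context[i],
                             allele, int(meth[i]), int(total[i])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "allele", "count_methylated",
                                       "count_total"])


@dataclass
class SimResult:
    """All tables of one synthetic study."""

    config: SimConfig
    genes: pd.DataFrame
    snps: pd.DataFrame
    truth: TruthSet
    ase_counts: pd.DataFrame
    methyl_sites: pd.DataFrame


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: annotation, truth, RNA counts, methylome."""
    genes, snps = gen_annotation(cfg)
    truth = assign_truth(cfg, genes)
    counts = simulate_ase_counts(cfg, truth, snps)
    meth = simulate_methylome(cfg, truth)
    return SimResult(config=cfg, genes=genes, snps=snps, truth=truth,
                     ase_counts=counts, methyl_sites=meth)


def write_fixtures(result: SimResult, outdir) -> dict[str, str]:
    """Write all tables as plain-text VCF/GFF3/TSV fixtures.

    One two-sample VCF of homozygous-different SNPs is written per hybrid
    pair.  Returns a name -> path map.
    """
    from . import io as hio  # local import to avoid a cycle
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths: dict[str, str] = {}
    gff = outdir / "genes.gff3"
    hio.write_gff3(result.genes, gff)
    paths["gff"] = str(gff)
    for hybrid in cfg.hybrids:
        fwd_id, _ = parse_hybrid(hybrid)
        fwd, _ = hybrid_designs(hybrid, "embryo")
        vcf = outdir / f"snps_{fwd_id}.vcf"
        hio.write_vcf(result.snps, fwd.maternal, fwd.paternal, vcf)
        paths[f"vcf_{fwd_id}"] = str(vcf)
    for name, frame in [("counts", result.ase_counts),
                        ("methylation", result.methyl_sites),
                        ("truth_genes", result.truth.genes),
                        ("truth_gdmrs", result.truth.gdmrs),
                        ("snp_table", result.snps)]:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    return paths
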