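"""Allele-specific DNA methylation: gDMR calling and metagene profiles.

Genotype-dependent differentially methylated regions (gDMRs) are called from
allele-resolved cytosine counts in the CG or CHG context: sites need >= 5
reads; a 200-bp window sliding by 20 bp is analyzable when both alleles have
more than five qualifying sites in it; allelic bias per window is tested with
a two-sided Fisher exact test on the pooled methylated/unmethylated counts;
window p-values are BH-adjusted per context, and windows with q < 0.01, an
allelic level difference > 30% and a hyper-allele level > 40% become
candidates.  Candidates are refined at 50-bp resolution and calls within
200 bp of each other are merged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_SITE_READS = 5
WINDOW, STEP, MIN_SITES = 200, 20, 6
GDMR_FDR, GDMR_MIN_DIFF, GDMR_MIN_HYPER = 0.01, 0.30, 0.40


def site_filter(sites: pd.DataFrame,
                min_reads: int = MIN_SITE_READS) -> pd.DataFrame:
    """Keep allele-resolved cytosine records with >= min_reads total reads."""
    return sites[sites["count_total"] >= min_reads].reset_index(drop=True)


def window_fisher(meth_a: int, unmeth_a: int, meth_b: int,
                  unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one window's pooled allele counts.

    Computed by hypergeometric enumeration: the p-value sums the
    probabilities of all tables (at fixed margins) no more likely than the
    observed one.  An all-zero table is uninformative and returns 1.
    """
    n = meth_a + unmeth_a + meth_b + unmeth_b
    if n == 0:
        log.info("window_fisher on an all-zero table; returning p=1")
        return 1.0
    row_a = meth_a + unmeth_a
    col_meth = meth_a + meth_b
    lo = max(0, row_a + col_meth - n)
    hi = min(row_a, col_meth)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col_meth, row_a)
    p_obs = stats.hypergeom.pmf(meth_a, n, col_meth, row_a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    if p > 1.0 - 1e-12:  # full support summed; absorb float round-off
        return 1.0
    return p


def _allele_pair(sites: pd.DataFrame) -> tuple[str, str]:
    alleles = sorted(sites["allele"].unique())
    if len(alleles) != 2:
        raise ValueError(f"expected exactly two alleles, found {alleles}")
    return alleles[0], alleles[1]


def window_scan(sites: pd.DataFrame, context: str, window: int = WINDOW,
                step: int = STEP, min_sites: int = MIN_SITES,
                min_reads: int = MIN_SITE_READS) -> pd.DataFrame:
    """Tile chromosomes and pool per-allele counts in analyzable windows.

    A window [start, start+window-1] (1-based) is analyzable when each
    allele has at least ``min_sites`` context sites with >= min_reads reads
    inside it ("more than five sites" at the defaults).
    """
    if step > window:
        log.warning("step %d > window %d leaves uncovered gaps", step, window)
    sites = site_filter(sites[sites["context"] == context], min_reads)
    if sites.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "context"])
    allele_a, allele_b = _allele_pair(sites)
    rows = []
    for chrom, chrom_sites in sites.groupby("chrom", sort=True):
        per_allele = {}
        for allele in (allele_a, allele_b):
            sub = chrom_sites[chrom_sites["allele"] == allele]
            sub = sub.sort_values("pos")
            per_allele[allele] = (
                sub["pos"].to_numpy(),
                np.concatenate(([0], np.cumsum(sub["count_methylated"]))),
                np.concatenate(([0], np.cumsum(sub["count_total"]))))
        max_pos = int(chrom_sites["pos"].max())
        starts = np.arange(1, max_pos + 1, step)
        stats_ = {}
        for allele, (pos, cmeth, ctot) in per_allele.items():
            left = np.searchsorted(pos, starts)
            right = np.searchsorted(pos, starts + window)
            stats_[allele] = (right - left, cmeth[right] - cmeth[left],
                              ctot[right] - ctot[left])
        n_a, meth_a, tot_a = stats_[allele_a]
        n_b, meth_b, tot_b = stats_[allele_b]
        keep = (n_a >= min_sites) & (n_b >= min_sites)
        for i in np.flatnonzero(keep):
            rows.append((chrom, int(starts[i]), int(starts[i] + window - 1),
                         context, int(n_a[i]), int(meth_a[i]),
                         int(tot_a[i] - meth_a[i]), int(n_b[i]),
                         int(meth_b[i]), int(tot_b[i] - meth_b[i])))
    out = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "context", "n_sites_a", "meth_a",
        "unmeth_a", "n_sites_b", "meth_b", "unmeth_b"])
    if len(out):
        out["level_a"] = out["meth_a"] / (out["meth_a"] + out["unmeth_a"])
        out["level_b"] = out["meth_b"] / (out["meth_b"] + out["unmeth_b"])
    out.attrs["alleles"] = (allele_a, allele_b)
    return out


def test_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Add Fisher p-values and BH q-values to scanned windows."""
    out = windows.copy()
    if out.empty:
        out["p_value"] = out["q_value"] = []
        return out
    out["p_value"] = [
        window_fisher(r.meth_a, r.unmeth_a, r.meth_b, r.unmeth_b)
        for r in out.itertuples()]
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out.attrs = dict(windows.attrs)
    return out


def merge_intervals(intervals: pd.DataFrame,
                    max_gap: int = 200) -> pd.DataFrame:
    """Coalesce 1-based inclusive intervals whose gap is <= max_gap.

    Intervals are grouped by every column other than start/end (chromosome,
    context, hyper-allele, ...) before merging; the result is independent of
    input order and idempotent.
    """
    if intervals.empty:
        return intervals.copy()
    keys = [c for c in intervals.columns if c not in ("start", "end")]
    rows = []
    grouped = intervals.groupby(keys, sort=True) if keys else \
        [((), intervals)]
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        grp = grp.sort_values("start")
        cur_start, cur_end = None, None
        for rec in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end = rec.start, rec.end
            elif rec.start - cur_end <= max_gap:
                cur_end = max(cur_end, rec.end)
            else:
                rows.append((*key, cur_start, cur_end))
                cur_start, cur_end = rec.start, rec.end
        if cur_start is not None:
            rows.append((*key, cur_start, cur_end))
    out = pd.DataFrame(rows, columns=[*keys, "start", "end"])
    return out[list(intervals.columns)].sort_values(
        keys + ["start"] if keys else ["start"]).reset_index(drop=True)


def _passing(frame: pd.DataFrame, fdr: float, min_diff: float,
             min_hyper: float) -> pd.Series:
    diff = (frame["level_a"] - frame["level_b"]).abs()
    hyper = frame[["level_a", "level_b"]].max(axis=1)
    return (frame["q_value"] < fdr) & (diff > min_diff) & (hyper > min_hyper)


def call_gdmrs(sites: pd.DataFrame, context: str, window: int = WINDOW,
               step: int = STEP, min_sites: int = MIN_SITES,
               min_reads: int = MIN_SITE_READS, fdr: float = GDMR_FDR,
               min_diff: float = GDMR_MIN_DIFF,
               min_hyper_level: float = GDMR_MIN_HYPER,
               refine_window: int = 50, merge_gap: int = 200,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call genotype-dependent DMRs in one context.

    Returns ``(gdmrs, windows)`` where ``windows`` is the tested window
    table.  Candidate windows passing FDR/level criteria are re-scored in
    50-bp sub-windows (>= 1 qualifying site per allele, BH over all
    sub-windows); the union of passing sub-windows is merged within
    ``merge_gap`` per hyper-allele to produce the final intervals, whose
    levels are re-pooled over their sites.
    """
    windows = test_windows(window_scan(sites, context, window, step,
                                       min_sites, min_reads))
    empty = pd.DataFrame(columns=["chrom", "start", "end", "context",
                                  "hyper_allele", "level_a", "level_b",
                                  "q_value"])
    if windows.empty:
        log.info("no analyzable %s windows", context)
        return empty, windows
    allele_a, allele_b = windows.attrs["alleles"]
    cand = windows[_passing(windows, fdr, min_diff, min_hyper_level)]
    if cand.empty:
        return empty, windows
    regions = merge_intervals(cand[["chrom", "start", "end"]], max_gap=0)

    # 50-bp refinement inside candidate regions
    fsites = site_filter(sites[sites["context"] == context], min_reads)
    sub_rows = []
    for reg in regions.itertuples():
        for s in range(int(reg.start), int(reg.end) - refine_window + 2,
                       step):
            e = s + refine_window - 1
            inside = fsites[(fsites["chrom"] == reg.chrom)
                            & (fsites["pos"] >= s) & (fsites["pos"] <= e)]
            pooled = inside.groupby("allele")[
                ["count_methylated", "count_total"]].sum()
            if not {allele_a, allele_b} <= set(pooled.index):
                continue
            ma, ta = pooled.loc[allele_a]
            mb, tb = pooled.loc[allele_b]
            if ta == 0 or tb == 0:
                continue
            sub_rows.append((reg.chrom, s, e, int(ma), int(ta - ma),
                             int(mb), int(tb - mb)))
    if not sub_rows:
        return empty, windows
    sub = pd.DataFrame(sub_rows, columns=["chrom", "start", "end", "meth_a",
                                          "unmeth_a", "meth_b", "unmeth_b"])
    sub["level_a"] = sub["meth_a"] / (sub["meth_a"] + sub["unmeth_a"])
    sub["level_b"] = sub["meth_b"] / (sub["meth_b"] + sub["unmeth_b"])
    sub["p_value"] = [window_fisher(r.meth_a, r.unmeth_a, r.meth_b,
                                    r.unmeth_b) for r in sub.itertuples()]
    sub["q_value"] = multipletests(sub["p_value"], method="fdr_bh")[1]
    sub = sub[_passing(sub, fdr, min_diff, min_hyper_level)]
    if sub.empty:
        return empty, windows
    sub = sub.copy()
    sub["hyper_allele"] = np.where(sub["level_a"] >= sub["level_b"],
                                   allele_a, allele_b)
    merged = merge_intervals(
        sub[["chrom", "hyper_allele", "start", "end"]], max_gap=merge_gap)

    out_rows = []
    for rec in merged.itertuples():
        inside = fsites[(fsites["chrom"] == rec.chrom)
                        & (fsites["pos"] >= rec.start)
                        & (fsites["pos"] <= rec.end)]
        pooled = inside.groupby("allele")[
            ["count_methylated", "count_total"]].sum()
        lev = {a: (pooled.loc[a, "count_methylated"]
                   / pooled.loc[a, "count_total"])
               if a in pooled.index and pooled.loc[a, "count_total"] else
               np.nan for a in (allele_a, allele_b)}
        contrib = sub[(sub["chrom"] == rec.chrom)
                      & (sub["hyper_allele"] == rec.hyper_allele)
                      & (sub["start"] <= rec.end)
                      & (sub["end"] >= rec.start)]
        out_rows.append((rec.chrom, int(rec.start), int(rec.end), context,
                         rec.hyper_allele, lev[allele_a], lev[allele_b],
                         float(contrib["q_value"].min())))
    gdmrs = pd.DataFrame(out_rows, columns=["chrom", "start", "end",
                                            "context", "hyper_allele",
                                            "level_a", "level_b", "q_value"])
    gdmrs.attrs["alleles"] = (allele_a, allele_b)
    return gdmrs.sort_values(["chrom", "start"]).reset_index(drop=True), \
        windows


def metagene_profile(sites: pd.DataFrame, genes: pd.DataFrame,
                     flank: int = 2000, context: str | None = None,
                     n_body: int = 60, n_flank: int = 20,
                     min_reads: int = MIN_SITE_READS) -> pd.DataFrame:
    """Pooled per-bin methylation levels over a gene set, per allele.

    Each gene contributes ``n_flank`` upstream bins, ``n_body`` gene-body
    bins and ``n_flank`` downstream bins (bins 0..99 at the defaults), with
    the bin order flipped for minus-strand genes so bin 0 is always the 5'
    end.  The bin level is the pooled sum(C)/sum(C+T) over all genes' sites
    assigned to the bin.
    """
    work = sites if context is None else sites[sites["context"] == context]
    work = site_filter(work, min_reads)
    alleles = sorted(work["allele"].unique())
    n_bins = n_body + 2 * n_flank
    meth = {a: np.zeros(n_bins) for a in alleles}
    total = {a: np.zeros(n_bins) for a in alleles}
    short = 0
    for gene in genes.itertuples():
        length = gene.end - gene.start + 1
        if length < n_body:
            short += 1
        near = work[(work["chrom"] == gene.chrom)
                    & (work["pos"] >= gene.start - flank)
                    & (work["pos"] <= gene.end + flank)]
        if near.empty:
            continue
        pos = near["pos"].to_numpy()
        rel = np.empty(len(pos), dtype=int)
        upstream = pos < gene.start
        downstream = pos > gene.end
        body = ~upstream & ~downstream
        rel[upstream] = ((pos[upstream] - (gene.start - flank))
                         * n_flank // flank)
        rel[body] = n_flank + (pos[body] - gene.start) * n_body // length
        rel[downstream] = (n_flank + n_body
                           + (pos[downstream] - gene.end - 1)
                           * n_flank // flank)
        rel = np.clip(rel, 0, n_bins - 1)
        if gene.strand == "-":
            rel = n_bins - 1 - rel
        for allele in alleles:
            mask = (near["allele"] == allele).to_numpy()
            np.add.at(meth[allele], rel[mask],
                      near["count_methylated"].to_numpy()[mask])
            np.add.at(total[allele], rel[mask],
                      near["count_total"].to_numpy()[mask])
    if short:
        log.info("%d genes shorter than %d bp use fractional body bins",
                 short, n_body)
    region = (["upstream"] * n_flank + ["body"] * n_body
              + ["downstream"] * n_flank)
    out = pd.DataFrame({"bin": np.arange(n_bins), "region": region})
    for allele in alleles:
        with np.errstate(invalid="ignore"):
            out[f"level_{allele}"] = np.where(total[allele] > 0,
                                              meth[allele] / total[allele],
                                              np.nan)
        out[f"meth_{allele}"] = meth[allele].astype(int)
        out[f"total_{allele}"] = total[allele].astype(int)
    return out


def overlap_aseg_gdmr(aseg_calls: pd.DataFrame, gdmrs: pd.DataFrame,
                      genes: pd.DataFrame) -> pd.DataFrame:
    """ASEG x gDMR overlaps (>= 1 bp intersection with the gene span).

    Returns one row per (ASEG, gDMR) overlap cross-classified by the ASEG's
    preferred genotype and the gDMR's hyper-methylated allele.
    """
    asegs = aseg_calls[aseg_calls["status"] == "biased"].merge(
        genes[["gene_id", "chrom", "start", "end"]], on="gene_id")
    if len(gdmrs):
        bad = set(gdmrs["chrom"]) - set(genes["chrom"])
        if bad:
            raise ValueError(
                f"gDMR chromosomes not in gene models: {sorted(bad)}")
    rows = []
    for gd in gdmrs.itertuples():
        hits = asegs[(asegs["chrom"] == gd.chrom)
                     & (asegs["start"] <= gd.end)
                     & (asegs["end"] >= gd.start)]
        for g in hits.itertuples():
            rows.append((g.gene_id, g.preferred_genotype, gd.chrom,
                         gd.start, gd.end, gd.context, gd.hyper_allele))
    return pd.DataFrame(rows, columns=["gene_id", "preferred_genotype",
                                       "gdmr_chrom", "gdmr_start",
                                       "gdmr_end", "context",
                                       "hyper_allele"])
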