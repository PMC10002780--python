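"""Genomic clustering of ASEGs and enrichment against chance.

A cluster is a maximal chain of consecutive ASEGs on one chromosome whose
adjacent start-to-start gaps are all <= 1 Mb (inclusive), with at least two
members.  Enrichment of the observed cluster count is assessed primarily by a
label-permutation test over the gene universe (exhaustive when the number of
arrangements is small), with a Fisher 2x2 of in-cluster membership as a
secondary statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MAX_GAP = 1_000_000
_EXHAUSTIVE_LIMIT = 50_000


@dataclass
class ClusterRecord:
    chrom: str
    genes: list[str]
    start: int
    end: int
    shared_direction: bool

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def size(self) -> int:
        return len(self.genes)


def _sorted_positions(positions: pd.DataFrame) -> pd.DataFrame:
    if not positions["start"].is_monotonic_increasing:
        log.info("cluster input not sorted; sorting by chrom,start")
    return positions.sort_values(["chrom", "start"]).reset_index(drop=True)


def find_clusters(positions: pd.DataFrame, max_gap: int = MAX_GAP,
                  min_size: int = 2,
                  max_span: int | None = None) -> list[ClusterRecord]:
    """Chain consecutive ASEGs with start-to-start gaps <= max_gap.

    ``positions``: gene_id, chrom, start (gene span end and
    preferred_genotype optional).  ``max_span`` optionally also caps the
    total cluster span.  Each gene belongs to at most one cluster.
    """
    pos = _sorted_positions(positions)
    has_dir = "preferred_genotype" in pos.columns
    out: list[ClusterRecord] = []
    for chrom, grp in pos.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        run = [0]
        for i in range(1, len(grp) + 1):
            if i < len(grp) and starts[i] - starts[i - 1] <= max_gap:
                run.append(i)
                continue
            if len(run) >= min_size:
                members = grp.iloc[run]
                end = int(members["end"].max()) if "end" in members \
                    else int(members["start"].max())
                shared = (members["preferred_genotype"].nunique() == 1
                          if has_dir else False)
                rec = ClusterRecord(chrom=chrom,
                                    genes=list(members["gene_id"]),
                                    start=int(members["start"].min()),
                                    end=end, shared_direction=bool(shared))
                if max_span is None or rec.span <= max_span:
                    out.append(rec)
            run = [i] if i < len(grp) else []
    return out


def mean_adjacent_distance(positions: pd.DataFrame) -> float:
    """Mean start-to-start gap between consecutive ASEGs, pooled over
    chromosomes."""
    pos = _sorted_positions(positions)
    gaps: list[np.ndarray] = []
    for _, grp in pos.groupby("chrom"):
        if len(grp) >= 2:
            gaps.append(np.diff(grp["start"].to_numpy()))
    if not gaps:
        raise ValueError("need at least two ASEGs on one chromosome")
    return float(np.mean(np.concatenate(gaps)))


def _count_clusters(chrom_codes: np.ndarray, starts: np.ndarray,
                    max_gap: int, min_size: int = 2) -> int:
    """Number of clusters among sorted (chrom_code, start) positions."""
    if len(starts) < min_size:
        return 0
    adj = (np.diff(starts) <= max_gap) & (np.diff(chrom_codes) == 0)
    # a cluster of size >= 2 begins at every True not preceded by a True
    begins = adj & ~np.concatenate(([False], adj[:-1]))
    if min_size <= 2:
        return int(begins.sum())
    count = 0
    run = 0
    for a in adj:
        run = run + 1 if a else 0
        if run == min_size - 1:
            count += 1
    return count


def cluster_enrichment(aseg_ids, universe: pd.DataFrame,
                       max_gap: int = MAX_GAP, min_size: int = 2,
                       n_perm: int = 2_000, seed: int = 0) -> dict:
    """Permutation and Fisher tests of ASEG clustering.

    ``universe``: gene_id, chrom, start for every analyzable gene.  The
    permutation shuffles ASEG labels over universe positions and recomputes
    the cluster count; when the number of distinct label arrangements is at
    most 50,000 all of them are enumerated and the p-value is exact,
    otherwise Monte Carlo with add-one correction is used.  The Fisher 2x2
    cross-classifies gene membership in observed cluster spans against ASEG
    status (one-sided, enrichment).
    """
    aseg_ids = set(aseg_ids)
    if not aseg_ids <= set(universe["gene_id"]):
        raise ValueError("ASEG set is not contained in the gene universe")
    if n_perm < 100:
        log.warning("n_perm=%d is small; permutation p will be coarse",
                    n_perm)
    uni = _sorted_positions(universe)
    codes = uni["chrom"].astype("category").cat.codes.to_numpy()
    starts = uni["start"].to_numpy()
    is_aseg = uni["gene_id"].isin(aseg_ids).to_numpy()
    k = int(is_aseg.sum())
    n = len(uni)

    observed = _count_clusters(codes[is_aseg], starts[is_aseg], max_gap,
                               min_size)

    def count_for(mask: np.ndarray) -> int:
        return _count_clusters(codes[mask], starts[mask], max_gap, min_size)

    if comb(n, k) <= _EXHAUSTIVE_LIMIT:
        from itertools import combinations

        hits = total = 0
        null_sum = 0.0
        for combo in combinations(range(n), k):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            c = count_for(mask)
            null_sum += c
            hits += c >= observed
            total += 1
        perm_p = hits / total
        null_mean = null_sum / total
        exact = True
    else:
        rng = np.random.default_rng(seed)
        counts = np.empty(n_perm, dtype=int)
        idx = np.arange(n)
        for i in range(n_perm):
            sel = rng.choice(idx, size=k, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[sel] = True
            counts[i] = count_for(mask)
        perm_p = (1 + int((counts >= observed).sum())) / (n_perm + 1)
        null_mean = float(counts.mean())
        exact = False

    clusters = find_clusters(uni[is_aseg], max_gap=max_gap,
                             min_size=min_size)
    in_cluster = np.zeros(n, dtype=bool)
    for rec in clusters:
        on_chrom = uni["chrom"].to_numpy() == rec.chrom
        in_cluster |= on_chrom & (starts >= rec.start) & (starts <= rec.end)
    table = [[int((in_cluster & is_aseg).sum()),
              int((in_cluster & ~is_aseg).sum())],
             [int((~in_cluster & is_aseg).sum()),
              int((~in_cluster & ~is_aseg).sum())]]
    odds, fisher_p = stats.fisher_exact(table, alternative="greater")
    return {"observed_clusters": observed, "perm_p": float(perm_p),
            "null_mean": float(null_mean), "exact": exact,
            "fisher_p": float(fisher_p), "fisher_odds": float(odds),
            "fisher_table": table}


def clusters_frame(clusters: list[ClusterRecord]) -> pd.DataFrame:
    rows = [(c.chrom, c.start, c.end, c.span, c.size,
             c.shared_direction, ",".join(c.genes)) for c in clusters]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "span",
                                       "n_genes", "shared_direction",
                                       "genes"])
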