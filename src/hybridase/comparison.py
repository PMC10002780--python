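"""Consistency tables of ASEG calls across tissues and across hybrids.

Given the genotype-dependent ASEGs of a reference call set (for example the
B73-preferring ASEGs of the BC/CB embryo), every reference gene is classified
by its state in a second call set: biased toward the same genotype, biased
toward the other genotype, non-biased, or non-analyzed.  Display percentages
are truncated (floored) to one decimal, matching the convention of the
tabulations this module reproduces (223/414 -> 53.8, not 53.9).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("biased_same_direction", "biased_opposite", "non_biased",
              "non_analyzed")


def truncate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated to one decimal: floor(n/d*1000)/10."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage of an empty reference set")
    return math.floor(numerator / denominator * 1000) / 10


@dataclass
class ComparisonTable:
    """Category counts and display percentages for one reference ASEG set."""

    reference: str
    counts: dict[str, int]
    percentages: dict[str, float] = field(init=False)
    consistent_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        self.percentages = {k: truncate_pct(v, total) if total else 0.0
                            for k, v in self.counts.items()}

    @property
    def size(self) -> int:
        return sum(self.counts.values())


def _biased(calls: pd.DataFrame, genotype: str | None = None) -> pd.DataFrame:
    sub = calls[calls["status"] == "biased"]
    if genotype is not None:
        sub = sub[sub["preferred_genotype"] == genotype]
    return sub


def classify_against(reference: pd.DataFrame,
                     other: pd.DataFrame) -> pd.Series:
    """Category of each reference ASEG in the ``other`` call set.

    Imprinted-like genes in the other set are not genotype-dependent ASEGs and
    fall in the non_biased category; genes absent from the other set are
    non_analyzed.
    """
    state = other.set_index("gene_id")
    out = {}
    for rec in reference.itertuples():
        if rec.gene_id not in state.index:
            out[rec.gene_id] = "non_analyzed"
            continue
        o = state.loc[rec.gene_id]
        if o["status"] == "non_analyzed":
            out[rec.gene_id] = "non_analyzed"
        elif o["status"] == "biased":
            same = o["preferred_genotype"] == rec.preferred_genotype
            out[rec.gene_id] = ("biased_same_direction" if same
                                else "biased_opposite")
        else:  # non_biased or imprinted_like
            out[rec.gene_id] = "non_biased"
    return pd.Series(out, name="category")


def comparison_table(reference_calls: pd.DataFrame, other_calls: pd.DataFrame,
                     label: str, genotype: str | None = None,
                     ) -> ComparisonTable:
    """Tabulate the state of one biased reference set in another call set."""
    ref = _biased(reference_calls, genotype)
    cats = classify_against(ref, other_calls)
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    consistent = sorted(cats[cats == "biased_same_direction"].index)
    return ComparisonTable(reference=label, counts=counts,
                           consistent_genes=consistent)


def cross_tissue_table(calls_embryo: pd.DataFrame,
                       calls_endosperm: pd.DataFrame, hybrid: str,
                       ) -> dict:
    """Embryo vs endosperm consistency for one hybrid pair.

    Returns per-genotype tables in both directions plus the intersection of
    genes biased toward the same genotype in both tissues, split by genotype.
    """
    for calls, tissue in ((calls_embryo, "embryo"),
                          (calls_endosperm, "endosperm")):
        if not (calls["hybrid"] == hybrid).all():
            raise ValueError(f"{tissue} calls are not all from {hybrid}")
    genotypes = sorted(set(_biased(calls_embryo)["preferred_genotype"])
                       | set(_biased(calls_endosperm)["preferred_genotype"]))
    tables = {}
    for g in genotypes:
        tables[("embryo", g)] = comparison_table(
            calls_embryo, calls_endosperm,
            f"{hybrid} embryo {g}-biased vs endosperm", genotype=g)
        tables[("endosperm", g)] = comparison_table(
            calls_endosperm, calls_embryo,
            f"{hybrid} endosperm {g}-biased vs embryo", genotype=g)
    consistent = {g: tables[("embryo", g)].consistent_genes
                  for g in genotypes}
    return {"hybrid": hybrid, "tables": tables, "consistent": consistent,
            "n_consistent": sum(len(v) for v in consistent.values())}


def cross_hybrid_overlap(calls_by_hybrid: dict[str, pd.DataFrame],
                         tissue: str) -> dict:
    """Venn region counts and pairwise consistency across hybrid pairs.

    Venn regions are computed over ASEG gene identity; consistency between
    two hybrids additionally requires the same preferred genotype (only
    possible for the parent the two hybrids share).  The triple-consistent
    share is reported both against the union and against each hybrid's set.
    """
    if len(calls_by_hybrid) < 2:
        raise ValueError("need at least two hybrids to compare")
    sets = {h: set(_biased(c)["gene_id"]) for h, c in calls_by_hybrid.items()}
    hybrids = sorted(sets)
    venn = {}
    for r in range(1, len(hybrids) + 1):
        for combo in itertools.combinations(hybrids, r):
            inside = set.intersection(*(sets[h] for h in combo))
            outside = set.union(*(sets[h] for h in sets if h not in combo),
                                set())
            venn["&".join(combo)] = len(inside - outside)
    tables = {}
    for ref, oth in itertools.permutations(hybrids, 2):
        genotypes = sorted(set(_biased(
            calls_by_hybrid[ref])["preferred_genotype"]))
        for g in genotypes:
            tables[(ref, g, oth)] = comparison_table(
                calls_by_hybrid[ref], calls_by_hybrid[oth],
                f"{ref} {tissue} {g}-biased vs {oth}", genotype=g)
    union = set.union(*sets.values())
    triple = (set.intersection(*sets.values())
              if len(hybrids) >= 3 else set())
    out = {"tissue": tissue, "venn": venn, "tables": tables,
           "n_union": len(union), "n_all_hybrids": len(triple)}
    if union:
        out["pct_all_of_union"] = truncate_pct(len(triple), len(union))
    out["pct_all_of_each"] = {h: truncate_pct(len(triple), len(s))
                              for h, s in sets.items() if s}
    return out


def table_frame(tables: dict) -> pd.DataFrame:
    """Flatten a dict of :class:`ComparisonTable` into a tidy frame."""
    rows = []
    for key, tab in tables.items():
        for cat in CATEGORIES:
            rows.append((tab.reference, cat, tab.counts[cat],
                         tab.percentages[cat]))
    return pd.DataFrame(rows, columns=["reference", "category", "count",
                                       "percent"])
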