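"""Allele-specific expression calling for reciprocal hybrid crosses.

Each analyzable gene is tested for deviation of its maternal:paternal read
ratio from the tissue expectation (1:1 embryo, 2:1 endosperm) with a
one-degree-of-freedom chi-square goodness-of-fit test; p-values are converted
to q-values by Benjamini-Hochberg within each cross x tissue.  A gene is
biased in a cross when q < 0.05 and the higher allele exceeds the lower by at
least the required fold tier (2-, 5- or 9-fold on raw counts).  The two
reciprocal crosses are then reconciled: a genotype-dependent ASEG must be
biased toward the SAME parental genotype in both crosses, whereas bias toward
the same parent-of-origin in both crosses marks the gene imprinted-like and
excludes it from the genotype-dependent set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import CrossDesign, DesignError

FOLD_TIERS = (9, 5, 2)


def chi2_ratio_test(maternal, paternal, ratio: float = 1.0):
    """Chi-square goodness-of-fit of counts against maternal:paternal ratio.

    ``ratio`` is maternal:paternal (1.0 embryo, 2.0 endosperm).  Expected
    counts are ``total*r/(r+1)`` and ``total/(r+1)``; the statistic is
    compared with the chi-square(1) tail, without continuity correction.
    Vectorized; total counts of zero are undefined and raise.
    """
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    total = m + p
    if np.any(total <= 0):
        raise ValueError("chi2_ratio_test requires maternal+paternal > 0")
    exp_m = total * ratio / (ratio + 1.0)
    exp_p = total - exp_m
    stat = (m - exp_m) ** 2 / exp_m + (p - exp_p) ** 2 / exp_p
    pval = stats.chi2.sf(stat, df=1)
    if np.ndim(maternal) == 0 and np.ndim(paternal) == 0:
        return float(stat), float(pval)
    return stat, pval


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1] and not NaN")
    return multipletests(p, method="fdr_bh")[1]


def fold_tier(maternal, paternal) -> int:
    """Highest of the 9/5/2-fold tiers met by the raw count pair (0 = none).

    A zero on the low side with any reads on the high side counts as the top
    tier (monoallelic expression).  Tiers are inclusive ("at least").
    """
    hi, lo = max(maternal, paternal), min(maternal, paternal)
    if hi + lo <= 0:
        raise ValueError("fold_tier requires a positive total")
    if lo == 0:
        return FOLD_TIERS[0]
    for t in FOLD_TIERS:
        if hi >= t * lo:
            return t
    return 0


def call_per_cross(gene_counts: pd.DataFrame, design: CrossDesign,
                   q_threshold: float = 0.05, tier_required: int = 9,
                   ) -> pd.DataFrame:
    """Per-cross biased/non-biased calls with the favored genotype resolved.

    ``gene_counts`` is the output of
    :func:`hybridase.counting.aggregate_gene_counts` for this design.  The
    chi-square test runs on analyzable genes only and q-values are BH over
    that family.  The favored allele is the higher raw count; its genotype is
    the maternal parent for the maternal allele and vice versa.
    """
    bad = gene_counts[(gene_counts["cross"] != design.cross)
                      | (gene_counts["tissue"] != design.tissue)]
    if len(bad):
        raise DesignError(
            f"counts contain rows not matching {design.cross}/{design.tissue}")
    out = gene_counts.copy()
    analyzable = out["status"] == "analyzable"
    out["q_value"] = np.nan
    out["fold_tier"] = 0
    out["preferred_genotype"] = ""
    if analyzable.any():
        sub = out.loc[analyzable]
        _, pvals = chi2_ratio_test(sub["maternal"].to_numpy(),
                                   sub["paternal"].to_numpy(),
                                   design.expected_ratio)
        out.loc[analyzable, "q_value"] = bh_adjust(pvals)
        out.loc[analyzable, "fold_tier"] = [
            fold_tier(m, p) for m, p in zip(sub["maternal"], sub["paternal"])]
    biased = (analyzable & (out["q_value"] < q_threshold)
              & (out["fold_tier"] >= tier_required))
    out.loc[analyzable, "status"] = "non_biased"
    out.loc[biased, "status"] = "biased"
    favored_maternal = out["maternal"] > out["paternal"]
    out.loc[biased & favored_maternal, "preferred_genotype"] = design.maternal
    out.loc[biased & ~favored_maternal, "preferred_genotype"] = design.paternal
    return out


def call_genotype_dependent(call_forward: pd.DataFrame,
                            call_reverse: pd.DataFrame,
                            design_forward: CrossDesign,
                            design_reverse: CrossDesign) -> pd.DataFrame:
    """Reconcile the two reciprocal crosses of one hybrid pair.

    Per gene: biased toward the same genotype in both crosses ->
    genotype-dependent ``biased``; biased toward the same parent-of-origin
    (hence different genotypes) -> ``imprinted_like`` and excluded; any cross
    non-analyzed -> ``non_analyzed``; otherwise ``non_biased``.  The pair
    q-value is the worse (larger) of the two cross q-values and the fold tier
    the lower of the two.
    """
    if design_forward.parents != design_reverse.parents or \
            design_forward.maternal != design_reverse.paternal:
        raise DesignError("calls do not come from reciprocal crosses")
    if design_forward.tissue != design_reverse.tissue:
        raise DesignError("reciprocal calls must share a tissue")
    hybrid = f"{design_forward.cross}/{design_reverse.cross}"
    cols = ["gene_id", "status", "q_value", "fold_tier", "preferred_genotype"]
    merged = call_forward[cols].merge(
        call_reverse[cols], on="gene_id", how="outer",
        suffixes=("_f", "_r"))
    for side in ("_f", "_r"):
        merged[f"status{side}"] = merged[f"status{side}"].fillna(
            "non_analyzed")

    status = np.full(len(merged), "non_biased", dtype=object)
    na = ((merged["status_f"] == "non_analyzed")
          | (merged["status_r"] == "non_analyzed"))
    both = (merged["status_f"] == "biased") & (merged["status_r"] == "biased")
    same = both & (merged["preferred_genotype_f"]
                   == merged["preferred_genotype_r"])
    status[na.to_numpy()] = "non_analyzed"
    status[(both & ~same).to_numpy()] = "imprinted_like"
    status[same.to_numpy()] = "biased"

    out = pd.DataFrame({
        "gene_id": merged["gene_id"],
        "hybrid": hybrid,
        "tissue": design_forward.tissue,
        "status": status,
        "q_value": merged[["q_value_f", "q_value_r"]].max(axis=1),
        "fold_tier": merged[["fold_tier_f", "fold_tier_r"]]
        .fillna(0).min(axis=1).astype(int),
        "preferred_genotype": np.where(
            status == "biased", merged["preferred_genotype_f"].fillna(""), ""),
    })
    return out.sort_values("gene_id").reset_index(drop=True)


def call_hybrid(per_snp_counts: pd.DataFrame, genes: pd.DataFrame,
                hybrid: str, tissue: str, q_threshold: float = 0.05,
                tier_required: int = 9, min_total: int = 20,
                informative: pd.DataFrame | None = None) -> pd.DataFrame:
    """End-to-end: aggregate both reciprocal crosses and reconcile them."""
    from .counting import aggregate_gene_counts, flag_analyzable
    from .design import hybrid_designs

    fwd, rev = hybrid_designs(hybrid, tissue)
    calls = []
    for design in (fwd, rev):
        counts = aggregate_gene_counts(per_snp_counts, genes, design,
                                       informative=informative)
        counts["status"] = flag_analyzable(counts["maternal"],
                                           counts["paternal"], min_total)
        calls.append(call_per_cross(counts, design, q_threshold,
                                    tier_required))
    return call_genotype_dependent(calls[0], calls[1], fwd, rev)
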