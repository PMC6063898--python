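"""Enhancer-to-gene linkage, expression fold changes and ranked tables.

Each enhancer is assigned the gene whose TSS is closest to the
enhancer midpoint (same chromosome).  Expression change between the
two conditions is the ratio of library-size-normalized counts, with an
exact conditional binomial test for significance — a test that needs
no dispersion estimate and is therefore usable with a single library
per condition — and Benjamini–Hochberg adjustment across genes.  The
final product is a ranked top-N table of genes linked to the activated
enhancer group, sorted by fold change.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GenomicInterval


def nearest_gene(
    enhancer: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str, int]:
    """Gene whose TSS is nearest the enhancer midpoint, with the distance.

    Only genes on the enhancer's chromosome are considered.  Ties are
    broken by the lower TSS coordinate, then lexicographic gene id, so
    the assignment is deterministic.
    """
    if not genes:
        raise ValueError("gene list is empty")
    mid = enhancer.midpoint
    best: tuple[int, int, str] | None = None
    for g in genes:
        if g.chrom != enhancer.chrom:
            continue
        key = (abs(mid - g.tss), g.tss, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no gene on chromosome {enhancer.chrom!r}")
    return best[2], best[0]


def link_enhancers(
    enhancers: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Nearest-gene table for a whole catalog (enhancer_id, gene_id, distance)."""
    rows = []
    for iv in enhancers:
        gene_id, dist = nearest_gene(iv, genes)
        rows.append((iv.name, gene_id, dist))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance"])


def expression_fold_change(
    counts_a: pd.Series,
    counts_b: pd.Series,
    libsize_a: float | None = None,
    libsize_b: float | None = None,
    pseudo_fraction: float = 1e-6,
) -> pd.Series:
    """Per-gene B/A ratio of library-size-normalized counts.

    fc = (count_B/L_B + eps) / (count_A/L_A + eps) with eps equal to
    ``pseudo_fraction`` of the mean normalized count, so genes silent
    in one condition get a large-but-finite ratio.  Library sizes
    default to the column totals.  Genes absent from one table are
    dropped with a warning.
    """
    common = counts_a.index.intersection(counts_b.index)
    if len(common) < len(counts_a) or len(common) < len(counts_b):
        warnings.warn(
            f"{max(len(counts_a), len(counts_b)) - len(common)} genes absent from "
            "one condition were excluded"
        )
    a = counts_a.loc[common].astype(float)
    b = counts_b.loc[common].astype(float)
    la = float(a.sum()) if libsize_a is None else float(libsize_a)
    lb = float(b.sum()) if libsize_b is None else float(libsize_b)
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")
    norm_a, norm_b = a / la, b / lb
    eps = pseudo_fraction * float(np.mean(np.concatenate([norm_a, norm_b])))
    fc = (norm_b + eps) / (norm_a + eps)
    fc.name = "fold_change"
    return fc


def de_significance(
    counts_a: pd.Series,
    counts_b: pd.Series,
    libsize_a: float | None = None,
    libsize_b: float | None = None,
) -> pd.Series:
    """Two-sided exact p-value per gene for a B-vs-A count difference.

    Conditional on the total n = count_A + count_B, count_B is
    Binomial(n, L_B/(L_A+L_B)) under the null of equal concentration;
    the two-sided p sums all outcomes no more likely than the observed
    one (minimum-likelihood method).  A gene with zero counts in both
    conditions gets p = 1.
    """
    common = counts_a.index.intersection(counts_b.index)
    a = counts_a.loc[common].round().astype(int)
    b = counts_b.loc[common].round().astype(int)
    la = float(a.sum()) if libsize_a is None else float(libsize_a)
    lb = float(b.sum()) if libsize_b is None else float(libsize_b)
    if la + lb <= 0:  # no reads at all: nothing to test
        return pd.Series(np.ones(len(common)), index=common, name="p_value")
    p_null = lb / (la + lb)
    pvals = np.ones(len(common))
    for i, (ka, kb) in enumerate(zip(a.to_numpy(), b.to_numpy())):
        n = ka + kb
        if n > 0:
            pvals[i] = stats.binomtest(kb, n, p_null, alternative="two-sided").pvalue
    return pd.Series(pvals, index=common, name="p_value")


def adjust_bh(p_values: Iterable[float] | pd.Series) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    if isinstance(p_values, pd.Series):
        adjusted = multipletests(p_values.to_numpy(), method="fdr_bh")[1]
        return pd.Series(adjusted, index=p_values.index, name="adjusted_p")
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def rank_group_genes(
    group: set[str],
    links: pd.DataFrame,
    fold_changes: pd.Series,
    p_values: pd.Series,
    adjusted_p: pd.Series,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top-N table of genes linked to a set of enhancers, by fold change.

    Genes linked by several group enhancers appear once, attributed to
    the closest enhancer.  Rows are sorted by fold change descending
    (ties by gene id) and numbered 1..n.  Both linear and log2 fold
    changes are reported.
    """
    sub = links[links["enhancer_id"].isin(group)]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "rank",
                "gene_id",
                "fold_change",
                "log2_fold_change",
                "p_value",
                "adjusted_p",
                "enhancer_id",
                "distance",
            ]
        )
    # one row per gene: the closest linking enhancer (ties by enhancer id)
    sub = sub.sort_values(["gene_id", "distance", "enhancer_id"]).drop_duplicates(
        "gene_id", keep="first"
    )
    table = sub.merge(fold_changes.rename("fold_change"), left_on="gene_id", right_index=True)
    table = table.merge(p_values.rename("p_value"), left_on="gene_id", right_index=True)
    table = table.merge(adjusted_p.rename("adjusted_p"), left_on="gene_id", right_index=True)
    table = table.sort_values(
        ["fold_change", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    table["rank"] = np.arange(1, len(table) + 1)
    table["log2_fold_change"] = np.log2(table["fold_change"])
    return table[
        [
            "rank",
            "gene_id",
            "fold_change",
            "log2_fold_change",
            "p_value",
            "adjusted_p",
            "enhancer_id",
            "distance",
        ]
    ].reset_index(drop=True)
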