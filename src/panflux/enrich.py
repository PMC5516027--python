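"""Term enrichment of a gene subset by one-sided Fisher's exact test with
Benjamini-Hochberg FDR correction (significance at adjusted p <= 0.05).

Term sets are flat (no ontology DAG propagation). Every term with at least
one background gene enters the multiple-testing family, whether or not it
intersects the target — restricting m to intersecting terms would bias the
correction; a convenience flag exists for callers who want it anyway.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_LEVEL = 0.05


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (gene_id, term_id) -> {term: set of genes}."""
    df = pd.read_csv(path, sep="\t", names=["gene_id", "term_id"], comment="#")
    return {term: set(grp["gene_id"]) for term, grp in df.groupby("term_id")}


def fisher_enrichment(
    target_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
    restrict_to_target: bool = False,
) -> pd.DataFrame:
    """Per-term 2x2 tables with one-sided (enrichment) hypergeometric p-values.

    For each term: a = |target ∩ term|, b = |target \\ term|,
    c = |term ∩ background \\ target|, d = the rest;
    p = P(X >= a) with X ~ Hypergeom(N=|background|, K=|term|, n=|target|).
    Terms without background genes are dropped; with ``restrict_to_target``
    only terms intersecting the target are tested (shrinking m).
    """
    target = set(target_genes)
    background = set(background_genes)
    if not background:
        raise ValueError("background is empty")
    stray = target - background
    if stray:
        raise ValueError(f"target genes outside background: {sorted(stray)[:5]}")
    n_bg = len(background)
    n_t = len(target)
    rows = []
    for term in sorted(term_map):
        term_genes = term_map[term] & background
        if not term_genes:
            continue
        a = len(target & term_genes)
        if restrict_to_target and a == 0:
            continue
        b = n_t - a
        c = len(term_genes) - a
        d = n_bg - a - b - c
        p = float(hypergeom.sf(a - 1, n_bg, len(term_genes), n_t))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": min(p, 1.0)}
        )
    return pd.DataFrame(rows, columns=["term", "a", "b", "c", "d", "odds_ratio", "p"])


def bh_adjust(pvalues: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_adj(i) = min over j >= rank(i) of m * p(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    target_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
    alpha: float = SIGNIFICANCE_LEVEL,
    restrict_to_target: bool = False,
) -> pd.DataFrame:
    """Full enrichment table with BH-adjusted p and a ``significant`` column."""
    table = fisher_enrichment(
        target_genes, background_genes, term_map, restrict_to_target=restrict_to_target
    )
    if table.empty:
        table["p_adj"] = []
        table["significant"] = []
        return table
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] <= alpha
    return table.sort_values("p_adj", kind="stable").reset_index(drop=True)
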