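"""Hypergeometric gene-set overrepresentation against an expressed-gene
background.

Generic replacement for GO-service queries: user-supplied GMT gene sets are
tested one-sided (upper tail) against a background of expressed genes, with
Benjamini-Hochberg correction across the tested sets.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .de import bh_adjust


def hypergeom_enrich(
    query, gene_sets: dict[str, list[str]], background
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of ``query`` in each set.

    ``background`` is the effective gene universe (e.g. all genes with DE
    statistics in every Bic comparison); the query and every set are
    intersected with it first. Sets with zero background overlap are skipped.

    Returns a table sorted by p: set, K (set size in background), n (query
    size), x (overlap), p, fdr, overlap gene ids.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query) & bg
    n = len(q)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        if K == 0:
            continue
        overlap = sorted(q & in_bg)
        x = len(overlap)
        # P(X >= x) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(x - 1, len(bg), K, n))
        rows.append({"set": name, "K": K, "n": n, "x": x, "p": min(p, 1.0),
                     "overlap": ",".join(overlap)})
    table = pd.DataFrame(rows, columns=["set", "K", "n", "x", "p", "overlap"])
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
        table = table[["set", "K", "n", "x", "p", "fdr", "overlap"]]
    else:
        table["fdr"] = []
    return table


def compare_queries(
    queries: dict[str, list], gene_sets: dict[str, list[str]], background,
    p_cutoff: float = 0.01, fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation across several gene clusters with a shared
    background; one stacked table filtered at the p and FDR cutoffs."""
    pieces = []
    for label, query in queries.items():
        tab = hypergeom_enrich(query, gene_sets, background)
        tab.insert(0, "query", label)
        pieces.append(tab)
    stacked = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
    if len(stacked):
        stacked = stacked[(stacked["p"] <= p_cutoff) & (stacked["fdr"] <= fdr_cutoff)]
        stacked = stacked.reset_index(drop=True)
    return stacked
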