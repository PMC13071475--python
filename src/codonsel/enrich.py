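"""Gene-set category enrichment by Pearson chi-square on 2x2 tables.

For each category, genes are cross-classified as in/out of the set of
interest and in/out of the category, and the df=1 Pearson chi-square
statistic is computed (no continuity correction by default, matching the
convention of large-scale GO/KEGG screens; Yates correction is available
behind a flag). Raw p-values are reported; Benjamini–Hochberg adjustment is
optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, false_discovery_control

__all__ = ["EnrichmentRow", "enrichment_test"]


@dataclass
class EnrichmentRow:
    """Chi-square enrichment outcome for one category."""

    category_id: str
    k: int  # genes of interest in category
    n: int  # genes of interest
    K: int  # universe genes in category
    N: int  # universe size
    chi2: float
    p: float
    direction: str  # "over" or "under"
    low_expected: bool  # any expected cell < 5
    p_adjusted: float | None = None


def enrichment_test(
    gene_set,
    universe,
    annotation_map: dict[str, list[str]],
    yates: bool = False,
    adjust: bool = False,
) -> list[EnrichmentRow]:
    """Per-category 2x2 chi-square enrichment of ``gene_set`` in ``universe``.

    ``annotation_map`` maps gene id to its categories; the universe defaults
    to covering every annotated gene passed in. Rows come back sorted by
    p-value; degenerate tables (empty margin) score chi2=0, p=1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError(
            f"gene set members outside universe: {sorted(gene_set - universe)[:5]}"
        )
    genes_by_cat: dict[str, set[str]] = {}
    for gene in universe:
        for cat in annotation_map.get(gene, ()):
            genes_by_cat.setdefault(cat, set()).add(gene)
    if not genes_by_cat:
        raise ValueError("annotation map covers no universe gene")
    n, N = len(gene_set), len(universe)
    rows: list[EnrichmentRow] = []
    for cat in sorted(genes_by_cat):
        members = genes_by_cat[cat]
        k, K = len(gene_set & members), len(members)
        table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]])
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = chi2_contingency(table, correction=yates)
        direction = "over" if k * N >= K * n else "under"
        rows.append(
            EnrichmentRow(
                category_id=cat, k=k, n=n, K=K, N=N,
                chi2=float(stat), p=float(p), direction=direction,
                low_expected=bool((expected < 5).any()),
            )
        )
    rows.sort(key=lambda r: (r.p, r.category_id))
    if adjust and rows:
        adj = false_discovery_control([r.p for r in rows], method="bh")
        for r, q in zip(rows, adj):
            r.p_adjusted = float(q)
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment rows."""
    return pd.DataFrame([r.__dict__ for r in rows])
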