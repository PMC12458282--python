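"""Over-representation analysis of gene lists against gene-set collections."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .data_model import GeneSetCollection
from .meta import benjamini_hochberg


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    fold_enrichment: float
    p: float
    fdr: float = float("nan")


def hypergeometric_enrichment(
    query: Iterable[str], background: Iterable[str], sets: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA with fold enrichment and BH FDR.

    Sets are intersected with the background before testing;
    fold_enrichment = (overlap/|query|) / (|set & background|/|background|).
    """
    query = set(query)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes absent from background, e.g. {extra}")
    n_bg, n_q = len(background), len(query)
    rows = []
    for name, genes in sets.sets.items():
        in_bg = set(genes) & background
        m = len(in_bg)
        if m == 0:
            continue
        overlap = len(in_bg & query)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=m, n=n_q)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, m, n_q))
        fold = (overlap / n_q) / (m / n_bg) if n_q else 0.0
        rows.append(
            EnrichmentResult(
                set_name=name,
                overlap=overlap,
                set_size=m,
                query_size=n_q,
                background_size=n_bg,
                fold_enrichment=fold,
                p=min(p, 1.0),
            )
        )
    if not rows:
        raise ValueError("no gene set overlaps the background")
    table = pd.DataFrame([r.__dict__ for r in rows]).set_index("set_name")
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    return table.sort_values(["p", "fold_enrichment"], ascending=[True, False])
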