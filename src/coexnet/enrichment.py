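"""Hypergeometric over-representation tests with Benjamini-Hochberg FDR.

Two presets mirror the two annotation layers of the analysis: GO-style
enrichment (significant at BH q <= 0.05, queries below a minimum size are
skipped) and KOG-style enrichment (raw p <= 1e-3 and BH q <= 0.05, whole
annotated gene set as background).  Annotations are assumed pre-propagated
to ancestor terms where an ontology applies; this module is purely the
statistics over a flat gene -> term table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_adjust",
    "enrich",
]


@dataclass
class AnnotationSet:
    """Term -> gene sets restricted to a background universe."""

    term_to_genes: dict[str, set]
    background: set
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.term_to_genes = {
            t: set(g) & self.background for t, g in self.term_to_genes.items()
        }
        self.term_to_genes = {t: g for t, g in self.term_to_genes.items() if g}

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        background: Collection | None = None,
        gene_col: str = "gene",
        term_col: str = "term",
    ) -> "AnnotationSet":
        """Build from a (gene, term) table; background defaults to all
        annotated genes."""
        mapping: dict[str, set] = {}
        for term, part in table.groupby(term_col):
            mapping[str(term)] = set(part[gene_col])
        bg = set(background) if background is not None else set(table[gene_col])
        meta_cols = [c for c in table.columns if c not in (gene_col, term_col)]
        meta = table[[term_col, *meta_cols]].drop_duplicates(term_col)
        return cls(term_to_genes=mapping, background=bg, metadata=meta)


@dataclass
class EnrichmentResult:
    """Per-term test results with the significance call."""

    table: pd.DataFrame  # term, k, K, n, N, p_value, fdr_q, significant
    flagged: str | None = None  # e.g. "below minimum query size"

    @property
    def significant_terms(self) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table.loc[self.table["significant"], "term"])


def hypergeometric_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(big_k, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    if big_k > big_n or n > big_n:
        raise ValueError("need K <= N and n <= N")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Collection,
    annotations: AnnotationSet,
    mode: str = "go",
    alpha: float = 0.05,
    p_cutoff: float = 1e-3,
    min_query: int | None = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation of each term within a query set.

    Only terms with at least one query hit are tested; BH runs across the
    tested terms.  ``mode='go'`` calls significance at q <= alpha and skips
    queries smaller than ``min_query`` (default 10); ``mode='kog'``
    additionally requires raw p <= ``p_cutoff`` and has no minimum query
    size by default.
    """
    if mode not in ("go", "kog"):
        raise ValueError("mode must be 'go' or 'kog'")
    if min_query is None:
        min_query = 10 if mode == "go" else 0
    query = set(query)
    stray = query - annotations.background
    if stray:
        raise ValueError(
            f"query genes absent from background: {sorted(stray)[:5]}"
        )
    columns = ["term", "k", "K", "n", "N", "p_value", "fdr_q", "significant"]
    if len(query) < min_query:
        return EnrichmentResult(
            table=pd.DataFrame(columns=columns),
            flagged="below minimum query size",
        )
    big_n = len(annotations.background)
    n = len(query)
    rows = []
    for term in sorted(annotations.term_to_genes):
        genes = annotations.term_to_genes[term]
        k = len(query & genes)
        if k == 0:
            continue
        rows.append({
            "term": term, "k": k, "K": len(genes), "n": n, "N": big_n,
            "p_value": hypergeometric_tail(k, len(genes), n, big_n),
        })
    if not rows:
        return EnrichmentResult(table=pd.DataFrame(columns=columns))
    table = pd.DataFrame(rows)
    table["fdr_q"] = bh_adjust(table["p_value"])
    if mode == "go":
        table["significant"] = table["fdr_q"] <= alpha
    else:
        table["significant"] = (table["p_value"] <= p_cutoff) & (table["fdr_q"] <= alpha)
    table = table.sort_values(["p_value", "term"], ignore_index=True)
    return EnrichmentResult(table=table[columns])
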