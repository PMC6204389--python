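"""Summary artifacts combining the network, DE, hub and binding-site layers.

Three report surfaces: a per-module summary table (nodes, within-module
edges, up/down DEG counts with percentages of the transcriptome-wide DEG
totals, plus a total row), a hub cross-tabulation (how many hubs are DE and
how many of those carry a predicted binding site), and a focal-gene
neighbourhood report (the genes sharing an edge with a focal regulator,
cross-tabulated with DE status, binding-site presence and functional class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .expression_preprocess import DEResult
from .graph_analysis import HubSet

__all__ = [
    "ModuleSummary",
    "NeighborhoodReport",
    "round_half_up",
    "summarize_module_counts",
    "module_summary",
    "hub_crosstab",
    "focal_neighborhood",
]

TOTAL_LABEL = "Total"


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (half-up), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ModuleSummary:
    """Per-module rows plus a total row."""

    rows: pd.DataFrame  # module, nodes, edges, up_count, up_pct, down_count, down_pct
    total_up: int
    total_down: int

    @property
    def total_row(self) -> pd.Series:
        return self.rows[self.rows["module"] == TOTAL_LABEL].iloc[0]


def summarize_module_counts(
    rows: pd.DataFrame, total_up: int, total_down: int
) -> ModuleSummary:
    """Percentage columns and the total row from per-module count rows.

    ``rows`` needs columns module, nodes, edges, up_count, down_count.
    Percentages are 100 * count / grand-total, rounded half-up to 1 decimal;
    the total row sums counts over modules and computes its percentages from
    the summed counts.
    """
    if total_up <= 0 or total_down <= 0:
        raise ValueError("DEG grand totals must be positive")
    out = rows.copy().reset_index(drop=True)
    out["up_pct"] = [round_half_up(100.0 * c / total_up) for c in out["up_count"]]
    out["down_pct"] = [round_half_up(100.0 * c / total_down) for c in out["down_count"]]
    total = {
        "module": TOTAL_LABEL,
        "nodes": int(out["nodes"].sum()),
        "edges": int(out["edges"].sum()),
        "up_count": int(out["up_count"].sum()),
        "down_count": int(out["down_count"].sum()),
    }
    total["up_pct"] = round_half_up(100.0 * total["up_count"] / total_up)
    total["down_pct"] = round_half_up(100.0 * total["down_count"] / total_down)
    out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    cols = ["module", "nodes", "edges", "up_count", "up_pct", "down_count", "down_pct"]
    return ModuleSummary(rows=out[cols], total_up=total_up, total_down=total_down)


def module_summary(
    partition,
    edges: pd.DataFrame,
    de: DEResult,
    totals: tuple[int, int],
) -> ModuleSummary:
    """Count nodes, within-module edges and DEGs per module, then summarise.

    ``totals`` are the transcriptome-wide (total_up, total_down) DEG counts
    used as percentage denominators.
    """
    total_up, total_down = totals
    rows = []
    overall = de.overall_status
    for module in sorted(partition.modules):
        genes = partition.genes_in(module)
        status = overall.reindex(genes).fillna("none")
        rows.append({
            "module": module,
            "nodes": len(genes),
            "edges": int((edges["module"] == module).sum()),
            "up_count": int((status == "up").sum()),
            "down_count": int((status == "down").sum()),
        })
    if not rows:
        rows = []
    frame = pd.DataFrame(
        rows, columns=["module", "nodes", "edges", "up_count", "down_count"]
    )
    return summarize_module_counts(frame, total_up, total_down)


def hub_crosstab(
    hub_sets: Mapping[str, Sequence[str]] | HubSet,
    de: DEResult,
    xbs: Mapping[str, bool],
) -> pd.DataFrame:
    """Per hub set: size, DE share (nearest integer %) and binding-site share.

    For an "up" set the DE share counts hubs upregulated at any time point
    (symmetrically "down"); the binding-site share (1 decimal %) is computed
    over the DE hubs of the set, matching how the study reports it.  A set
    name containing "down" is tallied against downregulation, anything else
    against upregulation.
    """
    if isinstance(hub_sets, HubSet):
        hub_sets = {
            m: hub_sets.hubs(m) for m in sorted(hub_sets.table["module"].unique())
        }
    overall = de.overall_status
    rows = []
    for name in hub_sets:
        hubs = list(hub_sets[name])
        direction = "down" if "down" in str(name).lower() else "up"
        de_hubs = [g for g in hubs if overall.get(g, "none") == direction]
        de_with_xbs = [g for g in de_hubs if xbs.get(g, False)]
        n, n_de, n_xbs = len(hubs), len(de_hubs), len(de_with_xbs)
        rows.append({
            "set": name,
            "n_hubs": n,
            "direction": direction,
            "n_de": n_de,
            "pct_de": int(round_half_up(100.0 * n_de / n, 0)) if n else 0,
            "n_de_with_xbs": n_xbs,
            "pct_de_with_xbs": round_half_up(100.0 * n_xbs / n_de) if n_de else 0.0,
        })
    return pd.DataFrame(rows, columns=[
        "set", "n_hubs", "direction", "n_de", "pct_de",
        "n_de_with_xbs", "pct_de_with_xbs",
    ])


@dataclass
class NeighborhoodReport:
    """Direct network neighbours of a focal gene, cross-tabulated."""

    focal: str
    neighbors: pd.DataFrame  # gene, status, has_xbs, functional_class
    n_up: int
    n_down: int
    n_with_xbs: int
    class_tallies: dict[str, int] = field(default_factory=dict)

    @property
    def n_neighbors(self) -> int:
        return len(self.neighbors)


def focal_neighborhood(
    focal: str,
    edges: pd.DataFrame,
    de: DEResult,
    xbs: Mapping[str, bool],
    classes: Mapping[str, str] | None = None,
    known_genes: Sequence[str] | None = None,
) -> NeighborhoodReport:
    """All genes sharing an exported edge with ``focal``, with layer tallies.

    A focal gene carrying no edges gives an empty neighbourhood as long as it
    is known to the network (present in ``known_genes`` when given); a focal
    gene absent altogether raises.
    """
    mask = (edges["gene_a"] == focal) | (edges["gene_b"] == focal)
    in_edges = focal in set(edges["gene_a"]) | set(edges["gene_b"])
    if not in_edges:
        if known_genes is None or focal not in set(known_genes):
            raise KeyError(f"focal gene {focal!r} absent from the edge list")
    sub = edges[mask]
    neighbors = sorted(
        set(sub["gene_a"]).union(sub["gene_b"]) - {focal}
    )
    classes = classes or {}
    overall = de.overall_status
    table = pd.DataFrame({
        "gene": neighbors,
        "status": [overall.get(g, "none") for g in neighbors],
        "has_xbs": [bool(xbs.get(g, False)) for g in neighbors],
        "functional_class": [classes.get(g, "other") for g in neighbors],
    })
    tallies = table["functional_class"].value_counts().to_dict()
    return NeighborhoodReport(
        focal=focal,
        neighbors=table,
        n_up=int((table["status"] == "up").sum()),
        n_down=int((table["status"] == "down").sum()),
        n_with_xbs=int(table["has_xbs"].sum()),
        class_tallies=tallies,
    )
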