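"""Service-radius bipartite eligibility graph.

A recipient i and supplier j are connected iff the Manhattan distance
l_ij between them does not exceed the supplier's service radius l_j;
eligibility is asymmetric — only the supplier's radius bounds the edge.
The edge weight is the distance itself.  The graph carries *residual*
capacities (demand left on each recipient, supply left on each supplier),
so the same structure serves every batching window and every matching
stage; the matching engines consume those capacities in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .entities import Recipient, Supplier

NO_EDGE = -1  # exported sentinel for audited ineligible pairs


def manhattan(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Manhattan (L1) grid distance between two integer coordinates."""
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


@dataclass
class BipartiteGraph:
    """Eligibility graph with residual vertex capacities.

    ``adj`` maps each recipient id to its eligible suppliers sorted by
    ascending distance (ties by supplier id); ``radj`` is the supplier-side
    mirror.  ``demand`` and ``supply`` are residual capacities, shared by
    reference with subgraphs produced by :func:`split_priority` and
    :func:`stage_subgraph` so that consumption in one phase or stage is
    visible in the others.
    """

    recipients: list[Recipient]
    suppliers: list[Supplier]
    adj: dict[str, list[tuple[int, str]]]
    radj: dict[str, list[tuple[int, str]]]
    demand: dict[str, int]
    supply: dict[str, int]

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {(i, j): d for i, lst in self.adj.items() for d, j in lst}

    def total_residual_demand(self) -> int:
        return sum(self.demand[r.id] for r in self.recipients)

    def total_residual_supply(self) -> int:
        return sum(self.supply[s.id] for s in self.suppliers)


def build_graph(
    recipients: Sequence[Recipient], suppliers: Sequence[Supplier]
) -> BipartiteGraph:
    """Construct the eligibility graph over entities with positive residuals.

    Edge rule: present iff ``manhattan(loc_i, loc_j) <= l_j`` with the
    distance as weight; zero-distance (co-located) edges are legal.
    """
    recipients = [r for r in recipients if r.remaining > 0]
    suppliers = [s for s in suppliers if s.remaining > 0]
    adj: dict[str, list[tuple[int, str]]] = {r.id: [] for r in recipients}
    radj: dict[str, list[tuple[int, str]]] = {s.id: [] for s in suppliers}

    if recipients and suppliers:
        r_xy = np.array([r.loc for r in recipients])
        s_xy = np.array([s.loc for s in suppliers])
        radius = np.array([s.l for s in suppliers])
        dist = np.abs(r_xy[:, None, :] - s_xy[None, :, :]).sum(axis=2)
        ii, jj = np.nonzero(dist <= radius[None, :])
        for i, j in zip(ii.tolist(), jj.tolist()):
            d = int(dist[i, j])
            adj[recipients[i].id].append((d, suppliers[j].id))
            radj[suppliers[j].id].append((d, recipients[i].id))

    for lst in adj.values():
        lst.sort()
    for lst in radj.values():
        lst.sort()

    return BipartiteGraph(
        recipients=list(recipients),
        suppliers=list(suppliers),
        adj=adj,
        radj=radj,
        demand={r.id: r.remaining for r in recipients},
        supply={s.id: s.remaining for s in suppliers},
    )


def _restrict(
    g: BipartiteGraph, recipients: list[Recipient], suppliers: list[Supplier]
) -> BipartiteGraph:
    """Subgraph on the given vertex subsets, sharing residual capacity dicts."""
    rid = {r.id for r in recipients}
    sid = {s.id for s in suppliers}
    adj = {i: [(d, j) for d, j in g.adj[i] if j in sid] for i in rid}
    radj = {j: [(d, i) for d, i in g.radj[j] if i in rid] for j in sid}
    return BipartiteGraph(
        recipients=recipients,
        suppliers=suppliers,
        adj=adj,
        radj=radj,
        demand=g.demand,
        supply=g.supply,
    )


def split_priority(g: BipartiteGraph) -> tuple[BipartiteGraph, BipartiteGraph]:
    """Partition by recipient priority into (G_PH, G_PL).

    Both parts keep the full supplier set and share the parent's residual
    capacities, so allocations made in the high-priority part deplete the
    supply seen by the low-priority part.
    """
    high = [r for r in g.recipients if r.dr == "high"]
    low = [r for r in g.recipients if r.dr == "low"]
    return _restrict(g, high, list(g.suppliers)), _restrict(g, low, list(g.suppliers))


def stage_subgraph(g: BipartiteGraph, sr: int) -> BipartiteGraph:
    """Restrict suppliers to tier ``sr`` with positive residual capacity."""
    if sr not in (1, 2, 3):
        raise ValueError(f"supply level must be 1, 2 or 3, got {sr}")
    keep = [s for s in g.suppliers if s.sr == sr and g.supply[s.id] > 0]
    return _restrict(g, list(g.recipients), keep)


def export_edge_list(
    g: BipartiteGraph, path: str | Path, include_ineligible: bool = False
) -> None:
    """Write edges as CSV ``(i, j, weight)``; optionally audit ineligible
    pairs as rows with weight -1."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["recipient_id", "supplier_id", "weight"])
        eligible = {(i, j) for i, lst in g.adj.items() for _, j in lst}
        for r in g.recipients:
            for d, j in g.adj[r.id]:
                writer.writerow([r.id, j, d])
            if include_ineligible:
                for s in g.suppliers:
                    if (r.id, s.id) not in eligible:
                        writer.writerow([r.id, s.id, NO_EDGE])
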