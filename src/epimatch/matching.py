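"""Many-to-many bipartite matching engines with vertex capacities.

Three engines operate on the residual-capacity eligibility graph:

* ``gmbmc`` — greedy nearest-neighbour-first allocation: each recipient, in
  buffer order, drains its eligible suppliers in ascending distance order.
  On output a recipient holds units from a farther supplier only if every
  nearer eligible supplier is saturated.
* ``hmbmc`` — a Hungarian-style algorithm extended to integer vertex
  capacities.  A recursive augmenting-path search ``get_path(i, need)``
  pushes integral flow and reroutes existing allocations along alternating
  paths, so the total allocated quantity equals the value of a maximum flow
  through the capacity network (source -> recipients -> edges -> suppliers
  -> sink).  Among maximum allocations it prefers short edges by always
  scanning suppliers in ascending distance order — a tie-break heuristic,
  not a guaranteed minimum-distance solution.
* ``g_hmbmc`` — the multi-stage driver: high-priority recipients are served
  first (greedily), then low-priority recipients (Hungarian); within each
  phase supply tiers 1, 2, 3 are opened in order, a later tier only once
  the phase's demand survived the earlier ones.

A standalone validator re-checks the feasibility system (capacity, radius,
priority and tier order, integrality) on any allocation.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

from .entities import Recipient, Supplier, buffer_sort_key
from .graph import BipartiteGraph, build_graph, split_priority, stage_subgraph


@dataclass
class AllocationEntry:
    recipient_id: str
    supplier_id: str
    q_alloc: int
    distance: int


@dataclass
class Allocation:
    """Result of one matching pass: integral recipient-supplier allocations."""

    entries: list[AllocationEntry] = field(default_factory=list)

    @property
    def total_q(self) -> int:
        return sum(e.q_alloc for e in self.entries)

    @property
    def total_distance_unit(self) -> int:
        return sum(e.distance for e in self.entries)

    @property
    def total_distance_weighted(self) -> int:
        return sum(e.q_alloc * e.distance for e in self.entries)

    def extend(self, other: "Allocation") -> None:
        self.entries.extend(other.entries)


def nnf_order(recipient_id: str, g: BipartiteGraph) -> list[str]:
    """Eligible suppliers of a recipient, nearest first, ties by supplier id."""
    return [j for _, j in sorted(g.adj[recipient_id])]


def _recipient_order(g: BipartiteGraph) -> list[Recipient]:
    return sorted(g.recipients, key=buffer_sort_key)


def gmbmc(g: BipartiteGraph) -> Allocation:
    """Greedy many-to-many matching with capacities (nearest neighbour first).

    Consumes ``g``'s residual capacities in place.
    """
    dist = {(i, j): d for i, lst in g.adj.items() for d, j in lst}
    alloc = Allocation()
    for r in _recipient_order(g):
        need = g.demand[r.id]
        if need <= 0:
            continue
        for j in nnf_order(r.id, g):
            if need <= 0:
                break
            avail = g.supply[j]
            if avail <= 0:
                continue
            take = min(need, avail)
            alloc.entries.append(AllocationEntry(r.id, j, take, dist[(r.id, j)]))
            g.supply[j] -= take
            need -= take
        g.demand[r.id] = need
    return alloc


def hmbmc(g: BipartiteGraph) -> Allocation:
    """Capacity-extended Hungarian matching: maximum total allocated quantity.

    Repeatedly calls the recursive augmenting search ``get_path(i, need)``
    for each recipient until no augmenting path remains, which certifies a
    maximum flow by integrality.  Consumes ``g``'s residual capacities.
    """
    dist = {(i, j): d for i, lst in g.adj.items() for d, j in lst}
    # flow[i][j]: units currently routed from supplier j to recipient i
    flow: dict[str, dict[str, int]] = {r.id: {} for r in g.recipients}
    holders: dict[str, dict[str, int]] = {s.id: {} for s in g.suppliers}

    limit = 4 * (len(g.recipients) + len(g.suppliers)) + 100
    if sys.getrecursionlimit() < limit:
        sys.setrecursionlimit(limit)

    def get_path(i: str, need: int, visited: set[str]) -> int:
        """Push up to ``need`` units of flow from recipient ``i``; returns
        the amount pushed.  ``visited`` marks suppliers already inspected in
        the current augmentation (Kuhn-style)."""
        for _, j in g.adj[i]:
            if j in visited:
                continue
            visited.add(j)
            free = g.supply[j]
            if free > 0:
                push = min(need, free)
                g.supply[j] -= push
                flow[i][j] = flow[i].get(j, 0) + push
                holders[j][i] = holders[j].get(i, 0) + push
                return push
            # supplier saturated: try to reroute units held by other recipients
            for i2 in list(holders[j].keys()):
                held = holders[j].get(i2, 0)
                if held <= 0 or i2 == i:
                    continue
                moved = get_path(i2, min(need, held), visited)
                if moved > 0:
                    flow[i2][j] -= moved
                    holders[j][i2] -= moved
                    if holders[j][i2] == 0:
                        del holders[j][i2]
                    flow[i][j] = flow[i].get(j, 0) + moved
                    holders[j][i] = holders[j].get(i, 0) + moved
                    return moved
        return 0

    for r in _recipient_order(g):
        while g.demand[r.id] > 0:
            pushed = get_path(r.id, g.demand[r.id], set())
            if pushed == 0:
                break
            g.demand[r.id] -= pushed

    alloc = Allocation()
    for r in _recipient_order(g):
        for j in sorted(flow[r.id]):
            q = flow[r.id][j]
            if q > 0:
                alloc.entries.append(AllocationEntry(r.id, j, q, dist[(r.id, j)]))
    return alloc


def g_hmbmc(
    recipients: list[Recipient], suppliers: list[Supplier]
) -> Allocation:
    """Service-level multi-stage driver combining both engines.

    High-priority recipients are matched first with the greedy engine, then
    low-priority recipients with the Hungarian engine, each iterating supply
    tiers 1 -> 2 -> 3 on shared residual capacities and stopping early once
    the phase's recipients are fully satisfied.
    """
    g = build_graph(recipients, suppliers)
    g_ph, g_pl = split_priority(g)
    merged = Allocation()
    for phase_graph, engine in ((g_ph, gmbmc), (g_pl, hmbmc)):
        for sr in (1, 2, 3):
            if all(g.demand[r.id] <= 0 for r in phase_graph.recipients):
                break
            stage = stage_subgraph(phase_graph, sr)
            if not stage.suppliers:
                continue
            merged.extend(engine(stage))
    return merged


def validate_allocation(
    alloc: Allocation,
    recipients: list[Recipient],
    suppliers: list[Supplier],
    t: int | None = None,
) -> list[str]:
    """Machine check of the feasibility system; returns violation messages.

    Checks, per allocation: recipient and supplier capacity bounds, the
    supplier service radius, integrality/positivity, arrival before the
    window timestamp (if ``t`` given), high-before-low recipient priority
    (no low-priority recipient holds units from a supplier whose residual
    could still serve an unsatisfied high-priority recipient in range) and
    supply-tier order (a tier-s supplier serves a recipient only if every
    lower-tier eligible supplier ended the window drained).
    """
    from .graph import manhattan

    rmap = {r.id: r for r in recipients}
    smap = {s.id: s for s in suppliers}
    violations: list[str] = []

    got: dict[str, int] = {}
    gave: dict[str, int] = {}
    for e in alloc.entries:
        if e.recipient_id not in rmap:
            violations.append(f"unknown recipient {e.recipient_id}")
            continue
        if e.supplier_id not in smap:
            violations.append(f"unknown supplier {e.supplier_id}")
            continue
        if not isinstance(e.q_alloc, int) or e.q_alloc < 1:
            violations.append(
                f"non-positive-integer allocation {e.q_alloc} on "
                f"({e.recipient_id},{e.supplier_id})"
            )
        r, s = rmap[e.recipient_id], smap[e.supplier_id]
        if manhattan(r.loc, s.loc) > s.l:
            violations.append(
                f"radius violated: d({r.id},{s.id})="
                f"{manhattan(r.loc, s.loc)} > l={s.l}"
            )
        if t is not None:
            if r.request_time > t:
                violations.append(f"recipient {r.id} matched before arrival")
            if s.request_time > t:
                violations.append(f"supplier {s.id} matched before arrival")
        got[r.id] = got.get(r.id, 0) + e.q_alloc
        gave[s.id] = gave.get(s.id, 0) + e.q_alloc

    for rid, total in got.items():
        if total > rmap[rid].remaining:
            violations.append(
                f"recipient {rid} over-allocated: {total} > residual "
                f"{rmap[rid].remaining}"
            )
    for sid, total in gave.items():
        if total > smap[sid].remaining:
            violations.append(
                f"supplier {sid} over-drawn: {total} > residual "
                f"{smap[sid].remaining}"
            )

    # end-of-window residuals implied by the allocation
    r_left = {r.id: r.remaining - got.get(r.id, 0) for r in recipients}
    s_left = {s.id: s.remaining - gave.get(s.id, 0) for s in suppliers}
    eligible = {
        (r.id, s.id)
        for r in recipients
        for s in suppliers
        if manhattan(r.loc, s.loc) <= s.l
    }

    # priority: a supplier serving a low-priority recipient must not be
    # reachable by any high-priority recipient that ended unsatisfied
    unsatisfied_high = [r for r in recipients if r.dr == "high" and r_left[r.id] > 0]
    for e in alloc.entries:
        r = rmap.get(e.recipient_id)
        if r is None or r.dr != "low":
            continue
        for hr in unsatisfied_high:
            if (hr.id, e.supplier_id) in eligible:
                violations.append(
                    f"priority violated: low recipient {r.id} took "
                    f"{e.q_alloc} from {e.supplier_id} while high recipient "
                    f"{hr.id} is unsatisfied and in range"
                )
                break

    # tier order: units from tier s imply all eligible lower tiers drained
    for e in alloc.entries:
        s = smap.get(e.supplier_id)
        r = rmap.get(e.recipient_id)
        if s is None or r is None or s.sr == 1:
            continue
        for s2 in suppliers:
            if s2.sr < s.sr and (r.id, s2.id) in eligible and s_left[s2.id] > 0:
                violations.append(
                    f"tier order violated: {r.id} took from tier-{s.sr} "
                    f"{s.id} while tier-{s2.sr} {s2.id} has residual "
                    f"{s_left[s2.id]}"
                )
                break

    return violations
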