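"""Seeded synthetic arrival streams.

The generator emulates a horizon of |T| = 120 discrete time units over which
3,000 recipient requests and 1,800 supplier lots arrive, with the total
demanded quantity calibrated to about 0.8 of the total supplied quantity.
Arrival times are i.i.d. uniform on {0, ..., T-1}; locations uniform on an
integer grid; priority and supply levels categorical; quantities and service
radii uniform integers.  Every draw comes from a single seeded generator, so
identical configurations with identical seeds yield identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entities import Recipient, Supplier


@dataclass
class StreamConfig:
    """Parameters of the synthetic arrival stream.

    Defaults reproduce the reference experimental design: 120 time units,
    3,000 recipients, 1,800 suppliers, demand/supply quantity ratio 0.8.
    Distributions not pinned down by that design (locations, quantities,
    radii) are uniform, with radii [10, 30] on a 100x100 grid so that a
    typical supplier reaches a sparse-but-nonempty recipient neighbourhood.
    """

    T: int = 120
    n_recipients: int = 3000
    n_suppliers: int = 1800
    demand_supply_ratio: float = 0.8
    grid_size: int = 100
    p_high: float = 0.5
    sr_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    q_recipient_range: tuple[int, int] = (1, 10)
    q_supplier_range: tuple[int, int] = (1, 10)
    radius_range: tuple[int, int] = (10, 30)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.T, self.n_recipients, self.n_suppliers, self.grid_size) <= 0:
            raise ValueError("counts, horizon and grid size must be positive")
        if self.demand_supply_ratio <= 0:
            raise ValueError("demand/supply ratio must be positive")
        for lo, hi in (self.q_recipient_range, self.q_supplier_range, self.radius_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty intervals of positive integers")
        if not 0 <= self.p_high <= 1:
            raise ValueError("p_high must be a probability")
        if len(self.sr_probs) != 3 or abs(sum(self.sr_probs) - 1.0) > 1e-9:
            raise ValueError("sr_probs must be a length-3 probability vector")


def calibrate_quantities(
    raw_demands: Sequence[int], raw_supplies: Sequence[int], ratio: float
) -> list[int]:
    """Rescale supplier quantities so total demand / total supply hits ``ratio``.

    Each raw supply is multiplied by ``(sum(demands) / ratio) / sum(supplies)``
    and rounded to the nearest integer with a floor of 1.  Because the raw
    quantities take few distinct values, plain per-item rounding can drift
    systematically, so a largest-remainder pass then nudges items by one unit
    until the total matches the target, keeping every item within one unit of
    its exact scaled value.
    """
    if not raw_demands or not raw_supplies:
        raise ValueError("demand and supply lists must be non-empty")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    target_supply = sum(raw_demands) / ratio
    if target_supply < len(raw_supplies):
        raise ValueError(
            "infeasible ratio: target supply total would force quantities "
            "below 1 per supplier"
        )
    factor = target_supply / sum(raw_supplies)
    exact = np.asarray(raw_supplies, dtype=float) * factor
    adj = np.maximum(1, np.rint(exact).astype(int))

    target_int = int(np.rint(target_supply))
    diff = target_int - int(adj.sum())
    if diff != 0:
        step = 1 if diff > 0 else -1
        # favour items whose rounded value sits farthest below (above) exact
        order = np.argsort(step * (adj - exact))
        pos = 0
        while diff != 0 and pos < 10 * len(adj):
            idx = order[pos % len(adj)]
            if adj[idx] + step >= 1:
                adj[idx] += step
                diff -= step
            pos += 1
    return [int(x) for x in adj]


def generate_stream(config: StreamConfig) -> tuple[list[Recipient], list[Supplier]]:
    """Draw a full recipient/supplier arrival stream from ``config``.

    Supplier quantities are calibrated post hoc (``calibrate_quantities``) so
    the realized demand/supply quantity ratio lands within 2% of the target.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(max(config.n_recipients, config.n_suppliers) - 1)))

    n_r = config.n_recipients
    r_x = rng.integers(0, config.grid_size, size=n_r)
    r_y = rng.integers(0, config.grid_size, size=n_r)
    r_dr = np.where(rng.random(n_r) < config.p_high, "high", "low")
    r_t = rng.integers(0, config.T, size=n_r)
    r_q = rng.integers(
        config.q_recipient_range[0], config.q_recipient_range[1] + 1, size=n_r
    )

    n_s = config.n_suppliers
    s_x = rng.integers(0, config.grid_size, size=n_s)
    s_y = rng.integers(0, config.grid_size, size=n_s)
    s_sr = rng.choice([1, 2, 3], size=n_s, p=list(config.sr_probs))
    s_t = rng.integers(0, config.T, size=n_s)
    s_q_raw = rng.integers(
        config.q_supplier_range[0], config.q_supplier_range[1] + 1, size=n_s
    )
    s_l = rng.integers(config.radius_range[0], config.radius_range[1] + 1, size=n_s)

    s_q = calibrate_quantities(
        [int(q) for q in r_q], [int(q) for q in s_q_raw], config.demand_supply_ratio
    )
    achieved = int(r_q.sum()) / sum(s_q)
    if abs(achieved / config.demand_supply_ratio - 1.0) > 0.02:
        raise ValueError(
            f"calibration failed: achieved ratio {achieved:.4f} vs "
            f"target {config.demand_supply_ratio}"
        )

    recipients = [
        Recipient(
            id=f"r{i:0{width}d}",
            loc=(int(r_x[i]), int(r_y[i])),
            dr=str(r_dr[i]),
            request_time=int(r_t[i]),
            q=int(r_q[i]),
        )
        for i in range(n_r)
    ]
    suppliers = [
        Supplier(
            id=f"s{j:0{width}d}",
            loc=(int(s_x[j]), int(s_y[j])),
            sr=int(s_sr[j]),
            request_time=int(s_t[j]),
            q=int(s_q[j]),
            l=int(s_l[j]),
        )
        for j in range(n_s)
    ]
    return recipients, suppliers


def realized_ratio(recipients: Sequence[Recipient], suppliers: Sequence[Supplier]) -> float:
    """Total demanded quantity over total supplied quantity."""
    return sum(r.q for r in recipients) / sum(s.q for s in suppliers)
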