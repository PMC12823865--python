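"""Domain types for the two-sided resource-matching platform.

A demand-side *recipient* asks for an integer quantity of a consumable
resource at a grid location, tagged with a prevention-priority class
(``high``/``low``).  A supply-side *supplier* offers an integer quantity
from a grid location, tagged with a supply tier (1, 2 or 3) and a service
radius: the maximum Manhattan distance it can deliver to.  Allocations are
integral and cumulative — a partially served entity stays in the platform
buffer, keeping its original request time so that batch waiting accrues.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

PRIORITY_LEVELS = ("high", "low")
SUPPLY_LEVELS = (1, 2, 3)


@dataclass
class Recipient:
    """Demand-side entity: ``(id, loc, dr, request_time, q)`` plus bookkeeping."""

    id: str
    loc: tuple[int, int]
    dr: str
    request_time: int
    q: int
    matched_q: int = 0

    def __post_init__(self) -> None:
        if self.dr not in PRIORITY_LEVELS:
            raise ValueError(f"dr must be one of {PRIORITY_LEVELS}, got {self.dr!r}")
        if self.q < 1:
            raise ValueError(f"recipient demand must be >= 1, got {self.q}")
        if self.request_time < 0:
            raise ValueError("request_time must be non-negative")
        if not 0 <= self.matched_q <= self.q:
            raise ValueError("matched_q must lie in [0, q]")

    @property
    def remaining(self) -> int:
        return self.q - self.matched_q

    @property
    def completion_rate(self) -> float:
        return self.matched_q / self.q


@dataclass
class Supplier:
    """Supply-side entity: ``(id, loc, sr, request_time, q, l)`` plus bookkeeping."""

    id: str
    loc: tuple[int, int]
    sr: int
    request_time: int
    q: int
    l: int
    matched_q: int = 0

    def __post_init__(self) -> None:
        if self.sr not in SUPPLY_LEVELS:
            raise ValueError(f"sr must be one of {SUPPLY_LEVELS}, got {self.sr!r}")
        if self.q < 1:
            raise ValueError(f"supplier quantity must be >= 1, got {self.q}")
        if self.l <= 0:
            raise ValueError(f"service radius must be positive, got {self.l}")
        if self.request_time < 0:
            raise ValueError("request_time must be non-negative")
        if not 0 <= self.matched_q <= self.q:
            raise ValueError("matched_q must lie in [0, q]")

    @property
    def remaining(self) -> int:
        return self.q - self.matched_q


Entity = Union[Recipient, Supplier]


@dataclass
class MatchResponse:
    """One allocation record ``(i, j, q_ij, tau_ij, rate_ij)``.

    ``tau`` is the recipient's total waiting time for this allocation:
    batch wait (match timestamp minus request time) plus travel time
    (distance over delivery speed).  ``rate`` is the contribution of this
    allocation to the recipient's completion rate, ``q_alloc / q_i``.
    """

    recipient_id: str
    supplier_id: str
    q_alloc: int
    tau: float
    rate: float

    def __post_init__(self) -> None:
        if self.q_alloc < 1:
            raise ValueError("allocated quantity must be >= 1")
        if self.tau < 0:
            raise ValueError("waiting time must be non-negative")


def remaining(entity: Entity) -> int:
    """Residual quantity ``q - matched_q`` of a recipient or supplier."""
    return entity.q - entity.matched_q


def completion_rate(recipient: Recipient) -> float:
    """Cumulative completion rate ``matched_q / q`` of a recipient."""
    if recipient.q < 1:
        raise ValueError("invalid recipient: q must be >= 1")
    return recipient.matched_q / recipient.q


def buffer_sort_key(entity: Entity) -> tuple[int, str]:
    """Platform buffers are ordered by request time, ties broken by id."""
    return (entity.request_time, entity.id)


@dataclass
class PlatformState:
    """Time-stamped buffers of the matching platform.

    ``future_recipients``/``future_suppliers`` hold entities that have not
    arrived yet; ``pending_*`` hold arrived-but-incomplete entities; the
    accumulated match set collects every allocation made so far.
    """

    clock: int = 0
    pending_recipients: list[Recipient] = field(default_factory=list)
    pending_suppliers: list[Supplier] = field(default_factory=list)
    match_set: list[MatchResponse] = field(default_factory=list)
    future_recipients: list[Recipient] = field(default_factory=list)
    future_suppliers: list[Supplier] = field(default_factory=list)

    @classmethod
    def from_stream(
        cls, recipients: Iterable[Recipient], suppliers: Iterable[Supplier]
    ) -> "PlatformState":
        """Fresh platform over a stream; entities are copied so a run never
        mutates the caller's stream (the same stream can feed many runs)."""
        return cls(
            clock=0,
            future_recipients=sorted((replace(r) for r in recipients), key=buffer_sort_key),
            future_suppliers=sorted((replace(s) for s in suppliers), key=buffer_sort_key),
        )

    def advance_to(self, t: int) -> None:
        """Move entities with ``request_time <= t`` into the pending buffers."""
        while self.future_recipients and self.future_recipients[0].request_time <= t:
            self.pending_recipients.append(self.future_recipients.pop(0))
        while self.future_suppliers and self.future_suppliers[0].request_time <= t:
            self.pending_suppliers.append(self.future_suppliers.pop(0))
        self.pending_recipients.sort(key=buffer_sort_key)
        self.pending_suppliers.sort(key=buffer_sort_key)
        self.clock = t


# --- CSV stream schema -------------------------------------------------------
#
# recipients.csv: id, x, y, dr, request_time, q
# suppliers.csv:  id, x, y, sr, request_time, q, l
# Header row required, UTF-8.

RECIPIENT_FIELDS = ["id", "x", "y", "dr", "request_time", "q"]
SUPPLIER_FIELDS = ["id", "x", "y", "sr", "request_time", "q", "l"]


def write_recipients_csv(recipients: Iterable[Recipient], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECIPIENT_FIELDS)
        for r in recipients:
            writer.writerow([r.id, r.loc[0], r.loc[1], r.dr, r.request_time, r.q])


def write_suppliers_csv(suppliers: Iterable[Supplier], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUPPLIER_FIELDS)
        for s in suppliers:
            writer.writerow([s.id, s.loc[0], s.loc[1], s.sr, s.request_time, s.q, s.l])


def read_recipients_csv(path: str | Path) -> list[Recipient]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Recipient(
                    id=row["id"],
                    loc=(int(row["x"]), int(row["y"])),
                    dr=row["dr"],
                    request_time=int(row["request_time"]),
                    q=int(row["q"]),
                )
            )
    return out


def read_suppliers_csv(path: str | Path) -> list[Supplier]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Supplier(
                    id=row["id"],
                    loc=(int(row["x"]), int(row["y"])),
                    sr=int(row["sr"]),
                    request_time=int(row["request_time"]),
                    q=int(row["q"]),
                    l=int(row["l"]),
                )
            )
    return out
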