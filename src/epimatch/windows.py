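"""Batching time windows over the arrival stream.

Two strategies pool arriving requests before a batch match executes:

* **FTWBM** (fixed time window): the horizon T is cut into equal windows of
  size ``bs``; matching runs at each window's end. ``bs = 1`` realizes
  instant matching.
* **ATWBM** (adaptive time window): before each round a multi-armed bandit
  picks the next window size from a finite arm set; the observed window
  average waiting time is the (minimized) reward.  Policies: epsilon-greedy
  with exponentially decaying exploration, a lower-confidence-bound variant
  of UCB, and Gaussian Thompson sampling.

Matching happens at the window END: the batch wait of a recipient is the
window timestamp minus its request time, and travel time is Manhattan
distance over a constant delivery speed (default 1 distance unit per time
unit).  Partially served entities persist in the buffer with their original
request time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .entities import (
    MatchResponse,
    PlatformState,
    Recipient,
    Supplier,
    buffer_sort_key,
)
from .matching import Allocation, g_hmbmc, validate_allocation
from .metrics import window_avg_rate, window_avg_wait

logger = logging.getLogger(__name__)

Matcher = Callable[[list[Recipient], list[Supplier]], Allocation]

DEFAULT_ARMS = (1, 2, 3, 4, 6, 8)


def window_count(T: int, bs: int) -> int:
    """Number of matching windows of size ``bs`` covering a horizon ``T``
    (last window truncated when ``bs`` does not divide ``T``)."""
    if bs <= 0:
        raise ValueError("window size must be positive")
    if T <= 0:
        raise ValueError("horizon must be positive")
    return math.ceil(T / bs)


def collect_eligible(
    state: PlatformState, t: int
) -> tuple[list[Recipient], list[Supplier]]:
    """Arrived, still-incomplete entities eligible at timestamp ``t``.

    Recipients with completion rate < 1 and suppliers with residual
    capacity > 0, both sorted by request time (ties by id).
    """
    state.advance_to(t)
    d_t = [r for r in state.pending_recipients if r.completion_rate < 1]
    s_t = [s for s in state.pending_suppliers if s.remaining > 0]
    return sorted(d_t, key=buffer_sort_key), sorted(s_t, key=buffer_sort_key)


def apply_matches(
    state: PlatformState,
    allocation: Allocation,
    t: int,
    speed: float = 1.0,
    validate: bool = False,
) -> list[MatchResponse]:
    """Commit an allocation at window end ``t``: decrement residuals, record
    match responses with tau = batch wait + travel time, and drop completed
    entities from the pending buffers."""
    rmap = {r.id: r for r in state.pending_recipients}
    smap = {s.id: s for s in state.pending_suppliers}
    if validate:
        problems = validate_allocation(
            allocation, list(rmap.values()), list(smap.values()), t=t
        )
        if problems:
            raise ValueError("infeasible allocation: " + "; ".join(problems))

    responses: list[MatchResponse] = []
    for e in allocation.entries:
        r = rmap[e.recipient_id]
        s = smap[e.supplier_id]
        tau = (t - r.request_time) + e.distance / speed
        resp = MatchResponse(
            recipient_id=r.id,
            supplier_id=s.id,
            q_alloc=e.q_alloc,
            tau=tau,
            rate=e.q_alloc / r.q,
        )
        r.matched_q += e.q_alloc
        s.matched_q += e.q_alloc
        responses.append(resp)
        state.match_set.append(resp)

    state.pending_recipients = [
        r for r in state.pending_recipients if r.completion_rate < 1
    ]
    state.pending_suppliers = [s for s in state.pending_suppliers if s.remaining > 0]
    return responses


@dataclass
class WindowResult:
    """Per-window outcome: matched responses plus the two summary metrics."""

    window_index: int
    bs_used: int
    timestamp: int
    responses: list[MatchResponse]
    avg_wait: float | None
    avg_rate: float | None
    n_participants: int


def _run_window(
    state: PlatformState,
    t: int,
    idx: int,
    bs: int,
    matcher: Matcher,
    speed: float,
    tau_agg: str,
    validate: bool = False,
) -> WindowResult:
    d_t, s_t = collect_eligible(state, t)
    allocation = matcher(d_t, s_t)
    responses = apply_matches(state, allocation, t, speed=speed, validate=validate)
    participants = {resp.recipient_id for resp in responses}
    rmap = {r.id: r for r in d_t}
    if participants:
        avg_wait = window_avg_wait(responses, agg=tau_agg)
        avg_rate = window_avg_rate(
            [rmap[i].completion_rate for i in sorted(participants)]
        )
    else:
        avg_wait = None
        avg_rate = None
        logger.info("window %d (t=%d, bs=%d): empty, metrics undefined", idx, t, bs)
    logger.info(
        "window %d: t=%d bs=%d |D_t|=%d |S_t|=%d matched_q=%d avg_wait=%s avg_rate=%s",
        idx, t, bs, len(d_t), len(s_t),
        sum(e.q_alloc for e in allocation.entries), avg_wait, avg_rate,
    )
    return WindowResult(
        window_index=idx,
        bs_used=bs,
        timestamp=t,
        responses=responses,
        avg_wait=avg_wait,
        avg_rate=avg_rate,
        n_participants=len(participants),
    )


def run_ftwbm(
    recipients: Sequence[Recipient],
    suppliers: Sequence[Supplier],
    bs: int,
    T: int = 120,
    matcher: Matcher = g_hmbmc,
    speed: float = 1.0,
    tau_agg: str = "max",
    validate: bool = False,
) -> list[WindowResult]:
    """Fixed time window batch matching over a full arrival stream.

    Windows end at bs, 2*bs, ..., with the final window truncated to T, so
    every entity that arrived inside the horizon is offered for matching.
    """
    n = window_count(T, bs)
    state = PlatformState.from_stream(list(recipients), list(suppliers))
    results = []
    for idx in range(1, n + 1):
        t = min(idx * bs, T)
        results.append(_run_window(state, t, idx, bs, matcher, speed, tau_agg, validate))
    return results


# --- bandit machinery --------------------------------------------------------


def epsilon_schedule(eps0: float, lam: float, k: int) -> float:
    """Exploration probability after k matches: eps_k = eps0 * lam**k."""
    if not 0 < eps0 <= 1:
        raise ValueError("eps0 must be in (0, 1]")
    if not 0 < lam < 1:
        raise ValueError("decay rate lam must be in (0, 1)")
    if k < 0:
        raise ValueError("round index must be non-negative")
    return eps0 * lam**k


@dataclass
class BanditState:
    """State of the window-size bandit.

    Rewards are per-arm running means of observed window average waiting
    times and are MINIMIZED.  ``R`` starts at zero, which with minimization
    makes never-pulled arms look optimal at refresh time — an optimistic
    initialization that forces early exploration and is kept deliberately;
    UCB independently selects unpulled arms first, and Thompson sampling's
    broad prior spreads its early picks.
    """

    arms: tuple[int, ...] = DEFAULT_ARMS
    eps0: float = 0.2
    lam: float = 0.8
    K_theta: int = 2
    R: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    k: int = 0
    omega: int = 0
    exploit_idx: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("arm set must be non-empty")
        self.arms = tuple(sorted(self.arms))
        if not self.R:
            self.R = [0.0 for _ in self.arms]
        if not self.counts:
            self.counts = [0 for _ in self.arms]

    def arm_index(self, arm: int) -> int:
        return self.arms.index(arm)


def update_reward(bandit: BanditState, arm: int, observed_avg_wait: float) -> BanditState:
    """Fold one observation into the arm's running mean (in place)."""
    a = bandit.arm_index(arm)
    c = bandit.counts[a] + 1
    bandit.R[a] += (observed_avg_wait - bandit.R[a]) / c
    bandit.counts[a] = c
    return bandit


def refresh_exploitation(bandit: BanditState) -> None:
    """Point the exploitation arm at argmin R (ties -> smallest arm)."""
    best = min(range(len(bandit.arms)), key=lambda a: (bandit.R[a], bandit.arms[a]))
    bandit.exploit_idx = best
    bandit.omega += 1


def select_arm_egreedy(bandit: BanditState, rng: np.random.Generator) -> int:
    """Epsilon-greedy with decay: explore uniformly w.p. eps_k = eps0*lam^k,
    otherwise play the current exploitation arm."""
    eps_k = epsilon_schedule(bandit.eps0, bandit.lam, bandit.k)
    if rng.random() <= eps_k:
        return int(rng.choice(bandit.arms))
    return bandit.arms[bandit.exploit_idx]


def select_arm_ucb(bandit: BanditState, k: int, c: float = 1.0) -> int:
    """Lower-confidence-bound selection for a minimized reward.

    Picks argmin of R[a] - c*sqrt(2 ln k / counts[a]); arms never pulled are
    selected first, in arm order.
    """
    if k < 1:
        raise ValueError("round index must be >= 1")
    for a, n in enumerate(bandit.counts):
        if n == 0:
            return bandit.arms[a]
    scores = [
        bandit.R[a] - c * math.sqrt(2.0 * math.log(k) / bandit.counts[a])
        for a in range(len(bandit.arms))
    ]
    best = min(range(len(bandit.arms)), key=lambda a: (scores[a], bandit.arms[a]))
    return bandit.arms[best]


def select_arm_ts(
    bandit: BanditState,
    rng: np.random.Generator,
    prior_var: float = 100.0,
    obs_var: float = 1.0,
) -> int:
    """Gaussian Thompson sampling for a minimized reward.

    Known-variance conjugate posterior per arm, prior mean set to the global
    mean of all observations so far (0 before any), prior variance broad.
    Samples every posterior and plays the minimum sample.
    """
    total = sum(bandit.counts)
    prior_mean = (
        sum(r * n for r, n in zip(bandit.R, bandit.counts)) / total if total else 0.0
    )
    samples = []
    for a in range(len(bandit.arms)):
        n = bandit.counts[a]
        prec = 1.0 / prior_var + n / obs_var
        post_var = 1.0 / prec
        post_mean = (prior_mean / prior_var + n * bandit.R[a] / obs_var) * post_var
        samples.append(rng.normal(post_mean, math.sqrt(post_var)))
    best = min(range(len(bandit.arms)), key=lambda a: (samples[a], bandit.arms[a]))
    return bandit.arms[best]


@dataclass
class RoundRecord:
    """One adaptive round: the arm played and the reward observed."""

    round_index: int
    arm: int
    timestamp: int
    avg_wait: float | None
    avg_rate: float | None


def run_atwbm(
    recipients: Sequence[Recipient],
    suppliers: Sequence[Supplier],
    T: int = 120,
    arms: tuple[int, ...] = DEFAULT_ARMS,
    policy: str = "egreedy",
    eps0: float = 0.2,
    lam: float = 0.8,
    K_theta: int = 2,
    seed: int | None = None,
    matcher: Matcher = g_hmbmc,
    speed: float = 1.0,
    tau_agg: str = "max",
    ucb_c: float = 1.0,
    ts_prior_var: float = 100.0,
    ts_obs_var: float = 1.0,
    validate: bool = False,
) -> tuple[list[WindowResult], BanditState, list[RoundRecord]]:
    """Adaptive time window batch matching driven by a bandit policy.

    Each round: select a window size, advance the clock by it, batch-match
    the eligible buffer, observe the window average waiting time and update
    that arm's reward; repeat until the clock reaches T.  The clock never
    exceeds T + max(arms).  A seeded run is fully reproducible.
    """
    if policy not in ("egreedy", "ucb", "ts"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(seed)
    bandit = BanditState(arms=arms, eps0=eps0, lam=lam, K_theta=K_theta)
    state = PlatformState.from_stream(list(recipients), list(suppliers))

    results: list[WindowResult] = []
    trace: list[RoundRecord] = []
    clock = 0
    k = 0
    while clock < T:
        k += 1
        bandit.k = k
        if policy == "egreedy":
            bs = select_arm_egreedy(bandit, rng)
        elif policy == "ucb":
            bs = select_arm_ucb(bandit, k, c=ucb_c)
        else:
            bs = select_arm_ts(bandit, rng, prior_var=ts_prior_var, obs_var=ts_obs_var)
        clock += bs
        res = _run_window(state, clock, k, bs, matcher, speed, tau_agg, validate)
        results.append(res)
        if res.avg_wait is not None:
            update_reward(bandit, bs, res.avg_wait)
        trace.append(RoundRecord(k, bs, clock, res.avg_wait, res.avg_rate))
        if bandit.K_theta == 0 or k == (bandit.omega + 1) * bandit.K_theta:
            refresh_exploitation(bandit)
    return results, bandit, trace


def unserved(results: Sequence[WindowResult], recipients: Sequence[Recipient]) -> list[str]:
    """Recipients that never received any allocation over a run.

    These are excluded from the per-window waiting-time and match-rate
    averages (which only see window participants) and reported separately.
    """
    served = {resp.recipient_id for res in results for resp in res.responses}
    return sorted(r.id for r in recipients if r.id not in served)
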