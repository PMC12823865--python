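"""Evaluation metrics and summary statistics.

Per matching window the platform reports two quantities over the set M of
participating recipients (recipients that received at least one allocation
in that window):

* average waiting time   avg_tau(t)  = sum_i tau_i(t) / |M|
* average match rate     avg_rate(t) = sum_i r_i(t)   / |M|

where r_i(t) = matched_q / q is the recipient's cumulative completion rate
at the window's end.  A recipient served by several suppliers within one
window contributes a single tau_i, by default the maximum over its
responses — it waits for the last delivery; ``sum`` and ``mean``
aggregations are available for sensitivity runs.

Collections of per-window values are condensed into the usual descriptive
table (n, median, mean, sample sd, standard error, margin of error, 95% CI)
with the CI built on the t distribution with n-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
from scipy import stats as sps

if TYPE_CHECKING:
    from .entities import MatchResponse

_TAU_AGGS = {
    "max": max,
    "sum": sum,
    "mean": lambda xs: sum(xs) / len(xs),
}


def window_avg_wait(responses: Sequence["MatchResponse"], agg: str = "max") -> float:
    """Average waiting time over the recipients participating in a window."""
    if not responses:
        raise ValueError("average waiting time is undefined for an empty window")
    if agg not in _TAU_AGGS:
        raise ValueError(f"tau aggregation must be one of {sorted(_TAU_AGGS)}")
    per_recipient: dict[str, list[float]] = {}
    for resp in responses:
        per_recipient.setdefault(resp.recipient_id, []).append(resp.tau)
    taus = [_TAU_AGGS[agg](v) for v in per_recipient.values()]
    return float(np.mean(taus))


def window_avg_rate(rates: Sequence[float]) -> float:
    """Average completion rate over participating recipients."""
    if len(rates) == 0:
        raise ValueError("average match rate is undefined for an empty window")
    rates = np.asarray(rates, dtype=float)
    if rates.min() < 0 or rates.max() > 1:
        raise ValueError("completion rates must lie in [0, 1]")
    return float(rates.mean())


@dataclass
class SummaryStats:
    """Descriptive row: n, median, mean, s, SE = s/sqrt(n), ME = t* SE, 95% CI."""

    n: int
    median: float
    mean: float
    s: float | None
    se: float | None
    me: float | None
    ci_low: float | None
    ci_high: float | None

    def rounded(self, ndigits: int = 3) -> dict:
        """Report-ready dict, rounded half-even to ``ndigits`` decimals."""

        def r(x):
            return None if x is None else float(np.round(x, ndigits))

        return {
            "n": self.n,
            "median": r(self.median),
            "mean": r(self.mean),
            "s": r(self.s),
            "SE": r(self.se),
            "ME": r(self.me),
            "ci_low": r(self.ci_low),
            "ci_high": r(self.ci_high),
        }


def summarize(samples: Sequence[float], confidence: float = 0.95) -> SummaryStats:
    """Summary statistics of a sample of per-window metric values.

    With fewer than two observations the dispersion fields are None.
    """
    xs = np.asarray([x for x in samples if x is not None], dtype=float)
    n = len(xs)
    if n == 0:
        raise ValueError("cannot summarize an empty sample")
    if n == 1:
        return SummaryStats(1, float(xs[0]), float(xs[0]), None, None, None, None, None)
    mean = float(xs.mean())
    s = float(xs.std(ddof=1))
    se = s / np.sqrt(n)
    tstar = sps.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    me = float(tstar * se)
    return SummaryStats(
        n=n,
        median=float(np.median(xs)),
        mean=mean,
        s=s,
        se=float(se),
        me=me,
        ci_low=mean - me,
        ci_high=mean + me,
    )


def se_me_from_s_n(s: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """SE and ME implied by a printed sample sd and sample size."""
    se = s / np.sqrt(n)
    tstar = sps.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return float(se), float(tstar * se)


@dataclass
class RegretTrace:
    """Per-round regret of a bandit run against the empirical best arm."""

    chosen_rewards: np.ndarray
    best_reward: float
    instantaneous: np.ndarray
    cumulative: np.ndarray


def cumulative_regret(
    trace: Sequence[tuple[int, float]], arm_means: Mapping[int, float]
) -> RegretTrace:
    """Cumulative regret of a sequence of (arm, realized avg wait) rounds.

    The reward is minimized, so instantaneous regret is the realized value
    minus the empirical best (lowest-mean) arm's mean.
    """
    if arm_means:
        best = min(arm_means.values())
    else:
        best = 0.0
    chosen = np.asarray([r for _, r in trace], dtype=float)
    inst = chosen - best
    return RegretTrace(
        chosen_rewards=chosen,
        best_reward=float(best),
        instantaneous=inst,
        cumulative=np.cumsum(inst),
    )
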