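"""Reproducible experiment grids.

Drives full simulation sweeps: the fixed-window batch-size sweep
(BS = {1, 2, 3, 4, 6, 8}), the adaptive-window epsilon-greedy grid
(eps0 x K_theta x lambda), and the bandit-policy comparison
(epsilon-greedy vs UCB vs Thompson sampling on common streams).  Every run
is reproducible from its manifest: a config hash plus the replicate seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import SummaryStats, cumulative_regret, summarize
from .stream import StreamConfig, generate_stream
from .windows import DEFAULT_ARMS, RoundRecord, WindowResult, run_atwbm, run_ftwbm

EGREEDY_GRID = {
    "eps0": (0.02, 0.2, 0.8),
    "K_theta": (0, 2),
    "lam": (0.2, 0.8),
}


@dataclass
class ExperimentConfig:
    """One experiment: a stream design, a strategy grid, replicate seeds."""

    stream: StreamConfig = field(default_factory=StreamConfig)
    strategy: str = "ftwbm"  # "ftwbm" | "atwbm"
    bs_list: tuple[int, ...] = DEFAULT_ARMS
    policies: tuple[str, ...] = ("egreedy",)
    eps0_grid: tuple[float, ...] = EGREEDY_GRID["eps0"]
    K_theta_grid: tuple[int, ...] = EGREEDY_GRID["K_theta"]
    lam_grid: tuple[float, ...] = EGREEDY_GRID["lam"]
    seeds: tuple[int, ...] = (42,)
    tau_agg: str = "max"
    speed: float = 1.0

    def __post_init__(self) -> None:
        if self.strategy not in ("ftwbm", "atwbm"):
            raise ValueError("strategy must be 'ftwbm' or 'atwbm'")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")
        if not self.bs_list or not self.policies:
            raise ValueError("grids must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _summary_row(results: Sequence[WindowResult]) -> dict:
    ar = summarize([r.avg_rate for r in results if r.avg_rate is not None])
    at = summarize([r.avg_wait for r in results if r.avg_wait is not None])
    row = {}
    for prefix, stats in (("AR", ar), ("AT", at)):
        for key, val in stats.rounded().items():
            row[f"{prefix}_{key}"] = val
    return row


def _trace_rows(results: Sequence[WindowResult]) -> list[dict]:
    return [
        {
            "window_index": r.window_index,
            "bs": r.bs_used,
            "timestamp": r.timestamp,
            "n_participants": r.n_participants,
            "matched_q": sum(resp.q_alloc for resp in r.responses),
            "avg_wait": r.avg_wait,
            "avg_rate": r.avg_rate,
        }
        for r in results
    ]


def run_grid(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run every grid cell for every replicate seed.

    Returns a bundle with one summary row per (cell, seed) plus the full
    per-window traces; optionally writes summary.csv / trace.csv /
    manifest.json to ``out_dir``.
    """
    summary_rows: list[dict] = []
    trace_rows: list[dict] = []

    for seed in config.seeds:
        stream_cfg = StreamConfig(**{**asdict(config.stream), "seed": seed})
        recipients, suppliers = generate_stream(stream_cfg)
        if config.strategy == "ftwbm":
            for bs in config.bs_list:
                results = run_ftwbm(
                    recipients,
                    suppliers,
                    bs=bs,
                    T=stream_cfg.T,
                    speed=config.speed,
                    tau_agg=config.tau_agg,
                )
                cell = {"strategy": "ftwbm", "bs": bs, "seed": seed}
                summary_rows.append({**cell, **_summary_row(results)})
                for tr in _trace_rows(results):
                    trace_rows.append({**cell, **tr})
        else:
            for policy in config.policies:
                for eps0 in config.eps0_grid:
                    for K_theta in config.K_theta_grid:
                        for lam in config.lam_grid:
                            results, _, _ = run_atwbm(
                                recipients,
                                suppliers,
                                T=stream_cfg.T,
                                arms=config.bs_list,
                                policy=policy,
                                eps0=eps0,
                                lam=lam,
                                K_theta=K_theta,
                                seed=seed,
                                speed=config.speed,
                                tau_agg=config.tau_agg,
                            )
                            cell = {
                                "strategy": "atwbm",
                                "policy": policy,
                                "eps0": eps0,
                                "K_theta": K_theta,
                                "lam": lam,
                                "seed": seed,
                            }
                            summary_rows.append({**cell, **_summary_row(results)})
                            for tr in _trace_rows(results):
                                trace_rows.append({**cell, **tr})

    summary = pd.DataFrame(summary_rows)
    trace = pd.DataFrame(trace_rows)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seeds": list(config.seeds),
        "n_summary_rows": len(summary),
    }
    bundle = {"summary": summary, "trace": trace, "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        trace.to_csv(out / "trace.csv", index=False)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle


def compare_policies(
    config: ExperimentConfig,
    eps0: float = 0.2,
    lam: float = 0.8,
    K_theta: int = 2,
    out_dir: str | Path | None = None,
) -> dict:
    """Run each bandit policy on common streams/seeds.

    Returns per-policy summary statistics for AR and AT plus per-seed
    cumulative-regret traces (regret against the empirical best arm of
    that run's own pulls).
    """
    for p in config.policies:
        if p not in ("egreedy", "ucb", "ts"):
            raise ValueError(f"unknown policy {p!r}")
    summary_rows: list[dict] = []
    regret_rows: list[dict] = []
    for seed in config.seeds:
        stream_cfg = StreamConfig(**{**asdict(config.stream), "seed": seed})
        recipients, suppliers = generate_stream(stream_cfg)
        for policy in config.policies:
            results, bandit, trace = run_atwbm(
                recipients,
                suppliers,
                T=stream_cfg.T,
                arms=config.bs_list,
                policy=policy,
                eps0=eps0,
                lam=lam,
                K_theta=K_theta,
                seed=seed,
                speed=config.speed,
                tau_agg=config.tau_agg,
            )
            cell = {"policy": policy, "seed": seed}
            summary_rows.append({**cell, **_summary_row(results)})
            observed = [
                (rec.arm, rec.avg_wait) for rec in trace if rec.avg_wait is not None
            ]
            arm_means = {
                arm: bandit.R[bandit.arm_index(arm)]
                for arm in bandit.arms
                if bandit.counts[bandit.arm_index(arm)] > 0
            }
            reg = cumulative_regret(observed, arm_means)
            for idx, (arm, reward) in enumerate(observed):
                regret_rows.append(
                    {
                        **cell,
                        "round": idx + 1,
                        "arm": arm,
                        "reward": reward,
                        "cumulative_regret": float(reg.cumulative[idx]),
                    }
                )
    summary = pd.DataFrame(summary_rows)
    regret = pd.DataFrame(regret_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "policy_summary.csv", index=False)
        regret.to_csv(out / "regret.csv", index=False)
    return {"summary": summary, "regret": regret}
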