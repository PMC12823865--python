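# epimatch

Online bipartite batch matching for emergency resource allocation: a seeded
simulator and library for pairing resource **suppliers** with **recipients**
that arrive over time on a sharing platform, under capacity, service-radius
and priority constraints, with fixed or bandit-adaptive batching windows.

It is aimed at operations and public-health researchers studying dispatch
policies for scarce consumables during an outbreak: when should a platform
match instantly, and when should it pool requests into batches — and how
large should the batch window be?

## The model

Recipients `i = (id, loc, dr, requesttime, q)` demand an integer quantity
`q_i` at a grid location with a prevention-priority class `dr ∈ {high, low}`.
Suppliers `j = (id, loc, sr, requesttime, q, l)` offer `q_j` units from a
location with a supply tier `sr ∈ {1,2,3}` and a service radius `l_j`: the
pair `(i, j)` is eligible iff the Manhattan distance `l_ij ≤ l_j`. Each
matching window maximizes the total allocated quantity

```
max  Σ_i Σ_j q_ij x_ij
s.t. Σ_j q_ij ≤ q_i,   Σ_i q_ij ≤ q_j,   l_ij ≤ l_j,
     high-priority recipients before low,  tier-1 supply before 2 before 3,
     arrivals before the window timestamp,  q_ij ∈ Z≥0
```

Three engines solve the window problem:

- **GMBMC** — greedy nearest-neighbour-first with capacities: each recipient
  drains its eligible suppliers in ascending distance order.
- **HMBMC** — a Hungarian algorithm extended to integer vertex capacities: a
  recursive `get_path(i, q_i)` augmenting search reroutes existing
  allocations, reaching the maximum total quantity (equal to a max-flow
  value, verified against an independent solver in the tests).
- **G-HMBMC** — the multi-stage driver: high-priority recipients first
  (greedy), then low-priority recipients (Hungarian), opening supply tiers
  1 → 2 → 3 within each phase.

Two batching strategies schedule the windows over a horizon `T`: **FTWBM**
(fixed window size `bs`, matching at each window's end; `bs = 1` is instant
matching) and **ATWBM**, where a multi-armed bandit picks each window size
from `BS = {1,2,3,4,6,8}` using the window's average waiting time as a
minimized reward — ε-greedy with decay `ε_k = ε₀·λ^k` and refresh interval
`K_θ`, a lower-confidence-bound UCB variant, or Gaussian Thompson sampling.

Per window the simulator reports the **average waiting time**
`avg_τ = Σ τ_i / |M|` (batch wait plus travel time at unit speed) and the
**average match rate** `avg_rate = Σ r_i / |M|` with `r_i = matched_q / q_i`,
and condenses runs into n / median / mean / s / SE / ME / 95% CI tables.

## Worked example

```python
from epimatch import StreamConfig, generate_stream, run_ftwbm, summarize

config = StreamConfig(T=60, n_recipients=900, n_suppliers=540, seed=7)
recipients, suppliers = generate_stream(config)
for bs in (1, 4, 8):
    results = run_ftwbm(recipients, suppliers, bs=bs, T=config.T)
    ar = summarize([r.avg_rate for r in results if r.avg_rate is not None])
    at = summarize([r.avg_wait for r in results if r.avg_wait is not None])
    print(f"bs={bs}: AR {ar.mean:.3f} [{ar.ci_low:.3f},{ar.ci_high:.3f}]  AT {at.mean:.2f}")
```

prints

```
bs=1: AR 0.969 [0.960,0.978]  AT 14.16
bs=4: AR 0.985 [0.977,0.992]  AT 15.70
bs=8: AR 0.988 [0.980,0.997]  AT 17.07
```

Larger batch windows pool more counterparties, so the per-window average
match rate (AR) rises with `bs`, while the average waiting time (AT) grows
because matched recipients waited longer for their batch to close. The
`examples/` directory walks through stream generation, the two matching
engines, the fixed-window sweep, an adaptive ε-greedy run, and the
three-policy comparison with cumulative regret.

A thin CLI wraps the same functions:

```bash
epimatch generate --seed 42 --out data/
epimatch run --strategy atwbm --policy egreedy --eps0 0.8 --lam 0.2 --seed 42
epimatch grid --strategy ftwbm --seeds 1,2,3 --out results/
epimatch compare --policies egreedy,ucb,ts --out results/
```

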