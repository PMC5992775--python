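"""Per-individual simulators and Monte Carlo population estimates.

These are the sampling-based comparators the product-basis engine is
validated against: direct synchronous trajectories of single individuals,
and vectorised Monte Carlo over populations of deterministic or
probabilistic networks.  Estimates carry standard errors, which shrink as
1/√n_runs — the scaling the exact engine is free of.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import (
    BooleanNetwork,
    DETERMINISTIC,
    RateVector,
    synchronous_step,
)
from .population import (
    EXPLICIT,
    KNOCKOUT,
    MARGINALS,
    UNIFORM,
    PopulationSpec,
    _marginal_lookup,
)
from .network import wildtype_pairs
from .subsets import Subset, members


def simulate_individual(net: BooleanNetwork, state0: Subset, steps: int) -> list[Subset]:
    """Synchronous trajectory of one deterministic individual (state bitmasks)."""
    tables = [rule.k_by_local_mask() for rule in net.rules]
    traj = [state0]
    state = state0
    for _ in range(steps):
        state = synchronous_step(net, state, tables)
        traj.append(state)
    return traj


@dataclass
class McEstimate:
    """Monte Carlo moment estimates: mean and standard error per subset/time."""

    times: np.ndarray
    subsets: tuple[Subset, ...]
    mean: np.ndarray    # (T, K)
    stderr: np.ndarray  # (T, K)
    n_runs: int
    seed: int

    def to_frame(self):
        import pandas as pd

        records = []
        for t, m_row, s_row in zip(self.times, self.mean, self.stderr):
            for subset, m, s in zip(self.subsets, m_row, s_row):
                records.append((t, subset, m, s))
        return pd.DataFrame.from_records(
            records, columns=["time", "subset", "mean", "stderr"]
        )


def sample_initial_states(
    spec: PopulationSpec, net: BooleanNetwork, n_runs: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample (n_runs, N) boolean initial states from a population spec."""
    n = net.n
    if spec.kind == EXPLICIT:
        weights = np.asarray([float(w) for w in spec.weights])
        choice = rng.choice(len(spec.states), size=n_runs, p=weights / weights.sum())
        states = np.zeros((n_runs, n), dtype=bool)
        for r, c in enumerate(choice):
            for i in members(spec.states[c]):
                states[r, i] = True
        return states
    if spec.kind in (UNIFORM, MARGINALS):
        marg = _marginal_lookup(
            None if spec.kind == UNIFORM else spec.marginals, net.names, exact=False
        )
        p = np.array([marg[name] for name in net.names])
        return rng.random((n_runs, n)) < p[None, :]
    if spec.kind == KNOCKOUT:
        pairs = wildtype_pairs(net)
        if not pairs:
            raise ValueError("knockout spec requires a wild-type-augmented network")
        companions = {wt: g for g, wt in pairs.items()}
        gene_names = [net.names[g] for g in pairs]
        marg = _marginal_lookup(spec.marginals, gene_names, exact=False)
        states = np.zeros((n_runs, n), dtype=bool)
        draws = rng.random((n_runs, n))
        for wt, g in companions.items():
            states[:, wt] = draws[:, wt] < (1.0 - spec.mu)
        for g, wt in pairs.items():
            states[:, g] = states[:, wt] & (draws[:, g] < marg[net.names[g]])
        for i in range(n):
            if i not in pairs and i not in companions:
                states[:, i] = draws[:, i] < marg.get(net.names[i], 0.5)
        return states
    raise ValueError(f"unknown population kind {spec.kind!r}")


def _step_population(
    net: BooleanNetwork, states: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    """One synchronous update of all runs; PBN draws are independent per variable."""
    n_runs, n = states.shape
    nxt = np.zeros_like(states)
    for i, rule in enumerate(net.rules):
        k_local = rule.k_by_local_mask()
        pat = np.zeros(n_runs, dtype=np.int64)
        for j, inp in enumerate(rule.inputs):
            pat |= states[:, inp].astype(np.int64) << j
        like = np.asarray(k_local, dtype=np.float64)[pat]
        if net.kind == DETERMINISTIC:
            nxt[:, i] = like > 0.5
        else:
            nxt[:, i] = rng.random(n_runs) < like
    return nxt


def _moments_of_runs(states: np.ndarray, subsets: Sequence[Subset]) -> np.ndarray:
    out = np.empty(len(subsets))
    for k, mask in enumerate(subsets):
        idx = members(mask)
        if not idx:
            out[k] = 1.0
        else:
            out[k] = states[:, list(idx)].all(axis=1).mean()
    return out


def simulate_pbn_population(
    net: BooleanNetwork,
    spec: PopulationSpec,
    n_runs: int,
    steps: int,
    seed: int,
    subsets: Sequence[Subset] | None = None,
) -> McEstimate:
    """Monte Carlo moment estimates over a sampled population.

    Each run samples an initial state from the spec and performs synchronous
    updates; probabilistic rules set each variable ON independently with its
    likelihood.  Works unchanged for deterministic networks (zero per-step
    randomness, sampling error from the initial draw only).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    if subsets is None:
        subsets = tuple(1 << i for i in range(net.n))
    subsets = tuple(subsets)
    states = sample_initial_states(spec, net, n_runs, rng)
    means = [_moments_of_runs(states, subsets)]
    for _ in range(steps):
        states = _step_population(net, states, rng)
        means.append(_moments_of_runs(states, subsets))
    mean = np.vstack(means)
    stderr = np.sqrt(np.clip(mean * (1.0 - mean), 0.0, None) / n_runs)
    return McEstimate(np.arange(steps + 1), subsets, mean, stderr, n_runs, seed)


def simulate_continuous_population(
    net: BooleanNetwork,
    rates,
    spec: PopulationSpec,
    t_max: float,
    n_runs: int,
    seed: int,
    subsets: Sequence[Subset] | None = None,
    max_step_prob: float = 0.05,
) -> McEstimate:
    """Continuous-time Monte Carlo via the small-Δt probabilistic limit.

    The jump process is discretised with per-step update probabilities
    r_i·Δt, with Δt chosen so the largest per-step probability is at most
    ``max_step_prob``; reported times are the discrete grid multiples of Δt.
    """
    r = np.asarray(RateVector.for_network(net, rates).r)
    r_max = float(r.max()) if len(r) else 1.0
    dt = max_step_prob / r_max if r_max > 0 else t_max
    steps = max(1, int(np.ceil(t_max / dt)))
    dt = t_max / steps
    pbn = _rate_blend(net, r * dt)
    est = simulate_pbn_population(pbn, spec, n_runs, steps, seed, subsets)
    est.times = est.times * dt
    return est


def _rate_blend(net: BooleanNetwork, r_eff: np.ndarray) -> BooleanNetwork:
    from .network import attach_rates

    return attach_rates(net, tuple(float(v) for v in r_eff))
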