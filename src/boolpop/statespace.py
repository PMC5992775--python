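"""Exact full-state-space evolution: the brute-force reference engine.

A population over an N-variable network is a weight vector over all 2^N
states.  Deterministic dynamics is a successor table, probabilistic dynamics
a column-stochastic 2^N × 2^N transition matrix, and continuous-time dynamics
a Markov jump process whose generator flips one variable at a time toward its
logic target.  Moments ⟨x_α⟩ are read off with a superset-zeta transform.

This engine is intentionally brute force and refuses networks beyond a small
size; it exists to validate the product-basis engine independently.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import BooleanNetwork, DETERMINISTIC, RateVector, local_pattern
from .population import (
    EXPLICIT,
    KNOCKOUT,
    MARGINALS,
    UNIFORM,
    PopulationSpec,
    _marginal_lookup,
)
from .network import wildtype_pairs
from .subsets import Subset, superset_zeta

#: Hard cap on N for any full-state-space construction.
MAX_STATE_VARS = 12


def _check_size(net: BooleanNetwork) -> None:
    if net.n > MAX_STATE_VARS:
        raise ValueError(
            f"state-space oracle refuses N = {net.n} > {MAX_STATE_VARS} variables; "
            "this engine is deliberately brute-force"
        )


def successor_table(net: BooleanNetwork) -> np.ndarray:
    """Deterministic synchronous successor state for every state bitmask."""
    _check_size(net)
    if net.kind != DETERMINISTIC:
        raise ValueError("successor table requires a deterministic network")
    n = net.n
    states = np.arange(1 << n, dtype=np.int64)
    succ = np.zeros(1 << n, dtype=np.int64)
    for i, rule in enumerate(net.rules):
        k_local = rule.k_by_local_mask()
        pat = np.zeros(1 << n, dtype=np.int64)
        for j, inp in enumerate(rule.inputs):
            pat |= ((states >> inp) & 1) << j
        succ |= (k_local[pat].astype(np.int64)) << i
    return succ


def likelihood_tables(net: BooleanNetwork) -> np.ndarray:
    """Per-variable ON-likelihood over all full states, shape (N, 2^N)."""
    _check_size(net)
    n = net.n
    states = np.arange(1 << n, dtype=np.int64)
    out = np.zeros((n, 1 << n), dtype=np.float64)
    for i, rule in enumerate(net.rules):
        k_local = np.asarray(rule.k_by_local_mask(), dtype=np.float64)
        pat = np.zeros(1 << n, dtype=np.int64)
        for j, inp in enumerate(rule.inputs):
            pat |= ((states >> inp) & 1) << j
        out[i] = k_local[pat]
    return out


def pbn_transition_matrix(net: BooleanNetwork) -> np.ndarray:
    """Column-stochastic matrix M with M[σ, κ] = P(κ → σ), variables independent."""
    _check_size(net)
    if net.n > 10:
        raise ValueError("full PBN transition matrix capped at N = 10")
    n = net.n
    like = likelihood_tables(net)  # (n, S)
    states = np.arange(1 << n, dtype=np.int64)
    m = np.ones((1 << n, 1 << n), dtype=np.float64)
    for i in range(n):
        on = ((states >> i) & 1).astype(bool)  # over target states sigma
        m[on, :] *= like[i][None, :]
        m[~on, :] *= 1.0 - like[i][None, :]
    return m


def initial_state_weights(
    spec: PopulationSpec, net: BooleanNetwork, exact: bool = False
) -> np.ndarray:
    """Weight vector over all 2^N states realising the population spec."""
    _check_size(net)
    n = net.n
    size = 1 << n
    if spec.kind == EXPLICIT:
        w = np.zeros(size, dtype=object if exact else np.float64)
        for s, wt in zip(spec.states, spec.weights):
            w[s] += Fraction(wt) if exact else float(wt)
        return w

    if spec.kind in (UNIFORM, MARGINALS):
        marg = _marginal_lookup(
            None if spec.kind == UNIFORM else spec.marginals, net.names, exact
        )
        p = [marg[name] for name in net.names]
    elif spec.kind == KNOCKOUT:
        pairs = wildtype_pairs(net)
        if not pairs:
            raise ValueError("knockout spec requires a wild-type-augmented network")
        mu = Fraction(spec.mu) if exact else float(spec.mu)
        gene_names = [net.names[g] for g in pairs]
        marg = _marginal_lookup(spec.marginals, gene_names, exact)
        one = Fraction(1) if exact else 1.0
        w = np.empty(size, dtype=object if exact else np.float64)
        companions = {wt: g for g, wt in pairs.items()}
        for state in range(size):
            acc = one
            for i in range(n):
                on = state >> i & 1
                if i in pairs:  # a gene with a companion
                    wt_on = state >> pairs[i] & 1
                    pg = marg[net.names[i]]
                    if wt_on:
                        acc = acc * (pg if on else (one - pg))
                    else:
                        if on:
                            acc = acc * 0
                            break
                        # gene pinned OFF given mutated companion: factor 1
                elif i in companions:
                    acc = acc * ((one - mu) if on else mu)
                else:
                    p_free = marg.get(net.names[i], Fraction(1, 2) if exact else 0.5)
                    acc = acc * (p_free if on else (one - p_free))
            w[state] = acc
        return w
    else:
        raise ValueError(f"unknown population kind {spec.kind!r}")

    one = Fraction(1) if exact else 1.0
    w = np.empty(size, dtype=object if exact else np.float64)
    for state in range(size):
        acc = one
        for i in range(n):
            acc = acc * (p[i] if state >> i & 1 else (one - p[i]))
        w[state] = acc
    return w


def moments_from_weights(weights: np.ndarray, subsets: Sequence[Subset]) -> np.ndarray:
    """⟨x_α⟩ = Σ_{κ ⊇ α} w_κ for each requested subset."""
    zeta = superset_zeta(weights)
    idx = np.asarray(subsets, dtype=np.int64)
    return zeta[idx]


def state_space_moments(
    net: BooleanNetwork,
    spec: PopulationSpec,
    steps: int,
    subsets: Sequence[Subset],
    exact: bool = False,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Exact moment series, shape (steps+1, len(subsets)), via full evolution.

    Deterministic networks scatter weights along the successor table (exact in
    rational or integer arithmetic if the weights are); probabilistic networks
    apply the full master-equation transition matrix.  ``weights`` overrides
    the spec with a raw state distribution (any numeric dtype, e.g. int64
    counts with an implicit W = 2^N).
    """
    _check_size(net)
    if weights is None:
        weights = initial_state_weights(spec, net, exact=exact)
    w = np.array(weights, copy=True)
    rows = [moments_from_weights(w, subsets)]
    if net.kind == DETERMINISTIC:
        succ = successor_table(net)
        for _ in range(steps):
            nxt = np.zeros_like(w)
            np.add.at(nxt, succ, w)
            w = nxt
            rows.append(moments_from_weights(w, subsets))
    else:
        m = pbn_transition_matrix(net)
        w = w.astype(np.float64)
        rows = [moments_from_weights(w, subsets)]
        for _ in range(steps):
            w = m @ w
            rows.append(moments_from_weights(w, subsets))
    return np.vstack(rows)


def ctmc_generator(net: BooleanNetwork, rates=None) -> np.ndarray:
    """Generator A of the continuous-time master equation dP/dt = A·P.

    Individuals are Markov jump processes: variable i flips toward its logic
    target g_i(state) at rate r_i whenever the current value disagrees with
    the target.  A[σ, κ] is the flow rate from state κ into σ.
    """
    _check_size(net)
    if net.kind != DETERMINISTIC:
        raise ValueError("continuous-time dynamics requires a deterministic logic network")
    r = RateVector.for_network(net, rates if rates is not None else 1.0).r
    n = net.n
    size = 1 << n
    a = np.zeros((size, size), dtype=np.float64)
    tables = [rule.k_by_local_mask() for rule in net.rules]
    for state in range(size):
        for i, rule in enumerate(net.rules):
            target = int(tables[i][local_pattern(state, rule.inputs)])
            current = state >> i & 1
            if target != current:
                dest = state ^ (1 << i)
                a[dest, state] += r[i]
                a[state, state] -= r[i]
    return a


def ctmc_moments(
    net: BooleanNetwork,
    spec: PopulationSpec,
    t_grid: Sequence[float],
    subsets: Sequence[Subset],
    rates=None,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Master-equation moment series on a time grid, shape (T, len(subsets))."""
    a = ctmc_generator(net, rates)
    w0 = initial_state_weights(spec, net).astype(np.float64)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda _t, w: a @ w,
        (t_grid[0], t_grid[-1]),
        w0,
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=rtol * 1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    return np.vstack([moments_from_weights(sol.y[:, j], subsets) for j in range(sol.y.shape[1])])
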