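"""Ensemble validation campaigns: product-basis engine vs independent oracles.

Three campaigns mirror the method's validation protocol on random networks:

* deterministic — exact equality (integer arithmetic) between the engine and
  full state-space evolution of a uniform initial mixture;
* probabilistic — engine within the 4/√n_runs sampling band of Monte Carlo,
  plus exact agreement with the full master equation on small networks;
* continuous-time — engine within a sup-norm tolerance of the master-equation
  ODE oracle.

Each function returns a plain dict so reports serialise directly to JSON.
"""

from __future__ import annotations

import numpy as np

from .closure import assemble_operator, close_system
from .montecarlo import simulate_pbn_population
from .network import attach_rates, edge_count, generate_random_network
from .population import PopulationSpec, evolve_continuous, evolve_discrete, initial_moments
from .statespace import ctmc_moments, state_space_moments
from .subsets import size as subset_size


def _singletons(n: int) -> list[int]:
    return [1 << i for i in range(n)]


def _uniform_int_moments(system) -> np.ndarray:
    """Uniform-mixture moments scaled by W = 2^N so everything is integer."""
    n = system.network.n
    return np.array(
        [1 << (n - subset_size(mask)) for mask in system.omega], dtype=np.int64
    )


def validate_deterministic(
    n_networks: int = 200,
    n_vars: int = 10,
    steps: int = 30,
    seed: int = 0,
    in_degree: tuple[int, int] = (1, 4),
) -> dict:
    """Engine vs exact state-space oracle on random deterministic networks.

    Both sides run in integer arithmetic (uniform mixture scaled to integer
    weights), so agreement is exact equality, not a tolerance.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    edges = 0
    max_dim = 0
    for _ in range(n_networks):
        net = generate_random_network(n_vars, in_degree, rng)
        edges += edge_count(net)
        system = close_system(net, _singletons(n_vars))
        max_dim = max(max_dim, system.dimension)
        op = assemble_operator(system)
        x0 = _uniform_int_moments(system)
        engine = evolve_discrete(op, x0, steps).values
        weights = np.ones(1 << n_vars, dtype=np.int64)  # uniform, W = 2^N
        oracle = state_space_moments(
            net, PopulationSpec.uniform(), steps, system.omega, weights=weights
        )
        if np.array_equal(engine, oracle):
            agree += 1
    return {
        "n_networks": n_networks,
        "n_vars": n_vars,
        "steps": steps,
        "agreement_fraction": agree / n_networks,
        "mean_edge_count": edges / n_networks,
        "max_system_dimension": max_dim,
    }


def validate_pbn(
    n_networks: int = 100,
    n_vars: int = 10,
    steps: int = 15,
    n_runs: int = 10**4,
    seed: int = 0,
    in_degree: tuple[int, int] = (1, 4),
) -> dict:
    """Engine vs Monte Carlo on rate-augmented probabilistic networks.

    Counts (variable, time) points where the engine's exact population mean
    lies within 4/√n_runs of the Monte Carlo estimate.
    """
    rng = np.random.default_rng(seed)
    band = 4.0 / np.sqrt(n_runs)
    within = 0
    total = 0
    max_abs = 0.0
    for trial in range(n_networks):
        net = generate_random_network(n_vars, in_degree, rng)
        rates = tuple(float(v) for v in rng.uniform(0.0, 1.0, size=n_vars))
        pbn = attach_rates(net, rates)
        system = close_system(pbn, _singletons(n_vars))
        op = assemble_operator(system)
        x0 = initial_moments(PopulationSpec.uniform(), system)
        engine = evolve_discrete(op, x0, steps)
        mc_seed = int(rng.integers(0, 2**31 - 1))
        est = simulate_pbn_population(
            pbn, PopulationSpec.uniform(), n_runs, steps, mc_seed
        )
        for k, mask in enumerate(est.subsets):
            diff = np.abs(engine.query(mask) - est.mean[:, k])
            within += int((diff <= band).sum())
            total += len(diff)
            max_abs = max(max_abs, float(diff.max()))
    return {
        "n_networks": n_networks,
        "n_vars": n_vars,
        "steps": steps,
        "n_runs": n_runs,
        "band": band,
        "fraction_within_band": within / total,
        "max_abs_deviation": max_abs,
    }


def validate_pbn_master(
    n_networks: int = 25,
    n_vars: int = 8,
    steps: int = 20,
    seed: int = 0,
    in_degree: tuple[int, int] = (1, 4),
) -> dict:
    """Engine vs the exact 2^N master equation for probabilistic networks."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_networks):
        net = generate_random_network(n_vars, in_degree, rng)
        rates = tuple(float(v) for v in rng.uniform(0.0, 1.0, size=n_vars))
        pbn = attach_rates(net, rates)
        system = close_system(pbn, _singletons(n_vars))
        op = assemble_operator(system)
        x0 = initial_moments(PopulationSpec.uniform(), system)
        engine = evolve_discrete(op, x0, steps).values
        oracle = state_space_moments(
            pbn, PopulationSpec.uniform(), steps, system.omega
        )
        max_err = max(max_err, float(np.abs(engine - oracle).max()))
    return {
        "n_networks": n_networks,
        "n_vars": n_vars,
        "steps": steps,
        "max_abs_error": max_err,
    }


def validate_continuous(
    n_networks: int = 25,
    n_vars: int = 6,
    t_max: float = 8.0,
    n_times: int = 17,
    seed: int = 0,
    in_degree: tuple[int, int] = (1, 4),
    tol: float = 1e-10,
) -> dict:
    """Engine vs the master-equation ODE oracle for continuous-time networks."""
    rng = np.random.default_rng(seed)
    t_grid = np.linspace(0.0, t_max, n_times)
    max_err = 0.0
    for _ in range(n_networks):
        net = generate_random_network(n_vars, in_degree, rng)
        rates = tuple(float(v) for v in rng.uniform(0.1, 1.0, size=n_vars))
        system = close_system(net, _singletons(n_vars), mode="differential", rates=rates)
        op = assemble_operator(system)
        x0 = initial_moments(PopulationSpec.uniform(), system)
        engine = evolve_continuous(op, x0, t_grid, tol=tol).values
        oracle = ctmc_moments(
            net, PopulationSpec.uniform(), t_grid, system.omega, rates=rates, rtol=tol
        )
        max_err = max(max_err, float(np.abs(engine - oracle).max()))
    return {
        "n_networks": n_networks,
        "n_vars": n_vars,
        "t_max": t_max,
        "max_sup_norm_error": max_err,
    }
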