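"""Population moment vectors: construction, evolution, and queries.

A population is summarised by the moments ⟨x_α⟩ — the fraction of individuals
in which every variable of α is simultaneously ON — for each tracked subset
α ∈ Ω.  With the W = 1 normalisation adopted throughout, ⟨x_∅⟩ = 1 and every
moment lies in [0, 1].  Because the update operator F is linear and was
derived for an individual, the same F evolves any weighted mixture
(superposition), which is what makes arbitrary heterogeneity free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .closure import ClosedSystem, TransitionOperator, DISCRETE, DIFFERENTIAL
from .network import WT_SUFFIX, wildtype_pairs
from .subsets import Subset, members, parse_subset, subset_name

WEIGHT_TOL = 1e-12

UNIFORM = "uniform"
MARGINALS = "marginals"
EXPLICIT = "explicit"
KNOCKOUT = "knockout"


@dataclass(frozen=True)
class PopulationSpec:
    """Description of an initial population.

    kinds:

    * ``uniform`` — every variable independently ON with probability 1/2
      (the uniform mixture over all states);
    * ``marginals`` — independent per-variable ON probabilities;
    * ``explicit`` — a weighted list of full states (weights sum to W = 1);
    * ``knockout`` — for a wild-type-augmented network: each companion is ON
      with probability 1−μ, its gene follows its activation marginal when the
      companion is ON and is pinned OFF when the companion is OFF (mutated
      genes always begin OFF).
    """

    kind: str
    marginals: Mapping[str, float] | float | None = None
    states: tuple[Subset, ...] | None = None
    weights: tuple[object, ...] | None = None
    mu: float | None = None

    @classmethod
    def uniform(cls) -> "PopulationSpec":
        return cls(UNIFORM)

    @classmethod
    def from_marginals(cls, marginals) -> "PopulationSpec":
        return cls(MARGINALS, marginals=marginals)

    @classmethod
    def explicit(cls, states: Iterable[Subset], weights: Iterable) -> "PopulationSpec":
        states = tuple(states)
        weights = tuple(weights)
        if len(states) != len(weights):
            raise ValueError("states and weights differ in length")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        total = sum(weights)
        if abs(float(total) - 1.0) > WEIGHT_TOL:
            raise ValueError(f"weights sum to {total}, expected 1 (W = 1)")
        return cls(EXPLICIT, states=states, weights=weights)

    @classmethod
    def single_state(cls, state: Subset) -> "PopulationSpec":
        return cls(EXPLICIT, states=(state,), weights=(1,))

    @classmethod
    def knockout(cls, mu: float, marginals=0.5) -> "PopulationSpec":
        if not 0 <= mu <= 1:
            raise ValueError("knockout rate must lie in [0, 1]")
        return cls(KNOCKOUT, marginals=marginals, mu=mu)


def _marginal_lookup(spec_marginals, names: Sequence[str], exact: bool):
    def convert(v):
        return Fraction(v) if exact else float(v)

    if spec_marginals is None:
        default = convert(Fraction(1, 2) if exact else 0.5)
        return {name: default for name in names}
    if isinstance(spec_marginals, (int, float, Fraction)):
        return {name: convert(spec_marginals) for name in names}
    out = {}
    for name in names:
        out[name] = convert(spec_marginals.get(name, 0.5))
    for key in spec_marginals:
        if key not in names:
            raise KeyError(f"marginal given for unknown variable {key!r}")
    return out


def initial_moments(
    spec: PopulationSpec,
    system: ClosedSystem,
    exact: bool = False,
) -> np.ndarray:
    """Moment vector ⟨x_α⟩ over the system's Ω for the specified population.

    Explicit mixtures use ⟨x_α⟩ = Σ_s w_s·[α ⊆ s]; independent marginals use
    ⟨x_α⟩ = Π_{i∈α} p_i; knockout populations use the per-gene factor model
    (one factor per gene/companion pair), never an enumeration of mutational
    profiles.  ``exact=True`` returns an object array of rationals.
    """
    net = system.network
    names = net.names
    one: object = Fraction(1) if exact else 1.0

    if spec.kind == EXPLICIT:
        for s in spec.states:
            if s >> net.n:
                raise ValueError("explicit state references a variable outside the network")
        values = []
        for mask in system.omega:
            acc: object = 0
            for s, w in zip(spec.states, spec.weights):
                if mask & s == mask:
                    acc = acc + (Fraction(w) if exact else float(w))
            values.append(acc)
    elif spec.kind in (UNIFORM, MARGINALS):
        marg = _marginal_lookup(
            None if spec.kind == UNIFORM else spec.marginals, names, exact
        )
        p = [marg[name] for name in names]
        values = []
        for mask in system.omega:
            acc = one
            for i in members(mask):
                acc = acc * p[i]
            values.append(acc)
    elif spec.kind == KNOCKOUT:
        pairs = wildtype_pairs(net)
        if not pairs:
            raise ValueError(
                "knockout population requires a wild-type-augmented network "
                f"(no '{WT_SUFFIX}' companions found)"
            )
        genes = set(pairs)
        companions = {wt: g for g, wt in pairs.items()}
        mu = Fraction(spec.mu) if exact else float(spec.mu)
        gene_names = [names[g] for g in genes]
        marg = _marginal_lookup(spec.marginals, gene_names, exact)
        values = []
        for mask in system.omega:
            acc = one
            for i in members(mask):
                if i in genes:
                    # gene ON requires companion ON; the companion's own bit,
                    # if also present in the subset, adds nothing further.
                    acc = acc * (one - mu) * marg[names[i]]
                elif i in companions:
                    gene = companions[i]
                    if mask >> gene & 1:
                        continue  # factor already charged by the gene
                    acc = acc * (one - mu)
                else:
                    acc = acc * marg.get(names[i], Fraction(1, 2) if exact else 0.5)
            values.append(acc)
    else:
        raise ValueError(f"unknown population kind {spec.kind!r}")

    if exact:
        return np.array(values, dtype=object)
    return np.asarray(values, dtype=np.float64)


@dataclass
class TimeSeries:
    """Moment trajectories: one row per time point, one column per Ω subset."""

    times: np.ndarray
    values: np.ndarray  # shape (T, |Omega|); float64 or object (exact)
    system: ClosedSystem
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values disagree in length")
        if np.any(np.diff(np.asarray(self.times, dtype=float)) < 0):
            raise ValueError("times must be monotone non-decreasing")

    def query(self, subset) -> np.ndarray:
        """Series ⟨x_subset⟩ over time; subset by mask or dotted name."""
        mask = self._resolve(subset)
        if mask not in self.system.index:
            name = subset_name(mask, self.system.network.names)
            raise KeyError(
                f"subset {name} is not tracked; add it to omega0 and rebuild the system"
            )
        return self.values[:, self.system.index[mask]]

    def _resolve(self, subset) -> Subset:
        if isinstance(subset, str):
            return parse_subset(subset, self.system.network.names)
        if isinstance(subset, int):
            return subset
        out = 0
        for v in subset:
            out |= 1 << (self.system.network.index(v) if isinstance(v, str) else v)
        return out

    def to_tidy(self) -> pd.DataFrame:
        """Long-form frame: columns time, subset, value."""
        names = self.system.subset_names()
        records = []
        for t, row in zip(self.times, self.values):
            for name, v in zip(names, row):
                records.append((t, name, float(v)))
        return pd.DataFrame.from_records(records, columns=["time", "subset", "value"])

    def to_wide(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            np.asarray(self.values, dtype=float),
            columns=self.system.subset_names(),
        )
        frame.insert(0, "time", self.times)
        return frame

    def write_tsv(self, path, wide: bool = False) -> None:
        frame = self.to_wide() if wide else self.to_tidy()
        with open(path, "w") as fh:
            for key, val in self.provenance.items():
                fh.write(f"# {key}: {val}\n")
            frame.to_csv(fh, sep="\t", index=False)


def evolve_discrete(
    op: TransitionOperator,
    x0: np.ndarray,
    steps: int,
    exact: bool = False,
) -> TimeSeries:
    """Iterate x(t+1) = F·x(t) for ``steps`` steps (t = 0 … steps).

    With ``exact=True`` (or an object/integer ``x0`` against an integer
    operator) the iteration runs in exact arithmetic: integer vectors go
    through the int64 operator, rational vectors through the rule
    dictionaries directly.
    """
    if op.mode != DISCRETE:
        raise ValueError("evolve_discrete requires a discrete-mode operator")
    x0 = np.asarray(x0)
    if len(x0) != op.dimension:
        raise ValueError(f"x0 has length {len(x0)}, operator dimension {op.dimension}")

    use_exact = exact or x0.dtype == object or np.issubdtype(x0.dtype, np.integer)
    if use_exact and not op.exact:
        raise ValueError("exact evolution requires an integer-coefficient operator")

    rows = [x0.copy()]
    if use_exact and np.issubdtype(x0.dtype, np.integer):
        x = x0.astype(np.int64)
        for _ in range(steps):
            x = op.matrix_int @ x
            rows.append(x)
        values = np.vstack(rows)
    elif use_exact:
        system = op.system
        x = {mask: x0[pos] for pos, mask in enumerate(system.omega)}
        for _ in range(steps):
            x = {
                mask: system.rules[mask].evaluate(x)
                for mask in system.omega
            }
            rows.append(np.array([x[m] for m in system.omega], dtype=object))
        values = np.vstack(rows)
    else:
        x = x0.astype(np.float64)
        for _ in range(steps):
            x = op.matrix @ x
            rows.append(x)
        values = np.vstack(rows)
    return TimeSeries(np.arange(steps + 1), values, op.system)


def evolve_continuous(
    op: TransitionOperator,
    x0: np.ndarray,
    t_grid: Sequence[float],
    tol: float = 1e-8,
) -> TimeSeries:
    """Integrate dx/dt = F·x on an explicit adaptive grid (DOP853).

    ``t_grid`` must start at the initial time; the local relative tolerance is
    ``tol`` with an absolute floor three orders tighter, keeping ⟨x_∅⟩
    constant to within the requested accuracy.
    """
    if op.mode != DIFFERENTIAL:
        raise ValueError("evolve_continuous requires a differential-mode operator")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a non-empty 1-D grid")
    x0 = np.asarray(x0, dtype=np.float64)
    if len(x0) != op.dimension:
        raise ValueError(f"x0 has length {len(x0)}, operator dimension {op.dimension}")

    matrix = op.matrix
    sol = solve_ivp(
        lambda _t, x: matrix @ x,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method="DOP853",
        rtol=tol,
        atol=tol * 1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1]}: {sol.message}")
    return TimeSeries(sol.t, sol.y.T.copy(), op.system)
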