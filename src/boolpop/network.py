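"""Boolean network models: variables, per-variable inputs, and output tables.

A network is a fixed, ordered list of named Boolean variables, each with one
update rule.  A rule lists its input variables (sorted by global index) and an
output vector ``k`` with one entry per subset of the inputs, in the canonical
(cardinality, lexicographic) enumeration order: entry ``ρ`` is the output —
0/1 for deterministic networks, an ON-likelihood in [0, 1] for probabilistic
ones — when exactly the input variables in ``ρ`` are ON.

The module also provides the two rule transformations used for population
studies: wild-type augmentation (a constant companion variable ANDed into a
gene's rule, so that companion = 0 encodes a permanent loss of function) and
rate augmentation (``f'_i = (1−r_i)·x_i + r_i·f_i``, turning a deterministic
network into a probabilistic one whose rates set the fraction of an update
taken per time step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .subsets import canonical_order, members, subset_of

#: Naming convention for wild-type companion variables.
WT_SUFFIX = ".WT"

DETERMINISTIC = "deterministic"
PROBABILISTIC = "probabilistic"


class ModelVariable(NamedTuple):
    name: str
    index: int


@dataclass(frozen=True)
class UpdateSpec:
    """One variable's update rule: ordered inputs plus output vector k.

    ``inputs`` are global variable indices, sorted ascending.  ``k`` has
    length ``2^len(inputs)`` and is indexed by input subset in canonical
    enumeration order.
    """

    target: int
    inputs: tuple[int, ...]
    k: tuple[float | int, ...]

    def __post_init__(self):
        if tuple(sorted(set(self.inputs))) != self.inputs:
            raise ValueError(f"inputs of variable {self.target} must be sorted and unique")
        if len(self.k) != 1 << len(self.inputs):
            raise ValueError(
                f"variable {self.target}: k has length {len(self.k)}, "
                f"expected {1 << len(self.inputs)}"
            )
        for v in self.k:
            if not 0 <= v <= 1:
                raise ValueError(f"variable {self.target}: k entry {v} outside [0, 1]")

    @property
    def deterministic(self) -> bool:
        return all(v in (0, 1) for v in self.k)

    def k_by_local_mask(self) -> np.ndarray:
        """Output vector re-indexed by local input bitmask (bit j = inputs[j])."""
        n = len(self.inputs)
        dtype = np.int64 if self.deterministic else np.float64
        out = np.empty(1 << n, dtype=dtype)
        for pos, local in enumerate(canonical_order(n)):
            out[local] = self.k[pos]
        return out


@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean network: named variables with one update rule each."""

    names: tuple[str, ...]
    rules: tuple[UpdateSpec, ...]
    kind: str = DETERMINISTIC
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if len(self.rules) != len(self.names):
            raise ValueError("exactly one rule per variable is required")
        for i, rule in enumerate(self.rules):
            if rule.target != i:
                raise ValueError(f"rule {i} targets variable {rule.target}")
            for j in rule.inputs:
                if not 0 <= j < len(self.names):
                    raise ValueError(f"rule for {self.names[i]} references undeclared index {j}")
        if self.kind == DETERMINISTIC:
            for rule in self.rules:
                if not rule.deterministic:
                    raise ValueError(
                        f"rule for {self.names[rule.target]} has non-binary outputs "
                        "in a deterministic network"
                    )
        elif self.kind != PROBABILISTIC:
            raise ValueError(f"unknown network kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def variables(self) -> list[ModelVariable]:
        return [ModelVariable(name, i) for i, name in enumerate(self.names)]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}") from None

    def truth_table(self, i: int | str) -> tuple[float | int, ...]:
        """Output vector k^[i] in canonical input-subset enumeration order."""
        if isinstance(i, str):
            i = self.index(i)
        return self.rules[i].k


def truth_table(net: BooleanNetwork, i: int | str) -> tuple[float | int, ...]:
    """Module-level alias for :meth:`BooleanNetwork.truth_table`."""
    return net.truth_table(i)


# ---------------------------------------------------------------------------
# Synchronous dynamics of one individual (used by oracles and augmentation
# checks; the population engine never iterates states).
# ---------------------------------------------------------------------------

def local_pattern(state: int, inputs: Sequence[int]) -> int:
    """Local bitmask of the input pattern seen by a rule in global state ``state``."""
    pat = 0
    for j, inp in enumerate(inputs):
        if state >> inp & 1:
            pat |= 1 << j
    return pat


def synchronous_step(net: BooleanNetwork, state: int,
                     tables: Sequence[np.ndarray] | None = None) -> int:
    """One deterministic synchronous update of a full network state bitmask."""
    if net.kind != DETERMINISTIC:
        raise ValueError("synchronous_step requires a deterministic network")
    if tables is None:
        tables = [r.k_by_local_mask() for r in net.rules]
    nxt = 0
    for i, rule in enumerate(net.rules):
        if tables[i][local_pattern(state, rule.inputs)]:
            nxt |= 1 << i
    return nxt


# ---------------------------------------------------------------------------
# Rule transformations
# ---------------------------------------------------------------------------

def augment_wildtype(net: BooleanNetwork, genes: Iterable[int | str] | None = None) -> BooleanNetwork:
    """AND a constant wild-type companion into each listed gene's rule.

    For each gene ``A`` a new variable ``A.WT`` is appended with the self-copy
    rule (constant over time), and A's rule ``g_A`` becomes ``g_A ∧ A.WT``.
    With every companion ON the dynamics is unchanged; a companion that is OFF
    pins its gene OFF permanently, encoding a loss-of-function alteration.
    ``genes=None`` augments every variable (doubling the network size).
    """
    if genes is None:
        gene_idx = list(range(net.n))
    else:
        gene_idx = [net.index(g) if isinstance(g, str) else g for g in genes]
        if len(set(gene_idx)) != len(gene_idx):
            raise ValueError("a gene is listed twice in the augmentation set")
        for g in gene_idx:
            if not 0 <= g < net.n:
                raise ValueError(f"gene index {g} out of range")
    if not gene_idx:
        return net

    names = list(net.names)
    wt_of: dict[int, int] = {}
    for g in gene_idx:
        wt_of[g] = len(names)
        names.append(net.names[g] + WT_SUFFIX)

    rules: list[UpdateSpec] = []
    for i, rule in enumerate(net.rules):
        if i in wt_of:
            wt = wt_of[i]
            new_inputs = tuple(sorted(set(rule.inputs) | {wt}))
            old_pos = {inp: p for p, inp in enumerate(rule.inputs)}
            k_local = rule.k_by_local_mask()
            new_k = []
            for rho in canonical_order(len(new_inputs)):
                rho_global = [new_inputs[j] for j in members(rho)]
                old_local = 0
                for v in rho_global:
                    if v in old_pos:
                        old_local |= 1 << old_pos[v]
                out = k_local[old_local] if wt in rho_global else 0
                new_k.append(int(out) if rule.deterministic else float(out))
            rules.append(UpdateSpec(i, new_inputs, tuple(new_k)))
        else:
            rules.append(rule)
    for g in gene_idx:
        wt = wt_of[g]
        rules.append(UpdateSpec(wt, (wt,), (0, 1)))  # self-copy: constant in time

    meta = dict(net.meta)
    meta["wildtype_of"] = {net.names[g]: names[wt_of[g]] for g in gene_idx}
    return BooleanNetwork(tuple(names), tuple(rules), net.kind, meta)


def wildtype_pairs(net: BooleanNetwork) -> dict[int, int]:
    """Map gene index → wild-type companion index, inferred from names."""
    idx = {name: i for i, name in enumerate(net.names)}
    return {
        i: idx[name + WT_SUFFIX]
        for i, name in enumerate(net.names)
        if name + WT_SUFFIX in idx
    }


@dataclass(frozen=True)
class RateVector:
    """Per-variable update rates r_i ∈ [0, 1]; r_i = 1 is the deterministic limit."""

    r: tuple[float, ...]

    def __post_init__(self):
        for v in self.r:
            if not 0 <= v <= 1:
                raise ValueError(f"rate {v} outside [0, 1]")

    @classmethod
    def uniform(cls, n: int, value: float = 1.0) -> "RateVector":
        return cls((float(value),) * n)

    @classmethod
    def for_network(cls, net: BooleanNetwork, rates: "RateVector | Sequence[float] | dict | float") -> "RateVector":
        if isinstance(rates, RateVector):
            r = rates.r
        elif isinstance(rates, dict):
            r = tuple(float(rates.get(name, 1.0)) for name in net.names)
        elif isinstance(rates, (int, float)):
            r = (float(rates),) * net.n
        else:
            r = tuple(float(v) for v in rates)
        if len(r) != net.n:
            raise ValueError(f"expected {net.n} rates, got {len(r)}")
        return cls(r)


def attach_rates(net: BooleanNetwork, rates) -> BooleanNetwork:
    """Blend each rule with the identity: ``f'_i = (1−r_i)·x_i + r_i·f_i``.

    Returns a probabilistic network over inputs ``θ^[i] ∪ {i}`` whose
    likelihood table realises the blend; ``r_i = 1`` reproduces the original
    deterministic update and ``r_i = 0`` freezes variable ``i``.
    """
    if net.kind != DETERMINISTIC:
        raise ValueError("attach_rates expects a deterministic network")
    r = RateVector.for_network(net, rates).r
    rules: list[UpdateSpec] = []
    for i, rule in enumerate(net.rules):
        new_inputs = tuple(sorted(set(rule.inputs) | {i}))
        old_pos = {inp: p for p, inp in enumerate(rule.inputs)}
        k_local = rule.k_by_local_mask()
        new_k = []
        for rho in canonical_order(len(new_inputs)):
            rho_global = {new_inputs[j] for j in members(rho)}
            old_local = 0
            for v in rho_global:
                if v in old_pos:
                    old_local |= 1 << old_pos[v]
            self_on = 1.0 if i in rho_global else 0.0
            new_k.append((1.0 - r[i]) * self_on + r[i] * float(k_local[old_local]))
        rules.append(UpdateSpec(i, new_inputs, tuple(new_k)))
    meta = dict(net.meta)
    meta["rates"] = tuple(r)
    return BooleanNetwork(net.names, tuple(rules), PROBABILISTIC, meta)


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------

def _essential_inputs(inputs: tuple[int, ...], k_local: np.ndarray) -> bool:
    """True iff the output depends on every input (no ignorable input)."""
    n = len(inputs)
    idx = np.arange(1 << n)
    for j in range(n):
        if np.array_equal(k_local[idx], k_local[idx ^ (1 << j)]):
            return False
    return True


def generate_random_network(
    n_vars: int,
    in_degree: tuple[int, int] = (1, 4),
    seed: int | np.random.Generator = 0,
    allow_self_inputs: bool = True,
    allow_degenerate: bool = True,
    name_prefix: str = "n",
) -> BooleanNetwork:
    """Random network: in-degrees uniform on a range, fair-coin truth tables.

    Each variable draws its in-degree uniformly from ``in_degree`` (inclusive),
    picks that many distinct input variables, and fills its truth table with
    i.i.d. fair coin flips.  ``allow_self_inputs=False`` excludes a variable
    from its own input set; ``allow_degenerate=False`` redraws truth tables
    until every input is essential (the rule depends on each of its inputs).
    Fully reproducible from ``seed``.
    """
    lo, hi = in_degree
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if not (1 <= lo <= hi <= n_vars):
        raise ValueError(f"in-degree range {in_degree} invalid for {n_vars} variables")
    if not allow_self_inputs and hi > n_vars - 1:
        raise ValueError("in-degree range exceeds n_vars - 1 with self-inputs disallowed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    width = len(str(n_vars - 1))
    names = tuple(f"{name_prefix}{i:0{width}d}" for i in range(n_vars))
    rules = []
    for i in range(n_vars):
        d = int(rng.integers(lo, hi + 1))
        pool = np.arange(n_vars)
        if not allow_self_inputs:
            pool = pool[pool != i]
        inputs = tuple(sorted(int(v) for v in rng.choice(pool, size=d, replace=False)))
        while True:
            k = tuple(int(b) for b in rng.integers(0, 2, size=1 << d))
            if allow_degenerate:
                break
            k_local = UpdateSpec(i, inputs, k).k_by_local_mask()
            if _essential_inputs(inputs, k_local):
                break
        rules.append(UpdateSpec(i, inputs, k))
    meta = {
        "generator": "boolpop.generate_random_network",
        "in_degree": (lo, hi),
        "allow_self_inputs": allow_self_inputs,
        "allow_degenerate": allow_degenerate,
    }
    return BooleanNetwork(names, tuple(rules), DETERMINISTIC, meta)


def edge_count(net: BooleanNetwork) -> int:
    """Total number of input edges across all rules."""
    return sum(len(rule.inputs) for rule in net.rules)


def state_from_names(net: BooleanNetwork, on: Iterable[str]) -> int:
    """Bitmask state with the named variables ON."""
    return subset_of(net.index(name) for name in on)
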