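"""Closure of the product-basis update equations into a finite linear system.

Single-variable rules come from the subset-Möbius transform of the rule's
output vector (``f_i = k^[i] · T^{-1} · x^[i]``, computed without building
T^{-1}).  Multi-index rules are products of the members' single rules under
the idempotent reduction (discrete time), or the product rule of derivatives
(continuous time).  Starting from the subsets of interest Ω₀, a FIFO worklist
adds a rule for every subset referenced on any right-hand side until the
system closes; the result is a square linear operator F with
``x(t+1) = F·x(t)`` (discrete) or ``dx/dt = F·x`` (continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .expressions import LinearExpression, reduce_product
from .network import BooleanNetwork, DETERMINISTIC, RateVector
from .subsets import (
    EMPTY,
    CapExceededError,
    Subset,
    members,
    subset_mobius,
    subset_name,
)

DISCRETE = "discrete"
DIFFERENTIAL = "differential"

#: Default cap on the number of inputs of any single rule (2^n table size).
DEFAULT_INPUT_CAP = 20

#: Default cap on the number of tracked subsets |Ω| before closure aborts.
DEFAULT_OMEGA_CAP = 10**6


class ClosureExplosionError(RuntimeError):
    """Closure exceeded the configured |Ω| cap.

    Carries the size reached and a sample of the unsolved frontier so the
    caller can see where the blow-up is coming from.
    """

    def __init__(self, size: int, cap: int, frontier: list[str]):
        self.size = size
        self.cap = cap
        self.frontier = frontier
        preview = ", ".join(frontier[:8])
        super().__init__(
            f"closure reached |Omega| = {size} (cap {cap}); "
            f"unsolved frontier starts: {preview}"
        )


def single_rule(net: BooleanNetwork, i: int | str,
                cap: int = DEFAULT_INPUT_CAP) -> LinearExpression:
    """Linear update rule f_i = k^[i] · T^{-1} · x^[i] over subsets of θ^[i].

    The coefficient of ``x_κ`` is the subset-Möbius transform
    ``Σ_{α ⊆ κ} (−1)^{|κ|−|α|} k_α`` of the output vector, evaluated by the
    fast in-place transform — the 2^n matrix is never materialised.
    Coefficients are exact integers for deterministic rules.
    """
    if isinstance(i, str):
        i = net.index(i)
    rule = net.rules[i]
    n = len(rule.inputs)
    if n > cap:
        raise CapExceededError(
            f"rule for {net.names[i]} has {n} inputs (cap {cap})"
        )
    coeffs = subset_mobius(rule.k_by_local_mask())
    terms: dict[Subset, object] = {}
    for local_mask in range(1 << n):
        c = coeffs[local_mask]
        if c == 0:
            continue
        global_mask = 0
        for j in members(local_mask):
            global_mask |= 1 << rule.inputs[j]
        value = int(c) if rule.deterministic else float(c)
        terms[global_mask] = terms.get(global_mask, 0) + value
    return LinearExpression(terms)


def differential_rule(mask: Subset,
                      singles: Mapping[int, LinearExpression]) -> LinearExpression:
    """Continuous-time rule for a product variable via the product rule.

    ``d(x_{AB…})/dt = Σ_{i ∈ α} (Π_{j ∈ α∖i} x_j) · f_i``, idempotently
    reduced.  The empty subset has zero derivative.
    """
    if mask == EMPTY:
        return LinearExpression.zero()
    out = LinearExpression.zero()
    for i in members(mask):
        rest = mask & ~(1 << i)
        out = out + LinearExpression.variable(rest) * singles[i]
    return out


@dataclass
class ClosedSystem:
    """A closed set Ω of subsets with one linear update rule per member."""

    network: BooleanNetwork
    omega: list[Subset]
    rules: dict[Subset, LinearExpression]
    mode: str
    rates: tuple[float, ...] | None = None
    index: dict[Subset, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {mask: pos for pos, mask in enumerate(self.omega)}
        missing = [
            m for rule in self.rules.values() for m in rule.terms if m not in self.index
        ]
        if missing:
            raise ValueError(f"system is not closed: {len(missing)} unsolved subsets")

    @property
    def dimension(self) -> int:
        return len(self.omega)

    @property
    def exact(self) -> bool:
        """True when every rule coefficient is an exact integer."""
        return all(rule.is_exact for rule in self.rules.values())

    def subset_names(self) -> list[str]:
        return [subset_name(m, self.network.names) for m in self.omega]

    def serialize_equations(self) -> str:
        """One ``f_SUBSET = ±c x_SUBSET …`` line per rule, in Ω order."""
        names = self.network.names
        lines = [
            f"# boolpop closed system; mode={self.mode}; dimension={self.dimension}",
            f"# variables: {' '.join(names)}",
        ]
        for mask in self.omega:
            lhs = subset_name(mask, names)
            lines.append(f"f_{lhs} = {self.rules[mask].format(names)}")
        return "\n".join(lines) + "\n"

    def serialize_operator(self) -> str:
        """Coordinate triplets ``row-subset TAB column-subset TAB coefficient``."""
        names = self.network.names
        lines = ["row\tcol\tcoeff"]
        for mask in self.omega:
            row = subset_name(mask, names)
            for col_mask, coeff in self.rules[mask].sorted_terms():
                lines.append(f"{row}\t{subset_name(col_mask, names)}\t{coeff}")
        return "\n".join(lines) + "\n"


def _normalize_omega0(net: BooleanNetwork, omega0: Iterable) -> list[Subset]:
    out: list[Subset] = []
    seen: set[Subset] = set()
    for item in omega0:
        if isinstance(item, int):
            mask = item
        elif isinstance(item, str):
            from .subsets import parse_subset

            mask = parse_subset(item, net.names)
        else:
            mask = 0
            for v in item:
                mask |= 1 << (net.index(v) if isinstance(v, str) else v)
        if mask >> net.n:
            raise ValueError("subset references a variable outside the network")
        if mask not in seen:
            seen.add(mask)
            out.append(mask)
    if not out:
        raise ValueError("omega0 must be nonempty")
    return out


def close_system(
    net: BooleanNetwork,
    omega0: Iterable,
    mode: str = DISCRETE,
    rates=None,
    omega_cap: int = DEFAULT_OMEGA_CAP,
    input_cap: int = DEFAULT_INPUT_CAP,
) -> ClosedSystem:
    """Algorithmic closure: solve f_α for Ω₀ and every subset it drags in.

    Discrete mode multiplies cached single rules (``f_{ij…} = f_i·f_j·…``);
    differential mode applies the product rule of derivatives with
    single-variable rates ``f_i = r_i·(g_i − x_i)`` where ``g_i`` is the
    discrete update expression (``rates=None`` means all rates are 1, which
    keeps the algebra exact).  The empty subset always carries its trivial
    rule (``f_∅ = x_∅`` discrete, ``f_∅ = 0`` differential).  The worklist is
    FIFO and newly referenced subsets are enqueued in canonical order, so the
    Ω ordering — and therefore the operator layout — is reproducible.
    """
    if mode not in (DISCRETE, DIFFERENTIAL):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == DIFFERENTIAL and net.kind != DETERMINISTIC:
        raise ValueError("differential mode requires a deterministic logic network")

    rate_tuple: tuple[float, ...] | None = None
    if mode == DIFFERENTIAL and rates is not None:
        rate_tuple = RateVector.for_network(net, rates).r

    singles: dict[int, LinearExpression] = {}

    def get_single(i: int) -> LinearExpression:
        if i not in singles:
            g = single_rule(net, i, cap=input_cap)
            if mode == DIFFERENTIAL:
                g = g - LinearExpression.variable(1 << i)
                if rate_tuple is not None:
                    g = g.scale(rate_tuple[i])
            singles[i] = g
        return singles[i]

    omega: list[Subset] = _normalize_omega0(net, omega0)
    present = set(omega)
    if EMPTY not in present:
        omega.append(EMPTY)
        present.add(EMPTY)

    rules: dict[Subset, LinearExpression] = {}
    queue = deque(omega)
    while queue:
        mask = queue.popleft()
        if mask in rules:
            continue
        if mask == EMPTY:
            rule = (
                LinearExpression.variable(EMPTY)
                if mode == DISCRETE
                else LinearExpression.zero()
            )
        elif mask.bit_count() == 1:
            rule = get_single(mask.bit_length() - 1)
        elif mode == DISCRETE:
            rule = reduce_product([get_single(i) for i in members(mask)])
        else:
            rule = differential_rule(mask, {i: get_single(i) for i in members(mask)})
        rules[mask] = rule
        for ref in rule.subsets():
            if ref not in present:
                present.add(ref)
                omega.append(ref)
                queue.append(ref)
                if len(omega) > omega_cap:
                    frontier = [
                        subset_name(m, net.names)
                        for m in omega
                        if m not in rules
                    ]
                    raise ClosureExplosionError(len(omega), omega_cap, frontier)
    # Termination invariant of the worklist construction: every subset that
    # appears anywhere has been solved.
    assert set(omega) == set(rules), "closure terminated with unsolved subsets"
    return ClosedSystem(net, omega, rules, mode, rate_tuple)


@dataclass
class TransitionOperator:
    """The square operator F aligned to a closed system's Ω ordering.

    ``matrix`` is a float CSR matrix for fast iteration; when every
    coefficient is an exact integer an int64 twin is kept so that evolution
    from integer moment vectors stays exact.
    """

    system: ClosedSystem
    matrix: sp.csr_matrix
    matrix_int: sp.csr_matrix | None

    @property
    def dimension(self) -> int:
        return self.system.dimension

    @property
    def mode(self) -> str:
        return self.system.mode

    @property
    def exact(self) -> bool:
        return self.matrix_int is not None

    def row_terms(self, mask: Subset) -> list[tuple[Subset, object]]:
        return self.system.rules[mask].sorted_terms()


def assemble_operator(system: ClosedSystem) -> TransitionOperator:
    """Lay the closed system's rules out as a sparse square matrix."""
    dim = system.dimension
    rows, cols, vals = [], [], []
    for mask in system.omega:
        r = system.index[mask]
        for col_mask, coeff in system.rules[mask].terms.items():
            rows.append(r)
            cols.append(system.index[col_mask])
            vals.append(coeff)
    matrix = sp.csr_matrix(
        (np.asarray(vals, dtype=np.float64), (rows, cols)), shape=(dim, dim)
    )
    matrix_int = None
    if system.exact:
        matrix_int = sp.csr_matrix(
            (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(dim, dim)
        )
    return TransitionOperator(system, matrix, matrix_int)
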