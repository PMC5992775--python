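"""Linear expressions over product-basis variables.

Every update rule produced by the engine is a finite weighted sum
``Σ_α c_α · x_α`` over variable subsets.  For deterministic networks the
coefficients are exact Python integers; probabilistic and continuous-time
networks introduce floats.  Multiplication implements the idempotent
reduction ``x_β · x_γ = x_{β∪γ}`` (Boolean variables satisfy ``x^p = x``),
which is what keeps products of rules inside the linear span of the basis.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .subsets import Subset, canonical_key, subset_name

#: Coefficients with magnitude at or below this are treated as exact zeros
#: during float arithmetic cleanup.  Cancellations that are exact in the
#: algebra (as in products of deterministic rules) must produce true zeros so
#: that closure does not chase phantom subsets.
DROP_TOL = 1e-12


def _is_zero(c) -> bool:
    if isinstance(c, float):
        return abs(c) <= DROP_TOL
    return c == 0


class LinearExpression:
    """A finite weighted sum of product-basis variables.

    Immutable by convention: arithmetic returns new instances.  Terms are kept
    in a dict keyed by subset bitmask with zero coefficients pruned.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[Subset, object] | None = None):
        pruned: dict[Subset, object] = {}
        if terms:
            for mask, coeff in terms.items():
                if not _is_zero(coeff):
                    pruned[mask] = coeff
        self.terms = pruned

    # -- constructors -----------------------------------------------------
    @classmethod
    def zero(cls) -> "LinearExpression":
        return cls()

    @classmethod
    def variable(cls, mask: Subset, coeff=1) -> "LinearExpression":
        """The expression ``coeff · x_mask`` (``x_∅`` is the constant 1)."""
        return cls({mask: coeff})

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.terms)

    def __bool__(self) -> bool:
        return bool(self.terms)

    def __iter__(self):
        return iter(self.sorted_terms())

    def subsets(self) -> list[Subset]:
        """Referenced subsets in canonical (cardinality, lexicographic) order."""
        return sorted(self.terms, key=canonical_key)

    def sorted_terms(self) -> list[tuple[Subset, object]]:
        return [(m, self.terms[m]) for m in self.subsets()]

    @property
    def is_exact(self) -> bool:
        """True when every coefficient is an exact integer/rational."""
        return all(not isinstance(c, float) for c in self.terms.values())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "LinearExpression") -> "LinearExpression":
        if not isinstance(other, LinearExpression):
            return NotImplemented
        out = dict(self.terms)
        for mask, coeff in other.terms.items():
            out[mask] = out.get(mask, 0) + coeff
        return LinearExpression(out)

    def __sub__(self, other: "LinearExpression") -> "LinearExpression":
        if not isinstance(other, LinearExpression):
            return NotImplemented
        out = dict(self.terms)
        for mask, coeff in other.terms.items():
            out[mask] = out.get(mask, 0) - coeff
        return LinearExpression(out)

    def __neg__(self) -> "LinearExpression":
        return LinearExpression({m: -c for m, c in self.terms.items()})

    def scale(self, factor) -> "LinearExpression":
        if _is_zero(factor):
            return LinearExpression()
        return LinearExpression({m: factor * c for m, c in self.terms.items()})

    def __mul__(self, other):
        """Product with idempotent reduction, or scalar scaling.

        ``x_β · x_γ`` maps to ``x_{β∪γ}``; like terms merge; exact zeros drop.
        """
        if isinstance(other, LinearExpression):
            out: dict[Subset, object] = {}
            for m1, c1 in self.terms.items():
                for m2, c2 in other.terms.items():
                    mu = m1 | m2
                    out[mu] = out.get(mu, 0) + c1 * c2
            return LinearExpression(out)
        return self.scale(other)

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if not isinstance(other, LinearExpression):
            return NotImplemented
        return self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    # -- evaluation and rendering -----------------------------------------
    def evaluate(self, moments: Mapping[Subset, object]):
        """Evaluate against a map subset → value (⟨x_∅⟩ must be supplied too)."""
        total = 0
        for mask, coeff in self.terms.items():
            total = total + coeff * moments[mask]
        return total

    def format(self, names: Sequence[str]) -> str:
        """Render as ``+1 x_A -1 x_A.B`` style text (canonical term order)."""
        if not self.terms:
            return "0"
        parts = []
        for mask, coeff in self.sorted_terms():
            sign = "-" if _negative(coeff) else "+"
            mag = _format_number(abs(coeff) if not isinstance(coeff, complex) else coeff)
            parts.append(f"{sign}{mag} x_{subset_name(mask, names)}")
        return " ".join(parts)

    def __repr__(self) -> str:
        body = ", ".join(f"{m:#x}: {c}" for m, c in self.sorted_terms())
        return f"LinearExpression({{{body}}})"


def _negative(c) -> bool:
    try:
        return c < 0
    except TypeError:
        return False


def _format_number(c) -> str:
    if isinstance(c, float):
        return f"{c:.12g}"
    return str(c)


def reduce_product(factors: Iterable[LinearExpression]) -> LinearExpression:
    """Distribute a product of linear expressions and reduce idempotently.

    Implements the multi-index rule construction: the discrete update of
    ``x_{ij…}`` is the product ``f_i · f_j · …`` of the members' single rules,
    re-expressed as a linear combination via ``x_β · x_γ = x_{β∪γ}``.
    """
    factors = list(factors)
    if not factors:
        raise ValueError("reduce_product requires at least one factor")
    # Multiply smallest expressions first to keep intermediates compact.
    factors.sort(key=len)
    out = factors[0]
    for f in factors[1:]:
        out = out * f
    return out
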