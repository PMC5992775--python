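"""Variable subsets and the zeta/Möbius change of basis on the subset lattice.

A subset of model variables is represented throughout the package as a Python
integer bitmask: bit ``i`` is set iff variable ``i`` (in the network's fixed
global order) belongs to the subset.  Integers are hashable, compare by value,
take unions with ``|`` and subset tests with ``a & b == a``, and — because
Python integers are arbitrary precision — impose no limit on the number of
model variables.  The empty subset is ``0``.

The product basis attaches one variable ``x_α`` to every subset ``α``; the
state basis attaches one indicator ``b_κ`` to every full network state ``κ``.
The two are related by the zeta matrix of the subset lattice
(``T_{ακ} = 1`` iff ``α ⊆ κ``) whose inverse is the Möbius matrix with entries
``(−1)^{|κ|−|α|}`` on ``α ⊆ κ``.  Both are produced here, along with the
in-place fast transforms that avoid materialising the ``2^n`` matrices.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np

Subset = int
EMPTY: Subset = 0

#: Default cap on the number of variables in any explicit 2^n construction.
DEFAULT_CAP = 20

#: Printable name of the empty subset in serialized equations and tables.
EMPTY_NAME = "empty"

#: Separator used when joining variable names into a subset name ("A.C").
NAME_SEP = "."


class CapExceededError(ValueError):
    """An operation would build an object of size 2^n beyond the configured cap."""


def subset_of(indices: Iterable[int]) -> Subset:
    """Build a subset bitmask from an iterable of variable indices."""
    mask = 0
    for i in indices:
        if i < 0:
            raise ValueError(f"negative variable index {i}")
        mask |= 1 << i
    return mask


def members(mask: Subset) -> tuple[int, ...]:
    """Sorted tuple of variable indices in ``mask``."""
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


def size(mask: Subset) -> int:
    """Cardinality |α| of the subset."""
    return mask.bit_count()


def canonical_key(mask: Subset) -> tuple[int, tuple[int, ...]]:
    """Sort key ordering subsets by (cardinality, lexicographic on members)."""
    return (mask.bit_count(), members(mask))


def canonical_order(n: int) -> list[Subset]:
    """All subsets of an ``n``-element ground set in canonical enumeration order.

    The order is by cardinality, then lexicographically on the sorted member
    indices, matching the (∅, A, C, AC) listing convention used for truth-table
    output vectors and printed basis matrices.
    """
    return sorted(range(1 << n), key=canonical_key)


def subset_name(mask: Subset, names: Sequence[str]) -> str:
    """Dot-joined variable-name rendering of a subset; ``"empty"`` for ∅."""
    if mask == EMPTY:
        return EMPTY_NAME
    return NAME_SEP.join(names[i] for i in members(mask))


def parse_subset(text: str, names: Sequence[str]) -> Subset:
    """Inverse of :func:`subset_name`: parse a dot-joined subset name.

    Variable names may themselves contain dots (the wild-type convention is
    ``"gene.WT"``), so matching is greedy over the declared names rather than a
    plain split.
    """
    text = text.strip()
    if text in ("", EMPTY_NAME):
        return EMPTY
    index = {name: i for i, name in enumerate(names)}
    # Greedy longest-prefix matching over declared names.
    mask = 0
    pos = 0
    ordered = sorted(index, key=len, reverse=True)
    while pos < len(text):
        if text[pos] == NAME_SEP:
            pos += 1
            continue
        for name in ordered:
            end = pos + len(name)
            if text.startswith(name, pos) and (end == len(text) or text[end] == NAME_SEP):
                mask |= 1 << index[name]
                pos = end
                break
        else:
            raise ValueError(f"cannot match a declared variable at {text[pos:]!r}")
    return mask


class BasisMatrix(NamedTuple):
    """Explicit 2^n × 2^n change-of-basis matrix over subsets of an n-set.

    ``subsets`` lists the row/column labels in canonical enumeration order;
    ``values[a, k]`` is the matrix element projecting the basis vector of
    ``subsets[k]`` onto that of ``subsets[a]``.
    """

    n: int
    subsets: tuple[Subset, ...]
    values: np.ndarray


def _check_cap(n: int, cap: int) -> None:
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > cap:
        raise CapExceededError(
            f"refusing to build a 2^{n} x 2^{n} basis matrix (cap {cap}); "
            "raise the cap explicitly if this is intended"
        )


def change_of_basis(n: int, cap: int = DEFAULT_CAP) -> BasisMatrix:
    """Zeta matrix T^(n) converting state-basis vectors to product-basis vectors.

    Entry (α, κ) is 1 iff α ⊆ κ, 0 otherwise; upper triangular with unit
    diagonal under the canonical subset order, hence invertible.
    """
    _check_cap(n, cap)
    order = canonical_order(n)
    values = np.zeros((1 << n, 1 << n), dtype=np.int64)
    for a, alpha in enumerate(order):
        for k, kappa in enumerate(order):
            if alpha & kappa == alpha:
                values[a, k] = 1
    return BasisMatrix(n, tuple(order), values)


def invert_change_of_basis(n: int, cap: int = DEFAULT_CAP) -> BasisMatrix:
    """Möbius matrix (T^(n))^{-1}: entry (α, κ) = (−1)^{|κ|−|α|} on α ⊆ κ."""
    _check_cap(n, cap)
    order = canonical_order(n)
    values = np.zeros((1 << n, 1 << n), dtype=np.int64)
    for a, alpha in enumerate(order):
        for k, kappa in enumerate(order):
            if alpha & kappa == alpha:
                values[a, k] = -1 if (kappa.bit_count() - alpha.bit_count()) % 2 else 1
    return BasisMatrix(n, tuple(order), values)


def subset_mobius(values: np.ndarray) -> np.ndarray:
    """In-place-style subset Möbius transform over bitmask-indexed values.

    Given ``k`` indexed by bitmask over an n-set (length 2^n), returns ``c``
    with ``c[κ] = Σ_{α ⊆ κ} (−1)^{|κ|−|α|} k[α]`` — the coefficient vector of
    the linear expression ``k · T^{-1} · x`` without materialising T^{-1}.
    """
    c = np.array(values, copy=True)
    m = len(c)
    if m & (m - 1):
        raise ValueError("length must be a power of two")
    n = m.bit_length() - 1
    idx = np.arange(m)
    for b in range(n):
        hi = (idx & (1 << b)).astype(bool)
        c[hi] = c[hi] - c[idx[hi] ^ (1 << b)]
    return c


def superset_zeta(weights: np.ndarray) -> np.ndarray:
    """Superset sums over the lattice: ``z[α] = Σ_{κ ⊇ α} w[κ]``.

    Applied to a weight distribution over full network states this reads off
    every product-basis moment ⟨x_α⟩ at once.  Works on any numpy dtype,
    including ``object`` arrays of :class:`fractions.Fraction`.
    """
    z = np.array(weights, copy=True)
    m = len(z)
    if m & (m - 1):
        raise ValueError("length must be a power of two")
    n = m.bit_length() - 1
    idx = np.arange(m)
    for b in range(n):
        lo = ~(idx & (1 << b)).astype(bool)
        z[lo] = z[lo] + z[idx[lo] | (1 << b)]
    return z
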