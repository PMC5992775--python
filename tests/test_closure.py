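"""Closure of the product-basis equations and the transition operator."""

import numpy as np
import pytest

from boolpop import (
    assemble_operator,
    close_system,
    differential_rule,
    generate_random_network,
    single_rule,
)
from boolpop.closure import ClosureExplosionError
from boolpop.expressions import LinearExpression
from boolpop.montecarlo import simulate_individual
from boolpop.network import local_pattern
from boolpop.subsets import CapExceededError, members, subset_mobius

E = LinearExpression.variable
A, B, C = 1, 2, 4


class TestSingleRules:
    def test_worked_example_rules(self, example3):
        assert single_rule(example3, "A") == E(0) - E(B)
        assert single_rule(example3, "B") == E(A | C)
        assert single_rule(example3, "C") == E(A) + E(B) - E(A | B)

    def test_rules_are_exact_integers(self, example3):
        for name in example3.names:
            assert single_rule(example3, name).is_exact

    def test_input_cap_enforced(self):
        net = generate_random_network(6, (3, 3), seed=0)
        with pytest.raises(CapExceededError):
            single_rule(net, 0, cap=2)

    @pytest.mark.parametrize("trial", range(10))
    def test_rule_evaluates_to_truth_table_on_states(self, trial):
        # f_i evaluated on the product-basis image of a state must equal the
        # rule output for that state, for every state.
        net = generate_random_network(7, (1, 4), seed=400 + trial)
        for i, rule in enumerate(net.rules):
            expr = single_rule(net, i)
            k_local = rule.k_by_local_mask()
            for state in range(1 << net.n):
                value = sum(c for m, c in expr.terms.items() if m & state == m)
                assert value == k_local[local_pattern(state, rule.inputs)]


class TestClosure:
    def test_worked_example_closure(self, example3):
        system = close_system(example3, ["A"])
        want = {
            A: E(0) - E(B),
            0: E(0),
            B: E(A | C),
            A | C: E(A) - E(A | B),
            A | B: E(A | C) - E(A | B | C),
            A | B | C: E(A | C) - E(A | B | C),
        }
        assert set(system.omega) == set(want)
        assert system.rules == want
        assert system.dimension == 6

    def test_omega_order_is_reproducible_fifo(self, example3):
        system = close_system(example3, ["A"])
        assert system.omega == [A, 0, B, A | C, A | B, A | B | C]

    def test_empty_omega0_only(self, example3):
        system = close_system(example3, [0])
        assert system.omega == [0]
        assert system.rules[0] == E(0)

    def test_omega0_accepts_names_and_masks(self, example3):
        by_name = close_system(example3, ["A.B"])
        by_mask = close_system(example3, [A | B])
        assert by_name.omega == by_mask.omega

    def test_closure_cap_raises_informative_error(self):
        net = generate_random_network(10, (3, 4), seed=1)
        with pytest.raises(ClosureExplosionError) as exc:
            close_system(net, [1 << i for i in range(10)], omega_cap=20)
        assert exc.value.size > 20
        assert exc.value.frontier

    @pytest.mark.parametrize("trial", range(8))
    def test_closure_matches_independent_fixpoint(self, trial):
        """Worklist closure equals a brute-force fixpoint that derives every
        multi-index rule from scratch via a joint truth table (no products)."""
        net = generate_random_network(10, (1, 3), seed=500 + trial)
        system = close_system(net, [1 << i for i in range(net.n)])
        oracle_rules = _fixpoint_via_joint_tables(net, [1 << i for i in range(net.n)])
        assert set(system.omega) == set(oracle_rules)
        for mask, rule in oracle_rules.items():
            assert system.rules[mask] == rule


def _joint_rule(net, mask):
    """Independent derivation of f_α: Möbius transform of the joint truth
    table of ∧_{i∈α} f_i over the union of the members' input sets."""
    if mask == 0:
        return E(0)
    union = 0
    for i in members(mask):
        for j in net.rules[i].inputs:
            union |= 1 << j
    inputs = members(union)
    n = len(inputs)
    tables = {i: net.rules[i].k_by_local_mask() for i in members(mask)}
    k = np.zeros(1 << n, dtype=np.int64)
    for pat in range(1 << n):
        state = 0
        for pos, var in enumerate(inputs):
            if pat >> pos & 1:
                state |= 1 << var
        out = 1
        for i in members(mask):
            out &= int(tables[i][local_pattern(state, net.rules[i].inputs)])
        k[pat] = out
    coeffs = subset_mobius(k)
    terms = {}
    for local in range(1 << n):
        if coeffs[local]:
            g = 0
            for pos in members(local):
                g |= 1 << inputs[pos]
            terms[g] = terms.get(g, 0) + int(coeffs[local])
    return LinearExpression(terms)


def _fixpoint_via_joint_tables(net, omega0):
    rules = {}
    pending = list(omega0) + [0]
    while pending:
        mask = pending.pop()
        if mask in rules:
            continue
        rules[mask] = _joint_rule(net, mask)
        for ref in rules[mask].terms:
            if ref not in rules:
                pending.append(ref)
    return rules


class TestDifferentialRules:
    def test_pair_uses_product_rule(self, example3):
        singles = {
            0: single_rule(example3, "A") - E(A),
            1: single_rule(example3, "B") - E(B),
        }
        out = differential_rule(A | B, singles)
        expected = E(B) * singles[0] + E(A) * singles[1]
        assert out == expected

    def test_empty_subset_has_zero_derivative(self):
        assert differential_rule(0, {}) == LinearExpression.zero()

    def test_singleton_passes_through(self, example3):
        f = single_rule(example3, "A") - E(A)
        assert differential_rule(A, {0: f}) == f

    def test_differential_closure_contains_zero_rule_for_empty(self, example3):
        system = close_system(example3, ["A"], mode="differential")
        assert system.rules[0] == LinearExpression.zero()

    def test_differential_mode_rejects_probabilistic(self, example3):
        from boolpop import attach_rates

        with pytest.raises(ValueError, match="deterministic"):
            close_system(attach_rates(example3, 0.5), ["A"], mode="differential")


class TestOperator:
    def test_example_operator_rows(self, example3):
        system = close_system(example3, ["A"])
        op = assemble_operator(system)
        assert op.dimension == 6
        assert op.exact
        dense = op.matrix_int.toarray()
        empty_row = dense[system.index[0]]
        unit = np.zeros(6, dtype=np.int64)
        unit[system.index[0]] = 1
        assert np.array_equal(empty_row, unit)
        row_ab = dense[system.index[A | B]]
        assert row_ab[system.index[A | C]] == 1
        assert row_ab[system.index[A | B | C]] == -1
        assert row_ab.sum() == 0

    def test_operator_reproduces_boolean_update_on_all_states(self, example3):
        system = close_system(example3, ["A"])
        op = assemble_operator(system)
        for state in range(8):
            x = np.array([1 if m & state == m else 0 for m in system.omega], dtype=np.int64)
            nxt_state = simulate_individual(example3, state, 1)[1]
            expected = np.array(
                [1 if m & nxt_state == m else 0 for m in system.omega], dtype=np.int64
            )
            assert np.array_equal(op.matrix_int @ x, expected)

    def test_serializations_list_every_rule(self, example3):
        system = close_system(example3, ["A"])
        eqs = system.serialize_equations()
        assert "f_A = +1 x_empty -1 x_B" in eqs
        assert "f_A.B.C = +1 x_A.C -1 x_A.B.C" in eqs
        coo = system.serialize_operator()
        assert "A.B\tA.C\t1" in coo
        assert len(coo.strip().splitlines()) == 1 + sum(
            len(r) for r in system.rules.values()
        )


@pytest.mark.parametrize("trial", range(5))
def test_deterministic_closure_keeps_booleans_boolean(trial):
    """Applying F to the product-basis image of any single state yields the
    image of the successor state: individuals stay Boolean."""
    net = generate_random_network(8, (1, 4), seed=600 + trial)
    system = close_system(net, [1 << i for i in range(net.n)])
    op = assemble_operator(system)
    rng = np.random.default_rng(trial)
    for state in rng.integers(0, 1 << net.n, size=10):
        x = np.array([1 if m & state == m else 0 for m in system.omega], dtype=np.int64)
        out = op.matrix_int @ x
        assert set(np.unique(out)).issubset({0, 1})
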