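"""Population moments: construction, discrete evolution, queries, invariants."""

from fractions import Fraction

import numpy as np
import pytest

from boolpop import (
    assemble_operator,
    augment_wildtype,
    close_system,
    generate_random_network,
    initial_moments,
)
from boolpop.population import PopulationSpec, evolve_discrete
from boolpop.subsets import size as subset_size


@pytest.fixture(scope="module")
def example_system(request):
    net = request.getfixturevalue("example3")
    system = close_system(net, ["A"])
    return system, assemble_operator(system)


class TestInitialMoments:
    def test_uniform_moments_are_half_powers(self, example_system):
        system, _ = example_system
        x0 = initial_moments(PopulationSpec.uniform(), system)
        for mask, value in zip(system.omega, x0):
            assert value == 0.5 ** subset_size(mask)

    def test_single_state_gives_indicator(self, example_system):
        system, _ = example_system
        x0 = initial_moments(PopulationSpec.single_state(0b001), system)
        by_mask = dict(zip(system.omega, x0))
        assert by_mask[0b001] == 1.0   # ⟨x_A⟩
        assert by_mask[0b010] == 0.0   # ⟨x_B⟩
        assert by_mask[0] == 1.0       # ⟨x_∅⟩

    def test_anticorrelated_mixture_has_zero_cooccurrence(self, example3):
        system = close_system(example3, ["A", "B", "A.B"])
        spec = PopulationSpec.explicit([0b001, 0b010], [0.5, 0.5])
        x0 = dict(zip(system.omega, initial_moments(spec, system)))
        assert x0[0b001] == 0.5 and x0[0b010] == 0.5
        assert x0[0b011] == 0.0

    def test_explicit_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PopulationSpec.explicit([0b01, 0b10], [0.6, 0.5])

    def test_explicit_state_outside_network_errors(self, example_system):
        system, _ = example_system
        spec = PopulationSpec.single_state(1 << 5)
        with pytest.raises(ValueError, match="outside"):
            initial_moments(spec, system)

    def test_knockout_factor_model(self):
        net = generate_random_network(4, (1, 2), seed=8, name_prefix="g")
        aug = augment_wildtype(net)
        gene = aug.index("g0")
        wt = aug.index("g0.WT")
        system = close_system(
            aug, [1 << gene, 1 << wt, (1 << gene) | (1 << wt)]
        )
        mu = 1e-4
        x0 = dict(zip(system.omega, initial_moments(PopulationSpec.knockout(mu), system)))
        assert x0[1 << wt] == pytest.approx(1 - mu, abs=1e-15)
        assert x0[1 << gene] == pytest.approx(0.5 * (1 - mu), abs=1e-15)
        # gene ON already implies companion ON: identical moment
        assert x0[(1 << gene) | (1 << wt)] == x0[1 << gene]

    def test_knockout_requires_augmented_network(self, example_system):
        system, _ = example_system
        with pytest.raises(ValueError, match="wild-type"):
            initial_moments(PopulationSpec.knockout(1e-4), system)

    def test_exact_moments_are_rationals(self, example_system):
        system, _ = example_system
        x0 = initial_moments(PopulationSpec.uniform(), system, exact=True)
        assert all(isinstance(v, Fraction) for v in x0)


class TestDiscreteEvolution:
    def test_zero_steps_returns_initial_vector(self, example_system):
        system, op = example_system
        x0 = initial_moments(PopulationSpec.uniform(), system)
        ts = evolve_discrete(op, x0, 0)
        assert len(ts.times) == 1
        assert np.array_equal(ts.values[0], x0)

    def test_uniform_example_trajectory(self, example_system):
        # enumeration over all 8 states gives ⟨x_A⟩ = 0.5, 0.5, 0.75 at t=0,1,2
        system, op = example_system
        x0 = initial_moments(PopulationSpec.uniform(), system)
        ts = evolve_discrete(op, x0, 2)
        assert ts.query("A")[0] == 0.5
        assert ts.query("A")[1] == 0.5
        assert ts.query("A")[2] == 0.75

    def test_single_state_trajectory_is_boolean_and_periodic(self, example_system):
        system, op = example_system
        x0 = initial_moments(PopulationSpec.single_state(0b001), system, exact=True)
        ts = evolve_discrete(op, x0, 10)
        assert set(np.unique(np.asarray(ts.values, dtype=object))) <= {
            Fraction(0), Fraction(1)
        }
        # the Example-1 state {A} lies on a period-5 cycle
        assert np.array_equal(ts.values[0], ts.values[5])
        assert np.array_equal(ts.values[5], ts.values[10])

    def test_exact_rational_evolution_matches_float(self, example_system):
        system, op = example_system
        spec = PopulationSpec.uniform()
        exact = evolve_discrete(op, initial_moments(spec, system, exact=True), 20)
        approx = evolve_discrete(op, initial_moments(spec, system), 20)
        assert np.allclose(np.asarray(exact.values, dtype=float), approx.values)

    def test_dimension_mismatch_errors(self, example_system):
        _, op = example_system
        with pytest.raises(ValueError, match="length"):
            evolve_discrete(op, np.zeros(3), 1)

    def test_conservation_of_empty_moment(self, example_system):
        system, op = example_system
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 30)
        assert np.allclose(ts.query("empty"), 1.0)


class TestInvariants:
    @pytest.mark.parametrize("trial", range(5))
    def test_superposition_of_subpopulations(self, trial):
        """Evolving a weighted mixture equals the weighted sum of separately
        evolved subpopulations — exactly, in rational arithmetic."""
        net = generate_random_network(8, (1, 3), seed=700 + trial)
        system = close_system(net, [1 << i for i in range(net.n)])
        op = assemble_operator(system)
        rng = np.random.default_rng(trial)
        states = rng.integers(0, 1 << net.n, size=4)
        weights = [Fraction(1, 4)] * 4
        mixture = PopulationSpec.explicit([int(s) for s in states], weights)
        mixed = evolve_discrete(
            op, initial_moments(mixture, system, exact=True), 15
        ).values
        parts = [
            evolve_discrete(
                op,
                initial_moments(PopulationSpec.single_state(int(s)), system, exact=True),
                15,
            ).values
            for s in states
        ]
        recombined = sum(w * p for w, p in zip(weights, parts))
        assert np.array_equal(mixed, recombined)

    @pytest.mark.parametrize("trial", range(5))
    def test_subset_monotonicity_of_moments(self, trial):
        # α ⊆ β implies ⟨x_β⟩ ≤ ⟨x_α⟩ at every time for a valid population
        net = generate_random_network(7, (1, 3), seed=800 + trial)
        system = close_system(net, [1 << i for i in range(net.n)])
        op = assemble_operator(system)
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 20)
        by_mask = {m: ts.query(m) for m in system.omega}
        for alpha in system.omega:
            for beta in system.omega:
                if alpha != beta and alpha & beta == alpha:
                    assert np.all(by_mask[beta] <= by_mask[alpha] + 1e-12)


class TestTimeSeries:
    def test_untracked_subset_raises_with_guidance(self, example_system):
        system, op = example_system
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 2)
        with pytest.raises(KeyError, match="omega0"):
            ts.query("B.C")

    def test_query_by_names_and_iterables(self, example_system):
        system, op = example_system
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 2)
        assert np.array_equal(ts.query("A.C"), ts.query(["A", "C"]))
        assert np.array_equal(ts.query("A.C"), ts.query(0b101))

    def test_tidy_and_wide_round_trip(self, example_system, tmp_path):
        system, op = example_system
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 3)
        ts.provenance = {"seed": 1}
        tidy = ts.to_tidy()
        assert set(tidy.columns) == {"time", "subset", "value"}
        assert len(tidy) == 4 * system.dimension
        wide = ts.to_wide()
        assert list(wide.columns)[0] == "time"
        out = tmp_path / "ts.tsv"
        ts.write_tsv(out)
        text = out.read_text()
        assert text.startswith("# seed: 1")

    def test_necessity_difference_series(self, ladder6):
        # ⟨OA∧OB⟩ − ⟨OA∧OB∧INH⟩ isolates co-activation without the inhibitor
        system = close_system(ladder6, ["OA.OB", "OA.OB.INH"])
        op = assemble_operator(system)
        ts = evolve_discrete(op, initial_moments(PopulationSpec.uniform(), system), 5)
        diff = ts.query("OA.OB") - ts.query("OA.OB.INH")
        assert np.all(diff >= -1e-12)
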