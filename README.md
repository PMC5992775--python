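# boolpop

Exact population-level simulation of heterogeneous Boolean-network
populations, without simulating subpopulations one by one.

## The problem

Boolean network models describe a cell as a vector of ON/OFF variables
(genes, signalling nodes) updated by logic rules. Many biological questions —
the emergence of rare cancerous clones, immune activation, the effect of
loss-of-function mutations spread across a population — concern *populations*
of such cells that are heterogeneous in state and even in wiring. Averaging
Monte Carlo runs over individuals resolves common behaviour but is blind to
subpopulations at frequencies like 10⁻¹², and enumerating subpopulations is
hopeless when there are ~10²⁰ of them.

`boolpop` instead simulates the population *moments* directly. For every
subset α of model variables there is a product-basis variable

    x_α = ∏_{i∈α} B_i        (x_∅ = 1),

whose population average ⟨x_α⟩ is the fraction of individuals with all
variables of α simultaneously ON. The package derives, for any set of
subsets of interest Ω₀, a **closed linear system**

    x(t+1) = F · x(t)        (or dx/dt = F·x in continuous time)

by combining three exact ingredients:

1. **Change of basis.** The zeta matrix of the subset lattice
   (T_{ακ} = 1 iff α ⊆ κ) converts state indicators into product variables;
   its inverse is the Möbius matrix with entries (−1)^{|κ|−|α|}.
2. **Single-variable rules.** Each rule's truth-table output vector k^[i]
   yields the linear update f_i = k^[i]·T⁻¹·x^[i], computed with the fast
   subset-Möbius transform (the 2ⁿ matrix is never built).
3. **Idempotent products.** Because Boolean variables satisfy x² = x,
   products of rules reduce linearly: x_β·x_γ = x_{β∪γ}. Multi-index rules
   are products of single rules (discrete time) or follow the product rule
   of derivatives (continuous time), and a worklist closes the system.

Because F is linear and was derived for an individual, the *same* operator
evolves any weighted mixture of individuals (superposition) — arbitrary
heterogeneity is free, and results are exact with no sampling error.
Probabilistic networks (per-variable update likelihoods, including
rate-blended rules f'_i = (1−r_i)x_i + r_i f_i and asynchronous updating in
the small-time-step limit) are covered in the large-population limit, and
continuous-time networks via Markov jump dynamics. Augmenting each gene A
with a constant wild-type companion A.WT (rule A ← g_A ∧ A.WT) extends the
same machinery to *mutationally* heterogeneous populations: a knockout rate
μ per gene defines a mixture over all loss-of-function profiles whose
moments factor per gene and never require enumerating profiles.

## Worked example

The bundled 3-node network (A ← !B, B ← A∧C, C ← A∨B):

```python
from boolpop import close_system, assemble_operator, initial_moments, evolve_discrete
from boolpop.examples import example_network
from boolpop.population import PopulationSpec

net = example_network()
system = close_system(net, ["A"])          # track ⟨x_A⟩
print(system.serialize_equations())
op = assemble_operator(system)
x0 = initial_moments(PopulationSpec.uniform(), system)
ts = evolve_discrete(op, x0, 2)
print(ts.query("A"))
```

prints the closed six-equation system

```
f_A = +1 x_empty -1 x_B
f_empty = +1 x_empty
f_B = +1 x_A.C
f_A.C = +1 x_A -1 x_A.B
f_A.B = +1 x_A.C -1 x_A.B.C
f_A.B.C = +1 x_A.C -1 x_A.B.C
```

and the series `[0.5 0.5 0.75]`: starting from the uniform mixture of all
8 states, half the population has A ON at t = 0 and t = 1, three quarters at
t = 2 — exactly the average over all 8 trajectories, obtained from a 6×6
integer matrix instead.

The same flow from the shell:

```bash
boolpop build  example3.bnet -t A -o example        # writes example.eqs.txt / example.op.tsv
boolpop simulate example3.bnet -t A --steps 50 -o ts.tsv
boolpop randomnet -N 10 --seed 1 -o rand.bnet
boolpop validate --kind deterministic --n-networks 20 --seed 1
```

Networks are plain-text rules files (`targets, factors` lines with
`!`, `&`, `|`, parentheses, constants `0`/`1`; or
`table target, inputs, k-values` lines for explicit/probabilistic truth
tables — see `boolpop/data/*.bnet`). Population specs are small YAML files
(`kind: uniform | marginals | explicit | knockout`). Per-variable rates are
two-column TSV. A user-transcribed network of any published model (e.g. a
T-cell receptor logic table) drops into the same commands; none is bundled
because those tables belong to their original publications.

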