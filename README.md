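# marrowsim

A deterministic cellular-automaton model of bone-marrow homeostasis.

Hematopoietic stem cells (HSCs) maintain the blood system: a single stem
cell can repopulate an entire marrow, yet the marrow also keeps a steady
output of differentiated cells (RBCs, WBCs, platelets) and holds a large
reserve of quiescent stem cells. `marrowsim` implements a fully
deterministic agent-based model of this system for researchers studying
stem-cell niche dynamics: cells live on the vertices of a connected,
locally finite graph — here a 2-D lattice with Moore (8-neighbor)
connectivity — and change type synchronously according to local rules,
with no random element anywhere in the dynamics.

## The model

Each lattice site holds one of four states:

| state | tuple | meaning |
|---|---|---|
| `S` | (S, d, τ, p) | stem cell: proliferation direction d ∈ 0..7, cycle counter τ ≤ Ψ, renewal count p ≤ Δ |
| `T` | (T, g, τ) | transitive (transit-amplifying) cell: generation g ∈ 1..M, cumulative counter τ ≤ gΘ |
| `D` | (D, τ) | differentiated cell: maturity counter τ ≤ Φ |
| `E` | (E) | empty space: no counters, no computation |

One rule per type, subrules in strict order so exactly one fires per cell
per step:

1. **Stem** (maturity Ψ, renewal budget Δ): at τ = Ψ it dies if p = Δ
   (apoptosis); converts to `T` if every existing neighbor is a stem cell
   (saturated microenvironment); otherwise proliferates into the first
   empty neighbor found scanning directions round-robin clockwise from d
   (daughter and parent both get renewed biological time, the parent's
   direction advances); otherwise goes quiescent, retaining its state.
   Below Ψ the counter ticks.
2. **Transitive** (per-generation maturity Θ, M generations, distance
   multiple η): with no stem cell within the ball B(v, gη) it
   dedifferentiates back into a fresh stem cell; at τ = gΘ it advances a
   generation (counter cumulative) or, from generation M, becomes `D`;
   otherwise the counter ticks.
3. **Differentiated** (maturity Φ): at τ = Φ it emigrates to the blood
   stream, leaving empty space; otherwise the counter ticks.
4. **Empty** space never changes by itself.

Simultaneous proliferation claims on one empty site are resolved
deterministically by row-major priority with clockwise re-scan, so
identical inputs always yield bit-identical trajectories.

The package also ships machine checkers for the model's homeostasis
guarantees — single-stem repopulation within Φ + ρμΨ steps, stem
persistence in every radius-Mη ball, a long-run stem-density floor, and a
differentiated-supply bound — plus classification of death, dying-out and
resonant states and exact cycle detection.

## Worked example

```python
import marrowsim as ms

params = ms.Params(psi=7, theta=2, phi=3, delta=100, m=3, eta=2,
                   width=31, height=31)
state = ms.single_center_stem(params)   # one HSC in an empty marrow
for t in range(1, 501):
    state, report = ms.step(state, params)
    if t in (20, 100, 500):
        print(t, report.n_stem, round(ms.quiescent_fraction(report, state), 2))
```

prints

```
20 4 0.0
100 216 44.44
500 732 60.38
```

— at step 20 the four stem cells are all still expanding (0% quiescent);
by step 100 the colony of 216 stem cells has filled enough of the lattice
that 44.44% of them are mature but locked in place; by step 500 the marrow
has reached its homeostatic plateau with 732 stem cells, ~60% of them
quiescent, while transitive and differentiated cells churn in the gaps and
a steady stream of matured cells leaves for the blood.

The same engine is scriptable from the shell:

```sh
marrowsim run    --config run.yaml          # time series + snapshots
marrowsim sweep  --config run.yaml --param phi --values 2,4,8,16 --out sweep.csv
marrowsim verify --config run.yaml          # check the homeostasis bounds
marrowsim render --snapshot out/final      # print the S/T/D/. grid
```

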