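"""Initial-condition builders and mid-run perturbations.

The model consumes no external biological data: every simulation starts
from one of the constructions here.  All builders are pure — the same
arguments always produce bit-identical states — and randomness enters only
through explicit integer seeds (``random_mixture``, ``ablate_stems``).

Shipped scenarios:

* ``single_center_stem`` — one fresh stem cell at the lattice center, the
  single-HSC repopulation experiment.
* ``even_fraction_stem`` — a deterministic stride sublattice realizing a
  requested stem fraction ("evenly distributed" seeding).
* ``all_stem_synchronized`` — every site a stem cell with identical
  counters; the construction behind the death and resonant states.
* ``random_mixture`` — a seeded random lattice of all four cell types with
  valid random counters, for robustness and oracle-equivalence testing.
* ``ablate_stems`` — a seeded random removal of a fraction of stem cells,
  modeling severe perturbation (radiation / organ damage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .automaton import (
    Differentiated,
    MarrowState,
    Params,
    S_CODE,
    Stem,
    Transitive,
)
from .grid import Vertex

__all__ = [
    "ScenarioSpec",
    "blank",
    "single_center_stem",
    "even_fraction_stem",
    "all_stem_synchronized",
    "random_mixture",
    "ablate_stems",
    "build",
]


#: Reference simulation conditions for the package's worked examples and
#: acceptance runs.  The original experimental settings behind the published
#: quiescence trajectories are not recoverable, so this is a synthetic
#: stand-in: a calibration chosen once so that a single central stem cell on
#: a bounded 31×31 lattice reproduces the reported quiescence dynamics
#: (0% at step 20, a rise through ~44% at step 100, and a plateau near
#: 59–61% from step 200 on).  See docs/methods.md for how it was fixed.
REFERENCE_PARAMS = Params(
    psi=7, theta=2, phi=3, delta=100, m=3, eta=2,
    width=31, height=31, topology="bounded",
)


def blank(params: Params) -> MarrowState:
    """The all-empty lattice at t=0 (the death state)."""
    return MarrowState(params.grid, t=0)


def single_center_stem(params: Params) -> MarrowState:
    """One Stem(d=0, τ=0, p=0) at (⌊height/2⌋, ⌊width/2⌋), rest empty.

    On even-sided grids the floor convention picks the lower-right of the
    four central sites.
    """
    state = blank(params)
    center = Vertex(params.height // 2, params.width // 2)
    state.set(center, Stem())
    return state


def even_fraction_stem(params: Params, fraction: float) -> MarrowState:
    """round(fraction·|V|) fresh stems on an evenly spaced sublattice.

    Placement is deterministic: stems go on the stride-⌊√(1/fraction)⌋
    sublattice in row-major order; if that sublattice is too small to hold
    the requested count, the remainder fills the other sites row-major.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    state = blank(params)
    n = round(fraction * params.grid.n_vertices)
    if n == 0:
        return state
    stride = max(1, math.floor(math.sqrt(1.0 / fraction)))
    chosen: list[Vertex] = [
        Vertex(r, c)
        for r in range(0, params.height, stride)
        for c in range(0, params.width, stride)
    ]
    if len(chosen) < n:
        taken = set(chosen)
        for v in params.grid.vertices():
            if len(chosen) >= n:
                break
            if v not in taken:
                chosen.append(v)
    for v in chosen[:n]:
        state.set(v, Stem())
    return state


def all_stem_synchronized(params: Params, tau: int, p: int) -> MarrowState:
    """Every vertex Stem(d=0, tau, p) — the synchronized-marrow fixture."""
    if not 0 <= tau <= params.psi:
        raise ValueError("tau must lie in [0, psi]")
    if not 0 <= p <= params.delta:
        raise ValueError("p must lie in [0, delta]")
    state = blank(params)
    state.kind[:] = S_CODE
    state.tau[:] = tau
    state.p[:] = p
    return state


def random_mixture(
    params: Params,
    seed: int,
    proportions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> MarrowState:
    """Seeded random lattice of (E, S, T, D) with valid random counters."""
    if len(proportions) != 4 or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must be 4 ratios summing to 1")
    rng = np.random.default_rng(seed)
    state = blank(params)
    for v in params.grid.vertices():
        k = int(rng.choice(4, p=proportions))
        if k == 1:
            state.set(
                v,
                Stem(
                    d=int(rng.integers(0, 8)),
                    tau=int(rng.integers(0, params.psi + 1)),
                    p=int(rng.integers(0, params.delta + 1)),
                ),
            )
        elif k == 2:
            g = int(rng.integers(1, params.m + 1))
            state.set(v, Transitive(g=g, tau=int(rng.integers(0, g * params.theta + 1))))
        elif k == 3:
            state.set(v, Differentiated(tau=int(rng.integers(0, params.phi + 1))))
    return state


def ablate_stems(state: MarrowState, fraction: float, seed: int) -> MarrowState:
    """Remove a seeded-pseudorandom fraction of the stem cells.

    round(fraction·#stems) stem sites become empty; everything else is
    untouched.  Same seed, same state → same ablation.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = state.copy()
    rows, cols = np.nonzero(state.kind == S_CODE)
    n_stems = len(rows)
    n_kill = round(fraction * n_stems)
    if n_kill == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_stems, size=n_kill, replace=False)
    for i in idx:
        r, c = int(rows[i]), int(cols[i])
        out.kind[r, c] = 0
        out.d[r, c] = out.tau[r, c] = out.g[r, c] = out.p[r, c] = 0
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of an initial condition (config-file facing)."""

    kind: str = "single_center_stem"
    fraction: float = 0.0
    seed: int | None = None
    sync_tau: int = 0
    sync_p: int = 0

    KINDS = (
        "single_center_stem",
        "even_fraction_stem",
        "random_mixture",
        "all_stem_synchronized",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.kind == "random_mixture" and self.seed is None:
            raise ValueError("random_mixture requires a seed")


def build(spec: ScenarioSpec, params: Params) -> MarrowState:
    """Construct the initial MarrowState described by ``spec``."""
    if spec.kind == "single_center_stem":
        return single_center_stem(params)
    if spec.kind == "even_fraction_stem":
        return even_fraction_stem(params, spec.fraction)
    if spec.kind == "random_mixture":
        assert spec.seed is not None
        return random_mixture(params, spec.seed)
    if spec.kind == "all_stem_synchronized":
        return all_stem_synchronized(params, spec.sync_tau, spec.sync_p)
    raise ValueError(f"unknown scenario kind {spec.kind!r}")
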