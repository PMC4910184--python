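"""Closed-form homeostasis bounds and trajectory verifiers.

The model's headline guarantees are theorems about every trajectory, not
statistics over replicates.  This module states the bounds as exact
arithmetic and provides machine checkers that scan recorded trajectories
for counterexamples:

* occupation bound — starting from a stem cell at u, any vertex v first
  hosts a stem cell within Φ + ρ(u, v)·μ·Ψ steps (single-stem
  repopulation);
* stem persistence — once v has hosted a stem cell, every ball B(v, Mη)
  contains a stem cell at time t or t+1, for all later t (stems never
  become too scattered);
* density bound — the long-run stem density of such a ball is at least
  (μ − 1)/(μ^{Mη} − 1);
* supply bound — every ball of radius 2Mη around a stem-occupied vertex
  emits at least one matured differentiated cell within
  (μ + 1)Ψ + MΘ + 1 + Φ steps, outside resonant states.

The persistence and supply guarantees presume the renewal budget Δ is not
exhausted, so the checkers confine themselves to the segment of the run
before the first apoptosis event; resonant configurations are likewise
excluded, mirroring the scope of the statements themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .automaton import MarrowState, Params, S_CODE, Trajectory
from .grid import Vertex, distance
from .metrics import classify

__all__ = [
    "BoundReport",
    "occupation_bound",
    "density_bound",
    "supply_bound",
    "first_occupation_times",
    "verify_lemma1",
    "verify_lemma2",
    "verify_lemma2_all",
    "verify_lemma3",
    "verify_lemma5",
    "verify_all",
]


@dataclass(frozen=True)
class BoundReport:
    """Outcome of one bound check against a recorded trajectory."""

    bound_name: str
    bound_value: float
    observed_value: float
    satisfied: bool
    witness: tuple[Vertex, int] | None = None  # first violating (vertex, time)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def occupation_bound(params: Params, rho: int) -> int:
    """Φ + ρ·μ·Ψ: worst-case steps for a vertex at distance ρ from a stem
    cell to itself become a stem cell."""
    if rho < 0:
        raise ValueError("rho must be non-negative")
    return params.phi + rho * params.mu * params.psi


def density_bound(params: Params) -> Fraction:
    """(μ − 1)/(μ^{Mη} − 1): guaranteed long-run stem density of balls of
    radius Mη, as an exact rational."""
    mu = params.mu
    return Fraction(mu - 1, mu ** (params.m * params.eta) - 1)


def supply_bound(params: Params) -> int:
    """(μ + 1)Ψ + MΘ + 1 + Φ: steps within which a ball of radius 2Mη
    around a stem-occupied vertex supplies a matured differentiated cell."""
    return (params.mu + 1) * params.psi + params.m * params.theta + 1 + params.phi


# ---------------------------------------------------------------------------
# trajectory scanning helpers
# ---------------------------------------------------------------------------


def _require_snapshots(trajectory: Trajectory) -> list[MarrowState]:
    if trajectory.snapshots is None:
        raise ValueError("verifier requires a trajectory recorded with snapshots")
    return trajectory.snapshots


def _stem_stack(snaps: list[MarrowState]) -> np.ndarray:
    return np.stack([s.kind == S_CODE for s in snaps])


def _dilate(mask: np.ndarray, radius: int, topology: str) -> np.ndarray:
    """Per-frame Chebyshev dilation: True where the mask holds within
    distance ``radius`` (graph balls on the Moore lattice)."""
    if radius == 0:
        return mask.copy()
    mode = "wrap" if topology == "torus" else "constant"
    size = (1, 2 * radius + 1, 2 * radius + 1)
    return ndimage.maximum_filter(
        mask.astype(np.uint8), size=size, mode=mode, cval=0
    ).astype(bool)


def pre_death_horizon(trajectory: Trajectory) -> int:
    """Number of leading steps free of apoptosis events.

    Returns the largest h such that no stem cell died during steps 1..h;
    the guarantees that presume an unexhausted renewal budget are checked
    on snapshots 0..h only.
    """
    for i, rep in enumerate(trajectory.reports):
        if rep.deaths > 0:
            return i
    return len(trajectory.reports)


def first_occupation_times(trajectory: Trajectory) -> np.ndarray:
    """Per-vertex first time hosting a stem cell (-1 if never, within the
    recorded horizon)."""
    snaps = _require_snapshots(trajectory)
    stems = _stem_stack(snaps)
    T = len(snaps)
    first = np.full(stems.shape[1:], -1, dtype=np.int64)
    for i in range(T - 1, -1, -1):
        first[stems[i]] = snaps[i].t
    return first


# ---------------------------------------------------------------------------
# verifiers
# ---------------------------------------------------------------------------


def verify_lemma1(
    trajectory: Trajectory, params: Params, source: Vertex | None = None
) -> BoundReport:
    """Single-stem repopulation: first stem occupation of every vertex
    within Φ + ρ(source, v)·μ·Ψ steps of the start.

    ``source`` defaults to the unique stem cell of the initial state.
    Vertices whose bound extends past the checkable (pre-apoptosis,
    in-horizon) window are not counted against the result.
    """
    snaps = _require_snapshots(trajectory)
    grid = trajectory.initial.grid
    if source is None:
        rows, cols = np.nonzero(trajectory.initial.kind == S_CODE)
        if len(rows) != 1:
            raise ValueError("source not given and initial state has != 1 stem")
        source = Vertex(int(rows[0]), int(cols[0]))
    t0 = trajectory.initial.t
    horizon = min(snaps[-1].t, t0 + pre_death_horizon(trajectory))
    first = first_occupation_times(trajectory)
    worst_excess = -np.inf
    witness = None
    n_checked = 0
    for v in grid.vertices():
        bound = t0 + occupation_bound(params, distance(grid, source, v))
        if bound > horizon:
            continue  # window does not fit inside the checkable segment
        n_checked += 1
        fo = int(first[v[0], v[1]])
        observed = fo if fo >= 0 else np.inf
        excess = observed - bound
        if excess > worst_excess:
            worst_excess = excess
            if excess > 0:
                witness = (v, fo)
    if n_checked == 0:
        raise ValueError("occupation-bound windows exceed the recorded horizon")
    return BoundReport(
        bound_name="occupation_bound",
        bound_value=0.0,
        observed_value=float(worst_excess),
        satisfied=worst_excess <= 0,
        witness=witness,
    )


def verify_lemma2(
    trajectory: Trajectory, v: Vertex, t0: int, params: Params
) -> BoundReport:
    """Stem persistence at one vertex: from t0 (when v hosts a stem cell)
    onward, B(v, Mη) contains a stem at time t or t+1."""
    snaps = _require_snapshots(trajectory)
    grid = trajectory.initial.grid
    base = trajectory.initial.t
    idx0 = t0 - base
    if not (0 <= idx0 < len(snaps)):
        raise ValueError(f"t0={t0} outside recorded horizon")
    if int(snaps[idx0].kind[v[0], v[1]]) != S_CODE:
        raise ValueError(f"vertex {tuple(v)} does not host a stem cell at t0={t0}")
    radius = params.m * params.eta
    stems = _stem_stack(snaps)
    near = _dilate(stems, radius, grid.topology)[:, v[0], v[1]]
    ok = near[:-1] | near[1:]  # stem in ball at t or t+1
    for i in range(idx0, len(ok)):
        if not ok[i]:
            return BoundReport(
                bound_name="stem_persistence",
                bound_value=1.0,
                observed_value=0.0,
                satisfied=False,
                witness=(v, base + i),
            )
    return BoundReport("stem_persistence", 1.0, 1.0, True, None)


def verify_lemma2_all(trajectory: Trajectory, params: Params) -> BoundReport:
    """Stem persistence at every vertex from its first occupation, over the
    pre-apoptosis segment of the run."""
    snaps = _require_snapshots(trajectory)
    grid = trajectory.initial.grid
    base = trajectory.initial.t
    h = pre_death_horizon(trajectory)
    stems = _stem_stack(snaps[: h + 1])
    radius = params.m * params.eta
    near = _dilate(stems, radius, grid.topology)
    ok = near[:-1] | near[1:]  # shape (h, H, W): check at t or t+1
    first = first_occupation_times(trajectory)
    for i in range(ok.shape[0]):
        t = base + i
        active = (first >= 0) & (first <= t)
        bad = active & ~ok[i]
        if bad.any():
            r, c = (int(x) for x in np.argwhere(bad)[0])
            return BoundReport(
                bound_name="stem_persistence",
                bound_value=1.0,
                observed_value=0.0,
                satisfied=False,
                witness=(Vertex(r, c), t),
            )
    return BoundReport("stem_persistence", 1.0, 1.0, True, None)


def verify_lemma3(
    trajectory: Trajectory, params: Params, tail: int | None = None
) -> BoundReport:
    """Long-run stem density of interior balls of radius Mη against
    (μ − 1)/(μ^{Mη} − 1).

    The density is measured over the last ``tail`` pre-apoptosis snapshots
    (default: the later half of the checkable segment), for every interior
    vertex occupied by a stem at some point before the window.
    """
    snaps = _require_snapshots(trajectory)
    grid = trajectory.initial.grid
    h = pre_death_horizon(trajectory)
    snaps = snaps[: h + 1]
    if tail is None:
        tail = max(1, len(snaps) // 2)
    tail = min(tail, len(snaps))
    radius = params.m * params.eta
    bound = float(density_bound(params))
    stems = _stem_stack(snaps)
    size = (1, 2 * radius + 1, 2 * radius + 1)
    mode = "wrap" if grid.topology == "torus" else "constant"
    counts = ndimage.uniform_filter(
        stems.astype(np.float64), size=size, mode=mode, cval=0.0
    )  # mean over the (2r+1)^2 window = ball density for interior vertices
    first = first_occupation_times(trajectory)
    window = counts[-tail:]
    base = trajectory.initial.t
    window_start_t = snaps[-tail].t
    worst = np.inf
    witness = None
    for v in grid.vertices():
        if not grid.interior(v, margin=radius):
            continue
        fo = int(first[v[0], v[1]])
        if fo < 0 or fo > window_start_t:
            continue
        dmin = float(window[:, v[0], v[1]].min())
        if dmin < worst:
            worst = dmin
            if dmin < bound:
                i = int(np.argmin(window[:, v[0], v[1]]))
                witness = (v, window_start_t + i)
    if witness is None and worst is np.inf:
        worst = 1.0  # no checkable interior vertex: vacuously satisfied
    return BoundReport(
        bound_name="density_bound",
        bound_value=bound,
        observed_value=float(worst),
        satisfied=worst >= bound,
        witness=witness,
    )


def verify_lemma5(trajectory: Trajectory, params: Params) -> BoundReport:
    """Differentiated-cell supply: for every time a vertex hosts a stem
    cell (with the bound's window inside the pre-apoptosis segment), the
    ball of radius 2Mη around it emits a matured cell within
    (μ + 1)Ψ + MΘ + 1 + Φ steps.

    Resonant trajectories are outside the statement's scope and vacuously
    satisfy the check.
    """
    snaps = _require_snapshots(trajectory)
    grid = trajectory.initial.grid
    if any(classify(s, params).label == "resonant" for s in snaps):
        return BoundReport("supply_bound", float(supply_bound(params)), 0.0, True, None)
    base = trajectory.initial.t
    h = pre_death_horizon(trajectory)
    bound = supply_bound(params)
    H, W = grid.height, grid.width
    em = np.zeros((h, H, W), dtype=bool)  # emissions during steps 1..h
    for i, rep in enumerate(trajectory.reports[:h]):
        for (r, c) in rep.emission_sites:
            em[i, r, c] = True
    radius = 2 * params.m * params.eta
    em_near = _dilate(em, radius, grid.topology) if h else em
    # next_em[i] = least step index >= i with an emission in the ball
    next_em = np.full((h + 1, H, W), np.iinfo(np.int64).max, dtype=np.int64)
    for i in range(h - 1, -1, -1):
        next_em[i] = np.where(em_near[i], i, next_em[i + 1])
    stems = _stem_stack(snaps[: h + 1])
    worst = -np.inf
    witness = None
    checked = False
    for i in range(h + 1):
        if i + bound > h:
            break  # window no longer fits in the checkable segment
        occupied = stems[i]
        if not occupied.any():
            continue
        checked = True
        # emissions strictly after time base+i are steps with index >= i
        wait = next_em[i] - i + 1  # steps until first emission, 1-based
        bad = occupied & (wait > bound)
        excess = float((wait[occupied].max() if occupied.any() else 0) - bound)
        if excess > worst:
            worst = excess
        if bad.any() and witness is None:
            r, c = (int(x) for x in np.argwhere(bad)[0])
            witness = (Vertex(r, c), base + i)
    if not checked:
        raise ValueError("supply-bound window exceeds the recorded horizon")
    return BoundReport(
        bound_name="supply_bound",
        bound_value=float(bound),
        observed_value=float(worst),
        satisfied=witness is None,
        witness=witness,
    )


def verify_all(trajectory: Trajectory, params: Params) -> list[BoundReport]:
    """Run every trajectory verifier applicable to a single-stem run."""
    return [
        verify_lemma1(trajectory, params),
        verify_lemma2_all(trajectory, params),
        verify_lemma3(trajectory, params),
        verify_lemma5(trajectory, params),
    ]
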