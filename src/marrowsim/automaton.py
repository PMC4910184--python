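"""The iterative operator of the bone-marrow model.

Four cell types live on the lattice: stem cells (S), transitive
(transit-amplifying) cells (T), differentiated cells (D), and empty space
(E).  Each cell carries internal counters; all behavior is a deterministic
function of the cell's own counters and the types of its neighbors, read
from the time-t configuration and applied synchronously to form time t+1.

Update rules, one per cell type, subrules evaluated strictly in order so
exactly one fires per cell per step:

Stem cell (S, d, τ, p) with maturity threshold Ψ and renewal budget Δ:
  1. τ = Ψ and p = Δ                → apoptosis: the site becomes empty.
  2. τ = Ψ and every existing immediate neighbor is a stem cell
                                    → converts to a transitive cell (T, 1, 0).
  3. τ = Ψ and some neighbor empty  → proliferates: scanning directions
     round-robin clockwise from d, the first empty neighbor receives a
     daughter (S, 0, 0, 0); the parent becomes (S, d'+1, 0, p+1) where d'
     is the direction actually used.  Both get renewed biological time.
  4. τ = Ψ                          → quiescence: the state is retained
     (τ stays pinned at Ψ) and re-evaluated every subsequent step.
  5. otherwise                      → τ is incremented.

Transitive cell (T, g, τ) with per-generation maturity Θ, M generations,
and dedifferentiation distance multiple η:
  * no stem cell within ball(v, g·η) → dedifferentiation: becomes a fresh
    stem cell (S, 0, 0, 0).
  * τ = g·Θ and g < M → advances to generation g+1 (counter is cumulative
    across generations and is not reset).
  * τ = g·Θ and g = M → converts to a differentiated cell (D, 0).
  * otherwise         → τ is incremented.

Differentiated cell (D, τ): at τ = Φ it matures and emigrates to the blood
stream, leaving empty space; otherwise τ is incremented.

Empty space (E) does not change by itself and carries no counters.

Because the per-cell rules never define simultaneous claims on one empty
site, proliferation conflicts are resolved deterministically: proliferating
stems are processed in row-major order, each claiming its scanned target if
still unclaimed, re-scanning its remaining directions otherwise, and
downgrading to quiescence if every empty neighbor has been taken.

The production :func:`step` is vectorized over numpy arrays; per-cell
functions (:func:`stem_intent`, :func:`transitive_update`,
:func:`differentiated_update`) expose the same semantics one vertex at a
time for inspection and testing.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
from scipy import ndimage

from .grid import MOORE_DIRECTIONS, MU, Grid, Vertex, ball, neighbors

__all__ = [
    "Params",
    "Stem",
    "Transitive",
    "Differentiated",
    "Empty",
    "EMPTY",
    "CellState",
    "MarrowState",
    "IntentKind",
    "StemIntent",
    "StepReport",
    "Trajectory",
    "stem_intent",
    "resolve_proliferation",
    "transitive_update",
    "differentiated_update",
    "step",
    "run",
]

# integer type codes used in the array representation
E_CODE, S_CODE, T_CODE, D_CODE = 0, 1, 2, 3
TYPE_CHARS = {E_CODE: ".", S_CODE: "S", T_CODE: "T", D_CODE: "D"}
CHAR_TYPES = {v: k for k, v in TYPE_CHARS.items()}


class ContractViolation(RuntimeError):
    """A per-cell operation was invoked on the wrong cell type."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Params:
    """Model constants and lattice geometry.

    psi   (Ψ) stem-cell maturity, steps; positive.
    theta (Θ) per-generation transitive maturity, steps; positive.
    phi   (Φ) differentiated-cell maturity, steps; positive.
    delta (Δ) maximum number of stem-cell renewals; positive.
    m     (M) number of transitive generations, ≥ 1.
    eta   (η) dedifferentiation distance multiple, ≥ 1.
    """

    psi: int
    theta: int
    phi: int
    delta: int
    m: int = 1
    eta: int = 1
    width: int = 9
    height: int = 9
    topology: str = "bounded"

    def __post_init__(self) -> None:
        for name in ("psi", "theta", "phi", "delta"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive nonzero integer")
        if self.m < 1:
            raise ValueError("m (transitive generations) must be >= 1")
        if self.eta < 1:
            raise ValueError("eta (distance multiple) must be >= 1")
        # validates width/height/topology
        object.__setattr__(self, "_grid", Grid(self.width, self.height, self.topology))

    @property
    def mu(self) -> int:
        return MU

    @property
    def grid(self) -> Grid:
        return self._grid  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# cell states (tagged union used at the per-vertex API surface)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stem:
    """(S, d, τ, p): direction index 0..7, internal counter, renewal count."""

    d: int = 0
    tau: int = 0
    p: int = 0


@dataclass(frozen=True)
class Transitive:
    """(T, g, τ): generation (starts at 1) and cumulative internal counter."""

    g: int = 1
    tau: int = 0


@dataclass(frozen=True)
class Differentiated:
    """(D, τ): internal counter up to Φ."""

    tau: int = 0


@dataclass(frozen=True)
class Empty:
    """(E): empty space; no counters, no computation."""


EMPTY = Empty()

CellState = Union[Stem, Transitive, Differentiated, Empty]


# ---------------------------------------------------------------------------
# lattice configuration
# ---------------------------------------------------------------------------


class MarrowState:
    """One full lattice configuration x^t : V → Ω at time ``t``.

    Internally stored as parallel integer arrays (kind, d, tau, g, p) of
    shape (height, width); fields unused by a cell type are kept at zero so
    that equality and hashing depend only on the meaningful tuple content.
    """

    __slots__ = ("grid", "t", "kind", "d", "tau", "g", "p")

    def __init__(self, grid: Grid, t: int = 0) -> None:
        shape = (grid.height, grid.width)
        self.grid = grid
        self.t = t
        self.kind = np.zeros(shape, dtype=np.int64)
        self.d = np.zeros(shape, dtype=np.int64)
        self.tau = np.zeros(shape, dtype=np.int64)
        self.g = np.zeros(shape, dtype=np.int64)
        self.p = np.zeros(shape, dtype=np.int64)

    # -- construction / access ------------------------------------------------

    def copy(self) -> "MarrowState":
        out = MarrowState(self.grid, self.t)
        for name in ("kind", "d", "tau", "g", "p"):
            getattr(out, name)[:] = getattr(self, name)
        return out

    def __getitem__(self, v: Vertex) -> CellState:
        self.grid.check_vertex(v)
        r, c = v
        k = int(self.kind[r, c])
        if k == S_CODE:
            return Stem(int(self.d[r, c]), int(self.tau[r, c]), int(self.p[r, c]))
        if k == T_CODE:
            return Transitive(int(self.g[r, c]), int(self.tau[r, c]))
        if k == D_CODE:
            return Differentiated(int(self.tau[r, c]))
        return EMPTY

    def set(self, v: Vertex, cs: CellState) -> None:
        """In-place assignment, used by scenario builders and tests."""
        self.grid.check_vertex(v)
        r, c = v
        self.kind[r, c] = 0
        self.d[r, c] = self.tau[r, c] = self.g[r, c] = self.p[r, c] = 0
        if isinstance(cs, Stem):
            self.kind[r, c] = S_CODE
            self.d[r, c], self.tau[r, c], self.p[r, c] = cs.d, cs.tau, cs.p
        elif isinstance(cs, Transitive):
            self.kind[r, c] = T_CODE
            self.g[r, c], self.tau[r, c] = cs.g, cs.tau
        elif isinstance(cs, Differentiated):
            self.kind[r, c] = D_CODE
            self.tau[r, c] = cs.tau
        elif not isinstance(cs, Empty):
            raise TypeError(f"not a cell state: {cs!r}")

    def cells(self) -> dict[Vertex, CellState]:
        """The state as an explicit map Vertex → CellState (row-major)."""
        return {v: self[v] for v in self.grid.vertices()}

    # -- summaries ------------------------------------------------------------

    def counts(self) -> dict[str, int]:
        flat = self.kind.ravel()
        return {
            "n_stem": int(np.count_nonzero(flat == S_CODE)),
            "n_transitive": int(np.count_nonzero(flat == T_CODE)),
            "n_differentiated": int(np.count_nonzero(flat == D_CODE)),
            "n_empty": int(np.count_nonzero(flat == E_CODE)),
        }

    def type_grid(self) -> list[str]:
        """Character rows, alphabet {S, T, D, .}, for human-readable marrow maps."""
        return ["".join(TYPE_CHARS[int(k)] for k in row) for row in self.kind]

    def state_hash(self) -> str:
        """Digest of the full configuration (time excluded).

        Two states differing only in a direction component hash differently.
        """
        h = hashlib.blake2b(digest_size=16)
        h.update(np.int64(self.grid.height).tobytes())
        h.update(np.int64(self.grid.width).tobytes())
        h.update(self.grid.topology.encode())
        for name in ("kind", "d", "tau", "g", "p"):
            h.update(np.ascontiguousarray(getattr(self, name)).tobytes())
        return h.hexdigest()

    def same_configuration(self, other: "MarrowState") -> bool:
        return (
            self.grid == other.grid
            and all(
                np.array_equal(getattr(self, n), getattr(other, n))
                for n in ("kind", "d", "tau", "g", "p")
            )
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarrowState):
            return NotImplemented
        return self.t == other.t and self.same_configuration(other)

    def __repr__(self) -> str:
        c = self.counts()
        return (
            f"<MarrowState t={self.t} {self.grid.height}x{self.grid.width} "
            f"S={c['n_stem']} T={c['n_transitive']} "
            f"D={c['n_differentiated']} E={c['n_empty']}>"
        )

    def validate(self, params: Params) -> None:
        """Assert every per-cell counter invariant; raises on violation."""
        s = self.kind == S_CODE
        t = self.kind == T_CODE
        d = self.kind == D_CODE
        if np.any(self.tau[s] > params.psi) or np.any(self.tau[s] < 0):
            raise AssertionError("stem tau out of [0, psi]")
        if np.any(self.p[s] > params.delta) or np.any((self.d[s] < 0) | (self.d[s] >= MU)):
            raise AssertionError("stem p or d out of range")
        if np.any(self.g[t] < 1) or np.any(self.g[t] > params.m):
            raise AssertionError("transitive generation out of [1, M]")
        if np.any(self.tau[t] > self.g[t] * params.theta):
            raise AssertionError("transitive tau exceeds g*theta")
        if np.any(self.tau[d] > params.phi):
            raise AssertionError("differentiated tau exceeds phi")
        unused = ~(s | t | d)
        for name in ("d", "tau", "g", "p"):
            arr = getattr(self, name)
            if np.any(arr[unused] != 0):
                raise AssertionError("empty site carries nonzero counters")


# ---------------------------------------------------------------------------
# per-cell semantics
# ---------------------------------------------------------------------------


class IntentKind(enum.Enum):
    DIE = "die"
    CONVERT = "convert_to_transitive"
    PROLIFERATE = "proliferate"
    QUIESCE = "quiesce"
    TICK = "tick"


@dataclass(frozen=True)
class StemIntent:
    """Staged outcome of Rule 1 for one stem cell at time t."""

    kind: IntentKind
    target: Vertex | None = None
    used_direction: int | None = None


def stem_intent(state: MarrowState, v: Vertex, params: Params) -> StemIntent:
    """Evaluate the stem-cell subrules, in order, on the time-t configuration."""
    cs = state[v]
    if not isinstance(cs, Stem):
        raise ContractViolation(f"stem_intent called on {cs!r} at {tuple(v)}")
    if cs.tau != params.psi:
        return StemIntent(IntentKind.TICK)
    if cs.p == params.delta:
        return StemIntent(IntentKind.DIE)
    nbs = neighbors(state.grid, v)
    if all(isinstance(state[u], Stem) for u in nbs):
        return StemIntent(IntentKind.CONVERT)
    for j in range(MU):
        k = (cs.d + j) % MU
        u = state.grid.shift(v, k)
        if u is not None and isinstance(state[u], Empty):
            return StemIntent(IntentKind.PROLIFERATE, target=u, used_direction=k)
    return StemIntent(IntentKind.QUIESCE)


def resolve_proliferation(
    intents: Mapping[Vertex, StemIntent], state: MarrowState
) -> dict[Vertex, StemIntent]:
    """Deterministic arbitration of simultaneous claims on empty sites.

    Proliferating stems are processed in row-major order.  Each claims its
    target if unclaimed; one whose target was taken re-scans its remaining
    directions round-robin from the failed one for an empty, unclaimed
    neighbor, and quiesces if none remains.  Each empty site ends up claimed
    by at most one stem.
    """
    out: dict[Vertex, StemIntent] = dict(intents)
    claimed: set[Vertex] = set()
    for v in sorted(intents):
        it = intents[v]
        if it.kind is not IntentKind.PROLIFERATE:
            continue
        assert it.target is not None and it.used_direction is not None
        chosen: StemIntent | None = None
        for j in range(MU):
            k = (it.used_direction + j) % MU
            u = state.grid.shift(v, k)
            if (
                u is not None
                and u not in claimed
                and isinstance(state[u], Empty)
            ):
                chosen = StemIntent(IntentKind.PROLIFERATE, target=u, used_direction=k)
                break
        if chosen is None:
            out[v] = StemIntent(IntentKind.QUIESCE)
        else:
            claimed.add(chosen.target)  # type: ignore[arg-type]
            out[v] = chosen
    return out


def transitive_update(state: MarrowState, v: Vertex, params: Params) -> CellState:
    """Rule 2 for one transitive cell, read from the time-t configuration."""
    cs = state[v]
    if not isinstance(cs, Transitive):
        raise ContractViolation(f"transitive_update called on {cs!r} at {tuple(v)}")
    near = ball(state.grid, v, cs.g * params.eta)
    if not any(isinstance(state[u], Stem) for u in near):
        return Stem(d=0, tau=0, p=0)  # dedifferentiation
    if cs.tau == cs.g * params.theta:
        if cs.g < params.m:
            return Transitive(g=cs.g + 1, tau=cs.tau)
        return Differentiated(tau=0)
    return Transitive(g=cs.g, tau=cs.tau + 1)


def differentiated_update(state: MarrowState, v: Vertex, params: Params) -> CellState:
    """Rule 3 for one differentiated cell; at τ = Φ it leaves the marrow."""
    cs = state[v]
    if not isinstance(cs, Differentiated):
        raise ContractViolation(
            f"differentiated_update called on {cs!r} at {tuple(v)}"
        )
    if cs.tau == params.phi:
        return EMPTY
    return Differentiated(tau=cs.tau + 1)


# ---------------------------------------------------------------------------
# synchronous step (production engine, vectorized)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepReport:
    """Event tally for one synchronous step; ``t`` is the time after it."""

    t: int
    deaths: int = 0
    stem_to_transitive: int = 0
    proliferations: int = 0
    quiescent: int = 0
    generation_advances: int = 0
    transitive_to_differentiated: int = 0
    dedifferentiations: int = 0
    emitted: int = 0
    n_stem: int = 0
    n_transitive: int = 0
    n_differentiated: int = 0
    n_empty: int = 0
    emission_sites: tuple[Vertex, ...] = ()


def _neighbor_kind_stack(state: MarrowState) -> np.ndarray:
    """kinds of the 8 directional neighbors; -1 marks off-lattice (bounded)."""
    H, W = state.grid.height, state.grid.width
    torus = state.grid.topology == "torus"
    out = np.full((MU, H, W), -1, dtype=np.int64)
    k = state.kind
    for i, (dr, dc) in enumerate(MOORE_DIRECTIONS):
        if torus:
            out[i] = np.roll(np.roll(k, -dr, axis=0), -dc, axis=1)
        else:
            rs = slice(max(dr, 0), H + min(dr, 0))
            cs = slice(max(dc, 0), W + min(dc, 0))
            rd = slice(max(-dr, 0), H + min(-dr, 0))
            cd = slice(max(-dc, 0), W + min(-dc, 0))
            out[i][rd, cd] = k[rs, cs]
    return out


def _stem_within(state: MarrowState, radius: int) -> np.ndarray:
    """Boolean array: a stem cell lies within Chebyshev distance ``radius``."""
    stem = (state.kind == S_CODE).astype(np.uint8)
    if radius == 0:
        return stem.astype(bool)
    mode = "wrap" if state.grid.topology == "torus" else "constant"
    return ndimage.maximum_filter(
        stem, size=2 * radius + 1, mode=mode, cval=0
    ).astype(bool)


def step(state: MarrowState, params: Params) -> tuple[MarrowState, StepReport]:
    """Apply all four rules synchronously: x^t → x^{t+1}.

    All reads come from the time-t arrays; writes go to a fresh state, so the
    order in which cell types are processed is immaterial.  Empty sites not
    claimed by a proliferation remain empty and take part in no computation.
    """
    if state.grid != params.grid:
        raise ValueError("state geometry does not match params")
    H, W = state.grid.height, state.grid.width
    torus = state.grid.topology == "torus"
    kind, d, tau, g, p = state.kind, state.d, state.tau, state.g, state.p

    nb = _neighbor_kind_stack(state)
    exist = nb >= 0
    all_exist_stem = np.logical_or(nb == S_CODE, ~exist).all(axis=0)
    has_empty_nb = (nb == E_CODE).any(axis=0)

    stem = kind == S_CODE
    mature = stem & (tau == params.psi)
    die = mature & (p == params.delta)
    convert = mature & ~die & all_exist_stem
    prolif_cand = mature & ~die & ~convert & has_empty_nb
    quiesce = mature & ~die & ~convert & ~has_empty_nb

    # -- sequential conflict resolution (row-major priority, re-scan) --------
    claimed = np.zeros((H, W), dtype=bool)
    commits: list[tuple[int, int, int, int, int]] = []  # r, c, used_dir, tr, tc
    downgraded = 0
    for r, c in zip(*np.nonzero(prolif_cand)):
        placed = False
        for j in range(MU):
            k = (int(d[r, c]) + j) % MU
            dr, dc = MOORE_DIRECTIONS[k]
            rr, cc = r + dr, c + dc
            if torus:
                rr, cc = rr % H, cc % W
            elif not (0 <= rr < H and 0 <= cc < W):
                continue
            if kind[rr, cc] == E_CODE and not claimed[rr, cc]:
                claimed[rr, cc] = True
                commits.append((int(r), int(c), k, int(rr), int(cc)))
                placed = True
                break
        if not placed:
            downgraded += 1

    # -- transitive cells -----------------------------------------------------
    trans = kind == T_CODE
    stem_near = np.zeros((H, W), dtype=bool)
    if trans.any():
        for radius in np.unique(g[trans] * params.eta):
            sel = trans & (g * params.eta == radius)
            stem_near[sel] = _stem_within(state, int(radius))[sel]
    dediff = trans & ~stem_near
    at_gen_threshold = trans & ~dediff & (tau == g * params.theta)
    advance = at_gen_threshold & (g < params.m)
    to_diff = at_gen_threshold & (g >= params.m)
    t_tick = trans & ~dediff & ~at_gen_threshold

    # -- differentiated cells -------------------------------------------------
    diff = kind == D_CODE
    emit = diff & (tau == params.phi)
    d_tick = diff & ~emit

    # -- commit ---------------------------------------------------------------
    new = MarrowState(state.grid, state.t + 1)
    nk, ndir, ntau, ng, npr = new.kind, new.d, new.tau, new.g, new.p
    nk[:] = kind
    ndir[:] = d
    ntau[:] = tau
    ng[:] = g
    npr[:] = p

    def clear(mask: np.ndarray) -> None:
        for arr in (ndir, ntau, ng, npr):
            arr[mask] = 0

    nk[die] = E_CODE
    clear(die)

    nk[convert] = T_CODE
    clear(convert)
    ng[convert] = 1

    s_tick = stem & ~mature
    ntau[s_tick] += 1
    # quiescent stems (incl. downgraded proliferators): state retained

    for r, c, used, rr, cc in commits:
        ndir[r, c] = (used + 1) % MU
        ntau[r, c] = 0
        npr[r, c] += 1
        nk[rr, cc] = S_CODE
        ndir[rr, cc] = ntau[rr, cc] = ng[rr, cc] = npr[rr, cc] = 0

    nk[dediff] = S_CODE
    clear(dediff)

    ntau[t_tick] += 1
    ng[advance] += 1  # cumulative counter: tau is not reset

    nk[to_diff] = D_CODE
    clear(to_diff)

    nk[emit] = E_CODE
    clear(emit)

    ntau[d_tick] += 1

    counts = new.counts()
    report = StepReport(
        t=new.t,
        deaths=int(die.sum()),
        stem_to_transitive=int(convert.sum()),
        proliferations=len(commits),
        quiescent=int(quiesce.sum()) + downgraded,
        generation_advances=int(advance.sum()),
        transitive_to_differentiated=int(to_diff.sum()),
        dedifferentiations=int(dediff.sum()),
        emitted=int(emit.sum()),
        emission_sites=tuple(Vertex(int(r), int(c)) for r, c in zip(*np.nonzero(emit))),
        **counts,
    )
    return new, report


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered record of a run: initial state, per-step reports, snapshots.

    ``snapshots`` holds the full configuration at every recorded time
    (always including t=0 and the final state when recording is on).
    """

    initial: MarrowState
    reports: list[StepReport] = field(default_factory=list)
    snapshots: list[MarrowState] | None = None
    final: MarrowState | None = None

    @property
    def horizon(self) -> int:
        return len(self.reports)

    def cumulative_emitted(self) -> int:
        return sum(r.emitted for r in self.reports)

    def to_frame(self):
        """Per-step time series as a pandas DataFrame (one row per step)."""
        import pandas as pd

        rows = []
        cum = 0
        for r in self.reports:
            cum += r.emitted
            qpct = 100.0 * r.quiescent / r.n_stem if r.n_stem else 0.0
            rows.append(
                {
                    "t": r.t,
                    "n_stem": r.n_stem,
                    "n_transitive": r.n_transitive,
                    "n_differentiated": r.n_differentiated,
                    "n_empty": r.n_empty,
                    "quiescent_fraction_pct": qpct,
                    "deaths": r.deaths,
                    "proliferations": r.proliferations,
                    "dedifferentiations": r.dedifferentiations,
                    "matured_emitted": r.emitted,
                    "cumulative_output": cum,
                }
            )
        return pd.DataFrame(rows)


def run(
    initial: MarrowState,
    params: Params,
    steps: int,
    record_snapshots: bool = False,
) -> Trajectory:
    """Apply :func:`step` ``steps`` times.  Fully deterministic."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    traj = Trajectory(initial=initial)
    if record_snapshots:
        traj.snapshots = [initial]
    state = initial
    for _ in range(steps):
        state, report = step(state, params)
        traj.reports.append(report)
        if record_snapshots:
            traj.snapshots.append(state)
    traj.final = state
    return traj
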