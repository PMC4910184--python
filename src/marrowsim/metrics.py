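"""Trajectory metrics and state classification.

Quantities reported per step or per trajectory:

* stem-cell density δ_t(U) of a region U — stems in U over |U|;
* quiescent fraction — the percentage of stem cells whose executed subrule
  in the step just taken was quiescence (mature but unable to convert,
  proliferate, or die), out of all stem cells present after that step;
* cumulative differentiated output — total matured cells emitted to the
  blood stream (D → E events).

State classification follows the model's steady-state taxonomy: the
*death* state is the all-empty lattice; *dying-out* states are those that
deterministically reach it (no stem and no transitive cells left, or a
fully synchronized all-stem marrow with exhausted renewal budgets); the
all-stem synchronized marrow with renewals remaining is the precursor of
the *resonant* oscillation between all-stem and all-transitive phases;
everything else is *active*.  Cycle detection hashes full configurations
(including direction components), so any recurrence — fixed point, the
resonant oscillation, or a long steady-state loop — is found exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .automaton import (
    D_CODE,
    E_CODE,
    MarrowState,
    Params,
    S_CODE,
    StepReport,
    T_CODE,
    Trajectory,
)
from .grid import Vertex

__all__ = [
    "StateClass",
    "CycleInfo",
    "stem_density",
    "quiescent_fraction",
    "cumulative_output",
    "classify",
    "detect_cycle",
]


@dataclass(frozen=True)
class StateClass:
    """Classification label plus a short evidence tag."""

    label: str  # death | dying_out | resonant | active
    evidence: str = ""


@dataclass(frozen=True)
class CycleInfo:
    """A detected recurrence: first entry time and period of the loop."""

    entry_time: int
    period: int


def stem_density(state: MarrowState, region: Iterable[Vertex]) -> float:
    """δ_t(U): fraction of the region's vertices occupied by stem cells."""
    region = list(region)
    if not region:
        raise ValueError("region must be nonempty")
    n_stem = sum(1 for v in region if int(state.kind[v[0], v[1]]) == S_CODE)
    return n_stem / len(region)


def quiescent_fraction(report: StepReport, state: MarrowState) -> float:
    """Percentage of stems that executed the quiescence subrule this step.

    Computed as 100 × (quiescent stems) / (stems after the step); defined
    as 0 when no stem cells remain.  ``report`` must describe the step that
    produced ``state``.
    """
    if report.t != state.t:
        raise ValueError(
            f"report is for t={report.t} but state is at t={state.t}"
        )
    if report.n_stem == 0:
        return 0.0
    return 100.0 * report.quiescent / report.n_stem


def cumulative_output(trajectory: Trajectory) -> int:
    """Total matured differentiated cells emitted over the whole run."""
    return sum(r.emitted for r in trajectory.reports)


def classify(state: MarrowState, params: Params) -> StateClass:
    """Classify a configuration as death / dying_out / resonant / active."""
    kind = state.kind
    if np.all(kind == E_CODE):
        return StateClass("death", "all vertices empty")
    no_s = not np.any(kind == S_CODE)
    no_t = not np.any(kind == T_CODE)
    if no_s and no_t:
        return StateClass(
            "dying_out", "no stem and no transitive cells remain"
        )
    all_stem = bool(np.all(kind == S_CODE))
    if all_stem:
        if np.all(state.tau == params.psi) and np.all(state.p == params.delta):
            return StateClass(
                "dying_out",
                "all-stem marrow, counters synchronized at psi with "
                "exhausted renewals",
            )
        taus = np.unique(state.tau)
        if len(taus) == 1:
            return StateClass(
                "resonant",
                f"all-stem marrow with counters synchronized at tau={int(taus[0])}",
            )
    return StateClass("active", "mixed composition")


def detect_cycle(trajectory: Trajectory) -> CycleInfo | None:
    """First exact state recurrence along a snapshot-recorded trajectory.

    Hash collisions are guarded by a full array comparison.  Returns None
    when no configuration repeats within the recorded horizon.
    """
    if trajectory.snapshots is None:
        raise ValueError("detect_cycle requires a trajectory recorded with snapshots")
    seen: dict[str, list[MarrowState]] = {}
    for snap in trajectory.snapshots:
        h = snap.state_hash()
        for prev in seen.get(h, ()):
            if prev.same_configuration(snap):
                return CycleInfo(entry_time=prev.t, period=snap.t - prev.t)
        seen.setdefault(h, []).append(snap)
    return None
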