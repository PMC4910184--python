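"""Update-rule semantics: per-cell subrules, conflict resolution, and the
synchronous step operator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowsim import (
    EMPTY,
    Differentiated,
    Empty,
    IntentKind,
    MarrowState,
    Params,
    Stem,
    StemIntent,
    Transitive,
    Vertex,
    blank,
    random_mixture,
    resolve_proliferation,
    run,
    single_center_stem,
    step,
    stem_intent,
    transitive_update,
    differentiated_update,
)
from marrowsim.automaton import ContractViolation

from .reference import ref_step, state_to_dict


# ---------------------------------------------------------------------------
# Rule 1: stem cells
# ---------------------------------------------------------------------------


class TestStemIntent:
    def test_apoptosis_when_mature_with_exhausted_renewals(self, make_params):
        p = make_params(delta=3)
        s = blank(p)
        s.set(Vertex(3, 3), Stem(d=0, tau=p.psi, p=3))
        assert stem_intent(s, Vertex(3, 3), p).kind is IntentKind.DIE

    def test_immature_stem_ticks(self, make_params):
        p = make_params()
        s = blank(p)
        s.set(Vertex(3, 3), Stem(d=0, tau=p.psi - 1, p=0))
        assert stem_intent(s, Vertex(3, 3), p).kind is IntentKind.TICK

    def test_saturated_neighborhood_converts(self, make_params):
        p = make_params()
        s = blank(p)
        for u in [Vertex(3, 3)] + [
            Vertex(3 + dr, 3 + dc)
            for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
        ]:
            s.set(u, Stem(d=0, tau=0, p=0))
        s.set(Vertex(3, 3), Stem(d=0, tau=p.psi, p=0))
        assert stem_intent(s, Vertex(3, 3), p).kind is IntentKind.CONVERT

    def test_boundary_saturation_counts_existing_neighbors_only(self, make_params):
        # a corner stem with its 3 existing neighbors all stems converts
        p = make_params()
        s = blank(p)
        for u in (Vertex(0, 0), Vertex(0, 1), Vertex(1, 0), Vertex(1, 1)):
            s.set(u, Stem(d=0, tau=0, p=0))
        s.set(Vertex(0, 0), Stem(d=0, tau=p.psi, p=0))
        assert stem_intent(s, Vertex(0, 0), p).kind is IntentKind.CONVERT

    def test_mature_stem_proliferates_into_first_empty_clockwise(self, make_params):
        p = make_params()
        s = blank(p)
        v = Vertex(3, 3)
        s.set(v, Stem(d=0, tau=p.psi, p=0))
        it = stem_intent(s, v, p)
        assert it.kind is IntentKind.PROLIFERATE
        assert it.target == Vertex(2, 4) and it.used_direction == 0  # NE

    def test_round_robin_scan_skips_occupied_directions(self, make_params):
        p = make_params()
        s = blank(p)
        v = Vertex(3, 3)
        s.set(v, Stem(d=1, tau=p.psi, p=0))      # pointing E
        s.set(Vertex(3, 4), Differentiated(0))    # E occupied
        s.set(Vertex(4, 4), Transitive(1, 0))     # SE occupied
        it = stem_intent(s, v, p)
        assert it.target == Vertex(4, 3) and it.used_direction == 3  # S

    def test_quiesces_when_blocked_but_not_saturated(self, make_params):
        p = make_params(width=3, height=3)
        s = blank(p)
        for v in p.grid.vertices():
            s.set(v, Stem(d=0, tau=0, p=0))
        s.set(Vertex(1, 1), Stem(d=0, tau=p.psi, p=0))
        s.set(Vertex(0, 0), Transitive(1, 0))  # breaks saturation, no empty
        assert stem_intent(s, Vertex(1, 1), p).kind is IntentKind.QUIESCE

    def test_contract_violation_on_non_stem(self, make_params):
        p = make_params()
        s = blank(p)
        s.set(Vertex(1, 1), Transitive(1, 0))
        with pytest.raises(ContractViolation):
            stem_intent(s, Vertex(1, 1), p)


class TestResolveProliferation:
    def _mature(self, p, d=0):
        return Stem(d=d, tau=p.psi, p=0)

    def test_rowmajor_earlier_stem_wins_single_contested_site(self, make_params):
        # two stems flank one empty site on a 1x3 strip; both point at it
        p = make_params(width=3, height=1)
        s = blank(p)
        a, b, mid = Vertex(0, 0), Vertex(0, 2), Vertex(0, 1)
        s.set(a, Stem(d=1, tau=p.psi, p=0))  # E
        s.set(b, Stem(d=5, tau=p.psi, p=0))  # W
        intents = {v: stem_intent(s, v, p) for v in (a, b)}
        assert intents[a].target == intents[b].target == mid
        resolved = resolve_proliferation(intents, s)
        assert resolved[a].kind is IntentKind.PROLIFERATE
        assert resolved[a].target == mid
        assert resolved[b].kind is IntentKind.QUIESCE

    def test_disjoint_targets_unchanged(self, make_params):
        p = make_params()
        s = blank(p)
        a, b = Vertex(1, 1), Vertex(5, 5)
        s.set(a, self._mature(p))
        s.set(b, self._mature(p))
        intents = {v: stem_intent(s, v, p) for v in (a, b)}
        assert resolve_proliferation(intents, s) == intents

    def test_loser_rescans_to_next_empty_direction(self, make_params):
        # three stems in a row; the middle one's NE target is claimed by the
        # row-major-earlier left stem, so it re-scans and takes the next
        # empty direction clockwise.  Fixture checked by hand against the
        # stated scan order.
        p = make_params(width=5, height=3)
        s = blank(p)
        top = Vertex(0, 2)
        left, midv = Vertex(1, 0), Vertex(1, 1)
        s.set(left, Stem(d=1, tau=p.psi, p=0))   # E -> (1,1)? occupied; scans
        s.set(midv, Stem(d=0, tau=p.psi, p=0))   # NE -> (0,2)
        s.set(top, Differentiated(0))
        # left: d=1 (E) is midv (occupied) -> SE (2,1) empty -> takes (2,1)
        # midv: d=0 (NE) is top (occupied) -> E (1,2) empty -> takes (1,2)
        intents = {v: stem_intent(s, v, p) for v in (left, midv)}
        resolved = resolve_proliferation(intents, s)
        assert resolved[left].target == Vertex(2, 1)
        assert resolved[midv].target == Vertex(1, 2)

        # now contested: make midv's only empties also left's; midv loses NE
        s2 = blank(p)
        s2.set(left, Stem(d=2, tau=p.psi, p=0))   # SE -> (2,1)
        s2.set(midv, Stem(d=4, tau=p.psi, p=0))   # SW -> (2,0)
        intents2 = {v: stem_intent(s2, v, p) for v in (left, midv)}
        assert intents2[left].target == Vertex(2, 1)
        assert intents2[midv].target == Vertex(2, 0)
        resolved2 = resolve_proliferation(intents2, s2)
        # no conflict here; both stand
        assert resolved2 == intents2

    def test_loser_of_claim_proliferates_into_next_empty_direction(self, make_params):
        # A=(0,0) and B=(0,2) both target (0,1); A wins by row-major
        # priority, B re-scans clockwise from the failed direction and
        # takes its south neighbor.  Checked against hand simulation.
        p = make_params(width=3, height=3)
        s = blank(p)
        a, b = Vertex(0, 0), Vertex(0, 2)
        s.set(a, Stem(d=1, tau=p.psi, p=0))   # E -> (0,1)
        s.set(b, Stem(d=5, tau=p.psi, p=0))   # W -> (0,1)
        intents = {v: stem_intent(s, v, p) for v in (a, b)}
        assert intents[a].target == intents[b].target == Vertex(0, 1)
        resolved = resolve_proliferation(intents, s)
        assert resolved[a].target == Vertex(0, 1)
        assert resolved[b].kind is IntentKind.PROLIFERATE
        assert resolved[b].target == Vertex(1, 2)
        assert resolved[b].used_direction == 3  # S

    def test_each_empty_claimed_at_most_once(self, make_params):
        p = make_params(width=4, height=4)
        s = blank(p)
        stems = [Vertex(1, 1), Vertex(1, 2), Vertex(2, 1), Vertex(2, 2)]
        for v in stems:
            s.set(v, Stem(d=0, tau=p.psi, p=0))
        intents = {v: stem_intent(s, v, p) for v in stems}
        resolved = resolve_proliferation(intents, s)
        targets = [
            it.target for it in resolved.values()
            if it.kind is IntentKind.PROLIFERATE
        ]
        assert len(targets) == len(set(targets))


# ---------------------------------------------------------------------------
# Rules 2 and 3: transitive and differentiated cells
# ---------------------------------------------------------------------------


class TestTransitiveUpdate:
    def test_dedifferentiates_without_stem_in_near_neighborhood(self, make_params):
        p = make_params()
        s = blank(p)
        s.set(Vertex(3, 3), Transitive(1, 0))
        assert transitive_update(s, Vertex(3, 3), p) == Stem(0, 0, 0)

    def test_near_neighborhood_radius_scales_with_generation(self, make_params):
        p = make_params(m=2, eta=2, width=11, height=11)
        s = blank(p)
        v = Vertex(5, 5)
        s.set(v, Transitive(2, 1))
        s.set(Vertex(5, 9), Stem(0, 0, 0))  # distance 4 = g*eta
        assert transitive_update(s, v, p) == Transitive(2, 2)
        s2 = blank(p)
        s2.set(v, Transitive(1, 1))
        s2.set(Vertex(5, 9), Stem(0, 0, 0))  # distance 4 > 1*eta = 2
        assert transitive_update(s2, v, p) == Stem(0, 0, 0)

    def test_generation_advance_is_cumulative(self, make_params):
        p = make_params(theta=3, m=2)
        s = blank(p)
        v = Vertex(3, 3)
        s.set(v, Transitive(1, 3))  # tau = 1*theta
        s.set(Vertex(3, 4), Stem(0, 0, 0))
        assert transitive_update(s, v, p) == Transitive(2, 3)  # tau kept

    def test_last_generation_becomes_differentiated(self, make_params):
        p = make_params(theta=3, m=2)
        s = blank(p)
        v = Vertex(3, 3)
        s.set(v, Transitive(2, 6))  # tau = M*theta
        s.set(Vertex(3, 4), Stem(0, 0, 0))
        assert transitive_update(s, v, p) == Differentiated(0)

    def test_contract_violation(self, make_params):
        p = make_params()
        s = blank(p)
        s.set(Vertex(1, 1), Stem(0, 0, 0))
        with pytest.raises(ContractViolation):
            transitive_update(s, Vertex(1, 1), p)


class TestDifferentiatedUpdate:
    def test_matures_to_empty_at_phi(self, make_params):
        p = make_params(phi=4)
        s = blank(p)
        s.set(Vertex(2, 2), Differentiated(4))
        assert differentiated_update(s, Vertex(2, 2), p) == EMPTY

    def test_ticks_below_phi(self, make_params):
        p = make_params(phi=4)
        s = blank(p)
        s.set(Vertex(2, 2), Differentiated(0))
        assert differentiated_update(s, Vertex(2, 2), p) == Differentiated(1)

    def test_contract_violation(self, make_params):
        p = make_params()
        s = blank(p)
        with pytest.raises(ContractViolation):
            differentiated_update(s, Vertex(0, 0), p)


# ---------------------------------------------------------------------------
# the synchronous step operator
# ---------------------------------------------------------------------------


class TestStep:
    def test_all_empty_is_a_fixed_point(self, make_params):
        p = make_params()
        s = blank(p)
        s2, rep = step(s, p)
        assert s2.same_configuration(s) and s2.t == 1
        assert rep.n_empty == p.grid.n_vertices

    def test_single_stem_doubles_after_psi_plus_one_steps(self):
        p = Params(psi=1, theta=1, phi=1, delta=10**6, width=9, height=9)
        s = single_center_stem(p)
        for _ in range(2):
            s, rep = step(s, p)
        assert rep.n_stem == 2
        assert s[Vertex(3, 5)] == Stem(0, 0, 0)          # daughter NE of center
        assert s[Vertex(4, 4)] == Stem(1, 0, 1)          # parent advanced d

    def test_lone_exhausted_stem_leaves_empty_lattice(self, make_params):
        p = make_params(delta=2)
        s = blank(p)
        s.set(Vertex(3, 3), Stem(d=0, tau=p.psi, p=2))
        s2, rep = step(s, p)
        assert rep.deaths == 1 and rep.n_empty == p.grid.n_vertices

    def test_all_differentiated_at_phi_steps_to_all_empty(self, make_params):
        p = make_params(phi=3)
        s = blank(p)
        for v in p.grid.vertices():
            s.set(v, Differentiated(3))
        s2, rep = step(s, p)
        assert rep.emitted == p.grid.n_vertices
        assert rep.n_empty == p.grid.n_vertices

    def test_quiescent_stem_retains_pinned_counter(self, make_params):
        p = make_params(width=3, height=3)
        s = blank(p)
        for v in p.grid.vertices():
            s.set(v, Stem(d=0, tau=0, p=0))
        s.set(Vertex(1, 1), Stem(d=2, tau=p.psi, p=1))
        s.set(Vertex(0, 0), Transitive(1, 0))
        s2, rep = step(s, p)
        assert s2[Vertex(1, 1)] == Stem(d=2, tau=p.psi, p=1)
        assert rep.quiescent == 1

    def test_semigroup_property(self, make_params):
        p = make_params()
        s = random_mixture(p, seed=7)
        whole = run(s, p, 30).final
        part = run(run(s, p, 12).final, p, 18).final
        assert whole == part

    def test_event_counts_partition_stem_population(self, make_params):
        # every stem executes exactly one subrule per step
        p = make_params(delta=3)
        s = random_mixture(p, seed=3)
        for _ in range(20):
            n_stem_before = s.counts()["n_stem"]
            s, rep = step(s, p)
            ticked = n_stem_before - (
                rep.deaths + rep.stem_to_transitive + rep.proliferations
                + rep.quiescent
            )
            assert ticked >= 0
            # stems after = before - died - converted + daughters + dediff
            assert rep.n_stem == (
                n_stem_before - rep.deaths - rep.stem_to_transitive
                + rep.proliferations + rep.dedifferentiations
            )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_invariants_preserved_along_random_runs(self, seed):
        p = Params(psi=2, theta=2, phi=3, delta=4, m=2, eta=1,
                   width=6, height=6)
        s = random_mixture(p, seed=seed)
        s.validate(p)
        for _ in range(12):
            s, rep = step(s, p)
            s.validate(p)  # counters never overshoot, empties carry no state
            assert rep.proliferations <= p.grid.n_vertices

    def test_run_is_deterministic_bit_for_bit(self, make_params):
        p = make_params()
        s = random_mixture(p, seed=11)
        t1 = run(s, p, 25, record_snapshots=True)
        t2 = run(s, p, 25, record_snapshots=True)
        assert [a.state_hash() for a in t1.snapshots] == [
            b.state_hash() for b in t2.snapshots
        ]
        assert t1.reports == t2.reports

    @pytest.mark.parametrize("topology", ["bounded", "torus"])
    def test_production_step_matches_naive_reference(self, topology):
        p = Params(psi=2, theta=2, phi=3, delta=4, m=2, eta=1,
                   width=8, height=8, topology=topology)
        s = random_mixture(p, seed=5)
        cells = state_to_dict(s)
        for _ in range(30):
            s, _ = step(s, p)
            cells = ref_step(cells, p.width, p.height, topology,
                             p.psi, p.theta, p.phi, p.delta, p.m, p.eta)
            assert cells == state_to_dict(s)


def test_run_rejects_nonpositive_horizon(small_params):
    with pytest.raises(ValueError):
        run(blank(small_params), small_params, 0)


def test_params_validation():
    with pytest.raises(ValueError):
        Params(psi=0, theta=1, phi=1, delta=1)
    with pytest.raises(ValueError):
        Params(psi=1, theta=1, phi=1, delta=1, m=0)
    with pytest.raises(ValueError):
        Params(psi=1, theta=1, phi=1, delta=1, eta=0)
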