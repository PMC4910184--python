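"""Naive per-cell reference implementation of the marrow update rules.

Deliberately slow and simple — plain dicts, tuples and loops, no numpy, and
no reuse of the production engine's helpers — so it can serve as an
independent oracle for trajectory-equivalence tests.

Cell encoding: ``("E",)``, ``("S", d, tau, p)``, ``("T", g, tau)``,
``("D", tau)``.
"""

from __future__ import annotations

DIRS = ((-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0))


def ref_neighbor(width, height, topology, v, k):
    dr, dc = DIRS[k]
    r, c = v[0] + dr, v[1] + dc
    if topology == "torus":
        return (r % height, c % width)
    if 0 <= r < height and 0 <= c < width:
        return (r, c)
    return None


def ref_neighbors(width, height, topology, v):
    out = []
    for k in range(8):
        u = ref_neighbor(width, height, topology, v, k)
        if u is not None and u != v and u not in out:
            out.append(u)
    return out


def ref_distance(width, height, topology, u, v):
    dr = abs(u[0] - v[0])
    dc = abs(u[1] - v[1])
    if topology == "torus":
        dr = min(dr, height - dr)
        dc = min(dc, width - dc)
    return max(dr, dc)


def ref_step(cells, width, height, topology, psi, theta, phi, delta, m, eta):
    """One synchronous update of the whole lattice, reading only ``cells``."""
    stems = [v for v, s in cells.items() if s[0] == "S"]

    # stage proliferation claims in row-major order with re-scan
    claimed = set()
    prolif = {}
    for v in sorted(cells):
        s = cells[v]
        if s[0] != "S":
            continue
        _, d, tau, p = s
        if tau != psi or p == delta:
            continue
        nbs = ref_neighbors(width, height, topology, v)
        if all(cells[u][0] == "S" for u in nbs):
            continue
        for j in range(8):
            k = (d + j) % 8
            u = ref_neighbor(width, height, topology, v, k)
            if u is not None and cells[u][0] == "E" and u not in claimed:
                claimed.add(u)
                prolif[v] = (k, u)
                break

    new = {}
    for v in sorted(cells):
        s = cells[v]
        if s[0] == "E":
            new.setdefault(v, ("E",))
        elif s[0] == "S":
            _, d, tau, p = s
            if tau != psi:
                new[v] = ("S", d, tau + 1, p)
            elif p == delta:
                new[v] = ("E",)
            elif all(
                cells[u][0] == "S"
                for u in ref_neighbors(width, height, topology, v)
            ):
                new[v] = ("T", 1, 0)
            elif v in prolif:
                k, u = prolif[v]
                new[v] = ("S", (k + 1) % 8, 0, p + 1)
                new[u] = ("S", 0, 0, 0)
            else:
                new[v] = s  # quiescent: state retained
        elif s[0] == "T":
            _, g, tau = s
            radius = g * eta
            if not any(
                ref_distance(width, height, topology, u, v) <= radius
                for u in stems
            ):
                new[v] = ("S", 0, 0, 0)
            elif tau == g * theta:
                new[v] = ("T", g + 1, tau) if g < m else ("D", 0)
            else:
                new[v] = ("T", g, tau + 1)
        elif s[0] == "D":
            _, tau = s
            new[v] = ("E",) if tau == phi else ("D", tau + 1)
    # daughters placed by proliferation overwrite the empty default
    for k, u in prolif.values():
        new[u] = ("S", 0, 0, 0)
    return new


def state_to_dict(state):
    """Convert a production MarrowState to the reference encoding."""
    from marrowsim import Differentiated, Stem, Transitive

    out = {}
    for v in state.grid.vertices():
        cs = state[v]
        if isinstance(cs, Stem):
            out[(v.row, v.col)] = ("S", cs.d, cs.tau, cs.p)
        elif isinstance(cs, Transitive):
            out[(v.row, v.col)] = ("T", cs.g, cs.tau)
        elif isinstance(cs, Differentiated):
            out[(v.row, v.col)] = ("D", cs.tau)
        else:
            out[(v.row, v.col)] = ("E",)
    return out


def dict_equal_state(cells, state):
    return cells == state_to_dict(state)
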