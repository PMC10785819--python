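"""Exact continuous-time Markov chain analysis of tiny scission models.

For models with at most one copy per slat type, the reachable state space is
small enough to enumerate: a state is simply the set of bonds (free-monomer
pools follow from which slats hold no bonds).  This module re-derives the
transition structure directly from the model definition — occupancy,
monomer-vs-complex binding, the 3-bond locality constraint and wobble
scaling — without touching the simulation engine's incremental machinery,
builds the generator, and solves the linear first-step equations for the
exact mean first-passage time to scission.  It is the reference against
which the Gillespie engine's stochastic estimates are validated.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import ModelSpec, SiteAddress, bond as canonical_bond, mode_rate_constants

__all__ = ["enumerate_ctmc", "exact_mean_scission_time"]

State = frozenset  # of canonical site-address pairs


def _pair_rates(spec: ModelSpec, mode: str):
    k_off, k_inter, k_intra = mode_rate_constants(spec.config.rates, mode)
    won, woff = spec.config.wobble_on_factor, spec.config.wobble_off_factor
    out = {}
    for a, b in spec.compatibility:
        wob = canonical_bond(a, b) in spec.wobble_bonds
        out[canonical_bond(a, b)] = (
            k_off * (woff if wob else 1.0),
            k_intra * (won if wob else 1.0),
            k_inter * (won if wob else 1.0),
        )
    return out


def _components(bonds: State) -> dict:
    adj: dict = {}
    for a, b in bonds:
        adj.setdefault(a.slat, set()).add(b.slat)
        adj.setdefault(b.slat, set()).add(a.slat)
    comp = {}
    cid = 0
    for s in sorted(adj):
        if s in comp:
            continue
        q = deque([s])
        comp[s] = cid
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in comp:
                    comp[v] = cid
                    q.append(v)
        cid += 1
    return comp


def _within3(bonds: State, sa, sb) -> bool:
    adj: dict = {}
    for a, b in bonds:
        adj.setdefault(a.slat, set()).add(b.slat)
        adj.setdefault(b.slat, set()).add(a.slat)
    frontier = {sa}
    seen = {sa}
    for _ in range(3):
        nxt = set()
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        if sb in nxt:
            return True
        frontier = nxt
    return sb in seen


def is_scission_state(spec: ModelSpec, bonds: State) -> bool:
    """No connected component contains growth slats of both halves."""
    comp = _components(bonds)
    halves: dict = {}
    for slat, cid in comp.items():
        h = spec.half_label.get(slat)
        if h is None:
            continue
        seen = halves.setdefault(cid, set())
        seen.add(h)
        if len(seen) == 2:
            return False
    return True


def transitions(spec: ModelSpec, bonds: State, mode: str = "standard"):
    """All (rate, next_state) transitions out of one state.

    Requires every slat type to have exactly one copy; the free pool is then
    implied by bondlessness.
    """
    rates = _pair_rates(spec, mode)
    occupied = {s for pair in bonds for s in pair}
    comp = _components(bonds)
    out = []
    for pair in bonds:
        off = rates[pair][0]
        out.append((off, bonds - {pair}))
    for pair, (off, intra, inter) in rates.items():
        a, b = pair
        if a in occupied or b in occupied:
            continue
        ca, cb = comp.get(a.slat), comp.get(b.slat)
        nxt = bonds | {pair}
        if ca is not None and cb is not None:
            if ca == cb and _within3(bonds, a.slat, b.slat):
                out.append((intra, nxt))
        elif ca is not None or cb is not None:
            out.append((inter, nxt))  # one free copy stands in for the pool
    return out


def enumerate_ctmc(
    spec: ModelSpec,
    mode: str = "standard",
    *,
    max_states: int = 500_000,
):
    """Breadth-first enumeration of the reachable state space.

    Scission states are absorbing (exploration stops there).  Returns
    ``(states, index, trans)`` where ``trans[i]`` lists ``(rate, j)``.
    """
    for info in spec.slats.values():
        if info.copies != 1:
            raise ValueError(
                "exact enumeration requires one copy per slat type "
                f"({info.slat_id} has {info.copies})"
            )
    init = frozenset(spec.initial_bonds)
    states = [init]
    index = {init: 0}
    trans: list[list[tuple[float, int]]] = []
    q = deque([0])
    absorbing = []
    while q:
        i = q.popleft()
        s = states[i]
        while len(trans) <= i:
            trans.append([])
        if is_scission_state(spec, s):
            absorbing.append(i)
            trans[i] = []
            continue
        rows = []
        for rate, nxt in transitions(spec, s, mode):
            j = index.get(nxt)
            if j is None:
                j = len(states)
                if j >= max_states:
                    raise RuntimeError("state space exceeds max_states")
                index[nxt] = j
                states.append(nxt)
                q.append(j)
            rows.append((rate, j))
        trans[i] = rows
    while len(trans) < len(states):
        trans.append([])
    return states, index, trans


def exact_mean_scission_time(
    spec: ModelSpec, mode: str = "standard", *, max_states: int = 500_000
):
    """Mean first-passage time to scission from the intact state.

    Solves the first-step equations ``Q_TT tau = -1`` over transient states.
    Returns ``(tau_initial, n_states)``.
    """
    states, index, trans = enumerate_ctmc(spec, mode, max_states=max_states)
    absorbing = {
        i for i, s in enumerate(states) if is_scission_state(spec, s)
    }
    transient = [i for i in range(len(states)) if i not in absorbing]
    if not transient:
        return 0.0, len(states)
    pos = {i: k for k, i in enumerate(transient)}
    n = len(transient)
    rows, cols, vals = [], [], []
    for i in transient:
        k = pos[i]
        total = 0.0
        for rate, j in trans[i]:
            total += rate
            if j in pos:
                rows.append(k)
                cols.append(pos[j])
                vals.append(rate)
        rows.append(k)
        cols.append(k)
        vals.append(-total)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    tau = spla.spsolve(Q, -np.ones(n))
    return float(tau[pos[0]]), len(states)
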