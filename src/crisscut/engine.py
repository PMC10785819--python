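"""Exact continuous-time Monte Carlo simulation of ribbon scission.

The state is a site graph: slat instances carrying named sites, bonds between
sites, plus a pool of free monomers.  Three event kinds exist:

``unbind``
    any bond breaks at its off-rate;
``bind_inter``
    a free monomer binds a free compatible site on a complex, with propensity
    ``k_on_inter * copies`` (copy number stands in for concentration);
``bind_intra``
    two free compatible sites within one complex bind at ``k_on_intra``,
    allowed only if the two slats are connected "within two slats" — a
    bond-graph path of at most 3 bonds.  This locality constraint is the
    graph proxy for physical proximity in an otherwise geometry-free model.

Wobble-flagged growth bonds have their on-rates scaled by ``wobble_on_factor``
and off-rates by ``wobble_off_factor``; competing cut-slat bonds at the same
positions are never scaled, which biases the displacement random walk.

The implementation keeps the candidate event set grouped by rate constant so
that a Gillespie step costs O(#groups), and maintains it incrementally after
each event; ``audit`` mode re-derives the whole candidate set from scratch at
a fixed stride and asserts equality, along with per-event occupancy,
conservation and locality assertions.

Determinism contract: a run is a pure function of ``(spec, mode, seed)``.
All randomness flows through one ``random.Random(seed)`` per replicate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import NamedTuple

from .model import (
    Bond,
    ModelSpec,
    SiteAddress,
    SlatId,
    bond as canonical_bond,
    mode_rate_constants,
)

__all__ = [
    "MODE_STANDARD",
    "MODE_PREBOUND",
    "EventCandidate",
    "Trajectory",
    "SimState",
    "initial_state",
    "locality_satisfied",
    "enumerate_candidates",
    "gillespie_step",
    "run",
    "run_ensemble",
    "AuditError",
]

MODE_STANDARD = "standard"
MODE_PREBOUND = "prebound"

KIND_UNBIND = "unbind"
KIND_INTER = "bind_inter"
KIND_INTRA = "bind_intra"

#: locality constraint: bond-graph path of at most this many bonds
#: (= at most two intermediate slats)
LOCALITY_BONDS = 3


class AuditError(AssertionError):
    pass


class EventCandidate(NamedTuple):
    kind: str
    site_a: SiteAddress  # for bind_inter: the free-monomer-type site
    site_b: SiteAddress  # the in-complex site
    propensity: float


@dataclass
class Trajectory:
    """Observables of a single replicate.

    ``samples`` rows are ``(t, tracked_size, n_complexes, largest_size,
    n_bridging)`` recorded at t=0 and whenever the complex partition changes
    (sizes, count, or half-bridging).  ``scission_time`` is the half-label
    ground truth: the first time no complex contains growth slats of both
    halves; ``products`` are the growth-slat counts of the two largest
    complexes at that moment.
    """

    samples: list[tuple[float, int, int, int, int]]
    seed: int
    mode: str
    termination: str  # scission | t_max | event_max | no_events
    scission_time: float | None
    products: tuple[int, int] | None
    n_events: int
    final_t: float
    events: list[tuple[float, str, str, str]] | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.samples,
            columns=[
                "time",
                "tracked_complex_size",
                "n_complexes",
                "largest_complex_size",
                "n_bridging",
            ],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Group:
    """Candidate events sharing one propensity coefficient.

    ``weight = rate * mult * len(items)``; ``mult`` is 1 except for
    inter-binding groups where it tracks the monomer pool count.
    """

    __slots__ = ("rate", "mult", "items", "pos")

    def __init__(self, rate: float):
        self.rate = rate
        self.mult = 1
        self.items: list = []
        self.pos: dict = {}

    @property
    def weight(self) -> float:
        return self.rate * self.mult * len(self.items) if self.mult else 0.0

    def add(self, item) -> None:
        if item in self.pos:
            raise AuditError(f"duplicate candidate {item}")
        self.pos[item] = len(self.items)
        self.items.append(item)

    def discard(self, item) -> bool:
        i = self.pos.pop(item, None)
        if i is None:
            return False
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i
        return True


def _bits(mask: int):
    while mask:
        b = mask & -mask
        yield b.bit_length() - 1
        mask ^= b


class SimState:
    """Dynamic simulation state bound to one compiled model.

    Not normally constructed directly — use :func:`initial_state`.
    """

    def __init__(
        self,
        spec: ModelSpec,
        mode: str = MODE_STANDARD,
        seed: int = 0,
        *,
        recycle_displaced: bool = True,
        audit: bool = False,
        audit_stride: int = 2000,
        record_events: bool = False,
    ):
        if mode not in (MODE_STANDARD, MODE_PREBOUND):
            raise ValueError(f"unknown mode {mode!r}")
        self.spec = spec
        self.mode = mode
        self.seed = seed
        self.rng = random.Random(seed)
        self.recycle_displaced = recycle_displaced
        self.audit = audit
        self.audit_stride = audit_stride
        self.t = 0.0
        self.n_events = 0
        self.event_log: list | None = [] if record_events else None

        self._compile(spec, mode)
        self._init_state()
        if mode == MODE_PREBOUND:
            self._prebind()
        self._build_candidates()
        if self.audit:
            self._full_audit()

    # ------------------------------------------------------------------
    # static compilation
    def _compile(self, spec: ModelSpec, mode: str) -> None:
        k_off, k_inter, k_intra = mode_rate_constants(spec.config.rates, mode)
        won, woff = spec.config.wobble_on_factor, spec.config.wobble_off_factor

        self.type_ids: dict[SlatId, int] = {}
        self.type_slat: list[SlatId] = []
        self.type_sites: list[tuple[SiteAddress, ...]] = []
        self.type_copies: list[int] = []
        self.type_is_growth: list[bool] = []
        self.type_half: list[str | None] = []
        site_key: dict[SiteAddress, tuple[int, int]] = {}
        for info in spec.slats.values():
            tid = len(self.type_slat)
            self.type_ids[info.slat_id] = tid
            self.type_slat.append(info.slat_id)
            self.type_sites.append(info.sites)
            self.type_copies.append(info.copies)
            self.type_is_growth.append(info.slat_id.is_growth)
            self.type_half.append(spec.half_label.get(info.slat_id, info.half))
            for ofs, s in enumerate(info.sites):
                site_key[s] = (tid, ofs)
        self._site_key = site_key
        self.S = max(len(s) for s in self.type_sites)  # gid block size

        # per-type compatibility with per-pair rates
        n_types = len(self.type_slat)
        self.compat: list[list[list[tuple[int, int, float, float, float]]]] = [
            [[] for _ in self.type_sites[t]] for t in range(n_types)
        ]
        for a, b in sorted(spec.compatibility):
            wob = canonical_bond(a, b) in spec.wobble_bonds
            off = k_off * (woff if wob else 1.0)
            intra = k_intra * (won if wob else 1.0)
            inter = k_inter * (won if wob else 1.0)
            (ta, oa), (tb, ob) = site_key[a], site_key[b]
            self.compat[ta][oa].append((tb, ob, off, intra, inter))
            self.compat[tb][ob].append((ta, oa, off, intra, inter))

    # ------------------------------------------------------------------
    # state initialisation
    def _init_state(self) -> None:
        spec = self.spec
        self.inst_tid: list[int] = []
        self.inst_alive: list[bool] = []
        self._free_inst: list[int] = []
        self.bond_of: list[int] = []  # gid -> partner gid or -1
        self.nbr: list[int] = []  # inst -> neighbour bitmask
        self.paircnt: dict[tuple[int, int], int] = {}
        self.pool: list[int] = list(self.type_copies)
        self.deleted: list[int] = [0] * len(self.type_copies)
        self.inst_of_type: list[set[int]] = [set() for _ in self.type_copies]
        self.comp_of: list[int] = []
        self.comps: dict[int, list[int]] = {}  # cid -> [size, nA, nB]
        self._next_cid = 0
        self._split_flag = False

        ribbon = [t for t in range(len(self.type_slat)) if self.type_is_growth[t]]
        cid = self._new_comp()
        for tid in ribbon:
            inst = self._new_instance(tid)
            self.pool[tid] -= 1
            self._join_comp(inst, cid)
        for a, b in sorted(spec.initial_bonds):
            self._set_bond(self._gid_of_addr(a), self._gid_of_addr(b))
        self._refresh_bridging()
        self.samples: list[tuple[float, int, int, int, int]] = []
        self._record_sample()

    def _prebind(self) -> None:
        # one copy of each cut type bound by all its toeholds
        cid = next(iter(self.comps))
        for tid in range(len(self.type_slat)):
            if self.type_is_growth[tid]:
                continue
            inst = self._new_instance(tid)
            self.pool[tid] -= 1
            self._join_comp(inst, cid)
            for ofs, s in enumerate(self.type_sites[tid]):
                if s.role != "toehold":
                    continue
                (pt, po, *_rest) = self.compat[tid][ofs][0]
                host_inst = self._only_inst(pt)
                self._set_bond(inst * self.S + ofs, host_inst * self.S + po)
        self._refresh_bridging()
        self.samples = []
        self._record_sample()

    # ------------------------------------------------------------------
    # low-level state helpers
    def _new_instance(self, tid: int) -> int:
        if self._free_inst:
            inst = self._free_inst.pop()
            self.inst_tid[inst] = tid
            self.inst_alive[inst] = True
            base = inst * self.S
            for g in range(base, base + self.S):
                self.bond_of[g] = -1
            self.nbr[inst] = 0
            self.comp_of[inst] = -1
        else:
            inst = len(self.inst_tid)
            self.inst_tid.append(tid)
            self.inst_alive.append(True)
            self.bond_of.extend([-1] * self.S)
            self.nbr.append(0)
            self.comp_of.append(-1)
        self.inst_of_type[tid].add(inst)
        return inst

    def _destroy_instance(self, inst: int) -> None:
        tid = self.inst_tid[inst]
        self.inst_of_type[tid].discard(inst)
        self.inst_alive[inst] = False
        self.comp_of[inst] = -1
        self._free_inst.append(inst)

    def _only_inst(self, tid: int) -> int:
        (inst,) = self.inst_of_type[tid]
        return inst

    def _gid_of_addr(self, s: SiteAddress) -> int:
        tid, ofs = self._site_key[s]
        return self._only_inst(tid) * self.S + ofs

    def addr_of_gid(self, gid: int) -> SiteAddress:
        inst, ofs = divmod(gid, self.S)
        return self.type_sites[self.inst_tid[inst]][ofs]

    def _set_bond(self, a: int, b: int) -> None:
        if self.bond_of[a] != -1 or self.bond_of[b] != -1:
            raise AuditError("occupancy violation: binding an occupied site")
        self.bond_of[a] = b
        self.bond_of[b] = a
        u, v = a // self.S, b // self.S
        key = (u, v) if u < v else (v, u)
        c = self.paircnt.get(key, 0)
        self.paircnt[key] = c + 1
        if c == 0:
            self.nbr[u] |= 1 << v
            self.nbr[v] |= 1 << u

    def _clear_bond(self, a: int, b: int) -> bool:
        """Remove bond; return True if the slat-pair edge disappeared."""
        self.bond_of[a] = -1
        self.bond_of[b] = -1
        u, v = a // self.S, b // self.S
        key = (u, v) if u < v else (v, u)
        c = self.paircnt[key] - 1
        if c:
            self.paircnt[key] = c
            return False
        del self.paircnt[key]
        self.nbr[u] &= ~(1 << v)
        self.nbr[v] &= ~(1 << u)
        return True

    # components -------------------------------------------------------
    def _new_comp(self) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.comps[cid] = [0, 0, 0]
        return cid

    def _join_comp(self, inst: int, cid: int) -> None:
        self.comp_of[inst] = cid
        rec = self.comps[cid]
        rec[0] += 1
        tid = self.inst_tid[inst]
        if self.type_is_growth[tid]:
            rec[1 if self.type_half[tid] == "A" else 2] += 1

    def _leave_comp(self, inst: int) -> None:
        cid = self.comp_of[inst]
        rec = self.comps[cid]
        rec[0] -= 1
        tid = self.inst_tid[inst]
        if self.type_is_growth[tid]:
            rec[1 if self.type_half[tid] == "A" else 2] -= 1
        if rec[0] == 0:
            del self.comps[cid]
        self.comp_of[inst] = -1

    def _refresh_bridging(self) -> None:
        self.n_bridging = sum(1 for s, a, b in self.comps.values() if a and b)

    # locality ---------------------------------------------------------
    def _local3(self, u: int, v: int) -> bool:
        """Bond-graph path of <= 3 bonds between slat instances u and v."""
        nu = self.nbr[u]
        if (nu >> v) & 1:
            return True
        nv = self.nbr[v]
        if nu & nv:
            return True
        for x in _bits(nu):
            if self.nbr[x] & nv:
                return True
        return False

    def _n2_mask(self, u: int) -> int:
        m = (1 << u) | self.nbr[u]
        for x in _bits(self.nbr[u]):
            m |= self.nbr[x]
        return m

    # ------------------------------------------------------------------
    # candidate bookkeeping
    def _build_candidates(self) -> None:
        self.groups: dict = {}
        self._inter_keys_of_type: dict[int, list] = {}
        self.watch: dict[tuple[int, int], tuple[float, bool]] = {}
        self._watch_by_inst: dict[int, set] = {}
        self.total_weight = 0.0
        gk, watch = self._scratch_candidates()
        for key, items in gk.items():
            g = self._group(key)
            for it in items:
                g.add(it)
        for item, (rate, elig) in watch.items():
            self._watch_add(item, rate, elig)
        self._resync_total()

    def _group(self, key) -> _Group:
        g = self.groups.get(key)
        if g is None:
            g = _Group(key[-1])
            if key[0] == KIND_INTER:
                tid = key[1]
                g.mult = self.pool[tid]
                self._inter_keys_of_type.setdefault(tid, []).append(key)
            self.groups[key] = g
        return g

    def _resync_total(self) -> None:
        self.total_weight = sum(g.weight for g in self.groups.values())

    def _g_add(self, key, item) -> None:
        g = self._group(key)
        g.add(item)
        self.total_weight += g.rate * g.mult

    def _g_discard(self, key, item) -> None:
        g = self.groups.get(key)
        if g is not None and g.discard(item):
            self.total_weight -= g.rate * g.mult

    def _pool_change(self, tid: int, new: int) -> None:
        self.pool[tid] = new
        for key in self._inter_keys_of_type.get(tid, ()):
            g = self.groups[key]
            self.total_weight += g.rate * len(g.items) * (new - g.mult)
            g.mult = new

    # watch = compatible free same-complex site pairs; eligible ones are
    # also members of their intra group
    def _watch_add(self, item, rate: float, elig: bool) -> None:
        self.watch[item] = (rate, elig)
        a, b = item
        self._watch_by_inst.setdefault(a // self.S, set()).add(item)
        self._watch_by_inst.setdefault(b // self.S, set()).add(item)
        if elig:
            self._g_add((KIND_INTRA, rate), item)

    def _watch_discard(self, item) -> None:
        rec = self.watch.pop(item, None)
        if rec is None:
            return
        rate, elig = rec
        a, b = item
        for inst in (a // self.S, b // self.S):
            s = self._watch_by_inst.get(inst)
            if s is not None:
                s.discard(item)
                if not s:
                    del self._watch_by_inst[inst]
        if elig:
            self._g_discard((KIND_INTRA, rate), item)

    def _site_freed(self, gid: int) -> None:
        """Register candidates for a newly free in-complex site."""
        inst, ofs = divmod(gid, self.S)
        tid = self.inst_tid[inst]
        for pt, po, off, intra, inter in self.compat[tid][ofs]:
            if self.pool[pt] > 0 or pt in self._inter_keys_of_type:
                key = (KIND_INTER, pt, inter)
                g = self._group(key)
                # the departure path (_expose_type_inter) may have registered
                # this site already within the same event
                if (gid, po) not in g.pos:
                    self._g_add(key, (gid, po))
            my_cid = self.comp_of[inst]
            for pinst in self.inst_of_type[pt]:
                pgid = pinst * self.S + po
                if self.bond_of[pgid] != -1:
                    continue
                if self.comp_of[pinst] != my_cid:
                    continue
                item = (gid, pgid) if gid < pgid else (pgid, gid)
                if item in self.watch:
                    continue
                self._watch_add(item, intra, self._local3(inst, pinst))

    def _site_occupied(self, gid: int) -> None:
        """Drop candidates that referenced this now-bound (or gone) site."""
        inst, ofs = divmod(gid, self.S)
        tid = self.inst_tid[inst]
        for pt, po, off, intra, inter in self.compat[tid][ofs]:
            self._g_discard((KIND_INTER, pt, inter), (gid, po))
        for item in list(self._watch_by_inst.get(inst, ())):
            if gid in item:
                self._watch_discard(item)

    def _drop_inst_candidates(self, inst: int) -> None:
        base = inst * self.S
        tid = self.inst_tid[inst]
        for ofs in range(len(self.type_sites[tid])):
            gid = base + ofs
            for pt, po, off, intra, inter in self.compat[tid][ofs]:
                self._g_discard((KIND_INTER, pt, inter), (gid, po))
        for item in list(self._watch_by_inst.get(inst, ())):
            self._watch_discard(item)

    def _recheck_locality_near(self, n2u: int, n2v: int) -> None:
        for item in list(self.watch):
            a, b = item
            ia, ib = a // self.S, b // self.S
            if not (
                ((n2u >> ia) & 1 and (n2v >> ib) & 1)
                or ((n2v >> ia) & 1 and (n2u >> ib) & 1)
            ):
                continue
            rate, elig = self.watch[item]
            now = self._local3(ia, ib)
            if now == elig:
                continue
            self.watch[item] = (rate, now)
            if now:
                self._g_add((KIND_INTRA, rate), item)
            else:
                self._g_discard((KIND_INTRA, rate), item)

    def _pair_rates(self, a_gid: int, b_gid: int) -> tuple[float, float, float]:
        inst, ofs = divmod(a_gid, self.S)
        bt, bo = self.inst_tid[b_gid // self.S], b_gid % self.S
        for pt, po, off, intra, inter in self.compat[self.inst_tid[inst]][ofs]:
            if pt == bt and po == bo:
                return off, intra, inter
        raise AuditError("incompatible site pair")

    # ------------------------------------------------------------------
    # event application
    def _apply_unbind(self, a: int, b: int, off_rate: float) -> None:
        self._g_discard((KIND_UNBIND, off_rate), (a, b) if a < b else (b, a))
        u, v = a // self.S, b // self.S
        n2u, n2v = self._n2_mask(u), self._n2_mask(v)  # pre-removal supersets
        edge_gone = self._clear_bond(a, b)
        if edge_gone and not self._local3(u, v):
            self._maybe_split(u, v)
        changed = False
        for w, g in ((u, a), (v, b)):
            if self.nbr[w] == 0:
                self._depart(w)
                changed = True
        if self.inst_alive[u]:
            self._site_freed(a)
        if self.inst_alive[v]:
            self._site_freed(b)
        self._recheck_locality_near(n2u, n2v)
        if changed or self._split_flag:
            self._refresh_bridging()
            self._record_sample()

    def _maybe_split(self, u: int, v: int) -> None:
        # BFS from u; if v unreached, the reached side becomes a new complex
        seen = 1 << u
        frontier = [u]
        while frontier:
            nxt = []
            for x in frontier:
                m = self.nbr[x] & ~seen
                seen |= m
                nxt.extend(_bits(m))
            frontier = nxt
        if (seen >> v) & 1:
            return
        cid = self._new_comp()
        for inst in _bits(seen):
            self._leave_comp(inst)
            self._join_comp(inst, cid)
        # watch pairs that now straddle the two complexes are no longer
        # intra-bind material
        for inst in _bits(seen):
            for item in list(self._watch_by_inst.get(inst, ())):
                x, y = item
                if self.comp_of[x // self.S] != self.comp_of[y // self.S]:
                    self._watch_discard(item)
        self._split_flag = True

    def _depart(self, inst: int) -> None:
        """A slat whose last bond broke leaves its complex."""
        tid = self.inst_tid[inst]
        self._drop_inst_candidates(inst)
        self._leave_comp(inst)
        self._destroy_instance(inst)
        if self.recycle_displaced:
            new = self.pool[tid] + 1
            if new == 1:
                # pool transition 0 -> 1: expose inter candidates for this type
                self._pool_change(tid, 1)
                self._expose_type_inter(tid)
            else:
                self._pool_change(tid, new)
        else:
            self.deleted[tid] += 1

    def _expose_type_inter(self, tid: int) -> None:
        for ofs in range(len(self.type_sites[tid])):
            for pt, po, off, intra, inter in self.compat[tid][ofs]:
                for pinst in self.inst_of_type[pt]:
                    pgid = pinst * self.S + po
                    if self.bond_of[pgid] == -1:
                        key = (KIND_INTER, tid, inter)
                        g = self._group(key)
                        if (pgid, ofs) not in g.pos:
                            self._g_add(key, (pgid, ofs))

    def _apply_bind_intra(self, a: int, b: int) -> None:
        u, v = a // self.S, b // self.S
        off, intra, inter = self._pair_rates(a, b)
        if self.audit and not self._local3(u, v):
            raise AuditError("locality violation on applied bind_intra")
        self._site_occupied(a)
        self._site_occupied(b)
        self._set_bond(a, b)
        self._g_add((KIND_UNBIND, off), (a, b) if a < b else (b, a))
        self._recheck_locality_near(self._n2_mask(u), self._n2_mask(v))

    def _apply_bind_inter(self, target: int, ptid: int, pofs: int) -> None:
        off, intra, inter = None, None, None
        for pt, po, o, ia, ie in self.compat[ptid][pofs]:
            tgt_t, tgt_o = self.inst_tid[target // self.S], target % self.S
            if pt == tgt_t and po == tgt_o:
                off, intra, inter = o, ia, ie
                break
        if off is None:
            raise AuditError("bind_inter on incompatible pair")
        self._pool_change(ptid, self.pool[ptid] - 1)
        inst = self._new_instance(ptid)
        self._join_comp(inst, self.comp_of[target // self.S])
        a = inst * self.S + pofs
        self._site_occupied(target)
        self._set_bond(a, target)
        self._g_add((KIND_UNBIND, off), (a, target) if a < target else (target, a))
        # remaining sites of the new instance are now in-complex free sites
        for ofs in range(len(self.type_sites[ptid])):
            if ofs != pofs:
                self._site_freed(inst * self.S + ofs)
        self._recheck_locality_near(
            self._n2_mask(inst), self._n2_mask(target // self.S)
        )
        self._refresh_bridging()
        self._record_sample()

    # ------------------------------------------------------------------
    # stepping
    def _select(self, r: float):
        cum = 0.0
        last = None
        for key, g in self.groups.items():
            w = g.weight
            if not w:
                continue
            last = (key, g, cum)
            if r < cum + w:
                break
            cum += w
        if last is None:
            return None
        key, g, cum = last
        idx = int((r - cum) / (g.rate * g.mult))
        if idx < 0:
            idx = 0
        elif idx >= len(g.items):
            idx = len(g.items) - 1
        return key, g.items[idx]

    def sample_candidate(self, u: float):
        """Pick a candidate for uniform u in [0, 1) without applying it."""
        return self._select(u * self.total_weight)

    def step(self) -> str | None:
        """Advance by one Gillespie event; returns event kind or None."""
        if self.n_events % 4096 == 0:
            self._resync_total()
        if self.total_weight <= 0.0:
            return None
        dt = self.rng.expovariate(self.total_weight)
        picked = self._select(self.rng.random() * self.total_weight)
        if picked is None:
            return None
        self.t += dt
        key, item = picked
        kind = key[0]
        self._split_flag = False
        if self.event_log is not None:
            self._log_event(kind, key, item)
        if kind == KIND_UNBIND:
            a, b = item
            self._apply_unbind(a, b, key[1])
        elif kind == KIND_INTRA:
            a, b = item
            self._apply_bind_intra(a, b)
        else:
            target, pofs = item
            self._apply_bind_inter(target, key[1], pofs)
        self.n_events += 1
        if self.audit:
            self._event_audit(key, item)
            if self.n_events % self.audit_stride == 0:
                self._full_audit()
        return kind

    def _log_event(self, kind, key, item) -> None:
        if kind == KIND_INTER:
            target, pofs = item
            a = str(self.type_sites[key[1]][pofs])
            b = str(self.addr_of_gid(target))
        else:
            a = str(self.addr_of_gid(item[0]))
            b = str(self.addr_of_gid(item[1]))
        self.event_log.append((self.t, kind, a, b))

    # ------------------------------------------------------------------
    # observables
    def _tracked_size(self) -> int:
        # the complex holding the half-A anchor growth slat
        anchor = self.type_ids[min(s for s in self.spec.half_label)]
        insts = self.inst_of_type[anchor]
        if not insts:
            return 0
        cid = self.comp_of[next(iter(insts))]
        return self.comps[cid][0] if cid in self.comps else 0

    def _record_sample(self) -> None:
        largest = max((rec[0] for rec in self.comps.values()), default=0)
        self.samples.append(
            (self.t, self._tracked_size(), len(self.comps), largest, self.n_bridging)
        )

    def growth_product_sizes(self) -> tuple[int, ...]:
        """Growth-slat counts of complexes, largest first."""
        return tuple(
            sorted((rec[1] + rec[2] for rec in self.comps.values()), reverse=True)
        )

    # public views ------------------------------------------------------
    @property
    def bonds(self) -> set[tuple[SiteAddress, SiteAddress]]:
        out = set()
        for a, p in enumerate(self.bond_of):
            if p > a:
                out.add(canonical_bond(self.addr_of_gid(a), self.addr_of_gid(p)))
        return out

    @property
    def pool_counts(self) -> dict[SlatId, int]:
        return {self.type_slat[t]: c for t, c in enumerate(self.pool)}

    @property
    def complexes(self) -> list[set[str]]:
        by_cid: dict[int, set[str]] = {}
        for inst, alive in enumerate(self.inst_alive):
            if alive:
                sid = self.type_slat[self.inst_tid[inst]]
                by_cid.setdefault(self.comp_of[inst], set()).add(f"{sid}#{inst}")
        return [by_cid[c] for c in sorted(by_cid)]

    def fingerprint(self) -> tuple:
        """Hashable full-state digest (used by determinism tests)."""
        return (
            round(self.t, 12),
            tuple(self.bond_of),
            tuple(self.pool),
            tuple(sorted((tuple(sorted(_bits(self.nbr[i]))) for i in range(len(self.nbr))))),
        )

    # ------------------------------------------------------------------
    # audits
    def _scratch_candidates(self):
        """Derive the full candidate set from the bare state (no groups)."""
        gk: dict = {}
        watch: dict = {}

        def put(key, item):
            gk.setdefault(key, set()).add(item)

        n_inst = len(self.inst_tid)
        for a in range(len(self.bond_of)):
            p = self.bond_of[a]
            if p > a:
                off, intra, inter = self._pair_rates(a, p)
                put((KIND_UNBIND, off), (a, p))
        for inst in range(n_inst):
            if not self.inst_alive[inst]:
                continue
            tid = self.inst_tid[inst]
            for ofs in range(len(self.type_sites[tid])):
                gid = inst * self.S + ofs
                if self.bond_of[gid] != -1:
                    continue
                for pt, po, off, intra, inter in self.compat[tid][ofs]:
                    if self.pool[pt] > 0:
                        put((KIND_INTER, pt, inter), (gid, po))
                    for pinst in self.inst_of_type[pt]:
                        pgid = pinst * self.S + po
                        if self.bond_of[pgid] != -1:
                            continue
                        if self.comp_of[pinst] != self.comp_of[inst]:
                            continue
                        item = (gid, pgid) if gid < pgid else (pgid, gid)
                        watch[item] = (intra, self._local3(inst, pinst))
        for item, (rate, elig) in watch.items():
            if elig:
                put((KIND_INTRA, rate), item)
        return gk, watch

    def _event_audit(self, key, item) -> None:
        # occupancy symmetry at the touched sites (full sweep in _full_audit)
        if key[0] != KIND_INTER:
            for g in item:
                p = self.bond_of[g]
                if p != -1 and self.bond_of[p] != g:
                    raise AuditError("bond symmetry broken")
        # exact agent conservation, every type, every event
        for tid in range(len(self.type_slat)):
            total = self.pool[tid] + len(self.inst_of_type[tid]) + self.deleted[tid]
            if total != self.type_copies[tid]:
                raise AuditError(
                    f"conservation broken for {self.type_slat[tid]}: {total} != "
                    f"{self.type_copies[tid]}"
                )

    def _full_audit(self) -> None:
        for a, p in enumerate(self.bond_of):
            if p != -1 and self.bond_of[p] != a:
                raise AuditError("bond symmetry broken")
        gk, watch = self._scratch_candidates()
        mine = {
            key: set(g.items) for key, g in self.groups.items() if g.items
        }
        # inter groups with zero pool are retained incrementally but carry
        # zero weight; scratch enumeration drops them
        for key in list(mine):
            if key[0] == KIND_INTER and self.pool[key[1]] == 0:
                del mine[key]
        if mine != {k: v for k, v in gk.items() if v}:
            for key in set(mine) | set(gk):
                a, b = mine.get(key, set()), gk.get(key, set())
                if a != b:
                    raise AuditError(
                        f"candidate set mismatch in group {key}: "
                        f"incremental-only {a - b}, scratch-only {b - a}"
                    )
        if watch != self.watch:
            raise AuditError("watch set mismatch against scratch enumeration")
        expect = sum(g.weight for g in self.groups.values())
        if abs(expect - self.total_weight) > 1e-6 * max(1.0, expect):
            raise AuditError("total propensity drift")


# ---------------------------------------------------------------------------
# module-level operations


def initial_state(
    spec: ModelSpec, mode: str = MODE_STANDARD, seed: int = 0, **kw
) -> SimState:
    """Construct the starting state for one replicate.

    ``standard``: intact ribbon, all cut slats free in the pool.
    ``prebound``: one copy of each cut type additionally starts bound by all
    of its toeholds (and the prebound rate set is active).
    """
    return SimState(spec, mode, seed, **kw)


def locality_satisfied(state: SimState, slat_a: SlatId, slat_b: SlatId) -> bool:
    """Whether two in-complex slats are connected within two intermediate
    slats (path of <= 3 bonds), computed on the current bond graph."""
    insts = []
    for s in (slat_a, slat_b):
        sid = SlatId(*s)
        live = state.inst_of_type[state.type_ids[sid]]
        if not live:
            raise ValueError(f"slat {sid} is free in the pool, not in a complex")
        insts.append(next(iter(live)))
    ia, ib = insts
    if state.comp_of[ia] != state.comp_of[ib] or state.comp_of[ia] == -1:
        raise ValueError("locality is undefined across complexes")
    # breadth-first search, independent of the engine's mask shortcut
    frontier = {ia}
    seen = {ia}
    for _ in range(LOCALITY_BONDS):
        nxt = set()
        for x in frontier:
            for y in _bits(state.nbr[x]):
                if y not in seen:
                    seen.add(y)
                    nxt.add(y)
        if ib in nxt:
            return True
        frontier = nxt
    return ib in seen


def enumerate_candidates(state: SimState, spec: ModelSpec | None = None):
    """All current event candidates, derived from scratch.

    This is the reference enumeration (also used by the audit machinery and
    the exact-CTMC oracle); the engine's incremental event set must always
    agree with it.
    """
    gk, _watch = state._scratch_candidates()
    out = []
    for key, items in sorted(gk.items(), key=lambda kv: repr(kv[0])):
        kind = key[0]
        for item in sorted(items):
            if kind == KIND_INTER:
                tid, rate = key[1], key[2]
                gid, pofs = item
                out.append(
                    EventCandidate(
                        kind,
                        state.type_sites[tid][pofs],
                        state.addr_of_gid(gid),
                        rate * state.pool[tid],
                    )
                )
            else:
                a, b = item
                out.append(
                    EventCandidate(
                        kind, state.addr_of_gid(a), state.addr_of_gid(b), key[1]
                    )
                )
    return out


def gillespie_step(state: SimState, spec: ModelSpec | None = None):
    """Advance one event; returns ``(kind, state)`` or ``(None, state)``
    when no events remain."""
    return state.step(), state


def run(
    spec: ModelSpec,
    mode: str = MODE_STANDARD,
    seed: int = 0,
    *,
    t_max: float = float("inf"),
    event_max: int | None = None,
    stop_on_scission: bool = True,
    audit: bool = False,
    audit_stride: int = 2000,
    record_events: bool = False,
    recycle_displaced: bool = True,
) -> Trajectory:
    """Simulate one replicate until scission, ``t_max``, ``event_max`` or
    candidate exhaustion; deterministic given ``(spec, mode, seed)``."""
    st = SimState(
        spec,
        mode,
        seed,
        audit=audit,
        audit_stride=audit_stride,
        record_events=record_events,
        recycle_displaced=recycle_displaced,
    )
    scission_t: float | None = None
    products = None
    if st.n_bridging == 0:  # degenerate: already separated at t = 0
        scission_t = 0.0
        sizes = st.growth_product_sizes()
        products = (sizes + (0, 0))[:2]
    termination = "t_max"
    while True:
        if scission_t is not None and stop_on_scission:
            termination = "scission"
            break
        if event_max is not None and st.n_events >= event_max:
            termination = "event_max"
            break
        kind = st.step()
        if kind is None:
            termination = "no_events"
            break
        if st.t > t_max:
            termination = "t_max"
            break
        if scission_t is None and st.n_bridging == 0:
            scission_t = st.t
            sizes = st.growth_product_sizes()
            products = (sizes + (0, 0))[:2]
    st._record_sample()
    return Trajectory(
        samples=st.samples,
        seed=seed,
        mode=mode,
        termination=termination,
        scission_time=scission_t,
        products=products,
        n_events=st.n_events,
        final_t=st.t,
        events=st.event_log,
    )


def run_ensemble(
    spec: ModelSpec,
    mode: str,
    n_replicates: int,
    base_seed: int,
    **run_kw,
) -> list[Trajectory]:
    """Independent replicates with seeds ``base_seed + r``; order-stable."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [run(spec, mode, base_seed + r, **run_kw) for r in range(n_replicates)]
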