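"""Coarse growth-fragmentation model of exponential ribbon amplification.

Ribbon elongation is treated as deterministic continuous growth (rate ``v``
per growing end) and scission as single stochastic events at fixed material
intervals: a cut site exists at every multiple of ``delta`` along a ribbon
and arms — its exponential clock (hazard ``lam``) starts — when the ribbon
first grows past ``site + delta``, i.e. when the repeat distal to the
interface is complete and can recruit its cut slats.  A firing splits the
ribbon in two; the proximal fragment gains a fresh growth front at the cut,
so every fragment keeps exactly one growing end.  In the fast-cutting limit
this reduces to exact binary fission: every fragment is born at length
``delta``, splits on reaching ``2 * delta``, and the population doubles
every ``delta / v`` — the doubling logic of the crisscross chain reaction.

The simulation is event-driven and exact: between events all lengths are
affine in time, so arming times are computed in closed form and the only
random draws are the per-site exponential delays.  ``lam = 0`` disables
cutting; ``lam = inf`` fires each site the instant it arms.
"""

from __future__ import annotations

import heapq
import math
import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoarseParams",
    "PopulationTrajectory",
    "simulate_population",
    "amplification_metrics",
]


@dataclass(frozen=True)
class CoarseParams:
    """Parameters of the continuous-growth / stochastic-cut model.

    ``v``: growth rate (length per time per growing end); ``delta``: material
    interval between cut sites (one ribbon repeat); ``lam``: per-site cut
    hazard once armed (may be ``math.inf`` for instantaneous cutting);
    ``ell0``: initial length of the single seeded ribbon.
    """

    v: float = 1.0
    delta: float = 1.0
    lam: float = 1.0
    t_max: float = 10.0
    seed: int = 0
    ell0: float = 0.0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("growth rate v must be > 0")
        if self.delta <= 0:
            raise ValueError("cut interval delta must be > 0")
        if self.lam < 0:
            raise ValueError("cut hazard lam must be >= 0")
        if self.ell0 < 0:
            raise ValueError("initial length must be >= 0")


@dataclass
class PopulationTrajectory:
    """Ribbon population over time.

    ``samples`` rows are ``(t, count, total_mass)`` at t=0, at every cut
    event, and at ``t_max``.  ``final_lengths`` is the full fragment-length
    list at ``t_max``.  ``cut_events`` records ``(t, parent_length,
    child_a, child_b)`` for every scission (children sum exactly to the
    parent: mass is conserved at cuts).
    """

    params: CoarseParams
    samples: list[tuple[float, int, float]]
    final_lengths: list[float]
    cut_events: list[tuple[float, float, float, float]]

    @property
    def final_count(self) -> int:
        return len(self.final_lengths)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples, columns=["time", "count", "mass"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Ribbon:
    __slots__ = ("rid", "t_ref", "len_ref", "armed", "next_site", "alive")

    def __init__(self, rid, t_ref, len_ref, armed, next_site):
        self.rid = rid
        self.t_ref = t_ref
        self.len_ref = len_ref
        self.armed = armed  # pos -> absolute fire time (inf if lam == 0)
        self.next_site = next_site  # next unarmed site position
        self.alive = True

    def length(self, t, v):
        return self.len_ref + v * (t - self.t_ref)


def simulate_population(params: CoarseParams) -> PopulationTrajectory:
    """Exact event-driven simulation; deterministic given ``params.seed``."""
    v, delta, lam, t_max = params.v, params.delta, params.lam, params.t_max
    rng = random.Random(params.seed)

    def fire_delay() -> float:
        if lam == 0:
            return math.inf
        if math.isinf(lam):
            return 0.0
        return rng.expovariate(lam)

    ribbons: dict[int, _Ribbon] = {}
    next_rid = 0
    heap: list[tuple[float, int, str, int, float]] = []  # (t, tiebreak, kind, rid, pos)
    n_push = 0

    def push(t, kind, rid, pos):
        nonlocal n_push
        if t <= t_max and math.isfinite(t):
            heapq.heappush(heap, (t, n_push, kind, rid, pos))
            n_push += 1

    def new_ribbon(t, length, armed, next_site) -> _Ribbon:
        nonlocal next_rid
        r = _Ribbon(next_rid, t, length, armed, next_site)
        ribbons[r.rid] = r
        next_rid += 1
        for pos, ft in armed.items():
            push(ft, "fire", r.rid, pos)
        # a site arms when length first exceeds next_site + delta
        push(t + max(0.0, (next_site + delta - length)) / v, "arm", r.rid, next_site)
        return r

    # seed ribbon: sites whose distal repeat is already complete start their
    # clocks at t = 0
    seed_armed = {}
    pos = delta
    while pos + delta < params.ell0:
        seed_armed[pos] = fire_delay()
        pos += delta
    new_ribbon(0.0, params.ell0, seed_armed, pos)

    mass = params.ell0
    mass_t = 0.0
    count = 1
    samples = [(0.0, count, mass)]
    cut_events: list[tuple[float, float, float, float]] = []

    def advance_mass(t):
        nonlocal mass, mass_t
        mass += v * count * (t - mass_t)
        mass_t = t

    while heap:
        t, _, kind, rid, pos = heapq.heappop(heap)
        r = ribbons.get(rid)
        if r is None or not r.alive:
            continue
        if kind == "arm":
            if pos != r.next_site:
                continue  # stale
            r.armed[pos] = t + fire_delay()
            push(r.armed[pos], "fire", rid, pos)
            r.next_site = pos + delta
            # length(t) == pos + delta here, so the next arming is delta/v away
            push(t + (r.next_site + delta - r.length(t, v)) / v, "arm", rid, r.next_site)
        else:  # fire
            if pos not in r.armed or r.armed[pos] != t:
                continue  # stale (site moved to a child)
            parent_len = r.length(t, v)
            r.alive = False
            del ribbons[rid]
            # proximal child [0, pos]: keeps interior clocks; the junction at
            # its capped end re-arms only after a full new repeat grows past it
            armed_a = {p: ft for p, ft in r.armed.items() if p < pos}
            new_ribbon(t, pos, armed_a, pos)
            # distal child (pos, parent_len]: coordinates shift by pos
            armed_b = {p - pos: ft for p, ft in r.armed.items() if p > pos}
            new_ribbon(t, parent_len - pos, armed_b, r.next_site - pos)
            advance_mass(t)
            count += 1
            cut_events.append((t, parent_len, pos, parent_len - pos))
            samples.append((t, count, mass))

    advance_mass(t_max)
    samples.append((t_max, count, mass))
    final_lengths = sorted(r.length(t_max, v) for r in ribbons.values())
    return PopulationTrajectory(params, samples, final_lengths, cut_events)


def amplification_metrics(traj: PopulationTrajectory) -> dict:
    """Doubling-time estimate and final fragment-length histogram.

    The doubling time is the inverse slope of a least-squares fit of
    log2(count) against time over the exponential phase (samples with
    count >= 2).  The estimate is flagged low-confidence when the
    trajectory spans fewer than 3 doublings.  The histogram uses bin width
    ``delta / 4``.
    """
    params = traj.params
    t = np.array([s[0] for s in traj.samples])
    n = np.array([s[1] for s in traj.samples], dtype=float)
    doublings = math.log2(n[-1]) if n[-1] >= 1 else 0.0
    mask = n >= 2
    result: dict = {"doublings": doublings, "low_confidence": doublings < 3}
    if mask.sum() >= 2 and n[-1] > n[mask][0]:
        slope = np.polyfit(t[mask], np.log2(n[mask]), 1)[0]
        result["doubling_time"] = 1.0 / slope if slope > 0 else None
    else:
        result["doubling_time"] = None
        result["low_confidence"] = True
    lengths = np.asarray(traj.final_lengths)
    width = params.delta / 4.0
    if len(lengths):
        n_bins = max(1, int(math.ceil(lengths.max() / width)))
        counts, edges = np.histogram(lengths, bins=n_bins, range=(0.0, n_bins * width))
    else:
        counts, edges = np.array([]), np.array([0.0])
    result["histogram"] = (counts, edges)
    result["mean_length"] = float(lengths.mean()) if len(lengths) else math.nan
    return result
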