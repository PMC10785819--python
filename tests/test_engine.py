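"""Engine tests: initial states, locality, candidate statistics, audits,
determinism, and semantic agreement with the independent CTMC transition
enumeration."""

import math
import random

import networkx as nx
import pytest
import scipy.stats

from crisscut import (
    BuildConfig,
    build_scission_model,
    enumerate_candidates,
    initial_state,
    locality_satisfied,
    run,
    run_ensemble,
)
from crisscut.engine import KIND_INTER, SimState, _bits
from crisscut import ctmc


# ---------------------------------------------------------------------------
# initial states


def test_standard_initial_state(default_spec):
    st = initial_state(default_spec, "standard", seed=0)
    pools = st.pool_counts
    cut_pools = {k: v for k, v in pools.items() if not k.is_growth}
    assert len(cut_pools) == 18 and set(cut_pools.values()) == {100}
    assert all(v == 0 for k, v in pools.items() if k.is_growth)
    comps = st.complexes
    assert len(comps) == 1 and len(comps[0]) == 47


def test_prebound_initial_state(default_spec):
    st = initial_state(default_spec, "prebound", seed=0)
    comps = st.complexes
    assert len(comps) == 1 and len(comps[0]) == 47 + 18
    cut_pools = {k: v for k, v in st.pool_counts.items() if not k.is_growth}
    assert set(cut_pools.values()) == {99}
    # each prebound cut slat holds exactly E toehold bonds
    E = default_spec.config.extension_length
    toe_bonds = [
        b for b in st.bonds if any(s.role == "toehold" for s in b)
    ]
    assert len(toe_bonds) == 18 * E


def test_unknown_mode_rejected(small_spec):
    with pytest.raises(ValueError, match="mode"):
        initial_state(small_spec, "fancy", seed=0)


def test_same_seed_gives_identical_states(small_spec):
    a = initial_state(small_spec, "standard", seed=7)
    b = initial_state(small_spec, "standard", seed=7)
    for _ in range(200):
        a.step()
        b.step()
    assert a.fingerprint() == b.fingerprint()


# ---------------------------------------------------------------------------
# locality


def _slat_graph(st: SimState) -> nx.Graph:
    g = nx.Graph()
    for inst, alive in enumerate(st.inst_alive):
        if alive:
            g.add_node(inst)
            for other in _bits(st.nbr[inst]):
                g.add_edge(inst, other)
    return g


def test_locality_direct_bond(toy_spec):
    st = initial_state(toy_spec, "standard", seed=0)
    assert locality_satisfied(st, ("X", 1), ("Y", 2))


def test_locality_matches_bfs_oracle(small_spec):
    st = initial_state(small_spec, "standard", seed=3)
    rng = random.Random(0)
    for _ in range(400):
        st.step()
    g = _slat_graph(st)
    lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=4))
    nodes = list(g.nodes)
    comp_of = st.comp_of
    for _ in range(300):
        u, v = rng.choice(nodes), rng.choice(nodes)
        if u == v or comp_of[u] != comp_of[v]:
            continue
        want = lengths.get(u, {}).get(v, 99) <= 3
        assert st._local3(u, v) == want
        sa = st.type_slat[st.inst_tid[u]]
        sb = st.type_slat[st.inst_tid[v]]
        if sa.is_growth and sb.is_growth:
            assert locality_satisfied(st, sa, sb) == want


def test_locality_undefined_across_complexes(toy_spec):
    tr = run(toy_spec, "standard", seed=1, stop_on_scission=True)
    assert tr.scission_time is not None
    st = initial_state(toy_spec, "standard", seed=1)
    while st.n_bridging:
        st.step()
    with pytest.raises(ValueError, match="complex"):
        # halves are now in different complexes (or free in the pool)
        locality_satisfied(st, ("X", 1), ("X", 4))


# ---------------------------------------------------------------------------
# candidate set and propensities


def test_initial_candidates_default(default_spec):
    st = initial_state(default_spec, "standard", seed=0)
    cands = enumerate_candidates(st)
    unbinds = [c for c in cands if c.kind == "unbind"]
    # 198 growth bonds, all at the unit off-rate
    assert len(unbinds) == 198
    assert {c.propensity for c in unbinds} == {1.0}
    inters = [c for c in cands if c.kind == "bind_inter"]
    # one capture candidate per free extension-host site, at 0.04 * 100
    assert len(inters) == 90
    assert {c.propensity for c in inters} == {4.0}
    assert not [c for c in cands if c.kind == "bind_intra"]


def test_wobble_propensities():
    spec = build_scission_model(BuildConfig(10, 5, wobble_layout=((10, 11),)))
    st = initial_state(spec, "standard", seed=0)
    offs = {}
    for key, g in st.groups.items():
        if key[0] == "unbind" and g.items:
            offs[key[1]] = len(g.items)
    assert offs == {1.0: 197, 1.5: 1}
    # break the wobble bond and check its re-formation propensity is 40 * 2/3
    (item,) = st.groups[("unbind", 1.5)].items
    st._apply_unbind(item[0], item[1], 1.5)
    intra = st.groups.get(("bind_intra", 40.0 * (2 / 3)))
    assert intra is not None and len(intra.items) == 1


def test_occupied_sites_yield_no_bind_candidates(small_spec):
    st = initial_state(small_spec, "standard", seed=0)
    for _ in range(300):
        st.step()
    bound = {g for g, p in enumerate(st.bond_of) if p != -1}
    for key, grp in st.groups.items():
        if key[0] == "unbind":
            continue
        for item in grp.items:
            if key[0] == KIND_INTER:
                assert item[0] not in bound
            else:
                assert item[0] not in bound and item[1] not in bound


def test_event_choice_frequencies_match_propensities(small_spec):
    # frozen state: sample candidates without applying them
    st = initial_state(small_spec, "standard", seed=0)
    for _ in range(150):
        st.step()
    weights = {
        key: g.weight for key, g in st.groups.items() if g.weight > 0
    }
    rng = random.Random(123)
    n = 10_000
    counts = {key: 0 for key in weights}
    for _ in range(n):
        key, _item = st.sample_candidate(rng.random())
        counts[key] += 1
    total = sum(weights.values())
    expected = [n * w / total for w in weights.values()]
    observed = [counts[k] for k in weights]
    stat = scipy.stats.chisquare(observed, expected)
    assert stat.pvalue > 0.01


def test_waiting_time_mean(toy_spec):
    # first-step waiting times across seeds: mean must equal 1/total rate
    st0 = initial_state(toy_spec, "standard", seed=0)
    total = st0.total_weight
    n = 2000
    dts = []
    for s in range(n):
        st = initial_state(toy_spec, "standard", seed=s)
        st.step()
        dts.append(st.t)
    mean = sum(dts) / n
    se = (sum((d - mean) ** 2 for d in dts) / (n - 1)) ** 0.5 / n**0.5
    assert abs(mean - 1.0 / total) < 3 * se


# ---------------------------------------------------------------------------
# audits, conservation, incremental-vs-scratch equality


def test_audited_run_passes(small_spec):
    tr = run(small_spec, "standard", seed=5, t_max=200.0, audit=True, audit_stride=50)
    assert tr.termination in ("scission", "t_max")


def test_audited_prebound_run_passes(small_spec):
    tr = run(small_spec, "prebound", seed=6, t_max=200.0, audit=True, audit_stride=50)
    assert tr.termination in ("scission", "t_max")


def test_incremental_candidates_match_scratch_after_events(small_spec):
    st = initial_state(small_spec, "standard", seed=11)
    for k in range(600):
        if st.step() is None:
            break
        if k % 97 == 0:
            st._full_audit()
    st._full_audit()


def test_agent_conservation(small_spec):
    st = initial_state(small_spec, "standard", seed=2)
    copies = dict(zip(st.type_slat, st.type_copies))
    for _ in range(500):
        st.step()
    for tid, slat in enumerate(st.type_slat):
        assert st.pool[tid] + len(st.inst_of_type[tid]) == copies[slat]


def test_discard_displaced_slats_flag(small_spec):
    tr = run(small_spec, "standard", seed=3, t_max=100.0, recycle_displaced=False)
    assert tr.termination in ("scission", "t_max")
    st = initial_state(small_spec, "standard", seed=3, recycle_displaced=False)
    for _ in range(400):
        st.step()
    for tid in range(len(st.type_slat)):
        total = st.pool[tid] + len(st.inst_of_type[tid]) + st.deleted[tid]
        assert total == st.type_copies[tid]


# ---------------------------------------------------------------------------
# runs and ensembles


def test_cut_free_ribbon_is_stable():
    spec = build_scission_model(
        BuildConfig(6, 0, include_cut_x=False, include_cut_y=False)
    )
    tr = run(spec, "standard", seed=4, t_max=100.0)
    assert tr.termination == "t_max"
    assert tr.scission_time is None


def test_run_determinism(small_spec):
    a = run(small_spec, "standard", seed=9, t_max=500.0, record_events=True)
    b = run(small_spec, "standard", seed=9, t_max=500.0, record_events=True)
    assert a.samples == b.samples
    assert a.events == b.events
    assert a.scission_time == b.scission_time


def test_trajectory_shape(small_spec):
    tr = run(small_spec, "standard", seed=1, t_max=500.0)
    ts = [row[0] for row in tr.samples]
    assert ts == sorted(ts)
    assert tr.samples[0][0] == 0.0
    # initial sample: one ribbon complex of all growth slats
    n_growth = len(small_spec.growth_slats)
    assert tr.samples[0][1:] == (n_growth, 1, n_growth, 1)
    df = tr.to_frame()
    assert list(df.columns)[:4] == [
        "time",
        "tracked_complex_size",
        "n_complexes",
        "largest_complex_size",
    ]


def test_default_run_shows_growth_then_drop(default_spec):
    tr = run(default_spec, "standard", seed=12, t_max=5000.0)
    assert tr.termination == "scission"
    peak = max(row[3] for row in tr.samples)
    assert peak > 47  # cut-slat capture grows the tracked complex
    assert tr.samples[-1][3] < peak  # followed by a sharp drop


def test_ensemble_seeds_and_stability(small_spec):
    trs = run_ensemble(small_spec, "standard", 5, 100, t_max=200.0)
    assert [t.seed for t in trs] == [100, 101, 102, 103, 104]
    again = run_ensemble(small_spec, "standard", 5, 100, t_max=200.0)
    assert [t.samples for t in trs] == [t.samples for t in again]
    # misuse with equal seeds is detectable: identical trajectories
    a = run(small_spec, "standard", 100, t_max=200.0)
    assert a.samples == trs[0].samples
    with pytest.raises(ValueError):
        run_ensemble(small_spec, "standard", 0, 1)


# ---------------------------------------------------------------------------
# semantic agreement with the independent CTMC transition enumeration


def test_candidates_match_ctmc_transitions_along_a_run():
    spec = build_scission_model(
        BuildConfig(3, 1, cut_excess=1)
    )
    st = initial_state(spec, "standard", seed=21)
    checked = 0
    for k in range(400):
        if st.step() is None:
            break
        if k % 25 != 0:
            continue
        bonds = frozenset(st.bonds)
        expect = []
        for rate, nxt in ctmc.transitions(spec, bonds, "standard"):
            ((sa, sb),) = bonds ^ nxt
            expect.append((round(rate, 12), tuple(sorted((str(sa), str(sb))))))
        expect.sort()
        got = []
        for c in enumerate_candidates(st):
            pair = tuple(sorted((str(c.site_a), str(c.site_b))))
            got.append((round(c.propensity, 12), pair))
        assert sorted(got) == expect
        checked += 1
    assert checked >= 5
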