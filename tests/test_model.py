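"""Model-builder tests: counts against brute-force enumeration, invariants,
and validation-report behaviour."""

import json

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisscut import (
    BuildConfig,
    ModelBuildError,
    RateParams,
    build_scission_model,
    cross_interface_bonds,
    validate_model,
)
from crisscut.model import SiteAddress, SlatId


def brute_force_cross_count(L: int, R: int = 2) -> int:
    """Count lattice pairs (i, j) with 0 <= j - i <= L - 1 and i <= N/2 < j."""
    N = R * L
    return sum(
        1
        for i in range(1, N + 1)
        for j in range(1, N + L)
        if 0 <= j - i <= L - 1 and i <= N // 2 < j
    )


@pytest.mark.parametrize("L", range(2, 13))
def test_cross_bond_count_matches_enumeration(L):
    spec = build_scission_model(BuildConfig(L, extension_length=min(2, L)))
    assert len(cross_interface_bonds(spec)) == brute_force_cross_count(L)
    assert len(cross_interface_bonds(spec)) == L * (L - 1) // 2


@given(L=st.integers(2, 10), R=st.integers(1, 3))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_cross_bond_count_property(L, R):
    spec = build_scission_model(BuildConfig(L, 1, repeats=R))
    assert len(cross_interface_bonds(spec)) == brute_force_cross_count(L, R)
    assert validate_model(spec).ok


def test_default_model_counts(default_spec):
    assert len(cross_interface_bonds(default_spec)) == 45
    kinds = [s.kind for s in default_spec.cut_slats]
    assert kinds.count("CY") == 9 and kinds.count("CX") == 9
    # growth slats: N x-slats plus N + L - 3 y-slats after edge pruning
    assert len(default_spec.growth_slats) == 20 + 27


def test_smallest_model():
    spec = build_scission_model(BuildConfig(2, 1))
    assert len(cross_interface_bonds(spec)) == 1
    assert validate_model(spec).ok


def test_degenerate_length_rejected():
    with pytest.raises(ModelBuildError, match="core_slat_length"):
        BuildConfig(1, 0)


def test_overlong_extension_rejected():
    with pytest.raises(ModelBuildError, match="extension_length"):
        BuildConfig(4, 7)  # E > L + 2


def test_slat_coordination_matches_lattice_enumeration(default_spec):
    # per-slat bond counts against brute-force enumeration of the pruned
    # stagger-1 parallelogram; interior slats reach full L coordination
    L, R = 10, 2
    N = R * L
    lattice = [
        (i, j)
        for i in range(1, N + 1)
        for j in range(1, N + L)
        if 0 <= j - i <= L - 1
    ]
    from collections import Counter

    dx, dy = Counter(i for i, _ in lattice), Counter(j for _, j in lattice)
    kept = [(i, j) for i, j in lattice if dx[i] >= 2 and dy[j] >= 2]
    want = Counter()
    for i, j in kept:
        want[SlatId("X", i)] += 1
        want[SlatId("Y", j)] += 1
    deg = Counter()
    for a, b in default_spec.initial_bonds:
        deg[a.slat] += 1
        deg[b.slat] += 1
    assert deg == want
    assert max(deg.values()) == L


def test_interface_removal_splits_into_two_halves(default_spec):
    g = nx.Graph()
    cross = cross_interface_bonds(default_spec)
    for a, b in default_spec.initial_bonds - cross:
        g.add_edge(a.slat, b.slat)
    for s in default_spec.growth_slats:
        g.add_node(s)
    comps = list(nx.connected_components(g))
    assert len(comps) == 2
    halves = [
        {default_spec.half_label[s] for s in comp} for comp in comps
    ]
    assert sorted(halves, key=sorted) == [{"A"}, {"B"}]


@pytest.mark.parametrize(
    "cfg",
    [
        BuildConfig(2, 1),
        BuildConfig(4, 3),
        BuildConfig(4, 5),  # toehold window wraps within the capping half
        BuildConfig(6, 5, include_cut_x=False),
        BuildConfig(10, 5, wobble_layout=((10, 11), (6, 15))),
        BuildConfig(6, 2, repeats=3),
    ],
)
def test_built_specs_validate(cfg):
    rep = validate_model(build_scission_model(cfg))
    assert rep.ok, str(rep)


def test_toeholds_anchor_in_capping_half():
    for L in (4, 6, 10):
        spec = build_scission_model(BuildConfig(L, 5))
        for sid in spec.cut_slats:
            info = spec.slats[sid]
            for site in info.sites:
                if site.role != "toehold":
                    continue
                (host,) = spec.partners(site)
                assert host.role == "extension_host"
                assert spec.half_label[host.slat] == info.half


def test_competed_sites_target_growth_bound_sites(default_spec):
    bound = {s for pair in default_spec.initial_bonds for s in pair}
    n_competed = 0
    for sid in default_spec.cut_slats:
        for site in default_spec.slats[sid].sites:
            if site.role != "competed":
                continue
            n_competed += 1
            targets = [p for p in default_spec.partners(site) if p.role == "core"]
            assert len(targets) == 1 and targets[0] in bound
    # each of the 45 interface bonds is attacked from both the x and y side
    assert n_competed == 2 * 45


def test_wobble_layout_must_exist():
    with pytest.raises(ModelBuildError, match="wobble"):
        build_scission_model(BuildConfig(4, 2, wobble_layout=((1, 99),)))


def test_validation_detects_tampering(small_spec):
    import copy

    spec = copy.copy(small_spec)
    # a wobble bond that is no longer an initial bond
    victim = next(iter(cross_interface_bonds(spec)))
    spec.initial_bonds = frozenset(spec.initial_bonds - {victim})
    spec.wobble_bonds = frozenset({victim})
    rep = validate_model(spec)
    assert not rep.ok
    names = [n for n, _ in rep.failures()]
    assert any("wobble" in n for n in names)

    # a toehold with two compatible partners
    spec2 = copy.copy(small_spec)
    toe = next(
        s
        for sid in spec2.cut_slats
        for s in spec2.slats[sid].sites
        if s.role == "toehold"
    )
    rogue = SiteAddress(SlatId("X", 1), "extension_host", 99)
    spec2.compatibility = frozenset(spec2.compatibility | {(rogue, toe)})
    spec2.__post_init__()  # rebuild the partner index
    rep2 = validate_model(spec2)
    assert not rep2.ok
    assert any("toehold" in n for n, _ in rep2.failures())


def test_rate_params_alpha_consistency():
    with pytest.raises(ModelBuildError, match="alpha"):
        RateParams(k_on_intra=30.0)  # 30 != 1000 * 0.04
    r = RateParams(k_on_inter=0.02, k_on_intra=20.0)
    assert r.alpha == 1000.0


def test_config_json_round_trip(tmp_path):
    cfg = BuildConfig(
        6,
        4,
        wobble_layout=((4, 7),),
        cut_excess=50,
        include_cut_x=False,
        rates=RateParams(k_on_inter=0.05, k_on_intra=50.0),
    )
    p = tmp_path / "cfg.json"
    p.write_text(json.dumps(cfg.to_dict()))
    assert BuildConfig.from_json(p) == cfg


def test_spec_serialization(tmp_path, small_spec):
    out = tmp_path / "model.json"
    small_spec.to_json(out)
    doc = json.loads(out.read_text())
    assert len(doc["slats"]) == len(small_spec.slats)
    assert len(doc["initial_bonds"]) == len(small_spec.initial_bonds)
    assert len(doc["compatibility"]) == len(small_spec.compatibility)
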