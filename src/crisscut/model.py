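"""Programmatic construction of crisscross-ribbon scission models.

A crisscross ribbon is a staggered lattice of "slat" monomers in two
perpendicular orientations (x and y).  Each slat presents ``L`` weak core
binding sites (one half-turn each), so a slat in the ribbon interior is held
by ``L`` perpendicular neighbours.  Scission is driven by "cut" slats:
invaders that are recruited by arrays of single-stranded extensions
(toeholds) near a designated cut interface and then displace the incumbent
growth slats site by site, severing the ribbon in two.

This module builds the static site-graph description of such a system — the
slat types, their sites, which site pairs may bond, the intact-ribbon bond
set, and the rate parameters — from a handful of integers.  The dynamic
simulation lives in :mod:`crisscut.engine`.

Topology convention
-------------------
Growth slats ``X_i`` (``i = 1..N``, ``N = R*L``) and ``Y_j``
(``j = 1..N+L-1``); a growth bond ``(X_i, Y_j)`` exists iff
``0 <= j - i <= L - 1``.  Lattice-edge slats with fewer than two bonds in the
full lattice (``Y_1`` and ``Y_{N+L-1}``) are pruned in a single pass.  Slats
with index ``<= N/2`` form half A, the rest half B; the bonds joining the two
halves are the cut interface (``L*(L-1)/2`` of them for ``R = 2``).

One cut-slat type is generated per interface-holding growth slat: ``CUT_Y_j``
competes for the x-side sites of ``Y_j``'s interface bonds and, once the
displacement completes, caps half A; ``CUT_X_i`` mirrors this on the y side
and caps half B.  Each cut type additionally carries ``E`` toehold sites,
each pairing with a dedicated extension-host site on a slat of the half it
caps (consecutive hosts, window clamped to stay inside that half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "GROWTH_X",
    "GROWTH_Y",
    "CUT_X",
    "CUT_Y",
    "SlatId",
    "SiteAddress",
    "RateParams",
    "BuildConfig",
    "SlatInfo",
    "ModelSpec",
    "ModelBuildError",
    "build_scission_model",
    "cross_interface_bonds",
    "validate_model",
    "ValidationReport",
]

GROWTH_X = "X"
GROWTH_Y = "Y"
CUT_X = "CX"
CUT_Y = "CY"

ROLE_CORE = "core"
ROLE_HOST = "extension_host"
ROLE_TOEHOLD = "toehold"
ROLE_COMPETED = "competed"


class SlatId(NamedTuple):
    kind: str  # one of GROWTH_X, GROWTH_Y, CUT_X, CUT_Y
    index: int

    def __str__(self) -> str:
        return f"{self.kind}{self.index}"

    @property
    def is_growth(self) -> bool:
        return self.kind in (GROWTH_X, GROWTH_Y)


class SiteAddress(NamedTuple):
    slat: SlatId
    role: str
    index: int

    def __str__(self) -> str:
        return f"{self.slat}.{self.role}.{self.index}"


Bond = tuple[SiteAddress, SiteAddress]


def bond(a: SiteAddress, b: SiteAddress) -> Bond:
    """Canonical (sorted) form of an unordered site pair."""
    return (a, b) if a <= b else (b, a)


class ModelBuildError(ValueError):
    pass


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the site-graph model.

    Time is measured in units of the growth-bond lifetime (``k_off = 1``).
    ``alpha = k_on_intra / k_on_inter`` at unit reference concentration
    encodes the positional-entropy loss upon capturing a free monomer from
    solution; one free copy stands in for the reference concentration.  The
    prebound parameterization is used when cut slats start toehold-bound so
    that they stay attached throughout.
    """

    k_off: float = 1.0
    k_on_inter: float = 0.04
    k_on_intra: float = 40.0
    alpha: float = 1000.0
    prebound_k_on_inter: float = 0.05
    prebound_k_off: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "k_off",
            "k_on_inter",
            "k_on_intra",
            "alpha",
            "prebound_k_on_inter",
            "prebound_k_off",
        ):
            if getattr(self, name) <= 0:
                raise ModelBuildError(f"rate parameter {name} must be > 0")
        if abs(self.k_on_intra - self.alpha * self.k_on_inter) > 1e-9 * self.k_on_intra:
            raise ModelBuildError(
                "alpha inconsistency: k_on_intra must equal alpha * k_on_inter "
                f"(got {self.k_on_intra} != {self.alpha} * {self.k_on_inter})"
            )


def mode_rate_constants(rates: "RateParams", mode: str) -> tuple[float, float, float]:
    """(off, intercomplex-on, intracomplex-on) for a parameterization.

    The prebound intracomplex on-rate is not independent: alpha governs it
    (alpha * prebound inter on-rate = 50 at the defaults).
    """
    if mode == "standard":
        return rates.k_off, rates.k_on_inter, rates.k_on_intra
    if mode == "prebound":
        return (
            rates.prebound_k_off,
            rates.prebound_k_on_inter,
            rates.alpha * rates.prebound_k_on_inter,
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class BuildConfig:
    """Parameters of a scission model build.

    ``wobble_layout`` lists growth bonds whose *growth-side* binding is
    weakened (G-T wobble pairs in the DNA implementation), as ``(i, j)``
    index pairs of the bond ``(X_i, Y_j)``.  Wobble factors scale only
    growth-growth bonds at those positions; cut-slat binding is never
    wobble-scaled, which is exactly the kinetic ratchet the design exploits.
    """

    core_slat_length: int
    extension_length: int
    repeats: int = 2
    wobble_layout: tuple[tuple[int, int], ...] = ()
    wobble_on_factor: float = 2.0 / 3.0
    wobble_off_factor: float = 1.5
    cut_excess: int = 100
    include_cut_x: bool = True
    include_cut_y: bool = True
    rates: RateParams = field(default_factory=RateParams)

    def __post_init__(self) -> None:
        L, E, R = self.core_slat_length, self.extension_length, self.repeats
        if L < 2:
            raise ModelBuildError(
                f"core_slat_length must be >= 2 (got {L}): L = 1 admits no "
                "cross-interface bonds (L*(L-1)/2 = 0), so scission is undefined"
            )
        if E < 0:
            raise ModelBuildError("extension_length must be >= 0")
        if E > L + 2:
            raise ModelBuildError(
                f"extension_length {E} exceeds L + 2 = {L + 2}: toehold host "
                "window cannot be addressed"
            )
        if R < 1:
            raise ModelBuildError("repeats must be >= 1")
        if self.wobble_on_factor <= 0 or self.wobble_off_factor <= 0:
            raise ModelBuildError("wobble factors must be > 0")
        if self.cut_excess < 1:
            raise ModelBuildError("cut_excess must be >= 1")
        object.__setattr__(self, "wobble_layout", tuple(map(tuple, self.wobble_layout)))

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "core_slat_length": self.core_slat_length,
            "extension_length": self.extension_length,
            "repeats": self.repeats,
            "wobble_layout": [list(p) for p in self.wobble_layout],
            "wobble_on_factor": self.wobble_on_factor,
            "wobble_off_factor": self.wobble_off_factor,
            "cut_excess": self.cut_excess,
            "include_cut_x": self.include_cut_x,
            "include_cut_y": self.include_cut_y,
            "rates": vars(self.rates).copy(),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BuildConfig":
        d = dict(d)
        rates = d.pop("rates", None)
        if rates is not None:
            d["rates"] = RateParams(**rates)
        d["wobble_layout"] = tuple(tuple(p) for p in d.get("wobble_layout", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "BuildConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SlatInfo:
    slat_id: SlatId
    sites: tuple[SiteAddress, ...]
    copies: int
    free_initially: bool
    half: str | None  # "A"/"B" for growth slats, capping half for cut slats


@dataclass
class ModelSpec:
    """Full static description of one scission-simulation system."""

    config: BuildConfig
    slats: dict[SlatId, SlatInfo]
    compatibility: frozenset[Bond]
    initial_bonds: frozenset[Bond]
    half_label: dict[SlatId, str]
    wobble_bonds: frozenset[Bond]
    half_coordination: int

    def __post_init__(self) -> None:
        compat_of: dict[SiteAddress, list[SiteAddress]] = {}
        for a, b in sorted(self.compatibility):
            compat_of.setdefault(a, []).append(b)
            compat_of.setdefault(b, []).append(a)
        self._compat_of = {s: tuple(p) for s, p in compat_of.items()}

    def partners(self, site: SiteAddress) -> tuple[SiteAddress, ...]:
        """Compatible partner sites of ``site`` (at most 2 in this model)."""
        return self._compat_of.get(site, ())

    @property
    def growth_slats(self) -> list[SlatId]:
        return [s for s in self.slats if s.is_growth]

    @property
    def cut_slats(self) -> list[SlatId]:
        return [s for s in self.slats if not s.is_growth]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "slats": [
                {
                    "id": str(info.slat_id),
                    "sites": [str(s) for s in info.sites],
                    "copies": info.copies,
                    "free_initially": info.free_initially,
                    "half": info.half,
                }
                for info in self.slats.values()
            ],
            "compatibility": [[str(a), str(b)] for a, b in sorted(self.compatibility)],
            "initial_bonds": [[str(a), str(b)] for a, b in sorted(self.initial_bonds)],
            "half_label": {str(k): v for k, v in self.half_label.items()},
            "wobble_bonds": [[str(a), str(b)] for a, b in sorted(self.wobble_bonds)],
            "half_coordination": self.half_coordination,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _lattice(L: int, N: int) -> tuple[set[SlatId], set[tuple[int, int]]]:
    """Unpruned slat set and growth-bond index pairs of the parallelogram."""
    bonds = {
        (i, j)
        for i in range(1, N + 1)
        for j in range(i, i + L)  # 0 <= j - i <= L - 1
        if 1 <= j <= N + L - 1
    }
    slats = {SlatId(GROWTH_X, i) for i in range(1, N + 1)}
    slats |= {SlatId(GROWTH_Y, j) for j in range(1, N + L)}
    return slats, bonds


def build_scission_model(config: BuildConfig) -> ModelSpec:
    """Generate the site-graph model of a ribbon with a cut interface.

    Raises :class:`ModelBuildError` when the requested extension length
    cannot be hosted inside the capping half (``E <= N/2`` for cut-y types,
    ``E <= N/2 + L - 2`` for cut-x types).
    """
    L = config.core_slat_length
    E = config.extension_length
    R = config.repeats
    N = R * L
    half_n = N // 2

    _, lattice_bonds = _lattice(L, N)

    # single-pass pruning: drop slats with < 2 bonds in the full lattice
    deg_x: dict[int, int] = {}
    deg_y: dict[int, int] = {}
    for i, j in lattice_bonds:
        deg_x[i] = deg_x.get(i, 0) + 1
        deg_y[j] = deg_y.get(j, 0) + 1
    keep_x = {i for i, d in deg_x.items() if d >= 2}
    keep_y = {j for j, d in deg_y.items() if d >= 2}
    bonds_ij = sorted((i, j) for i, j in lattice_bonds if i in keep_x and j in keep_y)

    if not any(i <= half_n < j for i, j in bonds_ij):
        raise ModelBuildError(
            f"configuration L={L}, R={R} yields no cross-interface bonds"
        )

    half_label: dict[SlatId, str] = {}
    for i in sorted(keep_x):
        half_label[SlatId(GROWTH_X, i)] = "A" if i <= half_n else "B"
    for j in sorted(keep_y):
        half_label[SlatId(GROWTH_Y, j)] = "A" if j <= half_n else "B"

    # growth core sites, indexed by the diagonal offset d = j - i
    sites_of: dict[SlatId, list[SiteAddress]] = {s: [] for s in half_label}
    initial: set[Bond] = set()
    compat: set[Bond] = set()
    for i, j in bonds_ij:
        sx = SiteAddress(SlatId(GROWTH_X, i), ROLE_CORE, j - i)
        sy = SiteAddress(SlatId(GROWTH_Y, j), ROLE_CORE, j - i)
        sites_of[sx.slat].append(sx)
        sites_of[sy.slat].append(sy)
        b = bond(sx, sy)
        initial.add(b)
        compat.add(b)

    cross_ij = [(i, j) for i, j in bonds_ij if i <= half_n < j]

    slats: dict[SlatId, SlatInfo] = {}
    host_counter: dict[SlatId, int] = {}

    def add_host(hslat: SlatId, partner: SiteAddress) -> None:
        if hslat not in sites_of:
            raise ModelBuildError(
                f"toehold host slat {hslat} does not exist in the pruned lattice"
            )
        k = host_counter.get(hslat, 0)
        host_counter[hslat] = k + 1
        hs = SiteAddress(hslat, ROLE_HOST, k)
        sites_of[hslat].append(hs)
        compat.add(bond(hs, partner))

    # cut-y types: one per B-half Y slat holding interface bonds; caps half A
    if config.include_cut_y:
        for j in sorted({j for _, j in cross_ij}):
            cid = SlatId(CUT_Y, j)
            csites: list[SiteAddress] = []
            for i, jj in cross_ij:
                if jj != j:
                    continue
                cs = SiteAddress(cid, ROLE_COMPETED, i)
                csites.append(cs)
                compat.add(bond(cs, SiteAddress(SlatId(GROWTH_X, i), ROLE_CORE, j - i)))
            # preferred window sits just below the competed range; when E
            # exceeds the A-half span the hosts wrap cyclically (a slat may
            # carry several extension segments)
            start = max(1, min(j - L, half_n - E + 1))
            for k in range(1, E + 1):
                ts = SiteAddress(cid, ROLE_TOEHOLD, k)
                csites.append(ts)
                host_i = (start + k - 2) % half_n + 1
                add_host(SlatId(GROWTH_X, host_i), ts)
            slats[cid] = SlatInfo(cid, tuple(csites), config.cut_excess, True, "A")

    # cut-x types: one per A-half X slat holding interface bonds; caps half B
    if config.include_cut_x:
        y_max = max(j for j in keep_y)
        for i in sorted({i for i, _ in cross_ij}):
            cid = SlatId(CUT_X, i)
            csites = []
            for ii, j in cross_ij:
                if ii != i:
                    continue
                cs = SiteAddress(cid, ROLE_COMPETED, j)
                csites.append(cs)
                compat.add(bond(cs, SiteAddress(SlatId(GROWTH_Y, j), ROLE_CORE, j - i)))
            span = y_max - half_n
            start = max(half_n, min(i + L - 1, y_max - E))
            for k in range(1, E + 1):
                ts = SiteAddress(cid, ROLE_TOEHOLD, k)
                csites.append(ts)
                host_j = half_n + (start + k - half_n - 1) % span + 1
                add_host(SlatId(GROWTH_Y, host_j), ts)
            slats[cid] = SlatInfo(cid, tuple(csites), config.cut_excess, True, "B")

    growth_infos = {
        s: SlatInfo(s, tuple(sites_of[s]), 1, False, half_label[s])
        for s in sorted(half_label)
    }
    slats = {**growth_infos, **slats}

    # resolve wobble layout (i, j) pairs against the built bond set
    wobble: set[Bond] = set()
    for i, j in config.wobble_layout:
        b = bond(
            SiteAddress(SlatId(GROWTH_X, i), ROLE_CORE, j - i),
            SiteAddress(SlatId(GROWTH_Y, j), ROLE_CORE, j - i),
        )
        if b not in initial:
            raise ModelBuildError(
                f"wobble position (X{i}, Y{j}) is not an initial growth bond"
            )
        wobble.add(b)

    return ModelSpec(
        config=config,
        slats=slats,
        compatibility=frozenset(compat),
        initial_bonds=frozenset(initial),
        half_label=half_label,
        wobble_bonds=frozenset(wobble),
        half_coordination=L // 2,
    )


def cross_interface_bonds(spec: ModelSpec) -> frozenset[Bond]:
    """Initial growth bonds joining an A-half slat to a B-half slat."""
    return frozenset(
        b
        for b in spec.initial_bonds
        if spec.half_label[b[0].slat] != spec.half_label[b[1].slat]
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]]

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, passed, detail in self.checks if not passed]

    def __str__(self) -> str:
        lines = []
        for name, passed, detail in self.checks:
            mark = "PASS" if passed else "FAIL"
            lines.append(f"[{mark}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


def _growth_components(spec: ModelSpec, bonds: Iterable[Bond]) -> int:
    adj: dict[SlatId, set[SlatId]] = {s: set() for s in spec.half_label}
    for a, b in bonds:
        if a.slat.is_growth and b.slat.is_growth:
            adj[a.slat].add(b.slat)
            adj[b.slat].add(a.slat)
    seen: set[SlatId] = set()
    n = 0
    for s in adj:
        if s in seen:
            continue
        n += 1
        stack = [s]
        seen.add(s)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
    return n


def validate_model(spec: ModelSpec) -> ValidationReport:
    """Check all static invariants of a :class:`ModelSpec`.

    Returns a report rather than raising, so deliberately broken specs can
    be inspected check by check.
    """
    checks: list[tuple[str, bool, str]] = []

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append((name, ok, detail if not ok else ""))

    missing = [b for b in spec.initial_bonds if b not in spec.compatibility]
    add("initial bonds are compatible", not missing, f"{len(missing)} bonds not in compatibility")

    occupancy: dict[SiteAddress, int] = {}
    for a, b in spec.initial_bonds:
        occupancy[a] = occupancy.get(a, 0) + 1
        occupancy[b] = occupancy.get(b, 0) + 1
    multi = [s for s, c in occupancy.items() if c > 1]
    add("each site in at most one initial bond", not multi, f"{len(multi)} overbooked sites")

    cross = cross_interface_bonds(spec)
    n_comp = _growth_components(spec, spec.initial_bonds - cross)
    add(
        "interface removal splits growth slats into exactly 2 halves",
        n_comp == 2,
        f"{n_comp} components",
    )

    bad_toe = []
    host_use: dict[SiteAddress, int] = {}
    for info in spec.slats.values():
        for s in info.sites:
            if s.role == ROLE_TOEHOLD:
                p = spec.partners(s)
                if len(p) != 1 or p[0].role != ROLE_HOST:
                    bad_toe.append(s)
                else:
                    host_use[p[0]] = host_use.get(p[0], 0) + 1
    add(
        "each toehold has exactly one dedicated host partner",
        not bad_toe and all(c == 1 for c in host_use.values()),
        f"{len(bad_toe)} bad toeholds",
    )

    bad_comp = []
    for info in spec.slats.values():
        for s in info.sites:
            if s.role != ROLE_COMPETED:
                continue
            p = spec.partners(s)
            targets = [t for t in p if t.role == ROLE_CORE]
            if len(targets) != 1 or occupancy.get(targets[0], 0) != 1:
                bad_comp.append(s)
    add(
        "every competed site targets a growth-bound core site",
        not bad_comp,
        f"{len(bad_comp)} bad competed sites",
    )

    bad_wob = [b for b in spec.wobble_bonds if b not in spec.initial_bonds]
    add("wobble bonds exist in initial bonds", not bad_wob, f"{len(bad_wob)} missing")

    try:
        spec.config.rates.__post_init__()
        add("rate parameters valid", True)
    except ModelBuildError as exc:
        add("rate parameters valid", False, str(exc))

    return ValidationReport(checks)
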