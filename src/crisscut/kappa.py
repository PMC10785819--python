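"""Kappa-language (KaSim 4 dialect) export of generated models.

One agent is declared per slat type, one unbinding and one intercomplex
binding rule per compatible site pair, and one intracomplex binding rule per
(site pair, bridging context): the left-hand side of each intracomplex rule
spells out one concrete bonded traversal of at most three bonds connecting
the two slats, which is how a purely local rule language encodes the
"within two slats" proximity constraint.  Traversals are enumerated over the
type-level potential-bond graph as simple paths (no slat type revisited, no
site used twice within an agent).

The bundled :func:`parse_kappa` reader validates the syntax and recovers
agent/rule/init counts; it keeps rule patterns verbatim, so
export -> parse -> render is a byte-identical fixed point.  Running KaSim
itself is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import ModelSpec, SiteAddress, SlatId, mode_rate_constants

__all__ = ["KappaModel", "export_kappa", "parse_kappa", "count_rule_templates"]

_ROLE_PREFIX = {"core": "c", "extension_host": "e", "toehold": "t", "competed": "d"}

_HEADER = [
    "# crisscut kappa export",
    "# observable: largest-complex size is tracked by the simulation engine"
    " (engine-specific; KaSim users can approximate it with snapshots)",
]


def site_name(s: SiteAddress) -> str:
    return f"{_ROLE_PREFIX[s.role]}{s.index}"


@dataclass
class KappaModel:
    """Parsed or generated Kappa document."""

    agents: list[tuple[str, list[str]]]
    rules: list[tuple[str, str, str, str]]  # (name, lhs, rhs, rate literal)
    inits: list[tuple[int, str]]
    header: list[str] = field(default_factory=lambda: list(_HEADER))

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def render(self) -> str:
        lines = list(self.header)
        for name, sites in self.agents:
            lines.append(f"%agent: {name}({','.join(sites)})")
        for name, lhs, rhs, rate in self.rules:
            lines.append(f"'{name}' {lhs} -> {rhs} @ {rate}")
        for count, expr in self.inits:
            lines.append(f"%init: {count} {expr}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        return self.render()




def _edges(spec: ModelSpec):
    """Type-level potential bonds as (site_a, site_b) sorted pairs."""
    return sorted(spec.compatibility)


def _adjacency(spec: ModelSpec):
    adj: dict[SlatId, list[tuple[SiteAddress, SiteAddress]]] = {}
    for a, b in _edges(spec):
        adj.setdefault(a.slat, []).append((a, b))
        adj.setdefault(b.slat, []).append((b, a))
    for k in adj:
        adj[k].sort()
    return adj


def _bridge_paths(spec, adj, sa: SiteAddress, sb: SiteAddress, max_bonds: int = 3):
    """Simple bonded traversals of <= ``max_bonds`` bonds joining the slats
    of ``sa`` and ``sb``, avoiding the candidate sites themselves and any
    same-site reuse within an agent.  Each path is a list of (here, there)
    site pairs."""
    start, goal = sa.slat, sb.slat
    out: list[list[tuple[SiteAddress, SiteAddress]]] = []

    def dfs(node, in_site, visited, path):
        if len(path) >= max_bonds:
            return
        for here, there in adj.get(node, ()):
            if here == in_site or (node == start and here == sa):
                continue
            nxt = there.slat
            if nxt == goal:
                if there != sb and not (here == sa and there == sb):
                    out.append(path + [(here, there)])
                continue
            if nxt in visited or nxt == start:
                continue
            dfs(nxt, there, visited | {nxt}, path + [(here, there)])

    dfs(start, None, {start}, [])
    return out


def count_rule_templates(spec: ModelSpec) -> dict[str, int]:
    """Template counts per rule class, straight from the compatibility map."""
    adj = _adjacency(spec)
    n_pairs = len(spec.compatibility)
    n_intra = sum(
        len(_bridge_paths(spec, adj, a, b)) for a, b in _edges(spec)
    )
    return {"unbind": n_pairs, "bind_inter": n_pairs, "bind_intra": n_intra}


def _agent_pattern(slots: dict[SlatId, list[tuple[str, str]]]) -> str:
    """Render agents with (site name, link state) slots, in slat order."""
    parts = []
    for slat in sorted(slots):
        sites = ",".join(f"{s}[{state}]" for s, state in slots[slat])
        parts.append(f"{slat}({sites})")
    return ",".join(parts)


def export_kappa(spec: ModelSpec, mode: str = "standard") -> KappaModel:
    """Generate the Kappa document for one model and parameterization."""
    k_off, k_inter, k_intra = mode_rate_constants(spec.config.rates, mode)
    won, woff = spec.config.wobble_on_factor, spec.config.wobble_off_factor

    agents = [
        (str(info.slat_id), [site_name(s) for s in info.sites])
        for info in spec.slats.values()
    ]

    rules: list[tuple[str, str, str, str]] = []
    adj = _adjacency(spec)
    nu = nx = nb = 0
    for a, b in _edges(spec):
        wob = (a, b) in spec.wobble_bonds or (b, a) in spec.wobble_bonds
        off = k_off * (woff if wob else 1.0)
        on_intra = k_intra * (won if wob else 1.0)
        on_inter = k_inter * (won if wob else 1.0)
        an, bn = site_name(a), site_name(b)
        bound = f"{a.slat}({an}[1]),{b.slat}({bn}[1])"
        free = f"{a.slat}({an}[.]),{b.slat}({bn}[.])"
        rules.append((f"u{nu}", bound, free, repr(off)))
        nu += 1
        # intercomplex capture: one side is a free monomer; the engine
        # multiplies this per-copy coefficient by the monomer pool
        rules.append((f"x{nx}", free, bound, repr(on_inter)))
        nx += 1
        for path in _bridge_paths(spec, adj, a, b):
            slots: dict[SlatId, list[tuple[str, str]]] = {a.slat: [], b.slat: []}
            slots[a.slat].append((an, "."))
            slots[b.slat].append((bn, "."))
            for i, (here, there) in enumerate(path, start=1):
                slots.setdefault(here.slat, []).append((site_name(here), str(i)))
                slots.setdefault(there.slat, []).append((site_name(there), str(i)))
            lhs = _agent_pattern(slots)
            new = str(len(path) + 1)
            slots[a.slat][0] = (an, new)
            slots[b.slat][0] = (bn, new)
            rhs = _agent_pattern(slots)
            rules.append((f"b{nb}", lhs, rhs, repr(on_intra)))
            nb += 1

    inits: list[tuple[int, str]] = []
    label: dict[SiteAddress, int] = {}
    for i, (sa, sb) in enumerate(sorted(spec.initial_bonds), start=1):
        label[sa] = label[sb] = i
    slots = {}
    for info in spec.slats.values():
        if info.free_initially:
            continue
        slots[info.slat_id] = [
            (site_name(s), str(label[s])) for s in info.sites if s in label
        ]
    inits.append((1, _agent_pattern(slots)))
    for info in spec.slats.values():
        if info.free_initially:
            inits.append((info.copies, f"{info.slat_id}()"))
    return KappaModel(agents=agents, rules=rules, inits=inits)


# ---------------------------------------------------------------------------
# reader

_AGENT_RE = re.compile(r"^%agent:\s*(\w+)\(([\w,]*)\)$")
_RULE_RE = re.compile(r"^'([^']+)'\s+(.*?)\s*->\s*(.*?)\s*@\s*(\S+)$")
_INIT_RE = re.compile(r"^%init:\s*(\d+)\s+(.*)$")
_MENTION_RE = re.compile(r"(\w+)\(([^()]*)\)")
_SITE_RE = re.compile(r"^\w+\[(?:\.|\d+)\]$")


class KappaParseError(ValueError):
    pass


def _check_pattern(expr: str, declared: dict[str, set[str]]) -> int:
    """Validate a site-graph expression; return the agent-mention count."""
    stripped = _MENTION_RE.sub("", expr).replace(",", "").strip()
    if stripped:
        raise KappaParseError(f"unparseable pattern fragment {stripped!r}")
    n = 0
    for name, sites in _MENTION_RE.findall(expr):
        if name not in declared:
            raise KappaParseError(f"undeclared agent {name!r}")
        n += 1
        if not sites:
            continue
        for tok in sites.split(","):
            if not _SITE_RE.match(tok):
                raise KappaParseError(f"bad site token {tok!r}")
            if tok.split("[")[0] not in declared[name]:
                raise KappaParseError(f"unknown site {tok!r} on {name}")
    return n


def parse_kappa(text: str) -> KappaModel:
    """Parse a document produced by :func:`export_kappa`.

    Validates syntax against the declared agents and preserves rule and
    init patterns verbatim (so rendering the result reproduces the input
    byte for byte)."""
    agents: list[tuple[str, list[str]]] = []
    rules: list[tuple[str, str, str, str]] = []
    inits: list[tuple[int, str]] = []
    header: list[str] = []
    declared: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            header.append(line)
            continue
        m = _AGENT_RE.match(line)
        if m:
            name, sites = m.group(1), [s for s in m.group(2).split(",") if s]
            agents.append((name, sites))
            declared[name] = set(sites)
            continue
        m = _RULE_RE.match(line)
        if m:
            name, lhs, rhs, rate = m.groups()
            if _check_pattern(lhs, declared) != _check_pattern(rhs, declared):
                raise KappaParseError(f"rule {name!r}: lhs/rhs agent mismatch")
            float(rate)  # must be a numeric literal
            rules.append((name, lhs, rhs, rate))
            continue
        m = _INIT_RE.match(line)
        if m:
            count, expr = int(m.group(1)), m.group(2)
            _check_pattern(expr, declared)
            inits.append((count, expr))
            continue
        raise KappaParseError(f"unrecognized line: {line!r}")
    return KappaModel(agents=agents, rules=rules, inits=inits, header=header)
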