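"""Combinatorial proteoform spaces, isobaric grouping, and the {}/<> notation.

A *proteoform* is a backbone plus a fully specified per-site PTM state;
angle brackets ``<>`` name one exact proteoform (everything not listed is
unmodified) while curly brackets ``{}`` name a *discrete PTM* — the set of
proteoforms containing the listed marks, whatever else they carry.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .masscalc import BACKBONES, MSConfig, BackboneSequence, MassScale, proteoform_mass

# Canonical state order: unmodified sorts first, then acetyl, then methyls.
STATE_ORDER = {"un": 0, "ac": 1, "me1": 2, "me2": 3, "me3": 4}


@dataclass(frozen=True)
class SiteStateSchema:
    """Allowed PTM states per lysine site for one histone family."""

    family: str
    backbone: str
    sites: tuple[tuple[int, tuple[str, ...]], ...]  # sorted by residue number

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate sites in schema")
        if positions != sorted(positions):
            raise ValueError("sites must be sorted by residue number")
        for pos, states in self.sites:
            if "un" not in states:
                raise ValueError(f"site K{pos} must list 'un'")

    @property
    def site_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.sites)

    def states_at(self, pos: int) -> tuple[str, ...]:
        for p, states in self.sites:
            if p == pos:
                return states
        raise KeyError(pos)

    def backbone_seq(self) -> BackboneSequence:
        return BACKBONES[self.backbone]


def load_schema(family: str) -> SiteStateSchema:
    raw = yaml.safe_load(
        resources.files("histoquant.data").joinpath("schemas.yaml").read_text()
    )
    try:
        fam = raw["families"][family]
    except KeyError:
        raise KeyError(f"no schema for family {family!r}") from None
    sites = tuple(
        sorted(
            ((int(site[1:]), tuple(states)) for site, states in fam["sites"].items()),
            key=lambda t: t[0],
        )
    )
    return SiteStateSchema(family, fam["backbone"], sites)


@dataclass(frozen=True, order=True)
class Proteoform:
    """One fully specified PTM state over a family's schema sites."""

    family: str
    states: tuple[tuple[int, str], ...]  # (site, state) for every schema site

    def state_at(self, pos: int) -> str:
        for p, s in self.states:
            if p == pos:
                return s
        raise KeyError(pos)

    @property
    def modified(self) -> dict[int, str]:
        return {p: s for p, s in self.states if s != "un"}

    def n_acetyl(self) -> int:
        """Side-chain acetyl count (H4's fixed N-terminal ac excluded)."""
        return sum(1 for _, s in self.states if s == "ac")

    def n_methyl(self) -> int:
        """Methyl-group count: me1=1, me2=2, me3=3."""
        return sum(int(s[2]) for _, s in self.states if s.startswith("me"))

    def notation(self) -> str:
        return format_notation(ExactQuery(self.family, self.modified))


def enumerate_proteoforms(schema: SiteStateSchema) -> list[Proteoform]:
    """All proteoforms of the schema, in canonical (site, state-rank) order."""
    if not schema.sites:
        raise ValueError("schema has no sites")
    per_site = [
        [(pos, st) for st in sorted(states, key=STATE_ORDER.__getitem__)]
        for pos, states in schema.sites
    ]
    return [Proteoform(schema.family, combo) for combo in itertools.product(*per_site)]


def proteoform_neutral_mass(
    p: Proteoform, schema: SiteStateSchema, scale: MassScale = "average"
) -> float:
    return proteoform_mass(schema.backbone_seq(), dict(p.states), scale)


@dataclass(frozen=True)
class IsobaricClass:
    """Proteoforms whose intact masses co-isolate within one MS1 window."""

    representative_mass: float
    members: tuple[Proteoform, ...]
    member_masses: tuple[float, ...]

    @property
    def width(self) -> float:
        return max(self.member_masses) - min(self.member_masses)


def isobaric_classes(
    proteoforms: Sequence[Proteoform],
    config: MSConfig,
    schema: SiteStateSchema,
) -> list[IsobaricClass]:
    """Single-linkage grouping of intact masses at the MS1 window width.

    Masses are computed on ``config.mass_scale``; classes are returned sorted
    by mass.  Single linkage (split where consecutive sorted masses gap by
    more than the window) avoids bin-edge splits of near-identical masses
    such as 3xme vs 1xac compositions (0.0364 Da apart monoisotopically).
    """
    if not proteoforms:
        return []
    masses = [proteoform_neutral_mass(p, schema, config.mass_scale) for p in proteoforms]
    order = sorted(range(len(masses)), key=lambda i: masses[i])
    groups: list[list[int]] = [[order[0]]]
    for i in order[1:]:
        if masses[i] - masses[groups[-1][-1]] > config.ms1_window_da:
            groups.append([i])
        else:
            groups[-1].append(i)
    out = []
    for g in groups:
        mm = tuple(masses[i] for i in g)
        out.append(
            IsobaricClass(
                representative_mass=sum(mm) / len(mm),
                members=tuple(proteoforms[i] for i in g),
                member_masses=mm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Notation


@dataclass(frozen=True)
class ExactQuery:
    """``<>`` query: listed marks are the *only* modifications."""

    family: str | None
    states: Mapping[int, str]

    def matches(self, p: Proteoform) -> bool:
        if self.family is not None and p.family != self.family:
            return False
        return all(s == self.states.get(pos, "un") for pos, s in p.states)


@dataclass(frozen=True)
class ContainsQuery:
    """``{}`` query: listed marks are present; other sites unconstrained.

    A site may carry an alternative set (``{K9me2/3}`` = me2 OR me3), and
    ``un`` is a legal constraint (``{K9un}`` = unmodified K9).
    """

    family: str | None
    constraints: Mapping[int, frozenset[str]]

    def matches(self, p: Proteoform) -> bool:
        if self.family is not None and p.family != self.family:
            return False
        try:
            return all(p.state_at(pos) in allowed for pos, allowed in self.constraints.items())
        except KeyError:
            return False


Query = ExactQuery | ContainsQuery

_TOKEN = re.compile(r"(N-ac)|K(\d+)(un|ac|me\d(?:/\d)*)")
_HEAD = re.compile(r"^([A-Za-z][\w.]*?)?\s*([{<])(.*)([}>])$")


def parse_notation(text: str) -> Query:
    """Parse a ``Family?{...}`` / ``Family?<...>`` PTM/proteoform string."""
    m = _HEAD.match(text.strip())
    if not m:
        raise ValueError(f"malformed notation: {text!r}")
    family, open_b, body, close_b = m.groups()
    if (open_b, close_b) not in (("{", "}"), ("<", ">")):
        raise ValueError(f"mismatched brackets in {text!r}")
    exact = open_b == "<"
    pos_states: dict[int, list[str]] = {}
    cursor = 0
    for tok in _TOKEN.finditer(body):
        if tok.start() != cursor:
            raise ValueError(f"unparseable token at {body[cursor:]!r} in {text!r}")
        cursor = tok.end()
        if tok.group(1):  # N-terminal ac: fixed mod, carries no query constraint
            continue
        site = int(tok.group(2))
        state = tok.group(3)
        if "/" in state:
            if exact:
                raise ValueError(f"alternative states not allowed in <>: {state!r}")
            base, *alts = state.split("/")
            levels = [base[2:]] + alts
            states = [f"me{l}" for l in levels]
        else:
            states = [state]
        for s in states:
            if s not in STATE_ORDER:
                raise ValueError(f"unknown state {s!r} in {text!r}")
        if site in pos_states:
            raise ValueError(f"duplicate site K{site} in {text!r}")
        pos_states[site] = states
    if cursor != len(body):
        raise ValueError(f"unparseable token at {body[cursor:]!r} in {text!r}")
    if family is not None:
        try:
            schema = load_schema(family)
        except KeyError:
            schema = None
        if schema is not None:
            for site, states in pos_states.items():
                if site not in schema.site_positions:
                    raise ValueError(f"unknown site K{site} for family {family}")
                allowed = schema.states_at(site)
                for s in states:
                    if s not in allowed:
                        raise ValueError(f"state {s!r} not allowed at K{site} for {family}")
    if exact:
        for site, states in pos_states.items():
            if states == ["un"]:
                raise ValueError("'un' is implicit inside <>")
        return ExactQuery(family, {site: st[0] for site, st in pos_states.items()})
    return ContainsQuery(family, {site: frozenset(st) for site, st in pos_states.items()})


def realize_exact(q: ExactQuery, schema: SiteStateSchema) -> Proteoform:
    """Materialize the single proteoform an exact (``<>``) query names."""
    states = []
    for pos, allowed in schema.sites:
        s = q.states.get(pos, "un")
        if s not in allowed:
            raise ValueError(f"state {s!r} not allowed at K{pos} for {schema.family}")
        states.append((pos, s))
    extra = set(q.states) - set(schema.site_positions)
    if extra:
        raise ValueError(f"sites {sorted(extra)} not in the {schema.family} schema")
    return Proteoform(schema.family, tuple(states))


def _fmt_states(states: Iterable[str]) -> str:
    states = sorted(states, key=STATE_ORDER.__getitem__)
    if len(states) == 1:
        return states[0]
    if all(s.startswith("me") for s in states):
        return "me" + "/".join(s[2] for s in states)
    raise ValueError(f"cannot format alternative set {states}")


def format_notation(q: Query) -> str:
    fam = q.family or ""
    if isinstance(q, ExactQuery):
        body = "".join(f"K{pos}{q.states[pos]}" for pos in sorted(q.states))
        return f"{fam}<{body}>"
    body = "".join(
        f"K{pos}{_fmt_states(q.constraints[pos])}" for pos in sorted(q.constraints)
    )
    return f"{fam}{{{body}}}"
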