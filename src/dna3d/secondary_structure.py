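"""Extended dot-bracket parsing and decomposition into smallest secondary elements.

A DNA secondary structure is written in extended dot-bracket notation:
``(`` / ``)`` for canonical (Watson-Crick / wobble) pairs, ``[`` / ``]`` for
pseudoknot pairs, ``.`` for unpaired nucleotides, and ``&`` for a chain break
between the strands of a multi-chain complex.

The structure is decomposed into Smallest Secondary Elements (SSEs): stems
(maximal runs of stacked pairs) and the loops bounded by them -- hairpin,
bulge, internal and junction loops, plus two exterior-like elements: the open
loop (carries the molecule's dangling 5'/3' termini outside a helix) and the
break loop (a helix end whose dangling strands are separated by a chain
break lying between the helix's two paired segments).  Every loop element
carries up to two boundary base pairs from each adjoining helix, so that
adjoining elements overlap on shared pairs; the elements form a secondary
structure tree used for template search and assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DotBracket",
    "PairTable",
    "Helix",
    "SSE",
    "Interface",
    "SecondaryStructureTree",
    "DotBracketError",
    "parse_dotbracket",
    "read_vienna",
    "find_helices",
    "decompose",
    "build_tree",
    "serialize_sses",
]

_VALID_CHARS = set(".()[]&")

LOOP_KINDS = ("hairpin", "bulge", "internal", "junction", "open", "break")
SSE_KINDS = ("stem",) + LOOP_KINDS


class DotBracketError(ValueError):
    """Raised for malformed extended dot-bracket input."""


@dataclass(frozen=True)
class DotBracket:
    """A multi-chain secondary structure string.

    ``chains`` holds one dot-bracket string per chain (no ``&`` inside).
    Global positions are 0-based and skip the ``&`` separators.
    """

    chains: tuple[str, ...]

    @property
    def global_length(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def break_positions(self) -> tuple[int, ...]:
        """Global indices after which a chain break occurs."""
        out, total = [], 0
        for c in self.chains[:-1]:
            total += len(c)
            out.append(total - 1)
        return tuple(out)

    @property
    def text(self) -> str:
        return "&".join(self.chains)

    def chain_of(self, pos: int) -> int:
        total = 0
        for k, c in enumerate(self.chains):
            total += len(c)
            if pos < total:
                return k
        raise IndexError(pos)


@dataclass(frozen=True)
class PairTable:
    """Canonical pair representation of a parsed dot-bracket.

    ``partner[i]`` is the round-bracket partner of global position ``i`` or
    -1; ``pk_partner`` the same for square-bracket (pseudoknot) pairs, which
    are recorded but treated as unpaired by the decomposition.
    """

    partner: tuple[int, ...]
    pk_partner: tuple[int, ...]
    break_positions: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return len(self.partner)

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.partner) if j > i]

    def break_after(self, pos: int) -> bool:
        return pos in self.break_positions


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked base pairs (i increasing, j decreasing)."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return len(self.pairs)

    def outer(self, k: int = 2) -> tuple[tuple[int, int], ...]:
        """The up-to-``k`` outermost pairs (interface toward the exterior)."""
        return self.pairs[: min(k, self.length)]

    def inner(self, k: int = 2) -> tuple[tuple[int, int], ...]:
        """The up-to-``k`` innermost pairs (interface toward the enclosed loop)."""
        return self.pairs[-min(k, self.length):]


@dataclass(frozen=True)
class Interface:
    """One adjoining helix of an SSE: which helix, which side, which shared pairs."""

    helix_index: int
    side: str  # "outer" or "inner"
    pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SSE:
    kind: str
    positions: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    local_2d: str
    interfaces: tuple[Interface, ...] = ()
    local_seq: str | None = None

    @property
    def unpaired_positions(self) -> tuple[int, ...]:
        paired = {p for ij in self.pairs for p in ij}
        return tuple(p for p in self.positions if p not in paired)

    def with_sequence(self, seq: str) -> "SSE":
        """Attach the member nucleotides taken from a global sequence."""
        sub = "".join(seq[p] for p in self.positions)
        return SSE(self.kind, self.positions, self.pairs, self.local_2d,
                   self.interfaces, sub)


def parse_dotbracket(text: str) -> tuple[DotBracket, PairTable]:
    """Parse an extended dot-bracket string into chains and a pair table.

    Round and square brackets each follow stack discipline; ``&`` separates
    chains and is not assigned a global index.
    """
    if not text:
        raise DotBracketError("empty secondary structure string")
    bad = set(text) - _VALID_CHARS
    if bad:
        pos = min(text.index(c) for c in bad)
        raise DotBracketError(
            f"illegal character {text[pos]!r} at position {pos}; allowed: . ( ) [ ] &")
    chains = text.split("&")
    if any(len(c) == 0 for c in chains):
        raise DotBracketError("empty chain (leading, trailing or doubled '&')")

    n = sum(len(c) for c in chains)
    partner = [-1] * n
    pk = [-1] * n
    stack: list[int] = []
    pk_stack: list[int] = []
    gpos = -1
    for ch in text:
        if ch == "&":
            continue
        gpos += 1
        if ch == "(":
            stack.append(gpos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at global position {gpos}")
            i = stack.pop()
            partner[i], partner[gpos] = gpos, i
        elif ch == "[":
            pk_stack.append(gpos)
        elif ch == "]":
            if not pk_stack:
                raise DotBracketError(f"unbalanced ']' at global position {gpos}")
            i = pk_stack.pop()
            pk[i], pk[gpos] = gpos, i
    if stack:
        raise DotBracketError(f"unbalanced '(' at global position {stack[-1]}")
    if pk_stack:
        raise DotBracketError(f"unbalanced '[' at global position {pk_stack[-1]}")

    db = DotBracket(tuple(chains))
    pt = PairTable(tuple(partner), tuple(pk), db.break_positions)
    return db, pt


def read_vienna(text: str) -> tuple[str | None, str | None, DotBracket, PairTable]:
    """Read a vienna-style record: optional ``>`` header, sequence line, structure line.

    A bare structure string (single line) is also accepted.  Returns
    ``(name, sequence, DotBracket, PairTable)``.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DotBracketError("empty input")
    name = seq = None
    if lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) >= 2:
        seq, ss = lines[0], lines[1]
    else:
        ss = lines[0]
        if set(ss) - _VALID_CHARS:  # looks like a sequence only
            raise DotBracketError("no structure line found")
    db, pt = parse_dotbracket(ss)
    if seq is not None and len(seq.replace("&", "")) != db.global_length:
        raise DotBracketError("sequence and structure lengths differ")
    if seq is not None:
        seq = seq.replace("&", "")
    return name, seq, db, pt


def find_helices(pt: PairTable) -> list[Helix]:
    """All maximal stacked runs of round-bracket pairs.

    Pairs (i, j) and (i+1, j-1) stack only when no chain break separates
    i/i+1 or j-1/j; every pair belongs to exactly one helix.
    """
    helices: list[Helix] = []
    seen: set[tuple[int, int]] = set()
    for i in range(pt.n):
        j = pt.partner[i]
        if j <= i or (i, j) in seen:
            continue
        # only start at the outermost pair of a run
        if (i > 0 and pt.partner[i - 1] == j + 1
                and not pt.break_after(i - 1) and not pt.break_after(j)):
            continue
        run = [(i, j)]
        while True:
            i2, j2 = run[-1][0] + 1, run[-1][1] - 1
            if (i2 < j2 and pt.partner[i2] == j2
                    and not pt.break_after(i2 - 1) and not pt.break_after(j2)):
                run.append((i2, j2))
            else:
                break
        seen.update(run)
        helices.append(Helix(tuple(run)))
    helices.sort(key=lambda h: h.pairs[0][0])
    return helices


def _local_2d(members: list[int], pt: PairTable) -> str:
    mem = set(members)
    out: list[str] = []
    for idx, p in enumerate(members):
        q = pt.partner[p]
        if q >= 0 and q in mem:
            out.append("(" if q > p else ")")
        else:
            out.append(".")
        if idx + 1 < len(members) and members[idx + 1] == p + 1 and pt.break_after(p):
            out.append("&")
    return "".join(out)


def _has_direct_break(members: list[int], pt: PairTable) -> bool:
    mem = set(members)
    return any(p in mem and p + 1 in mem for p in pt.break_positions)


def _make_sse(kind: str, pairs: list[tuple[int, int]], extra: list[int],
              interfaces: list[Interface], pt: PairTable) -> SSE:
    members = sorted(set(extra) | {p for ij in pairs for p in ij})
    return SSE(kind=kind,
               positions=tuple(members),
               pairs=tuple(sorted(set(pairs))),
               local_2d=_local_2d(members, pt),
               interfaces=tuple(interfaces))


def decompose(pt: PairTable, seq: str | None = None) -> list[SSE]:
    """Decompose a pair table into stems and loop SSEs.

    Each maximal helix becomes a stem; each loop region bounded by helix ends
    becomes a loop SSE carrying ``min(2, helix length)`` boundary pairs from
    every adjoining helix.  Pseudoknot pairs are treated as unpaired.  A
    structure without pairs yields open SSE(s) covering everything.
    """
    helices = find_helices(pt)
    helix_by_outer_open = {h.pairs[0][0]: k for k, h in enumerate(helices)}
    sses: list[SSE] = []

    for k, h in enumerate(helices):
        paired = sorted({p for ij in h.pairs for p in ij})
        ifaces = [Interface(k, "outer", h.outer()), Interface(k, "inner", h.inner())]
        sses.append(SSE("stem", tuple(paired), tuple(h.pairs),
                        _local_2d(paired, pt), tuple(ifaces)))

    # --- loops enclosed by each helix's innermost pair -------------------
    for k, h in enumerate(helices):
        a, b = h.pairs[-1]
        pos = a + 1
        unpaired: list[int] = []
        children: list[int] = []
        while pos < b:
            j = pt.partner[pos]
            if j > pos:
                children.append(helix_by_outer_open[pos])
                pos = j + 1
            else:
                unpaired.append(pos)
                pos += 1
        ends = 1 + len(children)
        pairs = list(h.inner())
        ifaces = [Interface(k, "inner", h.inner())]
        for c in children:
            pairs.extend(helices[c].outer())
            ifaces.append(Interface(c, "outer", helices[c].outer()))
        members = sorted(set(unpaired) | {p for ij in pairs for p in ij})
        direct_break = _has_direct_break(members, pt)
        if not unpaired and ends < 2 and not direct_break:
            continue  # nothing between the stacked pairs: no loop element
        if direct_break:
            kind = "break"
        elif ends == 1:
            kind = "hairpin"
        elif ends == 2:
            # sides: between helix inner open and child outer open, and
            # between child outer close and helix inner close
            c = children[0]
            ci, cj = helices[c].pairs[0]
            side1 = ci - a - 1
            side2 = b - cj - 1
            kind = "internal" if side1 > 0 and side2 > 0 else "bulge"
        else:
            kind = "junction"
        sses.append(_make_sse(kind, pairs, unpaired, ifaces, pt))

    # --- exterior loops ---------------------------------------------------
    group_unpaired: list[int] = []
    group_helices: list[int] = []

    def _flush_exterior() -> None:
        nonlocal group_unpaired, group_helices
        if group_unpaired or len(group_helices) >= 2:
            pairs: list[tuple[int, int]] = []
            ifaces: list[Interface] = []
            for c in group_helices:
                pairs.extend(helices[c].outer())
                ifaces.append(Interface(c, "outer", helices[c].outer()))
            sses.append(_make_sse("open", pairs, group_unpaired, ifaces, pt))
        group_unpaired, group_helices = [], []

    pos = 0
    while pos < pt.n:
        j = pt.partner[pos]
        if j > pos:
            group_helices.append(helix_by_outer_open[pos])
            end = j
        else:
            group_unpaired.append(pos)
            end = pos
        # a chain break at exterior depth separates physically disconnected
        # complexes: start a new exterior group
        if pt.break_after(end):
            _flush_exterior()
        pos = end + 1
    _flush_exterior()

    sses.sort(key=lambda s: (s.positions[0], s.kind != "open"))
    if seq is not None:
        sses = [s.with_sequence(seq) for s in sses]
    return sses


def serialize_sses(sses: list[SSE], n: int, break_positions: tuple[int, ...] = ()) -> str:
    """Re-assemble the full dot-bracket text from an SSE set (round-trip check)."""
    chars = ["."] * n
    for s in sses:
        strip = s.local_2d.replace("&", "")
        for p, c in zip(s.positions, strip):
            chars[p] = c
    out = []
    for i, c in enumerate(chars):
        out.append(c)
        if i in break_positions:
            out.append("&")
    return "".join(out)


@dataclass
class SecondaryStructureTree:
    """SSEs organized as a forest: stems alternate with loops along edges.

    ``edges`` are (parent_index, child_index, shared_pairs).  ``root`` is the
    node containing the global 5' terminus; for multi-component structures
    every component keeps its own root in ``component_roots``.
    """

    sses: list[SSE]
    edges: list[tuple[int, int, tuple[tuple[int, int], ...]]]
    root: int
    component_roots: tuple[int, ...] = ()
    _children: dict[int, list[tuple[int, tuple[tuple[int, int], ...]]]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {}
        for p, c, shared in self.edges:
            self._children.setdefault(p, []).append((c, shared))

    def children(self, i: int) -> list[tuple[int, tuple[tuple[int, int], ...]]]:
        return self._children.get(i, [])

    @property
    def n_nodes(self) -> int:
        return len(self.sses)


def build_tree(sses: list[SSE]) -> SecondaryStructureTree:
    """Connect SSEs that share interface base pairs into a forest of trees.

    Stems link to the loop on their outer side and the loop on their inner
    side; the shared pairs on each edge are the helix's boundary pairs, which
    appear in both endpoint SSEs.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(sses)))
    stem_of_helix: dict[int, int] = {}
    for idx, s in enumerate(sses):
        if s.kind == "stem":
            stem_of_helix[s.interfaces[0].helix_index] = idx
    for idx, s in enumerate(sses):
        if s.kind == "stem":
            continue
        for iface in s.interfaces:
            stem_idx = stem_of_helix.get(iface.helix_index)
            if stem_idx is None:
                raise RuntimeError(
                    f"SSE {idx} references helix {iface.helix_index} with no stem")
            if not set(iface.pairs) <= set(sses[stem_idx].pairs):
                raise RuntimeError(
                    f"interface pairs of SSE {idx} missing from stem {stem_idx}")
            g.add_edge(idx, stem_idx, shared=iface.pairs)

    if len(g.edges) != len(g.nodes) - nx.number_connected_components(g):
        raise RuntimeError("SSE sharing graph is not a forest")

    roots = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        first = min(comp, key=lambda i: sses[i].positions[0])
        # prefer an exterior (open) element containing the component 5' end
        start = sses[first].positions[0]
        cands = [i for i in comp
                 if sses[i].kind == "open" and start in sses[i].positions]
        roots.append(cands[0] if cands else first)
    roots.sort(key=lambda i: sses[i].positions[0])
    root = min(roots, key=lambda i: sses[i].positions[0])

    edges: list[tuple[int, int, tuple[tuple[int, int], ...]]] = []
    for r in roots:
        for parent, child in nx.bfs_edges(g, r):
            edges.append((parent, child, g.edges[parent, child]["shared"]))
    return SecondaryStructureTree(sses, edges, root, tuple(roots))
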