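"""SSE 3D template library: corpus filtering, extraction, search and scoring.

Library construction mirrors the classification of experimental DNA
structures: only molecules combining duplex and loop structure ("D" class)
contribute templates; pure duplexes, unpaired strands and very short
oligomers are filtered out.  Each kept structure is split into its SSEs and
every element's residues become one 3D template indexed by (kind, topology
key), the topology key being the exact local dot-bracket string including
'&' placement.

At search time candidates with the query's topology key are ranked by
5 * [same topology] + 1.0 per matching loop nucleotide + 0.2 per matching
helix nucleotide.  A DNA-library hit with matching topology is a "perfect"
template; otherwise the RNA library is consulted (U residues converted to T)
and, failing that, a de-novo fragment is built from ideal geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .secondary_structure import (
    DotBracket, PairTable, SSE, decompose, find_helices, parse_dotbracket,
)
from .structure_model import (
    Chain, Residue, Structure, StructureError, base_letter,
    mutate_residue, read_structure, write_structure,
)

__all__ = [
    "Template", "TemplateLibrary", "MatchScore", "corpus_filter",
    "extract_templates", "topology_key", "score_match", "search_template",
    "build_fallback", "build_library",
]


@dataclass
class Template:
    sse_kind: str
    local_2d: str
    local_seq: str
    fragment: Structure
    source_id: str
    source_kind: str = "dna"          # dna | rna | denovo
    resolution: float | None = None
    # filled in by search_template on the returned winner:
    score: float | None = None
    perfect: bool = False


@dataclass(frozen=True)
class MatchScore:
    """Template match score: topology points plus per-nucleotide sequence points."""

    topology_points: int
    loop_matches: int
    helix_matches: int

    @property
    def total(self) -> float:
        return self.topology_points + 1.0 * self.loop_matches + 0.2 * self.helix_matches


def topology_key(local_2d: str) -> str:
    """Canonical topology key: the local dot-bracket string itself."""
    bad = set(local_2d) - set(".()&[]")
    if bad:
        raise ValueError(f"invalid characters in local 2D string: {bad}")
    return local_2d


def corpus_filter(s: Structure, db: DotBracket) -> tuple[bool, str]:
    """Keep only structures with both duplex and loop content ("D" class).

    Labels: ``unStru`` (no pairs), ``Helix`` (everything canonically paired,
    one loop-free duplex per component), else ``D``.  Triplex/quadruplex
    detection is out of scope here (callers may pre-annotate and drop).
    Returns (keep, label); keep requires label ``D`` and length >= 4.
    """
    n = s.n_residues
    if n != db.global_length:
        raise StructureError(
            f"structure has {n} residues but 2D string has {db.global_length}")
    _, pt = parse_dotbracket(db.text)
    if not pt.pairs():
        return False, "unStru"
    if all(p >= 0 for p in pt.partner):
        loopy = [x for x in decompose(pt) if x.kind != "stem"
                 and (x.unpaired_positions or len(x.interfaces) >= 2)]
        if not loopy:
            return False, "Helix"
    return n >= 4, "D"


def _split_fragment(sse: SSE, residues: list[Residue], pt_breaks: tuple[int, ...]
                    ) -> Structure:
    """Member residues as a fragment Structure, chains split at '&'."""
    frag = Structure(name="fragment")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    current = Chain(chain_ids[0])
    ci = 0
    for k, (pos, res) in enumerate(zip(sse.positions, residues)):
        current.residues.append(res.copy())
        nxt = sse.positions[k + 1] if k + 1 < len(sse.positions) else None
        if nxt is not None and nxt == pos + 1 and pos in pt_breaks:
            frag.chains.append(current)
            ci += 1
            current = Chain(chain_ids[ci % 26])
    frag.chains.append(current)
    return frag


def extract_templates(s: Structure, db: DotBracket, source_id: str = "",
                      resolution: float | None = None,
                      source_kind: str = "dna") -> list[Template]:
    """Split one corpus structure into per-SSE 3D templates."""
    keep, label = corpus_filter(s, db)
    if not keep:
        raise StructureError(f"structure {source_id or s.name} filtered out ({label})")
    _, pt = parse_dotbracket(db.text)
    flat = s.residues()
    seq = "".join(base_letter(r.name) or "N" for r in flat)
    out: list[Template] = []
    for sse in decompose(pt, seq):
        members = [flat[p] for p in sse.positions]
        if any(not r.atoms for r in members):
            continue  # residue without coordinates: skip this template
        frag = _split_fragment(sse, members, pt.break_positions)
        out.append(Template(sse.kind, sse.local_2d, sse.local_seq or "",
                            frag, source_id or s.name,
                            source_kind=source_kind, resolution=resolution))
    return out


def score_match(query_2d: str, query_seq: str | None, t: Template) -> MatchScore:
    """Score a candidate template against a query SSE.

    5 points for identical secondary structure (exact local dot-bracket
    string); sequence traversal adds 1 point per identical nucleotide in the
    loop region and 0.2 per identical nucleotide in the helix region.
    Sequences are compared only at equal lengths.
    """
    topo = 5 if query_2d == t.local_2d else 0
    loop = helix = 0
    q2 = query_2d.replace("&", "")
    t2 = t.local_2d.replace("&", "")
    if (query_seq and t.local_seq and len(q2) == len(t2)
            and len(query_seq) == len(t.local_seq)):
        for c2d, a, b in zip(q2, query_seq.upper(), t.local_seq.upper()):
            if a != b:
                continue
            if c2d == ".":
                loop += 1
            else:
                helix += 1
    return MatchScore(topo, loop, helix)


@dataclass
class TemplateLibrary:
    templates: list[Template] = field(default_factory=list)
    kind: str = "dna"
    index: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def add(self, t: Template) -> None:
        self.index.setdefault((t.sse_kind, topology_key(t.local_2d)), []).append(
            len(self.templates))
        self.templates.append(t)

    def candidates(self, sse_kind: str, key: str) -> list[Template]:
        return [self.templates[i] for i in self.index.get((sse_kind, key), [])]

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.templates:
            out[t.sse_kind] = out.get(t.sse_kind, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.templates)

    # --- on-disk layout: fragment PDBs plus a TSV index -------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for k, t in enumerate(self.templates):
            fname = f"tpl_{k:06d}.pdb"
            (directory / fname).write_text(write_structure(t.fragment))
            rows.append({
                "source_id": t.source_id, "kind": t.sse_kind,
                "local_2d": t.local_2d, "local_seq": t.local_seq,
                "resolution": "" if t.resolution is None else t.resolution,
                "source_kind": t.source_kind, "file": fname,
            })
        pd.DataFrame(rows).to_csv(directory / "index.tsv", sep="\t", index=False)
        (directory / "library.json").write_text(json.dumps({"kind": self.kind}))

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateLibrary":
        directory = Path(directory)
        meta = json.loads((directory / "library.json").read_text()) \
            if (directory / "library.json").exists() else {"kind": "dna"}
        lib = cls(kind=meta.get("kind", "dna"))
        df = pd.read_csv(directory / "index.tsv", sep="\t",
                         keep_default_na=False)
        for _, row in df.iterrows():
            frag = read_structure((directory / row["file"]).read_text())
            res = row["resolution"]
            lib.add(Template(row["kind"], row["local_2d"], row["local_seq"],
                             frag, row["source_id"],
                             source_kind=row.get("source_kind", lib.kind),
                             resolution=float(res) if res != "" else None))
        return lib


def build_library(corpus: list[tuple[str, Structure, DotBracket, float | None]],
                  kind: str = "dna") -> TemplateLibrary:
    """Build a library from (source_id, structure, dotbracket, resolution) records.

    Structures failing the corpus filter are skipped silently (they simply
    contribute no templates), matching the library construction pipeline.
    """
    lib = TemplateLibrary(kind=kind)
    for source_id, s, db, resolution in corpus:
        try:
            for t in extract_templates(s, db, source_id, resolution, source_kind=kind):
                lib.add(t)
        except StructureError:
            continue
    return lib


def _rank_key(t: Template, score: MatchScore) -> tuple:
    return (-score.total,
            0 if t.source_kind == "dna" else 1,
            t.resolution if t.resolution is not None else float("inf"),
            t.source_id)


def _convert_rna_fragment(t: Template) -> Template:
    """U -> T on a RNA-library fragment (the rest is mutated at assembly time)."""
    frag = t.fragment
    for chain in frag.chains:
        for res in chain.residues:
            if base_letter(res.name) == "U":
                frag = mutate_residue(frag, chain.id, res.number, "DT")
    seq = t.local_seq.upper().replace("U", "T")
    return Template(t.sse_kind, t.local_2d, seq, frag, t.source_id,
                    source_kind="rna", resolution=t.resolution)


def search_template(sse: SSE, dna_lib: TemplateLibrary,
                    rna_lib: TemplateLibrary | None = None,
                    excluded_source_ids: frozenset | set = frozenset(),
                    ) -> tuple[Template, bool]:
    """Best-scoring template for an SSE; falls back to RNA then de novo.

    Returns (template, perfect); perfect means a DNA-library template with
    exactly matching local secondary structure.  Ties are broken by DNA over
    RNA, then better resolution, then source id.  ``excluded_source_ids``
    are removed before scoring (leave-out evaluation).
    """
    key = topology_key(sse.local_2d)
    qseq = sse.local_seq

    def best_from(lib: TemplateLibrary | None) -> tuple[Template, MatchScore] | None:
        if lib is None:
            return None
        cands = [t for t in lib.candidates(sse.kind, key)
                 if t.source_id not in excluded_source_ids]
        if not cands:
            return None
        scored = [(t, score_match(sse.local_2d, qseq, t)) for t in cands]
        scored.sort(key=lambda ts: _rank_key(*ts))
        return scored[0]

    hit = best_from(dna_lib)
    if hit is not None:
        t, sc = hit
        winner = Template(t.sse_kind, t.local_2d, t.local_seq,
                          t.fragment.copy(), t.source_id, t.source_kind,
                          t.resolution, score=sc.total, perfect=True)
        return winner, True
    hit = best_from(rna_lib)
    if hit is not None:
        t, sc = hit
        winner = _convert_rna_fragment(t)
        winner.score = sc.total
        winner.perfect = False
        return winner, False
    fallback = build_fallback(sse, qseq or "A" * len(sse.positions))
    return fallback, False


# ---------------------------------------------------------------------------
# De-novo fallback construction from ideal geometry
# ---------------------------------------------------------------------------

def _local_pt(local_2d: str) -> PairTable:
    _, pt = parse_dotbracket(local_2d)
    return pt


def build_fallback(sse: SSE, seq: str) -> Template:
    """Construct an SSE fragment from ideal geometry when no template exists.

    Helical (paired) regions are built as ideal B-form duplex; unpaired
    nucleotides are laid on smooth arcs between their backbone attachment
    points (or as helical single-strand continuations for dangling ends next
    to a chain break or terminus).
    """
    seq = (seq or "").upper().replace("U", "T")
    if len(seq) != len(sse.positions):
        raise ValueError("sequence length does not match SSE size")
    pt = _local_pt(sse.local_2d)
    n = pt.n
    helices = find_helices(pt)
    atoms_by_pos: dict[int, dict[str, np.ndarray]] = {}
    helix_of_pos: dict[int, int] = {}

    placements = _helix_placements(helices)
    for h_idx, h in enumerate(helices):
        rot, tr = placements[h_idx]
        for step, (i, j) in enumerate(h.pairs):
            r1 = geometry.strand_residue(seq[i], step, 1)
            r2 = geometry.strand_residue(seq[j], step, 2)
            atoms_by_pos[i] = {a: rot @ x + tr for a, x in r1.items()}
            atoms_by_pos[j] = {a: rot @ x + tr for a, x in r2.items()}
            helix_of_pos[i] = helix_of_pos[j] = h_idx

    # unpaired runs
    run: list[int] = []
    runs: list[list[int]] = []
    for p in range(n):
        if pt.partner[p] < 0:
            if run and (run[-1] != p - 1 or pt.break_after(p - 1)):
                runs.append(run)
                run = []
            run.append(p)
        else:
            if run:
                runs.append(run)
                run = []
    if run:
        runs.append(run)

    center = (np.mean([x for d in atoms_by_pos.values() for x in d.values()], axis=0)
              if atoms_by_pos else np.zeros(3))
    for r in runs:
        left = r[0] - 1 if r[0] > 0 and not pt.break_after(r[0] - 1) else None
        right = r[-1] + 1 if r[-1] + 1 < n and not pt.break_after(r[-1]) else None
        left = left if left is not None and left in atoms_by_pos else None
        right = right if right is not None and right in atoms_by_pos else None
        letters = "".join(seq[p] for p in r)
        if left is not None and right is not None:
            a = atoms_by_pos[left]["O3'"]
            b = atoms_by_pos[right]["P"]
            mid = 0.5 * (a + b)
            bulge = mid - center
            if np.linalg.norm(bulge) < 1e-6:
                bulge = np.array([1.0, 0.0, 0.0])
            placed = geometry.build_arc(a, b, letters, bulge)
            for p, d in zip(r, placed):
                atoms_by_pos[p] = d
        else:
            _place_dangle(r, letters, left, right, pt, helices, helix_of_pos,
                          placements, atoms_by_pos)

    frag = Structure(name="denovo")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    chain = Chain(chain_ids[0])
    ci = 0
    for p in range(n):
        chain.residues.append(Residue("D" + seq[p], len(chain.residues) + 1,
                                      {a: x.copy() for a, x in atoms_by_pos[p].items()}))
        if p in pt.break_positions:
            frag.chains.append(chain)
            ci += 1
            chain = Chain(chain_ids[ci % 26])
    frag.chains.append(chain)
    return Template(sse.kind, sse.local_2d, seq, frag, "denovo",
                    source_kind="denovo")


def _helix_placements(helices) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rigid placement per local helix: first coaxial, others fanned out."""
    if not helices:
        return []
    placements = [(np.eye(3), np.zeros(3))]
    k = len(helices)
    for j in range(1, k):
        if k == 2:
            # coaxial continuation leaving one rise of room (internal/bulge)
            gap = 2 + 1
            rot = geometry.rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                               geometry.TWIST * gap)
            tr = np.array([0.0, 0.0, geometry.RISE * gap])
            # child helix runs inward-to-outward: flip so its outer pairs
            # face away from helix 0
            placements.append((rot, tr))
        else:
            ang = 360.0 * j / k
            rot = (geometry.rotation_about_axis(np.array([0.0, 1.0, 0.0]), ang)
                   @ geometry.rotation_about_axis(np.array([0.0, 0.0, 1.0]), 180.0))
            axis_dir = rot @ np.array([0.0, 0.0, 1.0])
            tr = axis_dir * 14.0
            placements.append((rot, tr))
    return placements


def _place_dangle(run, letters, left, right, pt, helices, helix_of_pos,
                  placements, atoms_by_pos) -> None:
    """Helical single-strand continuation for terminal/break-side dangles."""
    if left is not None:
        h = helix_of_pos[left]
        rot, tr = placements[h]
        strand = 1 if any(left == i for i, _ in helices[h].pairs) else 2
        steps = {i: s for s, (i, j) in enumerate(helices[h].pairs)} if strand == 1 \
            else {j: s for s, (i, j) in enumerate(helices[h].pairs)}
        base_step = steps[left]
        direction = +1 if strand == 1 else -1
        for off, (p, b) in enumerate(zip(run, letters), start=1):
            r = geometry.strand_residue(b, base_step + direction * off, strand)
            atoms_by_pos[p] = {a: rot @ x + tr for a, x in r.items()}
    elif right is not None:
        h = helix_of_pos[right]
        rot, tr = placements[h]
        strand = 1 if any(right == i for i, _ in helices[h].pairs) else 2
        steps = {i: s for s, (i, j) in enumerate(helices[h].pairs)} if strand == 1 \
            else {j: s for s, (i, j) in enumerate(helices[h].pairs)}
        base_step = steps[right]
        direction = -1 if strand == 1 else +1
        for off, (p, b) in enumerate(zip(reversed(run), reversed(letters)), start=1):
            r = geometry.strand_residue(b, base_step + direction * off, strand)
            atoms_by_pos[p] = {a: rot @ x + tr for a, x in r.items()}
    else:
        # fully detached strand: extended helical single strand at the origin
        for s, (p, b) in enumerate(zip(run, letters)):
            atoms_by_pos[p] = geometry.strand_residue(b, s, 1)
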