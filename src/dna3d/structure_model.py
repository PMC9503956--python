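"""All-atom nucleic-acid structures: PDB I/O, standardization, mutation, coarse-graining.

The in-memory model is deliberately small: chains hold ordered residues,
residues hold named heavy atoms with coordinates in Angstrom.  Reading goes
through gemmi (first MODEL of NMR ensembles, highest-occupancy altloc);
writing emits plain ATOM records with TER between chains.

Standardization maps modified nucleotides onto their parent base, atom
completion grafts ideal-geometry atoms onto residues with missing atoms, and
mutation swaps the base atoms for an ideal target base superposed on the old
base's reference frame, leaving backbone and sugar untouched.  The 6-bead
coarse-grained view (P, C4', C2', C2, C4, C6 per residue) feeds the Monte
Carlo refiner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import (
    BASE_ATOMS, BACKBONE_ATOMS, COARSE_BEADS, SUGAR_ATOMS,
    ideal_nucleotide, kabsch_transform,
)

__all__ = [
    "Structure", "Chain", "Residue", "CoarseModel", "BaseFrame",
    "StructureError", "read_structure", "write_structure",
    "clean_and_standardize", "complete_atoms", "mutate_residue",
    "coarse_grain", "base_frame", "base_letter", "is_deoxy",
]

STANDARD_NAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "T"}

#: parent standard base for common modified nucleotides (resname -> letter)
MODIFIED_BASE_MAP: dict[str, str] = {
    "5MC": "C", "5CM": "C", "OMC": "C", "4OC": "C", "M5M": "C", "CBR": "C",
    "5BU": "U", "BRU": "U", "UMP": "U", "5MU": "U", "PSU": "U", "H2U": "U",
    "4SU": "U", "OMU": "U", "DHU": "U", "70U": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MA": "A", "OMA": "A", "A2M": "A",
    "8AN": "A", "AP7": "A",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "YG": "G",
    "G7M": "G", "8OG": "G", "GDP": "G", "GTP": "G",
    "I": "G", "DI": "G", "7DA": "A", "6OG": "G", "XUA": "A",
    "DOC": "C", "5IU": "U", "UR3": "U", "3DR": "T", "64T": "T", "TTD": "T",
}

_AA_NAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


class StructureError(ValueError):
    """Raised for unreadable or structurally invalid input."""


@dataclass
class Residue:
    name: str
    number: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    icode: str = ""

    def copy(self) -> "Residue":
        return Residue(self.name, self.number,
                       {k: v.copy() for k, v in self.atoms.items()}, self.icode)

    def coords(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.atoms[n] for n in names])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    name: str = ""
    remarks: list[str] = field(default_factory=list)

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.name,
                         list(self.remarks))

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def residues(self) -> list[Residue]:
        """All residues flattened in chain order (the global position order)."""
        return [r for c in self.chains for r in c.residues]

    def sequence(self) -> str:
        return "".join(base_letter(r.name) or "N" for r in self.residues())


def base_letter(resname: str) -> str | None:
    """Parent base letter (A/C/G/T/U) for a residue name, or None."""
    resname = resname.strip().upper()
    if resname in STANDARD_NAMES:
        return resname[-1]
    return MODIFIED_BASE_MAP.get(resname)


def is_deoxy(residue: Residue) -> bool:
    if residue.name.startswith("D") and residue.name in STANDARD_NAMES:
        return True
    return "O2'" not in residue.atoms


def _looks_nucleic(res: Residue) -> bool:
    if base_letter(res.name) is not None:
        return True
    if res.name.upper() in _AA_NAMES or res.name.upper() in {"HOH", "WAT"}:
        return False
    return "C1'" in res.atoms and ("N9" in res.atoms or "N1" in res.atoms)


def read_structure(pdb_text: str, name: str = "") -> Structure:
    """Parse PDB text: first MODEL, highest-occupancy altloc (ties prefer 'A')."""
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"PDB parse error: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no models in PDB input")
    model = st[0]

    structure = Structure(name=name or st.name)
    for ch in model:
        chain = Chain(ch.name or "A")
        for res in ch:
            out = Residue(res.name.strip(), res.seqid.num,
                          icode=(res.seqid.icode or "").strip())
            best_occ: dict[str, tuple[float, str]] = {}
            for atom in res:
                aname = atom.name.replace("*", "'")
                occ, alt = atom.occ, (atom.altloc or "A")
                prev = best_occ.get(aname)
                if (prev is None or occ > prev[0]
                        or (occ == prev[0] and alt < prev[1])):
                    best_occ[aname] = (occ, alt)
                    xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if not np.all(np.isfinite(xyz)):
                        raise StructureError(
                            f"non-finite coordinates in residue {res.name} {res.seqid.num}")
                    out.atoms[aname] = xyz
            if out.atoms:
                chain.residues.append(out)
        if chain.residues:
            structure.chains.append(chain)
    if not any(_looks_nucleic(r) for r in structure.residues()):
        raise StructureError("no nucleic-acid residues found")
    return structure


def write_structure(s: Structure) -> str:
    """Serialize to PDB ATOM records, TER between chains, 3-decimal coordinates."""
    lines: list[str] = []
    serial = 0
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
    for ci, chain in enumerate(s.chains):
        cid = (chain.id or chain_ids[ci % len(chain_ids)])[0]
        for res in chain.residues:
            for aname, xyz in res.atoms.items():
                serial += 1
                if serial > 99999:
                    raise StructureError("more than 99999 atoms")
                elem = next((c for c in aname if c.isalpha()), "C")
                pdb_name = f" {aname:<3s}" if len(aname) < 4 else f"{aname:<4s}"
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:4s} {res.name:>3s} {cid}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}")
        if chain.residues:
            serial += 1
            last = chain.residues[-1]
            lines.append(f"TER   {serial:5d}      {last.name:>3s} {cid}{last.number:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _allowed_atoms(letter: str, deoxy: bool) -> set[str]:
    allowed = set(BASE_ATOMS[letter]) | set(SUGAR_ATOMS) | set(BACKBONE_ATOMS)
    if not deoxy:
        allowed.add("O2'")
    return allowed


def _overlap_fallback(res: Residue) -> str | None:
    """Guess the parent base of an unknown nucleotide by ring-atom overlap."""
    best, best_n = None, 0
    for letter, names in BASE_ATOMS.items():
        n = sum(1 for a in names if a in res.atoms)
        if n > best_n:
            best, best_n = letter, n
    return best if best_n >= 3 else None


def clean_and_standardize(s: Structure) -> Structure:
    """Drop non-nucleic residues and map modified bases to their parent base.

    Nonstandard nucleotides are renamed via a built-in table (unknowns by
    maximal ring-atom overlap); atoms outside the parent base's ideal atom
    set are discarded.  Residues still missing a coarse-grain bead atom are
    flagged in ``remarks`` (atom completion can rebuild them).
    """
    out = Structure(name=s.name)
    for chain in s.chains:
        new = Chain(chain.id)
        for res in chain.residues:
            letter = base_letter(res.name)
            if letter is None:
                if not _looks_nucleic(res):
                    continue
                letter = _overlap_fallback(res)
                if letter is None:
                    out.remarks.append(f"dropped unidentifiable residue {res.name} {res.number}")
                    continue
            deoxy = "O2'" not in res.atoms
            if deoxy and letter == "U":
                letter = "T"  # deoxy-uridine variants are modelled as thymidine
            name = letter if not deoxy else "D" + letter
            allowed = _allowed_atoms(letter, deoxy)
            atoms = {a: xyz.copy() for a, xyz in res.atoms.items() if a in allowed}
            if not atoms:
                continue
            kept = Residue(name, res.number, atoms, res.icode)
            missing = [b for b in COARSE_BEADS if b not in atoms]
            if missing:
                out.remarks.append(
                    f"residue {name} {res.number} missing bead atoms {','.join(missing)}")
            new.residues.append(kept)
        if new.residues:
            out.chains.append(new)
    if not out.chains:
        out.remarks.append("no nucleic residues after cleaning")
    return out


def complete_atoms(s: Structure) -> Structure:
    """Rebuild missing heavy atoms from ideal residue geometry.

    The ideal nucleotide is superposed on >= 3 shared atoms of each residue
    and missing atoms copied over; residues with fewer than 3 usable
    reference atoms are dropped (and logged in ``remarks``).
    """
    out = Structure(name=s.name, remarks=list(s.remarks))
    for chain in s.chains:
        new = Chain(chain.id)
        for res in chain.residues:
            letter = base_letter(res.name)
            if letter is None:
                continue
            deoxy = is_deoxy(res)
            if deoxy and letter == "U":
                letter = "T"
            ideal = ideal_nucleotide(letter, deoxy=deoxy)
            shared = [a for a in ideal if a in res.atoms]
            missing = [a for a in ideal if a not in res.atoms]
            if not missing:
                new.residues.append(res.copy())
                continue
            if len(shared) < 3:
                out.remarks.append(
                    f"dropped residue {res.name} {res.number}: "
                    f"only {len(shared)} reference atoms")
                continue
            rot, t, _ = kabsch_transform(
                np.array([ideal[a] for a in shared]),
                np.array([res.atoms[a] for a in shared]))
            fixed = res.copy()
            for a in missing:
                fixed.atoms[a] = rot @ ideal[a] + t
            new.residues.append(fixed)
        if new.residues:
            out.chains.append(new)
    return out


@dataclass(frozen=True)
class BaseFrame:
    """Orthonormal right-handed frame anchored on the base ring (C2, C4, C6)."""

    origin: np.ndarray
    axes: np.ndarray  # rows are the unit axes


def base_frame(res: Residue) -> BaseFrame:
    try:
        c2, c4, c6 = res.atoms["C2"], res.atoms["C4"], res.atoms["C6"]
    except KeyError as exc:
        raise StructureError(f"residue {res.name} {res.number} lacks ring atom {exc}")
    origin = (c2 + c4 + c6) / 3.0
    x = c2 - origin
    x /= np.linalg.norm(x)
    v = c4 - origin
    y = v - (v @ x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return BaseFrame(origin, np.vstack([x, y, z]))


def _find_residue(s: Structure, chain_id: str, number: int) -> Residue:
    for chain in s.chains:
        if chain.id == chain_id:
            for res in chain.residues:
                if res.number == number:
                    return res
            raise StructureError(f"no residue {number} in chain {chain_id}")
    raise StructureError(f"no chain {chain_id}")


def mutate_residue(s: Structure, chain_id: str, number: int,
                   target_base: str) -> Structure:
    """Replace the base of one residue with an ideal target base.

    Backbone and sugar atoms are untouched; the new base is placed by
    superposing the ideal geometry of the *old* base onto its observed atoms
    (all standard-frame bases share the glycosidic attachment, so the
    linkage is preserved).  Converting a ribo template to DNA removes O2';
    U -> T gains the C7 methyl from the ideal table.
    """
    t = target_base.strip().upper()
    if t.startswith("D") and len(t) == 2:
        letter, deoxy = t[1], True
    elif t in {"A", "C", "G", "T", "U"}:
        letter, deoxy = t, False
    else:
        raise StructureError(f"unknown target base {target_base!r}")
    if deoxy and letter == "U":
        letter = "T"
    if letter not in BASE_ATOMS:
        raise StructureError(f"unknown target base {target_base!r}")

    out = s.copy()
    res = _find_residue(out, chain_id, number)
    old_letter = base_letter(res.name)
    if old_letter is None:
        raise StructureError(f"residue {res.name} {res.number} is not a standard base")
    ideal_old = ideal_nucleotide(old_letter, deoxy=is_deoxy(res))
    anchor_names = [a for a in BASE_ATOMS[old_letter] + ("C1'",) if a in res.atoms]
    if len(anchor_names) < 3:
        raise StructureError(
            f"residue {res.name} {res.number}: too few base atoms for a frame")
    rot, tv, _ = kabsch_transform(
        np.array([ideal_old[a] for a in anchor_names]),
        np.array([res.atoms[a] for a in anchor_names]))

    for a in BASE_ATOMS[old_letter]:
        res.atoms.pop(a, None)
    if deoxy:
        res.atoms.pop("O2'", None)
    ideal_new = ideal_nucleotide(letter, deoxy=True)
    for a in BASE_ATOMS[letter]:
        res.atoms[a] = rot @ ideal_new[a] + tv
    res.name = ("D" + letter) if deoxy else letter
    return out


@dataclass
class CoarseModel:
    """6 beads per residue: P, C4', C2' (backbone/sugar) and C2, C4, C6 (base)."""

    coords: np.ndarray            # (n_residues, 6, 3)
    chain_index: np.ndarray       # (n_residues,) chain of each residue
    resnames: tuple[str, ...]
    bead_names: tuple[str, ...] = COARSE_BEADS

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)


def coarse_grain(s: Structure) -> CoarseModel:
    """Extract the 6-bead representation; errors if any bead atom is absent."""
    coords, chain_idx, names = [], [], []
    for ci, chain in enumerate(s.chains):
        for res in chain.residues:
            try:
                coords.append([res.atoms[b] for b in COARSE_BEADS])
            except KeyError as exc:
                raise StructureError(
                    f"residue {res.name} {res.number} (chain {chain.id}) "
                    f"lacks bead atom {exc}") from exc
            chain_idx.append(ci)
            names.append(res.name)
    if not coords:
        raise StructureError("empty structure")
    return CoarseModel(np.array(coords), np.array(chain_idx), tuple(names))
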