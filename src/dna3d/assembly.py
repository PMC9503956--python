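"""Rigid assembly of SSE templates into a full 3D model.

Adjoining SSEs share up to two base pairs; each child template is superposed
onto its already-placed parent over all heavy atoms of those shared residues
(Kabsch least squares, proper rotation).  Duplicated interface residues keep
the parent's copy.  The assembled model is then mutated to the target
sequence and chain connectivity across O3'-P junctions is repaired by a
small harmonic minimizer standing in for a force-field relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_transform
from .secondary_structure import SecondaryStructureTree
from .structure_model import (
    Chain, Residue, Structure, StructureError, base_letter, complete_atoms,
    is_deoxy, mutate_residue,
)

__all__ = ["RigidTransform", "AssemblyResult", "AssemblyError",
           "kabsch", "assemble", "repair_connectivity"]


class AssemblyError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of point set ``p`` onto ``q`` and its RMSD."""
    rot, t, rms = kabsch_transform(p, q)
    return RigidTransform(rot, t), rms


@dataclass
class AssemblyResult:
    structure: Structure
    perfect: bool
    provenance: list[dict] = field(default_factory=list)


def _chain_layout(break_positions: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """(start, stop) global position ranges of each chain."""
    bounds, start = [], 0
    for b in break_positions:
        bounds.append((start, b + 1))
        start = b + 1
    bounds.append((start, n))
    return bounds


def assemble(tree: SecondaryStructureTree, chosen: dict[int, "Template"],
             target_seq: str, break_positions: tuple[int, ...] = ()
             ) -> AssemblyResult:
    """Place one template per SSE by superposition on shared base pairs.

    The root template sits in its own frame; children are grafted breadth
    first over the heavy atoms of the up-to-2 shared pairs.  Separate
    connected components (no shared pairs at all) are offset along x so they
    do not overlap.  Finally every residue is mutated to ``target_seq``.
    """
    n = len(target_seq)
    placed: dict[int, Residue] = {}
    provenance: list[dict] = []
    perfect = True

    for idx, sse in enumerate(tree.sses):
        if idx not in chosen:
            raise AssemblyError(f"no template chosen for SSE {idx} ({sse.kind})")

    def place_fragment(idx: int, transform: RigidTransform | None) -> None:
        tpl = chosen[idx]
        sse = tree.sses[idx]
        frag_res = tpl.fragment.residues()
        if len(frag_res) != len(sse.positions):
            raise AssemblyError(
                f"template for SSE {idx} has {len(frag_res)} residues, "
                f"expected {len(sse.positions)}")
        for pos, res in zip(sse.positions, frag_res):
            if pos in placed:
                continue  # interface residue: the parent's copy wins
            new = res.copy()
            if transform is not None:
                new.atoms = {a: transform.apply(x) for a, x in new.atoms.items()}
            placed[pos] = new

    for root in (tree.component_roots or (tree.root,)):
        # offset additional components so they don't sit on top of each other
        offset = RigidTransform.identity()
        if placed:
            xs = [x[0] for r in placed.values() for x in r.atoms.values()]
            offset = RigidTransform(np.eye(3),
                                    np.array([max(xs) + 30.0, 0.0, 0.0]))
        place_fragment(root, offset)
        stack = [root]
        while stack:
            parent = stack.pop(0)
            for child, shared in tree.children(parent):
                shared_pos = sorted(p for ij in shared for p in ij)
                sse_c = tree.sses[child]
                frag_res = chosen[child].fragment.residues()
                pos_index = {p: k for k, p in enumerate(sse_c.positions)}
                pts_child, pts_parent = [], []
                for p in shared_pos:
                    if p not in pos_index or p not in placed:
                        raise AssemblyError(
                            f"shared pair residue {p} missing between SSEs "
                            f"{parent} and {child}")
                    child_res = frag_res[pos_index[p]]
                    parent_res = placed[p]
                    names = sorted(set(child_res.atoms) & set(parent_res.atoms))
                    if not names:
                        raise AssemblyError(
                            f"no common atoms on shared residue {p} between "
                            f"SSEs {parent} and {child}")
                    pts_child.extend(child_res.atoms[a] for a in names)
                    pts_parent.extend(parent_res.atoms[a] for a in names)
                if len(pts_child) < 3:
                    raise AssemblyError(
                        f"fewer than 3 superposition atoms between SSEs "
                        f"{parent} and {child}")
                transform, _ = kabsch(np.array(pts_child), np.array(pts_parent))
                place_fragment(child, transform)
                stack.append(child)

    for idx, sse in enumerate(tree.sses):
        tpl = chosen[idx]
        perfect = perfect and bool(getattr(tpl, "perfect", False))
        provenance.append({
            "sse": idx, "kind": sse.kind, "local_2d": sse.local_2d,
            "template_source": tpl.source_id, "source_kind": tpl.source_kind,
            "score": getattr(tpl, "score", None),
            "perfect": bool(getattr(tpl, "perfect", False)),
        })

    missing = [p for p in range(n) if p not in placed]
    if missing:
        raise AssemblyError(f"positions never placed: {missing[:5]}...")

    structure = Structure(name="assembled")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for ci, (start, stop) in enumerate(_chain_layout(break_positions, n)):
        chain = Chain(chain_ids[ci % 26])
        for k, pos in enumerate(range(start, stop)):
            res = placed[pos]
            res.number = k + 1
            res.icode = ""
            chain.residues.append(res)
        structure.chains.append(chain)

    structure = _mutate_to_target(structure, target_seq)
    structure = complete_atoms(structure)
    structure.name = "assembled"
    return AssemblyResult(structure, perfect, provenance)


def _mutate_to_target(structure: Structure, target_seq: str) -> Structure:
    pos = 0
    todo = []  # (chain id, residue number, target) gathered before mutating
    for chain in structure.chains:
        for res in chain.residues:
            want = target_seq[pos].upper()
            if base_letter(res.name) != want or not is_deoxy(res):
                todo.append((chain.id, res.number, "D" + want))
            pos += 1
    for cid, num, target in todo:
        structure = mutate_residue(structure, cid, num, target)
    return structure


def repair_connectivity(s: Structure, max_iters: int = 1000) -> Structure:
    """Close O3'(i)-P(i+1) gaps across intra-chain junctions.

    Gradient descent on a harmonic objective: each junction distance is
    restrained to 1.60 A while every moving atom is tethered to its input
    position, so only junction neighborhoods shift.  The objective never
    increases (backtracking line search); stops at ``max_iters`` or when the
    gradient norm drops below 1e-6.
    """
    if max_iters <= 0:
        return s.copy()
    out = s.copy()
    k_bond, k_pos = 1.0, 0.05
    d0 = 1.60

    junctions = []  # (res_a, res_b) with O3' and P present
    for chain in out.chains:
        for a, b in zip(chain.residues, chain.residues[1:]):
            if "O3'" in a.atoms and "P" in b.atoms:
                junctions.append((a, b))
    if not junctions:
        return out

    # only the junction atoms feel a net force; collect them as variables
    xs = []
    for a, b in junctions:
        xs.append(a.atoms["O3'"])
        xs.append(b.atoms["P"])
    x = np.array(xs, dtype=float)
    x0 = x.copy()

    def objective_grad(xv: np.ndarray) -> tuple[float, np.ndarray]:
        obj = float(k_pos * ((xv - x0) ** 2).sum())
        grad = 2.0 * k_pos * (xv - x0)
        for j in range(len(junctions)):
            p, q = xv[2 * j], xv[2 * j + 1]
            d = np.linalg.norm(p - q)
            if d < 1e-9:
                continue
            obj += k_bond * (d - d0) ** 2
            g = 2.0 * k_bond * (d - d0) * (p - q) / d
            grad[2 * j] += g
            grad[2 * j + 1] -= g
        return obj, grad

    step = 0.1
    obj, grad = objective_grad(x)
    for _ in range(max_iters):
        if np.linalg.norm(grad) < 1e-6:
            break
        trial = x - step * grad
        obj_t, grad_t = objective_grad(trial)
        while obj_t > obj and step > 1e-12:
            step *= 0.5
            trial = x - step * grad
            obj_t, grad_t = objective_grad(trial)
        if obj_t > obj:
            break
        x, obj, grad = trial, obj_t, grad_t
        step = min(step * 1.5, 1.0)

    for j, (a, b) in enumerate(junctions):
        a.atoms["O3'"] = x[2 * j]
        b.atoms["P"] = x[2 * j + 1]
    return out
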