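"""Ideal nucleotide geometry and de-novo helix/loop construction.

Bases are kept as rigid planar units in the standard base reference frame
(the frame in which an ideal Watson-Crick pair is formed by rotating the
complementary base 180 deg about the pair x-axis).  A C2'-endo / anti
sugar-phosphate moiety is grown from the glycosidic nitrogen by internal
coordinates (bond lengths, angles and torsions typical of B-form DNA), giving
a full heavy-atom ideal nucleotide per base type.  Ideal B-form duplexes are
generated by stacking pair frames with a fixed helical twist and rise;
unpaired loop nucleotides are laid out on circular arcs connecting their
backbone attachment points.

These primitives back atom completion, base mutation, the de-novo template
fallback and the synthetic fixture generator.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "STANDARD_BASES", "BASE_ATOMS", "SUGAR_ATOMS", "BACKBONE_ATOMS",
    "COARSE_BEADS", "complement", "ideal_nucleotide", "ideal_atom_names",
    "build_duplex", "duplex_frames", "strand_residue", "build_arc",
    "rotation_about_axis", "nerf",
]

# --- standard base reference frame coordinates (x, y; base plane z = 0) ---
# Purines attach at N9, pyrimidines at N1; C1' is included so that a base
# can be grafted onto an existing glycosidic geometry by superposition.
STANDARD_BASES: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346), "N9": (-1.291, 4.498), "C8": (0.024, 4.897),
        "N7": (0.877, 3.902), "C5": (0.071, 2.771), "C6": (0.369, 1.398),
        "N6": (1.611, 0.909), "N1": (-0.668, 0.532), "C2": (-2.035, 1.023),
        "N3": (-2.531, 2.252), "C4": (-1.267, 3.124),
    },
    "G": {
        "C1'": (-2.477, 5.399), "N9": (-1.289, 4.551), "C8": (0.023, 4.962),
        "N7": (0.870, 3.969), "C5": (0.071, 2.833), "C6": (0.424, 1.460),
        "O6": (1.554, 0.955), "N1": (-0.700, 0.641), "C2": (-2.006, 1.087),
        "N2": (-2.928, 0.139), "N3": (-2.509, 2.304), "C4": (-1.265, 3.177),
    },
    "C": {
        "C1'": (-2.477, 5.402), "N1": (-1.285, 4.542), "C2": (-1.472, 3.158),
        "O2": (-2.628, 2.709), "N3": (-0.391, 2.344), "C4": (0.837, 2.868),
        "N4": (1.875, 2.027), "C5": (1.056, 4.275), "C6": (-0.023, 5.068),
    },
    "T": {
        "C1'": (-2.481, 5.354), "N1": (-1.284, 4.500), "C2": (-1.462, 3.135),
        "O2": (-2.562, 2.608), "N3": (-0.298, 2.407), "C4": (0.994, 2.897),
        "O4": (1.944, 2.119), "C5": (1.106, 4.338), "C7": (2.466, 4.961),
        "C6": (-0.024, 5.057),
    },
    "U": {
        "C1'": (-2.481, 5.354), "N1": (-1.284, 4.500), "C2": (-1.462, 3.131),
        "O2": (-2.563, 2.608), "N3": (-0.302, 2.397), "C4": (0.989, 2.884),
        "O4": (1.935, 2.094), "C5": (1.089, 4.311), "C6": (-0.024, 5.053),
    },
}

BASE_ATOMS: dict[str, tuple[str, ...]] = {
    b: tuple(n for n in tbl if n != "C1'") for b, tbl in STANDARD_BASES.items()
}
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "O3'")
COARSE_BEADS = ("P", "C4'", "C2'", "C2", "C4", "C6")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

# Glycosidic nitrogen and the base atom defining the chi torsion.
_GLYC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
_CHI_REF = {"A": "C4", "G": "C4", "C": "C2", "T": "C2", "U": "C2"}

# --- B-form internal-coordinate parameters --------------------------------
CHI = -135.0          # (high-)anti glycosidic torsion O4'-C1'-N-Cref (deg)
GAMMA = 70.0          # O5'-C5'-C4'-C3' (deg), gauche+
BETA = 130.0          # P-O5'-C5'-C4' (deg)
PSEUDOROT_P = 162.0   # sugar pucker phase: C2'-endo (deg)
PSEUDOROT_TM = 35.0   # pucker amplitude (deg)
TWIST = 36.0          # helical twist per base pair step (deg)
RISE = 3.38           # helical rise per base pair step (Angstrom)

# Branch signs fixing the chirality of substituents grown off the ring;
# calibrated once against backbone continuity and steric sanity of the
# generated duplex (see docs/methods.md).
_SIGN_C2 = -1.0  # improper offset placing C2' relative to O4' about N-C1'
_SIGN_O3 = -1.0  # O3' branch off C3'
_SIGN_C5 = -1.0  # C5' branch off C4'
_SIGN_O2 = 1.0   # O2' branch off C2' (ribonucleotides)
_HELIX_DIR = 1.0  # sign of twist/rise so strand I runs 5'->3' with the stack


def complement(letter: str) -> str:
    return _COMPLEMENT[letter.upper()]


def _deg(x: float) -> float:
    return np.deg2rad(x)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         r: float, theta_deg: float, tor_deg: float) -> np.ndarray:
    """Place atom D bonded to C given bond length, angle B-C-D and torsion A-B-C-D."""
    theta, tor = _deg(theta_deg), _deg(tor_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(tor),
        r * np.sin(theta) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_transform(p: np.ndarray, q: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of points ``p`` onto ``q``.

    Returns (rotation, translation, rmsd) with a proper rotation (det +1;
    reflections corrected by flipping the smallest singular direction), such
    that ``p @ rotation.T + translation`` best fits ``q``.  Requires >= 3
    points; degenerate (collinear) sets still return a minimizing transform
    with the free rotation fixed deterministically by the SVD.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be n x 3")
    if len(p) < 3:
        raise ValueError("at least 3 points are required for superposition")
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cq - rot @ cp
    diff = (p @ rot.T + t) - q
    return rot, t, float(np.sqrt((diff ** 2).sum() / len(p)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = _deg(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _nu(j: int) -> float:
    """Sugar ring torsion nu_j from the pseudorotation phase/amplitude."""
    return PSEUDOROT_TM * np.cos(_deg(PSEUDOROT_P + (j - 2) * 144.0))


@lru_cache(maxsize=None)
def ideal_nucleotide(letter: str, deoxy: bool = True) -> dict[str, np.ndarray]:
    """Full heavy-atom ideal nucleotide in the standard base reference frame.

    The base atoms sit exactly at the standard-frame coordinates; sugar and
    phosphate are grown from the glycosidic nitrogen with B-form internal
    coordinates (C2'-endo pucker, anti base).  Returns a fresh copy.
    """
    letter = letter.upper()
    tbl = STANDARD_BASES[letter]
    atoms: dict[str, np.ndarray] = {
        name: np.array([x, y, 0.0]) for name, (x, y) in tbl.items()
    }
    n = atoms[_GLYC_N[letter]]
    c1 = atoms["C1'"]
    cref = atoms[_CHI_REF[letter]]

    atoms["O4'"] = nerf(cref, n, c1, 1.414, 108.2, CHI)
    atoms["C2'"] = nerf(cref, n, c1, 1.526, 113.7, CHI + _SIGN_C2 * 121.0)
    atoms["C3'"] = nerf(atoms["O4'"], c1, atoms["C2'"], 1.525, 102.5, _nu(1))
    atoms["C4'"] = nerf(c1, atoms["C2'"], atoms["C3'"], 1.527, 102.7, _nu(2))
    atoms["O3'"] = nerf(c1, atoms["C2'"], atoms["C3'"], 1.423, 110.3,
                        _nu(2) + _SIGN_O3 * 119.0)
    atoms["C5'"] = nerf(atoms["C2'"], atoms["C3'"], atoms["C4'"], 1.510, 114.7,
                        _nu(3) + _SIGN_C5 * 119.0)
    atoms["O5'"] = nerf(atoms["C3'"], atoms["C4'"], atoms["C5'"], 1.440, 110.2, GAMMA)
    atoms["P"] = nerf(atoms["C4'"], atoms["C5'"], atoms["O5'"], 1.593, 120.9, BETA)
    atoms["OP1"] = nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.485, 108.0, -60.0 + 115.0)
    atoms["OP2"] = nerf(atoms["C5'"], atoms["O5'"], atoms["P"], 1.485, 108.0, -60.0 - 115.0)
    if not deoxy:
        atoms["O2'"] = nerf(atoms["O4'"], c1, atoms["C2'"], 1.413, 110.6,
                            _nu(1) + _SIGN_O2 * 120.0)
    return {k: v.copy() for k, v in atoms.items()}


def ideal_atom_names(letter: str, deoxy: bool = True) -> tuple[str, ...]:
    return tuple(ideal_nucleotide(letter, deoxy).keys())


_WC_FLIP = np.diag([1.0, -1.0, -1.0])


def duplex_frames(n: int, twist: float = TWIST, rise: float = RISE
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rigid frames (rotation, translation) for base-pair steps 0..n-1."""
    out = []
    for k in range(n):
        r = rotation_about_axis(np.array([0.0, 0.0, 1.0]), _HELIX_DIR * twist * k)
        t = np.array([0.0, 0.0, _HELIX_DIR * rise * k])
        out.append((r, t))
    return out


def strand_residue(letter: str, k: int, strand: int = 1,
                   twist: float = TWIST, rise: float = RISE,
                   deoxy: bool = True) -> dict[str, np.ndarray]:
    """One nucleotide placed at helical step ``k`` on strand 1 or 2.

    Strand 2 is the Watson-Crick mate: the base frame rotated 180 deg about
    the pair x-axis, so pairing ``strand_residue(b, k, 1)`` with
    ``strand_residue(complement(b), k, 2)`` yields an ideal pair at step k.
    """
    ideal = ideal_nucleotide(letter, deoxy=deoxy)
    r = rotation_about_axis(np.array([0.0, 0.0, 1.0]), _HELIX_DIR * twist * k)
    t = np.array([0.0, 0.0, _HELIX_DIR * rise * k])
    flip = np.eye(3) if strand == 1 else _WC_FLIP
    return {name: r @ (flip @ xyz) + t for name, xyz in ideal.items()}


def build_duplex(seq: str, twist: float = TWIST, rise: float = RISE
                 ) -> tuple[list[dict[str, np.ndarray]], list[dict[str, np.ndarray]]]:
    """Ideal B-form duplex for ``seq`` (strand 1, 5'->3').

    Returns two residue lists: strand 1 in 5'->3' order and the complementary
    strand 2, also in its own 5'->3' order (reverse of the step order).
    """
    seq = seq.upper()
    s1 = [strand_residue(b, k, 1, twist, rise) for k, b in enumerate(seq)]
    s2 = [strand_residue(complement(b), k, 2, twist, rise)
          for k, b in enumerate(seq)]
    return s1, list(reversed(s2))


def _arc_points(a: np.ndarray, b: np.ndarray, bulge_dir: np.ndarray,
                arc_length: float, stations: np.ndarray) -> np.ndarray:
    """Points along a circular arc from ``a`` to ``b`` of given length.

    ``stations`` are arc-length offsets from ``a``.  The arc lies in the
    plane spanned by the chord and ``bulge_dir`` and bulges toward it.  Falls
    back to a straight segment when the chord is (nearly) as long as the arc.
    """
    chord = b - a
    c = float(np.linalg.norm(chord))
    if c < 1e-9:
        # closed loop: small circle in the bulge plane through a
        u = bulge_dir / np.linalg.norm(bulge_dir)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        radius = arc_length / (2 * np.pi)
        center = a + radius * u
        ang = stations / radius
        return np.array([center - radius * (np.cos(t) * u - np.sin(t) * v)
                         for t in ang])
    if arc_length <= c * 1.0001:
        return np.array([a + (s / arc_length) * chord for s in stations])
    th = brentq(lambda t: np.sin(t) / t - c / arc_length, 1e-9, np.pi - 1e-9)
    radius = c / (2 * np.sin(th))
    e1 = chord / c
    u = bulge_dir - (bulge_dir @ e1) * e1
    nu = np.linalg.norm(u)
    if nu < 1e-9:  # bulge direction parallel to chord: pick any normal
        ref = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = ref - (ref @ e1) * e1
        nu = np.linalg.norm(u)
    u /= nu
    mid = 0.5 * (a + b)
    center = mid - u * radius * np.cos(th)  # major arcs put the center on +u
    va, vb = a - center, b - center
    ang_total = 2 * th  # subtended angle; > pi for major arcs
    rot_axis = np.cross(va, vb)
    if np.linalg.norm(rot_axis) < 1e-9:  # half circle: any axis in the plane normal
        rot_axis = np.cross(va, u)
    rot_axis /= np.linalg.norm(rot_axis)
    if ang_total > np.pi:
        # the short rotation from va to vb sweeps the -u side; go the long way
        rot_axis = -rot_axis
    pts = []
    for s in stations:
        ang = ang_total * s / arc_length
        rot = rotation_about_axis(rot_axis, np.rad2deg(ang))
        pts.append(center + rot @ va)
    return np.array(pts)


def build_arc(anchor_a: np.ndarray, anchor_b: np.ndarray, letters: str,
              bulge_dir: np.ndarray, deoxy: bool = True
              ) -> list[dict[str, np.ndarray]]:
    """Place loop nucleotides on a smooth arc between two backbone anchors.

    ``anchor_a`` is the O3' of the preceding residue, ``anchor_b`` the P of
    the following residue.  Each nucleotide is rigidly oriented with its
    local P->O3' direction along the arc tangent so consecutive O3'-P gaps
    come out near bonding distance; bases point toward ``bulge_dir``.
    """
    n = len(letters)
    if n == 0:
        return []
    ideals = [ideal_nucleotide(b, deoxy=deoxy) for b in letters.upper()]
    spans = [float(np.linalg.norm(i["O3'"] - i["P"])) for i in ideals]
    bond = 1.60
    # arc stations of each residue's P atom
    stations, s = [], 0.0
    for k in range(n):
        s += bond if k == 0 else bond + spans[k - 1]
        stations.append(s)
    total = stations[-1] + spans[-1] + bond
    stations = np.asarray(stations)
    pts = _arc_points(anchor_a, anchor_b, bulge_dir, total,
                      np.concatenate([stations, [total]]))
    p_pts, end = pts[:-1], pts[-1]

    residues = []
    for k in range(n):
        nxt = p_pts[k + 1] if k + 1 < n else end
        tangent = nxt - p_pts[k]
        tn = np.linalg.norm(tangent)
        tangent = tangent / tn if tn > 1e-9 else np.array([0.0, 0.0, 1.0])
        residues.append(_orient_on_tangent(ideals[k], spans[k], p_pts[k],
                                           tangent, bulge_dir))
    return residues


def _orient_on_tangent(ideal: dict[str, np.ndarray], span: float,
                       p_pos: np.ndarray, tangent: np.ndarray,
                       up: np.ndarray) -> dict[str, np.ndarray]:
    e1 = (ideal["O3'"] - ideal["P"]) / span
    ref = ideal["C1'"] - ideal["P"]
    e2 = ref - (ref @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    u = up - (up @ tangent) * tangent
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        ref2 = np.array([0.0, 0.0, 1.0]) if abs(tangent[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = ref2 - (ref2 @ tangent) * tangent
        nu = np.linalg.norm(u)
    u /= nu
    w = np.cross(tangent, u)
    rot = np.column_stack([tangent, u, w]) @ np.vstack([e1, e2, e3])
    return {name: rot @ (xyz - ideal["P"]) + p_pos for name, xyz in ideal.items()}
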