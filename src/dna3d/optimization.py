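"""Coarse-grained simulated-annealing Monte Carlo refinement.

Imperfect assemblies are refined at residue level on the 6-bead model.
Movable elements follow the secondary structure: helices and short loops
(hairpins < 5 nt, internal loops < 7 nt) are rigid bodies whose internal
conformation is frozen; other loop residues move individually.  Proposals
translate an element, rotate it about its centroid, or rotate it about an
axis through its interface P bead; acceptance is Metropolis at a geometric
cooling schedule.  Conformations are ranked by a knowledge-based statistical
potential (distance-dependent bead-pair terms plus pseudo-torsion terms,
energies -ln(observed/reference) against a quasi-chemical reference trained
from a user-supplied corpus), with a harmonic chain-connectivity term to
prevent fragmentation.  Snapshots are clustered by RMSD and up to five
cluster centroids are returned, lowest energy first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import COARSE_BEADS, kabsch_transform
from .secondary_structure import SecondaryStructureTree
from .structure_model import CoarseModel, Structure, coarse_grain

__all__ = [
    "EnergyModel", "MovableElement", "SAMCConfig", "Snapshot",
    "train_potential", "energies_from_counts", "identify_movable_elements",
    "samc_optimize", "cluster_and_rank", "metropolis_accept",
]

N_BEADS = len(COARSE_BEADS)
BIN_WIDTH = 0.3           # Angstrom
MAX_DIST = 20.0           # Angstrom; pairs beyond contribute zero energy
N_DIST_BINS = int(round(MAX_DIST / BIN_WIDTH))
TORSION_BIN_WIDTH = 10.0  # degrees
N_TORSION_BINS = 36


@dataclass
class EnergyModel:
    """Binned distance + pseudo-torsion statistical potential.

    ``pair_energies[t1, t2, b]`` is the energy of bead types t1, t2 (indices
    into the 6 coarse bead names) at distance bin ``b``;
    ``torsion_energies[k, b]`` the energy of pseudo-torsion eta (k=0) or
    theta (k=1) in 10-degree bin ``b``.  Energies are
    -ln((obs + p) / (ref + p)) with per-row normalization against the
    distance-marginal (quasi-chemical) reference.
    """

    pair_energies: np.ndarray      # (6, 6, N_DIST_BINS)
    torsion_energies: np.ndarray   # (2, N_TORSION_BINS)
    pseudocount: float = 1.0
    connectivity_k: float = 1.0
    connectivity_d0: float = 6.7   # target consecutive P-P distance (Angstrom)


def energies_from_counts(obs: np.ndarray, ref: np.ndarray,
                         pseudocount: float = 1.0) -> np.ndarray:
    """-ln of the normalized observed/reference ratio per bin.

    ``obs`` has shape (..., B); ``ref`` shape (B,) is the marginal over all
    types.  When the observed counts equal the reference in every bin the
    energies are exactly zero.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    b = obs.shape[-1]
    p = pseudocount
    f_obs = (obs + p) / (obs.sum(axis=-1, keepdims=True) + p * b)
    f_ref = (ref + p) / (ref.sum() + p * b)
    return -np.log(f_obs / f_ref)


def _pseudo_torsions(cm: CoarseModel) -> tuple[np.ndarray, np.ndarray]:
    """eta/theta-like torsions over consecutive P and C4' beads, in degrees."""
    etas, thetas = [], []
    p = cm.coords[:, COARSE_BEADS.index("P"), :]
    c4 = cm.coords[:, COARSE_BEADS.index("C4'"), :]
    for i in range(1, cm.n_residues - 1):
        ci = cm.chain_index
        if not (ci[i - 1] == ci[i] == ci[i + 1]):
            continue
        etas.append(_dihedral(c4[i - 1], p[i], c4[i], p[i + 1]))
        if i + 1 < cm.n_residues and ci[i + 1] == ci[i]:
            thetas.append(_dihedral(p[i], c4[i], p[i + 1], c4[i + 1]))
    return np.array(etas), np.array(thetas)


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = n1 @ n2, m1 @ n2
    return float(np.rad2deg(np.arctan2(y, x)))


def _torsion_bin(angle_deg: np.ndarray) -> np.ndarray:
    return np.clip(((np.asarray(angle_deg) + 180.0) // TORSION_BIN_WIDTH).astype(int),
                   0, N_TORSION_BINS - 1)


def train_potential(corpus: list[CoarseModel | Structure],
                    pseudocount: float = 1.0) -> EnergyModel:
    """Accumulate distance and torsion histograms over a corpus and convert
    to energies.  Deterministic and order-independent."""
    models: list[CoarseModel] = []
    for item in corpus:
        models.append(item if isinstance(item, CoarseModel) else coarse_grain(item))
    if not models or all(m.n_residues < 2 for m in models):
        raise ValueError("potential training needs at least one structure with >= 2 residues")

    obs = np.zeros((N_BEADS, N_BEADS, N_DIST_BINS))
    tors = np.zeros((2, N_TORSION_BINS))
    for cm in models:
        n = cm.n_residues
        if n < 2:
            continue
        flat = cm.flat()
        types = np.tile(np.arange(N_BEADS), n)
        resid = np.repeat(np.arange(n), N_BEADS)
        d = cdist(flat, flat)
        iu, ju = np.triu_indices(len(flat), k=1)
        mask = (resid[iu] != resid[ju]) & (d[iu, ju] < MAX_DIST)
        bins = (d[iu, ju][mask] / BIN_WIDTH).astype(int)
        t1, t2 = types[iu][mask], types[ju][mask]
        lo, hi = np.minimum(t1, t2), np.maximum(t1, t2)
        np.add.at(obs, (lo, hi, bins), 1.0)
        etas, thetas = _pseudo_torsions(cm)
        if len(etas):
            np.add.at(tors[0], _torsion_bin(etas), 1.0)
        if len(thetas):
            np.add.at(tors[1], _torsion_bin(thetas), 1.0)

    # symmetrize: (t1,t2) and (t2,t1) share one table
    obs = obs + np.transpose(obs, (1, 0, 2)) * (1 - np.eye(N_BEADS))[..., None]
    ref = obs.sum(axis=(0, 1))
    pair_e = energies_from_counts(obs.reshape(-1, N_DIST_BINS), ref,
                                  pseudocount).reshape(obs.shape)
    tors_e = energies_from_counts(tors, tors.sum(axis=0), pseudocount)
    return EnergyModel(pair_e, tors_e, pseudocount)


@dataclass(frozen=True)
class MovableElement:
    members: tuple[int, ...]   # residue indices (global order)
    rigid: bool
    kind: str


def identify_movable_elements(tree: SecondaryStructureTree) -> list[MovableElement]:
    """Partition residues into movable elements from the secondary structure.

    Stems are rigid; hairpin loops with < 5 unpaired nt and internal or
    bulge loops with < 7 unpaired nt are rigid; all other loop residues move
    one-by-one (flexible).  Interface pairs belong to their stem.
    """
    elements: list[MovableElement] = []
    for sse in tree.sses:
        if sse.kind == "stem":
            elements.append(MovableElement(sse.positions, True, "stem"))
            continue
        unpaired = sse.unpaired_positions
        if not unpaired:
            continue
        short = ((sse.kind == "hairpin" and len(unpaired) < 5)
                 or (sse.kind in ("internal", "bulge") and len(unpaired) < 7))
        if short:
            elements.append(MovableElement(unpaired, True, sse.kind))
        else:
            for p in unpaired:
                elements.append(MovableElement((p,), False, sse.kind))
    elements.sort(key=lambda e: e.members[0])
    return elements


@dataclass
class SAMCConfig:
    """Annealing schedule and move sizes.

    Temperatures are in units of the trained potential; cooling is geometric
    over ``n_stages`` with ``proposals_per_stage`` Metropolis proposals each.
    """

    n_stages: int = 50
    proposals_per_stage: int = 2000
    t_start: float = 5.0
    t_end: float = 0.1
    max_translation: float = 2.0    # Angstrom per proposal
    max_rotation_deg: float = 15.0  # degrees per proposal
    snapshot_stride: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.n_stages < 1 or self.proposals_per_stage < 0:
            raise ValueError("invalid step counts")

    @property
    def n_steps(self) -> int:
        return self.n_stages * self.proposals_per_stage

    def temperatures(self) -> np.ndarray:
        if self.n_stages == 1:
            return np.array([self.t_start])
        return self.t_start * (self.t_end / self.t_start) ** (
            np.arange(self.n_stages) / (self.n_stages - 1))


@dataclass
class Snapshot:
    coarse: CoarseModel
    energy: float
    rotations: np.ndarray     # (n_residues, 3, 3) cumulative per-residue
    translations: np.ndarray  # (n_residues, 3)


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: accept if dE <= 0, else with probability exp(-dE/T)."""
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / temperature))


class _EnergyState:
    """Incremental energy bookkeeping for the sampler."""

    def __init__(self, cm: CoarseModel, em: EnergyModel):
        self.em = em
        self.coords = cm.coords.copy()
        self.chain_index = cm.chain_index
        self.n = cm.n_residues
        self.p_idx = COARSE_BEADS.index("P")
        self.c4_idx = COARSE_BEADS.index("C4'")
        t = np.arange(N_BEADS)
        self._tt = (np.minimum.outer(t, t), np.maximum.outer(t, t))

    def pair_energy(self, set_a: np.ndarray, set_b: np.ndarray) -> float:
        """Sum of bead-pair energies between two disjoint residue index sets."""
        if len(set_a) == 0 or len(set_b) == 0:
            return 0.0
        xa = self.coords[set_a].reshape(-1, 3)
        xb = self.coords[set_b].reshape(-1, 3)
        d = cdist(xa, xb)
        mask = d < MAX_DIST
        if not mask.any():
            return 0.0
        bins = (d[mask] / BIN_WIDTH).astype(int)
        ta = np.tile(np.arange(N_BEADS), len(set_a))
        tb = np.tile(np.arange(N_BEADS), len(set_b))
        lo = np.minimum.outer(ta, tb)[mask]
        hi = np.maximum.outer(ta, tb)[mask]
        return float(self.em.pair_energies[lo, hi, bins].sum())

    def pair_energy_within(self, members: np.ndarray) -> float:
        if len(members) < 2:
            return 0.0
        x = self.coords[members].reshape(-1, 3)
        d = cdist(x, x)
        resid = np.repeat(np.arange(len(members)), N_BEADS)
        iu, ju = np.triu_indices(len(x), k=1)
        mask = (resid[iu] != resid[ju]) & (d[iu, ju] < MAX_DIST)
        if not mask.any():
            return 0.0
        bins = (d[iu, ju][mask] / BIN_WIDTH).astype(int)
        types = np.tile(np.arange(N_BEADS), len(members))
        t1, t2 = types[iu][mask], types[ju][mask]
        lo, hi = np.minimum(t1, t2), np.maximum(t1, t2)
        return float(self.em.pair_energies[lo, hi, bins].sum())

    def torsion_energy(self, centers: np.ndarray) -> float:
        """Torsion terms whose 4-bead windows touch the given residues."""
        e = 0.0
        p = self.coords[:, self.p_idx, :]
        c4 = self.coords[:, self.c4_idx, :]
        ci = self.chain_index
        seen = set()
        for c in centers:
            for i in range(max(1, c - 1), min(self.n - 1, c + 2)):
                if i in seen:
                    continue
                seen.add(i)
                if not (ci[i - 1] == ci[i] == ci[i + 1]):
                    continue
                eta = _dihedral(c4[i - 1], p[i], c4[i], p[i + 1])
                e += self.em.torsion_energies[0, _torsion_bin(np.array([eta]))[0]]
                if i + 1 < self.n and ci[i + 1] == ci[i]:
                    th = _dihedral(p[i], c4[i], p[i + 1], c4[i + 1])
                    e += self.em.torsion_energies[1, _torsion_bin(np.array([th]))[0]]
        return float(e)

    def connectivity_energy(self, centers: np.ndarray | None = None) -> float:
        p = self.coords[:, self.p_idx, :]
        idx = range(self.n - 1) if centers is None else sorted(
            {i for c in centers for i in (c - 1, c) if 0 <= i < self.n - 1})
        e = 0.0
        for i in idx:
            if self.chain_index[i] != self.chain_index[i + 1]:
                continue
            d = np.linalg.norm(p[i + 1] - p[i])
            e += self.em.connectivity_k * (d - self.em.connectivity_d0) ** 2
        return float(e)

    def total_energy(self) -> float:
        all_idx = np.arange(self.n)
        e = 0.0
        e += self.pair_energy_within(all_idx)
        e += self.torsion_energy(all_idx)  # counts each window once via seen-set
        e += self.connectivity_energy()
        return e

    def local_energy(self, members: np.ndarray) -> float:
        """Energy terms that change when ``members`` move rigidly."""
        others = np.setdiff1d(np.arange(self.n), members)
        return (self.pair_energy(members, others)
                + self.torsion_energy(members)
                + self.connectivity_energy(members))


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_deg, max_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def samc_optimize(assembled: Structure, tree: SecondaryStructureTree,
                  em: EnergyModel, cfg: SAMCConfig) -> list[Snapshot]:
    """Simulated-annealing Monte Carlo on the coarse-grained assembly.

    Returns snapshots (including the initial conformation) every
    ``cfg.snapshot_stride`` accepted-or-rejected proposals plus the final
    state.  Trajectories are reproducible for a given ``cfg.seed``.
    """
    cm = coarse_grain(assembled)
    elements = identify_movable_elements(tree)
    if sorted(p for e in elements for p in e.members) != list(range(cm.n_residues)):
        raise ValueError("movable elements do not partition the residues")
    state = _EnergyState(cm, em)
    rng = np.random.default_rng(cfg.seed)

    rot = np.tile(np.eye(3), (cm.n_residues, 1, 1))
    tra = np.zeros((cm.n_residues, 3))
    energy = state.total_energy()

    snapshots = [Snapshot(CoarseModel(state.coords.copy(), cm.chain_index,
                                      cm.resnames), energy,
                          rot.copy(), tra.copy())]
    if cfg.n_steps == 0:
        return snapshots

    temps = cfg.temperatures()
    step = 0
    for t in temps:
        for _ in range(cfg.proposals_per_stage):
            step += 1
            el = elements[rng.integers(len(elements))]
            members = np.asarray(el.members)
            move = rng.integers(3)
            if move == 0:  # translate
                r_m = np.eye(3)
                center = np.zeros(3)
                dvec = rng.normal(size=3)
                dvec = dvec / np.linalg.norm(dvec) * rng.uniform(0, cfg.max_translation)
            elif move == 1:  # rotate about the element centroid
                r_m = _random_rotation(rng, cfg.max_rotation_deg)
                center = state.coords[members].reshape(-1, 3).mean(axis=0)
                dvec = np.zeros(3)
            else:  # rotate about an axis through the interface P bead
                r_m = _random_rotation(rng, cfg.max_rotation_deg)
                center = state.coords[members[0], state.p_idx, :].copy()
                dvec = np.zeros(3)

            e_before = state.local_energy(members)
            old = state.coords[members].copy()
            state.coords[members] = (state.coords[members] - center) @ r_m.T \
                + center + dvec
            e_after = state.local_energy(members)
            if metropolis_accept(e_after - e_before, t, rng):
                energy += e_after - e_before
                # compose x -> r_m (x - center) + center + dvec into the
                # cumulative per-residue map x_cur = R x0 + t
                rot[members] = np.einsum("ab,nbc->nac", r_m, rot[members])
                tra[members] = (tra[members] - center) @ r_m.T + center + dvec
            else:
                state.coords[members] = old
                continue
            if step % cfg.snapshot_stride == 0:
                snapshots.append(Snapshot(
                    CoarseModel(state.coords.copy(), cm.chain_index, cm.resnames),
                    energy, rot.copy(), tra.copy()))

    if snapshots[-1].energy != energy or not np.allclose(
            snapshots[-1].coarse.coords, state.coords):
        snapshots.append(Snapshot(
            CoarseModel(state.coords.copy(), cm.chain_index, cm.resnames),
            energy, rot.copy(), tra.copy()))
    return snapshots


def cluster_and_rank(snapshots: list[Snapshot], em: EnergyModel, k: int = 5,
                     rmsd_threshold: float = 2.0,
                     assembled: Structure | None = None) -> list[Structure | Snapshot]:
    """Greedy RMSD-threshold clustering; centroids ranked by energy.

    Clusters are formed by repeatedly taking the snapshot with the most
    within-threshold neighbors; each cluster's representative is its
    lowest-energy member.  Up to ``k`` representatives are returned sorted
    by energy (ascending).  When ``assembled`` is given, representatives are
    reconstructed to all-atom structures by applying each residue's
    cumulative rigid transform to the assembly.
    """
    if not snapshots:
        raise ValueError("no snapshots to cluster")
    m = len(snapshots)
    rms = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, _, r = kabsch_transform(snapshots[i].coarse.flat(),
                                       snapshots[j].coarse.flat())
            rms[i, j] = rms[j, i] = r
    remaining = set(range(m))
    reps: list[Snapshot] = []
    while remaining:
        counts = {i: sum(1 for j in remaining if rms[i, j] <= rmsd_threshold)
                  for i in remaining}
        center = min(remaining, key=lambda i: (-counts[i], i))
        cluster = [j for j in remaining if rms[center, j] <= rmsd_threshold]
        best = min(cluster, key=lambda j: (snapshots[j].energy, j))
        reps.append(snapshots[best])
        remaining -= set(cluster)
    reps.sort(key=lambda s: s.energy)
    reps = reps[:k]
    if assembled is None:
        return reps
    return [_rebuild_all_atom(assembled, s) for s in reps]


def _rebuild_all_atom(assembled: Structure, snap: Snapshot) -> Structure:
    out = assembled.copy()
    i = 0
    for chain in out.chains:
        for res in chain.residues:
            r, t = snap.rotations[i], snap.translations[i]
            for a in res.atoms:
                res.atoms[a] = r @ res.atoms[a] + t
            i += 1
    out.name = "optimized"
    return out
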