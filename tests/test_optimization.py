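"""Statistical potential training, movable elements, SAMC sampling, clustering."""

from __future__ import annotations

import numpy as np
import pytest

from dna3d.optimization import (
    SAMCConfig, Snapshot, cluster_and_rank, energies_from_counts,
    identify_movable_elements, metropolis_accept, samc_optimize,
    train_potential,
)
from dna3d.secondary_structure import build_tree, decompose, parse_dotbracket
from dna3d.structure_model import CoarseModel, coarse_grain


class TestPotential:
    def test_zero_energy_when_obs_equals_ref(self):
        obs = np.array([[4.0, 8.0, 2.0]])
        ref = np.array([4.0, 8.0, 2.0])
        e = energies_from_counts(obs, ref, pseudocount=1.0)
        assert np.allclose(e, 0.0)

    def test_enrichment_limit_is_minus_log_two(self):
        """A bin observed at twice the reference frequency tends to -ln 2."""
        big = 1e9
        obs = np.array([2 * big, big, big])       # bin 0 enriched 2x vs ref shape
        ref = np.array([big, big, big])
        e = energies_from_counts(obs[None, :], ref, pseudocount=1e-9)[0]
        # normalize shapes: obs fraction 0.5 vs ref fraction 1/3 -> -ln(1.5)
        assert e[0] == pytest.approx(-np.log((2 * big / (4 * big)) / (1 / 3)), abs=1e-6)

    def test_training_deterministic_and_finite(self, corpus):
        structures = [s for _, s, _, _ in corpus]
        em1 = train_potential(structures)
        em2 = train_potential(list(reversed(structures)))
        assert np.allclose(em1.pair_energies, em2.pair_energies)
        assert np.all(np.isfinite(em1.pair_energies))
        assert np.all(np.isfinite(em1.torsion_energies))

    def test_single_residue_corpus_errors(self, corpus):
        s = corpus[0][1].copy()
        s.chains = [s.chains[0]]
        s.chains[0].residues = s.chains[0].residues[:1]
        with pytest.raises(ValueError):
            train_potential([s])


class TestMovableElements:
    def _elements(self, ss):
        _, pt = parse_dotbracket(ss)
        return identify_movable_elements(build_tree(decompose(pt)))

    def test_stems_always_rigid(self):
        els = self._elements("(((((....)))))")
        assert all(e.rigid for e in els if e.kind == "stem")

    def test_short_hairpin_rigid(self):
        els = self._elements("((((....))))")  # 4-nt hairpin: < 5 nt
        hp = [e for e in els if e.kind == "hairpin"]
        assert len(hp) == 1 and hp[0].rigid and len(hp[0].members) == 4

    def test_long_hairpin_flexible(self):
        els = self._elements("((((.....))))")  # 5-nt hairpin: not < 5
        hp = [e for e in els if e.kind == "hairpin"]
        assert len(hp) == 5 and all(not e.rigid and len(e.members) == 1 for e in hp)

    def test_internal_loop_boundary(self):
        rigid6 = self._elements("((...((....))...))")   # 3+3 = 6 nt internal
        il = [e for e in rigid6 if e.kind == "internal"]
        assert len(il) == 1 and il[0].rigid
        flex7 = self._elements("((....((....))...))")   # 4+3 = 7 nt internal
        il = [e for e in flex7 if e.kind == "internal"]
        assert len(il) == 7 and all(not e.rigid for e in il)

    def test_elements_partition_residues(self):
        for ss in ("(((((....)))))", "((((((.&.))))))", "..((((....)))).."):
            _, pt = parse_dotbracket(ss)
            els = identify_movable_elements(build_tree(decompose(pt)))
            members = sorted(p for e in els for p in e.members)
            assert members == list(range(pt.n))


class TestSAMC:
    @pytest.fixture()
    def small_case(self, corpus_by_name, energy_model):
        s, db = corpus_by_name["openloop_a"]
        _, pt = parse_dotbracket(db.text)
        tree = build_tree(decompose(pt))
        return s, tree, energy_model

    def test_zero_steps_returns_initial(self, small_case):
        s, tree, em = small_case
        cfg = SAMCConfig(n_stages=1, proposals_per_stage=0, seed=7)
        snaps = samc_optimize(s, tree, em, cfg)
        assert len(snaps) == 1
        assert np.allclose(snaps[0].coarse.coords, coarse_grain(s).coords)

    def test_seeded_determinism(self, small_case):
        s, tree, em = small_case
        cfg = SAMCConfig(n_stages=3, proposals_per_stage=60, snapshot_stride=30,
                         seed=42)
        a = samc_optimize(s, tree, em, cfg)
        b = samc_optimize(s, tree, em, cfg)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.energy == y.energy
            assert np.array_equal(x.coarse.coords, y.coarse.coords)

    def test_rigid_elements_keep_internal_distances(self, small_case):
        s, tree, em = small_case
        cfg = SAMCConfig(n_stages=4, proposals_per_stage=150, snapshot_stride=100,
                         seed=5)
        snaps = samc_optimize(s, tree, em, cfg)
        els = [e for e in identify_movable_elements(tree) if e.rigid]
        first, last = snaps[0].coarse, snaps[-1].coarse
        for e in els:
            m = np.asarray(e.members)
            d0 = _pairwise(first.coords[m].reshape(-1, 3))
            d1 = _pairwise(last.coords[m].reshape(-1, 3))
            assert np.max(np.abs(d0 - d1)) <= 1e-6

    def test_zero_temperature_limit_is_monotone(self, small_case):
        """As T -> 0 accepted moves never increase the energy."""
        s, tree, em = small_case
        cfg = SAMCConfig(n_stages=2, proposals_per_stage=150, t_start=1e-9,
                         t_end=1e-9, snapshot_stride=10, seed=11)
        snaps = samc_optimize(s, tree, em, cfg)
        energies = [x.energy for x in snaps]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_transform_history_rebuilds_coarse_coords(self, small_case):
        """Per-residue rigid transforms applied to the input reproduce the
        snapshot's bead coordinates exactly."""
        s, tree, em = small_case
        cfg = SAMCConfig(n_stages=3, proposals_per_stage=80, snapshot_stride=40,
                         seed=3)
        snaps = samc_optimize(s, tree, em, cfg)
        cm0 = coarse_grain(s)
        last = snaps[-1]
        rebuilt = np.einsum("nij,nbj->nbi", last.rotations, cm0.coords) \
            + last.translations[:, None, :]
        assert np.allclose(rebuilt, last.coarse.coords, atol=1e-8)


class TestMetropolis:
    def test_two_state_occupancy_matches_boltzmann(self):
        """A two-level system sampled with the package's acceptance rule
        reproduces the analytic Boltzmann ratio within 3 standard errors."""
        rng = np.random.default_rng(2024)
        de, temp = 1.3, 0.9
        energies = {0: 0.0, 1: de}
        state, counts = 0, np.zeros(2)
        n = 60_000
        for _ in range(n):
            proposal = 1 - state  # symmetric proposal
            if metropolis_accept(energies[proposal] - energies[state], temp, rng):
                state = proposal
            counts[state] += 1
        expected_p1 = np.exp(-de / temp) / (1 + np.exp(-de / temp))
        observed = counts[1] / n
        se = np.sqrt(expected_p1 * (1 - expected_p1) / n) * 3  # generous iid bound
        # correlated chain: inflate by the typical integrated autocorrelation
        assert abs(observed - expected_p1) < 5 * se

    def test_always_accepts_downhill(self, rng):
        assert metropolis_accept(-1e-9, 0.5, rng)
        assert metropolis_accept(0.0, 0.5, rng)


class TestCluster:
    def _snap(self, coords, energy):
        n = len(coords)
        return Snapshot(CoarseModel(np.asarray(coords, dtype=float),
                                    np.zeros(n, dtype=int), ("DA",) * n),
                        energy, np.tile(np.eye(3), (n, 1, 1)), np.zeros((n, 3)))

    def _random_conf(self, rng, scale=0.0):
        base = rng.normal(size=(4, 6, 3)) * 5
        return base + rng.normal(size=base.shape) * scale

    def test_single_snapshot(self, rng):
        snaps = [self._snap(self._random_conf(rng), 1.0)]
        out = cluster_and_rank(snaps, None)
        assert len(out) == 1

    def test_identical_copies_collapse_to_one(self, rng):
        conf = self._random_conf(rng)
        snaps = [self._snap(conf.copy(), float(k)) for k in range(100)]
        out = cluster_and_rank(snaps, None)
        assert len(out) == 1
        assert out[0].energy == 0.0  # lowest-energy member represents the cluster

    def test_energy_ordering_and_k_limit(self, rng):
        confs = [self._random_conf(rng) * (k + 1) for k in range(3)]
        snaps = [self._snap(c, e) for c, e in zip(confs, [3.0, 1.0, 2.0])]
        out = cluster_and_rank(snaps, None, k=2)
        assert [s.energy for s in out] == [1.0, 2.0]

    def test_never_more_than_five(self, rng):
        snaps = [self._snap(self._random_conf(rng) + k * 100, float(k))
                 for k in range(9)]
        out = cluster_and_rank(snaps, None, k=5)
        assert len(out) <= 5


def _pairwise(x):
    from scipy.spatial.distance import pdist
    return pdist(x)
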