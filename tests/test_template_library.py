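"""Corpus filtering, template extraction, scoring, search and fallback building."""

from __future__ import annotations

import numpy as np
import pytest

from dna3d.fixtures import FixtureSpec, generate_fixture
from dna3d.secondary_structure import decompose, parse_dotbracket
from dna3d.structure_model import base_letter, coarse_grain
from dna3d.template_library import (
    MatchScore, Template, TemplateLibrary, build_fallback, build_library,
    corpus_filter, extract_templates, score_match, search_template,
    topology_key,
)


class TestCorpusFilter:
    def test_pure_duplex_is_helix_class(self):
        s, db = generate_fixture(
            FixtureSpec("dup", "G" * 10 + "C" * 10, "((((((((((&))))))))))"))
        keep, label = corpus_filter(s, db)
        assert (keep, label) == (False, "Helix")

    def test_hairpin_is_d_class(self):
        s, db = generate_fixture(FixtureSpec("hp", "GGAAACC", "((...))"))
        keep, label = corpus_filter(s, db)
        assert (keep, label) == (True, "D")

    def test_short_oligomer_rejected(self):
        s, db = generate_fixture(FixtureSpec("tri", "GAC", "..."))
        keep, _ = corpus_filter(s, db)
        assert not keep

    def test_unstructured_label(self):
        s, db = generate_fixture(FixtureSpec("ss", "GACTTA", "......"))
        assert corpus_filter(s, db) == (False, "unStru")

    def test_length_mismatch_errors(self):
        s, _ = generate_fixture(FixtureSpec("hp", "GGAAACC", "((...))"))
        _, db = parse_dotbracket("((....))")
        db2, _ = parse_dotbracket("((....))")
        with pytest.raises(Exception):
            corpus_filter(s, db2)


class TestExtract:
    def test_two_chain_molecule_gives_five_templates(self):
        ss = ".(((((.....(((((.&.))))))))))."
        seq = "TGGGGGAAAAACCCCCT" + "TGGGGGCCCCCT"
        # build a pairing-consistent sequence
        _, pt = parse_dotbracket(ss)
        letters = list("A" * pt.n)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for k, (i, j) in enumerate(pt.pairs()):
            letters[i] = "GC"[k % 2]
            letters[j] = comp[letters[i]]
        seq = "".join(letters)
        s, db = generate_fixture(FixtureSpec("qsk", seq, ss))
        tpls = extract_templates(s, db, "qsk")
        kinds = sorted(t.sse_kind for t in tpls)
        assert kinds == ["break", "bulge", "open", "stem", "stem"]

    def test_hairpin_gives_two_templates(self):
        s, db = generate_fixture(FixtureSpec("hp", "GGGAAACCC", "(((...)))"))
        tpls = extract_templates(s, db, "hp")
        assert [t.sse_kind for t in tpls] == ["stem", "hairpin"]
        assert tpls[1].local_seq == "GGAAACC"

    def test_filtered_structure_rejected(self):
        s, db = generate_fixture(
            FixtureSpec("dup", "GGGGGCCCCC", "(((((&)))))"))
        with pytest.raises(Exception):
            extract_templates(s, db, "dup")

    def test_fragment_matches_local_strings(self, corpus):
        for name, s, db, _ in corpus[:4]:
            for t in extract_templates(s, db, name):
                n = len(t.local_2d.replace("&", ""))
                assert t.fragment.n_residues == n == len(t.local_seq)


class TestTopologyKey:
    def test_identity(self):
        assert topology_key("((.&.))") == "((.&.))"

    def test_distinct_loop_lengths_distinct_keys(self):
        assert topology_key("((...))") != topology_key("((..))")

    def test_invalid_chars_rejected(self):
        with pytest.raises(ValueError):
            topology_key("((x))")


class TestScore:
    def test_hand_computed_total(self):
        # identical topology, 3/3 loop matches, 8/8 helix matches
        t = Template("hairpin", "((((...))))", "GGCGAAACGCC",
                     fragment=None, source_id="x")
        sc = score_match("((((...))))", "GGCGAAACGCC", t)
        assert sc == MatchScore(5, 3, 8)
        assert sc.total == pytest.approx(5 + 3 * 1.0 + 8 * 0.2)
        assert sc.total == pytest.approx(9.6)

    def test_topology_only(self):
        t = Template("hairpin", "((...))", "GGAAACC", None, "x")
        sc = score_match("((...))", "CCTTTGG", t)
        assert sc.total == pytest.approx(5.0)

    def test_total_zero_for_incomparable(self):
        t = Template("hairpin", "((...))", "GGAAACC", None, "x")
        assert score_match("((....))", "GGAAAACC", t).total == 0.0

    def test_monotone_in_matches(self):
        t = Template("hairpin", "((...))", "GGAAACC", None, "x")
        base = score_match("((...))", "CCAAAGG", t).total
        plus_loop = score_match("((...))", "CCAATGG", t).total  # one fewer loop match
        assert base - plus_loop == pytest.approx(1.0)
        plus_helix = score_match("((...))", "GCAAAGG", t).total
        assert plus_helix - score_match("((...))", "CCAAAGG", t).total == pytest.approx(0.2)


class TestSearch:
    def test_leave_one_out_finds_homolog(self, library, corpus_by_name, seq_by_name):
        s, db = corpus_by_name["hairpin6_a"]
        _, pt = parse_dotbracket(db.text)
        for sse in decompose(pt, seq_by_name["hairpin6_a"]):
            tpl, perfect = search_template(sse, library,
                                           excluded_source_ids={"hairpin6_a"})
            assert perfect and tpl.source_id != "hairpin6_a"
            assert tpl.local_2d == sse.local_2d

    def test_rna_fallback_converts_u_to_t(self, corpus_by_name):
        # an RNA library whose only entry matches the query topology
        s, db = corpus_by_name["hairpin6_a"]
        _, pt = parse_dotbracket(db.text)
        sse = next(x for x in decompose(pt, "G" * pt.n) if x.kind == "hairpin")
        rna_t = _rna_template_for(sse)
        rna_lib = TemplateLibrary(kind="rna")
        rna_lib.add(rna_t)
        empty = TemplateLibrary()
        tpl, perfect = search_template(sse, empty, rna_lib)
        assert not perfect and tpl.source_kind == "rna"
        letters = {base_letter(r.name) for r in tpl.fragment.residues()}
        assert "U" not in letters and "T" in letters

    def test_denovo_when_nowhere(self, library):
        _, pt = parse_dotbracket("((.........))")
        sse = next(s for s in decompose(pt, "G" * 13) if s.kind == "hairpin")
        tpl, perfect = search_template(sse, library)
        assert not perfect and tpl.source_kind == "denovo"

    def test_leave_one_out_completeness(self, library, corpus):
        """With its own source excluded, every SSE that has a same-topology
        sibling in the corpus still finds a (perfect) DNA template."""
        for name, s, db, _ in corpus:
            _, pt = parse_dotbracket(db.text)
            seq = "".join(base_letter(r.name) for r in s.residues())
            for sse in decompose(pt, seq):
                others = [t for t in library.candidates(sse.kind, sse.local_2d)
                          if t.source_id != name]
                tpl, perfect = search_template(sse, library,
                                               excluded_source_ids={name})
                if others:
                    assert perfect and tpl.source_id != name


class TestFallback:
    def test_stem_geometry(self):
        _, pt = parse_dotbracket("((((....))))")
        sse = next(s for s in decompose(pt, "GGCGTTTTCGCC") if s.kind == "stem")
        tpl = build_fallback(sse, sse.local_seq)
        res = tpl.fragment.residues()
        assert len(res) == 8
        n = len(res)
        for k in range(n // 2):
            d = np.linalg.norm(res[k].atoms["C1'"] - res[n - 1 - k].atoms["C1'"])
            assert d == pytest.approx(10.4, abs=0.5)

    def test_hairpin_closure(self):
        _, pt = parse_dotbracket("((....))")
        sse = next(s for s in decompose(pt, "GGTTTTCC") if s.kind == "hairpin")
        tpl = build_fallback(sse, sse.local_seq)
        res = tpl.fragment.residues()
        for a, b in zip(res, res[1:]):
            assert np.linalg.norm(a.atoms["O3'"] - b.atoms["P"]) <= 2.5

    def test_zero_nt_bulge_side(self):
        _, pt = parse_dotbracket("((((..((((....))))))))")
        sse = next(s for s in decompose(pt, "G" * 22) if s.kind == "bulge")
        tpl = build_fallback(sse, "G" * len(sse.positions))
        coarse_grain(tpl.fragment)  # degenerate side still yields sane geometry

    @pytest.mark.parametrize("ss,kind", [
        ("((.&.))", "break"), (".((....)).", "open"),
        ("((.((....)).((....)).))", "junction"),
    ])
    def test_every_kind_coarse_grains(self, ss, kind):
        _, pt = parse_dotbracket(ss)
        sse = next(s for s in decompose(pt, "A" * pt.n) if s.kind == kind)
        tpl = build_fallback(sse, "A" * len(sse.positions))
        cm = coarse_grain(tpl.fragment)
        assert cm.n_residues == len(sse.positions)


class TestLibraryStore:
    def test_save_load_roundtrip(self, library, tmp_path):
        library.save(tmp_path / "lib")
        lib2 = TemplateLibrary.load(tmp_path / "lib")
        assert len(lib2) == len(library)
        assert lib2.counts == library.counts
        t1 = library.templates[0]
        t2 = lib2.templates[0]
        assert (t1.local_2d, t1.local_seq, t1.source_id) == \
               (t2.local_2d, t2.local_seq, t2.source_id)
        for a, b in zip(t1.fragment.residues(), t2.fragment.residues()):
            for n in a.atoms:
                assert np.linalg.norm(a.atoms[n] - b.atoms[n]) < 1e-3


def _rna_template_for(sse):
    """A synthetic all-U ribonucleotide template with the SSE's topology."""
    from dna3d.geometry import ideal_nucleotide, kabsch_transform
    tpl = build_fallback(sse, "T" * len(sse.positions))
    frag = tpl.fragment
    # convert the deoxy fragment to a ribo look-alike: T -> U plus an O2'
    ideal = ideal_nucleotide("U", deoxy=False)
    for chain in frag.chains:
        for res in chain.residues:
            res.name = "U"
            shared = [a for a in ideal if a in res.atoms]
            rot, t, _ = kabsch_transform(
                np.array([ideal[a] for a in shared]),
                np.array([res.atoms[a] for a in shared]))
            res.atoms.pop("C7", None)
            res.atoms["O2'"] = rot @ ideal["O2'"] + t
    return Template(sse.kind, sse.local_2d, "U" * len(sse.positions), frag,
                    "rna_fixture", source_kind="rna")
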