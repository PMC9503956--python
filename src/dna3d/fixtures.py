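"""Synthetic corpus generation: ideal-geometry DNA molecules with known 2D.

Each fixture molecule is built from its dot-bracket alone: the structure is
decomposed into SSEs, every element gets a de-novo ideal-geometry fragment
(B-form helices, arc loops, helical dangles), and the fragments are
assembled exactly like real templates.  The result is a self-consistent
all-atom model whose decomposition reproduces the requested dot-bracket --
a stand-in corpus for experimental structures that lets the library,
assembly and refinement machinery run end to end without any downloads.

Optional Gaussian coordinate noise emulates experimental variation between
homologous structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import assemble
from .secondary_structure import DotBracket, build_tree, decompose, parse_dotbracket
from .structure_model import Structure
from .template_library import build_fallback

__all__ = ["FixtureSpec", "generate_fixture", "generate_corpus", "default_corpus"]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    seq: str          # nucleotides, no '&'
    dotbracket: str   # extended dot-bracket, may contain '&'
    twist: float = 36.0   # degrees per base-pair step
    rise: float = 3.38    # Angstrom per base-pair step
    noise_sigma: float = 0.0  # Gaussian coordinate noise, Angstrom
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.seq) != len(self.dotbracket.replace("&", "")):
            raise ValueError(f"{self.name}: sequence/structure length mismatch")


def generate_fixture(spec: FixtureSpec) -> tuple[Structure, DotBracket]:
    """Build one all-atom fixture molecule from its dot-bracket."""
    db, pt = parse_dotbracket(spec.dotbracket)
    sses = decompose(pt, spec.seq.upper())
    tree = build_tree(sses)
    chosen = {i: build_fallback(s, s.local_seq or "") for i, s in enumerate(sses)}
    result = assemble(tree, chosen, spec.seq.upper(), pt.break_positions)
    s = result.structure
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for chain in s.chains:
            for res in chain.residues:
                for a in res.atoms:
                    res.atoms[a] = res.atoms[a] + rng.normal(
                        scale=spec.noise_sigma, size=3)
    s.name = spec.name
    return s, db


def generate_corpus(specs: list[FixtureSpec]
                    ) -> list[tuple[str, Structure, DotBracket, float | None]]:
    """Corpus records (id, structure, dotbracket, resolution) for library building."""
    out = []
    for spec in specs:
        s, db = generate_fixture(spec)
        out.append((spec.name, s, db, 2.0))
    return out


def default_corpus(seed: int = 0) -> list[FixtureSpec]:
    """A small standard corpus covering each SSE topology at least twice.

    Topology pairs share their dot-bracket but differ in sequence (and get a
    whisper of coordinate noise), emulating homologous experimental
    structures so leave-one-out template search still finds a match.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(ss: str) -> str:
        n = len(ss.replace("&", ""))
        _, pt = parse_dotbracket(ss)
        letters = rng.choice(list("ACGT"), size=n)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for i, j in pt.pairs():
            letters[j] = comp[letters[i]]
        return "".join(letters)

    topologies = [
        ("hairpin6", "(((((....)))))"),
        ("hairpin4", "((((....))))"),
        ("bulge", "((((..((((....))))))))"),
        ("internal", "(((..((((....))))..)))"),
        ("openloop", "..((((....)))).."),
        ("breakloop", "((((((.&.))))))"),
        ("duplex_break", "(((((((&)))))))..."),
        ("twochain_stem", "((((((....&....))))))"),
    ]
    specs: list[FixtureSpec] = []
    for name, ss in topologies:
        for copy in ("a", "b"):
            specs.append(FixtureSpec(
                name=f"{name}_{copy}",
                seq=rand_seq(ss),
                dotbracket=ss,
                noise_sigma=0.05 if copy == "b" else 0.0,
                seed=int(rng.integers(2 ** 31 - 1)),
            ))
    return specs
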