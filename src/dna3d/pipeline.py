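"""End-to-end prediction pipeline: decompose, search, assemble, refine, rank.

``run_pipeline`` chains the package stages: parse the target secondary
structure, decompose into SSEs, search the DNA (then RNA) template library
for each element, assemble by superposition on shared base pairs, repair
chain connectivity, and -- unless every SSE had a perfect template -- refine
by simulated annealing and return up to five cluster representatives ranked
by the statistical potential.  The "best" structure follows the perfect-
template rule: the assembly when perfect, otherwise the top optimized model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .assembly import AssemblyResult, assemble, repair_connectivity
from .evaluation import select_best
from .optimization import (
    EnergyModel, SAMCConfig, cluster_and_rank, samc_optimize,
)
from .secondary_structure import (
    SecondaryStructureTree, build_tree, decompose, parse_dotbracket,
)
from .structure_model import Structure, write_structure
from .template_library import TemplateLibrary, search_template

log = logging.getLogger("dna3d")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    assembled: Structure
    optimized: list[Structure]
    best: Structure
    best_kind: str
    perfect: bool
    tree: SecondaryStructureTree
    provenance: list[dict] = field(default_factory=list)


def run_pipeline(seq: str, ss: str, dna_lib: TemplateLibrary,
                 rna_lib: TemplateLibrary | None = None,
                 excluded_source_ids: set | frozenset = frozenset(),
                 samc: SAMCConfig | None = None,
                 energy_model: EnergyModel | None = None,
                 n_out: int = 5,
                 skip_optimize: bool = False,
                 out_prefix: str | Path | None = None) -> PipelineResult:
    """Predict a 3D structure for ``seq`` with secondary structure ``ss``.

    When optimization runs it needs ``energy_model`` (train one from the
    same corpus as the library); with ``skip_optimize`` or a perfect
    assembly the refinement stage is skipped per the selection rule.
    """
    seq = seq.upper().replace("&", "")
    db, pt = parse_dotbracket(ss)
    if len(seq) != db.global_length:
        raise ValueError("sequence and secondary structure lengths differ")
    sses = decompose(pt, seq)
    tree = build_tree(sses)
    log.info("decomposed into %d SSEs (%s)", len(sses),
             ", ".join(s.kind for s in sses))

    chosen = {}
    perfect_all = True
    for i, sse in enumerate(sses):
        tpl, perfect = search_template(sse, dna_lib, rna_lib,
                                       excluded_source_ids)
        chosen[i] = tpl
        perfect_all = perfect_all and perfect
        log.info("SSE %d (%s %s): template %s score=%s perfect=%s",
                 i, sse.kind, sse.local_2d, tpl.source_id, tpl.score, perfect)

    result: AssemblyResult = assemble(tree, chosen, seq, pt.break_positions)
    assembled = repair_connectivity(result.structure)
    log.info("assembled %d residues, perfect=%s", assembled.n_residues,
             result.perfect)

    optimized: list[Structure] = []
    if not result.perfect and not skip_optimize:
        if energy_model is None:
            raise ValueError("an energy model is required for optimization")
        cfg = samc or SAMCConfig()
        snapshots = samc_optimize(assembled, tree, energy_model, cfg)
        optimized = cluster_and_rank(snapshots, energy_model, k=n_out,
                                     assembled=assembled)
        optimized = [repair_connectivity(s) for s in optimized]
        log.info("optimization: %d snapshots -> %d ranked models",
                 len(snapshots), len(optimized))

    best, best_kind = select_best(assembled, optimized, result.perfect)

    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}_assembled.pdb").write_text(write_structure(assembled))
        for k, s in enumerate(optimized, start=1):
            Path(f"{prefix}_opt_{k}.pdb").write_text(write_structure(s))
        _write_report(Path(f"{prefix}_report.tsv"), result)

    return PipelineResult(assembled, optimized, best, best_kind,
                          result.perfect, tree, result.provenance)


def _write_report(path: Path, result: AssemblyResult) -> None:
    cols = ["sse_id", "kind", "local_2d", "template_source", "score", "perfect"]
    lines = ["\t".join(cols)]
    for row in result.provenance:
        lines.append("\t".join(str(x) for x in (
            row["sse"], row["kind"], row["local_2d"], row["template_source"],
            row["score"], row["perfect"])))
    path.write_text("\n".join(lines) + "\n")
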