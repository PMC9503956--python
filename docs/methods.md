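# Methods

This note records the modelling choices behind `dna3d`: what is computed,
which parameters matter, and what the synthetic test corpus does and does
not demonstrate.

## Secondary-structure decomposition

Input is extended dot-bracket text: `(`/`)` canonical pairs, `[`/`]`
pseudoknot pairs, `.` unpaired, `&` chain break. Global positions are
0-based and skip `&`; chain identity is recoverable from the break
positions. Pseudoknot pairs are recorded but treated as unpaired by the
decomposition — the SSE taxonomy has no pseudoknot element, so their
positions fall into loops and their geometry is left to templates or
refinement.

Maximal stacked runs of pairs form helices; stacking is broken by a chain
break between either pair of adjacent strand positions. Loop classification:

- *hairpin*: closed by one helix end, no chain break inside;
- *break loop*: any loop whose region directly contains a chain break
  (both nucleotides flanking the `&` belong to the loop). This is the
  DNA-specific element — a helix whose 3'-side strands are interrupted
  between the two paired segments, the mirror image of an open loop;
- *bulge* / *internal*: two helix ends with exactly one / both intervening
  unpaired segments non-empty;
- *junction*: three or more helix ends;
- *open loop*: an exterior element — depth-0 unpaired stretches together
  with the outer ends of the top-level helices they touch. Exterior regions
  are split at depth-0 chain breaks (physically disconnected complexes).

Every loop carries min(2, helix length) boundary pairs from each adjoining
helix, so adjoining elements overlap on shared pairs; re-serializing the SSE
set reproduces the input string exactly (a property test enforces this). A
loop element is emitted only if it has unpaired members, joins two or more
helices, or directly contains a chain break; a blunt broken duplex therefore
decomposes into a stem plus a zero-nucleotide break loop.

The elements form a forest whose edges connect each stem to the loop on its
outer and inner side. We deliberately connect by helix adjacency rather
than raw pair-set intersection: for 1-bp helices the latter would link the
inner and outer loop to each other as well, creating a cycle.

## Ideal geometry

Bases are rigid planar units in the standard base reference frame (the
frame in which an ideal Watson-Crick pair is the 180° rotation of the
complement about the pair x-axis). The sugar-phosphate moiety is grown
from the glycosidic nitrogen by internal coordinates: C2'-endo pucker
(pseudorotation phase 162°, amplitude 35°), anti base (χ = −135°),
γ = 70°, β = 130°, standard bond lengths/angles. The four branch-chirality
signs of the construction were fixed once by a grid search scoring backbone
continuity (O3'–P across stacked residues) and steric sanity of the
generated duplex; the chosen geometry gives ~1.8 Å O3'–P span at each step
(close to the 1.6 Å bond) and 10.8 Å C1'–C1' across a pair.

Ideal duplexes stack pair frames with twist 36°/bp and rise 3.38 Å/bp
(canonical B-form fiber values; configurable). Unpaired loop nucleotides
are placed on a circular arc between their backbone anchors, each residue
oriented with its P→O3' vector along the arc tangent so consecutive O3'–P
gaps come out near bonding distance; dangling ends next to a terminus or
chain break continue the helical stack as a single strand. Junction arms
are fanned at equal angles 14 Å from the center — crude, but downstream
superposition uses only the interface pairs, and refinement handles the
rest.

These primitives serve four roles: atom completion (grafting an ideal
residue onto ≥3 observed atoms; a deliberate replacement for force-field
based completion, keeping the same contract of "no missing atoms
downstream"), base mutation (ideal target base superposed on the old base's
frame; sugar pucker of templates is left unchanged when converting ribo
fragments), the de-novo template fallback, and the fixture generator.

## Template library and search

The corpus filter keeps only molecules with both duplex and loop structure
and ≥ 4 nucleotides; unpaired-only and pure-duplex molecules are labelled
`unStru` / `Helix` and skipped (triplex/quadruplex classes are out of scope
and expected to be pre-filtered by annotation). Kept structures are split
into one template per SSE, indexed by (kind, topology key), the topology key
being the exact local dot-bracket string including `&` placement — "same
secondary structure" is read as exact string equality, with no relaxation.

Match scoring is 5 points for identical topology plus 1.0 per matching loop
nucleotide and 0.2 per matching helix nucleotide; sequence points are
counted only at equal lengths. Ties break by DNA source over RNA, then
better resolution, then source id — deterministic search. RNA fallback
converts U residues to T (gaining the C7 methyl, dropping O2'); assembly
later mutates every residue to the target sequence anyway. When neither
library has the topology, the de-novo builder above constructs the
fragment.

On disk a library is a directory of fragment PDB files plus a TSV index
(source_id, kind, local_2d, local_seq, resolution, file).

## Assembly and connectivity repair

Templates are grafted breadth-first from the tree root (the element holding
the global 5' terminus). Each child is superposed on all heavy atoms of the
up-to-2 shared base pairs (atom names intersected; ≥ 3 points required —
all-heavy-atom superposition fully constrains the orientation, which C1'
atoms alone would not). Where parent and child both provide an interface
residue the parent's copy is kept. Disconnected components (no shared
pairs) are placed side by side with a 30 Å x-offset; their relative
orientation is genuinely undetermined by the method.

Junction repair is a stand-in for a short force-field minimization, scoped
to what that step is actually for — chain connectivity: gradient descent
(backtracking line search, hence monotone) on
`Σ k_b(d(O3'_i, P_{i+1}) − 1.60)² + k_p Σ |x − x₀|²` with k_b = 1,
k_p = 0.05, default 1000 iterations. Only junction atoms feel a net force,
so the rest of the structure is untouched; a 5 Å gap closes to ≈ 1.7 Å.

## Coarse-grained refinement

Each residue is reduced to 6 beads (P, C4', C2', C2, C4, C6). Movable
elements: stems are rigid; hairpin loops with < 5 unpaired nt and
internal/bulge loops with < 7 unpaired nt are rigid; all other loop
residues move individually. Proposals pick an element uniformly and either
translate it (≤ 2 Å), rotate it about its centroid, or rotate it about an
axis through its first P bead (≤ 15°); Metropolis acceptance with geometric
cooling from T = 5.0 to 0.1 (potential units) over 50 stages of 2000
proposals by default. The schedule and move sizes are package defaults —
the method itself fixes only the move types — and are exposed in
`SAMCConfig`; test and CLI runs use smaller, documented schedules sized in
the hundreds-of-proposals range so the whole suite stays fast.

The potential is trained from whatever corpus the user supplies (no
published tables are shipped): distance histograms in 0.3 Å bins to 20 Å
for the 21 unordered bead-type pairs, excluding same-residue pairs, plus
η/θ-like pseudo-torsions over consecutive P/C4' beads in 10° bins. Energies
are −ln of the pseudocounted observed frequency over the distance-marginal
(quasi-chemical) reference, so a type distributed like the marginal has
zero energy everywhere. A harmonic term on consecutive P–P distances
(target 6.7 Å) prevents chain fragmentation during sampling.

Every residue accumulates its own rigid transform over the trajectory, so
all-atom models are reconstructed exactly by applying those transforms to
the assembly (flexible residues are single rigid nucleotides; no internal
rebuild is needed). Snapshots are clustered by greedy RMSD-threshold
assignment (2.0 Å on beads, largest cluster first); each cluster is
represented by its lowest-energy member and up to 5 representatives are
returned, energy-ascending. The best structure is the assembly when all
templates were perfect, else the top refined model.

## Evaluation

RMSD is the Kabsch-minimized all-heavy-atom deviation over residues matched
by global order and atoms intersected by name. The "no open loop" variant
removes the unpaired nucleotides of open-kind elements from both models and
re-superposes — dangling termini are conformationally flexible in solution
and can dominate an otherwise accurate prediction. Because the exclusion
re-superposes, `rmsd_no_open ≤ rmsd_all` is not mathematically guaranteed
and is not asserted anywhere; tests instead check the exclusion set itself.

## Synthetic corpus: what it shows and what it does not

The fixture generator builds molecules from their dot-bracket alone using
the same ideal-geometry primitives as the fallback builder (helices from
stacked pair frames, loops on arcs), then assembles them through the
standard assembly path — so fixtures are exactly self-consistent with the
template machinery. The default corpus holds 8 topologies × 2 sequence
homologs (the second copy with 0.05 Å coordinate noise), covering stems,
hairpins, bulge, internal, open and break loops and two-chain molecules.

Passing the self-assembly (≤ 0.5 Å) and leave-one-out (≤ 2.0 Å) checks
demonstrates that decomposition, search, scoring, superposition, mutation
and bookkeeping are exact — the perfect-template limit. It does *not*
demonstrate accuracy on experimental structures, where templates deviate
from ideal geometry, loops are irregular, and homologs are farther away;
nor does the synthetic corpus exercise junction-rich or pseudoknotted
targets' 3D accuracy. Benchmarking against experimental structures
requires a user-supplied corpus of PDB files with their secondary
structures (the `build-lib` manifest route).

## Numerical choices and degenerate inputs

- Superposition enforces proper rotations (reflection corrected by flipping
  the smallest singular direction); collinear point sets still return a
  deterministic minimizer.
- Zero-pair inputs decompose to open elements covering everything; a
  single-chain all-dots input is one element.
- Altloc handling keeps the highest-occupancy conformer (ties prefer 'A');
  only the first MODEL of NMR ensembles is read.
- Unknown modified nucleotides map to the standard base with maximal
  ring-atom name overlap; residues with fewer than 3 reference atoms are
  dropped and logged.
- All randomness flows through explicit seeds (fixture corpus, Monte Carlo
  proposals); identical seeds give byte-identical outputs.
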