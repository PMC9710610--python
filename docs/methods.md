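# Methods

`screpsim` simulates paired single-cell adaptive immune receptor
repertoires (BCR or TCR) together with per-cell transcriptomes, spatial
placement and, crucially, the *ground truth* of clonal evolution: every
somatic variant's parent is recorded as it arises, so lineage-inference
algorithms can be benchmarked against a known answer. This note
documents the models, their assumptions, the defaults and why, and what
the synthetic data does and does not capture.

## V(D)J recombination

A chain is assembled as `trim3'(V) + ins + [trim5'3'(D) + ins +]
trim5'(J)`. Segment identities are drawn from configurable usage
distributions (uniform by default); deletion lengths are drawn
independently for each segment end flanking a junction (default uniform
on 0–3 nt) and insertion lengths per junction (default uniform on 0–6
nt, inserted bases uniform). All draws are recorded on the chain, so the
sequence is byte-exactly reconstructable from its provenance — the basis
of a standing test invariant. Heavy (IGH/TRB) and light (IGK/IGL/TRA)
chains are sampled independently; joint V–J pairing tables are not
modelled.

**Junction (CDR3 proxy).** Simulated sequences carry no conserved
Cys/Trp anchors, so the junction is *defined* as the 3'-most 3 nt of the
trimmed V through the 5'-most 3 nt of the trimmed J. Because SHM is
substitution-only, these coordinates remain valid for every downstream
variant.

**Productivity.** A chain is productive iff its length is a multiple of
3 and translation from position 0 contains no stop codon. Real
annotation tools additionally locate the V reading frame and check
anchor residues; this simplification keeps the rule self-contained and
deterministic. Under `productive_only`, each chain is rejection-sampled
(cap 1,000 attempts). The packaged synthetic reference draws V and J
segments from stop-free codons in frame 0 so productive outcomes arise
at a realistic rate (roughly 10–20 % per draw, dominated by the 1-in-3
frame match).

**Packaged reference.** ~20 synthetic segments per locus (12 V, 6 D
where applicable, 5 J) with realistic lengths (V ≈ 295 nt, D ≈ 15 nt,
J ≈ 50 nt) for IGH, IGK, IGL, TRB and TRA, shipped as FASTA. Users can
substitute any IMGT-style FASTA.

## Clonal dynamics

Time advances in discrete steps; each step applies, in this fixed
order: (1) new-clone influx (one founding event with probability
`p_new_clone`), (2) division with SHM, (3) class switching and phenotype
transition, (4) death. The order matters for the exact trajectories and
is therefore fixed and documented rather than configurable. Newborn
daughters are exempt from switching and death in their birth step; a
division leaves the mother in place and creates one new barcode.

- **Division.** `p = clamp(p_div0 + beta_div·(n−1), 0, p_max)` with `n`
  the clone's alive size, snapshotted at the start of the phase so the
  result does not depend on cell iteration order. The additive-linear
  form is the simplest that lets the rate rise or fall with clone size
  via the sign of `beta_div`.
- **Class switching.** A row-stochastic 5×5 matrix over (IgM, IgD, IgG,
  IgA, IgE), applied once per cell per step. The default is
  upper-triangular (switching is biologically irreversible) with
  per-step switch masses from IgM of 0.003/0.032/0.012/0.003 to
  D/G/A/E; over a default 15-step run this lands the repertoire at
  IgM > IgG > IgA > IgE with a wide margin (regression-tested).
- **Phenotypes.** Labels default to Naive/GC/Memory/Plasma with a
  row-stochastic per-step transition matrix (Plasma absorbing). Selected
  variants may use an alternative matrix (packaged plasma-absorbing
  override) to couple clonal selection to fate.
- **Variant selection.** Modes: none, random (uniform sample of up to
  *k* variants), germline (clones founded with a given V gene), and
  CDR3 length (heavy-chain junction ≥ threshold). Selected variants
  multiply their division probability by `sel_multiplier` (product
  capped at 1) and descendants with an identical receptor sequence
  inherit selection. The engine applies selection once per clone at
  `selection_step` (default: at founding).
- **SHM trigger.** Each daughter cell mutates with probability
  `max(p_isotype, p_phenotype)` (default 0.2 for all classes); the max
  is the chosen combination rule when both knobs are set, since neither
  dominates the other a priori.

Every event is appended to a log (step, kind, ids, payload); replaying
the log against an empty state reproduces the final cell table exactly,
which is both an export format and a correctness check.

## Somatic hypermutation

Mutation events are substitution-only (lineage trees then live in a
fixed coordinate system; no indel bookkeeping). Per event the count is
Poisson(λ) (default λ = 5) truncated at the number of mutable positions;
positions are drawn without replacement within an event, with
replacement across events.

Three models bind positional and substitution behaviour:

| model | position choice | substitution |
|---|---|---|
| `poisson` | uniform | uniform over the 3 alternatives |
| `data_driven` | interval multipliers (e.g. CDR weighting) | transition:transversion = κ:1 (default κ = 3) |
| `motif` | 5-mer mutability centred on the site | the 5-mer's substitution distribution |

With κ = 1 and a flat 5-mer table all three collapse to the same
process (tested by chi-square on position and substitution marginals).
The packaged 5-mer table is synthetic: WRC/GYW hotspot 5-mers carry 8×
baseline mutability and substitutions favour transitions 2:1:1.
Experimentally fitted tables can be supplied as TSV
(`fivemer, mutability, p_to_A..p_to_T`). Flank positions (within 2 nt of
an end) have no full 5-mer context and are treated as non-mutable under
the motif model; 5-mers absent from an incomplete user table fall back
to the table's mean mutability and uniform substitution.

## Lineage networks

Ground truth: each clone's variants form a tree rooted at the founder
receptor — the recombined sequence *after* junctional diversification
but *before* any SHM, which is exactly the "germline" an inference
method would be given. Re-mutation onto an existing sequence merges into
that node, keeping variants unique. A variant carried by no living cell
at the end is flagged *historical*.

Inference: nodes are added in ascending edit distance to the germline
(Levenshtein on the concatenated heavy `|` light string, computed with
edlib; the separator makes cross-chain edits maximally expensive) and
each new node attaches to the already-placed node at minimal distance.
Ties: by lexicographic sequence in the insertion order, by earliest
placement for attachment — arbitrary but fixed, since determinism is
required.

Topology metrics: depth (max root-to-leaf edges), size (non-root
nodes), breadth (max nodes per non-root level), Sackin index (sum of
root-to-leaf depths over leaves).

Matching criterion: nodes are mapped by sequence; the true network is
first reduced over its historical nodes — extinct dead-end leaves are
pruned recursively (their sequences cannot appear in the inference
input) and degree-2 pass-through nodes are spliced — and the directed
edge sets must then be identical. A historical node with two or more
surviving branches cannot be reduced and counts as a mismatch, since no
sequence-only method could recover it.

## Transcriptomes

Per cell: scale `s = exp(N(0, noise_sd²))` (default noise_sd = 0.3),
counts `Poisson(s·base_g)` per gene, with `base` the phenotype's mean
vector. The lognormal-Poisson choice gives closed-form moments
(`E[count] = base·exp(sd²/2)`) used directly in tests, and the per-cell
scale cancels under library-size normalization. The packaged profiles
cover 200 synthetic genes × 4 phenotypes: named markers (Cd19, Fas,
Cd38, Sdc1/Cd138, Taci, Xbp1) with hand-set means following the standard
phenotype orderings, 12 signature genes per phenotype at 10-fold
enrichment, and shared housekeeping genes. A nearest-centroid
regression test holds the profiles to ≥ 95 % label recovery at 2,000
cells.

## Spatial integration

Spots are annotated B/T/other by summed marker expression (T: Cd3e,
Cd4, Cd8a; B: Cd19, Sdc1, Xbp1) after unit-sum normalization and log1p;
exact ties and all-zero spots are `other`. Density is an isotropic
Gaussian KDE with Scott's-rule bandwidth, implemented directly so that
degenerate inputs (single spot, collinear spots) still return finite
densities. Assignment methods process clones in descending size:
*random* (uniform unassigned spots), *density* (spot probability
proportional to current density; density re-estimated over unassigned
spots after each completed clone, per-clone rather than per-cell), and
*germline* (founder — the member whose variant is closest to the root —
placed by density sampling, remaining members on the nearest unassigned
spots by Euclidean distance from the founder, ascending). Coordinates
follow the image convention (origin top-left, y downward). Trajectory
edges link assigned parent-variant cells to their mutated descendants,
either all parents or the geometrically nearest.

## Outputs

`filtered_contig_annotations.csv`, `filtered_contig.fasta` and
`clonotypes.csv` follow the cellranger-vdj column set; the gene-count
matrix is MatrixMarket triplet + barcodes/features. `reads`/`umis` are
synthetic depth placeholders (`umis ~ 1+Pois(3)`,
`reads = umis·(1+Pois(30))`) present only for format compatibility. The
`cdr3` amino-acid column is the frame-0 translation of `cdr3_nt` and may
contain `*` for nonproductive contigs. The whole pipeline is
byte-deterministic given a seed.

## Problem sizes and defaults

Defaults (15 steps, 200 initial clones, p_div0 = 0.2,
beta_div = 0.005, p_death = 0.02, p_new_clone = 0.05, SHM 0.2 per
division, λ = 5) produce ~2–5 k final cells in a couple of seconds — the
scale of one 10x channel — and per-clone lineages of ~1–15 variants,
comparable to typical single-sample clonal families. The inference
benchmark uses 20 clones under exactly these dynamics with influx
disabled, scored over 5 seed sets.

## What the synthetic data does not capture

Germline segments, 5-mer mutabilities and expression profiles are
generated, not fitted: absolute usage biases, allele-level nomenclature,
hotspot spectra and gene–gene covariation are not those of any real
organism. SHM has no indels; affinity and antigen are not modelled
(selection is a phenomenological multiplier); expression noise has no
batch effects, doublets or ambient RNA; spots hold at most one assigned
cell. Passing tests therefore demonstrate internal consistency and
algorithmic correctness — e.g. that the inference algorithm recovers
known topologies under realistic mutation loads — not fidelity to any
particular experimental dataset.
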