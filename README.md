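# screpsim

Simulation of single-cell adaptive immune receptor repertoires (paired
BCR/TCR) integrated with per-cell transcriptomes and spatial placement —
with the **ground truth of clonal evolution** preserved.

Single-cell immune repertoire sequencing couples each cell's V(D)J
rearrangement to its transcriptome, but benchmarking the analysis tools
built on such data (clonal lineage inference, clonotype–phenotype
association, spatial clonality) is hard because the true evolutionary
history of real B-cell clones is unobservable. `screpsim` generates that
history explicitly: paired V(D)J recombination with junctional
diversification, time-stepped clonal expansion and death, isotype class
switching, phenotype transitions, somatic hypermutation (SHM) recorded
as a rooted mutational network per clone, phenotype-conditioned gene
expression, and assignment of clonotypes onto spatial spot coordinates —
all emitted in 10x-cellranger-compatible files, byte-deterministic under
a fixed seed.

## The models in brief

- **Recombination**: `nt = trim3'(V)+ins+[trim5'3'(D)+ins+]trim5'(J)`,
  segment usage and junction length distributions configurable;
  productive = in-frame and stop-free.
- **Dynamics**: per step, each cell divides with
  `p = clamp(p_div0 + β(n−1), 0, p_max)` (clone size `n`), dies with
  `p_death`, switches isotype and phenotype via row-stochastic Markov
  matrices; selected variants gain a division multiplier.
- **SHM**: per division, a daughter mutates with probability
  `max(p_iso, p_phen)`; the event places Poisson(λ) substitutions under
  one of three models — uniform, transition-biased (κ:1), or 5-mer
  motif mutability (WRC/GYW hotspots by default).
- **Lineage inference** (benchmarked against the recorded truth): add
  unique sequences in ascending Levenshtein distance from the germline,
  attach each to the closest placed node; compare topologies by depth,
  size, breadth and Sackin index (sum of leaf depths).
- **Expression**: `counts_g ~ Poisson(exp(N(0,σ²))·base_g)` per
  phenotype profile. **Spatial**: spots annotated B/T by markers,
  clonotypes assigned by random / density (Gaussian KDE, Scott's rule) /
  germline-distance rules.

## Worked example

```python
from collections import Counter
from screpsim import SimulationParams, ShmModel, run_simulation, benchmark_networks, match_count

state = run_simulation(SimulationParams(seed=1), shm_model=ShmModel())
print(len(state.alive_cells()), Counter(c.isotype for c in state.alive_cells()))

report = benchmark_networks(n_clones=20, seed=3)
print(f"{match_count(report)}/{len(report)} lineage topologies recovered")
```

prints

```
4406 Counter({'IGHM': 2559, 'IGHG': 1152, 'IGHA': 493, 'IGHE': 144, 'IGHD': 58})
19/20 lineage topologies recovered
```

4,406 cells survive 15 steps across 201 clones; isotype frequencies
follow the biological ordering IgM > IgG > IgA > IgE because the default
switch matrix is slow and strictly forward. Of 20 simulated clonal
lineages, 19 are reconstructed edge-for-edge from their final variant
sequences alone — the one failure involves a variant nearly identical to
the unmutated germline, which makes the attachment order ambiguous.

The `examples/` directory holds one short script per capability
(recombination, expansion, lineage benchmark, integrated transcriptome,
spatial assignment, repertoire divergence). A thin CLI wraps the same
functions:

```bash
screpsim simulate --seed 1 --outdir out/        # vdj/ + truth/ + gex/
screpsim benchmark-networks --n 20 --seed 1
screpsim spatial-assign spots.csv gex/ --method density
screpsim kld repA.fasta repB.fasta
```

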