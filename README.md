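# sctem

Single-cell transposable-element methylation sequencing (scTEM-seq):
estimate a cell's **global DNA methylation** from amplicon bisulfite
sequencing of high-copy SINE Alu elements, at ~20 thousand reads per
cell instead of the ~20 million a genome-wide single-cell bisulfite
library needs.

The package is for people studying genome-wide methylation loss —
e.g. hypomethylating-agent (decitabine) response in AML — who want
per-cell methylation levels linked to matched expression data, plus a
fully controlled simulator to validate every pipeline stage against
known ground truth.

## The method

SINE Alu copies (~10^6 per genome) carry internal CpGs whose average
methylation tracks the global level.  One bisulfite-space primer pair
against an AluYa5-like consensus amplifies thousands of loci at once;
an internal dual 8 bp index in the primers identifies the cell, a
0–5 N spacer phases the low-diversity amplicons, and half the wells
sequence in reversed orientation.

Per cell, reads are demultiplexed on the internal indexes, aligned
non-directionally in the reduced bisulfite alphabet (C→T / G→A, all
four strand configurations, unique minimal-mismatch placements only),
and CpG states are called from the read base at reference cytosines.
The per-cell estimate is the **site-mean**

    m̂ = (1/|S|) Σ_{s∈S} 100 · M_s / (M_s + U_s)

over covered CpG sites S (unweighted across sites, not reads), with QC
requiring ≥ 1000 distinct annotated TE elements covered (≥ 500 in the
low-coverage preset) and non-CpG methylation (CHG/CHH) as a bisulfite
conversion check.  Depth stability is assessed by rarefaction: aligned
read pairs are subsampled without replacement and the estimate's
per-depth range reported.  Expression integration computes per-feature
Pearson correlations of log2(1 + RPM) values with the methylation
estimate and controls FDR by Benjamini–Hochberg.

A generative simulator produces the whole study design — diverged TE
mini-genomes, indexed primer plates, per-cell epiallele draws,
conversion failure/over-conversion, methylation-dependent PCR bias
`(1+β)^m`, sequencing error, pooled FASTQ with truth tables, and
matched negative-binomial expression with planted methylation-linked
features.  See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import numpy as np
from sctem import reference, simulate, demux, methylation

consensus = reference.build_consensus(length=300, cpg_density=0.08, seed=1)
genome, annotations = reference.synth_genome(consensus, n_copies=2000,
                                             divergence=0.05, seed=2)
plate = reference.design_plate(consensus, n_wells=96, seed=3)

params = simulate.CellSimParams(cell_id="cell00", well_id="A1",
                                true_methylation=0.8648,
                                n_read_pairs=20000, seed=4)
pairs, truth = simulate.simulate_cell(genome, annotations, plate, params)

by_well, report = demux.demultiplex(pairs, plate, max_mismatch=1)
trimmed, _ = demux.trim_all(by_well["A1"], 10, 10)
ref = methylation.BisulfiteReference(genome)
aligned = methylation.align_pairs(trimmed, ref)
calls = methylation.extract_methylation(aligned, trimmed, ref)
cov = methylation.cov_from_calls(calls, ref)
cell = methylation.cell_methylation(cov, annotations,
                                    te_site_threshold=1000,
                                    cell_id="cell00")
table, ranges = methylation.bootstrap_stability(calls, [5000, 10000],
                                                n_reps=20, seed=5)
```

prints (via the fuller script in the docstrings):

```
simulated 20000 read pairs; realized per-site methylation 86.20%
demultiplexed: 19999 pairs to well A1, 1 unassigned
aligned 17259 pairs; 25789 CpG sites over 1732 TE elements
site-mean methylation 85.87% (CHG 0.70%, QC pass: True)
depth 5000: estimate range 0.247 points
depth 10000: estimate range 0.053 points
```

The cell was generated at a true per-CpG methylation of 86.48%; its
realized draw is 86.20% and the pipeline recovers 85.87% from 17k
aligned pairs (the small shortfall is the modelled conversion
chemistry).  The CHG rate near 0.7% confirms efficient conversion, and
the estimate moves < 0.3 percentage points across 20 subsamples at
5000+ aligned pairs — the depth-stability property that makes the
shallow assay trustworthy.

The same flow is available from the shell:

```sh
sctem simulate --out-dir demo --n-cells 8 --seed 1
sctem demux --r1 demo/pool_R1.fastq.gz --r2 demo/pool_R2.fastq.gz \
      --plate demo/plate.tsv --out-dir demo/wells
sctem align --r1 demo/wells/A1_R1.fastq.gz --r2 demo/wells/A1_R2.fastq.gz \
      --genome demo/genome.fa --out demo/A1.cov
sctem methylation --cov demo/A1.cov --bed demo/annotations.bed
sctem run-all --out-dir demo_full --seed 1     # whole pipeline + manifest
```

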