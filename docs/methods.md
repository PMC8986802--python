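# Methods

## The problem

Single-cell bisulfite methods that survey the whole genome need ~20
million reads per cell; most questions about hypomethylating-agent
response only need a *global* methylation level per cell.  Because
SINE Alu elements are present in ~10^6 copies and their internal CpGs
track genome-wide methylation, a single bisulfite-space primer pair
against an AluYa5-like consensus can amplify thousands of loci at once
and estimate global methylation from ~20 thousand reads — three orders
of magnitude cheaper.  This package implements that computational
pipeline end to end, together with a generative simulator that serves
as ground truth for validating every stage.

## Pipeline model

1. **Reference.** A consensus sequence `S` with CpG density `d`
   (default 300 nt, d = 0.08, matching a young Alu's ~25 internal
   CpGs).  A mini-genome embeds `n` independently substituted copies
   (default 2000 copies at 5% divergence — the scale at which the
   assay recovers 1000–6000 unique elements per cell) separated by
   random flanks, with BED6 annotations spanning each copy.
2. **Plate.** 96 wells; each well carries a unique 8+8 bp internal
   dual index (enforced concatenated Hamming distance ≥ 2·m+1 so
   m-mismatch demultiplexing cannot cross wells), a 0–5 N phasing
   spacer cycled across wells, and bisulfite-space priming sequences:
   forward = C→T-converted consensus window, reverse = G→A-converted
   reverse complement, windows chosen to minimise CpG overlap.  Half
   the wells sequence the amplicon in reversed orientation (mate roles
   swapped) to break flow-cell low-diversity pathology.
3. **Chemistry model (simulator).**  Per cell, each CpG site in an
   amplifiable insert draws one epiallele state `Bernoulli(p_true)` —
   a single cell has one template molecule per locus, so conversion
   outcomes are *fixed per site*, not per read:
   - unmethylated C → T, failing with `conversion_failure`
     (default 0.007, the regime implied by the published 0.67% CHG
     rate);
   - methylated C → C, erroneously converted with
     `inappropriate_conversion` (default 0.005, a typical
     over-conversion magnitude; not directly measured in the assay);
   - template loci are drawn with weight `(1+β)^m`, `m` = methylated
     CpGs in the template and `β = amp_bias` (default 0.1) — the
     simplest monotone model of the preferential amplification of
     methylated molecules;
   - uniform per-base sequencing error (default 0.001), constant
     Q40 qualities; read length 150 nt, inserts truncated, never
     padded.
   Diploidy, PCR duplicate families and learned error profiles are
   deliberately out of the model; passing tests therefore speak to
   estimator logic, not to those real-data effects.
4. **Demultiplexing.**  Anchored, substitution-only matching of the
   first 8 nt of each mate against the well's expected index pair
   (orientation-aware).  Default tolerance 1 mismatch; with plate
   distance ≥ 3 this cannot mis-assign.  Among qualifying wells the
   unique minimal-distance well wins; equal ties are counted as
   ambiguous, never rescued.  Assigned reads are stripped of index +
   declared spacer + primer, then end-trimmed 10/10 bp.
5. **Alignment.**  Reads and reference are reduced C→T (top strand)
   and G→A (bottom strand); non-directional mode scores all four
   post-PCR strand configurations (OT/CTOT/OB/CTOB).  Candidates come
   from 16-mer seeds stepped every 16 nt; a seed hitting more than
   `count_cap` (64) positions is uninformative (it lies in sequence
   shared by many copies) and skipped — reads with no informative seed
   are inherently multi-mapping and are left unaligned, consistent
   with the unique-alignment-only policy.  Candidates are verified by
   full Hamming distance; a read aligns iff a unique location attains
   the minimum and the mismatch rate is ≤ `max_mismatch_rate`
   (default 0.1).  Mates must agree in reduction, oppose in
   orientation, and sit within `max_insert` (2000 bp).
6. **Extraction and estimation.**  Every reference cytosine covered
   by an aligned read yields one call; context (CpG/CHG/CHH) comes
   from the reference, state from the read base; mate-overlapping
   positions are counted once, first mate wins.  CpG calls aggregate
   to a Bismark-dialect `.cov` table (1-based, start = end).  The
   per-cell estimator is the **unweighted mean over covered CpG sites**
   of site-level methylation percent; the read-weighted mean is kept
   as a diagnostic.  QC requires ≥ 1000 distinct annotated TE elements
   overlapped (≥ 500 in the low-coverage preset).  "Annotated TE
   sites" is interpreted as distinct elements, not CpG positions; both
   counts are reported.
7. **Stability.**  Depth stability subsamples aligned read *pairs*
   without replacement (rarefaction semantics; a with-replacement mode
   is flag-gated), recomputing the site-mean per replicate and
   reporting the per-depth range.  Under amplification bias the
   site-mean inflates at low depth: shallow coverage samples sites
   preferentially from methylated templates, while saturated coverage
   weights every site once — the model reproduces this qualitatively.
8. **Integration.**  Counts → RPM → log2(1 + RPM) (base and
   pseudocount configurable; the transformation is only specified as
   "log" upstream).  Feature presets: inclusion (≥2 reads in ≥10
   cells), DE-style (≥5 in ≥3), expressed-background (≥10 in ≥2).
   Per-feature Pearson r against the per-cell estimate (QC-passing
   cells only, treated and untreated pooled), two-sided p from
   t = r·√((n−2)/(1−r²)), Benjamini–Hochberg step-up FDR across all
   tested features.  Constant features are skipped (undefined ≠ 0).
   TE ids carry `element|family:class`; family aggregation sums
   element counts.  DESeq2-style differential expression and GO
   testing are out of scope; ranked significant/background gene lists
   are exported for external tools.

## Numerical and degenerate-input choices

- Percents live in [0, 100] everywhere outside the simulator;
  proportions only inside the chemistry model.
- Empty coverage ⇒ estimate NaN, `qc_pass = False` (never an error).
- Zero non-CpG calls ⇒ conversion rates NaN and the QC flag raised.
- Alignment ties discard both candidates; demux ties are reported
  ambiguous.
- Subsample depths exceeding the available aligned pairs are skipped
  with a warning rather than clamped.
- All randomness flows from a master seed through
  `numpy.random.SeedSequence`-derived per-cell seeds (kept < 2^31);
  gzip output is written with fixed mtime and no embedded filename so
  reruns are byte-identical.

## Problem sizes

The validation suite runs the estimator at the published regime — two
cells (45% / 86.5%) and a 46-cell plate at 86.48%, 20,000 read pairs
per cell on the 2000-copy world — and smaller 60–200-copy worlds for
unit-level checks.  At the simulated unique-alignment rate (~86%) a
20,000-pair library yields ~17k aligned pairs, so the deepest
subsample level is the full aligned library.

## Known limitations

- The aligner is seed-and-verify over a mini-genome; it is not an
  FM-index genome-scale mapper and makes no indel model (index and
  primer synthesis errors are substitution-like; TE copies here differ
  by substitutions only).
- One epiallele per locus: allele-specific methylation and diploid
  heterozygosity are not modelled.
- The amplification-bias model is exponential in the methylated-CpG
  count; real PCR bias saturates with cycle number.
- Expression counts are independent negative binomials around a
  log-linear methylation effect; no gene–gene correlation, batch or
  dropout structure.
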