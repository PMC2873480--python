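# Methods note

This note records the models, parameter choices, and numerical conventions
behind `gutmir`, and the limits of the synthetic benchmark.

## Read processing

- **Adapter clipping.** The insert is the prefix before the *leftmost*
  occurrence of the first `min_adapter_overlap` (default 6) nucleotides of
  the 3′ adapter (`TGGAATTCTCGGGTGCCAAGG`). Reads without such a match are
  dropped (`dropped_no_adapter`); inserts outside 18–30 nt are dropped
  (`dropped_length`). The 6-nt overlap keeps the false-trigger rate of a
  random hexamer (~1 per 4 kb) negligible at read length while tolerating
  partial adapter read-through on 36-cycle reads.
- **Collapsing.** Identical inserts (U≡T) merge into `seq_N` records ordered
  by descending count, then lexicographically; total read count is conserved
  by construction.
- **Contig QC.** Contigs shorter than 200 nt or with an N fraction ≥ 0.20
  are excluded before mapping.
- **Mapping.** Perfect-match both-strand lookup via a dictionary keyed by
  read length (reads are short and few distinct lengths occur, so this is
  O(genome) preprocessing + O(1) per position). Reads with ≥ 5 total genomic
  hits (both strands combined) are treated as repeat-derived and removed
  from prediction.
- **Stacks.** Transitively overlapping hits on the same contig and strand
  merge into read stacks.

## Hairpin discovery

- **Excision.** Each stack yields two candidate windows,
  `[start − 70, end + 20)` and `[start − 20, end + 70)`, so a mature read at
  either arm of a precursor is covered; windows are clipped to the contig
  and deduplicated. Minus-strand windows are reverse-complemented and all
  read offsets are expressed in read orientation.
- **Folding.** ViennaRNA (Turner nearest-neighbor parameters, 37 °C)
  provides the minimum-free-energy structure.
- **Hairpin filter.** A candidate needs exactly one terminal loop over the
  read-covered region, a mature placement overlapping the loop by ≤ 1 nt,
  and ≥ 60% of mature positions paired. Rejection reasons are recorded
  (`no-reads`, `no-hairpin`, `multi-loop`, `mature-in-loop`,
  `mature-underpaired`).
- **Scoring.** Additive log-odds-style score:
  - signature: `clamp(log2((C+1)/(I+1)), ±10)` where `C` counts reads whose
    5′ end lies within ±2 nt of the mature or star 5′ ends and `I` the rest
    (count-weighted);
  - stability: ±1.3 at an MFE threshold of −25 kcal/mol;
  - star evidence: +1.6 if any non-mature read 5′ end falls within ±1 nt of
    the predicted star 5′ end (star predicted from the 2-nt 3′ overhang
    rule);
  - seed conservation: +3.0 / −0.6 for presence/absence of the mature seed
    (positions 2–8, DNA-spelled) in the catalog seed set.
  Candidates with score ≥ −3 pass; overlapping passing windows on one
  contig/strand are deduplicated keeping the best score (ties: lower MFE,
  then leftmost). A passing candidate whose mature lies within 2 edits of a
  catalog mature is labeled *known*, otherwise *novel*.
- **False-positive control.** Read signatures are permuted across
  read-bearing windows by a seeded derangement and rescored, 10 rounds; each
  round's passes are deduplicated by the same overlap rule as the real
  selection, and transplanted reads are kept under the same
  window-overlap rule used for real read attachment, so the control differs
  from the real run only in the read-to-window assignment. The
  signal-to-noise ratio is `round(n_pass_real / fp_mean, 1)` with
  round-half-away-from-zero.

## Conservation search

Reads with count ≥ 10 are compared to the catalog with edlib (Levenshtein,
U≡T); assignments allow ≤ 2 edits, one best read per catalog entry (highest
count, then fewest edits, then lexicographic). Assignments to
primate-specific catalog entries that do not map to the genome are flagged
as potential cross-species contamination.

## Array normalization and validation

Per sample: subtract the lowest-decile background, scale to equalize
medians across samples, then apply the glog transform
`h(x) = log2(x + √(x² + c²)) − 1` with `c` set to the median absolute
deviation of the background features. `h` is defined for the negative
values produced by background subtraction and approaches `log2(2x) − 1`
for bright signal, stabilizing replicate variance across the intensity
range. Replicates (7 per probe) are summarized by the median. Detection
requires normalized signal strictly > 7; a target whose mature probe fails
but whose star probe passes is rescued (`rescued_by_star`), and a target
whose star probe exceeds its mature probe in every sample is flagged
star-dominant (likely arm mis-annotation). `novel_fraction` reports
round-half-up percent (201 of 332 → 61).

## Expression analysis

Detection calls induce per-locus expression sets (Venn overlaps by
inclusion-exclusion). For targets detected in all samples, log ratios are
taken against the common-reference pool (reference column identically 0).
Two-way hierarchical clustering uses 1 − Pearson distance with average
linkage (scipy); zero-variance rows are assigned correlation 0 to keep
distances finite. Trees export to Newick. Cross-platform agreement is the
Pearson correlation per shared sample (≥ 3 shared targets required) and
globally.

## Genomic organization

Placement is an exact both-strand substring search (optionally ≤ 2
mismatches, ungapped, for conserved precursors). Reports: duplications
(one precursor at ≥ 2 loci, with percent identity of the oriented genomic
slices), single-linkage clusters within a 10 kb gap whose *span* is the
difference of extreme printed coordinates, alternative precursors (two
hairpins housing the identical mature with overlapping intervals; overlap is
the 1-based inclusive intersection length), and per-chromosome counts with
unplaced or unlabeled precursors reported as ND (percentages round half
up).

## Synthetic benchmark

The simulator's defaults are the study conditions: 12 contigs × 4 kb, 20
planted hairpins, 50 decoy inverted repeats, 2 repeat families × 5 copies,
mean read depth 100 per mature, 8% star and 2% loop reads, 300 background
reads, 36-cycle reads with adapter read-through. Key design points:

- **Hairpin realism.** Stems carry 3 interior mismatches so that a mature
  read maps uniquely to its own arm; perfect-complement stems would create
  phantom mirror candidates on the opposite strand. Precursors carry 2-nt
  3′ overhang geometry so the star strand is predictable.
- **Decoys receive no reads.** Decoys are structural confounders (12-bp-stem
  inverted repeats) testing that structure alone, without read evidence,
  does not pass scoring. A decoy "passes" if a passing candidate's called
  mature interval intersects the repeat interval.
- **Expression design.** Two hairpins are restricted to duodenum/proximal
  jejunum; a four-hairpin block is expressed everywhere with a +2.5 log2
  lift in both colonic loci, which makes the two colon samples cluster as
  siblings; remaining targets are ubiquitous. Star probes run 3 log2 units
  below mature (inverted for designed star-dominant targets). Replicate
  noise is multiplicative lognormal (σ = 0.10).
- **Problem sizes** are the package's own choice for desk-scale runtime
  (full pipeline ≈ 30 s); they are not calibrated to any sequencing
  campaign's scale.

## Limitations

- Mapping and placement are exact-match (plus an ungapped mismatch mode);
  there is no indel-tolerant genomic aligner.
- MFE values for short precursor sequences folded *in isolation* are
  systematically less negative than values reported for the same hairpins
  folded with flanking genomic context; energies quoted for a precursor are
  therefore comparable only under the same folding window convention.
  `scripts/acceptance.py` reports the isolation-fold values.
- The array model has no spatial/print-tip effects, no probe-affinity
  differences, and no cross-hybridization beyond the mature/star pair.
- The permuted-read control measures enrichment of consistent read
  signatures over a randomized assignment; it is not an FDR in the formal
  sense.
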