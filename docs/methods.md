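# Methods

## Problem setting

Transient toxicant exposure of a gestating female can alter the sperm
epigenome of her descendants. Upstream differential analyses yield, per
exposure lineage (vinclozolin, DDT) and generation (F1 offspring, F2
grand-offspring, F3 transgenerational great-grand-offspring), catalogs of
candidate epimutations of three types: DMRs (differential DNA methylation
regions), differentially expressed ncRNA loci (sncRNA and lncRNA pooled,
subtype kept as metadata), and DHRs (differential histone retention
sites). This package takes those processed catalogs — not reads or signal
— and quantifies where the mark types and generations colocalize on the
genome, and whether that colocalization exceeds random expectation.

## Coordinate and overlap conventions

- Coordinates are 0-based half-open `[start, end)` everywhere; BED I/O is
  native, 1-based TSV input is converted at the reader boundary.
- Strand is ignored; epimutations are unstranded sites.
- Chromosome names match by exact string equality (a reader column map
  can rename; nothing is renamed implicitly).
- Overlap means ≥ 1 shared bp; abutting intervals do not overlap.
- Deterministic ordering by (chrom, start, end, id) everywhere; the
  pairwise engine is a sorted sweep with end-keyed heaps,
  O((n+m)·log(n+m) + k), verified against an all-pairs oracle in tests.

## Thresholding

Each mark has a stringent cutoff (DMR 10⁻⁶, DHR 10⁻⁶, ncRNA 10⁻⁴) and all
marks share the relaxed cutoff 0.05. Comparisons are strict (`p < cutoff`)
and applied to raw p-values; no multiple-testing adjustment is performed,
since the catalogs' p-values are consumed as published by the upstream
pipelines. Every stringent set is therefore a subset of its relaxed
counterpart, which forces the overlap-matrix diagonal to 100% — a useful
built-in control.

## Extended overlap matrix

Cell (i, j) counts distinct stringent-row features overlapping ≥ 1
relaxed-column feature; the percentage divides by the row set size (the
stringent set), so the matrix is deliberately asymmetric. Empty rows
report counts of 0 and missing (NaN) percentages. For the 10 kb window
variant, **both** row and column features are extended by 5 kb per side
before overlap. Extending both sides was chosen for symmetry of the
induced "within 10 kb" relation; a row-only mode is available
(`extend_rows_only=True`) for sensitivity analysis. Window extension is
clipped at chromosome edges and never applied to stored coordinates —
ids, p-values and the original intervals are preserved.

## Venn partitioning

Features of 2-3 sets are pooled and clustered by single-linkage overlap
into connected components (for intervals this reduces to a linear scan in
start order, breaking whenever the next start is at or beyond the running
maximum end). A component's signature is the set of input sets
contributing ≥ 1 feature. Counting components rather than features avoids
double-counting when a wide feature of one set spans several features of
another; a per-feature counting mode is exported alongside for
comparison. Signature counts always sum to the number of components.

## Permutation null

The null re-places size-matched sites of fixed width (1 kb or 10 kb by
convention, matching the kilobase scale of the features) uniformly on the
genome: chromosome chosen with probability ∝ (length − width + 1), start
uniform over the valid range, sites free to overlap one another.
Per-chromosome counts are *not* preserved — the simplest defensible null;
a chromosome-preserving, width-preserving shuffle is available as an
option. Only the non-anchor set(s) are randomized: the pairwise test
conditions on the fixed set (extended once by any flank before both
observed and null statistics), and the multiway test holds the DMR set
fixed while randomizing ncRNA and DHR. Empirical p-values use
(r + 1)/(n_perm + 1), which cannot be zero and is conservative under the
null; n_perm defaults to 999. Reproducibility is bit-exact under a fixed
seed. Calibration (type-I error at α = 0.05 inside the exact binomial 95%
interval over 200 null replicates) and conservativeness (empirical p not
stochastically below uniform) are checked in the test suite.

## Synthetic catalog generator

The generator emulates the *structure* of the real catalogs, not their
signal level; its p-value tiers are explicit constructions rather than
fits to data:

| parameter | default | meaning |
|---|---|---|
| genome | 20 × 10 Mb | desk-scale stand-in assembly (`chrN`) |
| `n_latent_loci` | 600/lineage | latent genomic loci shared across generations |
| `mark_widths` | DMR 1000, DHR 1000, ncRNA 500 bp | kilobase-scale features |
| `dmr_retention` | 0.35 | fraction of F1 DMR loci re-emitted in F2 and F3 |
| `tri_colocalization` | 0.25 | fraction of loci planting F3 DHR + ncRNA |
| `pair_ncrna_colocalization` | 0.30 | fraction of loci planting an F1 ncRNA |
| `dhr_generations` | (F3,) | DHRs appear only transgenerationally |
| `jitter_bp` | 2000 | per-feature placement noise around the locus |
| `n_solo` | ncRNA 150, DHR 100, DMR 0 | independent stringent loci per set |
| `n_near_miss` / `n_background` | 200 / 300 | weaker features per set |

P-value tiers: planted features draw 10^(−U(6,12)) for DMR/DHR and
10^(−U(4,10)) for ncRNA (always below the stringent cutoffs); near-miss
features draw U(10⁻⁴, 0.05) (relaxed only); background draws U(0.05, 1)
(neither). Two design choices deserve note:

- The tri-mark fraction is assigned per latent locus independently of DMR
  retention; since only retained loci carry an F3 DMR, the expected
  tri-mark fraction *among F3 DMR anchors* equals `tri_colocalization`,
  which is the quantity the recovery tests measure.
- No novel stringent DMR loci are planted beyond the retained F1 loci, so
  the F1→F3 DMR overlap reads out `dmr_retention` directly; novel weak
  signal in later generations is represented by the near-miss and
  background tiers instead.

Jitter makes each mark's feature center miss the locus center by up to
±2 kb, so with kilobase features the planted colocalization is only
partially visible to direct overlap but fully recovered by the 10 kb
window — the contrast the windowed analysis exists to expose. Recovery
tests that need exact placement set `jitter_bp = 0` explicitly. Lineages
receive independent loci (each exposure induces its own sites). The
generator is byte-deterministic under its seed and emits a ground-truth
record (locus positions, retention flags, signatures, feature ids) for
exact recovery checks.

What the generator does **not** emulate: clustered/nonuniform genomic
feature density, chromosome-specific biases, GC/gap structure,
correlated p-values, or realistic per-set feature counts (the defaults
are order-of-magnitude placeholders). Passing tests therefore demonstrate
correctness of the overlap/permutation machinery and recoverability of
planted structure, not agreement with any real exposure dataset.

## Gene association

A site is linked to every overlapping gene (distance 0); otherwise to the
nearest gene within 10 kb — the same scale as the windowed analysis —
with the distance counted as bases between the intervals plus one
(bookended features are at distance 1, bedtools convention). Ties break
toward the leftmost gene. The synthetic gene annotation lays
non-overlapping genes on an evenly spaced grid with random offsets.

## Problem sizes and numerical notes

- Analysis drivers and tests run on the desk-scale genome above; the
  oracle-equivalence tests use up to 500 intervals per side, and the
  permutation calibration uses 200 replicate datasets at n_perm = 199.
  These sizes were chosen so the full pipeline and suite complete in a
  few minutes on one CPU; all of them scale up by configuration only.
- Percentages are reported as NaN (missing) for empty row sets, never 0,
  so absent marks (e.g. F1/F2 DHR) are distinguishable from observed
  non-overlap.
- p-values survive a write/read cycle bit-exactly (`%.17g` on write,
  round-trip float parsing on read).
- Degenerate inputs: empty sets are legal everywhere (empty overlap
  lists, NaN percentages, p = 1 permutation results); a chromosome too
  short for the requested site width is excluded from randomization, and
  an assembly with no host chromosome is an error.

## Known limitations

- The permutation null ignores annotation structure (no GC-, gap- or
  feature-matched randomization).
- Venn component counting depends on the chosen flank: large flanks can
  chain distinct loci into one component.
- The colocalization scan reports one record per anchor; a locus carrying
  several stringent anchors appears once per anchor, not merged.
- sncRNA/lncRNA are pooled before overlap by default; `filter_subtype`
  supports separate analyses, but no joint/union mode beyond pooling.
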