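# epioverlap

Integration analysis of environmentally induced sperm **epimutations**
across generations: differential DNA methylation regions (**DMRs**),
differentially expressed non-coding RNA loci (**ncRNA**, small and large
pooled), and differential histone retention sites (**DHRs**) called in the
sperm of exposure lineages (e.g. vinclozolin, DDT) at generations F1-F3.
The package is for epigenomics researchers who have per-generation,
per-mark candidate tables (chromosome, start, end, p-value) and want to
ask where, and how non-randomly, the different mark types and generations
colocalize on the genome.

## What it computes

All features are unstranded half-open intervals `[start, end)`. Two
features overlap iff they share ≥ 1 bp. The analyses contrast each mark's
**stringent** threshold (DMR and DHR *p* < 10⁻⁶, ncRNA *p* < 10⁻⁴, strict
inequalities) with a single **relaxed** threshold *p* < 0.05:

- **Extended overlap matrix** — rows are the nine stringent sets
  (F1/F2/F3 × DMR/ncRNA/DHR), columns the same sets at *p* < 0.05. Cell
  (i, j) is the number of distinct row-i features overlapping ≥ 1 column-j
  feature, and that count as a percentage of the row set size. Diagonal
  cells are exactly 100% because each stringent set is a subset of its
  relaxed counterpart.
- **10 kb window analysis** — the same matrix after extending every
  feature 5 kb on each side (clipped at chromosome edges), which joins
  near-but-not-touching sites into a 10 kb regional window.
- **Venn partitioning** — 2-3 sets are pooled and clustered by
  single-linkage overlap into connected components; each component is
  counted once under the signature of the sets present in it (features of
  different marks differ in width, so the region, not the feature, is the
  counting unit).
- **Colocalization scan** — every stringent-threshold anchor joined to the
  relaxed features of the *other* marks overlapping it, exported as
  TSV/BED and an ideogram-ready plot table.
- **Permutation tests** — the observed overlap statistic is compared with
  a null in which size-matched fixed-width sites (1 kb or 10 kb) are
  re-placed uniformly on the genome; the empirical p-value is the add-one
  estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)`. A multiway variant
  tests the count of F3 regions carrying all three marks, holding the
  DMRs fixed.
- **Gene association** — each site linked to overlapping genes, else the
  nearest gene within 10 kb.
- **Synthetic catalogs** — a generator plants DMR retention across
  generations, tri-mark colocalization, an F1 ncRNA-DMR pairing, and
  DHRs confined to F3, with three explicit p-value tiers
  (stringent / near-miss / background) and positional jitter, plus a
  ground-truth record for recovery tests.

## Worked example

```bash
python analysis/01_simulate_catalogs.py           # writes results/catalog/
python analysis/02_overlap_matrices.py            # direct + 10 kb matrices
python analysis/03_venn_and_colocalization.py
python analysis/04_permutation_tests.py
python analysis/05_gene_associations.py
```

With the default configuration (seed 0) the vinclozolin matrices print,
among other cells:

```
vinclozolin, flank 0 bp:  F1 DMR row -> F3 DMR column: 15.8%
vinclozolin, flank 5000:  F1 DMR row -> F3 DMR column: 39.3%
```

The generator plants 35% DMR retention with 2 kb positional jitter, so
direct overlap recovers only part of the planted signal (15.8%) while the
10 kb window recovers essentially all of it (39.3% ≈ retention plus
chance overlap) — the direct-versus-windowed contrast the pipeline is
built to expose. The permutation stage prints

```
vinclozolin F1 ncRNA vs F1 DMR (1000 bp sites): observed 62/324, null mean 2.6, p = 0.001
vinclozolin F3 tri-mark components: observed 13, null mean 0.00, p = 0.001
```

observed overlap far above the random-placement null, at the smallest p
attainable with 999 permutations. Equivalent subcommands are available on
the CLI (`epioverlap simulate|filter|overlap-matrix|venn|colocalize|`
`permute|annotate|run-all`).

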