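"""Permutation significance of the observed overlaps.

Two questions per lineage, both against uniform random placement of
size-matched fixed-width sites (1 kb and 10 kb):

* pairwise — do the stringent F1 ncRNA loci overlap the relaxed F1 DMRs
  more than chance?
* multiway — are there more F3 regions carrying all three stringent
  marks (DMR & ncRNA & DHR) than chance, holding the DMRs fixed and
  randomizing the ncRNA and DHR sets?

Empirical p-values use the add-one estimator over 999 permutations, so
the smallest attainable p is 0.001. Results are written as JSON under
``results/``.
"""

import argparse
from pathlib import Path

from epioverlap import (
    ThresholdScheme,
    apply_threshold,
    load_assembly,
    load_catalog,
    multiway_colocalization_test,
    permutation_overlap_test,
)
from epioverlap.report import write_permutation_result


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--catalog-dir", type=Path,
                        default=Path("results") / "catalog")
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-perm", type=int, default=999)
    args = parser.parse_args()

    assembly = load_assembly(args.catalog_dir / "assembly.chrom.sizes")
    catalog = load_catalog(args.catalog_dir)
    args.out.mkdir(parents=True, exist_ok=True)
    scheme = ThresholdScheme()
    for lineage in sorted({s.lineage for s in catalog}):
        by = {
            (s.generation, s.mark): s
            for s in catalog
            if s.lineage == lineage
        }
        fixed = apply_threshold(by[("F1", "DMR")], scheme.relaxed)
        test = apply_threshold(
            by[("F1", "ncRNA")], scheme.stringent_for("ncRNA")
        )
        for site_size in (1000, 10_000):
            res = permutation_overlap_test(
                fixed, test, assembly, site_size_bp=site_size,
                n_perm=args.n_perm, seed=args.seed,
            )
            name = f"{lineage}_F1ncRNA_vs_F1DMR_{site_size // 1000}kb"
            write_permutation_result(res, args.out / f"permutation_{name}.json")
            print(
                f"{lineage} F1 ncRNA vs F1 DMR ({site_size} bp sites): "
                f"observed {res.observed}/{len(test)}, "
                f"null mean {res.null_counts.mean():.1f}, "
                f"p = {res.p_empirical:.3g}"
            )
        res = multiway_colocalization_test(
            catalog, lineage, assembly, site_size_bp=1000,
            n_perm=args.n_perm, seed=args.seed,
        )
        write_permutation_result(
            res, args.out / f"permutation_{lineage}_multiway_F3.json"
        )
        print(
            f"{lineage} F3 tri-mark components: observed {res.observed}, "
            f"null mean {res.null_counts.mean():.2f}, "
            f"p = {res.p_empirical:.3g}"
        )


if __name__ == "__main__":
    main()
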