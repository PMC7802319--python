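"""Gene association of the retained (stringent F3) DMRs.

Generates a synthetic non-overlapping gene annotation on the catalog's
assembly, links each stringent F3 DMR to overlapping genes or to the
nearest gene within 10 kb, and reports the associated fraction. Output:
a TSV of associations per lineage under ``results/``.
"""

import argparse
from pathlib import Path

import numpy as np

from epioverlap import (
    ThresholdScheme,
    apply_threshold,
    associate_genes,
    generate_gene_annotation,
    load_assembly,
    load_catalog,
)
from epioverlap.report import write_gene_associations


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--catalog-dir", type=Path,
                        default=Path("results") / "catalog")
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-genes", type=int, default=2000)
    args = parser.parse_args()

    assembly = load_assembly(args.catalog_dir / "assembly.chrom.sizes")
    catalog = load_catalog(args.catalog_dir)
    args.out.mkdir(parents=True, exist_ok=True)
    genes = generate_gene_annotation(
        assembly, args.n_genes, np.random.default_rng(args.seed)
    )
    genes.to_csv(args.out / "genes.tsv", sep="\t", index=False)
    scheme = ThresholdScheme()
    for lineage in sorted({s.lineage for s in catalog}):
        dmr = next(
            s for s in catalog
            if s.label == (lineage, "F3", "DMR")
        )
        stringent = apply_threshold(dmr, scheme.stringent_for("DMR"))
        associations = associate_genes(
            stringent, genes, max_distance_bp=10_000, assembly=assembly
        )
        path = args.out / f"gene_associations_{lineage}_F3_DMR.tsv"
        write_gene_associations(associations, path)
        associated = len({a.epimutation_id for a in associations})
        print(
            f"{lineage}: {associated}/{len(stringent)} stringent F3 DMRs "
            f"({100 * associated / len(stringent):.0f}%) associated with a "
            f"gene (overlap or within 10 kb) -> {path}"
        )


if __name__ == "__main__":
    main()
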