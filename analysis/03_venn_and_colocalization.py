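"""Venn partitions and cross-mark colocalized sites.

Two Venn partitions per lineage (counting unit = connected overlap
component): the generational DMR overlap (F1/F2/F3 stringent DMRs) and
the F3 tri-mark overlap (stringent DMR/ncRNA/DHR). The colocalization
scan then lists every stringent-threshold anchor overlapped by relaxed
(p < 0.05) features of the other mark types, as a TSV table, a BED track
of anchors, and an ideogram-ready plot table.
"""

import argparse
from pathlib import Path

from epioverlap import (
    ThresholdScheme,
    apply_threshold,
    colocalization_scan,
    load_assembly,
    load_catalog,
    venn_partition,
)
from epioverlap.report import (
    chromosome_plot_table,
    write_colocalized_sites,
    write_venn,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--catalog-dir", type=Path,
                        default=Path("results") / "catalog")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    load_assembly(args.catalog_dir / "assembly.chrom.sizes")
    catalog = load_catalog(args.catalog_dir)
    args.out.mkdir(parents=True, exist_ok=True)
    scheme = ThresholdScheme()
    for lineage in sorted({s.lineage for s in catalog}):
        by = {
            (s.generation, s.mark): s
            for s in catalog
            if s.lineage == lineage
        }
        dmr = [
            apply_threshold(by[(g, "DMR")], scheme.stringent_for("DMR"))
            for g in ("F1", "F2", "F3")
        ]
        gen_venn = venn_partition(dmr, labels=["F1:DMR", "F2:DMR", "F3:DMR"])
        write_venn(gen_venn, args.out / f"venn_{lineage}_generational_DMR.json")
        tri_sets = [
            apply_threshold(by[("F3", m)], scheme.stringent_for(m))
            for m in ("DMR", "ncRNA", "DHR")
        ]
        tri_venn = venn_partition(tri_sets, labels=["DMR", "ncRNA", "DHR"])
        write_venn(tri_venn, args.out / f"venn_{lineage}_F3_trimark.json")
        tri = tri_venn.count("DMR", "ncRNA", "DHR")
        n_dmr = len(tri_sets[0])
        print(
            f"{lineage}: {gen_venn.count('F1:DMR', 'F2:DMR', 'F3:DMR')} "
            f"regions carry stringent DMRs in all three generations; "
            f"{tri} F3 regions carry all three marks "
            f"({100 * tri / n_dmr:.1f}% of {n_dmr} F3 stringent DMRs)"
        )

        sites = colocalization_scan(catalog, lineage)
        prefix = args.out / f"colocalized_{lineage}"
        write_colocalized_sites(sites, f"{prefix}.tsv", f"{prefix}.bed")
        chromosome_plot_table(sites).to_csv(
            f"{prefix}_plot_table.csv", index=False
        )
        print(f"{lineage}: {len(sites)} colocalized sites -> {prefix}.tsv")


if __name__ == "__main__":
    main()
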