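"""Tabular and JSON exports of every analysis product.

Writers emit plain-text formats (CSV/TSV/JSON/BED) that the module's own
readers re-parse without information loss; a run manifest records the
configuration, seed, and package versions for exact re-execution.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .annotate import GeneAssociation, associations_to_frame
from .overlap import ColocalizedSite, OverlapMatrix, VennPartition
from .permutation import PermutationTestResult

SIGNATURE_SEP = "&"


def write_overlap_matrix(
    matrix: OverlapMatrix, path: Union[str, Path]
) -> None:
    """Long-format CSV: one row per matrix cell with count and percent.

    A ``# flank_bp=<n>`` / ``# lineage=<name>`` comment header carries the
    matrix metadata; ``row_size`` repeats the percent denominator.
    """
    rows = []
    for (rg, rm) in matrix.counts.index:
        for (cg, cm) in matrix.counts.columns:
            rows.append(
                (
                    rg,
                    rm,
                    cg,
                    cm,
                    int(matrix.counts.loc[(rg, rm), (cg, cm)]),
                    float(matrix.percents.loc[(rg, rm), (cg, cm)]),
                    int(matrix.row_sizes.loc[(rg, rm)]),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "row_generation",
            "row_mark",
            "col_generation",
            "col_mark",
            "count",
            "percent",
            "row_size",
        ],
    )
    with open(path, "w") as fh:
        fh.write(f"# flank_bp={matrix.flank_bp}\n")
        fh.write(f"# lineage={matrix.lineage}\n")
        df.to_csv(fh, index=False)


def read_overlap_matrix(path: Union[str, Path]) -> OverlapMatrix:
    flank_bp, lineage = 0, ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key == "flank_bp":
                flank_bp = int(value)
            elif key == "lineage":
                lineage = value
    df = pd.read_csv(path, comment="#")
    counts = df.pivot_table(
        index=["row_generation", "row_mark"],
        columns=["col_generation", "col_mark"],
        values="count",
        sort=False,
    )
    percents = df.pivot_table(
        index=["row_generation", "row_mark"],
        columns=["col_generation", "col_mark"],
        values="percent",
        sort=False,
        dropna=False,
    )
    row_sizes = (
        df.drop_duplicates(["row_generation", "row_mark"])
        .set_index(["row_generation", "row_mark"])["row_size"]
    )
    return OverlapMatrix(
        counts=counts.astype(int),
        percents=percents,
        row_sizes=row_sizes,
        flank_bp=flank_bp,
        lineage=lineage,
    )


def _signature_key(sig: frozenset, labels: Sequence[str]) -> str:
    return SIGNATURE_SEP.join(l for l in labels if l in sig)


def write_venn(partition: VennPartition, path: Union[str, Path]) -> None:
    """Venn counts as JSON keyed by '&'-joined signatures in label order."""
    payload = {
        "labels": partition.labels,
        "n_components": partition.n_components,
        "component_counts": {
            _signature_key(sig, partition.labels): n
            for sig, n in sorted(
                partition.counts.items(),
                key=lambda kv: _signature_key(kv[0], partition.labels),
            )
        },
        "feature_counts": {
            _signature_key(sig, partition.labels): n
            for sig, n in sorted(
                partition.feature_counts.items(),
                key=lambda kv: _signature_key(kv[0], partition.labels),
            )
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_venn(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def colocalized_sites_to_frame(
    sites: Sequence[ColocalizedSite],
) -> pd.DataFrame:
    """TSV-ready table: chrom, midpoint, anchor mark/p, partner marks/p,
    genes (semicolon-joined)."""
    rows = []
    for site in sites:
        rows.append(
            (
                site.chrom,
                site.midpoint,
                site.anchor.id,
                site.anchor.mark,
                site.anchor.generation,
                site.anchor.p_value,
                ";".join(p.mark for p in site.partners),
                ";".join(p.id for p in site.partners),
                ";".join(f"{p.p_value:.3g}" for p in site.partners),
                ";".join(site.genes),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "midpoint",
            "anchor_id",
            "anchor_mark",
            "anchor_generation",
            "anchor_p",
            "partner_marks",
            "partner_ids",
            "partner_p",
            "genes",
        ],
    )


def write_colocalized_sites(
    sites: Sequence[ColocalizedSite],
    tsv_path: Union[str, Path],
    bed_path: Optional[Union[str, Path]] = None,
) -> None:
    colocalized_sites_to_frame(sites).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for site in sites:
                iv = site.anchor.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{site.anchor.id}|{'+'.join(sorted(site.marks_present))}\n"
                )


def chromosome_plot_table(
    sites: Sequence[ColocalizedSite],
) -> pd.DataFrame:
    """Ideogram-ready table (chrom, position in Mb, mark, color code) for
    external plotting of per-chromosome colocalization maps."""
    colors = {"DMR": "red", "ncRNA": "blue", "DHR": "green"}
    rows = [
        (
            site.chrom,
            site.midpoint / 1e6,
            site.anchor.mark,
            colors.get(site.anchor.mark, "black"),
        )
        for site in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "position_mb", "mark", "color"])


def write_permutation_result(
    result: PermutationTestResult,
    json_path: Union[str, Path],
    null_csv_path: Optional[Union[str, Path]] = None,
) -> None:
    Path(json_path).write_text(json.dumps(result.summary(), indent=1))
    if null_csv_path is not None:
        pd.DataFrame({"null_count": result.null_counts}).to_csv(
            null_csv_path, index=False
        )


def write_gene_associations(
    associations: list[GeneAssociation], path: Union[str, Path]
) -> None:
    associations_to_frame(associations).to_csv(path, sep="\t", index=False)


def write_manifest(
    out_dir: Union[str, Path],
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> Path:
    manifest = {
        "package": "epioverlap",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config or {},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def export_report(
    out_dir: Union[str, Path],
    matrices: Iterable[OverlapMatrix] = (),
    venns: Optional[dict] = None,
    sites: Optional[dict] = None,
    permutations: Optional[dict] = None,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
) -> list[Path]:
    """Write every computed product under ``out_dir``; idempotent.

    ``venns``/``sites``/``permutations`` map a name (used in the file
    name) to the respective result object. Returns the written paths.
    Empty inputs still produce a manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [write_manifest(out_dir, config=config, seed=seed)]
    for matrix in matrices:
        name = f"overlap_matrix_{matrix.lineage}_flank{matrix.flank_bp}.csv"
        write_overlap_matrix(matrix, out_dir / name)
        written.append(out_dir / name)
    for name, partition in (venns or {}).items():
        path = out_dir / f"venn_{name}.json"
        write_venn(partition, path)
        written.append(path)
    for name, site_list in (sites or {}).items():
        tsv = out_dir / f"colocalized_{name}.tsv"
        bed = out_dir / f"colocalized_{name}.bed"
        write_colocalized_sites(site_list, tsv, bed)
        written.extend([tsv, bed])
    for name, result in (permutations or {}).items():
        path = out_dir / f"permutation_{name}.json"
        write_permutation_result(result, path)
        written.append(path)
    return written
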