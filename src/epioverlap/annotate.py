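"""Gene association of epimutation sites.

An epimutation is linked to every gene it overlaps (distance 0); a site
touching no gene is linked to the nearest gene within a configurable
maximum distance (10 kb by default, the same scale as the windowed
overlap analysis). Distance between non-overlapping half-open intervals
counts the bases separating them plus one, so abutting features are at
distance 1 (bedtools convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import EpimutationSet
from .genome import GenomeAssembly

GENE_TABLE_COLUMNS = ("chrom", "start", "end", "symbol")


@dataclass(frozen=True)
class GeneAssociation:
    epimutation_id: str
    gene: str
    relation: str  # "overlapping" | "within_distance"
    distance_bp: int

    def __post_init__(self) -> None:
        if self.relation == "overlapping" and self.distance_bp != 0:
            raise ValueError("overlapping association must have distance 0")
        if self.relation == "within_distance" and self.distance_bp <= 0:
            raise ValueError("within_distance association needs distance > 0")


def _validate_gene_table(
    genes: pd.DataFrame, assembly: Optional[GenomeAssembly]
) -> pd.DataFrame:
    for col in GENE_TABLE_COLUMNS:
        if col not in genes.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if assembly is not None:
        unknown = set(genes["chrom"]) - set(assembly.names)
        if unknown:
            raise ValueError(
                f"gene table chromosomes not in assembly: {sorted(unknown)}"
            )
    return genes.sort_values(["chrom", "start"], ignore_index=True)


def associate_genes(
    s: EpimutationSet,
    genes: pd.DataFrame,
    max_distance_bp: int = 10_000,
    assembly: Optional[GenomeAssembly] = None,
) -> list[GeneAssociation]:
    """Link each epimutation to overlapping genes, else the nearest gene
    within ``max_distance_bp``; unassociated sites are omitted.

    Ties on nearest distance are broken by gene table order (leftmost
    first). Deterministic.
    """
    genes = _validate_gene_table(genes, assembly)
    out: list[GeneAssociation] = []
    by_chrom = {
        chrom: grp.reset_index(drop=True)
        for chrom, grp in genes.groupby("chrom", sort=False)
    }
    for m in s.members:
        grp = by_chrom.get(m.interval.chrom)
        if grp is None:
            continue
        gstart = grp["start"].to_numpy()
        gend = grp["end"].to_numpy()
        overlap = (gstart < m.interval.end) & (m.interval.start < gend)
        if overlap.any():
            for i in np.flatnonzero(overlap):
                out.append(
                    GeneAssociation(m.id, grp["symbol"].iloc[i], "overlapping", 0)
                )
            continue
        # gap in bp + 1 (abutting => 1); genes strictly left or right
        dist = np.where(
            gend <= m.interval.start,
            m.interval.start - gend + 1,
            np.where(gstart >= m.interval.end, gstart - m.interval.end + 1, 0),
        )
        best = int(np.argmin(dist))
        if 0 < dist[best] <= max_distance_bp:
            out.append(
                GeneAssociation(
                    m.id,
                    grp["symbol"].iloc[best],
                    "within_distance",
                    int(dist[best]),
                )
            )
    return out


def associations_to_frame(
    associations: list[GeneAssociation],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.epimutation_id, a.gene, a.relation, a.distance_bp)
            for a in associations
        ],
        columns=["epimutation_id", "gene", "relation", "distance_bp"],
    )
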