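"""Epimutation records, sets, dual-threshold scheme, and table I/O.

An *epimutation* is an environmentally induced alteration of an epigenetic
mark at a genomic site. Three mark types are analyzed: DMRs (differential
DNA methylated regions), DHRs (differential histone retention sites), and
differentially expressed ncRNA loci (small and large non-coding RNA pooled
by default, with the subtype kept as metadata). Each candidate carries a
raw p-value from the upstream differential analysis; the pipeline contrasts
a *stringent* per-mark cutoff (DMR/DHR p < 1e-06, ncRNA p < 1e-04) with a
single *relaxed* cutoff (p < 0.05). All threshold comparisons are strict.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomicInterval

logger = logging.getLogger(__name__)

MARKS = ("DMR", "ncRNA", "DHR")
GENERATIONS = ("F1", "F2", "F3")

#: Stringent per-mark cutoffs from the upstream differential analyses.
DEFAULT_STRINGENT = {"DMR": 1e-06, "DHR": 1e-06, "ncRNA": 1e-04}
#: Permissive cutoff used for the extended-overlap comparison.
DEFAULT_RELAXED = 0.05


class CatalogError(ValueError):
    """Malformed epimutation table or invalid set construction."""


@dataclass(frozen=True)
class Epimutation:
    """One candidate epimutation site."""

    id: str
    interval: GenomicInterval
    mark: str
    generation: str
    lineage: str
    p_value: float
    subtype: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise CatalogError(
                f"epimutation {self.id!r}: p_value {self.p_value} "
                "outside (0, 1]"
            )
        if self.mark not in MARKS:
            raise CatalogError(
                f"epimutation {self.id!r}: unknown mark {self.mark!r} "
                f"(expected one of {MARKS})"
            )
        if self.generation not in GENERATIONS:
            raise CatalogError(
                f"epimutation {self.id!r}: unknown generation "
                f"{self.generation!r} (expected one of {GENERATIONS})"
            )


def _sort_key(e: Epimutation):
    # deterministic tie-break: (chrom, start, end, id)
    return (e.interval.chrom, e.interval.start, e.interval.end, e.id)


class EpimutationSet:
    """Homogeneous, sorted collection of epimutations.

    All members share one (lineage, generation, mark) label. Members are
    kept as-is (duplicates/overlaps are not merged: counts are
    per-feature) and sorted by (chrom, start, end, id) at construction.
    """

    def __init__(
        self,
        lineage: str,
        generation: str,
        mark: str,
        members: Iterable[Epimutation] = (),
        threshold_applied: Optional[float] = None,
    ):
        members = sorted(members, key=_sort_key)
        for m in members:
            if (m.lineage, m.generation, m.mark) != (lineage, generation, mark):
                raise CatalogError(
                    f"member {m.id!r} labelled "
                    f"({m.lineage}, {m.generation}, {m.mark}) does not match "
                    f"set ({lineage}, {generation}, {mark})"
                )
            if threshold_applied is not None and not (
                m.p_value < threshold_applied
            ):
                raise CatalogError(
                    f"member {m.id!r} p={m.p_value} violates declared "
                    f"threshold {threshold_applied}"
                )
        self.lineage = lineage
        self.generation = generation
        self.mark = mark
        self.members: list[Epimutation] = members
        self.threshold_applied = threshold_applied
        self._by_id = {m.id: m for m in members}

    @property
    def label(self) -> tuple[str, str, str]:
        return (self.lineage, self.generation, self.mark)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, member_id: str) -> Epimutation:
        return self._by_id[member_id]

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    def __repr__(self) -> str:
        thr = (
            f", p<{self.threshold_applied:g}"
            if self.threshold_applied is not None
            else ""
        )
        return (
            f"EpimutationSet({self.lineage} {self.generation} {self.mark}, "
            f"n={len(self)}{thr})"
        )

    def filter_subtype(self, subtype: str) -> "EpimutationSet":
        """Restrict to one ncRNA subtype (e.g. sncRNA or lncRNA)."""
        return EpimutationSet(
            self.lineage,
            self.generation,
            self.mark,
            [m for m in self.members if m.subtype == subtype],
            self.threshold_applied,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per member, BED-like column order)."""
        return pd.DataFrame(
            {
                "chrom": [m.interval.chrom for m in self.members],
                "start": [m.interval.start for m in self.members],
                "end": [m.interval.end for m in self.members],
                "id": [m.id for m in self.members],
                "p_value": [m.p_value for m in self.members],
                "subtype": [m.subtype or "" for m in self.members],
                "gene": [m.gene or "" for m in self.members],
            }
        )


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-mark stringent cutoffs plus one relaxed cutoff (strict '<')."""

    stringent: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRINGENT)
    )
    relaxed: float = DEFAULT_RELAXED

    def __post_init__(self) -> None:
        if not (0 < self.relaxed <= 1):
            raise CatalogError(f"relaxed cutoff {self.relaxed} outside (0, 1]")
        for mark, cutoff in self.stringent.items():
            if not (0 < cutoff <= self.relaxed):
                raise CatalogError(
                    f"stringent cutoff for {mark} ({cutoff}) must lie in "
                    f"(0, relaxed={self.relaxed}]"
                )

    def stringent_for(self, mark: str) -> float:
        try:
            return self.stringent[mark]
        except KeyError:
            raise CatalogError(f"no stringent cutoff for mark {mark!r}") from None


def apply_threshold(s: EpimutationSet, p_max: float) -> EpimutationSet:
    """Keep members with ``p_value < p_max`` (strict). Input unmodified.

    Monotone in ``p_max`` and idempotent at a fixed cutoff.
    """
    if not (0 < p_max <= 1):
        raise CatalogError(f"p_max {p_max} outside (0, 1]")
    return EpimutationSet(
        s.lineage,
        s.generation,
        s.mark,
        [m for m in s.members if m.p_value < p_max],
        threshold_applied=p_max,
    )


def select_sets(
    catalog: Iterable[EpimutationSet],
    lineage: str,
    scheme: Optional[ThresholdScheme] = None,
) -> tuple[list[EpimutationSet], list[EpimutationSet]]:
    """Split a lineage's catalog into stringent and relaxed threshold sets.

    Returns paired lists ordered (F1, F2, F3) x (DMR, ncRNA, DHR): the
    stringent sets (per-mark cutoff; matrix rows) and the relaxed sets
    (single p < 0.05 cutoff; matrix columns). Missing (generation, mark)
    combinations are skipped with a warning. Because every stringent
    cutoff <= relaxed, each stringent set is a subset of its relaxed
    counterpart.
    """
    scheme = scheme or ThresholdScheme()
    catalog = [s for s in catalog if s.lineage == lineage]
    if not catalog:
        raise CatalogError(f"no epimutation sets for lineage {lineage!r}")
    by_label = {(s.generation, s.mark): s for s in catalog}
    stringent_sets: list[EpimutationSet] = []
    relaxed_sets: list[EpimutationSet] = []
    for generation in GENERATIONS:
        for mark in MARKS:
            s = by_label.get((generation, mark))
            if s is None:
                logger.warning(
                    "lineage %s: no %s %s set in catalog; skipping",
                    lineage,
                    generation,
                    mark,
                )
                continue
            stringent_sets.append(
                apply_threshold(s, scheme.stringent_for(mark))
            )
            relaxed_sets.append(apply_threshold(s, scheme.relaxed))
    return stringent_sets, relaxed_sets


# ---------------------------------------------------------------------------
# Table I/O

#: Canonical TSV column order (mirrors the supplementary-table layout:
#: location, p-value, gene association).
TSV_COLUMNS = ("chrom", "start", "end", "id", "p_value", "subtype", "gene")


def read_epimutation_table(
    path: Union[str, Path],
    mark: str,
    generation: str,
    lineage: str,
    format: str = "tsv",
    column_map: Optional[Mapping[str, str]] = None,
    one_based: bool = False,
) -> EpimutationSet:
    """Read one (lineage, generation, mark) table into an EpimutationSet.

    Parameters
    ----------
    format
        ``"tsv"``: tab-delimited with a header row; columns chrom, start,
        end, p_value resolved through ``column_map`` (optional id,
        subtype, gene). ``"bed"``: header-less BED whose columns are
        chrom, start, end, name, p_value.
    column_map
        Maps canonical names to file column names, e.g.
        ``{"p_value": "pval"}``.
    one_based
        Set for 1-based inclusive start coordinates in a TSV; they are
        converted to 0-based half-open at this boundary.
    """
    path = Path(path)
    if format == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "id", "p_value"],
            usecols=range(5),
            dtype={"chrom": str},
            float_precision="round_trip",
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str},
                         float_precision="round_trip")
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
    else:
        raise CatalogError(f"unknown table format {format!r}")

    for col in ("chrom", "start", "end", "p_value"):
        if col not in df.columns:
            raise CatalogError(f"{path}: missing required column {col!r}")

    members = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 1
        try:
            start = int(row.start) - (1 if one_based else 0)
            end = int(row.end)
            p_value = float(row.p_value)
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"{path}: row {rownum}: {exc}") from None
        member_id = (
            str(row.id)
            if hasattr(row, "id")
            else f"{mark}_{generation}_{lineage}_{rownum}"
        )
        subtype = getattr(row, "subtype", None)
        gene = getattr(row, "gene", None)
        subtype = None if pd.isna(subtype) or subtype == "" else str(subtype)
        gene = None if pd.isna(gene) or gene == "" else str(gene)
        try:
            members.append(
                Epimutation(
                    id=member_id,
                    interval=GenomicInterval(str(row.chrom), start, end),
                    mark=mark,
                    generation=generation,
                    lineage=lineage,
                    p_value=p_value,
                    subtype=subtype,
                    gene=gene,
                )
            )
        except (ValueError, CatalogError) as exc:
            raise CatalogError(f"{path}: row {rownum}: {exc}") from None
    return EpimutationSet(lineage, generation, mark, members)


def write_epimutation_table(
    s: EpimutationSet, path: Union[str, Path], format: str = "tsv"
) -> None:
    """Write a set as TSV (canonical columns) or 5-column BED."""
    df = s.to_frame()
    # %.17g keeps p-values bit-exact through a write/read cycle
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, columns=list(TSV_COLUMNS),
                  float_format="%.17g")
    elif format == "bed":
        df.to_csv(
            path,
            sep="\t",
            index=False,
            header=False,
            columns=["chrom", "start", "end", "id", "p_value"],
            float_format="%.17g",
        )
    else:
        raise CatalogError(f"unknown table format {format!r}")


def catalog_filename(lineage: str, generation: str, mark: str) -> str:
    return f"{lineage}_{generation}_{mark}.tsv"


def write_catalog(
    catalog: Sequence[EpimutationSet], directory: Union[str, Path]
) -> list[Path]:
    """Write every set of a catalog as one TSV per (lineage, gen, mark)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in catalog:
        path = directory / catalog_filename(*s.label)
        write_epimutation_table(s, path)
        paths.append(path)
    return paths


def load_catalog(directory: Union[str, Path]) -> list[EpimutationSet]:
    """Load every ``{lineage}_{generation}_{mark}.tsv`` in a directory."""
    directory = Path(directory)
    sets = []
    for path in sorted(directory.glob("*.tsv")):
        parts = path.stem.rsplit("_", 2)
        if len(parts) != 3:
            continue
        lineage, generation, mark = parts
        if generation not in GENERATIONS or mark not in MARKS:
            continue
        sets.append(
            read_epimutation_table(
                path, mark=mark, generation=generation, lineage=lineage
            )
        )
    if not sets:
        raise CatalogError(f"no catalog tables found in {directory}")
    return sets
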