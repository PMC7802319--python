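"""Interval-overlap engine.

Implements every overlap computation of the pipeline:

* pairwise overlap detection by a sorted sweep (O((n+m) log(n+m) + k));
* symmetric window extension (the "10 kb window" analysis extends every
  feature by 5 kb on each side, clipped at chromosome edges);
* the extended overlap matrix: rows are the stringent-threshold sets,
  columns the relaxed p < 0.05 sets, each cell the number and percentage
  of distinct row features overlapping >= 1 column feature;
* Venn partitioning of 2-3 sets into connected components of the overlap
  graph (features of different marks differ in width, so the counting
  unit is the component, i.e. a genomic region);
* colocalization scans: stringent-threshold anchors joined to relaxed
  partners of the other mark types at the same genomic location.

Overlap means >= 1 shared bp under half-open arithmetic; abutting
intervals do not overlap. The overlap *relation* is symmetric, but matrix
counts/percentages are not: the denominator is always the row set size.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, clip_span
from .catalog import (
    Epimutation,
    EpimutationSet,
    ThresholdScheme,
    select_sets,
)


@dataclass(frozen=True)
class OverlapPair:
    """One overlapping (row member, column member) pair."""

    row_member_id: str
    col_member_id: str
    shared_bp: int


def find_overlaps(
    a: EpimutationSet, b: EpimutationSet
) -> list[OverlapPair]:
    """All pairs (member of a, member of b) sharing >= 1 bp.

    Sorted sweep per chromosome: intervals of both sets are processed in
    start order while min-heaps keyed by end coordinate hold the still
    "active" intervals of each side; every interval entering the sweep is
    paired with the opposite side's active intervals. Empty inputs yield
    an empty list.
    """
    pairs: list[OverlapPair] = []
    events = sorted(
        itertools.chain(
            ((m.interval, 0, m.id) for m in a.members),
            ((m.interval, 1, m.id) for m in b.members),
        ),
        key=lambda t: (t[0].chrom, t[0].start, t[1], t[0].end, t[2]),
    )
    # one pass; heaps reset at chromosome boundaries
    active: tuple[list, list] = ([], [])  # (end, start, id) per side
    current_chrom: Optional[str] = None
    for iv, side, member_id in events:
        if iv.chrom != current_chrom:
            active = ([], [])
            current_chrom = iv.chrom
        for heap in active:
            while heap and heap[0][0] <= iv.start:
                heapq.heappop(heap)
        for other_end, other_start, other_id in active[1 - side]:
            shared = min(iv.end, other_end) - max(iv.start, other_start)
            if shared > 0:
                row_id, col_id = (
                    (member_id, other_id) if side == 0 else (other_id, member_id)
                )
                pairs.append(OverlapPair(row_id, col_id, shared))
        heapq.heappush(active[side], (iv.end, iv.start, member_id))
    pairs.sort(key=lambda p: (p.row_member_id, p.col_member_id))
    return pairs


def overlap_count_percent(
    a: EpimutationSet, b: EpimutationSet
) -> tuple[int, float]:
    """(count, percent) of distinct members of ``a`` overlapping ``b``.

    percent = 100 * count / |a|; NaN when ``a`` is empty.
    """
    if len(a) == 0:
        return 0, float("nan")
    count = _count_hits(a, b)
    return count, 100.0 * count / len(a)


def _merged_intervals(s: EpimutationSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (union) intervals as sorted start/end arrays."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, members in itertools.groupby(
        s.members, key=lambda m: m.interval.chrom
    ):
        starts: list[int] = []
        ends: list[int] = []
        for m in members:  # already sorted by start
            if starts and m.interval.start < ends[-1]:
                ends[-1] = max(ends[-1], m.interval.end)
            else:
                starts.append(m.interval.start)
                ends.append(m.interval.end)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def _count_hits(a: EpimutationSet, b: EpimutationSet) -> int:
    """Number of distinct members of ``a`` overlapping the union of ``b``.

    Vectorized against the merged intervals of ``b`` (binary search per
    chromosome); equivalent to counting distinct row ids in
    :func:`find_overlaps` but O((n+m) log m) with small constants, which
    the permutation test relies on.
    """
    merged = _merged_intervals(b)
    count = 0
    for chrom, members in itertools.groupby(
        a.members, key=lambda m: m.interval.chrom
    ):
        if chrom not in merged:
            continue
        mstarts, mends = merged[chrom]
        group = list(members)
        starts = np.fromiter(
            (m.interval.start for m in group), dtype=np.int64, count=len(group)
        )
        ends = np.fromiter(
            (m.interval.end for m in group), dtype=np.int64, count=len(group)
        )
        # first merged interval with end > start; hit iff it begins before our end
        idx = np.searchsorted(mends, starts, side="right")
        hit = (idx < len(mstarts)) & (mstarts[np.minimum(idx, len(mstarts) - 1)] < ends)
        count += int(hit.sum())
    return count


def extend_window(
    s: EpimutationSet, flank_bp: int, assembly: GenomeAssembly
) -> EpimutationSet:
    """Extend every feature by ``flank_bp`` on each side, clipped to its
    chromosome. Ids, p-values and metadata are preserved; flank 0 returns
    the set unchanged.
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    if flank_bp == 0:
        return s
    members = []
    for m in s.members:
        iv = clip_span(
            m.interval.chrom,
            m.interval.start - flank_bp,
            m.interval.end + flank_bp,
            assembly,
        )
        members.append(
            Epimutation(
                id=m.id,
                interval=iv,
                mark=m.mark,
                generation=m.generation,
                lineage=m.lineage,
                p_value=m.p_value,
                subtype=m.subtype,
                gene=m.gene,
            )
        )
    return EpimutationSet(
        s.lineage, s.generation, s.mark, members, s.threshold_applied
    )


# ---------------------------------------------------------------------------
# Extended overlap matrix


@dataclass
class OverlapMatrix:
    """Counts and percentages of stringent rows overlapping relaxed columns.

    ``counts.loc[(gen, mark), (gen', mark')]`` is the number of distinct
    (gen, mark) stringent features overlapping >= 1 (gen', mark') relaxed
    feature; ``percents`` divides by the row set size (x100). The diagonal
    cell pairing a non-empty set with its own relaxed superset is exactly
    100%. ``row_sizes`` holds the stringent set sizes (the denominators).
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    row_sizes: pd.Series
    flank_bp: int
    lineage: str = ""

    def cell(self, row: tuple[str, str], col: tuple[str, str]) -> tuple[int, float]:
        return int(self.counts.loc[row, col]), float(self.percents.loc[row, col])


def extended_overlap_matrix(
    catalog: Iterable[EpimutationSet],
    lineage: str,
    scheme: Optional[ThresholdScheme] = None,
    flank_bp: int = 0,
    assembly: Optional[GenomeAssembly] = None,
    extend_rows_only: bool = False,
) -> OverlapMatrix:
    """Build the stringent-vs-relaxed overlap matrix for one lineage.

    With ``flank_bp > 0`` both row and column features are extended
    symmetrically before overlap (``extend_rows_only`` restricts the
    extension to the row sets). ``assembly`` is required when a flank is
    used (for clipping at chromosome edges).
    """
    if flank_bp > 0 and assembly is None:
        raise ValueError("an assembly is required when flank_bp > 0")
    stringent_sets, relaxed_sets = select_sets(catalog, lineage, scheme)
    if flank_bp > 0:
        assert assembly is not None
        rows = [extend_window(s, flank_bp, assembly) for s in stringent_sets]
        cols = (
            relaxed_sets
            if extend_rows_only
            else [extend_window(s, flank_bp, assembly) for s in relaxed_sets]
        )
    else:
        rows, cols = stringent_sets, relaxed_sets

    row_index = pd.MultiIndex.from_tuples(
        [(s.generation, s.mark) for s in rows], names=["generation", "mark"]
    )
    col_index = pd.MultiIndex.from_tuples(
        [(s.generation, s.mark) for s in cols], names=["generation", "mark"]
    )
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    percents = np.full((len(rows), len(cols)), np.nan)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            counts[i, j], percents[i, j] = overlap_count_percent(r, c)
    return OverlapMatrix(
        counts=pd.DataFrame(counts, index=row_index, columns=col_index),
        percents=pd.DataFrame(percents, index=row_index, columns=col_index),
        row_sizes=pd.Series([len(r) for r in rows], index=row_index),
        flank_bp=flank_bp,
        lineage=lineage,
    )


# ---------------------------------------------------------------------------
# Venn partitioning


@dataclass
class VennPartition:
    """Connected-component partition of 2-3 sets' features.

    ``counts`` maps a membership signature (frozenset of set labels) to
    the number of components whose features come from exactly those sets;
    signature counts sum to ``n_components``. ``feature_counts`` is the
    alternative per-feature counting mode: for each signature, the number
    of *features* lying in components with that signature.
    """

    labels: list[str]
    counts: dict[frozenset, int]
    feature_counts: dict[frozenset, int]
    components: list[list[tuple[str, str]]] = field(repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def count(self, *labels: str) -> int:
        return self.counts.get(frozenset(labels), 0)


def venn_partition(
    sets: Sequence[EpimutationSet],
    flank_bp: int = 0,
    assembly: Optional[GenomeAssembly] = None,
    labels: Optional[Sequence[str]] = None,
) -> VennPartition:
    """Partition the union of 2-3 sets into overlap components.

    Features are optionally extended by ``flank_bp``, pooled, and
    clustered by single-linkage overlap (a linear scan in start order per
    chromosome: a new component starts whenever a feature begins at or
    after the running maximum end). Each component is counted once under
    the signature of the sets contributing >= 1 feature to it.
    """
    if not (2 <= len(sets) <= 3):
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    if labels is None:
        labels = [f"{s.generation} {s.mark}" for s in sets]
    if len(set(labels)) != len(sets):
        raise ValueError(f"set labels must be distinct, got {labels!r}")
    if flank_bp > 0:
        if assembly is None:
            raise ValueError("an assembly is required when flank_bp > 0")
        sets = [extend_window(s, flank_bp, assembly) for s in sets]

    pooled = sorted(
        (
            (m.interval, label, m.id)
            for label, s in zip(labels, sets)
            for m in s.members
        ),
        key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1], t[2]),
    )
    components: list[list[tuple[str, str]]] = []
    chrom, max_end = None, -1
    for iv, label, member_id in pooled:
        if iv.chrom != chrom or iv.start >= max_end:
            components.append([])
            chrom, max_end = iv.chrom, iv.end
        else:
            max_end = max(max_end, iv.end)
        components[-1].append((label, member_id))

    counts: dict[frozenset, int] = {}
    feature_counts: dict[frozenset, int] = {}
    for comp in components:
        sig = frozenset(label for label, _ in comp)
        counts[sig] = counts.get(sig, 0) + 1
        feature_counts[sig] = feature_counts.get(sig, 0) + len(comp)
    return VennPartition(
        labels=list(labels),
        counts=counts,
        feature_counts=feature_counts,
        components=components,
    )


# ---------------------------------------------------------------------------
# Colocalization scan


@dataclass
class ColocalizedSite:
    """A stringent-threshold anchor plus the relaxed features of other
    marks overlapping it (directly or within the declared window)."""

    anchor: Epimutation
    partners: list[Epimutation]
    chrom: str
    midpoint: int

    @property
    def marks_present(self) -> frozenset:
        return frozenset({self.anchor.mark, *(p.mark for p in self.partners)})

    @property
    def genes(self) -> list[str]:
        seen = []
        for e in (self.anchor, *self.partners):
            if e.gene and e.gene not in seen:
                seen.append(e.gene)
        return seen


def colocalization_scan(
    catalog: Iterable[EpimutationSet],
    lineage: str,
    scheme: Optional[ThresholdScheme] = None,
    flank_bp: int = 0,
    assembly: Optional[GenomeAssembly] = None,
) -> list[ColocalizedSite]:
    """Find every stringent epimutation overlapped by relaxed epimutations
    of the OTHER mark types.

    Anchors with no cross-mark partner are dropped. Output is sorted by
    (chrom, anchor midpoint). Midpoints refer to the unextended anchor.
    """
    stringent_sets, relaxed_sets = select_sets(catalog, lineage, scheme)
    relaxed_by_label = {(s.generation, s.mark): s for s in relaxed_sets}
    if flank_bp > 0:
        if assembly is None:
            raise ValueError("an assembly is required when flank_bp > 0")
        relaxed_by_label = {
            k: extend_window(s, flank_bp, assembly)
            for k, s in relaxed_by_label.items()
        }

    sites: list[ColocalizedSite] = []
    for anchor_set in stringent_sets:
        anchors = (
            extend_window(anchor_set, flank_bp, assembly)
            if flank_bp > 0 and assembly is not None
            else anchor_set
        )
        partner_lists: dict[str, list[Epimutation]] = {
            m.id: [] for m in anchors.members
        }
        for (gen, mark), rel in relaxed_by_label.items():
            if mark == anchor_set.mark:
                continue
            for pair in find_overlaps(anchors, rel):
                partner_lists[pair.row_member_id].append(rel[pair.col_member_id])
        for original in anchor_set.members:
            partners = partner_lists[original.id]
            if partners:
                partners.sort(
                    key=lambda p: (p.mark, p.interval.start, p.id)
                )
                sites.append(
                    ColocalizedSite(
                        anchor=original,
                        partners=partners,
                        chrom=original.interval.chrom,
                        midpoint=original.interval.midpoint,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.midpoint, s.anchor.id))
    return sites
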