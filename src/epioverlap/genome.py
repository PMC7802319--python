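"""Coordinate system primitives: genome assemblies and genomic intervals.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package; BED I/O uses the same convention natively. Strand is ignored
everywhere: epimutations are treated as unstranded genomic sites.
Chromosome names are matched by exact string equality (no implicit
``chr``-prefix normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union


class AssemblyError(ValueError):
    """Malformed chromosome-sizes input or unknown chromosome lookup."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open arithmetic).

        Abutting intervals ([0,10) vs [10,20)) do NOT overlap.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shared_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeAssembly:
    """Ordered set of named chromosomes with lengths.

    Defines the coordinate universe for every interval operation
    (clipping, window extension, random site placement).
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chromosomes = list(chromosomes)
        names = [name for name, _ in chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AssemblyError(f"duplicate chromosome name(s): {dupes}")
        for name, length in chromosomes:
            if not name:
                raise AssemblyError("empty chromosome name")
            if length <= 0:
                raise AssemblyError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
        self._chromosomes: list[tuple[str, int]] = [
            (str(n), int(length)) for n, length in chromosomes
        ]
        self._lengths = dict(self._chromosomes)
        self._order = {name: i for i, (name, _) in enumerate(self._chromosomes)}

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return list(self._chromosomes)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self._chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self._chromosomes)

    def __len__(self) -> int:
        return len(self._chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAssembly):
            return NotImplemented
        return self._chromosomes == other._chromosomes

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise AssemblyError(f"unknown chromosome {chrom!r}") from None

    def index_of(self, chrom: str) -> int:
        """Position of a chromosome in assembly order (for sorting)."""
        try:
            return self._order[chrom]
        except KeyError:
            raise AssemblyError(f"unknown chromosome {chrom!r}") from None

    def __repr__(self) -> str:
        return (
            f"GenomeAssembly({len(self)} chromosomes, "
            f"{self.total_bp:,} bp)"
        )


def load_assembly(path: Union[str, Path]) -> GenomeAssembly:
    """Read a UCSC-style two-column chrom.sizes file.

    Lines are whitespace-delimited ``name length`` pairs; blank lines and
    ``#`` comments are skipped. File order is preserved.
    """
    chromosomes: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise AssemblyError(
                    f"{path}:{lineno}: expected 'name length', got {line!r}"
                )
            name, length_str = fields
            try:
                length = int(length_str)
            except ValueError:
                raise AssemblyError(
                    f"{path}:{lineno}: non-integer length {length_str!r}"
                ) from None
            if length <= 0:
                raise AssemblyError(
                    f"{path}:{lineno}: non-positive length for {name!r}"
                )
            chromosomes.append((name, length))
    try:
        return GenomeAssembly(chromosomes)
    except AssemblyError as exc:
        raise AssemblyError(f"{path}: {exc}") from None


def write_assembly(assembly: GenomeAssembly, path: Union[str, Path]) -> None:
    """Write a chrom.sizes file (inverse of :func:`load_assembly`)."""
    with open(path, "w") as fh:
        for name, length in assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")


def clip_span(
    chrom: str, start: int, end: int, assembly: GenomeAssembly
) -> GenomicInterval:
    """Clip raw coordinates (start may be negative, e.g. after flank
    extension near an origin) to ``[0, chromosome length)``.

    Raises ``AssemblyError`` for an unknown chromosome or a span entirely
    outside the chromosome.
    """
    chrom_len = assembly.length_of(chrom)
    clipped_start = max(0, start)
    clipped_end = min(end, chrom_len)
    if clipped_start >= clipped_end:
        raise AssemblyError(
            f"interval [{start}, {end}) lies entirely outside "
            f"{chrom!r} (length {chrom_len})"
        )
    return GenomicInterval(chrom, clipped_start, clipped_end)


def clip_interval(
    iv: GenomicInterval, assembly: GenomeAssembly
) -> GenomicInterval:
    """Clip an interval to ``[0, chromosome length)``.

    Interior intervals are returned unchanged (same object). Clipping is
    idempotent and never increases interval length.
    """
    clipped = clip_span(iv.chrom, iv.start, iv.end, assembly)
    if clipped.start == iv.start and clipped.end == iv.end:
        return iv
    return clipped
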