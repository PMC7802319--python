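"""Permutation significance of observed overlaps against random placement.

The null model re-places size-matched fixed-width sites (1 kb or 10 kb by
convention) uniformly over the genome: a chromosome is chosen with
probability proportional to the number of valid start positions
(length - site_size + 1), and the start is uniform within that range.
Random sites may overlap each other; per-chromosome counts of the
observed set are not preserved (a width-preserving shuffle and a
per-chromosome-preserving mode are available as options).

Empirical p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_perm)``, which can never be zero
and is conservative under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .catalog import EpimutationSet, ThresholdScheme, select_sets
from .genome import GenomeAssembly, GenomicInterval
from .overlap import _count_hits, extend_window, venn_partition


@dataclass
class PermutationTestResult:
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    n_perm: int
    site_size_bp: int
    seed: int

    def summary(self) -> dict:
        """JSON-ready summary (null quantiles instead of the full draw)."""
        q = np.quantile(self.null_counts, [0.0, 0.25, 0.5, 0.75, 0.95, 1.0])
        return {
            "observed": int(self.observed),
            "p_empirical": float(self.p_empirical),
            "n_perm": int(self.n_perm),
            "site_size_bp": int(self.site_size_bp),
            "seed": int(self.seed),
            "null_mean": float(np.mean(self.null_counts)),
            "null_quantiles": {
                "min": float(q[0]),
                "q25": float(q[1]),
                "median": float(q[2]),
                "q75": float(q[3]),
                "q95": float(q[4]),
                "max": float(q[5]),
            },
        }


def _empirical_p(observed: int, null_counts: np.ndarray) -> float:
    return (1 + int(np.sum(null_counts >= observed))) / (1 + len(null_counts))


def randomize_sites(
    n: int,
    site_size_bp: int,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    lineage: str = "null",
    generation: str = "F1",
    mark: str = "DMR",
) -> EpimutationSet:
    """Place ``n`` sites of exactly ``site_size_bp`` uniformly on the genome.

    Chromosomes shorter than the site size are excluded (with a warning
    via ValueError when none remains). Sites may overlap one another.
    The returned set carries placeholder labels and p-value 0.5 (the
    label plays no role in overlap counting).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if site_size_bp < 1:
        raise ValueError(f"site_size_bp must be >= 1, got {site_size_bp}")
    hosts = [
        (name, length)
        for name, length in assembly.chromosomes
        if length >= site_size_bp
    ]
    if not hosts:
        raise ValueError(
            f"no chromosome can host a {site_size_bp} bp site"
        )
    if n == 0:
        return EpimutationSet(lineage, generation, mark, [])
    weights = np.array(
        [length - site_size_bp + 1 for _, length in hosts], dtype=float
    )
    chrom_idx = rng.choice(len(hosts), size=n, p=weights / weights.sum())
    starts = rng.integers(0, weights.astype(np.int64)[chrom_idx])
    from .catalog import Epimutation  # local import avoids cycle at module load

    members = [
        Epimutation(
            id=f"rand_{i}",
            interval=GenomicInterval(
                hosts[ci][0], int(s), int(s) + site_size_bp
            ),
            mark=mark,
            generation=generation,
            lineage=lineage,
            p_value=0.5,
        )
        for i, (ci, s) in enumerate(zip(chrom_idx, starts))
    ]
    return EpimutationSet(lineage, generation, mark, members)


def shuffle_sites(
    s: EpimutationSet,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    preserve_chromosome: bool = False,
) -> EpimutationSet:
    """Width-preserving randomization option: re-place each observed
    feature at a uniform position, keeping its width (and optionally its
    chromosome)."""
    from .catalog import Epimutation

    members = []
    chroms = assembly.chromosomes
    for i, m in enumerate(s.members):
        width = m.interval.length
        if preserve_chromosome:
            name = m.interval.chrom
            length = assembly.length_of(name)
            if length < width:
                raise ValueError(
                    f"feature {m.id!r} wider than its chromosome"
                )
        else:
            hosts = [(n_, l_) for n_, l_ in chroms if l_ >= width]
            if not hosts:
                raise ValueError(f"no chromosome can host a {width} bp site")
            w = np.array([l_ - width + 1 for _, l_ in hosts], dtype=float)
            name, length = hosts[rng.choice(len(hosts), p=w / w.sum())]
        start = int(rng.integers(0, length - width + 1))
        members.append(
            Epimutation(
                id=m.id,
                interval=GenomicInterval(name, start, start + width),
                mark=m.mark,
                generation=m.generation,
                lineage=m.lineage,
                p_value=m.p_value,
                subtype=m.subtype,
            )
        )
    return EpimutationSet(s.lineage, s.generation, s.mark, members)


def _null_hit_counts(
    fixed: EpimutationSet,
    n_test: int,
    site_size_bp: int,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    n_perm: int,
) -> np.ndarray:
    """Vectorized null loop: overlap counts of ``n_perm`` uniform
    placements of ``n_test`` fixed-width sites against ``fixed``.

    Follows the same placement law as :func:`randomize_sites`
    (chromosome ~ valid start positions, start uniform) without
    materializing per-site records.
    """
    from .overlap import _merged_intervals

    hosts = [
        (name, length)
        for name, length in assembly.chromosomes
        if length >= site_size_bp
    ]
    if not hosts:
        raise ValueError(f"no chromosome can host a {site_size_bp} bp site")
    valid = np.array([l - site_size_bp + 1 for _, l in hosts], dtype=np.int64)
    probs = valid / valid.sum()
    merged = _merged_intervals(fixed)
    merged_by_idx = [
        merged.get(name, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
        for name, _ in hosts
    ]
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        if n_test == 0:
            counts[i] = 0
            continue
        chrom_idx = rng.choice(len(hosts), size=n_test, p=probs)
        starts = rng.integers(0, valid[chrom_idx])
        total = 0
        for ci in np.unique(chrom_idx):
            mstarts, mends = merged_by_idx[ci]
            if len(mstarts) == 0:
                continue
            s = starts[chrom_idx == ci]
            idx = np.searchsorted(mends, s, side="right")
            hit = (idx < len(mstarts)) & (
                mstarts[np.minimum(idx, len(mstarts) - 1)] < s + site_size_bp
            )
            total += int(hit.sum())
        counts[i] = total
    return counts


def permutation_overlap_test(
    fixed: EpimutationSet,
    test: EpimutationSet,
    assembly: GenomeAssembly,
    site_size_bp: int = 1000,
    n_perm: int = 999,
    seed: int = 0,
    flank_bp: int = 0,
    width_preserving: bool = False,
) -> PermutationTestResult:
    """Is the overlap of ``test`` with ``fixed`` greater than random?

    The statistic is the number of ``test`` members overlapping >= 1
    ``fixed`` feature. ``fixed`` is extended once by ``flank_bp`` before
    both the observed and null computations; ``test`` conditions only
    through its size. Each permutation replaces ``test`` with
    ``randomize_sites(|test|, site_size_bp, ...)`` (or a width-preserving
    shuffle when requested) and recomputes the statistic. Identical
    (inputs, seed, n_perm) give bit-identical results.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if flank_bp > 0:
        fixed = extend_window(fixed, flank_bp, assembly)
    observed = _count_hits(test, fixed)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    if width_preserving:
        for i in range(n_perm):
            rand = shuffle_sites(test, assembly, rng)
            null_counts[i] = _count_hits(rand, fixed)
    else:
        null_counts = _null_hit_counts(
            fixed, len(test), site_size_bp, assembly, rng, n_perm
        )
    return PermutationTestResult(
        observed=observed,
        null_counts=null_counts,
        p_empirical=_empirical_p(observed, null_counts),
        n_perm=n_perm,
        site_size_bp=site_size_bp,
        seed=seed,
    )


def multiway_colocalization_test(
    catalog: Iterable[EpimutationSet],
    lineage: str,
    assembly: GenomeAssembly,
    scheme: Optional[ThresholdScheme] = None,
    site_size_bp: int = 1000,
    n_perm: int = 999,
    seed: int = 0,
    generation: str = "F3",
) -> PermutationTestResult:
    """Significance of tri-mark (DMR & ncRNA & DHR) colocalization.

    The statistic is the number of overlap components containing all
    three stringent mark sets of one generation (F3 by default, where
    DHRs exist). The DMR set is held fixed; each permutation replaces the
    ncRNA and DHR sets with size-matched random sites and recomputes the
    triple-signature component count.
    """
    stringent_sets, _ = select_sets(catalog, lineage, scheme)
    by_label = {(s.generation, s.mark): s for s in stringent_sets}
    try:
        dmr = by_label[(generation, "DMR")]
        ncrna = by_label[(generation, "ncRNA")]
        dhr = by_label[(generation, "DHR")]
    except KeyError as exc:
        raise ValueError(
            f"missing stringent set for lineage {lineage!r}, "
            f"generation {generation!r}: {exc}"
        ) from None

    labels = ("DMR", "ncRNA", "DHR")
    triple = frozenset(labels)

    def triple_count(nc: EpimutationSet, dh: EpimutationSet) -> int:
        part = venn_partition([dmr, nc, dh], labels=labels)
        return part.counts.get(triple, 0)

    observed = triple_count(ncrna, dhr)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        rand_nc = randomize_sites(
            len(ncrna), site_size_bp, assembly, rng,
            generation=generation, mark="ncRNA",
        )
        rand_dh = randomize_sites(
            len(dhr), site_size_bp, assembly, rng,
            generation=generation, mark="DHR",
        )
        null_counts[i] = triple_count(rand_nc, rand_dh)
    return PermutationTestResult(
        observed=observed,
        null_counts=null_counts,
        p_empirical=_empirical_p(observed, null_counts),
        n_perm=n_perm,
        site_size_bp=site_size_bp,
        seed=seed,
    )
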