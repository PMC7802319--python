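import pytest

from epioverlap import (
    Epimutation,
    EpimutationSet,
    GenomeAssembly,
    GenomicInterval,
    SyntheticConfig,
    generate_catalog,
)


def make_set(
    intervals,
    lineage="vinclozolin",
    generation="F1",
    mark="DMR",
    p_value=1e-08,
    threshold_applied=None,
):
    """Build an EpimutationSet from (chrom, start, end[, p]) tuples."""
    members = []
    for i, iv in enumerate(intervals):
        chrom, start, end = iv[:3]
        p = iv[3] if len(iv) > 3 else p_value
        members.append(
            Epimutation(
                id=f"{mark}_{generation}_{i}",
                interval=GenomicInterval(chrom, start, end),
                mark=mark,
                generation=generation,
                lineage=lineage,
                p_value=p,
            )
        )
    return EpimutationSet(
        lineage, generation, mark, members, threshold_applied=threshold_applied
    )


def random_interval_set(rng, n, n_chrom=3, chrom_len=100_000, max_width=2_000,
                        **labels):
    """n random intervals on a small multi-chromosome genome."""
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    intervals = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, n_chrom))]
        width = int(rng.integers(1, max_width + 1))
        start = int(rng.integers(0, chrom_len - width))
        intervals.append((chrom, start, start + width))
    return make_set(intervals, **labels)


def brute_force_pairs(a, b):
    """Quadratic all-pairs oracle for find_overlaps."""
    return sorted(
        (ma.id, mb.id, ma.interval.shared_bp(mb.interval))
        for ma in a
        for mb in b
        if ma.interval.overlaps(mb.interval)
    )


@pytest.fixture(scope="session")
def small_assembly():
    return GenomeAssembly([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture(scope="session")
def synthetic_run():
    """One default-configuration synthetic dataset shared across tests."""
    cfg = SyntheticConfig(seed=7)
    assembly, catalog, ground_truth = generate_catalog(cfg)
    return cfg, assembly, catalog, ground_truth


@pytest.fixture(scope="session")
def zero_jitter_run():
    """Synthetic dataset with exact feature placement (jitter 0)."""
    cfg = SyntheticConfig(seed=11, jitter_bp=0)
    assembly, catalog, ground_truth = generate_catalog(cfg)
    return cfg, assembly, catalog, ground_truth
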