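import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epioverlap import (
    GenomeAssembly,
    ThresholdScheme,
    apply_threshold,
    colocalization_scan,
    extend_window,
    extended_overlap_matrix,
    find_overlaps,
    overlap_count_percent,
    select_sets,
    venn_partition,
)
from conftest import brute_force_pairs, make_set, random_interval_set


class TestFindOverlaps:
    def test_empty_set_yields_no_pairs(self):
        a = make_set([])
        b = make_set([("chr1", 0, 100)], mark="ncRNA")
        assert find_overlaps(a, b) == []
        assert find_overlaps(b, a) == []

    def test_identical_interval_full_share(self):
        a = make_set([("chr1", 0, 100)])
        b = make_set([("chr1", 0, 100)], mark="ncRNA")
        (pair,) = find_overlaps(a, b)
        assert pair.shared_bp == 100

    def test_abutting_intervals_do_not_overlap(self):
        a = make_set([("chr1", 0, 10)])
        b = make_set([("chr1", 10, 20)], mark="ncRNA")
        assert find_overlaps(a, b) == []

    def test_sweep_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(42)
        a = random_interval_set(rng, 200)
        b = random_interval_set(rng, 200, mark="ncRNA")
        got = sorted(
            (p.row_member_id, p.col_member_id, p.shared_bp)
            for p in find_overlaps(a, b)
        )
        assert got == brute_force_pairs(a, b)

    def test_overlap_relation_is_symmetric(self):
        rng = np.random.default_rng(5)
        a = random_interval_set(rng, 80)
        b = random_interval_set(rng, 80, mark="DHR")
        ab = {(p.row_member_id, p.col_member_id) for p in find_overlaps(a, b)}
        ba = {(p.col_member_id, p.row_member_id) for p in find_overlaps(b, a)}
        assert ab == ba

    def test_agrees_with_pyranges_join(self):
        # independent third-party cross-check of the pair count
        pyranges = pytest.importorskip("pyranges")
        rng = np.random.default_rng(13)
        a = random_interval_set(rng, 150)
        b = random_interval_set(rng, 150, mark="ncRNA")

        def to_pr(s):
            df = s.to_frame().rename(
                columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
            )
            return pyranges.PyRanges(df[["Chromosome", "Start", "End", "id"]])

        joined = to_pr(a).join(to_pr(b))
        assert len(find_overlaps(a, b)) == len(joined)


class TestCountPercent:
    def test_hand_computed_fraction(self):
        a = make_set([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)])
        b = make_set([("chr1", 250, 260)], mark="ncRNA")
        count, percent = overlap_count_percent(a, b)
        assert count == 1
        assert percent == pytest.approx(100 / 3)

    def test_self_comparison_is_total(self):
        rng = np.random.default_rng(2)
        a = random_interval_set(rng, 50)
        count, percent = overlap_count_percent(a, a)
        assert (count, percent) == (50, 100.0)

    def test_empty_denominator_reported_missing(self):
        a = make_set([])
        b = make_set([("chr1", 0, 10)], mark="ncRNA")
        count, percent = overlap_count_percent(a, b)
        assert count == 0 and math.isnan(percent)

    def test_counts_are_asymmetric(self):
        # two row features hit one wide column feature: 100% one way, 50% back
        a = make_set([("chr1", 0, 100), ("chr1", 200, 300)])
        b = make_set([("chr1", 50, 250), ("chr1", 5000, 5100)], mark="ncRNA")
        assert overlap_count_percent(a, b) == (2, 100.0)
        assert overlap_count_percent(b, a) == (1, 50.0)

    def test_planted_colocalization_fraction_recovered(self, zero_jitter_run):
        cfg, _, catalog, _ = zero_jitter_run
        scheme = ThresholdScheme()
        by_label = {
            (s.generation, s.mark): s
            for s in catalog
            if s.lineage == "vinclozolin"
        }
        ncrna = apply_threshold(by_label[("F1", "ncRNA")],
                                scheme.stringent_for("ncRNA"))
        dmr = apply_threshold(by_label[("F1", "DMR")], scheme.relaxed)
        count, percent = overlap_count_percent(ncrna, dmr)
        # planted pair fraction among F1 stringent ncRNA anchors:
        # pair loci / (pair loci + solo loci)
        expected = (
            cfg.pair_ncrna_colocalization
            * cfg.n_latent_loci
            / (cfg.pair_ncrna_colocalization * cfg.n_latent_loci
               + cfg.n_solo["ncRNA"])
        )
        sd = math.sqrt(expected * (1 - expected) / len(ncrna))
        assert abs(percent / 100 - expected) < 4 * sd + 0.01


class TestExtendWindow:
    def test_interior_interval_gains_exactly_ten_kb(self, small_assembly):
        s = make_set([("chr1", 10_000, 11_000)])
        (m,) = extend_window(s, 5_000, small_assembly).members
        assert (m.interval.start, m.interval.end) == (5_000, 16_000)
        assert m.interval.length == 1_000 + 10_000

    def test_flank_zero_is_identity(self, small_assembly):
        s = make_set([("chr1", 10, 20)])
        assert extend_window(s, 0, small_assembly) is s

    def test_clipped_at_origin(self, small_assembly):
        s = make_set([("chr1", 0, 1_000)])
        (m,) = extend_window(s, 5_000, small_assembly).members
        assert (m.interval.start, m.interval.end) == (0, 6_000)

    def test_unknown_chromosome_is_an_error(self, small_assembly):
        s = make_set([("chr9", 0, 1_000)])
        with pytest.raises(Exception):
            extend_window(s, 5_000, small_assembly)


class TestOverlapMatrix:
    def test_diagonal_cells_are_exactly_100(self, synthetic_run):
        _, assembly, catalog, _ = synthetic_run
        matrix = extended_overlap_matrix(catalog, "vinclozolin")
        for label, size in matrix.row_sizes.items():
            if size > 0:
                assert matrix.percents.loc[label, label] == 100.0

    def test_windowed_matrix_dominates_direct(self, synthetic_run):
        _, assembly, catalog, _ = synthetic_run
        m0 = extended_overlap_matrix(catalog, "DDT", flank_bp=0)
        m5 = extended_overlap_matrix(
            catalog, "DDT", flank_bp=5_000, assembly=assembly
        )
        assert (m5.counts.values >= m0.counts.values).all()
        assert m5.flank_bp == 5_000

    def test_disjoint_sets_give_zero_off_diagonal(self):
        # construct 9 sets on separate coordinate blocks: no cross overlap
        catalog = []
        block = 0
        for gen in ("F1", "F2", "F3"):
            for mark in ("DMR", "ncRNA", "DHR"):
                catalog.append(
                    make_set(
                        [("chr1", block * 100_000 + i * 1_000,
                          block * 100_000 + i * 1_000 + 500, 1e-08)
                         for i in range(5)],
                        generation=gen, mark=mark,
                    )
                )
                block += 1
        matrix = extended_overlap_matrix(catalog, "vinclozolin")
        off = ~np.eye(9, dtype=bool)
        assert (matrix.counts.values[off] == 0).all()
        assert (np.diag(matrix.percents.values) == 100.0).all()

    def test_percent_consistent_with_count_and_row_size(self, synthetic_run):
        _, _, catalog, _ = synthetic_run
        matrix = extended_overlap_matrix(catalog, "vinclozolin")
        for label, size in matrix.row_sizes.items():
            row_counts = matrix.counts.loc[label]
            row_percents = matrix.percents.loc[label]
            if size == 0:
                assert row_percents.isna().all()
            else:
                assert np.allclose(row_percents, 100.0 * row_counts / size)
                assert (row_counts <= size).all()


class TestVennPartition:
    def test_disjoint_sets(self):
        a = make_set([("chr1", 0, 100), ("chr1", 1_000, 1_100)])
        b = make_set(
            [("chr2", 0, 100), ("chr2", 1_000, 1_100), ("chr2", 2_000, 2_100)],
            mark="ncRNA",
        )
        part = venn_partition([a, b], labels=["A", "B"])
        assert part.count("A") == 2
        assert part.count("B") == 3
        assert part.count("A", "B") == 0

    def test_identical_triplicate_sets(self):
        intervals = [("chr1", i * 10_000, i * 10_000 + 100) for i in range(7)]
        sets = [
            make_set(intervals, generation=gen)
            for gen in ("F1", "F2", "F3")
        ]
        part = venn_partition(sets, labels=["A", "B", "C"])
        assert part.count("A", "B", "C") == 7
        assert part.n_components == 7

    def test_counts_sum_to_number_of_components(self, synthetic_run):
        _, _, catalog, _ = synthetic_run
        stringent, _ = select_sets(catalog, "vinclozolin")
        by = {(s.generation, s.mark): s for s in stringent}
        part = venn_partition(
            [by[("F1", "DMR")], by[("F2", "DMR")], by[("F3", "DMR")]],
            labels=["F1", "F2", "F3"],
        )
        assert sum(part.counts.values()) == part.n_components
        assert sum(part.feature_counts.values()) == sum(
            len(by[(g, "DMR")]) for g in ("F1", "F2", "F3")
        )

    def test_matches_graph_component_oracle(self):
        # independent oracle: connected components of the brute-force
        # pairwise overlap graph (networkx)
        rng = np.random.default_rng(21)
        sets = [
            random_interval_set(rng, 60, n_chrom=2, chrom_len=50_000,
                                mark=mark)
            for mark in ("DMR", "ncRNA", "DHR")
        ]
        labels = ["A", "B", "C"]
        part = venn_partition(sets, labels=labels)

        graph = nx.Graph()
        nodes = [
            (label, m.id, m.interval)
            for label, s in zip(labels, sets)
            for m in s
        ]
        graph.add_nodes_from((label, mid) for label, mid, _ in nodes)
        for i, (la, ida, iva) in enumerate(nodes):
            for lb, idb, ivb in nodes[i + 1:]:
                if iva.overlaps(ivb):
                    graph.add_edge((la, ida), (lb, idb))
        oracle: dict[frozenset, int] = {}
        for comp in nx.connected_components(graph):
            sig = frozenset(label for label, _ in comp)
            oracle[sig] = oracle.get(sig, 0) + 1
        assert part.counts == oracle

    def test_rejects_wrong_set_count(self):
        a = make_set([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            venn_partition([a])
        with pytest.raises(ValueError):
            venn_partition([a, a, a, a])


class TestColocalizationScan:
    def test_constructed_tri_mark_site(self):
        # one strong DMR anchor overlapped by weaker ncRNA and DHR
        catalog = [
            make_set([("chr1", 10_000, 11_000, 1e-07)], mark="DMR"),
            make_set([("chr1", 10_200, 10_700, 0.01)], mark="ncRNA"),
            make_set([("chr1", 10_500, 11_500, 0.03)], mark="DHR"),
        ]
        (site,) = colocalization_scan(catalog, "vinclozolin")
        assert site.anchor.mark == "DMR"
        assert sorted(p.mark for p in site.partners) == ["DHR", "ncRNA"]
        assert site.marks_present == {"DMR", "ncRNA", "DHR"}

    def test_no_cross_mark_overlap_gives_empty_list(self):
        catalog = [
            make_set([("chr1", 0, 1_000, 1e-07)], mark="DMR"),
            make_set([("chr2", 0, 500, 1e-05)], mark="ncRNA"),
            make_set([("chr1", 50_000, 51_000, 1e-07)], mark="DHR"),
        ]
        assert colocalization_scan(catalog, "vinclozolin") == []

    def test_partners_never_share_anchor_mark(self, synthetic_run):
        _, _, catalog, _ = synthetic_run
        sites = colocalization_scan(catalog, "DDT")
        assert sites
        for site in sites[:500]:
            assert all(p.mark != site.anchor.mark for p in site.partners)

    def test_sorted_by_chrom_and_midpoint(self, synthetic_run):
        _, _, catalog, _ = synthetic_run
        sites = colocalization_scan(catalog, "vinclozolin")
        keys = [(s.chrom, s.midpoint) for s in sites]
        assert keys == sorted(keys)

    def test_recovers_planted_tri_mark_loci_exactly(self, zero_jitter_run):
        cfg, _, catalog, ground_truth = zero_jitter_run
        sites = colocalization_scan(catalog, "vinclozolin")
        tri_anchored = {
            site.anchor.id
            for site in sites
            if site.anchor.generation == "F3"
            and site.anchor.mark == "DMR"
            and {"ncRNA", "DHR"} <= {p.mark for p in site.partners}
        }
        planted = set()
        for locus in ground_truth:
            if (locus.lineage == "vinclozolin" and locus.tri_mark
                    and locus.dmr_retained):
                planted.update(
                    fid for fid in locus.feature_ids
                    if fid.startswith("vinclozolin_F3_DMR")
                )
        assert planted <= tri_anchored
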