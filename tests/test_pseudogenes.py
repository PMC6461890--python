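"""Pseudogene prediction, classification, orientation and window scans."""

import warnings

import numpy as np
import pandas as pd
import pytest

from picevo import pseudogenes as pgm
from picevo.core_io import GeneModel, GenomeSequences, MappedRead, overlap_bp
from picevo.engine import KmerAligner
from picevo.pseudogenes import (
    PseudogeneUnit,
    assign_parent,
    classify_unit,
    orient_and_place,
    pseudogene_homologs,
    window_scan,
)
from picevo.synthetic_data import evolve_sequence


def _matches(truth, units, min_frac=0.5):
    out = []
    for t in truth:
        best = None
        for u in units:
            ov = overlap_bp((t.start, t.end), u.interval)
            if ov >= min_frac * (t.end - t.start) and (
                best is None or ov > best[0]
            ):
                best = (ov, u)
        if best:
            out.append((t, best[1]))
    return out


class TestPrediction:
    def test_planted_units_recovered_with_correct_parents_and_classes(
        self, default_study, predicted_units
    ):
        truth = default_study.pseudogenes
        matched = _matches(truth, predicted_units)
        recall = len({t.pg_id for t, _u in matched}) / len(truth)
        assert recall >= 0.9
        parent_acc = np.mean(
            [u.parent_gene_id == t.parent_gene_id for t, u in matched]
        )
        assert parent_acc >= 0.95
        class_acc = np.mean([u.klass == t.klass for t, u in matched])
        assert class_acc >= 0.9

    def test_no_spurious_units(self, default_study, predicted_units):
        truth = default_study.pseudogenes
        for u in predicted_units:
            assert any(
                overlap_bp((t.start, t.end), u.interval) > 0 for t in truth
            ), f"unit {u.id} at {u.start}-{u.end} matches no planted pseudogene"

    def test_every_unit_passes_span_and_coverage_filters(self, predicted_units):
        assert pgm.audit_units(predicted_units)
        for u in predicted_units:
            assert u.span >= 300
            assert u.query_coverage >= 0.10

    def test_unit_strand_matches_planted_strand(
        self, default_study, predicted_units
    ):
        matched = _matches(default_study.pseudogenes, predicted_units)
        strand_acc = np.mean([u.strand == t.strand for t, u in matched])
        assert strand_acc >= 0.95

    def test_short_fragment_filtered_out(self):
        rng = np.random.default_rng(0)
        genome_codes = rng.integers(0, 4, size=60_000).astype(np.uint8)
        from picevo.synthetic_data import _decode

        gene = GeneModel("gA", "chr1", 1_000, 1_450, "+", [(1_000, 1_450)])
        seq = _decode(genome_codes)
        # plant only a 200-bp fragment of the CDS far away
        frag = seq[1_000:1_200]
        seq = seq[:40_000] + frag + seq[40_200:]
        genome = GenomeSequences({"chr1": seq})
        cds = {"gA": seq[1_000:1_450]}
        units = pgm.predict_pseudogenes(cds, genome, [gene])
        assert units == []


class TestAssignAndClassify:
    def test_single_candidate_returned(self):
        assert assign_parent([("gA", 0.9, 0.5, 1e-30)])[0] == "gA"

    def test_score_is_identity_times_coverage(self):
        winner, _ = assign_parent(
            [("gA", 0.9, 0.5, 1e-50), ("gB", 0.7, 0.8, 1e-40)]
        )
        assert winner == "gB"  # 0.56 > 0.45

    def test_tie_broken_by_evalue_then_id(self):
        winner, _ = assign_parent(
            [("gB", 0.8, 0.5, 1e-20), ("gA", 0.8, 0.5, 1e-30)]
        )
        assert winner == "gA"
        winner, _ = assign_parent(
            [("gB", 0.8, 0.5, 1e-20), ("gA", 0.8, 0.5, 1e-20)]
        )
        assert winner == "gA"

    @pytest.mark.parametrize(
        "pseudo_exons,coverage,parent_exons,expected",
        [
            (3, 0.8, 10, "processed"),   # 3 <= 4
            (5, 0.8, 10, "unprocessed"), # 5 > 4
            (1, 1.0, 2, "processed"),    # 1 <= 1
            (1, 1.0, 1, "unprocessed"),  # full-length retrocopy edge case
        ],
    )
    def test_processed_rule(self, pseudo_exons, coverage, parent_exons, expected):
        assert classify_unit(pseudo_exons, coverage, parent_exons) == expected

    def test_zero_parent_exons_raises(self):
        with pytest.raises(ValueError):
            classify_unit(1, 0.5, 0)


class TestOrientation:
    def test_reverse_and_parallel_labels(self, default_study, predicted_units):
        fx = default_study.species["spcA"]
        # truth clusters stand in for called loci here
        from picevo.cluster_caller import ClusterLocus

        loci = [
            ClusterLocus(
                id=c.cluster_id, chrom=c.chrom, start=c.start, end=c.end,
                main_strand=c.main_strand, main_strand_fraction=1.0,
                weighted_read_count=1, rpm=1, rpkm=1, frac_1Tor10A=1,
                frac_1U=1, frac_10A=1, top1_share=0, leaning=30,
            )
            for c in default_study.clusters
        ]
        table = orient_and_place(predicted_units, loci, fx.genes)
        truth_by_span = {
            (t.start, t.end): t for t in default_study.pseudogenes
        }
        matched = _matches(default_study.pseudogenes, predicted_units)
        checked = 0
        for t, u in matched:
            if t.in_cluster is None:
                continue
            assert u.in_cluster == t.in_cluster
            assert u.orientation == t.orientation
            checked += 1
        assert checked >= 10

    def test_planted_orientation_mix_recovered(self, default_study, predicted_units):
        matched = _matches(default_study.pseudogenes, predicted_units)
        truth_in = [t for t, _u in matched if t.in_cluster]
        got_in = [u for t, u in matched if t.in_cluster]
        truth_rev = np.mean([t.orientation == "reverse" for t in truth_in])
        got_rev = np.mean([u.orientation == "reverse" for u in got_in])
        assert got_rev == pytest.approx(truth_rev, abs=1e-9)

    def test_unit_outside_clusters_and_introns_is_na(self):
        u = PseudogeneUnit(
            "p1", "chr1", 100, 600, "+", "gA", 0.9, 0.5, 1, "processed"
        )
        table = orient_and_place([u], [], [])
        assert u.orientation is None
        assert u.intronic_host is None

    def test_intronic_insertions_found(self, default_study, predicted_units):
        truth_intronic = {
            t.pg_id: t.intronic_host
            for t in default_study.pseudogenes
            if t.intronic_host
        }
        if not truth_intronic:
            pytest.skip("no intronic pseudogenes planted")
        fx = default_study.species["spcA"]
        orient_and_place(predicted_units, [], fx.genes)
        matched = _matches(default_study.pseudogenes, predicted_units)
        hits = [
            u.intronic_host == t.intronic_host
            for t, u in matched
            if t.intronic_host
        ]
        assert np.mean(hits) >= 0.8


class TestHomologs:
    def test_identical_sister_locus_full_coverage(self):
        rng = np.random.default_rng(1)
        pg_seq = "".join(rng.choice(list("ACGT"), size=800))
        flank = "".join(rng.choice(list("ACGT"), size=2_000))
        region_seq = flank + pg_seq + flank
        genomes = {"sp2": GenomeSequences({"chr1": region_seq})}
        res = pseudogene_homologs(
            pg_seq, {"sp2": ("chr1", 0, len(region_seq))}, genomes
        )
        assert "sp2" in res
        assert res["sp2"]["coverage"] > 0.95
        assert res["sp2"]["start"] == pytest.approx(2_000, abs=5)

    def test_short_remnant_rejected(self):
        rng = np.random.default_rng(2)
        pg_seq = "".join(rng.choice(list("ACGT"), size=800))
        remnant = pg_seq[:100]  # 100 alignable bp < 150 bp threshold
        region_seq = (
            "".join(rng.choice(list("ACGT"), size=1_000))
            + remnant
            + "".join(rng.choice(list("ACGT"), size=1_000))
        )
        genomes = {"sp2": GenomeSequences({"chr1": region_seq})}
        res = pseudogene_homologs(
            pg_seq, {"sp2": ("chr1", 0, len(region_seq))}, genomes
        )
        assert res == {}

    def test_planted_ortholog_shared_across_species(self, default_study):
        # pseudogene coordinates are colinear across species; a planted
        # in-cluster unit must be found in every species retaining the
        # cluster
        t = next(
            p for p in default_study.pseudogenes if p.in_cluster is not None
        )
        cluster = next(
            c for c in default_study.clusters if c.cluster_id == t.in_cluster
        )
        spA = default_study.species["spcA"]
        pg_seq = spA.genome.fetch(t.chrom, t.start, t.end).upper()
        regions = {}
        genomes = {}
        expected = set()
        for sp, fx in default_study.species.items():
            if sp == "spcA":
                continue
            regions[sp] = (cluster.chrom, cluster.start, cluster.end)
            genomes[sp] = fx.genome
            if cluster.present[sp]:
                expected.add(sp)
        res = pseudogene_homologs(pg_seq, regions, genomes)
        assert set(res) == expected


class TestWindowScan:
    def _unit_with_hits(self, span, chrom="chr1", start=10_000):
        from picevo.engine import SimilarityHit

        hit = SimilarityHit(
            "gA", chrom, 0, span, start, start + span, "+", 0.95, span, 1e-60
        )
        return PseudogeneUnit(
            "p1", chrom, start, start + span, "+", "gA", 0.95, 0.9, 1,
            "processed", hits=[hit],
        )

    def test_short_unit_raises(self):
        u = self._unit_with_hits(20)
        genome = GenomeSequences({"chr1": "A" * 20_000})
        with pytest.raises(ValueError, match="32"):
            window_scan(u, genome, "A" * 20, [], 1e6)

    def test_uniform_case_flags_zero_variance(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        genome = GenomeSequences({"chr1": seq})
        span = 500
        u = self._unit_with_hits(span)
        parent = seq[10_000 : 10_000 + span]  # identical -> identity 1.0
        scan = window_scan(u, genome, parent, [], 1e6)
        assert scan.zero_variance
        assert scan.pearson_r == 0.0
        assert np.all(scan.densities == 0)

    def test_no_antisense_reads_all_windows_silent(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        genome = GenomeSequences({"chr1": seq})
        u = self._unit_with_hits(500)
        parent = evolve_sequence(seq[10_000:10_500], 0.05, seed=1)
        sense_reads = [
            MappedRead("A" * 26, [("chr1", 10_100, "+")], copies=5.0)
        ]
        scan = window_scan(u, genome, parent, sense_reads, 1e6)
        assert np.all(scan.densities == 0)
        assert np.isnan(scan.mean_identity_producing)

    def test_planted_anticorrelation_detected(self):
        rng = np.random.default_rng(5)
        seq_list = list("".join(rng.choice(list("ACGT"), size=20_000)))
        span = 800
        start = 10_000
        parent = "".join(seq_list[start : start + span])
        # second half of the unit diverges strongly from the parent
        mutated = evolve_sequence(parent[span // 2 :], 0.3, seed=2)
        seq_list[start + span // 2 : start + span] = list(mutated)
        genome = GenomeSequences({"chr1": "".join(seq_list)})
        u = self._unit_with_hits(span)
        # antisense reads only over the diverged second half: sequence
        # similarity anti-correlates with read density
        reads = [
            MappedRead(
                "A" * 26, [("chr1", start + span // 2 + 20 * i, "-")],
                copies=3.0,
            )
            for i in range((span // 2 - 32) // 20)
        ]
        scan = window_scan(u, genome, parent, reads, 1e6)
        assert scan.pearson_r < -0.3
        assert scan.mean_identity_producing < scan.mean_identity_silent
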