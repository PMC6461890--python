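"""Transcript matching asymmetry, coverage, ping-pong genes, overlaps."""

import numpy as np
import pandas as pd
import pytest

from picevo import targets as tg
from picevo.core_io import MappedRead
from picevo.engine import revcomp
from picevo.pseudogenes import PseudogeneUnit
from picevo.targets import (
    TranscriptIndex,
    call_targets,
    cross_species_overlap,
    gene_coverage,
    gene_pingpong,
    map_to_transcripts,
    mismatch_audit,
    pseudogene_antisense_targets,
)


@pytest.fixture(scope="module")
def cdna():
    rng = np.random.default_rng(0)
    return {
        f"g{i}": "".join(rng.choice(list("ACGT"), size=1_000))
        for i in range(5)
    }


def _mm(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def _read(seq, copies=1.0):
    return MappedRead(seq, [("chr1", 0, "+")], copies=copies)


class TestMismatchAsymmetry:
    def test_exact_sense_match_kept(self, cdna):
        read = _read(cdna["g0"][100:128])
        per_gene = map_to_transcripts([read], cdna)
        placements = [p for _r, p in per_gene["g0"]]
        assert any(p.orientation == "sense" and p.position == 100 for p in placements)

    def test_sense_with_one_mismatch_discarded(self, cdna):
        read = _read(_mm(cdna["g0"][100:128], [10]))
        per_gene = map_to_transcripts([read], cdna)
        assert not any(
            p.orientation == "sense"
            for placed in per_gene.values()
            for _r, p in placed
        )

    @pytest.mark.parametrize("n_mm,kept", [(0, True), (2, True), (3, False)])
    def test_antisense_mismatch_threshold(self, cdna, n_mm, kept):
        sub = cdna["g1"][200:230]
        read = _read(_mm(revcomp(sub), list(range(n_mm))))
        per_gene = map_to_transcripts([read], cdna)
        anti = [
            p
            for placed in per_gene.values()
            for _r, p in placed
            if p.orientation == "antisense"
        ]
        assert bool(anti) == kept
        if kept:
            assert anti[0].mismatches == n_mm

    def test_exhaustive_audit_on_simulated_library(self, default_study):
        fx = default_study.species["spcA"]
        per_gene = map_to_transcripts(fx.reads[:5_000], fx.cdna)
        sense_bad, anti_bad = mismatch_audit(per_gene)
        assert sense_bad == 0
        assert anti_bad == 0


class TestCoverage:
    def test_rpkm_arithmetic(self, cdna):
        read = _read(cdna["g0"][0:28], copies=10.0)
        per_gene = map_to_transcripts([read], cdna)
        cov = gene_coverage(per_gene, {g: 1_000 for g in cdna}, 1e6)
        assert cov.loc["g0", "total_rpkm"] == pytest.approx(10.0)
        assert cov.loc["g0", "passes_rpkm"]

    def test_zero_length_transcript_raises(self, cdna):
        read = _read(cdna["g0"][0:28])
        per_gene = map_to_transcripts([read], cdna)
        with pytest.raises(ValueError, match="zero-length"):
            gene_coverage(per_gene, {"g0": 0}, 1e6)

    def test_weight_conservation(self, cdna):
        reads = [
            _read(cdna["g0"][i : i + 26], copies=2.0) for i in (0, 50, 100)
        ]
        per_gene = map_to_transcripts(reads, cdna)
        total = sum(
            tg._placement_weight(r, p)
            for placed in per_gene.values()
            for r, p in placed
        )
        assert total <= sum(r.copies for r in reads) + 1e-9


class TestGenePingpong:
    def _pingpong_reads(self, cdna_seq, n_pairs, rng, start=50, spacing=30):
        reads = []
        for i in range(n_pairs):
            p = start + i * spacing
            L1, L2 = int(rng.integers(26, 31)), int(rng.integers(26, 31))
            sense = cdna_seq[p : p + L1]
            # antisense partner: 5' ends overlap by 10 on the transcript
            anti = revcomp(cdna_seq[p + 10 - L2 : p + 10])
            reads.append(_read(sense))
            reads.append(_read(anti))
        return reads

    def test_sense_only_not_significant(self, cdna):
        reads = [_read(cdna["g0"][i : i + 26]) for i in range(0, 300, 30)]
        per_gene = map_to_transcripts(reads, cdna)
        sig = gene_pingpong(per_gene["g0"])
        assert not sig.significant

    def test_planted_transcript_pairs_significant(self, cdna):
        rng = np.random.default_rng(1)
        reads = self._pingpong_reads(cdna["g0"], 20, rng)
        per_gene = map_to_transcripts(reads, cdna)
        sig = gene_pingpong(per_gene["g0"])
        assert sig.significant
        assert sig.z10 > 2.3264

    def test_argmax_not_at_ten_never_significant(self, cdna):
        # pairs with 9-nt overlaps only
        rng = np.random.default_rng(2)
        seq = cdna["g2"]
        reads = []
        for i in range(20):
            p = 50 + i * 30
            sense = seq[p : p + 26]
            anti = revcomp(seq[p + 9 - 26 : p + 9])
            reads.append(_read(sense))
            reads.append(_read(anti))
        per_gene = map_to_transcripts(reads, cdna)
        sig = gene_pingpong(per_gene["g2"])
        assert sig.score(9) > sig.score(10)
        assert not sig.significant

    def test_shuffled_controls_rarely_significant(self, cdna):
        rng = np.random.default_rng(3)
        reads = self._pingpong_reads(cdna["g3"], 15, rng)
        seq = cdna["g3"]
        n_sig = 0
        for s in range(100):
            sh = np.random.default_rng(s)
            shuffled = []
            for r in reads:
                p = int(sh.integers(0, len(seq) - r.length))
                orientation = sh.random() < 0.5
                if orientation:
                    shuffled.append(_read(seq[p : p + r.length]))
                else:
                    shuffled.append(_read(revcomp(seq[p : p + r.length])))
            per_gene = map_to_transcripts(shuffled, cdna)
            if gene_pingpong(per_gene.get("g3", [])).significant:
                n_sig += 1
        assert n_sig <= 5


class TestPseudogeneDerived:
    def test_no_reverse_pseudogenes_empty(self, cdna):
        assert pseudogene_antisense_targets([], [], cdna, 1e6) == {}

    def test_parallel_orientation_contributes_nothing(self, cdna):
        u = PseudogeneUnit(
            "p1", "chr1", 1_000, 2_000, "+", "g0", 0.95, 0.9, 1,
            "processed", in_cluster="cl0", orientation="parallel",
        )
        reads = [MappedRead("A" * 26, [("chr1", 1_100, "-")], copies=5.0)]
        assert pseudogene_antisense_targets([u], reads, cdna, 1e6) == {}

    def test_planted_reverse_pseudogene_targets_parent(self, default_study, predicted_units):
        fx = default_study.species["spcA"]
        from picevo.cluster_caller import ClusterLocus
        from picevo.pseudogenes import orient_and_place

        loci = [
            ClusterLocus(
                id=c.cluster_id, chrom=c.chrom, start=c.start, end=c.end,
                main_strand=c.main_strand, main_strand_fraction=1.0,
                weighted_read_count=1, rpm=1, rpkm=1, frac_1Tor10A=1,
                frac_1U=1, frac_10A=1, top1_share=0, leaning=30,
            )
            for c in default_study.clusters
        ]
        orient_and_place(predicted_units, loci, fx.genes)
        lib = sum(r.copies for r in fx.reads)
        res = pseudogene_antisense_targets(
            predicted_units, fx.reads, fx.cdna, lib
        )
        assert res  # at least one pseudogene-derived target
        reverse_parents = {
            u.parent_gene_id
            for u in predicted_units
            if u.orientation == "reverse"
        }
        assert reverse_parents & set(res)
        for rep in res.values():
            assert rep.pseudogene_derived
            assert rep.source_pseudogenes


class TestCrossSpecies:
    def test_disjoint_sets_all_k1(self):
        table = pd.DataFrame({"a": ["g1", "g2"], "b": ["g1", "g2"]})
        counts = cross_species_overlap(
            {"a": ["g1"], "b": ["g2"]}, table
        )
        assert counts[1] == 2
        assert counts[2] == 0

    def test_identical_sets_all_k3(self):
        table = pd.DataFrame(
            {"a": ["g1", "g2"], "b": ["g1", "g2"], "c": ["g1", "g2"]}
        )
        counts = cross_species_overlap(
            {"a": ["g1", "g2"], "b": ["g1", "g2"], "c": ["g1", "g2"]}, table
        )
        assert counts[3] == 2
        assert counts[1] == counts[2] == 0

    def test_gene_missing_from_table_counts_species_specific(self):
        table = pd.DataFrame({"a": ["g1"], "b": ["g1"]})
        counts = cross_species_overlap(
            {"a": ["gX"], "b": ["gX"]}, table
        )
        assert counts[1] == 2

    def test_partial_sharing_counts_match_truth(self):
        table = pd.DataFrame(
            {"a": [f"g{i}" for i in range(6)],
             "b": [f"g{i}" for i in range(6)],
             "c": [f"g{i}" for i in range(6)]}
        )
        sets = {
            "a": ["g0", "g1", "g2", "g3"],
            "b": ["g0", "g1", "g4"],
            "c": ["g0", "g5"],
        }
        counts = cross_species_overlap(sets, table)
        assert counts[3] == 1  # g0
        assert counts[2] == 1  # g1
        assert counts[1] == 4  # g2 g3 g4 g5


class TestDoseResponse:
    def test_pingpong_probability_increases_with_coverage(self, cdna):
        """More planted pairs (higher RPKM) -> ping-pong called more often."""
        rng = np.random.default_rng(5)
        seq = cdna["g4"]
        rates = []
        for n_pairs in (2, 8, 20):
            calls = 0
            for trial in range(20):
                tr = np.random.default_rng(100 * n_pairs + trial)
                reads = []
                for _ in range(n_pairs):
                    p = int(tr.integers(0, len(seq) - 40))
                    sense = seq[p : p + 28]
                    anti = revcomp(seq[p + 10 - 28 : p + 10])
                    if p + 10 - 28 < 0:
                        continue
                    reads.append(_read(sense))
                    reads.append(_read(anti))
                # positional noise
                for _ in range(10):
                    p = int(tr.integers(0, len(seq) - 30))
                    reads.append(_read(seq[p : p + 27]))
                per_gene = map_to_transcripts(reads, cdna)
                if gene_pingpong(per_gene.get("g4", [])).significant:
                    calls += 1
            rates.append(calls / 20)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]
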