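"""Transcript-level piRNA target calling.

Reads of 24-32 nt are matched ungapped and end-to-end against the cDNA
catalog with at most two mismatches; sense placements (read equals the
cDNA substring) are kept only when mismatch-free, antisense placements
(reverse complement of the read matches the cDNA) tolerate up to two
mismatches.  Per-gene coverage is thresholded at 5 RPKM, and genes with a
significant ping-pong signature in transcript coordinates (argmax uniquely
at a 10-nt 5' overlap, z > 2.3264) are called ping-pong genes.

Reads overlapping reverse-oriented pseudogene spans inside piRNA clusters
are additionally mapped on their own, yielding pseudogene-derived
antisense target genes; cross-species target overlap is computed over an
ortholog table.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import srna_stats
from .core_io import MappedRead, filter_by_length
from .engine import revcomp
from .pseudogenes import PseudogeneUnit
from .srna_stats import OverlapSignature

MAX_MISMATCHES = 2
RPKM_THRESHOLD = 5.0
_SEED_LEN = 8


@dataclass
class TranscriptPlacement:
    gene_id: str
    position: int  # 0-based on the cDNA
    orientation: str  # sense | antisense
    mismatches: int


@dataclass
class GeneTargetReport:
    gene_id: str
    sense_rpkm: float
    antisense_rpkm: float
    total_rpkm: float
    signature: OverlapSignature | None
    pingpong_gene: bool
    pseudogene_derived: bool = False
    source_pseudogenes: list[str] = field(default_factory=list)


class TranscriptIndex:
    """Seed-and-verify ungapped matcher over a cDNA catalog.

    With at most two mismatches over a 24-32 nt read, splitting the read
    into three seeds guarantees one exact seed (pigeonhole), which is
    looked up in an 8-mer index and verified by direct comparison.
    """

    def __init__(self, cdna: Mapping[str, str]):
        self.cdna = {g: s.upper() for g, s in cdna.items()}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for gid, seq in self.cdna.items():
            for i in range(0, len(seq) - _SEED_LEN + 1):
                self.index[seq[i : i + _SEED_LEN]].append((gid, i))

    def match(
        self, read_seq: str, max_mm: int = MAX_MISMATCHES
    ) -> list[tuple[str, int, int]]:
        """(gene, position, mismatches) for all end-to-end ungapped
        placements of ``read_seq`` on the catalog with <= max_mm."""
        read_seq = read_seq.upper()
        L = len(read_seq)
        hits: dict[tuple[str, int], int] = {}
        n_seeds = max_mm + 1
        offsets = [round(j * (L - _SEED_LEN) / max(n_seeds - 1, 1)) for j in range(n_seeds)]
        seen_anchor: set[tuple[str, int]] = set()
        for off in offsets:
            word = read_seq[off : off + _SEED_LEN]
            for gid, pos in self.index.get(word, ()):
                start = pos - off
                key = (gid, start)
                if key in seen_anchor:
                    continue
                seen_anchor.add(key)
                seq = self.cdna[gid]
                if start < 0 or start + L > len(seq):
                    continue
                mm = sum(
                    1 for a, b in zip(read_seq, seq[start : start + L]) if a != b
                )
                if mm <= max_mm:
                    hits[key] = mm
        return [(g, p, mm) for (g, p), mm in sorted(hits.items())]


def map_to_transcripts(
    reads: Sequence[MappedRead],
    cdna: Mapping[str, str] | TranscriptIndex,
    max_mm: int = MAX_MISMATCHES,
) -> dict[str, list[tuple[MappedRead, TranscriptPlacement]]]:
    """Place 24-32 nt reads on the cDNA catalog.

    Sense placements require zero mismatches; antisense placements allow
    ``max_mm``.  Per-gene weights fractionate each read's copies over its
    transcript placements only (reads/hits in transcript space).
    """
    index = cdna if isinstance(cdna, TranscriptIndex) else TranscriptIndex(cdna)
    per_gene: dict[str, list[tuple[MappedRead, TranscriptPlacement]]] = (
        defaultdict(list)
    )
    for r in filter_by_length(reads):
        placements: list[TranscriptPlacement] = []
        for gid, pos, mm in index.match(r.sequence, max_mm):
            if mm == 0:
                placements.append(TranscriptPlacement(gid, pos, "sense", mm))
        for gid, pos, mm in index.match(revcomp(r.sequence), max_mm):
            placements.append(TranscriptPlacement(gid, pos, "antisense", mm))
        for p in placements:
            per_gene[p.gene_id].append((r, p))
        # stash the fractionation denominator on each placement
        for p in placements:
            p.n_placements = len(placements)  # type: ignore[attr-defined]
    return dict(per_gene)


def _placement_weight(read: MappedRead, placement: TranscriptPlacement) -> float:
    n = getattr(placement, "n_placements", 1)
    return read.copies / n


def gene_coverage(
    per_gene: Mapping[str, list[tuple[MappedRead, TranscriptPlacement]]],
    transcript_lengths: Mapping[str, int],
    library_size: float,
) -> pd.DataFrame:
    """RPKM per gene and the pass flag at the 5 RPKM threshold.

    RPKM = weight x 1e9 / (library_size x transcript length bp); the
    transcript length is that of the representative (longest) cDNA.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rows = []
    for gid, placed in per_gene.items():
        length = transcript_lengths[gid]
        if length <= 0:
            raise ValueError(f"zero-length transcript for gene {gid}")
        sense_w = sum(
            _placement_weight(r, p) for r, p in placed if p.orientation == "sense"
        )
        anti_w = sum(
            _placement_weight(r, p)
            for r, p in placed
            if p.orientation == "antisense"
        )
        scale = 1e9 / (library_size * length)
        rows.append(
            {
                "gene_id": gid,
                "sense_rpkm": sense_w * scale,
                "antisense_rpkm": anti_w * scale,
                "total_rpkm": (sense_w + anti_w) * scale,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "sense_rpkm", "antisense_rpkm", "total_rpkm"]
    )
    df["passes_rpkm"] = df.total_rpkm >= RPKM_THRESHOLD
    return df.set_index("gene_id")


def gene_pingpong(
    placed: Sequence[tuple[MappedRead, TranscriptPlacement]],
) -> OverlapSignature:
    """Ping-pong signature of one gene in transcript coordinates.

    Sense placements act as plus-strand reads at their cDNA position;
    antisense placements as minus-strand reads (their 5' end sits at
    position + length - 1 on the cDNA).  Delegates to the genomic
    overlap-signature statistic on synthetic transcript-space reads.
    """
    pseudo: list[MappedRead] = []
    for r, p in placed:
        strand = "+" if p.orientation == "sense" else "-"
        pseudo.append(
            MappedRead(
                sequence=r.sequence,
                placements=[("tx", p.position, strand)],
                copies=_placement_weight(r, p),
            )
        )
    return srna_stats.overlap_signature(pseudo)


def call_targets(
    reads: Sequence[MappedRead],
    cdna: Mapping[str, str],
    library_size: float | None = None,
) -> dict[str, GeneTargetReport]:
    """Full target-gene calling for one species."""
    reads = filter_by_length(reads)
    if library_size is None:
        library_size = sum(r.copies for r in reads)
    per_gene = map_to_transcripts(reads, cdna)
    lengths = {g: len(s) for g, s in cdna.items()}
    cov = gene_coverage(per_gene, lengths, library_size)
    out: dict[str, GeneTargetReport] = {}
    for gid, placed in per_gene.items():
        row = cov.loc[gid]
        if row.passes_rpkm:
            sig = gene_pingpong(placed)
            pingpong = sig.significant
        else:
            sig, pingpong = None, False
        out[gid] = GeneTargetReport(
            gene_id=gid,
            sense_rpkm=float(row.sense_rpkm),
            antisense_rpkm=float(row.antisense_rpkm),
            total_rpkm=float(row.total_rpkm),
            signature=sig,
            pingpong_gene=pingpong,
        )
    return out


def pseudogene_antisense_targets(
    units: Sequence[PseudogeneUnit],
    reads: Sequence[MappedRead],
    cdna: Mapping[str, str],
    library_size: float,
) -> dict[str, GeneTargetReport]:
    """Targets reachable through reverse in-cluster pseudogenes.

    Reads overlapping the spans of reverse-oriented in-cluster units on
    the strand opposite the unit's gene-sense strand (i.e. antisense to
    the parent mRNA) are mapped to the cDNA catalog; resulting genes are
    flagged pseudogene-derived with their source unit ids.
    """
    reverse_units = [
        u for u in units if u.in_cluster is not None and u.orientation == "reverse"
    ]
    if not reverse_units:
        return {}
    subset: list[MappedRead] = []
    sources: dict[str, set[str]] = defaultdict(set)
    picked: set[int] = set()
    for u in reverse_units:
        anti = "-" if u.strand == "+" else "+"
        for i, r in enumerate(reads):
            if i in picked:
                continue
            for chrom, start, strand in r.placements:
                if (
                    chrom == u.chrom
                    and strand == anti
                    and start < u.end
                    and start + r.length > u.start
                ):
                    subset.append(r)
                    picked.add(i)
                    sources[r.sequence].add(u.id)
                    break
    if not subset:
        return {}
    per_gene = map_to_transcripts(subset, cdna)
    lengths = {g: len(s) for g, s in cdna.items()}
    cov = gene_coverage(per_gene, lengths, library_size)
    out: dict[str, GeneTargetReport] = {}
    for gid, placed in per_gene.items():
        row = cov.loc[gid]
        sig = gene_pingpong(placed) if row.passes_rpkm else None
        src = sorted(
            {u for r, _p in placed for u in sources.get(r.sequence, ())}
        )
        out[gid] = GeneTargetReport(
            gene_id=gid,
            sense_rpkm=float(row.sense_rpkm),
            antisense_rpkm=float(row.antisense_rpkm),
            total_rpkm=float(row.total_rpkm),
            signature=sig,
            pingpong_gene=bool(sig.significant) if sig else False,
            pseudogene_derived=True,
            source_pseudogenes=src,
        )
    return out


def cross_species_overlap(
    target_sets: Mapping[str, Iterable[str]],
    ortholog_table: pd.DataFrame,
) -> pd.Series:
    """Counts of ortholog groups targeted in exactly k species.

    ``ortholog_table`` holds one column per species with per-row
    orthologous gene ids.  Genes absent from the table count as
    species-specific (k = 1)."""
    species = list(target_sets)
    group_of: dict[tuple[str, str], int] = {}
    for gi, row in enumerate(ortholog_table.itertuples(index=False)):
        for sp, gid in zip(ortholog_table.columns, row):
            group_of[(sp, gid)] = gi
    hit_groups: dict[int, set[str]] = defaultdict(set)
    orphan = 0
    next_virtual = len(ortholog_table)
    for sp in species:
        for gid in target_sets[sp]:
            key = (sp, gid)
            if key in group_of:
                hit_groups[group_of[key]].add(sp)
            else:
                hit_groups[next_virtual + orphan].add(sp)
                orphan += 1
    counts = pd.Series(
        0, index=pd.RangeIndex(1, len(species) + 1, name="n_species")
    )
    for members in hit_groups.values():
        counts[len(members)] += 1
    return counts


def mismatch_audit(
    per_gene: Mapping[str, list[tuple[MappedRead, TranscriptPlacement]]]
) -> tuple[int, int]:
    """(sense violations with mm > 0, antisense violations with mm > 2)."""
    sense_bad = sum(
        1
        for placed in per_gene.values()
        for _r, p in placed
        if p.orientation == "sense" and p.mismatches > 0
    )
    anti_bad = sum(
        1
        for placed in per_gene.values()
        for _r, p in placed
        if p.orientation == "antisense" and p.mismatches > MAX_MISMATCHES
    )
    return sense_bad, anti_bad
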