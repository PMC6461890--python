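"""Readers/writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally.  GFF3 and RepeatMasker
``.out`` files (both 1-based closed) are converted at the boundary; BED and
SAM-derived coordinates are used natively (pysam already reports 0-based).

Mapped small-RNA reads are collapsed by exact sequence identity and their
read counts fractionated over genomic placements ("reads/hits"), so a
sequence observed ``c`` times with ``h`` placements contributes weight
``c / h`` at each placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

VALID_BASES = set("ACGTNacgtn")

# SAM tag carrying the collapsed read count of a distinct sequence.
COUNT_TAG = "XC"


class FormatError(ValueError):
    """Raised for malformed records in any supported input format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequences:
    """Genome as a mapping from chromosome name to nucleotide string.

    ``masked`` records whether lowercase/N masking is present; lowercase
    bases are treated as repeat-masked by the similarity-search stages.
    """

    records: dict[str, str]
    masked: bool = False

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r}: invalid characters {sorted(bad)}"
                )
        if not self.masked:
            self.masked = any(
                any(c.islower() or c in "Nn" for c in seq)
                for seq in self.records.values()
            )

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.records[chrom][start:end]

    def unmasked(self) -> "GenomeSequences":
        return GenomeSequences(
            {k: v.upper() for k, v in self.records.items()}, masked=False
        )


@dataclass
class GeneModel:
    """A gene with exon structure on 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: end <= start")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise FormatError(f"gene {self.gene_id}: empty exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def largest_intron(self) -> int:
        if len(self.exons) < 2:
            return 0
        return max(b[0] - a[1] for a, b in zip(self.exons, self.exons[1:]))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: GenomeSequences) -> str:
        """Exon concatenation in transcription order (reverse-complemented
        for minus-strand genes)."""
        parts = [genome.fetch(self.chrom, s, e).upper() for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class RepeatFeature:
    """One RepeatMasker element with percent divergence from consensus."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    divergence: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError("repeat feature with end <= start")
        if not 0.0 <= self.divergence <= 100.0:
            raise FormatError(f"divergence {self.divergence} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MappedRead:
    """A distinct small-RNA sequence with genomic placements.

    ``weight_per_placement`` fractionates the observed copy count over the
    number of placements, so multi-mappers are not over-counted.
    """

    sequence: str
    placements: list[tuple[str, int, str]]
    copies: float = 1.0
    unknown_chroms: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def weight_per_placement(self) -> float:
        return self.copies / len(self.placements)

    def five_prime(self, placement: tuple[str, int, str]) -> int:
        """Genomic coordinate of the 5' end for one placement."""
        chrom, start, strand = placement
        return start if strand == "+" else start + self.length - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> GenomeSequences:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return GenomeSequences(records)


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# mapped reads: SAM and a documented BED dialect
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path,
    format: str = "sam",
    known_chroms: Iterable[str] | None = None,
) -> list[MappedRead]:
    """Load mapped reads, collapsing by exact sequence identity.

    SAM: one line per placement of a collapsed sequence; the copy count of
    the sequence is carried in the integer tag ``XC`` (default 1).  The
    stored SEQ field always gives the read in its original (sequenced)
    orientation, i.e. reverse-strand placements are reverse-complemented
    back before collapsing.

    BED: the name field encodes ``seq:<sequence>|n:<count>``.

    Placements are deduplicated per sequence; total copies are preserved.
    Placements on chromosomes not in ``known_chroms`` (when given) are kept
    but flagged in ``unknown_chroms``.
    """
    if format == "sam":
        raw = _iter_sam(path)
    elif format == "bed":
        raw = _iter_bed(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    by_seq: dict[str, MappedRead] = {}
    known = set(known_chroms) if known_chroms is not None else None
    for seq, chrom, start, strand, count in raw:
        read = by_seq.get(seq)
        if read is None:
            read = MappedRead(sequence=seq, placements=[], copies=float(count))
            by_seq[seq] = read
        placement = (chrom, start, strand)
        if placement not in read.placements:
            read.placements.append(placement)
        if known is not None and chrom not in known:
            read.unknown_chroms.add(chrom)
    return list(by_seq.values())


def _iter_sam(path: str | Path) -> Iterator[tuple[str, str, int, str, int]]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, aln in enumerate(fh, start=1):
            if aln.is_unmapped:
                continue
            seq = aln.query_sequence
            if seq is None:
                raise FormatError(f"SAM record {i}: missing sequence")
            if aln.is_reverse:
                seq = str(Seq(seq).reverse_complement())
                strand = "-"
            else:
                strand = "+"
            count = aln.get_tag(COUNT_TAG) if aln.has_tag(COUNT_TAG) else 1
            yield seq.upper(), aln.reference_name, aln.reference_start, strand, int(count)


def _iter_bed(path: str | Path) -> Iterator[tuple[str, str, int, str, int]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: BED dialect needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                seq, count = _parse_bed_name(name)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            start_i, end_i = int(start), int(end)
            if end_i - start_i != len(seq):
                raise FormatError(
                    f"line {lineno}: interval length {end_i - start_i} != "
                    f"sequence length {len(seq)}"
                )
            yield seq.upper(), chrom, start_i, strand, count


def _parse_bed_name(name: str) -> tuple[str, int]:
    parts = dict(p.split(":", 1) for p in name.split("|") if ":" in p)
    if "seq" not in parts or "n" not in parts:
        raise ValueError(f"name field {name!r} lacks seq:/n: keys")
    return parts["seq"], int(parts["n"])


def write_alignments_sam(
    reads: Sequence[MappedRead],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write collapsed reads as SAM, one line per placement, count in XC."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in chrom_lengths.items()],
    }
    tid = {n: i for i, n in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ri, read in enumerate(reads):
            for pi, (chrom, start, strand) in enumerate(read.placements):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{ri}_{pi}"
                a.reference_id = tid[chrom]
                a.reference_start = start
                a.mapping_quality = 255
                a.cigarstring = f"{read.length}M"
                if strand == "-":
                    a.flag = 16
                    a.query_sequence = str(Seq(read.sequence).reverse_complement())
                else:
                    a.flag = 0
                    a.query_sequence = read.sequence
                a.set_tag(COUNT_TAG, int(round(read.copies)), "i")
                out.write(a)


def write_alignments_bed(reads: Sequence[MappedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            for chrom, start, strand in read.placements:
                name = f"seq:{read.sequence}|n:{int(round(read.copies))}"
                fh.write(
                    f"{chrom}\t{start}\t{start + read.length}\t{name}\t0\t{strand}\n"
                )


def total_copies(reads: Iterable[MappedRead]) -> float:
    return sum(r.copies for r in reads)


def filter_by_length(
    reads: Iterable[MappedRead], min_len: int = 24, max_len: int = 32
) -> list[MappedRead]:
    return [r for r in reads if min_len <= r.length <= max_len]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon hierarchy).

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Exons without resolvable parent linkage are skipped with a warning;
    exons outside the gene span raise.
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = []
        for ex in db.children(g, featuretype="exon"):
            s, e = ex.start - 1, ex.end
            if s < g.start - 1 or e > g.end:
                raise FormatError(
                    f"gene {g.id}: exon {s}-{e} outside gene span"
                )
            if (s, e) not in exons:
                exons.append((s, e))
        if not exons:
            exons = [(g.start - 1, g.end)]
        biotype = g.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=exons,
                biotype=biotype,
            )
        )
    # orphan exons (parent feature absent) -> warning
    known_parents = {g.id for g in db.features_of_type("gene")} | {
        m.id for m in db.features_of_type("mRNA")
    }
    for ex in db.features_of_type("exon"):
        parents = ex.attributes.get("Parent", [])
        if parents and not any(p in known_parents for p in parents):
            warnings.warn(f"exon with unknown parent {parents}: skipped")
    return genes


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tpicevo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpicevo\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tpicevo\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.e{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = """\
   SW   perc perc perc  query     position in query              matching repeat             position in repeat
score   div. del. ins.  sequence  begin  end          (left)    repeat        class/family  begin  end    (left)   ID

"""


def read_repeatmasker(path: str | Path) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out`` (3 header lines, whitespace columns)."""
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) < 11:
            raise FormatError(f"line {lineno}: expected >=11 columns")
        try:
            div = float(cols[1])
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric divergence {cols[1]!r}")
        chrom = cols[4]
        start_1 = int(cols[5])
        end = int(cols[6])
        strand = "-" if cols[8] == "C" else "+"
        family = cols[10]
        feats.append(
            RepeatFeature(
                chrom=chrom,
                start=start_1 - 1,
                end=end,
                strand=strand,
                family=family,
                divergence=div,
            )
        )
    return feats


def write_repeatmasker(feats: Sequence[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(feats, start=1):
            strand = "C" if f.strand == "-" else "+"
            name = f.family.split("/")[-1]
            fh.write(
                f"  225 {f.divergence:5.1f}  0.0  0.0  {f.chrom} "
                f"{f.start + 1} {f.end} (0) {strand} {name} {f.family} "
                f"1 {f.end - f.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals (peaks, centromeres)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: BED needs >=3 columns")
            start, end = int(cols[1]), int(cols[2])
            if end < start:
                raise FormatError(f"line {lineno}: end < start")
            out.append((cols[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bp of two half-open intervals (0 when merely adjacent)."""
    for iv in (a, b):
        if iv[0] > iv[1]:
            raise ValueError(f"interval with start > end: {iv}")
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def interval_overlap(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """All overlapping pairs between interval sets ``a`` and ``b``.

    Returns (index_in_a, index_in_b, overlap_bp) for each pair with
    overlap > 0, using an interval tree for the scan.
    """
    tree = IntervalTree()
    for j, (s, e) in enumerate(b):
        if s > e:
            raise ValueError(f"interval with start > end: {(s, e)}")
        if e > s:
            tree[s:e] = j
    out = []
    for i, (s, e) in enumerate(a):
        if s > e:
            raise ValueError(f"interval with start > end: {(s, e)}")
        if e <= s:
            continue
        for hit in sorted(tree[s:e], key=lambda h: h.data):
            out.append((i, hit.data, overlap_bp((s, e), (hit.begin, hit.end))))
    return out


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge intervals whose gap is < ``max_gap`` (0 merges only overlaps
    and adjacencies are kept separate unless gap < max_gap or overlap)."""
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] < max_gap or s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(ov/|a|, ov/|b|) — the reciprocal-overlap fraction."""
    ov = overlap_bp(a, b)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la == 0 or lb == 0:
        return 0.0
    return min(ov / la, ov / lb)
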