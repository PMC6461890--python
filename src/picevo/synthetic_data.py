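"""Deterministic multi-species synthetic fixtures with truth tables.

The generator emulates the data layer of a comparative testis piRNA study:
per-species genomes carrying planted piRNA clusters, multi-exon genes,
repeat annotations with divergence values, processed/unprocessed pseudogene
insertions, and simulated 24-32 nt reads with bimodal length peaks (~26 and
~30 nt), 1U/10A biases and planted ping-pong pairs with exact 10-nt
5' overlaps.

A single ancestral ("root") genome is laid out once; each species genome is
derived from it by per-site Jukes-Cantor substitutions scaled by the
species' divergence-from-root time, so all features stay colinear across
species and homology truth is exact.  Cluster loss (sequence replaced by
random DNA) and transcriptional silencing (no reads emitted) are planted
with deterministic per-species counts that grow with divergence time, which
makes homolog-retention-versus-time curves decrease by construction.

Everything is driven by one integer seed; identical config + seed yields
byte-identical fixture files.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core_io
from .core_io import GeneModel, GenomeSequences, MappedRead, RepeatFeature

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_T, _A = 3, 0  # code indices: A=0 C=1 G=2 T=3


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    if (out == 255).any():
        bad = chr(arr[out == 255][0])
        raise ValueError(f"non-ACGT base {bad!r} in input sequence")
    return out


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ReadModel:
    """Parameters of the simulated small-RNA library.

    Lengths come from a two-component normal mixture with peaks at 26 and
    30 nt truncated to [24, 32]; ``length_weights`` is the genome-wide
    mixture, tilted per cluster by its 26/30 leaning.  ``p_1u`` is the
    probability that a primary read starts with U; responder reads of
    ping-pong pairs acquire 10A automatically from the pair geometry.
    """

    total_reads: int = 100_000
    length_peaks: tuple[int, int] = (26, 30)
    length_weights: tuple[float, float] = (0.35, 0.65)
    length_sd: float = 0.9
    p_1u: float = 0.75
    pingpong_fraction: float = 0.25
    noise_fraction: float = 0.2
    main_strand_fraction: float = 0.85
    multimap_fraction: float = 0.02

    def validate(self) -> None:
        for name in (
            "p_1u",
            "pingpong_fraction",
            "noise_fraction",
            "main_strand_fraction",
            "multimap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"read_model.{name}={v} outside [0, 1]")


@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    ``species_tree`` lists (name, divergence-from-root in My) on a ladder
    topology: the pairwise split time of two species is the larger of
    their two times.  Default times 1/25/65 My echo the macaque pair,
    the hominoid-cercopithecoid split and the haplorrhine-strepsirrhine
    split of the primate phylogeny.
    """

    species_tree: tuple[tuple[str, float], ...] = (
        ("spcA", 1.0),
        ("spcB", 25.0),
        ("spcC", 65.0),
    )
    subst_rate: float = 0.002  # substitutions / site / My
    genome_length: int = 5_000_000
    chrom_name: str = "chr1"
    n_genes: int = 160
    exon_count_range: tuple[int, int] = (3, 8)
    exon_size_range: tuple[int, int] = (150, 400)
    intron_size_range: tuple[int, int] = (200, 2000)
    lnc_fraction: float = 0.08
    paralog_fraction: float = 0.12
    paralog_divergence: float = 0.10
    n_clusters: int = 20
    cluster_size_range: tuple[int, int] = (6_000, 12_000)
    frac_26_leaning: float = 0.25
    n_pseudogenes: int = 60
    processed_fraction: float = 0.6
    pg_in_cluster_fraction: float = 0.5
    pg_reverse_fraction: float = 0.6
    pg_intronic_fraction: float = 0.2
    pg_divergence_range: tuple[float, float] = (0.02, 0.10)
    pg_truncation_prob: float = 0.3
    n_repeats: int = 300
    repeats_per_cluster: int = 3
    repeat_families: tuple[tuple[str, float, float, int, int], ...] = (
        # (family, mean divergence %, sd, min len, max len)
        ("SINE/Alu", 12.0, 3.0, 150, 400),
        ("LINE/L1", 18.0, 4.0, 500, 1500),
        ("LTR/ERVL", 15.0, 3.5, 300, 900),
    )
    old_repeat_shift: float = 8.0  # added to divergence in category-1 clusters
    young_repeat_shift: float = -5.0  # category-2/3 clusters
    loss_rate_per_my: float = 0.0105
    silent_rate_per_my: float = 0.004
    expression_sigma: float = 0.04  # sd on log10 expression per sqrt(My)
    expression_base_sigma: float = 0.25
    n_peaks: int = 200
    peak_cluster_enrichment: float = 3.0
    peak_width: int = 500
    centromere_width: int = 100_000
    gc_block: int = 100_000
    gc_mean: float = 0.42
    gc_sd: float = 0.05
    read_model: ReadModel = field(default_factory=ReadModel)
    seed: int = 42

    def validate(self) -> None:
        self.read_model.validate()
        for name in (
            "lnc_fraction",
            "paralog_fraction",
            "frac_26_leaning",
            "processed_fraction",
            "pg_in_cluster_fraction",
            "pg_reverse_fraction",
            "pg_intronic_fraction",
            "pg_truncation_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 1_000_000:
            raise ValueError("genome_length must be >= 1 Mb")

    def split_time(self, a: str, b: str) -> float:
        times = dict(self.species_tree)
        if a == b:
            return 0.0
        return max(times[a], times[b])


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass
class ClusterTruth:
    cluster_id: str
    chrom: str
    start: int
    end: int
    main_strand: str
    leaning: int  # 26 or 30
    present: dict[str, bool]
    expressed: dict[str, bool]
    planted_reads: dict[str, int] = field(default_factory=dict)

    @property
    def category(self) -> int:
        if not all(self.present.values()):
            return 3
        if not all(self.expressed.values()):
            return 2
        return 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PseudogeneTruth:
    pg_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    klass: str  # processed | unprocessed
    divergence: float
    in_cluster: str | None = None
    orientation: str | None = None  # parallel | reverse | None
    intronic_host: str | None = None
    n_source_exons: int = 1


@dataclass
class SpeciesFixture:
    name: str
    time: float
    genome: GenomeSequences
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    reads: list[MappedRead]
    cds: dict[str, str]
    cdna: dict[str, str]
    peaks: list[tuple[str, int, int]]
    centromere: list[tuple[str, int, int]]
    lost_clusters: set[str]
    silent_clusters: set[str]
    read_truth: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    species: dict[str, SpeciesFixture]
    clusters: list[ClusterTruth]
    pseudogenes: list[PseudogeneTruth]
    expression: pd.DataFrame  # planted read counts, clusters x species

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for name, fx in self.species.items():
            d = outdir / name
            d.mkdir(parents=True, exist_ok=True)
            core_io.write_fasta(fx.genome.records, d / "genome.fa")
            core_io.write_gff(fx.genes, d / "genes.gff3")
            core_io.write_repeatmasker(fx.repeats, d / "repeats.out")
            core_io.write_alignments_sam(
                fx.reads, fx.genome.lengths(), d / "reads.sam"
            )
            core_io.write_fasta(fx.cds, d / "cds.fa")
            core_io.write_fasta(fx.cdna, d / "cdna.fa")
            core_io.write_bed(fx.peaks, d / "peaks.bed")
            core_io.write_bed(fx.centromere, d / "centromere.bed")
            fx.read_truth.to_csv(d / "read_truth.tsv", sep="\t", index=False)
        t = outdir / "truth"
        t.mkdir(parents=True, exist_ok=True)
        self.cluster_table().to_csv(t / "clusters.tsv", sep="\t", index=False)
        self.pseudogene_table().to_csv(
            t / "pseudogenes.tsv", sep="\t", index=False
        )
        self.expression.to_csv(t / "expression.tsv", sep="\t")
        self.ortholog_table().to_csv(t / "orthologs.tsv", sep="\t", index=False)
        with open(outdir / "config.txt", "w") as fh:
            for k, v in asdict(self.config).items():
                fh.write(f"{k}\t{v}\n")

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "main_strand": c.main_strand,
                "leaning": c.leaning,
                "category": c.category,
            }
            for sp in self.species:
                row[f"present_{sp}"] = c.present[sp]
                row[f"expressed_{sp}"] = c.expressed[sp]
            rows.append(row)
        return pd.DataFrame(rows)

    def pseudogene_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.pseudogenes])

    def ortholog_table(self) -> pd.DataFrame:
        ref = next(iter(self.species.values()))
        ids = [g.gene_id for g in ref.genes if g.biotype == "protein_coding"]
        return pd.DataFrame({sp: ids for sp in self.species})


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def jc_expected_identity(d: float) -> float:
    """Expected observed identity after divergence ``d`` subst/site under
    the Jukes-Cantor model: 1/4 + 3/4 exp(-4d/3)."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def _evolve_codes(codes: np.ndarray, divergence: float, rng) -> np.ndarray:
    """Per-site substitutions at JC substitution load ``divergence``.

    The per-site probability of an observed change is
    3/4 (1 - exp(-4d/3)), i.e. multiple hits are collapsed."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence == 0:
        return codes.copy()
    p = 0.75 * (1.0 - math.exp(-4.0 * divergence / 3.0))
    out = codes.copy()
    hit = np.nonzero(rng.random(len(codes)) < p)[0]
    shift = rng.integers(1, 4, size=len(hit)).astype(np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


def evolve_sequence(seq: str, divergence: float, seed: int) -> str:
    """Mutate ``seq`` by Jukes-Cantor substitutions (length preserved).

    ``divergence`` is the substitution load in substitutions/site; the
    expected realized identity is ``jc_expected_identity(divergence)``.
    Deterministic given ``seed``.  Non-ACGT input raises ValueError.
    """
    rng = np.random.default_rng(seed)
    return _decode(_evolve_codes(_encode(seq), divergence, rng))


# ---------------------------------------------------------------------------
# root genome layout
# ---------------------------------------------------------------------------


class _Layout:
    """Root-genome feature layout shared by all species."""

    def __init__(self, cfg: SimulationConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.genes: list[GeneModel] = []
        self.paralog_parent: dict[str, str] = {}
        self.clusters: list[ClusterTruth] = []
        self.pseudogenes: list[PseudogeneTruth] = []
        self.repeats: list[RepeatFeature] = []
        L = cfg.genome_length
        c0 = L // 2 - cfg.centromere_width // 2
        self.centromere = (c0, c0 + cfg.centromere_width)
        self.occupied: list[tuple[int, int]] = [self.centromere]
        self._place_genes_and_clusters()

    # -- placement helpers ------------------------------------------------

    def _gene_structure(self):
        cfg, rng = self.cfg, self.rng
        n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        ex_sizes = rng.integers(
            cfg.exon_size_range[0], cfg.exon_size_range[1] + 1, size=n_ex
        )
        in_sizes = rng.integers(
            cfg.intron_size_range[0], cfg.intron_size_range[1] + 1,
            size=max(n_ex - 1, 0),
        )
        return list(map(int, ex_sizes)), list(map(int, in_sizes))

    def _place_genes_and_clusters(self):
        cfg, rng = self.cfg, self.rng
        n_gaps = cfg.n_clusters + 1
        base, rem = divmod(cfg.n_genes, n_gaps)
        genes_per_gap = [base + (1 if i < rem else 0) for i in range(n_gaps)]
        cursor = 10_000
        gi = 0
        prev_structure = None
        prev_gene_id = None
        for gap_i in range(n_gaps):
            for _ in range(genes_per_gap[gap_i]):
                is_paralog = (
                    prev_structure is not None
                    and rng.random() < cfg.paralog_fraction
                )
                if is_paralog:
                    ex_sizes, in_sizes = prev_structure
                else:
                    ex_sizes, in_sizes = self._gene_structure()
                span = sum(ex_sizes) + sum(in_sizes)
                cursor = self._skip_centromere(cursor, span)
                start = cursor
                exons = []
                pos = start
                for k, es in enumerate(ex_sizes):
                    exons.append((pos, pos + es))
                    pos += es
                    if k < len(in_sizes):
                        pos += in_sizes[k]
                strand = "+" if rng.random() < 0.5 else "-"
                biotype = (
                    "lncRNA"
                    if (not is_paralog and rng.random() < cfg.lnc_fraction)
                    else "protein_coding"
                )
                gene = GeneModel(
                    gene_id=f"g{gi:04d}",
                    chrom=cfg.chrom_name,
                    start=start,
                    end=start + span,
                    strand=strand,
                    exons=exons,
                    biotype=biotype,
                )
                self.genes.append(gene)
                self.occupied.append((start, start + span))
                if is_paralog and biotype == "protein_coding":
                    self.paralog_parent[gene.gene_id] = prev_gene_id
                if biotype == "protein_coding" and not is_paralog:
                    prev_structure = (ex_sizes, in_sizes)
                    prev_gene_id = gene.gene_id
                gi += 1
                cursor = start + span + int(rng.integers(2_000, 8_000))
            if gap_i < cfg.n_clusters:
                size = int(
                    rng.integers(
                        cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1
                    )
                )
                cursor = self._skip_centromere(cursor, size)
                self.clusters.append(
                    ClusterTruth(
                        cluster_id=f"pic{gap_i:03d}",
                        chrom=cfg.chrom_name,
                        start=cursor,
                        end=cursor + size,
                        main_strand="+" if rng.random() < 0.5 else "-",
                        leaning=26 if rng.random() < cfg.frac_26_leaning else 30,
                        present={},
                        expressed={},
                    )
                )
                self.occupied.append((cursor, cursor + size))
                cursor += size + int(rng.integers(12_000, 20_000))
        if cursor > cfg.genome_length - 10_000:
            raise ValueError(
                "infeasible packing: features exceed genome length "
                f"({cursor} > {cfg.genome_length - 10_000})"
            )

    def _skip_centromere(self, cursor: int, span: int) -> int:
        c0, c1 = self.centromere
        if cursor + span + 1000 > c0 and cursor < c1 + 1000:
            return c1 + 1000
        return cursor

    def free_gaps(self, min_len: int) -> list[tuple[int, int]]:
        occ = core_io.merge_intervals(sorted(self.occupied), max_gap=1)
        gaps = []
        prev = 5_000
        for s, e in occ:
            if s - prev >= min_len:
                gaps.append((prev, s))
            prev = max(prev, e)
        tail = self.cfg.genome_length - 5_000
        if tail - prev >= min_len:
            gaps.append((prev, tail))
        return gaps

    def place_in_free_space(self, length: int, margin: int = 200) -> int | None:
        gaps = self.free_gaps(length + 2 * margin)
        if not gaps:
            return None
        widths = np.array([e - s for s, e in gaps], dtype=float)
        gi = int(self.rng.choice(len(gaps), p=widths / widths.sum()))
        s, e = gaps[gi]
        start = int(self.rng.integers(s + margin, e - margin - length + 1))
        self.occupied.append((start, start + length))
        return start


# ---------------------------------------------------------------------------
# pseudogene planting
# ---------------------------------------------------------------------------


def plant_pseudogene(
    codes: np.ndarray,
    parent: GeneModel,
    klass: str,
    target_start: int,
    strand: str,
    divergence: float,
    rng,
    gene_exons: Sequence[tuple[int, int]] = (),
    truncate_keep: float = 1.0,
) -> PseudogeneTruth:
    """Write a mutated copy of ``parent`` into the genome at ``target_start``.

    processed: spliced exon concatenation (optionally 5'-truncated);
    unprocessed: genomic copy retaining introns.  The inserted sequence is
    evolved to ``divergence`` substitutions/site.  Raises if the target
    span overlaps any interval in ``gene_exons``.
    """
    if klass == "processed":
        parts = [codes[s:e] for s, e in parent.exons]
        src = np.concatenate(parts)
        if parent.strand == "-":
            src = _revcomp_codes(src)
        if truncate_keep < 1.0:
            keep = max(100, int(len(src) * truncate_keep))
            src = src[len(src) - keep :]  # keep the 3' end
        n_src_exons = parent.n_exons
    elif klass == "unprocessed":
        src = codes[parent.start : parent.end]
        if parent.strand == "-":
            src = _revcomp_codes(src)
        n_src_exons = parent.n_exons
    else:
        raise ValueError(f"unknown pseudogene class {klass!r}")
    ins = _evolve_codes(src, divergence, rng)
    if strand == "-":
        ins = _revcomp_codes(ins)
    t_end = target_start + len(ins)
    for es, ee in gene_exons:
        if max(target_start, es) < min(t_end, ee):
            raise ValueError(
                f"pseudogene target {target_start}-{t_end} overlaps gene exon "
                f"{es}-{ee}"
            )
    codes[target_start:t_end] = ins
    return PseudogeneTruth(
        pg_id="",
        chrom=parent.chrom,
        start=target_start,
        end=t_end,
        strand=strand,
        parent_gene_id=parent.gene_id,
        klass=klass,
        divergence=divergence,
        n_source_exons=n_src_exons,
    )


def _plan_pseudogenes(layout: _Layout, codes: np.ndarray, rng) -> None:
    cfg = layout.cfg
    coding = [
        g for g in layout.genes
        if g.biotype == "protein_coding" and g.gene_id not in layout.paralog_parent
    ]
    all_exons = [e for g in layout.genes for e in g.exons]
    cluster_occ: dict[str, list[tuple[int, int]]] = {
        c.cluster_id: [] for c in layout.clusters
    }
    n_in_cluster = int(round(cfg.n_pseudogenes * cfg.pg_in_cluster_fraction))
    pgs: list[PseudogeneTruth] = []
    for i in range(cfg.n_pseudogenes):
        klass = (
            "processed"
            if rng.random() < cfg.processed_fraction
            else "unprocessed"
        )
        div = rng.uniform(*cfg.pg_divergence_range)
        truncate = (
            rng.uniform(0.5, 0.9)
            if (klass == "processed" and rng.random() < cfg.pg_truncation_prob)
            else 1.0
        )
        placed = None
        for _attempt in range(500):
            parent = coding[int(rng.integers(len(coding)))]
            if klass == "processed":
                pg_len = max(100, int(parent.cds_length * truncate)) if truncate < 1.0 else parent.cds_length
            else:
                pg_len = parent.end - parent.start
            if i < n_in_cluster:
                c = layout.clusters[int(rng.integers(len(layout.clusters)))]
                if pg_len + 800 > c.end - c.start:
                    continue
                start = int(rng.integers(c.start + 300, c.end - 300 - pg_len))
                if any(
                    max(start, s) < min(start + pg_len, e)
                    for s, e in cluster_occ[c.cluster_id]
                ):
                    continue
                reverse = rng.random() < cfg.pg_reverse_fraction
                # strand on which the parent-sense sequence lies
                if reverse:
                    strand = "-" if c.main_strand == "+" else "+"
                else:
                    strand = c.main_strand
                placed = (parent, start, strand, c.cluster_id,
                          "reverse" if reverse else "parallel", None)
                cluster_occ[c.cluster_id].append((start, start + pg_len))
                break
            elif rng.random() < cfg.pg_intronic_fraction and klass == "processed":
                hosts = [
                    g for g in layout.genes
                    if g.largest_intron >= pg_len + 200 and g.gene_id != parent.gene_id
                ]
                if not hosts:
                    continue
                host = hosts[int(rng.integers(len(hosts)))]
                gaps = [
                    (a[1], b[0])
                    for a, b in zip(host.exons, host.exons[1:])
                ]
                gaps = [g for g in gaps if g[1] - g[0] >= pg_len + 200]
                s, e = gaps[int(rng.integers(len(gaps)))]
                start = int(rng.integers(s + 100, e - 100 - pg_len))
                if any(
                    max(start, p.start) < min(start + pg_len, p.end) for p in pgs
                ):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                placed = (parent, start, strand, None, None, host.gene_id)
                break
            else:
                start = layout.place_in_free_space(pg_len)
                if start is None:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                placed = (parent, start, strand, None, None, None)
                break
        if placed is None:
            raise ValueError("could not place pseudogene; genome too crowded")
        parent, start, strand, in_cluster, orientation, host = placed
        rec = plant_pseudogene(
            codes,
            parent,
            klass,
            start,
            strand,
            div,
            rng,
            gene_exons=all_exons,
            truncate_keep=truncate,
        )
        rec.pg_id = f"pg{i:03d}"
        rec.in_cluster = in_cluster
        rec.orientation = orientation
        rec.intronic_host = host
        pgs.append(rec)
    layout.pseudogenes = pgs


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------


def _plan_repeats(layout: _Layout, codes: np.ndarray, rng) -> None:
    cfg = layout.cfg
    fam_specs = list(cfg.repeat_families)
    consensus = {
        fam: rng.integers(0, 4, size=lmax).astype(np.uint8)
        for fam, _m, _s, _lmin, lmax in fam_specs
    }
    feats: list[RepeatFeature] = []
    pg_spans = [(p.start, p.end) for p in layout.pseudogenes]

    def _add(start: int, fam_spec, div_shift: float):
        fam, mdiv, sdiv, lmin, lmax = fam_spec
        length = int(rng.integers(lmin, lmax + 1))
        div = float(np.clip(rng.normal(mdiv + div_shift, sdiv), 0.5, 45.0))
        seg = consensus[fam][:length]
        seg = _evolve_codes(seg, div / 100.0, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seg = _revcomp_codes(seg)
        codes[start : start + length] = seg
        feats.append(
            RepeatFeature(
                chrom=cfg.chrom_name,
                start=start,
                end=start + length,
                strand=strand,
                family=fam,
                divergence=div,
            )
        )

    # repeats inside clusters, age tied to cluster category
    for c in layout.clusters:
        shift = (
            cfg.old_repeat_shift if c.category == 1 else cfg.young_repeat_shift
        )
        placed = 0
        for _attempt in range(60):
            if placed >= cfg.repeats_per_cluster:
                break
            fam_spec = fam_specs[int(rng.integers(len(fam_specs)))]
            length = fam_spec[3]
            start = int(rng.integers(c.start + 100, c.end - 100 - fam_spec[4]))
            span = (start, start + fam_spec[4])
            if any(max(span[0], s) < min(span[1], e) for s, e in pg_spans):
                continue
            if any(
                f.chrom == cfg.chrom_name
                and max(span[0], f.start) < min(span[1], f.end)
                for f in feats
            ):
                continue
            _add(start, fam_spec, shift)
            placed += 1
    # genome-wide repeats in free space
    n_left = max(0, cfg.n_repeats - len(feats))
    for _ in range(n_left):
        fam_spec = fam_specs[int(rng.integers(len(fam_specs)))]
        start = layout.place_in_free_space(fam_spec[4])
        if start is None:
            break
        _add(start, fam_spec, 0.0)
    layout.repeats = sorted(feats, key=lambda f: f.start)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _draw_lengths(n: int, model: ReadModel, weights, rng) -> np.ndarray:
    comp = rng.random(n) >= weights[0]
    peaks = np.where(comp, model.length_peaks[1], model.length_peaks[0])
    lens = np.rint(rng.normal(peaks, model.length_sd)).astype(int)
    return np.clip(lens, 24, 32)


def _pick_start_with_base(
    codes: np.ndarray, lo: int, hi: int, strand: str, want_t: bool, rng
) -> int:
    """Pick a 5'-end coordinate in [lo, hi) whose first base is (not) U."""
    target = _T if strand == "+" else _A  # minus-strand U == genomic A
    for _ in range(200):
        p = int(rng.integers(lo, hi))
        if (codes[p] == target) == want_t:
            return p
    return int(rng.integers(lo, hi))  # degenerate composition; give up


def _read_from(codes: np.ndarray, chrom: str, five: int, length: int,
               strand: str) -> MappedRead | None:
    if strand == "+":
        start = five
    else:
        start = five - length + 1
    if start < 0 or start + length > len(codes):
        return None
    seg = codes[start : start + length]
    if strand == "-":
        seg = _revcomp_codes(seg)
    return MappedRead(
        sequence=_decode(seg), placements=[(chrom, start, strand)], copies=1.0
    )


def simulate_cluster_reads(
    codes: np.ndarray,
    chrom: str,
    start: int,
    end: int,
    main_strand: str,
    leaning: int,
    n_reads: int,
    model: ReadModel,
    rng,
) -> list[tuple[MappedRead, bool]]:
    """Simulate ``n_reads`` single-copy reads from one cluster.

    Returns (read, is_pingpong) tuples; ping-pong pairs sit on opposite
    strands with exactly 10-nt 5' overlaps, and responder 10A follows from
    primary 1U by complementarity.
    """
    if end - start < 40:
        raise ValueError("cluster shorter than maximum read length")
    weights = (
        (0.75, 0.25) if leaning == 26 else (0.25, 0.75)
    )
    out: list[tuple[MappedRead, bool]] = []
    lo, hi = start + 35, end - 35
    n_pp_pairs = int(round(n_reads * model.pingpong_fraction / 2.0))
    other = "-" if main_strand == "+" else "+"
    for _ in range(n_pp_pairs):
        l1, l2 = _draw_lengths(2, model, weights, rng)
        want_t = rng.random() < model.p_1u
        p5 = _pick_start_with_base(codes, lo, hi, main_strand, want_t, rng)
        if main_strand == "+":
            q5 = p5 + 9
        else:
            q5 = p5 - 9
        r1 = _read_from(codes, chrom, p5, int(l1), main_strand)
        r2 = _read_from(codes, chrom, q5, int(l2), other)
        if r1 is None or r2 is None:
            continue
        out.append((r1, True))
        out.append((r2, True))
    n_single = n_reads - 2 * n_pp_pairs
    for _ in range(n_single):
        strand = (
            main_strand
            if rng.random() < model.main_strand_fraction
            else other
        )
        want_t = rng.random() < model.p_1u
        p5 = _pick_start_with_base(codes, lo, hi, strand, want_t, rng)
        (length,) = _draw_lengths(1, model, weights, rng)
        r = _read_from(codes, chrom, p5, int(length), strand)
        if r is not None:
            out.append((r, False))
    return out


def _collapse(
    tagged: list[tuple[MappedRead, str, bool]]
) -> tuple[list[MappedRead], pd.DataFrame]:
    """Collapse single-copy reads by sequence; keep origin of first sight."""
    by_seq: dict[str, MappedRead] = {}
    origin: dict[str, tuple[str, bool]] = {}
    for read, orig, is_pp in tagged:
        prev = by_seq.get(read.sequence)
        if prev is None:
            by_seq[read.sequence] = read
            origin[read.sequence] = (orig, is_pp)
        else:
            prev.copies += read.copies
            for pl in read.placements:
                if pl not in prev.placements:
                    prev.placements.append(pl)
    truth = pd.DataFrame(
        {
            "sequence": list(by_seq),
            "origin": [origin[s][0] for s in by_seq],
            "is_pingpong": [origin[s][1] for s in by_seq],
            "copies": [by_seq[s].copies for s in by_seq],
        }
    )
    return list(by_seq.values()), truth


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------


def _expression_weights(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Planted expression levels per cluster and species.

    Each cluster has a base log10 level shared by all species; each
    species adds an independent drift term with standard deviation
    ``expression_sigma * sqrt(divergence time)``.  Between-species
    expression correlation therefore decays with time, so clustering the
    expression matrix recovers the species ordering of the tree."""
    names = [n for n, _t in cfg.species_tree]
    times = np.array([t for _n, t in cfg.species_tree])
    base = rng.normal(0.0, cfg.expression_base_sigma, size=cfg.n_clusters)
    dev = rng.standard_normal((cfg.n_clusters, len(names))) * (
        cfg.expression_sigma * np.sqrt(times)[None, :]
    )
    log10 = base[:, None] + dev
    return pd.DataFrame(
        10.0**log10,
        index=[f"pic{i:03d}" for i in range(cfg.n_clusters)],
        columns=names,
    )


def _plan_fates(cfg: SimulationConfig, layout: _Layout, rng) -> None:
    """Deterministic per-species lost/silent cluster counts from divergence."""
    n = cfg.n_clusters
    for name, t in cfg.species_tree:
        lost_frac = 1.0 - math.exp(-cfg.loss_rate_per_my * t)
        silent_frac = 1.0 - math.exp(-cfg.silent_rate_per_my * t)
        n_lost = int(round(lost_frac * n))
        lost = set(rng.choice(n, size=n_lost, replace=False).tolist())
        remaining = [i for i in range(n) if i not in lost]
        n_silent = min(int(round(silent_frac * n)), len(remaining))
        silent = set(
            rng.choice(len(remaining), size=n_silent, replace=False).tolist()
        )
        silent = {remaining[i] for i in silent}
        for i, c in enumerate(layout.clusters):
            c.present[name] = i not in lost
            c.expressed[name] = i not in lost and i not in silent


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the full multi-species study in memory."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length

    # root genome with block-varying GC
    n_blocks = max(1, L // cfg.gc_block)
    block_gc = np.clip(
        rng.normal(cfg.gc_mean, cfg.gc_sd, size=n_blocks + 1), 0.30, 0.60
    )
    codes = np.empty(L, dtype=np.uint8)
    for b in range(n_blocks + 1):
        s, e = b * cfg.gc_block, min((b + 1) * cfg.gc_block, L)
        if s >= e:
            break
        gc = block_gc[b]
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes[s:e] = rng.choice(4, size=e - s, p=p).astype(np.uint8)

    layout = _Layout(cfg, rng)
    _plan_fates(cfg, layout, rng)

    # paralog sequence identity: copy parent span, mutated
    gene_by_id = {g.gene_id: g for g in layout.genes}
    for pid, parent_id in layout.paralog_parent.items():
        g, par = gene_by_id[pid], gene_by_id[parent_id]
        src = codes[par.start : par.end]
        codes[g.start : g.end] = _evolve_codes(
            src[: g.end - g.start], cfg.paralog_divergence, rng
        )

    _plan_pseudogenes(layout, codes, rng)
    _plan_repeats(layout, codes, rng)

    expression = _expression_weights(cfg, rng)
    repeat_spans = [(f.start, f.end) for f in layout.repeats]
    cen = [(cfg.chrom_name, *layout.centromere)]

    species: dict[str, SpeciesFixture] = {}
    for name, t in cfg.species_tree:
        sp_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, zlib.crc32(name.encode())])
        )
        d = cfg.subst_rate * t
        sp_codes = _evolve_codes(codes, d, sp_rng)
        lost = {
            c.cluster_id for c in layout.clusters if not c.present[name]
        }
        silent = {
            c.cluster_id
            for c in layout.clusters
            if c.present[name] and not c.expressed[name]
        }
        for c in layout.clusters:
            if c.cluster_id in lost:
                sp_codes[c.start : c.end] = sp_rng.integers(
                    0, 4, size=c.end - c.start
                ).astype(np.uint8)

        reads, read_truth, planted = _simulate_library(
            cfg, layout, sp_codes, name, expression[name], sp_rng
        )
        for c in layout.clusters:
            c.planted_reads[name] = planted.get(c.cluster_id, 0)

        seq = _decode(sp_codes)
        # lowercase masking over repeat annotation
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for s, e in repeat_spans:
            arr[s:e] = arr[s:e] + 32  # ASCII to lowercase
        genome = GenomeSequences({cfg.chrom_name: arr.tobytes().decode("ascii")})

        cds = {
            g.gene_id: g.spliced_sequence(genome)
            for g in layout.genes
            if g.biotype == "protein_coding"
        }
        cdna = dict(cds)

        peaks = _simulate_peaks(cfg, layout, name, sp_rng)
        species[name] = SpeciesFixture(
            name=name,
            time=t,
            genome=genome,
            genes=layout.genes,
            repeats=layout.repeats,
            reads=reads,
            cds=cds,
            cdna=cdna,
            peaks=peaks,
            centromere=cen,
            lost_clusters=lost,
            silent_clusters=silent,
            read_truth=read_truth,
        )

    return SimulatedStudy(
        config=cfg,
        species=species,
        clusters=layout.clusters,
        pseudogenes=layout.pseudogenes,
        expression=expression,
    )


def _simulate_library(cfg, layout, sp_codes, name, expr, rng):
    model = cfg.read_model
    active = [
        c for c in layout.clusters if c.present[name] and c.expressed[name]
    ]
    n_noise = int(round(model.total_reads * model.noise_fraction))
    n_cluster_reads = model.total_reads - n_noise
    tagged: list[tuple[MappedRead, str, bool]] = []
    planted: dict[str, int] = {}
    if active:
        w = np.array([expr[c.cluster_id] for c in active])
        counts = rng.multinomial(n_cluster_reads, w / w.sum())
        for c, n_c in zip(active, counts):
            planted[c.cluster_id] = int(n_c)
            if n_c == 0:
                continue
            for read, is_pp in simulate_cluster_reads(
                sp_codes, cfg.chrom_name, c.start, c.end, c.main_strand,
                c.leaning, int(n_c), model, rng,
            ):
                tagged.append((read, c.cluster_id, is_pp))
    # uniform background noise
    n_multi = int(round(n_noise * model.multimap_fraction))
    L = len(sp_codes)
    free_gaps = layout.free_gaps(100)
    for i in range(n_noise):
        strand = "+" if rng.random() < 0.5 else "-"
        (length,) = _draw_lengths(1, model, model.length_weights, rng)
        start = int(rng.integers(50, L - 50))
        five = start if strand == "+" else start + int(length) - 1
        r = _read_from(sp_codes, cfg.chrom_name, five, int(length), strand)
        if r is None:
            continue
        if i < n_multi and free_gaps:
            # plant an identical second copy in feature-free space
            gs, ge = free_gaps[int(rng.integers(len(free_gaps)))]
            pos2 = int(rng.integers(gs, ge - int(length)))
            seg = sp_codes[start : start + int(length)]
            sp_codes[pos2 : pos2 + int(length)] = seg
            r.placements.append((cfg.chrom_name, pos2, strand))
            r.copies = 2.0
        tagged.append((r, "background", False))
    reads, truth = _collapse(tagged)
    return reads, truth, planted


def _simulate_peaks(cfg, layout, name, rng):
    cluster_spans = [
        (c.start, c.end)
        for c in layout.clusters
        if c.present[name]
    ]
    cluster_bp = sum(e - s for s, e in cluster_spans)
    L = cfg.genome_length
    p_cluster = (
        cluster_bp * cfg.peak_cluster_enrichment
        / (cluster_bp * cfg.peak_cluster_enrichment + (L - cluster_bp))
    )
    peaks = []
    for _ in range(cfg.n_peaks):
        if cluster_spans and rng.random() < p_cluster:
            s, e = cluster_spans[int(rng.integers(len(cluster_spans)))]
            mid = int(rng.integers(s, e))
        else:
            mid = int(rng.integers(0, L))
        half = cfg.peak_width // 2
        peaks.append((cfg.chrom_name, max(0, mid - half), min(L, mid + half)))
    return sorted(peaks)


def simulate_species_set(
    config: SimulationConfig | None = None, outdir: str | Path | None = None
) -> SimulatedStudy:
    """Generate the study and (optionally) write all fixture files."""
    study = simulate_study(config)
    if outdir is not None:
        study.write(outdir)
    return study
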