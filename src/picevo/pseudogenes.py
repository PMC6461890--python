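"""Pseudogene prediction, classification and piRNA production scans.

Prediction pipeline: (1) similarity search of the CDS catalog against the
repeat-masked genome; (2) hits overlapping annotated gene exons are
discarded; (3) overlapping hits are merged into blocks (pseudo-exons);
(4) adjacent blocks of the same parent are joined into units when the gap
does not exceed 1.5x the largest parent intron, floored at 30 kb;
(5) the parent gene is assigned by mean identity x query coverage (ties by
best e-value, then gene id); (6) units spanning < 300 bp or covering < 10%
of the parent CDS are discarded; (7) units are classified processed when
the number of pseudo-exons is at most half the expected pseudo-exon count
(query coverage x parent exon count), else unprocessed.

Orientation relative to the main transcription strand of a containing
piRNA cluster (parallel/reverse) drives the gene-antisense targeting
analyses; 32-nt window scans correlate local identity-to-parent with
antisense read density.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import core_io
from .cluster_caller import ClusterLocus
from .core_io import GeneModel, GenomeSequences, MappedRead
from .engine import KmerAligner, SimilarityHit

MIN_UNIT_SPAN = 300
MIN_QUERY_COVERAGE = 0.10
INTRON_GAP_FACTOR = 1.5
MIN_GAP_FLOOR = 30_000
HOMOLOG_MIN_ALIGNED = 150
HOMOLOG_MIN_COVERAGE = 0.30
WINDOW = 32


@dataclass
class PseudogeneUnit:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    identity_to_parent: float
    query_coverage: float
    pseudo_exons: int
    klass: str  # processed | unprocessed
    in_cluster: str | None = None
    orientation: str | None = None  # parallel | reverse | None
    intronic_host: str | None = None
    hits: list[SimilarityHit] = field(default_factory=list, repr=False)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def predict_pseudogenes(
    cds_catalog: Mapping[str, str],
    genome: GenomeSequences,
    genes: Sequence[GeneModel],
    engine: KmerAligner | None = None,
) -> list[PseudogeneUnit]:
    """Annotate pseudogene units from CDS-versus-masked-genome search."""
    engine = engine or KmerAligner()
    gene_by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in cds_catalog if gid not in gene_by_id]
    if missing:
        warnings.warn(
            f"{len(missing)} CDS records without annotation linkage skipped"
        )
    queries = {
        gid: seq for gid, seq in cds_catalog.items() if gid in gene_by_id
    }
    hits = engine.search(queries, genome.records)

    # (2) drop hits overlapping annotated exons
    exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for s, e in g.exons:
            exon_trees[g.chrom][s:e] = g.gene_id
    hits = [
        h
        for h in hits
        if not exon_trees[h.subject_id].overlap(h.s_start, h.s_end)
    ]

    # (3)-(4): per parent, merge overlapping hits then join within gap
    candidates: list[dict] = []
    by_parent: dict[tuple[str, str], list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        by_parent[(h.query_id, h.subject_id)].append(h)
    for (parent_id, chrom), ph in by_parent.items():
        gene = gene_by_id[parent_id]
        max_gap = max(INTRON_GAP_FACTOR * gene.largest_intron, MIN_GAP_FLOOR)
        blocks = _merge_blocks(ph)
        unit_blocks: list[list[dict]] = [[blocks[0]]]
        for b in blocks[1:]:
            if b["start"] - unit_blocks[-1][-1]["end"] > max_gap:
                unit_blocks.append([])
            unit_blocks[-1].append(b)
        for ub in unit_blocks:
            candidates.append(
                {
                    "parent": parent_id,
                    "chrom": chrom,
                    "start": ub[0]["start"],
                    "end": ub[-1]["end"],
                    "blocks": ub,
                    "hits": [h for b in ub for h in b["hits"]],
                }
            )

    # (5) competing parents over the same locus: keep the best-scoring one
    units = _resolve_parents(candidates, len_by_parent={
        gid: len(seq) for gid, seq in queries.items()
    })

    # (6) final filters + (7) classification
    out: list[PseudogeneUnit] = []
    for i, u in enumerate(sorted(units, key=lambda u: (u["chrom"], u["start"]))):
        if u["end"] - u["start"] < MIN_UNIT_SPAN:
            continue
        if u["query_coverage"] < MIN_QUERY_COVERAGE:
            continue
        gene = gene_by_id[u["parent"]]
        klass = classify_unit(
            len(u["blocks"]), u["query_coverage"], gene.n_exons
        )
        out.append(
            PseudogeneUnit(
                id=f"ps{i:03d}",
                chrom=u["chrom"],
                start=u["start"],
                end=u["end"],
                strand=u["strand"],
                parent_gene_id=u["parent"],
                identity_to_parent=u["identity"],
                query_coverage=u["query_coverage"],
                pseudo_exons=len(u["blocks"]),
                klass=klass,
                hits=u["hits"],
            )
        )
    return out


def _merge_blocks(hits: Sequence[SimilarityHit]) -> list[dict]:
    """Merge genomically overlapping hits into pseudo-exon blocks."""
    hits = sorted(hits, key=lambda h: h.s_start)
    blocks: list[dict] = []
    for h in hits:
        if blocks and h.s_start < blocks[-1]["end"]:
            b = blocks[-1]
            b["end"] = max(b["end"], h.s_end)
            b["hits"].append(h)
        else:
            blocks.append({"start": h.s_start, "end": h.s_end, "hits": [h]})
    return blocks


def _unit_stats(u: dict, query_len: int) -> None:
    hits = u["hits"]
    total = sum(h.aligned_bp for h in hits)
    u["identity"] = sum(h.identity * h.aligned_bp for h in hits) / total
    covered = core_io.merge_intervals([(h.q_start, h.q_end) for h in hits])
    u["query_coverage"] = sum(e - s for s, e in covered) / query_len
    plus = sum(h.aligned_bp for h in hits if h.strand == "+")
    u["strand"] = "+" if plus * 2 >= total else "-"
    u["best_evalue"] = min(h.e_value for h in hits)


def _resolve_parents(candidates: list[dict], len_by_parent) -> list[dict]:
    for u in candidates:
        _unit_stats(u, len_by_parent[u["parent"]])
    candidates.sort(
        key=lambda u: (
            -(u["identity"] * u["query_coverage"]),
            u["best_evalue"],
            u["parent"],
        )
    )
    taken: dict[str, IntervalTree] = defaultdict(IntervalTree)
    kept: list[dict] = []
    for u in candidates:
        if taken[u["chrom"]].overlap(u["start"], u["end"]):
            continue
        taken[u["chrom"]][u["start"]:u["end"]] = True
        kept.append(u)
    return kept


def assign_parent(
    candidates: Sequence[tuple[str, float, float, float]]
) -> tuple[str, float]:
    """Pick the parent among (gene_id, mean identity, query coverage,
    best e-value) candidates: argmax identity x coverage, ties by lower
    e-value, then lexicographic id."""
    if not candidates:
        raise ValueError("no parent candidates")
    ranked = sorted(
        candidates, key=lambda c: (-(c[1] * c[2]), c[3], c[0])
    )
    best = ranked[0]
    return best[0], best[1] * best[2]


def classify_unit(
    pseudo_exons: int, query_coverage: float, parent_exon_count: int
) -> str:
    """processed iff pseudo-exons <= 0.5 x (coverage x parent exons)."""
    if parent_exon_count <= 0:
        raise ValueError("parent exon count must be positive")
    if pseudo_exons < 1:
        raise ValueError("unit must have at least one pseudo-exon")
    expected = query_coverage * parent_exon_count
    return "processed" if pseudo_exons <= 0.5 * expected else "unprocessed"


# ---------------------------------------------------------------------------
# orientation / placement
# ---------------------------------------------------------------------------


def orient_and_place(
    units: Sequence[PseudogeneUnit],
    clusters: Sequence[ClusterLocus],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Label in-cluster units parallel/reverse to the cluster main strand
    and units inside gene introns relative to the host strand.

    Mutates ``units`` in place (in_cluster/orientation/intronic_host) and
    returns a per-unit table with summary-ready columns.
    """
    cluster_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for c in clusters:
        cluster_tree[c.chrom][c.start:c.end] = c
    intron_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for a, b in zip(g.exons, g.exons[1:]):
            if b[0] > a[1]:
                intron_tree[g.chrom][a[1]:b[0]] = g
    rows = []
    for u in units:
        hit = cluster_tree[u.chrom].overlap(u.start, u.end)
        if hit:
            c = max(
                hit, key=lambda h: min(h.end, u.end) - max(h.begin, u.start)
            ).data
            u.in_cluster = c.id
            u.orientation = (
                "parallel" if u.strand == c.main_strand else "reverse"
            )
        else:
            u.in_cluster = None
            u.orientation = None
        ih = intron_tree[u.chrom].overlap(u.start, u.end)
        host = None
        host_orient = None
        for h in ih:
            if h.begin <= u.start and u.end <= h.end:
                host = h.data
                host_orient = (
                    "parallel" if u.strand == host.strand else "reverse"
                )
                break
        u.intronic_host = host.gene_id if host else None
        rows.append(
            {
                "unit_id": u.id,
                "parent": u.parent_gene_id,
                "class": u.klass,
                "in_cluster": u.in_cluster,
                "orientation": u.orientation,
                "intronic_host": u.intronic_host,
                "intronic_orientation": host_orient,
            }
        )
    return pd.DataFrame(rows)


def orientation_shares(table: pd.DataFrame) -> dict[str, float]:
    """Reverse/parallel shares among in-cluster units."""
    sub = table[table.orientation.notna()]
    if sub.empty:
        return {"reverse": float("nan"), "parallel": float("nan")}
    counts = sub.orientation.value_counts(normalize=True)
    return {
        "reverse": float(counts.get("reverse", 0.0)),
        "parallel": float(counts.get("parallel", 0.0)),
    }


# ---------------------------------------------------------------------------
# cross-species pseudogene homologs
# ---------------------------------------------------------------------------


def pseudogene_homologs(
    unit_seq: str,
    homologous_regions: Mapping[str, tuple[str, int, int]],
    genomes: Mapping[str, GenomeSequences],
    engine: KmerAligner | None = None,
) -> dict[str, dict]:
    """Search a pseudogene unit in homologous cluster regions per species.

    A match is kept iff total aligned >= 150 bp and query coverage >= 30%.
    Returns per-species match records (empty dict entries are omitted).
    """
    engine = engine or KmerAligner.sensitive()
    out: dict[str, dict] = {}
    for sp, (chrom, start, end) in homologous_regions.items():
        subject = {chrom: genomes[sp].fetch(chrom, start, end)}
        hits = engine.search({"pg": unit_seq}, subject)
        if not hits:
            continue
        aligned = sum(h.aligned_bp for h in hits)
        cov = sum(
            e - s
            for s, e in core_io.merge_intervals(
                [(h.q_start, h.q_end) for h in hits]
            )
        ) / len(unit_seq)
        if aligned < HOMOLOG_MIN_ALIGNED or cov < HOMOLOG_MIN_COVERAGE:
            continue
        out[sp] = {
            "chrom": chrom,
            "start": start + min(h.s_start for h in hits),
            "end": start + max(h.s_end for h in hits),
            "aligned_bp": aligned,
            "coverage": cov,
            "identity": sum(h.identity * h.aligned_bp for h in hits) / aligned,
        }
    return out


# ---------------------------------------------------------------------------
# 32-nt window scans
# ---------------------------------------------------------------------------


@dataclass
class WindowScan:
    unit_id: str
    offsets: np.ndarray
    identities: np.ndarray
    densities: np.ndarray  # antisense read rpm per window
    pearson_r: float
    zero_variance: bool
    mean_identity_producing: float
    mean_identity_silent: float


def window_scan(
    unit: PseudogeneUnit,
    genome: GenomeSequences,
    parent_seq: str,
    reads: Sequence[MappedRead],
    library_size: float,
    antisense_strand: str | None = None,
) -> WindowScan:
    """Slide 32-nt windows (step 1) along a unit, comparing local
    identity-to-parent with antisense read density (rpm).

    ``antisense_strand`` is the genomic strand whose reads are antisense
    to the parent mRNA (defaults to the strand opposite the unit's
    gene-sense strand).  Zero-variance identity or density yields r = 0
    with the ``zero_variance`` flag set.
    """
    if unit.span < WINDOW:
        raise ValueError("unit shorter than one 32-nt window")
    if antisense_strand is None:
        antisense_strand = "-" if unit.strand == "+" else "+"
    ident = _window_identity(unit, genome, parent_seq)
    n_win = unit.span - WINDOW + 1
    cover = np.zeros(unit.span)
    for r in reads:
        w = r.weight_per_placement
        for chrom, start, strand in r.placements:
            if chrom != unit.chrom or strand != antisense_strand:
                continue
            lo = max(start, unit.start) - unit.start
            hi = min(start + r.length, unit.end) - unit.start
            if hi > lo:
                cover[lo:hi] += w
    win_cov = np.array(
        [cover[i : i + WINDOW].sum() for i in range(n_win)]
    )
    dens = win_cov * 1e6 / library_size
    zero_var = bool(np.std(ident) == 0 or np.std(dens) == 0)
    r_val = 0.0 if zero_var else float(np.corrcoef(ident, dens)[0, 1])
    producing = dens > 0
    mean_prod = float(np.mean(ident[producing])) if producing.any() else float("nan")
    mean_silent = (
        float(np.mean(ident[~producing])) if (~producing).any() else float("nan")
    )
    return WindowScan(
        unit_id=unit.id,
        offsets=np.arange(n_win),
        identities=ident,
        densities=dens,
        pearson_r=r_val,
        zero_variance=zero_var,
        mean_identity_producing=mean_prod,
        mean_identity_silent=mean_silent,
    )


def _window_identity(
    unit: PseudogeneUnit, genome: GenomeSequences, parent_seq: str
) -> np.ndarray:
    """Per-window identity to parent from the unit's alignment hits."""
    from .engine import encode, revcomp

    match = np.zeros(unit.span, dtype=bool)
    aligned = np.zeros(unit.span, dtype=bool)
    useq = genome.fetch(unit.chrom, unit.start, unit.end).upper()
    u_codes = encode(useq, respect_mask=False)
    p_plus = encode(parent_seq.upper(), respect_mask=False)
    p_minus = encode(revcomp(parent_seq.upper()), respect_mask=False)
    plen = len(parent_seq)
    for h in unit.hits:
        s0 = h.s_start - unit.start
        s1 = h.s_end - unit.start
        if s1 <= 0 or s0 >= unit.span or (s1 - s0) != (h.q_end - h.q_start):
            continue
        if h.strand == "+":
            pseg = p_plus[h.q_start : h.q_end]
        else:
            pseg = p_minus[plen - h.q_end : plen - h.q_start]
        useg = u_codes[max(s0, 0) : s1]
        off = max(s0, 0) - s0
        pseg = pseg[off : off + len(useg)]
        n = min(len(useg), len(pseg))
        sl = slice(max(s0, 0), max(s0, 0) + n)
        match[sl] = useg[:n] == pseg[:n]
        aligned[sl] = True
    n_win = unit.span - WINDOW + 1
    csum_m = np.concatenate([[0], np.cumsum(match)])
    csum_a = np.concatenate([[0], np.cumsum(aligned)])
    m = csum_m[WINDOW:] - csum_m[:-WINDOW]
    return m[:n_win] / WINDOW


def audit_units(units: Sequence[PseudogeneUnit]) -> bool:
    """Self-audit: every unit satisfies the span and coverage filters."""
    return all(
        u.span >= MIN_UNIT_SPAN and u.query_coverage >= MIN_QUERY_COVERAGE
        for u in units
    )


def units_to_gff(units: Sequence[PseudogeneUnit], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in units:
            attrs = (
                f"ID={u.id};parent_gene={u.parent_gene_id};class={u.klass};"
                f"coverage={u.query_coverage:.3f};"
                f"identity={u.identity_to_parent:.3f}"
            )
            fh.write(
                f"{u.chrom}\tpicevo\tpseudogene\t{u.start + 1}\t{u.end}\t.\t"
                f"{u.strand}\t.\t{attrs}\n"
            )
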