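"""Synteny-based identification of homologous piRNA cluster loci.

The three-step procedure:

1. Extract the exons of the ten protein-coding genes up- and downstream
   of a query cluster and search them against the repeat-masked subject
   genome.  Hits of the same query gene within 200 kb are merged into one
   gene locus; gene loci within 2 Mb are grouped into candidate syntenic
   flanks; the best flank by (homologous gene count, mean identity) wins,
   and regions supported by fewer than four homologous genes are rejected.
2. Screen the syntenic region for homology to the query cluster sequence
   with a sensitive search; hit groups are accepted when query coverage
   >= 5%, total aligned length >= 1.5 kb and subject span >= 15% of the
   query cluster length.
3. Combine pairwise homologous loci to chains (connected components)
   across species and categorize each chain: category 1 = present and
   expressed in every species, 2 = present in every genome but not
   expressed everywhere, 3 = homolog missing in at least one genome.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import core_io
from .cluster_caller import ClusterLocus
from .core_io import GeneModel, GenomeSequences
from .engine import KmerAligner, SimilarityHit

#: default primate split times in My used for identity-versus-time tables
DEFAULT_SPLIT_TIMES = {
    ("Mmul", "Mfas"): 1.0,
    ("hominoid", "cercopithecoid"): 25.0,
    ("catarrhine", "platyrrhine"): 40.0,
    ("lemuriform", "lorisiform"): 58.0,
    ("haplorrhine", "strepsirrhine"): 65.0,
}

GENE_LOCUS_DISTANCE = 200_000
FLANK_DISTANCE = 2_000_000
MIN_SYNTENY_GENES = 4
MIN_QUERY_COVERAGE = 0.05
MIN_ALIGNED_BP = 1_500
MIN_RELATIVE_SIZE = 0.15


@dataclass
class SyntenicRegion:
    chrom: str
    start: int
    end: int
    supporting_genes: int
    mean_gene_identity: float


@dataclass
class ClusterHomolog:
    """A homologous locus of one query cluster in one subject species."""

    query_cluster: str
    subject_species: str
    chrom: str
    start: int
    end: int
    query_coverage: float
    aligned_bp: int
    identity: float
    expressed: bool = False


@dataclass
class HomologGroup:
    group_id: str
    members: dict[str, str]  # species -> cluster/locus label
    present: dict[str, bool]
    expressed: dict[str, bool]

    @property
    def category(self) -> int:
        if not all(self.present.values()):
            return 3
        if not all(self.expressed.values()):
            return 2
        return 1


def flanking_exons(
    cluster: ClusterLocus | tuple[str, int, int],
    genes: Sequence[GeneModel],
    genome: GenomeSequences,
    n: int = 10,
) -> tuple[dict[str, str], list[str]]:
    """Exon sequences of the ``n`` protein-coding genes on each side.

    Returns (exon sequences keyed "<gene>|e<i>", ordered flank gene ids).
    Genes overlapping the cluster are excluded; lncRNA and other biotypes
    never anchor synteny.  Fewer than four flanking genes in total flags
    the cluster unmappable (ValueError).
    """
    if isinstance(cluster, ClusterLocus):
        chrom, start, end = cluster.chrom, cluster.start, cluster.end
    else:
        chrom, start, end = cluster
    coding = [
        g
        for g in genes
        if g.chrom == chrom and g.biotype == "protein_coding"
        and (g.end <= start or g.start >= end)
    ]
    up = sorted(
        (g for g in coding if g.end <= start), key=lambda g: start - g.end
    )[:n]
    down = sorted(
        (g for g in coding if g.start >= end), key=lambda g: g.start - end
    )[:n]
    flank = sorted(up + down, key=lambda g: g.start)
    if len(flank) < MIN_SYNTENY_GENES:
        raise ValueError(
            f"cluster {chrom}:{start}-{end} has only {len(flank)} flanking "
            "protein-coding genes; unmappable"
        )
    queries: dict[str, str] = {}
    for g in flank:
        for i, (es, ee) in enumerate(g.exons, start=1):
            queries[f"{g.gene_id}|e{i}"] = genome.fetch(g.chrom, es, ee).upper()
    return queries, [g.gene_id for g in flank]


def locate_syntenic_region(
    queries: Mapping[str, str],
    subject_genome: GenomeSequences,
    engine: KmerAligner | None = None,
) -> SyntenicRegion | None:
    """Best syntenic flank in the subject genome, or None.

    Hits of the same query gene within 200 kb merge into one gene locus;
    gene loci within 2 Mb group into candidate flanks scored
    lexicographically by (gene count, mean identity)."""
    engine = engine or KmerAligner()
    hits = engine.search(queries, subject_genome.records)
    if not hits:
        return None
    # gene loci: per (gene, chrom), group subject positions within 200 kb
    gene_loci: list[tuple[str, str, int, int, float]] = []
    keyfunc = lambda h: (h.query_id.split("|")[0], h.subject_id)
    for (gene, chrom), gh in itertools.groupby(
        sorted(hits, key=lambda h: (keyfunc(h), h.s_start)), key=keyfunc
    ):
        cur: list[SimilarityHit] = []
        for h in gh:
            if cur and h.s_start - cur[-1].s_end > GENE_LOCUS_DISTANCE:
                gene_loci.append(_gene_locus(gene, chrom, cur))
                cur = []
            cur.append(h)
        if cur:
            gene_loci.append(_gene_locus(gene, chrom, cur))
    # candidate flanks: gene loci within 2 Mb on one chromosome
    best: SyntenicRegion | None = None
    bykey = lambda gl: gl[1]
    for chrom, gl_iter in itertools.groupby(
        sorted(gene_loci, key=lambda gl: (gl[1], gl[2])), key=bykey
    ):
        block: list[tuple[str, str, int, int, float]] = []
        for gl in gl_iter:
            if block and gl[2] - max(b[3] for b in block) > FLANK_DISTANCE:
                best = _better(best, _flank_region(chrom, block))
                block = []
            block.append(gl)
        if block:
            best = _better(best, _flank_region(chrom, block))
    if best is None or best.supporting_genes < MIN_SYNTENY_GENES:
        return None
    return best


def _gene_locus(gene, chrom, hits):
    start = min(h.s_start for h in hits)
    end = max(h.s_end for h in hits)
    wsum = sum(h.aligned_bp for h in hits)
    ident = sum(h.identity * h.aligned_bp for h in hits) / wsum
    return (gene, chrom, start, end, ident)


def _flank_region(chrom, block) -> SyntenicRegion:
    genes = {}
    for gene, _c, s, e, ident in block:
        prev = genes.get(gene)
        if prev is None or ident > prev[2]:
            genes[gene] = (s, e, ident)
    return SyntenicRegion(
        chrom=chrom,
        start=min(s for s, _e, _i in genes.values()),
        end=max(e for _s, e, _i in genes.values()),
        supporting_genes=len(genes),
        mean_gene_identity=float(
            np.mean([i for _s, _e, i in genes.values()])
        ),
    )


def _better(a: SyntenicRegion | None, b: SyntenicRegion) -> SyntenicRegion:
    if a is None:
        return b
    ka = (a.supporting_genes, a.mean_gene_identity)
    kb = (b.supporting_genes, b.mean_gene_identity)
    return b if kb > ka else a


def find_cluster_homolog(
    cluster_seq: str,
    region: SyntenicRegion,
    subject_genome: GenomeSequences,
    engine: KmerAligner | None = None,
    margin: int = 50_000,
) -> dict | None:
    """Locate the cluster homolog inside a syntenic region.

    Runs a sensitive search of the cluster sequence against the region
    (padded by ``margin``), groups hits by proximity and accepts the best
    group by (aligned bp, coverage) iff query coverage >= 5%, aligned
    length >= 1.5 kb and subject span >= 15% of the query length.
    """
    engine = engine or KmerAligner.sensitive()
    r_start = max(0, region.start - margin)
    r_end = min(len(subject_genome[region.chrom]), region.end + margin)
    # search the whole chromosome (its k-mer index is cached across calls)
    # and keep only hits inside the padded syntenic region
    hits = engine.search(
        {"cluster": cluster_seq},
        {region.chrom: subject_genome[region.chrom]},
    )
    hits = [h for h in hits if h.s_start >= r_start and h.s_end <= r_end]
    if not hits:
        return None
    qlen = len(cluster_seq)
    hits.sort(key=lambda h: h.s_start)
    groups: list[list[SimilarityHit]] = [[hits[0]]]
    for h in hits[1:]:
        if h.s_start - max(x.s_end for x in groups[-1]) > qlen:
            groups.append([])
        groups[-1].append(h)
    best = None
    for g in groups:
        # coverage over union of query intervals
        qcov = _union_len([(h.q_start, h.q_end) for h in g]) / qlen
        aligned = sum(h.aligned_bp for h in g)
        span = (max(h.s_end for h in g) - min(h.s_start for h in g))
        if qcov < MIN_QUERY_COVERAGE or aligned < MIN_ALIGNED_BP:
            continue
        if span < MIN_RELATIVE_SIZE * qlen:
            continue
        ident = sum(h.identity * h.aligned_bp for h in g) / aligned
        cand = {
            "chrom": region.chrom,
            "start": min(h.s_start for h in g),
            "end": max(h.s_end for h in g),
            "query_coverage": qcov,
            "aligned_bp": aligned,
            "identity": ident,
        }
        if best is None or (aligned, qcov) > (
            best["aligned_bp"],
            best["query_coverage"],
        ):
            best = cand
    return best


def _union_len(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in core_io.merge_intervals(intervals))


def expression_status(
    homolog: dict, subject_clusters: Sequence[ClusterLocus]
) -> bool:
    """True iff the homologous interval overlaps any lenient-preset
    cluster of the subject species by >= 1 bp."""
    for cl in subject_clusters:
        if cl.chrom != homolog["chrom"]:
            continue
        if core_io.overlap_bp(
            (homolog["start"], homolog["end"]), (cl.start, cl.end)
        ) >= 1:
            return True
    return False


def map_cluster(
    cluster: ClusterLocus | tuple[str, int, int],
    query_genes: Sequence[GeneModel],
    query_genome: GenomeSequences,
    subject_genome: GenomeSequences,
    subject_clusters: Sequence[ClusterLocus] = (),
    engine: KmerAligner | None = None,
    sensitive_engine: KmerAligner | None = None,
) -> dict | None:
    """Full three-step mapping of one cluster into one subject species."""
    try:
        queries, _flank = flanking_exons(cluster, query_genes, query_genome)
    except ValueError:
        return None
    region = locate_syntenic_region(queries, subject_genome, engine)
    if region is None:
        return None
    if isinstance(cluster, ClusterLocus):
        chrom, start, end = cluster.chrom, cluster.start, cluster.end
    else:
        chrom, start, end = cluster
    cluster_seq = query_genome.fetch(chrom, start, end).upper()
    hom = find_cluster_homolog(
        cluster_seq, region, subject_genome, sensitive_engine
    )
    if hom is None:
        return None
    hom["expressed"] = expression_status(hom, subject_clusters)
    hom["syntenic_genes"] = region.supporting_genes
    return hom


def build_groups(
    links: Sequence[tuple[tuple[str, str], tuple[str, str], float]],
    species: Sequence[str],
    expressed: Mapping[tuple[str, str], bool],
) -> list[HomologGroup]:
    """Chain pairwise homolog links into cross-species groups.

    ``links`` are ((species_a, locus_a), (species_b, locus_b), coverage)
    tuples; groups are connected components.  A component holding two
    loci of one species is resolved to the higher-coverage link.  The
    ``expressed`` map flags (species, locus) pairs with piRNA expression.
    """
    graph = nx.Graph()
    for a, b, cov in links:
        if graph.has_edge(a, b):
            graph[a][b]["coverage"] = max(graph[a][b]["coverage"], cov)
        else:
            graph.add_edge(a, b, coverage=cov)
    groups: list[HomologGroup] = []
    for gi, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        sub = graph.subgraph(comp)
        per_species: dict[str, list[tuple[str, str]]] = {}
        for node in comp:
            per_species.setdefault(node[0], []).append(node)
        # ambiguity: keep the locus with the best incident coverage
        members: dict[str, str] = {}
        for sp, nodes in per_species.items():
            if len(nodes) > 1:
                warnings.warn(
                    f"ambiguous homology chain for {sp}: {sorted(nodes)}"
                )
                nodes = sorted(
                    nodes,
                    key=lambda n: max(
                        d["coverage"] for _u, _v, d in sub.edges(n, data=True)
                    ),
                    reverse=True,
                )
            members[sp] = nodes[0][1]
        present = {sp: sp in members for sp in species}
        expr = {
            sp: bool(expressed.get((sp, members[sp]), False))
            if sp in members
            else False
            for sp in species
        }
        groups.append(
            HomologGroup(
                group_id=f"hg{gi:03d}",
                members=members,
                present=present,
                expressed=expr,
            )
        )
    return groups


def identity_vs_time(
    pair_identities: Mapping[tuple[str, str], Sequence[float]],
    split_times: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Join per-pair mean alignment identities with split times."""
    rows = []
    for pair, idents in pair_identities.items():
        if len(idents) == 0:
            warnings.warn(f"no alignments for species pair {pair}; omitted")
            continue
        t = split_times.get(pair, split_times.get((pair[1], pair[0])))
        rows.append(
            {
                "species_a": pair[0],
                "species_b": pair[1],
                "split_time_my": t,
                "mean_identity": float(np.mean(idents)),
                "n_alignments": len(idents),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "species_a", "species_b", "split_time_my",
                "mean_identity", "n_alignments",
            ]
        )
    return pd.DataFrame(rows).sort_values("split_time_my", ignore_index=True)


def gene_pair_identities(
    cds_a: Mapping[str, str], cds_b: Mapping[str, str]
) -> list[float]:
    """Alignment identity of shared-id CDS orthologs (edlib NW)."""
    import edlib

    out = []
    for gid, seq_a in cds_a.items():
        seq_b = cds_b.get(gid)
        if seq_b is None:
            continue
        res = edlib.align(seq_a.upper(), seq_b.upper(), task="distance")
        out.append(1.0 - res["editDistance"] / max(len(seq_a), len(seq_b)))
    return out


def genome_pair_identities(
    genome_a: GenomeSequences,
    genome_b: GenomeSequences,
    window: int = 5_000,
    n_windows: int = 50,
    seed: int = 0,
) -> list[float]:
    """Identity of sampled colinear windows between two genomes."""
    import edlib

    rng = np.random.default_rng(seed)
    out = []
    for chrom, seq_a in genome_a.records.items():
        if chrom not in genome_b:
            continue
        seq_b = genome_b[chrom]
        lim = min(len(seq_a), len(seq_b)) - window
        if lim <= 0:
            continue
        for s in rng.integers(0, lim, size=n_windows):
            a = seq_a[s : s + window].upper()
            b = seq_b[s : s + window].upper()
            res = edlib.align(a, b, task="distance")
            out.append(1.0 - res["editDistance"] / window)
    return out
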