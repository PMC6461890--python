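"""Density-based piRNA cluster prediction.

Re-implements the two-preset cluster calling protocol: candidate regions
are maximal runs of 1-kb tiles whose fractionated read density exceeds an
empirical genome-wide quantile (the density P value), extended to the
outermost read boundaries; candidates must then pass a minimum size, the
1U/10A composition filters, a main-strand fraction, and a read-diversity
rule rejecting loci dominated by their top 1% of distinct sequences.
Neighboring clusters closer than 10 kb are merged and all attributes are
recomputed from the union of reads.

Presets (size bp, density P, 1U-or-10A, 1U-and-10A rescue, main strand,
top-1% share cap, merge bp):

* strict  — 5000, 0.01, 0.75, 0.33, 0.5, 0.90, 10000
* lenient — 2500, 0.05, 0.50, 0.33, 0.5, 0.90, 10000

Clusters are classified as 26 nt-leaning (pre-pachytene-like) or 30
nt-leaning (pachytene-like) depending on whether the 25-27 nt or the
29-31 nt read weight is greater.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MappedRead, filter_by_length

TILE = 1_000


@dataclass(frozen=True)
class ClusterParams:
    min_size: int
    density_p: float
    min_1Tor10A: float
    min_1Tand10A_rescue: float
    min_main_strand: float
    top1_max_share: float
    merge_distance: int


STRICT = ClusterParams(5_000, 0.01, 0.75, 0.33, 0.5, 0.90, 10_000)
LENIENT = ClusterParams(2_500, 0.05, 0.50, 0.33, 0.5, 0.90, 10_000)

PRESETS = {"strict": STRICT, "lenient": LENIENT}


@dataclass
class ClusterLocus:
    id: str
    chrom: str
    start: int
    end: int
    main_strand: str
    main_strand_fraction: float
    weighted_read_count: float
    rpm: float
    rpkm: float
    frac_1Tor10A: float
    frac_1U: float
    frac_10A: float
    top1_share: float
    leaning: int
    contains_genes: bool = False
    contains_pseudogenes: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _placement_table(reads: Sequence[MappedRead]) -> pd.DataFrame:
    rows = []
    for ri, r in enumerate(reads):
        w = r.weight_per_placement
        has_1t = r.sequence[0] in "Tt"
        has_10a = r.length >= 10 and r.sequence[9] in "Aa"
        for chrom, start, strand in r.placements:
            rows.append(
                (ri, chrom, start, start + r.length, strand, w, has_1t, has_10a)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read", "chrom", "start", "end", "strand", "weight", "t1", "a10",
        ],
    )


def call_clusters(
    reads: Sequence[MappedRead],
    chrom_lengths: Mapping[str, int],
    params: ClusterParams = LENIENT,
    library_size: float | None = None,
) -> list[ClusterLocus]:
    """Predict piRNA clusters from 24-32 nt mapped reads.

    ``library_size`` defaults to the total copy count of the 24-32 nt
    reads and normalizes rpm/RPKM.
    """
    reads = filter_by_length(reads)
    if not reads:
        return []
    if library_size is None:
        library_size = sum(r.copies for r in reads)
    table = _placement_table(reads)
    table = table[table.chrom.isin(chrom_lengths)]
    if table.empty:
        return []

    # genome-wide nonzero tile-density distribution
    tile_weights: list[np.ndarray] = []
    per_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in table.groupby("chrom", sort=True):
        n_tiles = max(1, math.ceil(chrom_lengths[chrom] / TILE))
        dens = np.zeros(n_tiles)
        np.add.at(dens, (sub.start // TILE).to_numpy(), sub.weight.to_numpy())
        tile_weights.append(dens)
        per_chrom[chrom] = sub
    all_tiles = np.concatenate(tile_weights)
    nonzero = all_tiles[all_tiles > 0]
    threshold = float(np.quantile(nonzero, 1.0 - params.density_p))

    loci: list[ClusterLocus] = []
    for (chrom, sub), dens in zip(
        sorted(per_chrom.items()), tile_weights
    ):
        hot = dens > threshold
        if not hot.any():
            continue
        # maximal runs of qualifying tiles
        edges = np.diff(np.concatenate([[0], hot.astype(int), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        tiles = (sub.start // TILE).to_numpy()
        for t0, t1 in zip(starts, ends):
            in_run = (tiles >= t0) & (tiles < t1)
            run = sub[in_run]
            lo = int(run.start.min())
            hi = int(run.end.max())
            locus = _build_locus(chrom, lo, hi, sub, library_size)
            if _passes(locus, params, chrom, lo, hi, sub):
                loci.append(locus)
    loci = merge_adjacent(loci, params.merge_distance, table, library_size)
    for i, locus in enumerate(loci):
        locus.id = f"cl{i:03d}"
    return loci


def _locus_reads(sub: pd.DataFrame, lo: int, hi: int) -> pd.DataFrame:
    return sub[(sub.start < hi) & (sub.end > lo)]


def _build_locus(
    chrom: str, lo: int, hi: int, sub: pd.DataFrame, library_size: float
) -> ClusterLocus:
    inside = _locus_reads(sub, lo, hi)
    w = inside.weight.to_numpy()
    total = float(w.sum())
    plus_w = float(inside.weight[inside.strand == "+"].sum())
    if plus_w > total - plus_w:
        main, main_frac = "+", plus_w / total
    elif plus_w < total - plus_w:
        main, main_frac = "-", 1.0 - plus_w / total
    else:
        warnings.warn(f"main-strand tie at {chrom}:{lo}-{hi}; reporting '+'")
        main, main_frac = "+", 0.5
    t1 = inside.t1.to_numpy()
    a10 = inside.a10.to_numpy()
    frac_or = float(w[t1 | a10].sum() / total)
    frac_1u = float(w[t1].sum() / total)
    frac_10a = float(w[a10].sum() / total)
    # top 1% (ceiling) of distinct sequences by locus weight
    per_read = inside.groupby("read").weight.sum().sort_values(ascending=False)
    n_top = max(1, math.ceil(0.01 * len(per_read)))
    top1 = float(per_read.iloc[:n_top].sum() / total)
    rpm = total * 1e6 / library_size
    length = hi - lo
    rpkm = rpm / (length / 1000.0)
    lean = classify_leaning_from_table(inside)
    return ClusterLocus(
        id="",
        chrom=chrom,
        start=lo,
        end=hi,
        main_strand=main,
        main_strand_fraction=main_frac,
        weighted_read_count=total,
        rpm=rpm,
        rpkm=rpkm,
        frac_1Tor10A=frac_or,
        frac_1U=frac_1u,
        frac_10A=frac_10a,
        top1_share=top1,
        leaning=lean,
    )


def _passes(
    locus: ClusterLocus,
    params: ClusterParams,
    chrom: str,
    lo: int,
    hi: int,
    sub: pd.DataFrame,
) -> bool:
    if locus.length < params.min_size:
        return False
    if locus.frac_1Tor10A < params.min_1Tor10A and not (
        locus.frac_1U >= params.min_1Tand10A_rescue
        and locus.frac_10A >= params.min_1Tand10A_rescue
    ):
        return False
    if locus.main_strand_fraction < params.min_main_strand:
        return False
    if locus.top1_share > params.top1_max_share:
        return False
    return True


def merge_adjacent(
    loci: Sequence[ClusterLocus],
    merge_distance: int,
    table: pd.DataFrame,
    library_size: float,
) -> list[ClusterLocus]:
    """Transitively merge loci on a chromosome with gaps < merge_distance;
    attributes are recomputed from the union of reads.  Idempotent."""
    out: list[ClusterLocus] = []
    by_chrom: dict[str, list[ClusterLocus]] = defaultdict(list)
    for l in loci:
        by_chrom[l.chrom].append(l)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: l.start)
        sub = table[table.chrom == chrom]
        block = [group[0]]
        for nxt in group[1:]:
            if nxt.start - max(l.end for l in block) < merge_distance:
                block.append(nxt)
            else:
                out.append(_merge_block(block, chrom, sub, library_size))
                block = [nxt]
        out.append(_merge_block(block, chrom, sub, library_size))
    return out


def _merge_block(block, chrom, sub, library_size) -> ClusterLocus:
    if len(block) == 1:
        return block[0]
    lo = min(l.start for l in block)
    hi = max(l.end for l in block)
    return _build_locus(chrom, lo, hi, sub, library_size)


def classify_leaning_from_table(inside: pd.DataFrame) -> int:
    lens = (inside.end - inside.start).to_numpy()
    w = inside.weight.to_numpy()
    w26 = float(w[(lens >= 25) & (lens <= 27)].sum())
    w30 = float(w[(lens >= 29) & (lens <= 31)].sum())
    return 26 if w26 > w30 else 30


def classify_leaning(
    locus_interval: tuple[str, int, int], reads: Sequence[MappedRead]
) -> int:
    """26 if the 25-27 nt weight inside the locus exceeds the 29-31 nt
    weight, else 30 (ties lean 30, the majority class)."""
    chrom, lo, hi = locus_interval
    w26 = w30 = total = 0.0
    for r in reads:
        for pchrom, start, _strand in r.placements:
            if pchrom != chrom or start + r.length <= lo or start >= hi:
                continue
            w = r.weight_per_placement
            total += w
            if 25 <= r.length <= 27:
                w26 += w
            elif 29 <= r.length <= 31:
                w30 += w
    if total == 0:
        raise ValueError("locus has zero read weight")
    return 26 if w26 > w30 else 30


def quantify(
    locus_interval: tuple[str, int, int],
    reads: Sequence[MappedRead],
    library_size: float,
) -> tuple[float, float]:
    """(rpm, rpkm) of a locus: rpm = weight x 1e6 / library size,
    rpkm = rpm / (length/1000)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    chrom, lo, hi = locus_interval
    total = 0.0
    for r in reads:
        for pchrom, start, _strand in r.placements:
            if pchrom == chrom and start < hi and start + r.length > lo:
                total += r.weight_per_placement
    rpm = total * 1e6 / library_size
    rpkm = rpm / ((hi - lo) / 1000.0)
    return rpm, rpkm


def validate_locus(locus: ClusterLocus, params: ClusterParams) -> bool:
    """Self-audit: does an emitted locus satisfy its ClusterParams?"""
    if locus.length < params.min_size:
        return False
    if locus.frac_1Tor10A < params.min_1Tor10A and not (
        locus.frac_1U >= params.min_1Tand10A_rescue
        and locus.frac_10A >= params.min_1Tand10A_rescue
    ):
        return False
    if locus.main_strand_fraction < params.min_main_strand:
        return False
    return locus.top1_share <= params.top1_max_share


def loci_table(loci: Sequence[ClusterLocus]) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in loci])
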