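"""1-Mb genomic-environment profiling.

Genomes are tiled into fixed 1-Mb windows from position 0 (terminal
partial windows are kept; their per-Mb features are length-normalized).
Each window carries gene and pseudogene counts (midpoint rule), per-family
repeat coverage shares, the length-weighted mean repeat divergence, GC
content (ambiguous bases ignored) and a cluster-containment flag; windows
overlapping centromere intervals are excluded from statistics.  Windows
containing piRNA clusters are compared with the remaining windows by
two-sided Wilcoxon-Mann-Whitney rank-sum tests.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_caller import ClusterLocus
from .core_io import GeneModel, GenomeSequences, RepeatFeature, overlap_bp
from .pseudogenes import PseudogeneUnit

WINDOW_MB = 1_000_000


@dataclass
class GenomeWindow:
    chrom: str
    index: int
    start: int
    end: int
    gene_count: int = 0
    pseudogene_count: int = 0
    repeat_share: dict[str, float] = field(default_factory=dict)
    mean_repeat_divergence: float = float("nan")
    gc: float = float("nan")
    contains_cluster: bool = False
    excluded: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mb(self) -> float:
        return self.length / 1e6


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive, ambiguous bases ignored.

    Raises on a sequence with no unambiguous bases."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def build_windows(
    genome: GenomeSequences,
    genes: Sequence[GeneModel] = (),
    pseudogenes: Sequence[PseudogeneUnit] = (),
    repeats: Sequence[RepeatFeature] = (),
    clusters: Sequence[ClusterLocus] = (),
    centromeres: Sequence[tuple[str, int, int]] = (),
) -> list[GenomeWindow]:
    """Fixed 1-Mb tiling with per-window features.

    Genes/pseudogenes are counted in the window containing their midpoint;
    repeat shares are covered bp / window bp; divergence is the
    length-weighted mean over repeat bp in the window.
    """
    lengths = genome.lengths()
    for feat in genes:
        if feat.chrom not in lengths:
            raise ValueError(f"chromosome {feat.chrom!r} absent from genome")
    windows: list[GenomeWindow] = []
    by_chrom: dict[str, list[GenomeWindow]] = {}
    for chrom in sorted(lengths):
        L = lengths[chrom]
        rows = []
        for i in range(0, max(1, -(-L // WINDOW_MB))):
            start = i * WINDOW_MB
            end = min(start + WINDOW_MB, L)
            if end <= start:
                continue
            rows.append(GenomeWindow(chrom=chrom, index=i, start=start, end=end))
        by_chrom[chrom] = rows
        windows.extend(rows)

    def _window_of(chrom: str, midpoint: int) -> GenomeWindow | None:
        rows = by_chrom.get(chrom)
        if rows is None:
            return None
        i = midpoint // WINDOW_MB
        return rows[i] if i < len(rows) else None

    for g in genes:
        w = _window_of(g.chrom, (g.start + g.end) // 2)
        if w:
            w.gene_count += 1
    for p in pseudogenes:
        w = _window_of(p.chrom, (p.start + p.end) // 2)
        if w:
            w.pseudogene_count += 1

    rep_bp: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    rep_div: dict[int, float] = defaultdict(float)
    rep_len: dict[int, int] = defaultdict(int)
    win_id = {id(w): k for k, w in enumerate(windows)}
    for r in repeats:
        rows = by_chrom.get(r.chrom, [])
        for w in rows:
            ov = overlap_bp((r.start, r.end), (w.start, w.end))
            if ov > 0:
                k = win_id[id(w)]
                rep_bp[k][r.family] += ov
                rep_div[k] += r.divergence * ov
                rep_len[k] += ov
    for k, w in enumerate(windows):
        w.repeat_share = {
            fam: bp / w.length for fam, bp in sorted(rep_bp[k].items())
        }
        if rep_len[k]:
            w.mean_repeat_divergence = rep_div[k] / rep_len[k]

    for w in windows:
        seq = genome.fetch(w.chrom, w.start, w.end)
        try:
            w.gc = gc_content(seq)
        except ValueError:
            w.gc = float("nan")

    for c in clusters:
        for w in by_chrom.get(c.chrom, []):
            if overlap_bp((c.start, c.end), (w.start, w.end)) > 0:
                w.contains_cluster = True
    for chrom, s, e in centromeres:
        for w in by_chrom.get(chrom, []):
            if overlap_bp((s, e), (w.start, w.end)) > 0:
                w.excluded = True
    return windows


def windows_table(windows: Sequence[GenomeWindow]) -> pd.DataFrame:
    families = sorted({f for w in windows for f in w.repeat_share})
    rows = []
    for w in windows:
        row = {
            "chrom": w.chrom,
            "index": w.index,
            "start": w.start,
            "end": w.end,
            "gene_count": w.gene_count,
            "pseudogene_count": w.pseudogene_count,
            "gene_per_mb": w.gene_count / w.mb,
            "pseudogene_per_mb": w.pseudogene_count / w.mb,
            "mean_repeat_divergence": w.mean_repeat_divergence,
            "gc": w.gc,
            "contains_cluster": w.contains_cluster,
            "excluded": w.excluded,
        }
        for fam in families:
            row[f"share_{fam}"] = w.repeat_share.get(fam, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_intergenic(
    clusters: Sequence[ClusterLocus],
    genes: Sequence[GeneModel],
    pseudogenes: Sequence[PseudogeneUnit],
) -> dict[str, bool]:
    """intergenic <=> a cluster overlaps no gene span and no pseudogene."""
    out: dict[str, bool] = {}
    for c in clusters:
        hit = any(
            g.chrom == c.chrom and overlap_bp((g.start, g.end), c.interval) > 0
            for g in genes
        ) or any(
            p.chrom == c.chrom and overlap_bp(p.interval, c.interval) > 0
            for p in pseudogenes
        )
        out[c.id] = not hit
    return out


@dataclass
class WindowComparison:
    feature: str
    n_cluster: int
    n_other: int
    statistic: float
    p_value: float
    mean_cluster: float
    mean_other: float
    median_cluster: float
    median_other: float
    constant: bool = False


def compare_cluster_windows(
    windows: Sequence[GenomeWindow] | pd.DataFrame, feature: str
) -> WindowComparison:
    """Two-sided rank-sum test of a feature between cluster-containing
    and the remaining non-excluded windows."""
    df = windows if isinstance(windows, pd.DataFrame) else windows_table(windows)
    df = df[~df.excluded]
    a = df.loc[df.contains_cluster, feature].dropna().to_numpy()
    b = df.loc[~df.contains_cluster, feature].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 windows on each side")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn(f"feature {feature!r} constant; p set to 1")
        stat, p, const = 0.0, 1.0, True
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p, const = float(res.statistic), float(res.pvalue), False
    return WindowComparison(
        feature=feature,
        n_cluster=len(a),
        n_other=len(b),
        statistic=stat,
        p_value=p,
        mean_cluster=float(np.mean(a)),
        mean_other=float(np.mean(b)),
        median_cluster=float(np.median(a)),
        median_other=float(np.median(b)),
        constant=const,
    )


def peak_density(
    peaks: Sequence[tuple[str, int, int]],
    regions: Sequence[tuple[str, int, int]],
    genome_lengths: Mapping[str, int],
) -> dict[str, float]:
    """Peaks per Mb inside regions (midpoint rule) and the ratio to the
    genome-wide density.  An empty peak set flags the ratio undefined."""
    region_mb = sum(e - s for _c, s, e in regions) / 1e6
    genome_mb = sum(genome_lengths.values()) / 1e6
    in_regions = 0
    for chrom, s, e in peaks:
        mid = (s + e) // 2
        if any(
            chrom == rc and rs <= mid < re for rc, rs, re in regions
        ):
            in_regions += 1
    density_regions = in_regions / region_mb if region_mb else float("nan")
    density_genome = len(peaks) / genome_mb
    if len(peaks) == 0:
        warnings.warn("empty peak set; ratio undefined")
        ratio = float("nan")
    else:
        ratio = density_regions / density_genome
    return {
        "density_regions": density_regions,
        "density_genome": density_genome,
        "ratio": ratio,
        "n_in_regions": float(in_regions),
    }
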