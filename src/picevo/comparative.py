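"""Cross-species synthesis over homologous piRNA cluster groups.

Expression matrices (rpm, zero for absent/non-expressed loci), hierarchical
clustering with average linkage on Pearson distance (d = 1 - r),
category-1/2/3 read shares, HEC (highly-expressed-cluster) ping-pong
partner-share ratios, and per-category transposon divergence with paired
rank tests.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .cluster_caller import ClusterLocus
from .core_io import MappedRead, RepeatFeature, overlap_bp
from .homology import HomologGroup
from .srna_stats import partner_share

HEC_FOLD_LEVELS = (1, 2, 5, 10)


def expression_matrix(
    groups: Sequence[HomologGroup],
    rpm_by_species: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """rpm matrix over homolog groups (rows) x species (columns).

    ``rpm_by_species[species][locus_label]`` quantifies the member locus;
    absent or non-expressed members get 0.  Row categories are attached
    as a 'category' column-level-free attribute table via ``.attrs``.
    """
    species = sorted(rpm_by_species)
    for g in groups:
        for sp in g.members:
            if sp not in rpm_by_species:
                raise ValueError(f"species {sp!r} missing from quantifications")
    rows = {}
    cats = {}
    for g in groups:
        vals = []
        for sp in species:
            locus = g.members.get(sp)
            rpm = rpm_by_species[sp].get(locus, 0.0) if locus else 0.0
            if not g.expressed.get(sp, False):
                rpm = 0.0
            vals.append(rpm)
        rows[g.group_id] = vals
        cats[g.group_id] = g.category
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    mat.index.name = "group"
    mat.attrs["category"] = cats
    return mat


def pearson_distance_matrix(mat: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """d = 1 - Pearson r between items; constant profiles get d = 1."""
    data = mat.T if axis == "columns" else mat
    items = data.index
    n = len(items)
    d = np.ones((n, n))
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                warnings.warn(
                    f"constant profile for {items[i]!r} or {items[j]!r}; "
                    "Pearson distance set to 1"
                )
                dij = 1.0
            else:
                dij = 1.0 - float(np.corrcoef(arr[i], arr[j])[0, 1])
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=items, columns=items)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> pd.DataFrame:
        from scipy.spatial.distance import squareform

        coph = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(
            squareform(coph), index=self.labels, columns=self.labels
        )

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_h):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_h - 0.0:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{max(parent_h - node.dist, 0.0):.6g}"

        return f"({_fmt(tree.left, tree.dist)},{_fmt(tree.right, tree.dist)});"

    def first_merge(self) -> tuple[str, str] | None:
        """Leaf pair merged first, if the first merge joins two leaves."""
        n = len(self.labels)
        a, b = int(self.linkage[0, 0]), int(self.linkage[0, 1])
        if a < n and b < n:
            return tuple(sorted((self.labels[a], self.labels[b])))
        return None


def hierarchical_cluster(
    mat: pd.DataFrame, axis: str = "columns"
) -> Dendrogram:
    """Average-linkage (UPGMA) clustering on Pearson distance.

    Items are pre-sorted by label so equal-distance merges resolve
    deterministically."""
    data = (mat.T if axis == "columns" else mat).sort_index()
    if len(data) < 2:
        raise ValueError("need at least 2 items to cluster")
    dm = pearson_distance_matrix(data.T, axis="columns")
    from scipy.spatial.distance import squareform

    condensed = squareform(dm.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(labels=list(data.index), linkage=Z)


def group_read_shares(
    groups: Sequence[HomologGroup],
    cluster_weights: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Per-species share of cluster-derived read weight by category.

    ``cluster_weights[species][locus_label]`` is the weighted read count
    of the member locus in that species.  Shares sum to 1 per species
    over homolog-group-assigned cluster reads."""
    species = sorted(cluster_weights)
    acc = {sp: {1: 0.0, 2: 0.0, 3: 0.0} for sp in species}
    for g in groups:
        cat = g.category
        for sp, locus in g.members.items():
            w = cluster_weights.get(sp, {}).get(locus, 0.0)
            acc[sp][cat] += w
    rows = {}
    for sp in species:
        total = sum(acc[sp].values())
        rows[sp] = [
            acc[sp][k] / total if total else float("nan") for k in (1, 2, 3)
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["category_1", "category_2", "category_3"]
    )


def hec_sets(
    mat: pd.DataFrame, fold_levels: Sequence[int] = HEC_FOLD_LEVELS
) -> dict[int, dict[str, list[str]]]:
    """Highly expressed clusters per fold level and species.

    A group is an HEC at level f in species s iff rpm_s >= f x max(rpm of
    the other species in the group) and rpm_s > 0.  Monotone: the HEC set
    at a higher fold is a subset of the set at a lower fold."""
    out: dict[int, dict[str, list[str]]] = {}
    for f in fold_levels:
        per_sp: dict[str, list[str]] = {sp: [] for sp in mat.columns}
        for gid, row in mat.iterrows():
            for sp in mat.columns:
                others = row.drop(sp)
                if row[sp] > 0 and row[sp] >= f * others.max():
                    per_sp[sp].append(gid)
        out[f] = per_sp
    return out


def hec_pingpong_ratio(
    mat: pd.DataFrame,
    reads_per_cluster: Mapping[str, Mapping[str, Sequence[MappedRead]]],
    fold_levels: Sequence[int] = HEC_FOLD_LEVELS,
) -> pd.DataFrame:
    """Ratio of ping-pong partner shares in HECs versus remaining clusters.

    ``reads_per_cluster[species][group_id]`` holds the member locus reads.
    Rows: (species, fold); the ratio is partner_share(HEC reads) /
    partner_share(remaining reads), NaN-flagged when a side is empty."""
    sets = hec_sets(mat, fold_levels)
    rows = []
    for f in fold_levels:
        for sp in mat.columns:
            hec_ids = set(sets[f][sp])
            sp_reads = reads_per_cluster.get(sp, {})
            hec_reads = [
                r for gid in hec_ids for r in sp_reads.get(gid, ())
            ]
            rc_reads = [
                r
                for gid, rs in sp_reads.items()
                if gid not in hec_ids
                for r in rs
            ]
            if not hec_reads or not rc_reads:
                warnings.warn(
                    f"empty HEC or remaining set at fold {f} for {sp}"
                )
                ratio = float("nan")
                hec_share = rc_share = float("nan")
            else:
                hec_share = partner_share(hec_reads)
                rc_share = partner_share(rc_reads)
                ratio = (
                    hec_share / rc_share if rc_share > 0 else float("nan")
                )
            rows.append(
                {
                    "species": sp,
                    "fold": f,
                    "n_hec": len(hec_ids),
                    "hec_partner_share": hec_share,
                    "rc_partner_share": rc_share,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def group_transposon_divergence(
    groups: Sequence[HomologGroup],
    cluster_intervals: Mapping[str, Mapping[str, tuple[str, int, int]]],
    repeats_by_species: Mapping[str, Sequence[RepeatFeature]],
) -> tuple[pd.DataFrame, dict[tuple[int, int], float]]:
    """Length-weighted mean repeat divergence per cluster, aggregated by
    homolog-group category, with paired rank tests across species.

    Returns (per species x category mean table, {(cat_a, cat_b): p}).
    Clusters without repeats are excluded with a warning.
    """
    rows = []
    for g in groups:
        cat = g.category
        for sp, locus in g.members.items():
            iv = cluster_intervals.get(sp, {}).get(locus)
            if iv is None:
                continue
            chrom, start, end = iv
            num = den = 0.0
            for r in repeats_by_species.get(sp, ()):
                if r.chrom != chrom:
                    continue
                ov = overlap_bp((r.start, r.end), (start, end))
                if ov > 0:
                    num += r.divergence * ov
                    den += ov
            if den == 0:
                warnings.warn(
                    f"cluster {locus} ({sp}) has no repeats; excluded"
                )
                continue
            rows.append(
                {
                    "species": sp,
                    "group": g.group_id,
                    "category": cat,
                    "mean_divergence": num / den,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {}
    table = df.pivot_table(
        index="species", columns="category", values="mean_divergence"
    )
    tests: dict[tuple[int, int], float] = {}
    if len(table) >= 2:
        cats = sorted(c for c in table.columns)
        for i, ca in enumerate(cats):
            for cb in cats[i + 1 :]:
                paired = table[[ca, cb]].dropna()
                if len(paired) < 2:
                    continue
                a, b = paired[ca].to_numpy(), paired[cb].to_numpy()
                if np.allclose(a, b):
                    tests[(ca, cb)] = 1.0
                    continue
                res = stats.wilcoxon(a, b)
                tests[(ca, cb)] = float(res.pvalue)
    return df, tests
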