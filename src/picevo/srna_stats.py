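"""Basic piRNA characterization.

Length distributions, positional base composition (the 1U/10A biases),
5'-overlap score vectors with the ping-pong z-score, partner shares, and
ping-pong read-length pairing matrices.

Overlap geometry: a plus-strand read with 5' end at genomic position ``p``
and a minus-strand read with 5' end at genomic position ``q`` overlap by
``k = q - p + 1`` nt at their 5' ends; the ping-pong signature is the mass
at ``k = 10``.  Pair mass is the product of the fractionated placement
weights of the two reads.  The z-score of s(10) is computed against the
background bins k in 1..9 and 11..20 (sample standard deviation, n-1), and
a signature is called significant when the argmax over k is uniquely at 10
and z exceeds 2.3264 (upper-tail normal, P < 0.01).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import MappedRead

#: one-sided z cutoff corresponding to P < 0.01 (4 decimals)
PINGPONG_Z_CUTOFF = 2.3264

MAX_OVERLAP = 20


def pingpong_z_cutoff(alpha: float = 0.01, decimals: int = 4) -> float:
    """Smallest z (rounded up at ``decimals``) with upper-tail normal
    probability <= ``alpha``."""
    from scipy.stats import norm

    z = norm.isf(alpha)
    scale = 10**decimals
    return float(np.ceil(z * scale) / scale)


@dataclass
class OverlapSignature:
    """5'-overlap score vector s(1..20) with ping-pong significance."""

    scores: np.ndarray  # length 20, scores[k-1] = s(k)
    z10: float
    significant: bool
    partner_share: float

    def score(self, k: int) -> float:
        return float(self.scores[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"overlap_nt": np.arange(1, MAX_OVERLAP + 1), "score": self.scores}
        )


def _placements_in_region(
    reads: Iterable[MappedRead],
    region: tuple[str, int, int] | None,
) -> list[tuple[MappedRead, tuple[str, int, str]]]:
    out = []
    for r in reads:
        for pl in r.placements:
            if region is not None:
                chrom, start, strand = pl
                if chrom != region[0]:
                    continue
                if start + r.length <= region[1] or start >= region[2]:
                    continue
            out.append((r, pl))
    return out


def length_distribution(
    reads: Sequence[MappedRead], weight: str = "copies"
) -> pd.Series:
    """Histogram over read lengths.

    ``weight='copies'`` sums observed copy counts per distinct sequence;
    ``weight='weighted'`` sums fractionated placement weights, which
    differs only when multi-mappers are present and placements are
    restricted.  Bins sum to the respective total.
    """
    if not reads:
        raise ValueError("empty read collection")
    acc: defaultdict[int, float] = defaultdict(float)
    for r in reads:
        if weight == "copies":
            acc[r.length] += r.copies
        elif weight == "weighted":
            acc[r.length] += r.weight_per_placement * len(r.placements)
        else:
            raise ValueError(f"unknown weight mode {weight!r}")
    lengths = sorted(acc)
    return pd.Series(
        [acc[l] for l in lengths], index=pd.Index(lengths, name="length")
    )


def positional_composition(
    reads: Sequence[MappedRead],
    position: int,
    min_len: int = 24,
    max_len: int = 32,
) -> dict[str, float]:
    """Copy-weighted base fractions at a 1-based read position.

    Reads are filtered to the 24-32 nt piRNA range and to those long
    enough to cover the position; T is reported as U.  Fractions sum to 1.
    """
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    totals = {"A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0}
    grand = 0.0
    for r in reads:
        if not (min_len <= r.length <= max_len) or r.length < position:
            continue
        base = r.sequence[position - 1].upper().replace("T", "U")
        if base in totals:
            totals[base] += r.copies
            grand += r.copies
    if grand == 0:
        raise ValueError("no reads cover the requested position")
    return {b: v / grand for b, v in totals.items()}


def overlap_signature(
    reads: Sequence[MappedRead],
    region: tuple[str, int, int] | None = None,
    min_len: int = 24,
    max_len: int = 32,
) -> OverlapSignature:
    """Weighted 5'-overlap score vector and ping-pong call.

    Scores: s(k) = sum over plus/minus 5'-end position pairs at overlap k
    of (plus weight x minus weight), k = 1..20.  The optional ``region``
    restricts placements to one (chrom, start, end) interval.
    """
    reads = [r for r in reads if min_len <= r.length <= max_len]
    placed = _placements_in_region(reads, region)
    plus: dict[str, defaultdict[int, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    minus: dict[str, defaultdict[int, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for r, (chrom, start, strand) in placed:
        w = r.weight_per_placement
        five = start if strand == "+" else start + r.length - 1
        (plus if strand == "+" else minus)[chrom][five] += w

    scores = np.zeros(MAX_OVERLAP)
    for chrom, pw in plus.items():
        mw = minus.get(chrom)
        if not mw:
            continue
        p_pos = np.fromiter(pw.keys(), dtype=np.int64)
        p_w = np.fromiter(pw.values(), dtype=float)
        m_sorted = np.array(sorted(mw.keys()), dtype=np.int64)
        m_w = np.array([mw[q] for q in m_sorted])
        for k in range(1, MAX_OVERLAP + 1):
            target = p_pos + k - 1
            idx = np.searchsorted(m_sorted, target)
            ok = (idx < len(m_sorted)) & (m_sorted[np.minimum(idx, len(m_sorted) - 1)] == target)
            scores[k - 1] += float(np.sum(p_w[ok] * m_w[idx[ok]]))

    bg = np.delete(scores, 9)
    if scores.sum() == 0:
        z10 = float("nan")
        significant = False
    elif bg.std(ddof=1) == 0:
        # background-free signature: every pair overlaps by the same k.
        # All mass at k=10 is the cleanest possible ping-pong signal.
        if scores[9] > bg.max():
            z10 = float("inf")
            significant = True
        else:
            z10 = float("nan")
            significant = False
    else:
        z10 = float((scores[9] - bg.mean()) / bg.std(ddof=1))
        argmax_unique = scores[9] > np.max(bg)
        significant = bool(argmax_unique and z10 > PINGPONG_Z_CUTOFF)

    share = partner_share(reads, region=region, min_len=min_len, max_len=max_len)
    return OverlapSignature(
        scores=scores, z10=z10, significant=significant, partner_share=share
    )


def partner_share(
    reads: Sequence[MappedRead],
    region: tuple[str, int, int] | None = None,
    min_len: int = 24,
    max_len: int = 32,
) -> float:
    """Fraction of distinct 24-32 nt sequences with at least one exact
    10-nt 5'-overlap partner.  Invariant to copy counts."""
    reads = [r for r in reads if min_len <= r.length <= max_len]
    if not reads:
        return 0.0
    placed = _placements_in_region(reads, region)
    plus_pos: dict[str, set[int]] = defaultdict(set)
    minus_pos: dict[str, set[int]] = defaultdict(set)
    for r, (chrom, start, strand) in placed:
        five = start if strand == "+" else start + r.length - 1
        (plus_pos if strand == "+" else minus_pos)[chrom].add(five)
    seqs_with_partner: set[str] = set()
    seen_seqs: set[str] = set()
    for r, (chrom, start, strand) in placed:
        seen_seqs.add(r.sequence)
        five = start if strand == "+" else start + r.length - 1
        if strand == "+":
            if five + 9 in minus_pos.get(chrom, ()):
                seqs_with_partner.add(r.sequence)
        else:
            if five - 9 in plus_pos.get(chrom, ()):
                seqs_with_partner.add(r.sequence)
    if not seen_seqs:
        return 0.0
    return len(seqs_with_partner) / len(seen_seqs)


def pingpong_length_matrix(
    reads: Sequence[MappedRead],
    region: tuple[str, int, int] | None = None,
    min_len: int = 24,
    max_len: int = 32,
) -> pd.DataFrame:
    """Weighted 2-D histogram over (length_A, length_B) of 10-nt-overlap
    pairs; unordered pairs are counted once (upper triangle + diagonal).
    The matrix total equals s(10) of :func:`overlap_signature`."""
    reads = [r for r in reads if min_len <= r.length <= max_len]
    placed = _placements_in_region(reads, region)
    plus: dict[str, defaultdict[int, defaultdict[int, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float))
    )
    minus: dict[str, defaultdict[int, defaultdict[int, float]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(float))
    )
    for r, (chrom, start, strand) in placed:
        w = r.weight_per_placement
        five = start if strand == "+" else start + r.length - 1
        (plus if strand == "+" else minus)[chrom][five][r.length] += w
    sizes = list(range(min_len, max_len + 1))
    mat = pd.DataFrame(0.0, index=sizes, columns=sizes)
    for chrom, by_pos in plus.items():
        mby = minus.get(chrom)
        if not mby:
            continue
        for p, p_lens in by_pos.items():
            m_lens = mby.get(p + 9)
            if not m_lens:
                continue
            for la, wa in p_lens.items():
                for lb, wb in m_lens.items():
                    lo, hi = min(la, lb), max(la, lb)
                    mat.loc[lo, hi] += wa * wb
    mat.index.name = "length_A"
    mat.columns.name = "length_B"
    return mat
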