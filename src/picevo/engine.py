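"""Similarity-search engine adapter.

Homology mapping and pseudogene prediction both need a local nucleotide
similarity search.  The default engine is a built-in k-mer-seeded aligner:
exact word matches are grouped on alignment diagonals, diagonal seed runs
are extended with an x-drop criterion, and each hit is scored ungapped
(+1 match / -2 mismatch, the classic blastn reward/penalty).  This is
sufficient and fast for substitution-diverged sequences; an adapter around
the external ``blastn`` binary producing the standard 12-column tabular
format is provided for gapped/low-identity work.

Lowercase (repeat-masked) and N positions in the subject never seed a hit;
extension may run through them but they count as mismatches.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_CODE_UNMASKED = _CODE.copy()
for i, b in enumerate("acgt"):
    _CODE_UNMASKED[ord(b)] = i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# rough ungapped Karlin-Altschul parameters for +1/-2 scoring
_LAMBDA = 1.28
_KAPPA = 0.46


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def encode(seq: str, respect_mask: bool = True) -> np.ndarray:
    """Map a sequence to codes 0-3; masked/ambiguous positions become 4.

    With ``respect_mask=False`` lowercase bases are treated as ordinary
    bases (used for query sequences and identity computation)."""
    table = _CODE if respect_mask else _CODE_UNMASKED
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SimilarityHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # strand of the subject relative to the query
    identity: float
    aligned_bp: int
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aligned_bp <= 0:
            raise ValueError("aligned_bp must be positive")


class KmerAligner:
    """Built-in k-mer-seeded ungapped local aligner.

    Parameters
    ----------
    word_size:
        Seed length.  11 (default) suits gene-level searches; 9 increases
        sensitivity for diverged non-coding sequence (the "sensitive"
        mode used for cluster-homolog detection).
    chain_gap:
        Seeds on the same diagonal closer than this are chained into one
        candidate before extension.
    xdrop:
        Extension stops when the running score falls this far below its
        maximum.
    min_length / min_identity:
        Hits below either threshold are discarded.
    max_word_hits:
        Words occurring more often than this in the subject are ignored
        (low-complexity guard).
    """

    def __init__(
        self,
        word_size: int = 11,
        chain_gap: int = 200,
        xdrop: int = 20,
        min_length: int = 30,
        min_identity: float = 0.6,
        max_word_hits: int = 100,
        min_run_seeds: int = 2,
        extend_window: int = 800,
    ) -> None:
        self.word_size = word_size
        self.chain_gap = chain_gap
        self.xdrop = xdrop
        self.min_length = min_length
        self.min_identity = min_identity
        self.max_word_hits = max_word_hits
        # isolated single seeds are overwhelmingly chance matches; hits
        # detectable at min_length/min_identity carry several seeds
        self.min_run_seeds = min_run_seeds
        # x-drop cannot plausibly extend further than this through
        # non-homologous sequence (expected score slope is about -1.25/nt)
        self.extend_window = extend_window
        # subject k-mer indices are expensive for Mb-scale genomes; cache
        # them per subject string for the lifetime of the aligner
        self._index_cache: dict[int, tuple[str, tuple]] = {}

    @classmethod
    def sensitive(cls) -> "KmerAligner":
        """Preset for diverged non-coding sequence (smaller word size)."""
        return cls(word_size=9, xdrop=30, min_identity=0.55)

    # -- subject indexing ------------------------------------------------

    def _kmer_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(positions, packed kmers) for all valid k-mers of ``codes``."""
        k = self.word_size
        n = len(codes) - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        valid = codes[: n] < 4
        packed = np.zeros(n, dtype=np.int64)
        for i in range(k):
            c = codes[i : n + i]
            if i > 0:
                valid &= c < 4
            packed = packed * 4 + np.where(c < 4, c, 0)
        pos = np.nonzero(valid)[0]
        return pos, packed[pos]

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
    ) -> list[SimilarityHit]:
        """All local hits of each query against each subject, both strands."""
        hits: list[SimilarityHit] = []
        for sid, sseq in subjects.items():
            cached = self._index_cache.get(id(sseq))
            if cached is not None and cached[0] is sseq:
                s_codes, s_kmers_sorted, s_pos_sorted = cached[1]
            else:
                s_codes_masked = encode(sseq, respect_mask=True)
                s_codes = encode(sseq, respect_mask=False)
                s_pos, s_kmers = self._kmer_codes(s_codes_masked)
                order = np.argsort(s_kmers, kind="stable")
                s_kmers_sorted = s_kmers[order]
                s_pos_sorted = s_pos[order]
                self._index_cache[id(sseq)] = (
                    sseq,
                    (s_codes, s_kmers_sorted, s_pos_sorted),
                )
            if len(s_pos_sorted) == 0:
                continue
            for qid, qseq in queries.items():
                for strand, q in (("+", qseq), ("-", revcomp(qseq))):
                    for hit in self._search_one(
                        q, s_codes, s_kmers_sorted, s_pos_sorted
                    ):
                        qs, qe, ss, se, ident, alen, score = hit
                        if strand == "-":
                            qs, qe = len(qseq) - qe, len(qseq) - qs
                        e = self._evalue(score, len(qseq), len(sseq))
                        hits.append(
                            SimilarityHit(
                                query_id=qid,
                                subject_id=sid,
                                q_start=qs,
                                q_end=qe,
                                s_start=ss,
                                s_end=se,
                                strand=strand,
                                identity=ident,
                                aligned_bp=alen,
                                e_value=e,
                            )
                        )
        return hits

    def _search_one(self, qseq, s_codes, s_kmers_sorted, s_pos_sorted):
        q_codes = encode(qseq, respect_mask=False)
        q_pos, q_kmers = self._kmer_codes(q_codes)
        if len(q_pos) == 0:
            return
        left = np.searchsorted(s_kmers_sorted, q_kmers, side="left")
        right = np.searchsorted(s_kmers_sorted, q_kmers, side="right")
        counts = right - left
        keep = (counts > 0) & (counts <= self.max_word_hits)
        if not keep.any():
            return
        q_idx = np.repeat(q_pos[keep], counts[keep])
        starts = left[keep]
        ends = right[keep]
        s_idx = np.concatenate(
            [s_pos_sorted[a:b] for a, b in zip(starts, ends)]
        )
        diag = s_idx - q_idx
        order = np.lexsort((q_idx, diag))
        diag, q_idx, s_idx = diag[order], q_idx[order], s_idx[order]
        # break into diagonal runs with bounded seed gaps
        brk = np.nonzero(
            (np.diff(diag) != 0) | (np.diff(q_idx) > self.chain_gap)
        )[0] + 1
        run_starts = np.concatenate([[0], brk])
        run_ends = np.concatenate([brk, [len(diag)]])
        seen: set[tuple[int, int, int]] = set()
        for a, b in zip(run_starts, run_ends):
            if b - a < self.min_run_seeds:
                continue
            d = int(diag[a])
            q0 = int(q_idx[a])
            q1 = int(q_idx[b - 1]) + self.word_size
            res = self._extend(q_codes, s_codes, d, q0, q1)
            if res is None:
                continue
            key = (d, res[0], res[1])
            if key in seen:
                continue
            seen.add(key)
            yield res

    def _extend(self, q_codes, s_codes, diag, q0, q1):
        """Ungapped x-drop extension of [q0, q1) on a diagonal."""
        lq, ls = len(q_codes), len(s_codes)
        lo = max(0, -diag, q0 - self.extend_window)
        hi = min(lq, ls - diag, q1 + self.extend_window)
        if hi - lo <= 0:
            return None
        seg_q = q_codes[lo:hi]
        seg_s = s_codes[lo + diag : hi + diag]
        match = (seg_q == seg_s) & (seg_q < 4)
        score = np.where(match, 1, -2)
        i0, i1 = q0 - lo, q1 - lo
        start = self._xdrop_back(score, i0)
        end = self._xdrop_fwd(score, i1)
        # trim mismatching edges
        m = match[start:end]
        nz = np.nonzero(m)[0]
        if len(nz) == 0:
            return None
        start2, end2 = start + nz[0], start + nz[-1] + 1
        alen = end2 - start2
        matches = int(m[nz[0] : nz[-1] + 1].sum())
        ident = matches / alen
        if alen < self.min_length or ident < self.min_identity:
            return None
        sc = matches - 2 * (alen - matches)
        return (lo + start2, lo + end2, lo + diag + start2, lo + diag + end2,
                ident, alen, sc)

    def _xdrop_fwd(self, score: np.ndarray, i1: int) -> int:
        run = np.cumsum(score[i1:])
        if len(run) == 0:
            return i1
        best = np.maximum.accumulate(run)
        dropped = np.nonzero(best - run > self.xdrop)[0]
        stop = dropped[0] if len(dropped) else len(run)
        if stop == 0:
            return i1
        return i1 + int(np.argmax(run[:stop])) + 1

    def _xdrop_back(self, score: np.ndarray, i0: int) -> int:
        rev = score[:i0][::-1]
        run = np.cumsum(rev)
        if len(run) == 0:
            return i0
        best = np.maximum.accumulate(run)
        dropped = np.nonzero(best - run > self.xdrop)[0]
        stop = dropped[0] if len(dropped) else len(run)
        if stop == 0:
            return i0
        return i0 - (int(np.argmax(run[:stop])) + 1)

    @staticmethod
    def _evalue(score: int, qlen: int, slen: int) -> float:
        return float(_KAPPA * qlen * slen * math.exp(-_LAMBDA * min(score, 700)))


class BlastnEngine:
    """Adapter around the external NCBI ``blastn`` binary.

    Emits the same :class:`SimilarityHit` records from blastn's standard
    12-column tabular output.  ``task`` may be ``blastn``, ``megablast``
    or ``dc-megablast``.
    """

    def __init__(self, task: str = "dc-megablast", evalue: float = 1e-3) -> None:
        if shutil.which("blastn") is None:
            raise RuntimeError("blastn not found on PATH")
        self.task = task
        self.evalue = evalue

    def search(
        self, queries: Mapping[str, str], subjects: Mapping[str, str]
    ) -> list[SimilarityHit]:
        from . import core_io

        with tempfile.TemporaryDirectory() as tmp:
            qpath = Path(tmp) / "q.fa"
            spath = Path(tmp) / "s.fa"
            core_io.write_fasta(queries, qpath)
            core_io.write_fasta(subjects, spath)
            proc = subprocess.run(
                [
                    "blastn", "-task", self.task, "-query", str(qpath),
                    "-subject", str(spath), "-evalue", str(self.evalue),
                    "-outfmt", "6", "-dust", "no", "-soft_masking", "false",
                ],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
            return parse_tabular(proc.stdout)


def parse_tabular(text: str) -> list[SimilarityHit]:
    """Parse standard 12-column tabular hit format (blast -outfmt 6)."""
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        (qid, sid, pident, alen, _mm, _go, qs, qe, ss, se, ev, _bits) = (
            line.split("\t")[:12]
        )
        ss_i, se_i = int(ss), int(se)
        if ss_i <= se_i:
            strand, s_lo, s_hi = "+", ss_i - 1, se_i
        else:
            strand, s_lo, s_hi = "-", se_i - 1, ss_i
        hits.append(
            SimilarityHit(
                query_id=qid,
                subject_id=sid,
                q_start=int(qs) - 1,
                q_end=int(qe),
                s_start=s_lo,
                s_end=s_hi,
                strand=strand,
                identity=float(pident) / 100.0,
                aligned_bp=int(alen),
                e_value=float(ev),
            )
        )
    return hits
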