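"""Seed-and-extend nucleotide mapping against genome-scale subjects.

Exact k-mer seeds (2-bit packed, numpy-sorted) locate a candidate window on
the subject; the query is then aligned inside that window with edlib
(infix semi-global alignment) and identity is read off the extended cigar.
This keeps fragment-vs-genome and contig-vs-genome comparisons linear-ish
in practice, where a full dynamic program would be quadratic in genome
length.

Identity here is percent of alignment columns that are matches, counting
mismatches and indel columns in the denominator — the same convention as
:func:`novitax.seqcore.align`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, start positions) of all valid (N-free) k-mers of *seq*."""
    vals = _encode(seq)
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = vals[i : i + n]
        valid &= window != 255
        codes = (codes << np.uint64(2)) | window.astype(np.uint64)
    pos = np.nonzero(valid)[0]
    return codes[pos], pos


@dataclass(frozen=True)
class FragmentHit:
    identity: float        # percent over alignment columns
    coverage: float        # fraction of query consumed by the alignment
    subject_start: int
    subject_end: int
    n_seeds: int


class GenomeIndex:
    """Sorted-array exact k-mer index over one nucleotide sequence."""

    def __init__(self, seq: str, k: int = 15):
        self.seq = seq
        self.k = k
        codes, pos = _kmer_codes(seq, k)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def seed_positions(self, query: str, max_per_kmer: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, subject_pos) pairs of exact k-mer matches."""
        qcodes, qpos = _kmer_codes(query, self.k)
        if qcodes.size == 0 or self._codes.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        counts = np.minimum(hi - lo, max_per_kmer)
        total = int(counts.sum())
        qout = np.empty(total, dtype=np.int64)
        sout = np.empty(total, dtype=np.int64)
        at = 0
        for i in np.nonzero(counts)[0]:
            c = counts[i]
            qout[at : at + c] = qpos[i]
            sout[at : at + c] = self._pos[lo[i] : lo[i] + c]
            at += c
        return qout, sout

    def map_fragment(self, query: str, min_seeds: int = 2, pad: float = 0.15,
                     both_strands: bool = True) -> FragmentHit | None:
        """Best placement of *query* on the indexed subject, or None.

        The densest seed diagonal picks a subject window (query span plus a
        *pad* fraction margin for indels); edlib then aligns the whole query
        inside that window.  With *both_strands* the orientation with more
        seed matches is used.
        """
        if both_strands:
            from .seqcore import reverse_complement

            rc = reverse_complement(query)
            if self.seed_positions(rc)[0].size > self.seed_positions(query)[0].size:
                query = rc
        qpos, spos = self.seed_positions(query)
        if qpos.size < min_seeds:
            return None
        diag = spos - qpos
        # cluster diagonals into coarse bins so small indels stay together
        binsize = max(16, int(pad * len(query) / 2))
        bins = diag // binsize
        uniq, counts = np.unique(bins, return_counts=True)
        best_bin = uniq[np.argmax(counts)]
        sel = np.abs(bins - best_bin) <= 1
        if int(sel.sum()) < min_seeds:
            return None
        d0 = int(np.median(diag[sel]))
        margin = int(pad * len(query)) + 32
        w0 = max(0, d0 - margin)
        w1 = min(len(self.seq), d0 + len(query) + margin)
        if w1 - w0 < self.k:
            return None
        window = self.seq[w0:w1]
        res = edlib.align(query, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        matches = columns = qconsumed = 0
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(num)
            columns += n
            if op == "=":
                matches += n
                qconsumed += n
            elif op == "X":
                qconsumed += n
            elif op == "I":  # insertion relative to target = query-only column
                qconsumed += n
        loc = res["locations"][0]
        identity = 100.0 * matches / columns if columns else 0.0
        return FragmentHit(
            identity=identity,
            coverage=qconsumed / len(query) if query else 0.0,
            subject_start=w0 + loc[0],
            subject_end=w0 + loc[1] + 1,
            n_seeds=int(sel.sum()),
        )
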