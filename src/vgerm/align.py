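"""Pairwise alignment of reads against germline alleles.

Implements an affine-gap local alignment with free end gaps on both
sequences: the reference (germline allele) may be truncated at either end and
the query (read) may have unaligned flanks, which is exactly the geometry of
a V segment embedded in a 5'RACE amplicon.  Default scoring is match +1,
mismatch -2, gap open -5, gap extend -2.

The dynamic-programming kernel is numba-compiled; the traceback additionally
produces a reference-to-query coordinate map used downstream for reading-frame
anchoring and CDR3 detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

NEG = -(10**8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _align_kernel(r, q, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m = r.shape[0]
    n = q.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            if r[i - 1] == q[j - 1] and r[i - 1] < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            # deterministic argmax: strictly greater, or equal with larger
            # reference end then smaller query end
            if h > best or (h == best and (i > bi or (i == bi and j < bj))):
                best = h
                bi = i
                bj = j

    # traceback with explicit affine state, diagonal preferred on ties
    ref2query = np.full(m, -2, dtype=np.int32)
    n_sub = 0
    n_gap = 0
    i = bi
    j = bj
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, ref2query
    state = 0  # 0=H, 1=E (gap in ref, consumes query), 2=F (gap in query)
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if r[i - 1] == q[j - 1] and r[i - 1] < 4:
                s = match
            else:
                s = mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ref2query[i - 1] = j - 1
                if s == mismatch:
                    n_sub += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:
            # gap in reference: query base j-1 is an insertion
            n_gap += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            # gap in query: reference base i-1 is deleted
            ref2query[i - 1] = -1
            n_gap += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return best, i, bi, j, bj, n_sub, n_gap, ref2query


@dataclass
class Alignment:
    """Result of aligning a query read against one reference allele.

    ``r_start``/``r_end`` and ``q_start``/``q_end`` are half-open spans on the
    reference and query.  ``ref2query[i]`` maps reference position ``i`` to
    its aligned query position (-1: deleted reference base; -2: outside the
    aligned span).  ``errors`` counts substitutions plus gapped bases.
    """

    score: int
    r_start: int
    r_end: int
    q_start: int
    q_end: int
    n_sub: int
    n_gap: int
    ref2query: np.ndarray
    ref_length: int

    @property
    def errors(self) -> int:
        return self.n_sub + self.n_gap

    @property
    def ref_span(self) -> int:
        return self.r_end - self.r_start

    @property
    def coverage(self) -> float:
        return self.ref_span / self.ref_length if self.ref_length else 0.0

    @property
    def percent_difference(self) -> float:
        return 100.0 * self.errors / self.ref_span if self.ref_span else 100.0


DEFAULT_SCORING = dict(match=1, mismatch=-2, gap_open=-5, gap_extend=-2)


def align(query: str, reference: str, **scoring) -> Alignment:
    """Align ``query`` against ``reference`` (free end gaps, affine)."""
    sc = {**DEFAULT_SCORING, **scoring}
    score, r0, r1, q0, q1, n_sub, n_gap, ref2query = _align_kernel(
        encode(reference), encode(query),
        sc["match"], sc["mismatch"], sc["gap_open"], sc["gap_extend"],
    )
    return Alignment(
        score=int(score), r_start=int(r0), r_end=int(r1),
        q_start=int(q0), q_end=int(q1), n_sub=int(n_sub), n_gap=int(n_gap),
        ref2query=ref2query, ref_length=len(reference),
    )


# Karlin-Altschul ungapped parameters for the +1/-2 nucleotide scheme
# (blastn defaults); used for the E-value surrogate of the assignment gate.
KA_LAMBDA = 1.33
KA_K = 0.621


def evalue(score: int, query_length: int, database_length: int) -> float:
    """E-value surrogate ``m * n * 2^(-bit score)`` for an alignment score."""
    bit = (KA_LAMBDA * score - np.log(KA_K)) / np.log(2.0)
    return float(query_length) * float(database_length) * 2.0 ** (-bit)


__all__ = ["Alignment", "align", "encode", "evalue", "DEFAULT_SCORING"]
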