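"""Assignment of reads to germline V and J alleles, CDR3 detection, quality filter.

Each preprocessed read is aligned against every database V allele and
assigned to the best-scoring one; the J segment is then searched 3' of the V
alignment end.  The CDR3 is detected at the amino-acid level between the
conserved second cysteine at the end of the V segment and the J anchor motif
(W-G-x-G for heavy chains, F-G-x-G for light chains).  The reading frame is
inherited from the database allele, whose first position is codon position 1
(the convention of curated V databases).

A fast edit-distance prescreen (edlib) limits the number of full
dynamic-programming alignments per read; the winning allele is always scored
with the exact affine aligner of :mod:`vgerm.align`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import pandas as pd
from Bio.Seq import Seq

from .align import Alignment, align, evalue
from .filters import FilterThresholds
from .records import GermlineAllele, GermlineDatabase, SequenceRecord

J_ANCHOR = {"heavy": re.compile(r"WG.G"), "kappa": re.compile(r"FG.G"),
            "lambda": re.compile(r"FG.G")}

# conserved Cys must sit within this many codons of the reference V end
CYS_WINDOW_CODONS = 7


@dataclass
class AssignConfig:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    prescreen_margin: int = 4
    # terminal reference segments up to this length that the local alignment
    # clipped (mutations at the very edge of the V) are re-included, with
    # their mismatches counted as errors, provided the read covers them
    terminal_extension: int = 12

    def scoring(self) -> dict:
        return dict(match=self.match, mismatch=self.mismatch,
                    gap_open=self.gap_open, gap_extend=self.gap_extend)


def _extend_terminal(aln: Alignment, query: str, reference: str, max_ext: int) -> Alignment:
    """Re-include short clipped terminal reference segments.

    A substitution in the first or last bases of the V segment makes the
    optimal local alignment clip the reference end, which would truncate the
    read's V-region sequence and hide the mismatch.  When the clipped
    reference overhang is at most ``max_ext`` bases and the read extends far
    enough, the overhang is aligned base-for-base and its mismatches counted.
    """
    if aln.ref_span == 0:
        return aln
    r0, r1, q0, q1 = aln.r_start, aln.r_end, aln.q_start, aln.q_end
    n_sub = aln.n_sub
    head = aln.r_start
    if 0 < head <= max_ext and q0 >= head:
        for k in range(head):
            aln.ref2query[k] = q0 - head + k
            if reference[k] != query[q0 - head + k]:
                n_sub += 1
        r0, q0 = 0, q0 - head
    tail = aln.ref_length - aln.r_end
    if 0 < tail <= max_ext and len(query) - q1 >= tail:
        for k in range(tail):
            aln.ref2query[r1 + k] = q1 + k
            if reference[r1 + k] != query[q1 + k]:
                n_sub += 1
        r1, q1 = aln.ref_length, q1 + tail
    if (r0, r1, q0, q1, n_sub) == (aln.r_start, aln.r_end, aln.q_start, aln.q_end, aln.n_sub):
        return aln
    return Alignment(
        score=aln.score, r_start=r0, r_end=r1, q_start=q0, q_end=q1,
        n_sub=n_sub, n_gap=aln.n_gap, ref2query=aln.ref2query,
        ref_length=aln.ref_length,
    )


@dataclass
class VJAssignment:
    """One read's V/J assignment and derived annotations."""

    query_id: str
    v_name: Optional[str] = None
    j_name: Optional[str] = None
    v_score: float = 0.0
    v_evalue: float = float("inf")
    v_coverage: float = 0.0
    j_coverage: float = 0.0
    v_errors: int = 0
    v_percent_difference: float = 0.0
    v_sequence: str = ""
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    has_stop: bool = False
    upstream_sequence: str = ""
    count: int = 1


def align_to_allele(query: str, allele: GermlineAllele, config: Optional[AssignConfig] = None) -> Alignment:
    """Optimal free-end-gap alignment of a read against one allele."""
    config = config or AssignConfig()
    return align(query, allele.sequence, **config.scoring())


def _translate(nt: str) -> str:
    usable = len(nt) - len(nt) % 3
    if usable <= 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def _frame_anchors(aln: Alignment) -> tuple[Optional[int], Optional[int]]:
    """Query positions of the first and last fully aligned reference codons."""
    r2q = aln.ref2query
    n_codons = aln.ref_length // 3
    first = last = None
    for k in range(n_codons):
        a, b, c = r2q[3 * k], r2q[3 * k + 1], r2q[3 * k + 2]
        if a >= 0 and b == a + 1 and c == a + 2:
            if first is None:
                first = int(a)
            last = int(a)
    return first, last


def detect_cdr3(
    record: SequenceRecord, aln: Alignment, chain: str = "heavy"
) -> tuple[Optional[str], Optional[str]]:
    """Detect the CDR3 of a read given its V alignment.

    Returns ``(cdr3_nt, cdr3_aa)`` from (and including) the conserved
    second-cysteine codon to (and excluding) the J anchor motif, or
    ``(None, None)`` when either anchor is missing.  The frame is anchored at
    the last fully aligned reference codon so that indels upstream of FR3 do
    not shift the search.
    """
    r2q = aln.ref2query
    n_codons = aln.ref_length // 3
    # anchor the frame at the first fully aligned codon inside the terminal
    # Cys search window, so indels upstream of FR3 cannot shift the search
    kw = q3 = None
    for k in range(max(0, n_codons - CYS_WINDOW_CODONS), n_codons):
        a, b, c = r2q[3 * k], r2q[3 * k + 1], r2q[3 * k + 2]
        if a >= 0 and b == a + 1 and c == a + 2:
            kw, q3 = k, int(a)
            break
    if q3 is None:
        return None, None
    pep = _translate(record.sequence[q3:])
    hi = min(len(pep), n_codons - kw)
    pc = None
    for p in range(hi):
        if pep[p] == "C":
            pc = p
    if pc is None:
        return None, None
    m = J_ANCHOR.get(chain, J_ANCHOR["heavy"]).search(pep, pc + 1)
    if m is None:
        return None, None
    pw = m.start()
    cdr3_nt = record.sequence[q3 + 3 * pc: q3 + 3 * pw]
    return cdr3_nt, pep[pc:pw]


def assign_vj(
    record: SequenceRecord,
    vdb: GermlineDatabase,
    jdb: Optional[GermlineDatabase] = None,
    config: Optional[AssignConfig] = None,
) -> VJAssignment:
    """Assign a read to its best V (and J) allele and annotate it.

    The best V allele maximizes the alignment score; ties are broken by
    fewest errors, then database order.  The J segment is searched only 3'
    of the V alignment end.
    """
    config = config or AssignConfig()
    if len(vdb) == 0:
        raise ValueError("V database must be non-empty")
    seq = record.sequence

    # edit-distance prescreen: only alleles within the margin of the best
    # edit distance are aligned exactly
    dists = []
    for a in vdb.alleles:
        d = edlib.align(a.sequence, seq, mode="HW", task="distance")["editDistance"]
        dists.append(d if d >= 0 else 10**9)
    dmin = min(dists)
    candidates = [i for i, d in enumerate(dists) if d <= dmin + config.prescreen_margin]

    best: Optional[tuple] = None
    total_db_len = sum(len(a.sequence) for a in vdb.alleles)
    for i in candidates:
        aln = align(seq, vdb.alleles[i].sequence, **config.scoring())
        key = (-aln.score, aln.errors, i)
        if best is None or key < best[0]:
            best = (key, i, aln)
    assert best is not None
    _, vi, valn = best
    out = VJAssignment(query_id=record.id, count=record.count)
    if valn.score <= 0 or valn.ref_span == 0:
        return out
    vallele = vdb.alleles[vi]
    valn = _extend_terminal(valn, seq, vallele.sequence, config.terminal_extension)
    out.v_name = vallele.name
    out.v_score = float(valn.score)
    out.v_evalue = evalue(valn.score, len(seq), total_db_len)
    out.v_coverage = valn.coverage
    out.v_errors = valn.errors
    out.v_percent_difference = valn.percent_difference
    out.v_sequence = seq[valn.q_start:valn.q_end]
    out.upstream_sequence = seq[:valn.q_start]

    j_end_abs = len(seq)
    if jdb is not None and len(jdb) > 0:
        region = seq[valn.q_end:]
        jbest: Optional[tuple] = None
        if region:
            for i, ja in enumerate(jdb.alleles):
                jaln = align(region, ja.sequence, **config.scoring())
                key = (-jaln.score, jaln.errors, i)
                if jbest is None or key < jbest[0]:
                    jbest = (key, i, jaln)
        if jbest is not None and jbest[2].score > 0:
            _, ji, jaln = jbest
            out.j_name = jdb.alleles[ji].name
            out.j_coverage = jaln.coverage
            j_end_abs = valn.q_end + jaln.q_end

    cdr3_nt, cdr3_aa = detect_cdr3(record, valn, chain=vdb.chain)
    out.cdr3_nt = cdr3_nt
    out.cdr3_aa = cdr3_aa

    q5, _ = _frame_anchors(valn)
    if q5 is not None:
        out.has_stop = "*" in _translate(seq[q5:j_end_abs])
    return out


def assign_all(
    records: Sequence[SequenceRecord],
    vdb: GermlineDatabase,
    jdb: Optional[GermlineDatabase] = None,
    config: Optional[AssignConfig] = None,
) -> list[VJAssignment]:
    """Assign every record; order preserved."""
    config = config or AssignConfig()
    return [assign_vj(r, vdb, jdb, config) for r in records]


def quality_filter(
    assignments: Sequence[VJAssignment],
    thresholds: Optional[FilterThresholds] = None,
    require_j: bool = True,
) -> list[VJAssignment]:
    """Keep assignments passing the quality gate.

    Requires an assigned V (and J, unless ``require_j`` is off because no J
    database was given), no stop codon, E-value at most ``max_evalue``, V
    coverage at least ``min_v_coverage`` and J coverage at least
    ``min_j_coverage``.  Boundary values pass ("at least").  Idempotent.
    """
    t = thresholds or FilterThresholds()
    out = []
    for a in assignments:
        if a.v_name is None:
            continue
        if require_j and a.j_name is None:
            continue
        if a.has_stop:
            continue
        if a.v_evalue > t.max_evalue:
            continue
        if a.v_coverage < t.min_v_coverage:
            continue
        if require_j and a.j_coverage < t.min_j_coverage:
            continue
        out.append(a)
    return out


TABLE_COLUMNS = [
    "query_id", "v_name", "j_name", "v_score", "v_evalue", "v_coverage",
    "j_coverage", "v_errors", "v_percent_difference", "v_sequence",
    "cdr3_nt", "cdr3_aa", "has_stop", "upstream_sequence", "count",
]


def to_table(assignments: Sequence[VJAssignment]) -> pd.DataFrame:
    """Assignment table, one row per read (written as TSV by the CLI)."""
    return pd.DataFrame(
        [{c: getattr(a, c) for c in TABLE_COLUMNS} for a in assignments],
        columns=TABLE_COLUMNS,
    )


def from_table(df: pd.DataFrame) -> list[VJAssignment]:
    """Rebuild assignments from a table produced by :func:`to_table`."""
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for key in ("v_name", "j_name", "cdr3_nt", "cdr3_aa"):
            if pd.isna(d[key]):
                d[key] = None
        for key in ("v_sequence", "upstream_sequence"):
            if pd.isna(d[key]):
                d[key] = ""
        d["has_stop"] = bool(d["has_stop"])
        d["count"] = int(d["count"])
        out.append(VJAssignment(**d))
    return out


__all__ = [
    "AssignConfig", "VJAssignment", "align_to_allele", "assign_vj",
    "assign_all", "detect_cdr3", "quality_filter", "to_table", "from_table",
    "TABLE_COLUMNS",
]
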