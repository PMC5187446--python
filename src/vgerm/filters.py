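"""Candidate validation: evidence counting, pregermline/germline filters.

A candidate consensus becomes a germline allele only if independent
rearrangements support it: the exact occurrences of the candidate in the full
data set must carry enough distinct CDR3 junctions and J genes.  Candidates
within two bases of a better-supported candidate are collapsed; candidates
identical to a starting-database sequence are whitelisted past the criteria.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .records import GermlineAllele, GermlineDatabase

if TYPE_CHECKING:  # pragma: no cover
    from .assign import VJAssignment


@dataclass
class FilterThresholds:
    """All configurable filter thresholds.

    Germline-filter defaults: cluster of >= 100 sequences, >= 10 unique
    CDR3s, >= 3 unique J genes.  The pregermline filter applies no cluster
    size and requires >= 2 unique CDR3s and >= 2 unique J genes.  Quality
    gate: E-value <= 1e-3, V coverage >= 90%, J coverage >= 60%.
    """

    min_cluster_size: int = 100
    pregermline_min_unique_cdr3: int = 2
    pregermline_min_unique_j: int = 2
    min_unique_cdr3: int = 10
    min_unique_j: int = 3
    max_near_duplicate_diff: int = 2
    terminal_tolerance: int = 3
    exact_match_tolerance: int = 0
    j_criterion_enabled: bool = True
    max_evalue: float = 1e-3
    min_v_coverage: float = 0.90
    min_j_coverage: float = 0.60

    def __post_init__(self) -> None:
        for name in ("min_cluster_size", "min_unique_cdr3", "min_unique_j",
                     "max_near_duplicate_diff", "terminal_tolerance",
                     "exact_match_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CandidateAllele:
    """A consensus sequence proposed as a germline allele.

    ``origin`` records how it was produced: ``window:<lo>-<hi>`` (percent
    difference bin), ``linkage:<cluster id>`` or ``full``.  Evidence fields
    are filled in by :func:`annotate_candidate`.
    """

    sequence: str
    source_allele: str
    origin: str
    cluster_size: int
    exact_occurrences: int = 0
    unique_cdr3: int = 0
    unique_j: int = 0
    name: str = ""
    whitelisted: bool = False


def equal_with_terminal_tolerance(a: str, b: str, tolerance: int) -> tuple[bool, int]:
    """Compare two sequences ignoring small terminal length differences.

    The shorter sequence is slid fully within the longer, each terminal
    overhang at most ``tolerance`` bases; ``diffs`` is the smallest number of
    internal mismatches over the allowed offsets.  Sequences whose length
    difference exceeds ``2 * tolerance`` are incomparable (``(False, inf)``).
    """
    if len(a) > len(b):
        a, b = b, a
    short, long_ = a, b
    gap = len(long_) - len(short)
    if gap > 2 * tolerance:
        return False, float("inf")
    best = None
    for off in range(gap + 1):
        if off > tolerance or gap - off > tolerance:
            continue
        diffs = sum(1 for x, y in zip(short, long_[off:off + len(short)]) if x != y)
        if best is None or diffs < best:
            best = diffs
    if best is None:
        return False, float("inf")
    return best == 0, best


def has_stop_in_frame(sequence: str) -> bool:
    usable = len(sequence) - len(sequence) % 3
    return "*" in str(Seq(sequence[:usable]).translate())


_SUFFIX_RE = re.compile(r"(_S\d{4})+$")


def candidate_name(source_allele: str, sequence: str) -> str:
    """Stable name ``<source>_S<4 digits>`` hashed from the sequence.

    A hash suffix already present on the source allele (a candidate
    rediscovered in a later iteration) is not chained.
    """
    stem = _SUFFIX_RE.sub("", source_allele)
    return f"{stem}_S{zlib.crc32(sequence.encode()) % 10000:04d}"


def annotate_candidate(
    candidate: CandidateAllele,
    all_assignments: Sequence["VJAssignment"],
    tolerance: int = 0,
) -> CandidateAllele:
    """Count evidence for a candidate over the full assignment table.

    ``exact_occurrences`` is the number of reads whose V-region sequence
    equals the candidate (terminal-tolerant when ``tolerance`` > 0);
    ``unique_cdr3``/``unique_j`` count distinct junctions and J genes among
    those reads.  Candidates containing N or an in-frame stop are rejected.
    """
    if "N" in candidate.sequence:
        raise ValueError("candidate contains ambiguous bases")
    if has_stop_in_frame(candidate.sequence):
        raise ValueError("candidate contains a stop codon")
    if tolerance == 0:
        hits = [a for a in all_assignments if a.v_sequence == candidate.sequence]
    else:
        hits = [
            a for a in all_assignments
            if equal_with_terminal_tolerance(a.v_sequence, candidate.sequence, tolerance)[0]
        ]
    cdr3s = {a.cdr3_nt for a in hits if a.cdr3_nt}
    js = {a.j_name for a in hits if a.j_name}
    return replace(
        candidate,
        exact_occurrences=len(hits),
        unique_cdr3=len(cdr3s),
        unique_j=len(js),
    )


def collapse_near_duplicates(
    candidates: Sequence[CandidateAllele], thresholds: Optional[FilterThresholds] = None
) -> list[CandidateAllele]:
    """Remove the weaker of any two candidates differing by at most two bases.

    For each terminal-tolerant pair with internal differences at most
    ``max_near_duplicate_diff``, the candidate with fewer unique CDR3s is
    dropped; ties keep the longer sequence, then the lexicographically
    smaller name.  Iterated to a fixpoint.
    """
    t = thresholds or FilterThresholds()
    kept = list(candidates)
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                _, diffs = equal_with_terminal_tolerance(
                    a.sequence, b.sequence, t.terminal_tolerance
                )
                if diffs > t.max_near_duplicate_diff:
                    continue
                ka = (a.unique_cdr3, len(a.sequence), a.name < b.name)
                kb = (b.unique_cdr3, len(b.sequence), b.name < a.name)
                loser = j if ka >= kb else i
                kept.pop(loser)
                changed = True
                break
            if changed:
                break
    return kept


def apply_filter(
    candidates: Sequence[CandidateAllele],
    mode: str,
    starting_db: GermlineDatabase,
    thresholds: Optional[FilterThresholds] = None,
) -> tuple[GermlineDatabase, pd.DataFrame]:
    """Apply the pregermline or germline filter to annotated candidates.

    A candidate passes if it is whitelisted (identical to a starting-database
    sequence) or meets the evidence criteria of the requested ``mode``; the
    survivors are collapsed for near-duplicates and emitted as the next
    germline database.  Also returns the per-candidate report table.
    """
    if mode not in ("pregermline", "germline"):
        raise ValueError("mode must be 'pregermline' or 'germline'")
    t = thresholds or FilterThresholds()
    start_seqs = starting_db.sequences()
    min_cdr3 = t.min_unique_cdr3 if mode == "germline" else t.pregermline_min_unique_cdr3
    min_j = t.min_unique_j if mode == "germline" else t.pregermline_min_unique_j

    rows = []
    passing: list[CandidateAllele] = []
    for c in candidates:
        whitelisted = c.sequence in start_seqs
        reason = ""
        if whitelisted:
            ok = True
        else:
            ok = True
            if mode == "germline" and c.cluster_size < t.min_cluster_size:
                ok, reason = False, "cluster_size"
            elif c.unique_cdr3 < min_cdr3:
                ok, reason = False, "unique_cdr3"
            elif t.j_criterion_enabled and c.unique_j < min_j:
                ok, reason = False, "unique_j"
        name = c.name
        if whitelisted:
            name = next(a.name for a in starting_db.alleles if a.sequence == c.sequence)
        elif not name:
            name = candidate_name(c.source_allele, c.sequence)
        c = replace(c, name=name, whitelisted=whitelisted)
        rows.append({
            "name": name, "source_allele": c.source_allele, "origin": c.origin,
            "cluster_size": c.cluster_size, "exact_occurrences": c.exact_occurrences,
            "unique_cdr3": c.unique_cdr3, "unique_j": c.unique_j,
            "whitelisted": whitelisted, "passed": ok, "reason": reason,
        })
        if ok:
            passing.append(c)

    passing = collapse_near_duplicates(passing, t)
    alleles = []
    used_names: set[str] = set()
    seen_seqs: set[str] = set()
    for c in sorted(passing, key=lambda c: c.name):
        if c.sequence in seen_seqs:
            continue
        seen_seqs.add(c.sequence)
        name = c.name
        k = 2
        while name in used_names:
            name = f"{c.name}.{k}"
            k += 1
        used_names.add(name)
        alleles.append(GermlineAllele(
            name=name, sequence=c.sequence,
            source="whitelisted" if c.whitelisted else "discovered",
        ))
    report = pd.DataFrame(rows, columns=[
        "name", "source_allele", "origin", "cluster_size", "exact_occurrences",
        "unique_cdr3", "unique_j", "whitelisted", "passed", "reason",
    ])
    return GermlineDatabase(alleles=alleles, chain=starting_db.chain), report


__all__ = [
    "FilterThresholds", "CandidateAllele", "equal_with_terminal_tolerance",
    "annotate_candidate", "collapse_near_duplicates", "apply_filter",
    "candidate_name", "has_stop_in_frame",
]
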