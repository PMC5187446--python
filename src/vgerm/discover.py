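"""Iterative germline V database discovery.

Each iteration assigns all reads to the current database, quality-filters
the assignments, proposes candidate germline sequences per database allele
(windowed clustering, a full consensus, and linkage cluster analysis on a
random subsample), counts independent-rearrangement evidence for each
candidate over the full data set, applies the pregermline filter (the
germline filter on the last iteration) and replaces the database with the
survivors.  A final assignment pass against the finished database produces
the usage profile and the per-allele upstream (5'UTR + leader) consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .assign import AssignConfig, VJAssignment, assign_all, quality_filter
from .cluster import (
    consensus,
    detect_subclusters,
    distance_matrix,
    subsample,
    upgma,
    windowed_clusters,
)
from .filters import (
    CandidateAllele,
    FilterThresholds,
    annotate_candidate,
    apply_filter,
)
from .records import GermlineDatabase, SequenceRecord

logger = logging.getLogger(__name__)

RECOMMENDED_MIN_READS = 400_000


class DiscoveryError(RuntimeError):
    """The database became empty during iteration."""


@dataclass
class DiscoveryConfig:
    iterations: int = 3
    seed: int = 1
    subsample_size: int = 1000
    window_width_percent: float = 2.0
    min_window_members: int = 5
    min_subtree_size: int = 5
    subcluster_ratio: float = 0.8
    consensus_majority: float = 0.6
    include_full_consensus: bool = True
    early_stop: bool = False
    max_v_error_rate: float = 0.01  # upstream detection gate
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    assign: AssignConfig = field(default_factory=AssignConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class IterationState:
    iteration: int
    input_db: GermlineDatabase
    n_assigned: int
    n_passed: int
    candidate_table: pd.DataFrame
    output_db: GermlineDatabase


@dataclass
class UpstreamRecord:
    allele_name: str
    consensus: str
    support: int


@dataclass
class DiscoveryResult:
    final_db: GermlineDatabase
    iterations: list[IterationState]
    final_assignments: list[VJAssignment]
    usage: pd.DataFrame
    upstream: list[UpstreamRecord]


def _subsample_seed(seed: int, iteration: int, allele_index: int) -> int:
    return (seed * 1_000_003 + iteration * 10_007 + allele_index * 101) % (2**31 - 1)


def _propose_candidates(
    allele_name: str,
    group: Sequence[VJAssignment],
    config: DiscoveryConfig,
    iteration: int,
    allele_index: int,
) -> list[CandidateAllele]:
    out: list[CandidateAllele] = []
    for w in windowed_clusters(
        group, config.window_width_percent, config.min_window_members
    ):
        cons = consensus(w.members, w.counts, config.consensus_majority)
        out.append(CandidateAllele(
            sequence=cons, source_allele=allele_name,
            origin=f"window:{w.interval[0]:g}-{w.interval[1]:g}",
            cluster_size=w.n_unique,
        ))

    uniq: dict[str, int] = {}
    for a in group:
        uniq[a.v_sequence] = uniq.get(a.v_sequence, 0) + a.count
    if config.include_full_consensus and len(uniq) >= config.min_window_members:
        members = list(uniq)
        cons = consensus(members, [uniq[m] for m in members],
                         config.consensus_majority)
        out.append(CandidateAllele(
            sequence=cons, source_allele=allele_name, origin="full",
            cluster_size=len(uniq),
        ))

    sub = subsample(group, config.subsample_size,
                    seed=_subsample_seed(config.seed, iteration, allele_index))
    sub_uniq: dict[str, int] = {}
    for a in sub:
        sub_uniq[a.v_sequence] = sub_uniq.get(a.v_sequence, 0) + a.count
    seqs = list(sub_uniq)
    if len(seqs) >= 2 * config.min_subtree_size:
        tree = upgma(distance_matrix(seqs))
        for ci, lc in enumerate(detect_subclusters(
            tree, config.min_subtree_size, config.subcluster_ratio,
            source_allele=allele_name,
        )):
            members = [seqs[i] for i in lc.member_indices]
            cons = consensus(members, [sub_uniq[m] for m in members],
                             config.consensus_majority)
            out.append(CandidateAllele(
                sequence=cons, source_allele=allele_name,
                origin=f"linkage:{ci}", cluster_size=len(members),
            ))
    return out


def _dedupe_candidates(candidates: list[CandidateAllele]) -> list[CandidateAllele]:
    by_seq: dict[str, CandidateAllele] = {}
    for c in candidates:
        prev = by_seq.get(c.sequence)
        if prev is None or c.cluster_size > prev.cluster_size:
            by_seq[c.sequence] = c
    return list(by_seq.values())


def run_discovery(
    reads: Sequence[SequenceRecord],
    starting_db: GermlineDatabase,
    jdb: Optional[GermlineDatabase] = None,
    config: Optional[DiscoveryConfig] = None,
) -> DiscoveryResult:
    """Run the full iterative discovery loop on preprocessed reads.

    Iterations 1..n-1 apply the pregermline filter; iteration n applies the
    germline filter.  An extra assignment pass against the final database
    yields the usage profile and upstream consensi.  Raises
    :class:`DiscoveryError` if the database becomes empty.
    """
    config = config or DiscoveryConfig()
    if len(starting_db) == 0:
        raise ValueError("starting database must be non-empty")
    total_reads = sum(r.count for r in reads)
    if total_reads < RECOMMENDED_MIN_READS:
        logger.warning(
            "library has %d reads; ~%d are recommended for a complete "
            "germline repertoire", total_reads, RECOMMENDED_MIN_READS,
        )
    require_j = jdb is not None and len(jdb) > 0

    db = starting_db
    states: list[IterationState] = []
    for it in range(1, config.iterations + 1):
        assignments = assign_all(reads, db, jdb, config.assign)
        passed = quality_filter(assignments, config.thresholds, require_j=require_j)
        by_allele: dict[str, list[VJAssignment]] = {}
        for a in passed:
            by_allele.setdefault(a.v_name, []).append(a)

        candidates: list[CandidateAllele] = []
        for ai, allele in enumerate(db.alleles):
            group = by_allele.get(allele.name)
            if group:
                candidates.extend(
                    _propose_candidates(allele.name, group, config, it, ai)
                )
        candidates = _dedupe_candidates(candidates)

        annotated: list[CandidateAllele] = []
        rejected_rows: list[dict] = []
        for c in candidates:
            try:
                annotated.append(annotate_candidate(
                    c, passed, config.thresholds.exact_match_tolerance
                ))
            except ValueError as exc:
                rejected_rows.append({
                    "name": "", "source_allele": c.source_allele,
                    "origin": c.origin, "cluster_size": c.cluster_size,
                    "exact_occurrences": 0, "unique_cdr3": 0, "unique_j": 0,
                    "whitelisted": False, "passed": False, "reason": str(exc),
                })

        mode = "germline" if it == config.iterations else "pregermline"
        new_db, report = apply_filter(annotated, mode, starting_db, config.thresholds)
        if rejected_rows:
            report = pd.concat(
                [report, pd.DataFrame(rejected_rows, columns=report.columns)],
                ignore_index=True,
            )
        states.append(IterationState(
            iteration=it, input_db=db, n_assigned=len(assignments),
            n_passed=len(passed), candidate_table=report, output_db=new_db,
        ))
        if len(new_db) == 0:
            raise DiscoveryError(f"database empty after iteration {it}")
        stop = config.early_stop and new_db.sequences() == db.sequences()
        db = new_db
        if stop:
            break

    final_assignments = assign_all(reads, db, jdb, config.assign)
    final_passed = quality_filter(final_assignments, config.thresholds,
                                  require_j=require_j)
    usage = usage_profile(db, final_passed)
    upstream: list[UpstreamRecord] = []
    by_allele = {}
    for a in final_passed:
        by_allele.setdefault(a.v_name, []).append(a)
    for allele in db.alleles:
        rec = detect_upstream(by_allele.get(allele.name, []),
                              config.max_v_error_rate,
                              config.consensus_majority,
                              allele_name=allele.name)
        if rec is not None:
            upstream.append(rec)
    return DiscoveryResult(
        final_db=db, iterations=states, final_assignments=final_assignments,
        usage=usage, upstream=upstream,
    )


def usage_profile(
    final_db: GermlineDatabase, assignments: Sequence[VJAssignment]
) -> pd.DataFrame:
    """Per-allele usage: assigned sequences and unique CDR3s (zeros kept)."""
    reads: dict[str, int] = {a.name: 0 for a in final_db.alleles}
    cdr3s: dict[str, set] = {a.name: set() for a in final_db.alleles}
    for a in assignments:
        if a.v_name in reads:
            reads[a.v_name] += 1
            if a.cdr3_nt:
                cdr3s[a.v_name].add(a.cdr3_nt)
    return pd.DataFrame({
        "name": [a.name for a in final_db.alleles],
        "reads": [reads[a.name] for a in final_db.alleles],
        "unique_cdr3": [len(cdr3s[a.name]) for a in final_db.alleles],
    })


def detect_upstream(
    assignments_for_allele: Sequence[VJAssignment],
    max_v_error_rate: float = 0.01,
    majority: float = 0.6,
    allele_name: str = "",
) -> Optional[UpstreamRecord]:
    """Consensus of the 5'UTR+leader sequence upstream of one V allele.

    Uses reads with a low error rate in the V match (percent difference at
    most ``max_v_error_rate * 100``).  Only sequences at least as long as the
    tenth longest contribute, right-aligned at the V start; per column the
    60%-majority base is emitted, N otherwise.
    """
    ups = [
        a.upstream_sequence
        for a in assignments_for_allele
        if a.v_percent_difference <= max_v_error_rate * 100 and a.upstream_sequence
    ]
    if not ups:
        return None
    lengths = sorted((len(u) for u in ups), reverse=True)
    cutoff = lengths[min(9, len(lengths) - 1)]
    members = [u for u in ups if len(u) >= cutoff]
    width = max(len(u) for u in members)
    total = len(members)
    cols = []
    for c in range(width):  # c counted from the right (V-proximal) end
        votes: dict[str, int] = {}
        present = 0
        for u in members:
            if len(u) > c:
                b = u[len(u) - 1 - c]
                votes[b] = votes.get(b, 0) + 1
                present += 1
        if present <= total / 2:
            break
        base, w = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        cols.append(base if w >= majority * present else "N")
    return UpstreamRecord(
        allele_name=allele_name, consensus="".join(reversed(cols)),
        support=total,
    )


def compare_databases(
    a: GermlineDatabase, b: GermlineDatabase, tolerance: int = 0
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Partition two databases into shared and unique alleles.

    Sequences are compared with terminal tolerance; each allele pairs with at
    most one partner (greedy in database order).  Returns
    ``(shared pairs, names only in a, names only in b)``.
    """
    from .filters import equal_with_terminal_tolerance

    shared: list[tuple[str, str]] = []
    used_b: set[int] = set()
    only_a: list[str] = []
    for aa in a.alleles:
        match = None
        for i, bb in enumerate(b.alleles):
            if i in used_b:
                continue
            if tolerance == 0:
                ok = aa.sequence == bb.sequence
            else:
                ok = equal_with_terminal_tolerance(aa.sequence, bb.sequence, tolerance)[0]
            if ok:
                match = i
                break
        if match is None:
            only_a.append(aa.name)
        else:
            used_b.add(match)
            shared.append((aa.name, b.alleles[match].name))
    only_b = [bb.name for i, bb in enumerate(b.alleles) if i not in used_b]
    return shared, only_a, only_b


__all__ = [
    "DiscoveryConfig", "DiscoveryError", "DiscoveryResult", "IterationState",
    "UpstreamRecord", "run_discovery", "usage_profile", "detect_upstream",
    "compare_databases",
]
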