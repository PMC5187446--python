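"""Read preprocessing: pair merging, primer trimming, length filter, dereplication.

Raw paired or pre-merged amplicon reads are turned into the deduplicated
full-length sequence set that every discovery iteration consumes.  The merger
scans all candidate overlap lengths and accepts the one with the most matching
bases, subject to a minimum overlap and a maximum mismatch fraction;
disagreeing overlap bases are resolved in favor of the higher quality score
(forward base on ties or when qualities are absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import SequenceRecord, reverse_complement


@dataclass
class PreprocessConfig:
    min_length: int = 300
    min_overlap: int = 16
    max_overlap_mismatch_fraction: float = 0.2
    primers_5p: Sequence[str] = field(default_factory=tuple)
    primers_3p: Sequence[str] = field(default_factory=tuple)
    max_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if not 0 <= self.max_overlap_mismatch_fraction <= 1:
            raise ValueError("max_overlap_mismatch_fraction must be in [0, 1]")


class MergeFailure(Exception):
    """No acceptable overlap between a read pair."""


def merge_read_pair(
    forward: SequenceRecord, reverse: SequenceRecord, config: PreprocessConfig
) -> SequenceRecord:
    """Merge a read pair into one amplicon sequence.

    The reverse read is given in sequencer orientation and is
    reverse-complemented internally.  Raises :class:`MergeFailure` when no
    overlap of at least ``min_overlap`` bases with mismatch fraction at most
    ``max_overlap_mismatch_fraction`` exists.
    """
    fseq = forward.sequence
    rseq = reverse_complement(reverse.sequence)
    fq = list(forward.qualities) if forward.qualities is not None else None
    rq = list(reverse.qualities)[::-1] if reverse.qualities is not None else None

    best = None  # (matches, L)
    max_l = min(len(fseq), len(rseq))
    for L in range(config.min_overlap, max_l + 1):
        ftail = fseq[-L:]
        rhead = rseq[:L]
        matches = sum(1 for a, b in zip(ftail, rhead) if a == b)
        if (L - matches) / L > config.max_overlap_mismatch_fraction:
            continue
        if best is None or (matches, L) > best[:2]:
            best = (matches, L)
    if best is None:
        raise MergeFailure(
            f"no overlap >= {config.min_overlap} with mismatch fraction "
            f"<= {config.max_overlap_mismatch_fraction}"
        )

    _, L = best
    off = len(fseq) - L
    merged = list(fseq[:off])
    quals: Optional[list[int]] = None
    if fq is not None or rq is not None:
        quals = list(fq[:off]) if fq is not None else [2] * off
    for i in range(L):
        fb, rb = fseq[off + i], rseq[i]
        fqv = fq[off + i] if fq is not None else None
        rqv = rq[i] if rq is not None else None
        if fb == rb:
            base = fb
        elif fqv is not None and rqv is not None and rqv > fqv:
            base = rb
        else:
            base = fb  # forward wins on tie or missing qualities
        merged.append(base)
        if quals is not None:
            quals.append(max(fqv or 2, rqv or 2))
    merged.extend(rseq[L:])
    if quals is not None:
        quals.extend(rq[L:] if rq is not None else [2] * (len(rseq) - L))

    return SequenceRecord(
        id=forward.id, sequence="".join(merged), qualities=quals, count=forward.count
    )


def _match_end(seq: str, primer: str, end: str) -> bool:
    lp = len(primer)
    if lp == 0 or len(seq) < lp:
        return False
    window = seq[:lp] if end == "5p" else seq[-lp:]
    mismatches = sum(1 for a, b in zip(window, primer) if a != b)
    return mismatches <= lp // 10


def trim_primers(record: SequenceRecord, config: PreprocessConfig) -> SequenceRecord:
    """Remove configured primer spans from the read ends.

    A primer matches when anchored at its expected end with at most one
    mismatch per 10 primer bases.  No-match leaves the record unchanged.
    """
    seq = record.sequence
    quals = list(record.qualities) if record.qualities is not None else None
    for p in config.primers_5p:
        if _match_end(seq, p.upper(), "5p"):
            seq = seq[len(p):]
            if quals is not None:
                quals = quals[len(p):]
            break
    for p in config.primers_3p:
        if _match_end(seq, p.upper(), "3p"):
            seq = seq[: -len(p)]
            if quals is not None:
                quals = quals[: -len(p)]
            break
    if seq == record.sequence:
        return record
    return SequenceRecord(id=record.id, sequence=seq, qualities=quals, count=record.count)


def length_filter(
    records: Iterable[SequenceRecord], config: PreprocessConfig
) -> list[SequenceRecord]:
    """Keep exactly the records with length >= ``min_length``, order preserved."""
    return [r for r in records if len(r) >= config.min_length]


def dereplicate(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse identical full-length sequences.

    One record per distinct sequence string; ``count`` sums the input counts;
    the first-seen id is kept.  Output ordered by descending count, then
    first appearance.
    """
    seen: dict[str, SequenceRecord] = {}
    order: dict[str, int] = {}
    for i, r in enumerate(records):
        if r.sequence in seen:
            prev = seen[r.sequence]
            seen[r.sequence] = SequenceRecord(
                id=prev.id, sequence=prev.sequence, qualities=prev.qualities,
                count=prev.count + r.count,
            )
        else:
            seen[r.sequence] = r
            order[r.sequence] = i
    return sorted(seen.values(), key=lambda r: (-r.count, order[r.sequence]))


def preprocess(
    records: Optional[Iterable[SequenceRecord]] = None,
    pairs: Optional[Iterable[tuple[SequenceRecord, SequenceRecord]]] = None,
    config: Optional[PreprocessConfig] = None,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Full preprocessing pipeline.

    Accepts either pre-merged ``records`` or raw read ``pairs``.  Returns the
    dereplicated record list and a per-stage read-count log.
    """
    config = config or PreprocessConfig()
    log: dict[str, int] = {}
    if pairs is not None:
        merged = []
        n_pairs = 0
        for fwd, rev in pairs:
            n_pairs += 1
            try:
                merged.append(merge_read_pair(fwd, rev, config))
            except MergeFailure:
                pass
        log["input_pairs"] = n_pairs
        log["merged"] = len(merged)
        records = merged
    elif records is not None:
        records = list(records)
        log["input"] = len(records)
    else:
        raise ValueError("either records or pairs must be given")

    records = [trim_primers(r, config) for r in records]
    records = length_filter(records, config)
    log["length_filtered"] = len(records)
    records = [
        r for r in records
        if r.sequence.count("N") / len(r) <= config.max_n_fraction
    ]
    log["n_filtered"] = len(records)
    records = dereplicate(records)
    log["unique"] = len(records)
    return records, log


__all__ = [
    "PreprocessConfig",
    "MergeFailure",
    "merge_read_pair",
    "trim_primers",
    "length_filter",
    "dereplicate",
    "preprocess",
]
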