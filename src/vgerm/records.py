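"""Core domain types: sequence records and germline databases.

A :class:`SequenceRecord` is one (merged) amplicon read; duplicate reads are
collapsed into a single record carrying a ``count``.  A
:class:`GermlineDatabase` is the named set of germline V (or J) allele
sequences that the discovery loop iteratively replaces.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_SIZE_RE = re.compile(r";size=(\d+)")

VALID_BASES = frozenset("ACGTN")


@dataclass
class SequenceRecord:
    """One nucleotide read, possibly representing several identical raw reads.

    Parameters
    ----------
    id : str
        Read identifier.
    sequence : str
        Nucleotide string over ``{A, C, G, T, N}``.
    qualities : list of int, optional
        Per-base Phred scores, same length as ``sequence``.
    count : int
        Number of identical raw reads collapsed into this record (>= 1).
    """

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must match sequence length")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GermlineAllele:
    """A named germline V or J allele sequence.

    ``source`` records provenance: present in the starting database,
    discovered by the pipeline, or retained through whitelisting.
    """

    name: str
    sequence: str
    source: str = "starting"  # starting | discovered | whitelisted

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("allele sequence must be non-empty")


@dataclass
class GermlineDatabase:
    """Ordered collection of germline alleles with unique names and sequences."""

    alleles: list[GermlineAllele] = field(default_factory=list)
    chain: str = "heavy"  # heavy | kappa | lambda

    def __post_init__(self) -> None:
        names = [a.name for a in self.alleles]
        if len(names) != len(set(names)):
            raise ValueError("allele names must be unique")
        seqs = [a.sequence for a in self.alleles]
        if len(seqs) != len(set(seqs)):
            raise ValueError("allele sequences must be unique")

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self.alleles)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.sequences()

    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def sequences(self) -> set[str]:
        return {a.sequence for a in self.alleles}

    def get(self, name: str) -> GermlineAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: Optional[str] = None) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (optionally gzip-compressed) into records.

    A ``;size=N`` suffix on a FASTA header is parsed back into ``count``.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    out: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            header = rec.description or rec.id
            m = _SIZE_RE.search(header)
            count = int(m.group(1)) if m else 1
            rid = _SIZE_RE.sub("", rec.id)
            out.append(
                SequenceRecord(
                    id=rid,
                    sequence=str(rec.seq).upper(),
                    qualities=list(quals) if quals else None,
                    count=count,
                )
            )
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, with_size: bool = True) -> None:
    """Write records as FASTA, appending ``;size=<count>`` to each header."""
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as fh:
        for r in records:
            header = f"{r.id};size={r.count}" if with_size else r.id
            fh.write(f">{header}\n{r.sequence}\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as fh:
        for r in records:
            quals = r.qualities if r.qualities is not None else [37] * len(r.sequence)
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            SeqIO.write(rec, fh, "fastq")


def read_database(path: str | Path, chain: str = "heavy", source: str = "starting") -> GermlineDatabase:
    """Read a germline database from FASTA; allele name = first header token."""
    alleles = []
    seen_seqs: set[str] = set()
    with _open_maybe_gzip(Path(path)) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if seq in seen_seqs:
                continue
            seen_seqs.add(seq)
            alleles.append(GermlineAllele(name=rec.id, sequence=seq, source=source))
    return GermlineDatabase(alleles=alleles, chain=chain)


def write_database(db: GermlineDatabase, path: str | Path) -> None:
    with _open_maybe_gzip(Path(path), "wt") as fh:
        for a in db.alleles:
            fh.write(f">{a.name}\n{a.sequence}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


__all__ = [
    "SequenceRecord",
    "GermlineAllele",
    "GermlineDatabase",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_database",
    "write_database",
    "reverse_complement",
]
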