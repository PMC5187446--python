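"""Synthetic IgM repertoire simulation with a full ground-truth ledger.

The simulator emulates the statistical structure the discovery method relies
on: a family-structured set of germline V alleles, V(D)J rearrangements with
diverse in-frame CDR3 junctions, a naive/SHM-mutated read mixture, per-allele
5'UTR+leader upstream sequence, and independent per-base sequencing error.
Every emitted read is logged in a truth ledger (source alleles, SHM and error
positions, planted junction), which serves as the exact oracle for tests.

Simulated V alleles end with the conserved ...Y-Y-C motif (the second
cysteine opening the CDR3) and J alleles start with a short in-frame tail
followed by the W-G-x-G FR4 anchor, so that CDR3 detection operates exactly
as on curated germline databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import GermlineAllele, GermlineDatabase, SequenceRecord

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
# junction codons: no stops and no tryptophan (TGG), so a planted junction
# can never introduce a premature J anchor
JUNCTION_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOPS and a + b + c != "TGG"
]
V_TAIL = "TATTACTGT"  # Y Y C — conserved second cysteine ends the V
J_ANCHOR_FR4 = "TGGGGCCAAGGGACCACGGTCACCGTCTCCTCA"  # W G Q G T T V T V S S
J_TAIL_LEN = 6

ALLELES_PER_FAMILY = 5
FAMILY_DIVERGENCE_FRACTION = 0.18
MIN_ALLELE_SPACING = 4


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic IgM library."""

    n_alleles: int = 20
    allele_divergence: float = 10.0  # expected pairwise nt differences within a family
    n_reads: int = 50_000
    naive_fraction: float = 0.55
    shm_mean: float = 4.0  # mean substitutions per mutated read (geometric)
    error_rate: float = 0.003  # per-base sequencing error
    n_j_alleles: int = 4
    junction_length_range: tuple[int, int] = (12, 33)
    utr_length: int = 100
    expression_weights: Optional[Sequence[float]] = None
    seed: int = 1
    full_upstream_fraction: float = 0.3
    hotspot_bias: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.naive_fraction <= 1:
            raise ValueError("naive_fraction must be in [0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.expression_weights is not None and any(
            w <= 0 for w in self.expression_weights
        ):
            raise ValueError("expression weights must be positive")


TRUTH_COLUMNS = [
    "read_id", "v_allele", "j_allele", "junction", "n_shm", "shm_positions",
    "n_errors", "error_positions", "upstream_length", "v_start", "is_artefact",
    "artefact_kind",
]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(JUNCTION_CODONS[i] for i in rng.integers(0, len(JUNCTION_CODONS), n))


def _mutate_codon_safe(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    """Substitute seq[pos] with a different base without creating a stop codon."""
    codon_start = pos - pos % 3
    old = seq[pos]
    choices = [b for b in BASES if b != old]
    rng.shuffle(choices)
    for b in choices:
        seq[pos] = b
        codon = "".join(seq[codon_start:codon_start + 3])
        if codon not in STOPS:
            return
    seq[pos] = old


def generate_germline_db(
    config: SimulationConfig,
) -> tuple[GermlineDatabase, dict[str, int]]:
    """Generate a family-structured germline V database.

    Alleles are organized into families of up to five members: family
    ancestors diverge from a common framework at ~18% of positions, members
    of one family differ from each other by ``allele_divergence`` positions
    in expectation (and by at least a few positions, as real alleles do).
    All sequences are in reading frame 1 without stop codons and end with
    the conserved Y-Y-C motif.  Deterministic per seed.
    """
    if config.n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    rng = np.random.default_rng([config.seed, 7])
    n_fam = math.ceil(config.n_alleles / ALLELES_PER_FAMILY)

    max_codons = 100
    base = _random_codons(rng, max_codons - len(V_TAIL) // 3)

    alleles: list[GermlineAllele] = []
    families: dict[str, int] = {}
    all_seqs: list[str] = []
    fam_id = 0
    while len(alleles) < config.n_alleles:
        n_codons = int(rng.integers(97, max_codons + 1))
        core_len = n_codons * 3 - len(V_TAIL)
        ancestor = list(base[:core_len] + V_TAIL)
        n_div = int(round(FAMILY_DIVERGENCE_FRACTION * core_len))
        for pos in rng.choice(core_len, size=n_div, replace=False):
            _mutate_codon_safe(ancestor, int(pos), rng)
        n_members = min(ALLELES_PER_FAMILY, config.n_alleles - len(alleles))
        member = 0
        attempts = 0
        while member < n_members:
            attempts += 1
            if attempts > 200:
                raise RuntimeError("could not place distinct alleles; lower n_alleles")
            d = max(1, int(rng.poisson(config.allele_divergence / 2)))
            allele = list(ancestor)
            for pos in rng.choice(core_len, size=min(d, core_len), replace=False):
                _mutate_codon_safe(allele, int(pos), rng)
            seq = "".join(allele)
            if any(
                len(s) == len(seq)
                and sum(1 for x, y in zip(s, seq) if x != y) < MIN_ALLELE_SPACING
                for s in all_seqs
            ) or seq in all_seqs:
                continue
            name = f"VH{fam_id + 1}.{member + 1}"
            alleles.append(GermlineAllele(name=name, sequence=seq, source="starting"))
            families[name] = fam_id
            all_seqs.append(seq)
            member += 1
        fam_id += 1
        if fam_id > n_fam + config.n_alleles:
            raise RuntimeError("family generation did not converge")
    return GermlineDatabase(alleles=alleles, chain="heavy"), families


def generate_j_db(config: SimulationConfig) -> GermlineDatabase:
    """Generate J alleles: 6 nt in-frame CDR3 tail + W-G-x-G anchor + FR4."""
    rng = np.random.default_rng([config.seed, 11])
    alleles = []
    seen = set()
    i = 0
    while len(alleles) < config.n_j_alleles:
        i += 1
        tail = _random_codons(rng, J_TAIL_LEN // 3)
        fr4 = list(J_ANCHOR_FR4)
        # distinguish alleles by a couple of substitutions downstream of the
        # W-G-x-G anchor (first 12 nt stay intact)
        if len(alleles) > 0:
            for pos in rng.choice(np.arange(12, len(fr4)), size=3, replace=False):
                _mutate_codon_safe(fr4, int(pos), rng)
        seq = tail + "".join(fr4)
        if seq in seen:
            continue
        seen.add(seq)
        alleles.append(GermlineAllele(name=f"JH{len(alleles) + 1}", sequence=seq))
    return GermlineDatabase(alleles=alleles, chain="heavy")


def _hotspot_weights(v: str) -> np.ndarray:
    """Position weights upweighting AID hotspots (WRC/GYW motifs)."""
    w = np.ones(len(v))
    for i in range(len(v) - 2):
        tri = v[i:i + 3]
        if tri[0] in "AT" and tri[1] in "AG" and tri[2] == "C":
            w[i + 2] = 3.0
        if tri[0] == "G" and tri[1] in "CT" and tri[2] in "AT":
            w[i] = 3.0
    return w / w.sum()


def _generate_upstreams(
    db: GermlineDatabase, config: SimulationConfig
) -> dict[str, str]:
    rng = np.random.default_rng([config.seed, 13])
    return {
        a.name: "".join(BASES[i] for i in rng.integers(0, 4, config.utr_length))
        for a in db.alleles
    }


def simulate_repertoire(
    db: GermlineDatabase,
    jdb: GermlineDatabase,
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate an IgM-like read set with its ground-truth ledger.

    Each read is UTR/leader (possibly 5'-truncated) + V (with SHM
    substitutions at uniform positions for the mutated fraction) + a random
    in-frame junction + a possibly 5'-truncated J, with independent per-base
    sequencing errors over the whole read.  Reproducible per seed.
    """
    if len(db) == 0 or len(jdb) == 0:
        raise ValueError("V and J databases must be non-empty")
    rng = np.random.default_rng([config.seed, 17])
    upstreams = _generate_upstreams(db, config)
    weights = None
    if config.expression_weights is not None:
        w = np.asarray(config.expression_weights, dtype=float)
        weights = w / w.sum()

    lo, hi = config.junction_length_range
    lo_c, hi_c = max(1, lo // 3), max(1, hi // 3)
    records: list[SequenceRecord] = []
    rows: list[dict] = []
    for i in range(config.n_reads):
        vi = int(rng.choice(len(db), p=weights))
        ji = int(rng.integers(len(jdb)))
        vallele = db.alleles[vi]
        jallele = jdb.alleles[ji]

        v = list(vallele.sequence)
        naive = rng.random() < config.naive_fraction
        n_shm = 0 if naive else int(rng.geometric(1.0 / max(config.shm_mean, 1.0)))
        shm_pos: list[int] = []
        if n_shm > 0:
            p = _hotspot_weights(vallele.sequence) if config.hotspot_bias else None
            pos = rng.choice(len(v), size=min(n_shm, len(v)), replace=False, p=p)
            for q in sorted(int(x) for x in pos):
                alt = [b for b in BASES if b != v[q]]
                v[q] = alt[int(rng.integers(3))]
                shm_pos.append(q)
        n_shm = len(shm_pos)

        insert = _random_codons(rng, int(rng.integers(lo_c, hi_c + 1)))
        j_trunc = int(rng.choice([0, 3, 6]))
        j_part = jallele.sequence[j_trunc:]
        junction = "TGT" + insert + jallele.sequence[j_trunc:J_TAIL_LEN]

        full_up = upstreams[vallele.name]
        if rng.random() < config.full_upstream_fraction:
            up = full_up
        else:
            cut = int(rng.integers(1, len(full_up) + 1))
            up = full_up[cut:]

        read = up + "".join(v) + insert + j_part
        n_err = int(rng.binomial(len(read), config.error_rate))
        err_pos: list[int] = []
        if n_err > 0:
            seq = list(read)
            for q in sorted(int(x) for x in rng.choice(len(read), size=n_err, replace=False)):
                alt = [b for b in BASES if b != seq[q]]
                seq[q] = alt[int(rng.integers(3))]
                err_pos.append(q)
            read = "".join(seq)

        rid = f"read{i:06d}"
        records.append(SequenceRecord(
            id=rid, sequence=read, qualities=[37] * len(read)
        ))
        rows.append({
            "read_id": rid, "v_allele": vallele.name, "j_allele": jallele.name,
            "junction": junction, "n_shm": n_shm,
            "shm_positions": ";".join(str(len(up) + q) for q in shm_pos),
            "n_errors": n_err, "error_positions": ";".join(map(str, err_pos)),
            "upstream_length": len(up), "v_start": len(up),
            "is_artefact": False, "artefact_kind": "",
        })
    return records, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def perturb_database(
    db: GermlineDatabase, n_mutations: int = 10, seed: int = 0
) -> GermlineDatabase:
    """Apply exactly ``n_mutations`` random substitutions to every allele.

    Positions are distinct within each allele; names gain a ``_mut`` suffix.
    """
    if n_mutations == 0:
        return db
    rng = np.random.default_rng([seed, 23])
    alleles = []
    for a in db.alleles:
        if n_mutations >= len(a.sequence):
            raise ValueError("n_mutations must be smaller than the allele length")
        seq = list(a.sequence)
        for pos in rng.choice(len(seq), size=n_mutations, replace=False):
            old = seq[int(pos)]
            alt = [b for b in BASES if b != old]
            seq[int(pos)] = alt[int(rng.integers(3))]
        alleles.append(GermlineAllele(
            name=a.name + "_mut", sequence="".join(seq), source="starting"
        ))
    return GermlineDatabase(alleles=alleles, chain=db.chain)


def inject_artefacts(
    reads: list[SequenceRecord],
    truth: pd.DataFrame,
    db: GermlineDatabase,
    jdb: GermlineDatabase,
    config: SimulationConfig,
    kind: str,
    n: int,
    seed: int = 99,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Append non-germline artefact reads, flagged in the ledger.

    ``clonal_expansion``: many copies of one SHM-mutated rearrangement
    (a single CDR3).  ``hotspot``: a recurrent single V substitution spread
    over many reads but carried by fewer than ten distinct junctions.
    """
    if kind not in ("clonal_expansion", "hotspot"):
        raise ValueError("kind must be 'clonal_expansion' or 'hotspot'")
    rng = np.random.default_rng([seed, 29])
    upstreams = _generate_upstreams(db, config)
    vallele = db.alleles[int(rng.integers(len(db)))]
    out_reads = list(reads)
    rows = []

    def emit(rid: str, v_seq: str, insert: str, jallele, j_trunc: int) -> None:
        full_up = upstreams[vallele.name]
        if rng.random() < config.full_upstream_fraction:
            up = full_up
        else:
            up = full_up[int(rng.integers(1, len(full_up) + 1)):]
        read = up + v_seq + insert + jallele.sequence[j_trunc:]
        n_err = int(rng.binomial(len(read), config.error_rate))
        if n_err > 0:
            seq = list(read)
            for q in rng.choice(len(read), size=n_err, replace=False):
                alt = [b for b in BASES if b != seq[int(q)]]
                seq[int(q)] = alt[int(rng.integers(3))]
            read = "".join(seq)
        out_reads.append(SequenceRecord(id=rid, sequence=read,
                                        qualities=[37] * len(read)))
        rows.append({
            "read_id": rid, "v_allele": vallele.name,
            "j_allele": jallele.name,
            "junction": "TGT" + insert + jallele.sequence[j_trunc:J_TAIL_LEN],
            "n_shm": -1, "shm_positions": "", "n_errors": n_err,
            "error_positions": "", "upstream_length": len(up),
            "v_start": len(up), "is_artefact": True, "artefact_kind": kind,
        })

    if kind == "clonal_expansion":
        v = list(vallele.sequence)
        for pos in rng.choice(len(v) - len(V_TAIL), size=8, replace=False):
            _mutate_codon_safe(v, int(pos), rng)
        v_seq = "".join(v)
        insert = _random_codons(rng, 7)
        jallele = jdb.alleles[int(rng.integers(len(jdb)))]
        j_trunc = int(rng.choice([0, 3, 6]))
        for i in range(n):
            emit(f"artefact_clonal{i:05d}", v_seq, insert, jallele, j_trunc)
    else:
        v = list(vallele.sequence)
        _mutate_codon_safe(v, int(rng.integers(len(v) - len(V_TAIL))), rng)
        v_seq = "".join(v)
        pool = [
            (_random_codons(rng, int(rng.integers(4, 11))),
             jdb.alleles[int(rng.integers(len(jdb)))],
             int(rng.choice([0, 3, 6])))
            for _ in range(9)
        ]
        for i in range(n):
            insert, jallele, j_trunc = pool[int(rng.integers(len(pool)))]
            emit(f"artefact_hotspot{i:05d}", v_seq, insert, jallele, j_trunc)

    truth_out = pd.concat([truth, pd.DataFrame(rows, columns=TRUTH_COLUMNS)],
                          ignore_index=True)
    return out_reads, truth_out


def simulate_library(
    config: SimulationConfig,
) -> tuple[GermlineDatabase, GermlineDatabase, list[SequenceRecord], pd.DataFrame, dict[str, int]]:
    """Convenience wrapper: germline DBs + repertoire + ledger + families."""
    db, families = generate_germline_db(config)
    jdb = generate_j_db(config)
    reads, truth = simulate_repertoire(db, jdb, config)
    return db, jdb, reads, truth, families


__all__ = [
    "SimulationConfig", "TRUTH_COLUMNS", "generate_germline_db",
    "generate_j_db", "simulate_repertoire", "perturb_database",
    "inject_artefacts", "simulate_library",
]
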