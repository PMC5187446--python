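"""Shared fixtures.

The heavy session-scoped fixtures build one synthetic study library (20
alleles in 4 families) and the baseline discovery run that several
whole-pipeline tests compare against.  Library size is scaled to keep the
whole suite fast while preserving the evidence density the filters assume
(several hundred reads per allele, subsample of 1,000).
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from vgerm.discover import DiscoveryConfig, run_discovery
from vgerm.preprocess import preprocess
from vgerm.records import GermlineDatabase
from vgerm.simulate import SimulationConfig, simulate_library

logging.getLogger("vgerm").setLevel(logging.ERROR)

STUDY_N_ALLELES = 20
STUDY_N_READS = 12_000
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """The default synthetic IgM study library with ground truth."""
    config = SimulationConfig(
        n_alleles=STUDY_N_ALLELES, n_reads=STUDY_N_READS,
        naive_fraction=0.55, shm_mean=4.0, error_rate=0.003, seed=STUDY_SEED,
    )
    db, jdb, reads, truth, families = simulate_library(config)
    records, _ = preprocess(records=reads)
    return {
        "config": config, "db": db, "jdb": jdb, "raw_reads": reads,
        "records": records, "truth": truth, "families": families,
    }


@pytest.fixture(scope="session")
def baseline_run(study):
    """Three iterations starting from the full truth database."""
    return run_discovery(
        study["records"], study["db"], study["jdb"],
        DiscoveryConfig(iterations=3, seed=1),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small library for unit-level checks (fast)."""
    config = SimulationConfig(n_alleles=8, n_reads=1500, seed=3)
    db, jdb, reads, truth, families = simulate_library(config)
    return {"config": config, "db": db, "jdb": jdb, "reads": reads,
            "truth": truth, "families": families}


def minimal_database(db: GermlineDatabase, families: dict[str, int]) -> GermlineDatabase:
    """One allele per family (the 'minimal starting database' scenario)."""
    first = {}
    for a in db.alleles:
        first.setdefault(families[a.name], a)
    return GermlineDatabase(list(first.values()), chain=db.chain)


def deleted_database(db: GermlineDatabase, n_delete: int, seed: int):
    """Remove ``n_delete`` expressed alleles from the starting database."""
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(len(db), size=n_delete, replace=False).tolist())
    kept = GermlineDatabase(
        [a for i, a in enumerate(db.alleles) if i not in drop], chain=db.chain
    )
    removed = [db.alleles[i] for i in sorted(drop)]
    return kept, removed
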