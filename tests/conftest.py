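"""Shared fixtures: one default synthetic cohort per session plus small helpers."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning)
logging.getLogger("tcrpersist").setLevel(logging.ERROR)

from tcrpersist import tracking
from tcrpersist.clonotyping import call_clonotypes, build_repertoire_table
from tcrpersist.io_model import qc_filter_cells
from tcrpersist.synthetic import SimConfig, simulate_cohort


@dataclass
class ProcessedCohort:
    """A simulated cohort with the standard upstream stages applied."""

    config: SimConfig
    cohort: object
    truth: object
    kept: list
    assignment: object
    table: object
    calls: dict  # pair_id -> PersistenceCall

    @property
    def persisting_called(self) -> set[str]:
        out = set()
        for call in self.calls.values():
            out |= call.persisting_keys
        return out


def process(config: SimConfig) -> ProcessedCohort:
    cohort, truth = simulate_cohort(config)
    kept, _ = qc_filter_cells(cohort.cells)
    assignment = call_clonotypes(cohort.chains, kept)
    table = build_repertoire_table(assignment, cohort.samples)
    calls = {}
    for pid in config.pair_ids():
        sub = table.restrict_to_pair(cohort.samples, pid)
        calls[pid] = tracking.call_persistence(sub, cohort.samples)
    return ProcessedCohort(
        config=config, cohort=cohort, truth=truth, kept=kept,
        assignment=assignment, table=table, calls=calls,
    )


@pytest.fixture(scope="session")
def default_run() -> ProcessedCohort:
    """The study-scale default cohort (4 pairs x 4 timepoints x 2500 cells)."""
    return process(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_signature(default_run):
    """Persistence-vs-other CD8TEM differential expression on the default cohort."""
    from tcrpersist import signature as sig

    run = default_run
    persisting = run.persisting_called
    strata = {}
    for c in run.kept:
        key = run.assignment.key_of(c.cell_id)
        if key is not None:
            strata[c.cell_id] = "persisting" if key in persisting else "other"
    pb = sig.pseudobulk_aggregate(
        run.cohort.counts, [c for c in run.kept if c.cell_id in strata],
        run.cohort.samples, strata=strata, celltypes=["CD8 TEM"],
    )
    de = sig.fit_paired_de(pb)
    selected = sig.select_signature(de)
    return {"pb": pb, "de": de, "selected": selected, "strata": strata}


@pytest.fixture(scope="session")
def small_run() -> ProcessedCohort:
    """A light cohort for unit-level checks (fast to simulate)."""
    return process(SimConfig(
        n_pairs=2, cells_per_sample=600, clone_count=200, n_genes=500, seed=11
    ))
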