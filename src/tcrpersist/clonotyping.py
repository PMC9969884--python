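"""Paired-chain clonotype calling and per-sample repertoire tables.

A clonotype is defined strictly: a cell contributes to a clonotype only
when it has both a productive TRA and a productive TRB chain, and the
clonotype key concatenates the V gene and CDR3 nucleotide sequence of
each chain. Cells with only one locus recovered are left unassigned —
single-chain cells are never merged into paired clonotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .io_model import CellRecord, ChainRecord, Sample

logger = logging.getLogger(__name__)

#: Expansion bins on clonotype frequency, half-open intervals (lo, hi].
#: The cut-offs are the widely used convention for human TCR repertoires.
EXPANSION_BINS = (
    ("Rare", 0.0, 1e-4),
    ("Small", 1e-4, 1e-3),
    ("Medium", 1e-3, 1e-2),
    ("Large", 1e-2, 1e-1),
    ("Hyperexpanded", 1e-1, 1.0),
)


def chain_key(v_gene: str, cdr3_nt: str) -> str:
    return f"{v_gene}_{cdr3_nt}"


def clonotype_key(alpha_v: str, alpha_cdr3_nt: str, beta_v: str, beta_cdr3_nt: str) -> str:
    """Strict paired key: ``TRAV_cdr3nt|TRBV_cdr3nt``."""
    return f"{chain_key(alpha_v, alpha_cdr3_nt)}|{chain_key(beta_v, beta_cdr3_nt)}"


@dataclass
class ClonotypeAssignment:
    """Map from cell id (sample_id, barcode) to paired clonotype key.

    Cells lacking a TRA or a TRB are absent from ``assigned`` and counted
    in ``n_unpaired``.
    """

    assigned: dict[tuple[str, str], str]
    n_unpaired: int

    def key_of(self, cell_id: tuple[str, str]) -> str | None:
        return self.assigned.get(cell_id)


def _select_chain(chains: list[ChainRecord]) -> ChainRecord:
    """Highest-UMI chain; ties broken by lexicographically smallest cdr3_nt."""
    return min(chains, key=lambda c: (-c.umis, c.cdr3_nt))


def call_clonotypes(
    chains: list[ChainRecord], cells: list[CellRecord]
) -> ClonotypeAssignment:
    """Assign a paired clonotype to every cell with both TRA and TRB.

    Per cell and locus the highest-UMI productive chain is selected (ties
    resolved towards the lexicographically smallest CDR3 nucleotide
    sequence, so the call is deterministic). Duplicate
    (barcode, locus, cdr3_nt) rows are collapsed to the highest-UMI copy
    with a warning.
    """
    known = {c.cell_id for c in cells}
    per_cell: dict[tuple[str, str], dict[str, list[ChainRecord]]] = {}
    seen: dict[tuple[tuple[str, str], str, str], ChainRecord] = {}
    n_dup = 0
    for ch in chains:
        if not ch.productive:
            continue
        if ch.cell_id not in known:
            continue
        dedup_key = (ch.cell_id, ch.locus, ch.cdr3_nt)
        prev = seen.get(dedup_key)
        if prev is not None:
            n_dup += 1
            if ch.umis <= prev.umis:
                continue
            per_cell[ch.cell_id][ch.locus].remove(prev)
        seen[dedup_key] = ch
        per_cell.setdefault(ch.cell_id, {"TRA": [], "TRB": []})[ch.locus].append(ch)
    if n_dup:
        logger.warning("deduplicated %d duplicate (barcode, locus, cdr3_nt) rows", n_dup)

    assigned: dict[tuple[str, str], str] = {}
    n_unpaired = 0
    for cell_id, loci in per_cell.items():
        if not loci["TRA"] or not loci["TRB"]:
            n_unpaired += 1
            continue
        alpha = _select_chain(loci["TRA"])
        beta = _select_chain(loci["TRB"])
        assigned[cell_id] = clonotype_key(alpha.v_gene, alpha.cdr3_nt, beta.v_gene, beta.cdr3_nt)
    logger.info(
        "clonotype calling: %d cells paired, %d cells with a single locus only",
        len(assigned), n_unpaired,
    )
    return ClonotypeAssignment(assigned=assigned, n_unpaired=n_unpaired)


@dataclass
class RepertoireTable:
    """Clonotype x sample cell counts with derived frequencies.

    Frequencies are normalized over cells with a paired assignment in the
    sample (the sampled repertoire), not over all sequenced cells.
    """

    counts: pd.DataFrame  # index: clonotype key; columns: sample_id; int counts

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts / totals.replace(0, np.nan)
        return freq.fillna(0.0)

    def restrict_to_pair(self, samples: list[Sample], pair_id: str) -> "RepertoireTable":
        cols = [s.sample_id for s in samples if s.pair_id == pair_id and s.sample_id in self.counts.columns]
        sub = self.counts[cols]
        return RepertoireTable(counts=sub.loc[sub.sum(axis=1) > 0])


def build_repertoire_table(
    assignment: ClonotypeAssignment, samples: list[Sample]
) -> RepertoireTable:
    """Tabulate paired-cell counts per clonotype and sample."""
    sample_ids = [s.sample_id for s in samples]
    if not assignment.assigned:
        return RepertoireTable(counts=pd.DataFrame(columns=sample_ids, dtype=int))
    rows = pd.DataFrame(
        [(key, sid) for (sid, _bc), key in assignment.assigned.items()],
        columns=["clonotype", "sample"],
    )
    counts = (
        rows.value_counts(["clonotype", "sample"])
        .unstack(fill_value=0)
        .reindex(columns=sample_ids, fill_value=0)
        .sort_index()
    )
    counts.columns.name = None
    counts.index.name = "clonotype"
    empty = [s for s in sample_ids if counts[s].sum() == 0]
    if empty:
        logger.warning("samples with zero assigned cells: %s", ", ".join(empty))
    return RepertoireTable(counts=counts.astype(int))


def bin_expansion(table: RepertoireTable) -> pd.DataFrame:
    """Map each nonzero clonotype frequency to its expansion bin.

    Bins are half-open (lo, hi]; zero frequencies (clone absent from the
    sample) are left as missing values.
    """
    freq = table.frequencies
    labels = pd.DataFrame(index=freq.index, columns=freq.columns, dtype=object)
    for name, lo, hi in EXPANSION_BINS:
        mask = (freq > lo) & (freq <= hi)
        labels = labels.mask(mask, name)
    return labels.where(freq > 0)


def check_single_pair(samples: list[Sample]) -> str:
    """Return the unique pair id, or raise if samples span multiple pairs."""
    pairs = {s.pair_id for s in samples}
    if len(pairs) != 1:
        raise UsageError(
            "operation is defined within one donor-recipient pair; got pairs: "
            + ", ".join(sorted(pairs))
        )
    return pairs.pop()
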