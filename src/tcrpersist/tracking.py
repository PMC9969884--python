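"""Persistence classification and clonotype-fate analytics.

A clonotype *persists* when it is observed in at least one donor sample
and at least one recipient sample of the same donor-recipient pair.
Persistence is never computed across pairs: repertoires of unrelated
individuals share essentially no paired clonotypes, and a cross-pair
match would indicate a data-handling error rather than persistence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonotyping import ClonotypeAssignment, RepertoireTable, check_single_pair
from .errors import UsageError
from .io_model import CellRecord, Sample, TIMEPOINTS

logger = logging.getLogger(__name__)


@dataclass
class PersistenceCall:
    """Per-clonotype persistence labels for one donor-recipient pair."""

    pair_id: str
    table: pd.DataFrame
    # index: clonotype key; columns: persisting (bool),
    # donor_samples / recipient_samples (frozenset of sample ids)

    @property
    def persisting_keys(self) -> set[str]:
        return set(self.table.index[self.table["persisting"]])


def call_persistence(table: RepertoireTable, samples: list[Sample]) -> PersistenceCall:
    """Label each clonotype of one pair as persisting or other.

    persisting <=> observed (count > 0) in >= 1 donor sample AND >= 1
    recipient sample of the pair. The supporting sample sets are returned
    alongside the label.
    """
    relevant = [s for s in samples if s.sample_id in table.counts.columns]
    pair_id = check_single_pair(relevant)
    donor_cols = [s.sample_id for s in relevant if s.role == "donor"]
    recipient_cols = [s.sample_id for s in relevant if s.role == "recipient"]

    counts = table.counts
    rows = []
    for key, row in counts.iterrows():
        donors = frozenset(c for c in donor_cols if row[c] > 0)
        recipients = frozenset(c for c in recipient_cols if row[c] > 0)
        rows.append({
            "clonotype": key,
            "persisting": bool(donors) and bool(recipients),
            "donor_samples": donors,
            "recipient_samples": recipients,
        })
    out = pd.DataFrame(rows, columns=["clonotype", "persisting", "donor_samples",
                                      "recipient_samples"]).set_index("clonotype")
    logger.info(
        "pair %s: %d persisting / %d clonotypes", pair_id,
        int(out["persisting"].sum()), len(out),
    )
    return PersistenceCall(pair_id=pair_id, table=out)


@dataclass
class ClonotypeTrajectory:
    """Frequencies of one clonotype over the four ordered timepoints."""

    clonotype: str
    frequencies: tuple[float, float, float, float]  # pre, post, d90, d180


def _timepoint_frequencies(
    table: RepertoireTable, samples: list[Sample]
) -> pd.DataFrame:
    """Clonotype x timepoint frequency matrix (mean over samples at a timepoint)."""
    freq = table.frequencies
    cols = {}
    by_tp: dict[str, list[str]] = {tp: [] for tp in TIMEPOINTS}
    for s in samples:
        if s.sample_id in freq.columns:
            by_tp[s.timepoint].append(s.sample_id)
    for tp in TIMEPOINTS:
        cols[tp] = freq[by_tp[tp]].mean(axis=1) if by_tp[tp] else pd.Series(0.0, index=freq.index)
    return pd.DataFrame(cols).fillna(0.0)


def trace_top_clonotypes(
    table: RepertoireTable, samples: list[Sample], anchor: str = "recipient",
    n: int = 10,
) -> list[ClonotypeTrajectory]:
    """Trajectories of the top-n clonotypes of the anchor role.

    Ranking is by summed frequency across the anchor role's samples; ties
    are broken by clonotype key so the selection is deterministic. Absence
    at a timepoint appears as frequency 0.
    """
    if n < 1:
        raise UsageError("n must be >= 1")
    if anchor not in ("donor", "recipient"):
        raise UsageError(f"anchor must be donor or recipient, got {anchor!r}")
    freq = table.frequencies
    anchor_cols = [
        s.sample_id for s in samples
        if s.role == anchor and s.sample_id in freq.columns
    ]
    score = freq[anchor_cols].sum(axis=1)
    ranked = score.sort_index().sort_values(ascending=False, kind="stable")
    top = ranked.index[:n].tolist()
    if len(top) < n:
        logger.warning("only %d clonotypes available for top-%d request", len(top), n)
    tp_freq = _timepoint_frequencies(table, samples)
    return [
        ClonotypeTrajectory(
            clonotype=key,
            frequencies=tuple(float(tp_freq.loc[key, tp]) for tp in TIMEPOINTS),
        )
        for key in top
    ]


def persisting_share_of_top(
    table: RepertoireTable, call: PersistenceCall, samples: list[Sample],
    n: int = 10,
) -> float:
    """Fraction of the top-n recipient clonotypes that are persisting."""
    freq = table.frequencies
    recipient_cols = [
        s.sample_id for s in samples
        if s.role == "recipient" and s.sample_id in freq.columns
    ]
    if not recipient_cols or table.counts[recipient_cols].to_numpy().sum() == 0:
        raise UsageError("no recipient cells: persisting share is undefined")
    score = freq[recipient_cols].sum(axis=1)
    score = score[score > 0]
    top = score.sort_index().sort_values(ascending=False, kind="stable").index[:n]
    persisting = call.persisting_keys
    return float(np.mean([key in persisting for key in top]))


def expansion_log2fc(
    table: RepertoireTable, samples: list[Sample]
) -> pd.Series:
    """Per-clonotype log2(recipient mean freq / donor mean freq).

    Absence on one side is handled with a pseudo-frequency of 0.5 divided
    by the total paired-cell count of that side, so the statistic stays
    finite; the sign then still reflects the direction of the dynamics.
    """
    freq = table.frequencies
    donor_cols = [s.sample_id for s in samples
                  if s.role == "donor" and s.sample_id in freq.columns]
    rec_cols = [s.sample_id for s in samples
                if s.role == "recipient" and s.sample_id in freq.columns]
    donor_total = table.counts[donor_cols].to_numpy().sum()
    rec_total = table.counts[rec_cols].to_numpy().sum()
    donor_pseudo = 0.5 / max(donor_total, 1)
    rec_pseudo = 0.5 / max(rec_total, 1)
    d = freq[donor_cols].mean(axis=1).clip(lower=donor_pseudo)
    r = freq[rec_cols].mean(axis=1).clip(lower=rec_pseudo)
    return np.log2(r / d)


def phenotype_attribution(
    call: PersistenceCall,
    cells: list[CellRecord],
    assignment: ClonotypeAssignment,
) -> pd.DataFrame:
    """Dominant cell type and phenotype consistency per clonotype.

    The dominant label is the modal cell type over the clone's cells
    pooled across samples; ties are broken towards the label with the
    larger total cell count in the input, then lexicographically.
    Consistency is the fraction of the clone's cells carrying the
    dominant label. Clonotypes with zero cells are skipped.
    """
    celltype_totals: dict[str, int] = {}
    for c in cells:
        celltype_totals[c.celltype] = celltype_totals.get(c.celltype, 0) + 1

    by_clone: dict[str, dict[str, int]] = {}
    for c in cells:
        key = assignment.key_of(c.cell_id)
        if key is None:
            continue
        by_clone.setdefault(key, {})[c.celltype] = by_clone.get(key, {}).get(c.celltype, 0) + 1

    rows = []
    for key in call.table.index:
        labels = by_clone.get(key)
        if not labels:
            continue
        dominant = min(
            labels.items(),
            key=lambda kv: (-kv[1], -celltype_totals.get(kv[0], 0), kv[0]),
        )[0]
        total = sum(labels.values())
        rows.append({
            "clonotype": key,
            "dominant_celltype": dominant,
            "consistency": labels[dominant] / total,
            "n_cells": total,
            "persisting": bool(call.table.loc[key, "persisting"]),
        })
    return pd.DataFrame(
        rows, columns=["clonotype", "dominant_celltype", "consistency",
                       "n_cells", "persisting"],
    ).set_index("clonotype")


def cross_pair_overlap_keys(
    tables: dict[str, RepertoireTable]
) -> set[str]:
    """Clonotype keys shared between different pairs (public-clonotype screen).

    Reported for QC only; never used for persistence calling.
    """
    seen: dict[str, str] = {}
    shared: set[str] = set()
    for pair_id, table in tables.items():
        for key in table.counts.index[table.counts.sum(axis=1) > 0]:
            if key in seen and seen[key] != pair_id:
                shared.add(key)
            seen.setdefault(key, pair_id)
    return shared
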