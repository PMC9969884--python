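"""Repertoire diversity, overlap and cell-composition statistics.

Diversity uses the inverse Simpson index D = 1 / sum_i p_i^2, the
effective number of equally abundant clones. Overlap uses the Morisita
index in its frequency-based (Morisita-Horn) form, bounded in [0, 1];
the classical count-based Morisita estimator is available behind a flag.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .clonotyping import RepertoireTable
from .errors import UsageError
from .io_model import CellRecord

logger = logging.getLogger(__name__)


def inverse_simpson(frequencies: Iterable[float]) -> float:
    """Inverse Simpson diversity D = 1 / sum p_i^2.

    ``frequencies`` must be nonnegative and sum to 1 (within 1e-9);
    D equals n for n equally abundant clones and 1 for a monoclonal
    repertoire.
    """
    p = np.asarray(list(frequencies), dtype=float)
    if p.size == 0:
        raise UsageError("inverse Simpson is undefined for an empty repertoire")
    if (p < 0).any():
        raise UsageError("frequencies must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise UsageError(f"frequencies must sum to 1 (got {total})")
    return float(1.0 / np.square(p).sum())


def sample_diversity(table: RepertoireTable) -> pd.Series:
    """Inverse Simpson per sample over that sample's clone frequencies."""
    out = {}
    for sid in table.counts.columns:
        col = table.counts[sid]
        col = col[col > 0]
        if col.sum() == 0:
            logger.warning("sample %s has no assigned cells; diversity undefined", sid)
            out[sid] = np.nan
            continue
        out[sid] = inverse_simpson(col / col.sum())
    return pd.Series(out, name="inverse_simpson")


def pooled_diversity(table: RepertoireTable, sample_ids: list[str]) -> float:
    """Inverse Simpson of the pooled counts of several samples."""
    pooled = table.counts[sample_ids].sum(axis=1)
    pooled = pooled[pooled > 0]
    if pooled.sum() == 0:
        raise UsageError("no assigned cells in the pooled samples")
    return inverse_simpson(pooled / pooled.sum())


def morisita_overlap(x, y, form: str = "horn") -> float:
    """Morisita overlap between two repertoires on aligned clone indices.

    With ``form='horn'`` (default) the bounded frequency-based
    Morisita-Horn index is computed:

        C = 2 * sum(x_i * y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y)

    with X = sum x_i, Y = sum y_i. ``form='classical'`` uses the original
    count-based estimator with the unbiased within-sample term
    sum x_i (x_i - 1) / (X (X - 1)), which can exceed 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("count vectors must be aligned on the same clonotype set")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise UsageError("Morisita overlap is undefined for an empty sample")
    cross = float(np.dot(x, y))
    if form == "horn":
        denom = (np.square(x).sum() / X**2 + np.square(y).sum() / Y**2) * X * Y
        return 2.0 * cross / denom
    if form == "classical":
        lx = float(np.dot(x, x - 1)) / (X * (X - 1)) if X > 1 else 0.0
        ly = float(np.dot(y, y - 1)) / (Y * (Y - 1)) if Y > 1 else 0.0
        if lx + ly == 0:
            raise UsageError("classical Morisita undefined: no repeated observations")
        return 2.0 * cross / ((lx + ly) * X * Y)
    raise UsageError(f"unknown Morisita form {form!r}")


def overlap_matrix(table: RepertoireTable, form: str = "horn") -> pd.DataFrame:
    """Pairwise Morisita overlap between all samples of a repertoire table.

    Clonotype indices are aligned on the union of keys (the table rows);
    the matrix is symmetric with unit diagonal for nonempty samples.
    """
    sids = list(table.counts.columns)
    if len(sids) < 2:
        raise UsageError("overlap matrix requires at least two samples")
    mat = pd.DataFrame(np.eye(len(sids)), index=sids, columns=sids)
    counts = table.counts
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            c = morisita_overlap(counts[a].to_numpy(), counts[b].to_numpy(), form=form)
            mat.loc[a, b] = mat.loc[b, a] = c
    return mat


def composition_fractions(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-sample cell-type fractions (rows sum to 1)."""
    df = pd.DataFrame(
        [(c.sample_id, c.celltype) for c in cells], columns=["sample", "celltype"]
    )
    counts = df.value_counts(["sample", "celltype"]).unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.columns.name = None
    fractions.index.name = "sample"
    return fractions
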