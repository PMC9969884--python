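"""Domain types and file IO for the clonal-tracking pipeline.

The pipeline consumes three kinds of files, all plain text:

* 10x-style ``filtered_contig_annotations.csv`` tables with one row per
  assembled V(D)J contig (TRA/TRB chains of single cells),
* a cell metadata TSV carrying sample assignment, transplant role and
  timepoint, cell-type label and the per-cell QC fields,
* a MatrixMarket gene x cell count matrix with ``features.tsv`` /
  ``barcodes.tsv`` sidecars.

Cells are identified by the ``(sample_id, barcode)`` pair throughout;
10x barcodes are only unique within one library, so the bare barcode is
never used as a key across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Longitudinal design: donors are sampled around stem-cell mobilization
#: (before and after G-CSF), recipients on days +90 and +180 post-transplant.
TIMEPOINTS = ("pre", "post", "d90", "d180")
DONOR_TIMEPOINTS = frozenset({"pre", "post"})
RECIPIENT_TIMEPOINTS = frozenset({"d90", "d180"})

#: QC thresholds: cells are removed when pct_mito > 10, n_genes outside
#: [250, 5000], or the level-1 label-transfer prediction score < 0.75.
QC_MAX_PCT_MITO = 10.0
QC_MIN_GENES = 250
QC_MAX_GENES = 5000
QC_MIN_PREDICTION_SCORE = 0.75

CONTIG_REQUIRED_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "umis",
    "productive",
)

METADATA_REQUIRED_COLUMNS = (
    "barcode",
    "sample",
    "pair",
    "role",
    "timepoint",
    "celltype",
    "l1_prediction_score",
    "pct_mito",
    "n_genes",
)


@dataclass(frozen=True)
class Sample:
    """One sequencing library from one individual at one timepoint."""

    sample_id: str
    pair_id: str
    role: str  # "donor" | "recipient"
    timepoint: str  # "pre" | "post" | "d90" | "d180"

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient"):
            raise ValidationError(f"unknown role {self.role!r} for sample {self.sample_id!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r} for sample {self.sample_id!r}"
            )
        expected = DONOR_TIMEPOINTS if self.role == "donor" else RECIPIENT_TIMEPOINTS
        if self.timepoint not in expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: role {self.role!r} is incompatible with "
                f"timepoint {self.timepoint!r}"
            )


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata: identity, phenotype label and QC fields."""

    barcode: str
    sample_id: str
    celltype: str
    l1_prediction_score: float
    pct_mito: float
    n_genes: int

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValidationError("cell barcode must be nonempty")
        if not 0.0 <= self.pct_mito <= 100.0:
            raise ValidationError(
                f"pct_mito {self.pct_mito} out of [0, 100] for {self.sample_id}:{self.barcode}"
            )

    @property
    def cell_id(self) -> tuple[str, str]:
        return (self.sample_id, self.barcode)


@dataclass(frozen=True)
class ChainRecord:
    """One productive TRA or TRB contig of one cell."""

    barcode: str
    sample_id: str
    locus: str  # "TRA" | "TRB"
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umis: int
    productive: bool

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ValidationError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.umis < 1:
            raise ValidationError(f"umis must be >= 1, got {self.umis}")
        if self.productive and len(self.cdr3_nt) % 3 != 0:
            raise ValidationError(
                f"productive CDR3 nucleotide length must be divisible by 3 "
                f"(got {len(self.cdr3_nt)} for {self.barcode})"
            )

    @property
    def cell_id(self) -> tuple[str, str]:
        return (self.sample_id, self.barcode)


@dataclass
class CountMatrix:
    """Sparse gene x cell integer count matrix.

    ``matrix`` is genes in rows, cells in columns (the MatrixMarket
    convention for 10x output); ``barcodes`` holds ``(sample_id, barcode)``
    pairs in column order.
    """

    genes: list[str]
    barcodes: list[tuple[str, str]]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"count matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValidationError("counts must be nonnegative")

    def column_index(self) -> dict[tuple[str, str], int]:
        return {cid: j for j, cid in enumerate(self.barcodes)}

    def subset_cells(self, cell_ids: Iterable[tuple[str, str]]) -> "CountMatrix":
        """Column subset in the order of ``cell_ids``; unknown ids raise KeyError."""
        idx = self.column_index()
        cols = [idx[c] for c in cell_ids]
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[j] for j in cols],
            matrix=self.matrix[:, cols].tocsr(),
        )


@dataclass
class Cohort:
    """A complete study: samples, cells, TCR chains and expression counts."""

    samples: list[Sample]
    cells: list[CellRecord]
    chains: list[ChainRecord]
    counts: CountMatrix | None = None

    def validate(self) -> None:
        sample_ids = {s.sample_id for s in self.samples}
        for cell in self.cells:
            if cell.sample_id not in sample_ids:
                raise ValidationError(f"cell {cell.barcode!r} references unknown sample "
                                      f"{cell.sample_id!r}")
        known_cells = {c.cell_id for c in self.cells}
        for chain in self.chains:
            if chain.cell_id not in known_cells:
                raise ValidationError(
                    f"chain for {chain.sample_id}:{chain.barcode} has no cell record"
                )

    def cells_by_sample(self) -> dict[str, list[CellRecord]]:
        out: dict[str, list[CellRecord]] = {s.sample_id: [] for s in self.samples}
        for cell in self.cells:
            out[cell.sample_id].append(cell)
        return out


def _as_bool(value) -> bool:
    """10x writes booleans as 'True'/'true'/'TRUE'/'None'; normalize."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() == "true"


def read_contig_annotations(path, sample_id: str = "") -> list[ChainRecord]:
    """Read a 10x-style ``filtered_contig_annotations.csv``.

    Only productive TRA/TRB rows are kept; everything else (non-productive
    contigs, BCR/gamma-delta loci) is dropped and the drop count logged.

    Parameters
    ----------
    path : path-like
        CSV file with at least the columns in :data:`CONTIG_REQUIRED_COLUMNS`.
    sample_id : str
        Sample the file belongs to; 10x writes one file per library, so the
        sample is not encoded inside the file. An existing ``sample`` column
        takes precedence.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CONTIG_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table {path} is missing required column(s): "
                          + ", ".join(missing))
    has_sample_col = "sample" in df.columns

    records: list[ChainRecord] = []
    n_unproductive = 0
    n_other_locus = 0
    for row in df.itertuples(index=False):
        if row.chain not in ("TRA", "TRB"):
            n_other_locus += 1
            continue
        if not _as_bool(row.productive):
            n_unproductive += 1
            continue
        records.append(
            ChainRecord(
                barcode=row.barcode,
                sample_id=(getattr(row, "sample") if has_sample_col else sample_id),
                locus=row.chain,
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                cdr3_aa=row.cdr3,
                cdr3_nt=row.cdr3_nt,
                umis=int(row.umis),
                productive=True,
            )
        )
    if n_unproductive or n_other_locus:
        logger.info(
            "%s: kept %d chains, dropped %d non-productive and %d non-TRA/TRB rows",
            path, len(records), n_unproductive, n_other_locus,
        )
    return records


def read_cell_metadata(path) -> tuple[list[Sample], list[CellRecord]]:
    """Read the cell metadata TSV into samples and cell records.

    The sample table is derived from the unique (sample, pair, role,
    timepoint) combinations; inconsistent annotation of one sample raises.
    """
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample": str, "pair": str})
    missing = [c for c in METADATA_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} is missing required column(s): "
                          + ", ".join(missing))
    for col in ("l1_prediction_score", "pct_mito", "n_genes"):
        if df[col].isna().any():
            raise ValidationError(f"metadata column {col!r} has missing values")

    sample_df = df[["sample", "pair", "role", "timepoint"]].drop_duplicates()
    if sample_df["sample"].duplicated().any():
        dup = sample_df.loc[sample_df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"sample {dup!r} has inconsistent pair/role/timepoint annotation")
    samples = [
        Sample(sample_id=r.sample, pair_id=r.pair, role=r.role, timepoint=r.timepoint)
        for r in sample_df.itertuples(index=False)
    ]
    cells = [
        CellRecord(
            barcode=r.barcode,
            sample_id=r.sample,
            celltype=r.celltype,
            l1_prediction_score=float(r.l1_prediction_score),
            pct_mito=float(r.pct_mito),
            n_genes=int(r.n_genes),
        )
        for r in df.itertuples(index=False)
    ]
    return samples, cells


def read_count_matrix(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a MatrixMarket count matrix with features/barcodes sidecars.

    ``features.tsv`` has the gene symbol in its first column.
    ``barcodes.tsv`` has either two columns (sample_id, barcode) — the
    dialect this package writes — or the bare 10x single-column form, in
    which case the sample id is left empty.
    """
    matrix = sp.csr_matrix(scipy.io.mmread(mtx_path))
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    genes = features.iloc[:, 0].tolist()
    bc = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    if bc.shape[1] >= 2:
        barcodes = list(zip(bc.iloc[:, 0], bc.iloc[:, 1]))
    else:
        barcodes = [("", b) for b in bc.iloc[:, 0]]
    if matrix.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix dimensions {matrix.shape} do not match {len(genes)} features "
            f"and {len(barcodes)} barcodes"
        )
    if matrix.nnz:
        data = matrix.data
        if not np.allclose(data, np.round(data)):
            raise FormatError("count matrix contains non-integer values")
        matrix.data = np.asarray(np.round(data), dtype=np.int64)
    return CountMatrix(genes=genes, barcodes=barcodes, matrix=matrix)


def qc_filter_cells(
    cells: list[CellRecord],
    max_pct_mito: float = QC_MAX_PCT_MITO,
    min_genes: int = QC_MIN_GENES,
    max_genes: int = QC_MAX_GENES,
    min_score: float = QC_MIN_PREDICTION_SCORE,
) -> tuple[list[CellRecord], list[tuple[CellRecord, str]]]:
    """Apply the per-cell QC filter.

    A cell is kept when pct_mito <= 10, 250 <= n_genes <= 5000 and the
    level-1 prediction score >= 0.75 (removal thresholds are strict, so
    boundary values survive). Removed cells carry the first failing reason
    in the fixed order ``mito``, ``n_genes``, ``score``.

    Returns
    -------
    (kept, removed)
        ``removed`` is a list of ``(cell, reason)`` pairs; kept and removed
        together partition the input.
    """
    kept: list[CellRecord] = []
    removed: list[tuple[CellRecord, str]] = []
    for cell in cells:
        if cell.pct_mito > max_pct_mito:
            removed.append((cell, "mito"))
        elif not (min_genes <= cell.n_genes <= max_genes):
            removed.append((cell, "n_genes"))
        elif cell.l1_prediction_score < min_score:
            removed.append((cell, "score"))
        else:
            kept.append(cell)
    logger.info("QC: kept %d / %d cells (%d removed)", len(kept), len(cells), len(removed))
    return kept, removed


def compute_pct_mito(counts: CountMatrix, prefix: str = "MT-") -> dict[tuple[str, str], float]:
    """Fraction of counts in mitochondrial genes, as a percentage per cell.

    Fallback for metadata lacking a pct_mito column; genes are recognized
    by symbol prefix.
    """
    mito_rows = [i for i, g in enumerate(counts.genes) if g.startswith(prefix)]
    total = np.asarray(counts.matrix.sum(axis=0)).ravel()
    mito = (
        np.asarray(counts.matrix[mito_rows, :].sum(axis=0)).ravel()
        if mito_rows
        else np.zeros_like(total, dtype=float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    return {cid: float(p) for cid, p in zip(counts.barcodes, pct)}
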