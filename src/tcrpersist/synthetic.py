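"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a longitudinal donor/recipient study of
allogeneic HSCT: 4-5 donor-recipient pairs, four timepoints (donor pre/post
G-CSF mobilization, recipient day +90 and +180), roughly 2,500 cells per
sample, heavily skewed clone-size distributions, and a planted persisting
CD8 effector-memory (CD8TEM) subpopulation whose cells carry an
upregulated expression signature.

The generative model, per pair:

* T-cell clones are created per T subset with Zipf-like rank weights
  (rank-frequency exponent ``1/(a-1)`` for a clone-size power law with
  exponent ``a``), so a few clones dominate each repertoire.
* A size-biased subset of the donor CD8TEM clones is marked persisting;
  those clones reappear in the recipient with their donor weight
  multiplied by ``persist_expansion``. All other recipient clones are
  novel, so repertoires of different pairs never share a clonotype.
* Each cell draws a cell type from ``baseline_celltype_mix``; T cells
  then draw a clone from the subset-conditional clone distribution of
  their sample. Paired TRA/TRB chains are emitted per clone with
  per-locus dropout, occasional secondary (lower-UMI) alpha chains, and
  globally unique (V gene, CDR3nt) keys.
* Gene counts follow a negative binomial with variance mu + phi*mu^2.
  log2 mean offsets encode cell-type programs (cytotoxicity gradient,
  CD8TEM markers, naive markers, lineage markers) and, for cells of
  persisting clones, the planted persistence signature.

Everything is deterministic given ``SimConfig.seed``; per-sample draws
use sub-streams keyed by (pair, timepoint) so one sample can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .clonotyping import clonotype_key
from .errors import ConfigError, UsageError
from .io_model import (
    CellRecord,
    ChainRecord,
    Cohort,
    CountMatrix,
    Sample,
    TIMEPOINTS,
)

# --------------------------------------------------------------------------
# Gene panels and cell-type programs

#: Literature cytotoxicity panel (12 genes).
CYTOTOXICITY_GENES = (
    "PRF1", "GZMB", "GZMA", "GZMH", "GNLY", "NKG7",
    "KLRD1", "KLRG1", "FCGR3A", "CTSW", "CST7", "FGFBP2",
)

#: Persistence signature: 54 genes upregulated in cells of persisting
#: CD8TEM clones. The leading members are the NK-like effector markers;
#: the remainder are synthetic placeholders.
DEFAULT_SIGNATURE_GENES = (
    "NKG7", "GZMH", "ADGRG1", "KLRD1", "FCGR3A",
) + tuple(f"PSG{i:03d}" for i in range(6, 55))
DEFAULT_SIGNATURE_LOG2_EFFECT = 0.8

#: Top-50 marker panel for the CD8TEM population.
CD8TEM_MARKERS = (
    "CCL5", "GZMK", "CD8A", "CD8B", "EOMES", "CCL4", "CMC1", "KLRB1",
    "CRTAM", "DUSP2",
) + tuple(f"TEM{i:03d}" for i in range(11, 51))

NAIVE_MARKERS = ("CCR7", "SELL", "TCF7", "LEF1", "IL7R", "BACH2")

MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")

#: Non-T lineage markers: gene -> (celltype, log2 effect).
LINEAGE_MARKERS = {
    "MS4A1": ("B", 3.0), "CD79A": ("B", 2.5),
    "LYZ": ("Mono", 3.5), "CD14": ("Mono", 2.5),
    "NCAM1": ("NK", 2.5), "KLRF1": ("NK", 2.0),
}

#: Default CITE-seq surface panel (names only; ADT counts are not simulated).
DEFAULT_ADT_PANEL = (
    "ADT_CD45RA", "ADT_CD45RO", "ADT_CD57", "ADT_KLRG1", "ADT_GPR56",
    "ADT_CD16", "ADT_CD94", "ADT_CX3CR1", "ADT_PD1", "ADT_CD27",
)

T_CELLTYPES = ("CD8 TEM", "CD8 TCM", "CD8 Naive", "CD4 TEM", "CD4 TCM", "CD4 Naive")
CD8_CELLTYPES = ("CD8 TEM", "CD8 TCM", "CD8 Naive")

#: Position of each population on the naive -> effector axis; scales the
#: cytotoxicity-gene program.
EFFECTORNESS_LEVEL = {
    "CD8 Naive": 0.0, "CD8 TCM": 0.35, "CD8 TEM": 0.8,
    "CD4 Naive": 0.0, "CD4 TCM": 0.30, "CD4 TEM": 0.55,
    "NK": 1.0, "B": 0.0, "Mono": 0.0,
}

DEFAULT_CELLTYPE_MIX = {
    "CD8 TEM": 0.19, "CD8 TCM": 0.08, "CD8 Naive": 0.11,
    "CD4 TEM": 0.08, "CD4 TCM": 0.12, "CD4 Naive": 0.17,
    "NK": 0.08, "B": 0.08, "Mono": 0.09,
}

_CYTO_AMPLITUDE = 2.2  # log2 span of the cytotoxicity program, naive -> NK
_TEM_MARKER_EFFECT = 1.6
_NAIVE_MARKER_EFFECT = 1.4

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _translate(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt), 3))


# --------------------------------------------------------------------------
# Configuration and ground truth


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 4 pairs, 2,500 cells per
    sample, skewed clone sizes, a persisting CD8TEM subpopulation whose
    cells make up roughly 6-19% of donor T cells, and 54 signature genes
    upregulated by 0.8 log2 units in persisting cells.
    """

    n_pairs: int = 4
    cells_per_sample: int = 2500
    clone_count: int = 600  # T-cell clones per pair (donor pool)
    clone_size_distribution: float = 2.0  # power-law exponent a; rank weights r^(-1/(a-1))
    persist_fraction: float = 0.10  # fraction of donor CD8TEM clones that persist
    persist_expansion: float = 5.0  # recipient frequency multiplier for persisting clones
    signature_genes: dict[str, float] = field(
        default_factory=lambda: {g: DEFAULT_SIGNATURE_LOG2_EFFECT for g in DEFAULT_SIGNATURE_GENES}
    )
    n_genes: int = 1000
    nb_dispersion: float = 0.3
    baseline_celltype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLTYPE_MIX)
    )
    seed: int = 0
    # secondary knobs
    recipient_cd8tem_shift: float = 2.0  # recipient CD8TEM mix multiplier (clonal expansion)
    recipient_novel_exponent: float = 2.5  # flatter size distribution for novel recipient clones
    lib_size: float = 2500.0  # mean counts per cell before depth scaling
    depth_sd: float = 0.1  # lognormal sd of per-sample depth factors
    recipient_only_fraction: float = 1.0  # novel recipient clones per donor clone
    alpha_dropout: float = 0.12  # per-cell probability of missing the TRA chain
    beta_dropout: float = 0.06
    dual_alpha_rate: float = 0.04  # secondary lower-UMI TRA contigs
    qc_fail_mito_rate: float = 0.02
    qc_fail_score_rate: float = 0.02

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        mix_sum = sum(self.baseline_celltype_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigError(f"baseline_celltype_mix sums to {mix_sum}, expected 1")
        for name, value in (
            ("persist_fraction", self.persist_fraction),
            ("recipient_only_fraction", min(self.recipient_only_fraction, 1.0)),
            ("alpha_dropout", self.alpha_dropout),
            ("beta_dropout", self.beta_dropout),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not all(np.isfinite(list(self.signature_genes.values()))):
            raise ConfigError("signature effect sizes must be finite")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.persist_fraction * self.clone_count < 1:
            raise ConfigError(
                "persist_fraction x clone_count < 1: no persisting clones can be planted"
            )

    def pair_ids(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_pairs)]

    def celltype_mix(self, role: str = "donor") -> dict[str, float]:
        """Cell-type mix for a role; recipients shift mass towards CD8 TEM.

        Post-transplant repertoires are reconstituted by expanded effector
        clones, so the recipient CD8 TEM fraction is multiplied by
        ``recipient_cd8tem_shift`` and the mix renormalized.
        """
        mix = dict(self.baseline_celltype_mix)
        if role == "recipient" and "CD8 TEM" in mix:
            mix["CD8 TEM"] *= self.recipient_cd8tem_shift
        total = sum(mix.values())
        return {ct: v / total for ct, v in mix.items()}

    def t_mix(self, role: str = "donor") -> dict[str, float]:
        """Cell-type mix conditional on being a T cell."""
        mix = self.celltype_mix(role)
        t_total = sum(mix.get(ct, 0.0) for ct in T_CELLTYPES)
        return {ct: mix.get(ct, 0.0) / t_total for ct in T_CELLTYPES}


@dataclass
class GroundTruth:
    """Planted truth of one simulated cohort.

    ``clones`` is indexed by clonotype key with columns pair_id, celltype,
    persisting; ``frequencies`` holds the planted per-sample clone
    frequency over T cells; ``genes`` records per-gene signature
    membership and log2 effect; ``undersampled`` lists planted persisting
    clones that were not observed on both sides of their pair.
    """

    clones: pd.DataFrame
    frequencies: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig
    undersampled: list[str] = field(default_factory=list)

    @property
    def persisting_keys(self) -> set[str]:
        return set(self.clones.index[self.clones["persisting"]])

    def signature_gene_set(self) -> set[str]:
        return set(self.genes.index[self.genes["is_signature"]])


# --------------------------------------------------------------------------
# Internal helpers


def _rank_weights(n: int, exponent: float) -> np.ndarray:
    """Zipf-like rank weights for a clone-size power law with exponent a."""
    if n == 0:
        return np.zeros(0)
    beta = 1.0 / (exponent - 1.0) if exponent > 1.0 else 1.0
    w = np.arange(1, n + 1, dtype=float) ** (-beta)
    return w / w.sum()


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by ``proportions``."""
    raw = proportions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def build_gene_panel(config: SimConfig) -> list[str]:
    """Assemble the gene list: named marker/signature genes, then filler."""
    named: list[str] = []
    for group in (
        MITO_GENES,
        CYTOTOXICITY_GENES,
        tuple(config.signature_genes),
        CD8TEM_MARKERS,
        NAIVE_MARKERS,
        tuple(LINEAGE_MARKERS),
    ):
        for g in group:
            if g not in named:
                named.append(g)
    if config.n_genes < len(named):
        raise ConfigError(
            f"n_genes={config.n_genes} smaller than the {len(named)} named marker genes"
        )
    filler = [f"G{i:04d}" for i in range(1, config.n_genes - len(named) + 1)]
    return named + filler


def _celltype_log2_effects(genes: list[str], config: SimConfig) -> dict[str, np.ndarray]:
    """Per-celltype log2 offsets over the gene panel (persistence excluded)."""
    gidx = {g: i for i, g in enumerate(genes)}
    effects = {ct: np.zeros(len(genes)) for ct in config.baseline_celltype_mix}
    for ct in effects:
        level = EFFECTORNESS_LEVEL.get(ct, 0.0)
        for g in CYTOTOXICITY_GENES:
            effects[ct][gidx[g]] += _CYTO_AMPLITUDE * level
        if ct == "CD8 TEM":
            for g in CD8TEM_MARKERS:
                effects[ct][gidx[g]] += _TEM_MARKER_EFFECT
        elif ct == "CD8 TCM":
            for g in CD8TEM_MARKERS:
                effects[ct][gidx[g]] += 0.4
        if ct in ("CD8 Naive", "CD4 Naive"):
            for g in NAIVE_MARKERS:
                effects[ct][gidx[g]] += _NAIVE_MARKER_EFFECT
        elif ct in ("CD8 TCM", "CD4 TCM"):
            for g in NAIVE_MARKERS:
                effects[ct][gidx[g]] += 0.5
    for g, (ct, eff) in LINEAGE_MARKERS.items():
        if ct in effects:
            effects[ct][gidx[g]] += eff
    return effects


def _baseline_means(genes: list[str], config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline mean counts, scaled so a baseline cell totals lib_size."""
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.1, size=n)
    named = sum(1 for g in genes if not g.startswith("G"))
    # keep marker genes comfortably expressed so planted effects are detectable
    base[:named] = np.maximum(base[:named], 1.0) * 2.0
    for i, g in enumerate(genes):
        if g in MITO_GENES:
            base[i] = 0.01 * n  # ~1% of library mass each before scaling
    return base * (config.lib_size / base.sum())


@dataclass
class _CloneInfo:
    key: str
    pair_id: str
    celltype: str
    persisting: bool
    alpha: tuple[str, str, str, str]  # v, j, cdr3_nt, cdr3_aa
    beta: tuple[str, str, str, str]
    donor_weight: float  # conditional within celltype, donor samples
    recipient_weight: float  # conditional within celltype, recipient samples


def _make_chain(rng: np.random.Generator, locus: str, used: set) -> tuple[str, str, str, str]:
    while True:
        if locus == "TRA":
            v = f"TRAV{rng.integers(1, 42)}"
            j = f"TRAJ{rng.integers(1, 62)}"
        else:
            v = f"TRBV{rng.integers(1, 31)}"
            j = f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}"
        n_codons = int(rng.integers(10, 16))  # CDR3nt length 30..45, divisible by 3
        nt = "TGT" + "".join(
            _NONSTOP_CODONS[k] for k in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 1)
        )
        if (v, nt) not in used:
            used.add((v, nt))
            return v, j, nt, _translate(nt)


def _plan_clones(config: SimConfig, rng: np.random.Generator) -> list[_CloneInfo]:
    """Create the clone pools of all pairs with planted weights."""
    t_mix = config.t_mix()
    used_alpha: set = set()
    used_beta: set = set()
    clones: list[_CloneInfo] = []
    per_ct = _largest_remainder(
        np.array([t_mix[ct] for ct in T_CELLTYPES]), config.clone_count
    )
    for pair_id in config.pair_ids():
        for ct, n_donor in zip(T_CELLTYPES, per_ct):
            if n_donor == 0:
                continue
            donor_w = _rank_weights(n_donor, config.clone_size_distribution)
            persisting = np.zeros(n_donor, dtype=bool)
            if ct == "CD8 TEM":
                n_persist = int(round(config.persist_fraction * n_donor))
                if n_persist < 1:
                    raise ConfigError(
                        "persist_fraction too small: no CD8 TEM clone can be planted"
                    )
                # size-biased choice: expanded clones are the ones seen on both sides
                chosen = rng.choice(n_donor, size=n_persist, replace=False, p=donor_w)
                persisting[chosen] = True
            n_novel = int(round(config.recipient_only_fraction * n_donor))
            novel_w = _rank_weights(n_novel, config.recipient_novel_exponent)

            # recipient pool: persisting clones expanded + novel clones
            rec_raw = np.concatenate([
                np.where(persisting, donor_w * config.persist_expansion, 0.0),
                novel_w,
            ])
            rec_w = rec_raw / rec_raw.sum() if rec_raw.sum() > 0 else rec_raw

            for i in range(n_donor):
                a = _make_chain(rng, "TRA", used_alpha)
                b = _make_chain(rng, "TRB", used_beta)
                clones.append(_CloneInfo(
                    key=clonotype_key(a[0], a[2], b[0], b[2]),
                    pair_id=pair_id, celltype=ct, persisting=bool(persisting[i]),
                    alpha=a, beta=b,
                    donor_weight=float(donor_w[i]),
                    recipient_weight=float(rec_w[i]),
                ))
            for i in range(n_novel):
                a = _make_chain(rng, "TRA", used_alpha)
                b = _make_chain(rng, "TRB", used_beta)
                clones.append(_CloneInfo(
                    key=clonotype_key(a[0], a[2], b[0], b[2]),
                    pair_id=pair_id, celltype=ct, persisting=False,
                    alpha=a, beta=b,
                    donor_weight=0.0,
                    recipient_weight=float(rec_w[n_donor + i]),
                ))
    return clones


# --------------------------------------------------------------------------
# Main entry points


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Deterministic given ``config.seed``: the clone plan, gene baseline and
    every per-sample draw use fixed sub-streams of the master seed.
    """
    config.validate()
    clone_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    genes = build_gene_panel(config)
    gidx = {g: i for i, g in enumerate(genes)}
    baseline = _baseline_means(genes, config, gene_rng)
    ct_effects = _celltype_log2_effects(genes, config)
    sig_vec = np.zeros(len(genes))
    for g, eff in config.signature_genes.items():
        sig_vec[gidx[g]] = eff

    clones = _plan_clones(config, clone_rng)
    clones_by_pair_ct: dict[tuple[str, str], list[_CloneInfo]] = {}
    for cl in clones:
        clones_by_pair_ct.setdefault((cl.pair_id, cl.celltype), []).append(cl)

    celltypes = list(config.baseline_celltype_mix)
    mix_by_role = {
        role: np.array([config.celltype_mix(role)[ct] for ct in celltypes])
        for role in ("donor", "recipient")
    }
    t_mix_by_role = {role: config.t_mix(role) for role in ("donor", "recipient")}

    samples: list[Sample] = []
    cells: list[CellRecord] = []
    chains: list[ChainRecord] = []
    cols: list[sp.csr_matrix] = []
    barcodes: list[tuple[str, str]] = []
    observed_sides: dict[str, set[str]] = {}

    nb_n = 1.0 / config.nb_dispersion

    for pair_id in config.pair_ids():
        for tp in TIMEPOINTS:
            role = "donor" if tp in ("pre", "post") else "recipient"
            sample_id = f"{pair_id}_{tp}"
            samples.append(Sample(sample_id=sample_id, pair_id=pair_id, role=role, timepoint=tp))
            stream = zlib.crc32(f"{pair_id}|{tp}".encode())
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, stream]))
            depth = float(rng.lognormal(mean=0.0, sigma=config.depth_sd))

            n_cells = config.cells_per_sample
            ct_draw = rng.choice(len(celltypes), size=n_cells, p=mix_by_role[role])
            cell_ct = [celltypes[k] for k in ct_draw]
            cell_clone: list[_CloneInfo | None] = [None] * n_cells
            for i, ct in enumerate(cell_ct):
                if ct not in T_CELLTYPES:
                    continue
                pool = clones_by_pair_ct.get((pair_id, ct), [])
                w = np.array([
                    cl.donor_weight if role == "donor" else cl.recipient_weight
                    for cl in pool
                ])
                if w.sum() <= 0:
                    continue
                cell_clone[i] = pool[rng.choice(len(pool), p=w / w.sum())]

            # expression counts, drawn per (celltype, persisting) group
            counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
            persist_flag = np.array([
                cl is not None and cl.persisting for cl in cell_clone
            ])
            for ct in celltypes:
                for pf in (False, True):
                    idx = [
                        i for i in range(n_cells)
                        if cell_ct[i] == ct and persist_flag[i] == pf
                    ]
                    if not idx:
                        continue
                    log2_mu = np.log2(baseline) + ct_effects[ct] + (sig_vec if pf else 0.0)
                    mu = depth * np.exp2(log2_mu)
                    p = nb_n / (nb_n + mu)
                    counts[idx, :] = rng.negative_binomial(nb_n, p, size=(len(idx), len(genes)))

            n_detected = (counts > 0).sum(axis=1)
            pct_mito = np.clip(rng.gamma(shape=4.0, scale=1.0, size=n_cells), 0.0, 100.0)
            mito_fail = rng.random(n_cells) < config.qc_fail_mito_rate
            pct_mito[mito_fail] = np.clip(10.5 + rng.gamma(2.0, 4.0, size=mito_fail.sum()), 0, 100)
            score = rng.beta(40.0, 3.0, size=n_cells)
            score_fail = rng.random(n_cells) < config.qc_fail_score_rate
            score[score_fail] = rng.uniform(0.3, 0.7, size=score_fail.sum())

            for i in range(n_cells):
                barcode = f"BC{i:05d}"
                cells.append(CellRecord(
                    barcode=barcode, sample_id=sample_id, celltype=cell_ct[i],
                    l1_prediction_score=float(score[i]),
                    pct_mito=float(pct_mito[i]), n_genes=int(n_detected[i]),
                ))
                barcodes.append((sample_id, barcode))
                cl = cell_clone[i]
                if cl is None:
                    continue
                observed_sides.setdefault(cl.key, set()).add(role)
                drop_a = rng.random() < config.alpha_dropout
                drop_b = rng.random() < config.beta_dropout
                if not drop_a:
                    umis_a = 1 + int(rng.poisson(3.0))
                    chains.append(ChainRecord(
                        barcode=barcode, sample_id=sample_id, locus="TRA",
                        v_gene=cl.alpha[0], j_gene=cl.alpha[1],
                        cdr3_aa=cl.alpha[3], cdr3_nt=cl.alpha[2],
                        umis=umis_a, productive=True,
                    ))
                    if umis_a > 1 and rng.random() < config.dual_alpha_rate:
                        v2, j2, nt2, aa2 = _make_chain(rng, "TRA", set())
                        chains.append(ChainRecord(
                            barcode=barcode, sample_id=sample_id, locus="TRA",
                            v_gene=v2, j_gene=j2, cdr3_aa=aa2, cdr3_nt=nt2,
                            umis=int(rng.integers(1, umis_a)), productive=True,
                        ))
                if not drop_b:
                    chains.append(ChainRecord(
                        barcode=barcode, sample_id=sample_id, locus="TRB",
                        v_gene=cl.beta[0], j_gene=cl.beta[1],
                        cdr3_aa=cl.beta[3], cdr3_nt=cl.beta[2],
                        umis=1 + int(rng.poisson(3.0)), productive=True,
                    ))
            cols.append(sp.csr_matrix(counts))

    matrix = sp.vstack(cols).T.tocsr() if cols else sp.csr_matrix((len(genes), 0))
    count_matrix = CountMatrix(genes=genes, barcodes=barcodes, matrix=matrix)
    cohort = Cohort(samples=samples, cells=cells, chains=chains, counts=count_matrix)

    # ground truth tables
    clone_rows = []
    freq_rows = []
    sample_ids = [s.sample_id for s in samples]
    for cl in clones:
        clone_rows.append({
            "clonotype": cl.key, "pair_id": cl.pair_id, "celltype": cl.celltype,
            "persisting": cl.persisting,
        })
        freqs = {}
        for s in samples:
            if s.pair_id != cl.pair_id:
                freqs[s.sample_id] = 0.0
            else:
                w = cl.donor_weight if s.role == "donor" else cl.recipient_weight
                freqs[s.sample_id] = t_mix_by_role[s.role][cl.celltype] * w
        freq_rows.append(freqs)
    clones_df = pd.DataFrame(clone_rows).set_index("clonotype")
    freq_df = pd.DataFrame(freq_rows, index=clones_df.index)[sample_ids]
    genes_df = pd.DataFrame({
        "is_signature": [g in config.signature_genes for g in genes],
        "log2_effect": [config.signature_genes.get(g, 0.0) for g in genes],
    }, index=pd.Index(genes, name="gene"))

    undersampled = sorted(
        cl.key for cl in clones
        if cl.persisting and observed_sides.get(cl.key, set()) != {"donor", "recipient"}
    )
    truth = GroundTruth(
        clones=clones_df, frequencies=freq_df, genes=genes_df,
        config=config, undersampled=undersampled,
    )
    return cohort, truth


# --------------------------------------------------------------------------
# Fixture writer / truth IO


def write_fixture(cohort: Cohort, truth: GroundTruth, outdir, force: bool = False) -> dict[str, Path]:
    """Write a cohort to disk in the dialects the readers consume.

    Emits ``contigs.csv``, ``metadata.tsv``, ``matrix.mtx`` +
    ``features.tsv``/``barcodes.tsv`` and ``truth.json``. Refuses to write
    into a non-empty directory unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise UsageError(f"output directory {outdir} is not empty (use force=True)")

    paths = {
        "contigs": outdir / "contigs.csv",
        "metadata": outdir / "metadata.tsv",
        "mtx": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "truth": outdir / "truth.json",
    }

    sample_info = {s.sample_id: s for s in cohort.samples}
    pd.DataFrame([
        {
            "barcode": c.barcode, "sample": c.sample_id,
            "pair": sample_info[c.sample_id].pair_id,
            "role": sample_info[c.sample_id].role,
            "timepoint": sample_info[c.sample_id].timepoint,
            "celltype": c.celltype,
            "l1_prediction_score": c.l1_prediction_score,
            "pct_mito": c.pct_mito, "n_genes": c.n_genes,
        }
        for c in cohort.cells
    ], columns=["barcode", "sample", "pair", "role", "timepoint", "celltype",
                "l1_prediction_score", "pct_mito", "n_genes"],
    ).to_csv(paths["metadata"], sep="\t", index=False)

    pd.DataFrame([
        {
            "barcode": ch.barcode, "sample": ch.sample_id, "chain": ch.locus,
            "v_gene": ch.v_gene, "j_gene": ch.j_gene, "cdr3": ch.cdr3_aa,
            "cdr3_nt": ch.cdr3_nt, "umis": ch.umis,
            "productive": "true" if ch.productive else "false",
        }
        for ch in cohort.chains
    ], columns=["barcode", "sample", "chain", "v_gene", "j_gene", "cdr3",
                "cdr3_nt", "umis", "productive"],
    ).to_csv(paths["contigs"], index=False)

    counts = cohort.counts
    if counts is None:
        counts = CountMatrix(genes=[], barcodes=[], matrix=sp.csr_matrix((0, 0), dtype=np.int64))
    scipy.io.mmwrite(paths["mtx"], counts.matrix.astype(np.int64).tocoo())
    with open(paths["features"], "w") as fh:
        for g in counts.genes:
            fh.write(f"{g}\n")
    with open(paths["barcodes"], "w") as fh:
        for sid, bc in counts.barcodes:
            fh.write(f"{sid}\t{bc}\n")

    truth_payload = {
        "config": dataclasses.asdict(truth.config),
        "clones": truth.clones.reset_index().to_dict(orient="records"),
        "frequencies": {
            key: {s: float(v) for s, v in row.items()}
            for key, row in truth.frequencies.iterrows()
        },
        "genes": truth.genes.reset_index().to_dict(orient="records"),
        "undersampled": truth.undersampled,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return paths


def read_truth(path) -> GroundTruth:
    """Load a ``truth.json`` written by :func:`write_fixture`."""
    with open(path) as fh:
        payload = json.load(fh)
    config = SimConfig(**payload["config"])
    clones = pd.DataFrame(payload["clones"]).set_index("clonotype")
    freq = pd.DataFrame.from_dict(payload["frequencies"], orient="index")
    freq.index.name = "clonotype"
    genes = pd.DataFrame(payload["genes"]).set_index("gene")
    return GroundTruth(
        clones=clones, frequencies=freq.loc[clones.index], genes=genes,
        config=config, undersampled=list(payload.get("undersampled", [])),
    )
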