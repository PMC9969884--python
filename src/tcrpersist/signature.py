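"""Pseudobulk differential expression and transcriptional scoring.

The persistence signature is derived replicate-aware: per-cell counts are
summed into (sample, cell type, persistence-stratum) pseudobulk profiles,
and a negative-binomial log-linear model with donor-recipient pair
identity as a fixed-effect covariate tests the persisting-vs-other
contrast gene by gene. Size factors use the median-of-ratios estimator;
gene-wise dispersions come from a method-of-moments estimate on the
normalized counts. P-values are Benjamini-Hochberg adjusted.

Scoring: the cytotoxicity score projects log-CPM profiles onto the first
principal component of a cytotoxicity reference panel (NK cells anchor
the positive end); the effectorness score orders CD8 T-cells along the
naive-to-effector axis via PC1 rank pseudotime, a deliberately simple
stand-in for trajectory-based pseudotime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .clonotyping import ClonotypeAssignment
from .errors import UsageError, ValidationError
from .io_model import CellRecord, CountMatrix, Sample
from .synthetic import CD8_CELLTYPES, CYTOTOXICITY_GENES, EFFECTORNESS_LEVEL

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


# --------------------------------------------------------------------------
# Pseudobulk aggregation


@dataclass
class PseudobulkMatrix:
    """Gene x group matrix of summed integer counts.

    ``groups`` carries one row per column of ``counts`` with sample_id,
    celltype, stratum, pair_id, role and the number of member cells.
    """

    counts: pd.DataFrame  # genes x group ids, integer
    groups: pd.DataFrame  # index: group id


def pseudobulk_aggregate(
    counts: CountMatrix,
    cells: list[CellRecord],
    samples: list[Sample],
    strata: dict[tuple[str, str], str] | None = None,
    celltypes: list[str] | None = None,
) -> PseudobulkMatrix:
    """Sum per-cell counts into (sample, celltype, stratum) groups.

    ``strata`` maps cell ids to a persistence stratum; cells without an
    entry get stratum ``"all"``. ``celltypes`` optionally restricts the
    aggregation. Conservation holds exactly: each group column is the
    integer sum of its member cells' count vectors.
    """
    col_of = counts.column_index()
    group_ids: list[str] = []
    group_index: dict[str, int] = {}
    meta: list[dict] = []
    sample_info = {s.sample_id: s for s in samples}
    rows_cell: list[int] = []
    rows_group: list[int] = []
    for cell in cells:
        if celltypes is not None and cell.celltype not in celltypes:
            continue
        j = col_of.get(cell.cell_id)
        if j is None:
            raise ValidationError(
                f"cell {cell.sample_id}:{cell.barcode} missing from the count matrix"
            )
        stratum = (strata or {}).get(cell.cell_id, "all")
        gid = f"{cell.sample_id}|{cell.celltype}|{stratum}"
        if gid not in group_index:
            group_index[gid] = len(group_ids)
            group_ids.append(gid)
            info = sample_info[cell.sample_id]
            meta.append({
                "group": gid, "sample_id": cell.sample_id, "celltype": cell.celltype,
                "stratum": stratum, "pair_id": info.pair_id, "role": info.role,
                "timepoint": info.timepoint, "n_cells": 0,
            })
        g = group_index[gid]
        meta[g]["n_cells"] += 1
        rows_cell.append(j)
        rows_group.append(g)

    if not group_ids:
        raise UsageError("no cells left to aggregate")
    indicator = sp.csr_matrix(
        (np.ones(len(rows_cell)), (rows_cell, rows_group)),
        shape=(len(counts.barcodes), len(group_ids)),
    )
    pb = (counts.matrix @ indicator).toarray().astype(np.int64)
    counts_df = pd.DataFrame(pb, index=pd.Index(counts.genes, name="gene"), columns=group_ids)
    groups_df = pd.DataFrame(meta).set_index("group")
    return PseudobulkMatrix(counts=counts_df, groups=groups_df)


# --------------------------------------------------------------------------
# Paired NB differential expression


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors: median ratio to the geometric-mean profile."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_counts = np.log(counts.where(counts > 0))
    log_geo = log_counts.mean(axis=1)
    usable = log_geo.notna() & np.isfinite(log_geo)
    if usable.sum() < 1:
        raise UsageError("no gene is expressed in all groups; cannot estimate size factors")
    ratios = np.log(counts.loc[usable]).sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())  # normalize to geometric mean 1


def _dispersion_from_fit(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments dispersion around fitted means.

    Solves sum_j [(y_j - mu_j)^2 - mu_j] / mu_j^2 = (m - k) * alpha, the
    moment equation of Var(Y) = mu + alpha * mu^2 with a degrees-of-freedom
    correction for the k fitted parameters; works for designs without
    replicated groups.
    """
    m = len(y)
    df = max(m - n_params, 1)
    mu = np.maximum(mu, 1e-8)
    alpha = float(np.sum(((y - mu) ** 2 - mu) / mu**2) / df)
    return min(max(alpha, DISPERSION_FLOOR), 100.0)


def _pooled_nb_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Pooled NB dispersion via the Pearson chi-square estimating equation.

    Solves sum_g sum_j (y - mu)^2 / (mu + alpha * mu^2) = n_genes * (m - k)
    for the common alpha, with fitted means held fixed and the residual
    degrees of freedom accounting for the k fitted parameters per gene.
    Gene-specific departures from the pooled value are handled downstream
    by quasi-dispersion moderation.
    """
    from scipy.optimize import brentq

    mu = np.maximum(mu, 1e-8)
    resid_sq = (y - mu) ** 2
    target = y.shape[0] * max(y.shape[1] - n_params, 1)

    def equation(alpha: float) -> float:
        return float(np.sum(resid_sq / (mu + alpha * mu**2))) - target

    if equation(DISPERSION_FLOOR) <= 0:  # underdispersed relative to Poisson
        return DISPERSION_FLOOR
    if equation(100.0) > 0:
        return 100.0
    return float(brentq(equation, DISPERSION_FLOOR, 100.0, xtol=1e-10))


def _invert_trigamma(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y in (0, inf))."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _squeeze_dispersion(phi: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes moderation of quasi-dispersions across genes.

    Treats each Pearson dispersion phi_g as a scaled chi^2 with ``df``
    degrees of freedom and shrinks towards a common prior (method of
    moments on log phi); returns the squeezed values and the prior
    degrees of freedom d0 added to the residual df of each gene's test.
    """
    from scipy.special import digamma, polygamma

    phi = np.maximum(np.asarray(phi, dtype=float), 1e-4)
    z = np.log(phi)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    excess_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if excess_var <= 0:
        d0 = np.inf
        phi0 = float(np.exp(np.mean(e)))
        return np.full_like(phi, phi0), d0
    d0 = 2.0 * _invert_trigamma(excess_var)
    phi0 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    squeezed = (d0 * phi0 + df * phi) / (d0 + df)
    return squeezed, float(d0)


@dataclass
class DEResult:
    """Per-gene contrast estimates: log2FC, Wald p and BH-adjusted p."""

    table: pd.DataFrame  # index gene; columns log2FC, p, p_adj, base_mean, dispersion

    def significant(self, p_adj_max: float = 0.01, lfc_min: float = 0.5) -> pd.DataFrame:
        t = self.table
        hits = t[(t["p_adj"] < p_adj_max) & (t["log2FC"].abs() > lfc_min)]
        return hits.sort_values("p_adj", kind="stable")


def fit_paired_de(
    pb: PseudobulkMatrix,
    contrast_col: str = "stratum",
    level_test: str = "persisting",
    level_ref: str = "other",
    min_total: int = 10,
) -> DEResult:
    """Paired negative-binomial differential expression on pseudobulk.

    Model per gene: log mu = offset(log s) + b0 + b1 * [level == test]
    + pair effects; Wald test on b1 with a t reference on the residual
    degrees of freedom (the moment dispersion estimate is noisy at few
    replicates, and the t reference keeps the test calibrated there).
    The contrast defaults to persisting-vs-other but any group column
    works (e.g. ``contrast_col="role"`` for donor-vs-recipient). Pairs
    lacking either level are dropped; fewer than two usable pairs is an
    error. Genes with total count below ``min_total`` are excluded.
    """
    groups = pb.groups
    keep = groups[contrast_col].isin([level_test, level_ref])
    groups = groups[keep]
    by_pair = groups.groupby("pair_id")[contrast_col].agg(set)
    usable_pairs = [p for p, s in by_pair.items() if {level_test, level_ref} <= s]
    dropped = sorted(set(by_pair.index) - set(usable_pairs))
    if dropped:
        logger.warning("dropping pair(s) without both contrast levels: %s",
                       ", ".join(dropped))
    if len(usable_pairs) < 2:
        raise UsageError(
            f"need >= 2 pairs with both contrast levels, got {len(usable_pairs)}"
        )
    groups = groups[groups["pair_id"].isin(usable_pairs)]
    counts = pb.counts[groups.index]
    counts = counts[counts.sum(axis=1) >= min_total]
    if counts.empty:
        raise UsageError("no gene passes the minimum-count filter")

    sf = size_factors_median_of_ratios(counts)
    norm = counts / sf

    contrast = (groups[contrast_col] == level_test).astype(float)
    pair_dummies = pd.get_dummies(groups["pair_id"], drop_first=True, dtype=float)
    X = np.column_stack([
        np.ones(len(groups)), contrast.to_numpy(), pair_dummies.to_numpy()
    ])
    offset = np.log(sf.to_numpy())
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise UsageError("design has no residual degrees of freedom")

    from scipy import stats as sps

    y_all = counts.to_numpy()
    n_params = X.shape[1]

    # stage 1: Poisson fits give consistent means for dispersion estimation
    mu_pois = np.empty_like(y_all, dtype=float)
    alpha_mom = np.full(counts.shape[0], np.nan)
    for i in range(counts.shape[0]):
        try:
            mu_pois[i] = sm.GLM(
                y_all[i], X, family=sm.families.Poisson(), offset=offset
            ).fit(maxiter=100, tol=1e-8).fittedvalues
        except Exception:
            mu_pois[i] = np.maximum(y_all[i].mean(), 1e-8)
        alpha_mom[i] = _dispersion_from_fit(y_all[i], mu_pois[i], n_params)

    # stage 2: pooled NB dispersion; gene-specific departures are
    # absorbed by the quasi-dispersion below
    alpha_pool = _pooled_nb_dispersion(y_all, mu_pois, n_params)

    # stage 3: per-gene NB fit at the pooled dispersion + Pearson
    # quasi-dispersion of that fit
    out = np.full((counts.shape[0], 3), np.nan)  # beta, se_raw, phi
    for i in range(counts.shape[0]):
        y = y_all[i]
        try:
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha_pool), offset=offset
            ).fit(maxiter=100, tol=1e-8)
            beta, se = fit.params[1], fit.bse[1]
            mu_hat = np.maximum(np.asarray(fit.fittedvalues), 1e-8)
            phi = float(np.sum((y - mu_hat) ** 2 / (mu_hat + alpha_pool * mu_hat**2)) / df_resid)
        except Exception:  # non-convergence on degenerate genes
            beta, se, phi = 0.0, np.inf, 1.0
        out[i] = (beta, se, phi)

    # moderate the quasi-dispersions across genes to stabilize the scale;
    # the t reference keeps the residual df as a small-sample guard for
    # the Wald statistic
    phi_sq, d0 = _squeeze_dispersion(out[:, 2], df_resid)
    se_scaled = out[:, 1] * np.sqrt(phi_sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(np.isfinite(se_scaled) & (se_scaled > 0), out[:, 0] / se_scaled, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df=df_resid)

    table = pd.DataFrame({
        "base_mean": norm.mean(axis=1),
        "log2FC": out[:, 0] / np.log(2.0),
        "se_log2FC": se_scaled / np.log(2.0),
        "p": pvals,
        "dispersion": alpha_mom,
        "pooled_dispersion": alpha_pool,
        "quasi_dispersion": phi_sq,
    }, index=counts.index)
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy())
    return DEResult(table=table)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def select_signature(
    de: DEResult, p_adj_max: float = 0.01, lfc_min: float = 0.5
) -> list[str]:
    """Genes passing adjusted p < ``p_adj_max`` and |log2FC| > ``lfc_min``.

    Ordered by adjusted p-value; an empty selection is returned with a
    warning rather than raising.
    """
    hits = de.significant(p_adj_max=p_adj_max, lfc_min=lfc_min)
    if hits.empty:
        logger.warning("no gene passes the signature thresholds")
    return hits.index.tolist()


def de_gene_union(results: list[DEResult], p_adj_max: float = 0.01,
                 lfc_min: float = 0.5) -> list[str]:
    """Union of significant genes across several contrasts.

    Mirrors the construction of a pseudobulk PCA gene set from multiple
    differential-expression comparisons (donor vs recipient, persisting
    vs other within each role); order follows the best adjusted p-value.
    """
    best: dict[str, float] = {}
    for de in results:
        for gene, row in de.significant(p_adj_max, lfc_min).iterrows():
            best[gene] = min(best.get(gene, 1.0), float(row["p_adj"]))
    return sorted(best, key=lambda g: (best[g], g))


def pseudobulk_pca(
    pb_counts: pd.DataFrame, genes: list[str], n_components: int = 2
) -> pd.DataFrame:
    """PCA coordinates of pseudobulk profiles on a gene subset.

    Log-CPM over the full table, restricted to ``genes``, per-gene
    centered/scaled; returns a group x component coordinate frame.
    """
    present = [g for g in genes if g in pb_counts.index]
    if len(present) < 2:
        raise UsageError("need at least two of the requested genes present")
    log_pb = _log_cpm(pb_counts).loc[present]
    center = log_pb.mean(axis=1)
    scale = log_pb.std(axis=1, ddof=1).replace(0, 1.0)
    Z = ((log_pb.sub(center, axis=0)).div(scale, axis=0)).to_numpy().T
    n_comp = min(n_components, Z.shape[0] - 1, Z.shape[1])
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :n_comp] * S[:n_comp]
    return pd.DataFrame(coords, index=pb_counts.columns,
                        columns=[f"PC{i + 1}" for i in range(n_comp)])


# --------------------------------------------------------------------------
# Cytotoxicity score: reference-PCA projection


def _log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    cpm = counts.div(totals.where(totals > 0, 1.0), axis=1) * 1e6
    return np.log2(cpm + 1.0)


@dataclass
class ReferenceProjection:
    """Frozen projection onto the first PC of a cytotoxicity reference.

    The loading is unit-norm; the sign is fixed so NK reference profiles
    score above naive reference profiles.
    """

    genes: list[str]
    center: np.ndarray
    scale: np.ndarray
    loading: np.ndarray
    reference_scores: pd.Series = field(repr=False, default=None)


def build_reference_projection(
    reference: pd.DataFrame, gene_list: list[str]
) -> ReferenceProjection:
    """PCA of reference profiles restricted to a cytotoxicity gene list.

    ``reference`` is a gene x profile count table whose column names
    identify the populations (used for orientation: columns containing
    "NK" anchor the positive end, columns containing "Naive" the
    negative end). At least two profiles and two thirds of ``gene_list``
    must be present.
    """
    if reference.shape[1] < 2:
        raise UsageError("reference must contain at least two profiles")
    present = [g for g in gene_list if g in reference.index]
    missing = sorted(set(gene_list) - set(present))
    if len(present) < (2 / 3) * len(gene_list):
        raise UsageError(
            "too few reference genes present; missing: " + ", ".join(missing)
        )
    if missing:
        logger.warning("reference lacks %d/%d genes: %s",
                       len(missing), len(gene_list), ", ".join(missing))

    # library normalization over the full reference table, then panel subset
    log_ref = _log_cpm(reference).loc[present]
    center = log_ref.mean(axis=1).to_numpy()
    scale = log_ref.std(axis=1, ddof=1).to_numpy()
    scale = np.where(scale > 0, scale, 1.0)
    Z = ((log_ref.to_numpy().T - center) / scale)  # profiles x genes
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loading = vt[0]
    loading = loading / np.linalg.norm(loading)
    scores = pd.Series(Z @ loading, index=reference.columns)

    nk = scores[[c for c in scores.index if "NK" in c.upper()]]
    naive = scores[[c for c in scores.index if "NAIVE" in c.upper()]]
    if len(nk) and len(naive):
        if nk.mean() < naive.mean():
            loading, scores = -loading, -scores
    else:
        logger.warning("reference lacks NK/Naive labels; orientation unverified")
    return ReferenceProjection(
        genes=present, center=center, scale=scale, loading=loading,
        reference_scores=scores,
    )


def cytotoxicity_score(query: pd.DataFrame, proj: ReferenceProjection) -> pd.Series:
    """Project query count profiles (genes x units) onto the reference PC1.

    Genes missing from the query are imputed at the reference mean, i.e.
    contribute zero after centering. A query equal to the reference mean
    profile scores 0.
    """
    present = [g for g in proj.genes if g in query.index]
    if not present:
        raise UsageError("query shares no genes with the reference projection")
    # normalize over the full query library, then subset to the panel
    log_q = _log_cpm(query).reindex(proj.genes)
    Z = np.zeros((query.shape[1], len(proj.genes)))
    pos = {g: i for i, g in enumerate(proj.genes)}
    for g in present:
        i = pos[g]
        Z[:, i] = (log_q.iloc[i].to_numpy() - proj.center[i]) / proj.scale[i]
    return pd.Series(Z @ proj.loading, index=query.columns, name="cytotoxicity")


def make_synthetic_reference(
    genes: list[str], seed: int = 0, n_replicates: int = 3, depth: float = 1e5
) -> pd.DataFrame:
    """Synthetic cytotoxicity reference panel (gene x profile counts).

    Stands in for an external sorted-population reference dataset: NK,
    CD8 and CD4 subset profiles with a graded cytotoxicity program, drawn
    as Poisson counts around population means. Columns are named
    ``<population>_<replicate>`` so the projection can orient itself.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, size=len(genes)) + 0.2
    profiles = {}
    for pop in ("NK", "CD8 TEM", "CD8 TCM", "CD8 Naive", "CD4 TEM", "CD4 TCM", "CD4 Naive"):
        level = EFFECTORNESS_LEVEL.get(pop, 0.0)
        eff = np.array([
            2.2 * level if g in CYTOTOXICITY_GENES else 0.0 for g in genes
        ])
        mu = base * np.exp2(eff)
        mu = mu / mu.sum() * depth
        for r in range(1, n_replicates + 1):
            profiles[f"{pop.replace(' ', '_')}_{r}"] = rng.poisson(mu)
    return pd.DataFrame(profiles, index=pd.Index(genes, name="gene"))


# --------------------------------------------------------------------------
# Effectorness score


def effectorness_score(
    counts: CountMatrix,
    cells: list[CellRecord],
    naive_label: str = "CD8 Naive",
    n_components: int = 10,
) -> pd.Series:
    """Rank-based pseudotime along the naive-to-effector axis of CD8 T-cells.

    Restricted to CD8 subsets: counts are log-normalized (counts per 10k,
    log1p), centered per sample as a batch proxy, and reduced by PCA; the
    score is the rank of each cell along PC1, oriented so the naive-CD8
    centroid sits at the low end, min-max scaled to [0, 1]. If no naive
    cells are present, orientation falls back to the correlation of PC1
    with mean cytotoxicity-gene expression.
    """
    cd8 = [c for c in cells if c.celltype in CD8_CELLTYPES]
    subtypes = {c.celltype for c in cd8}
    if len(subtypes) < 2:
        raise UsageError("effectorness needs >= 2 CD8 subtypes")
    sub = counts.subset_cells([c.cell_id for c in cd8])
    X = sub.matrix.toarray().astype(float).T  # cells x genes
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    X = np.log1p(X / totals * 1e4)

    sample_ids = np.array([c.sample_id for c in cd8])
    for sid in np.unique(sample_ids):
        mask = sample_ids == sid
        X[mask] -= X[mask].mean(axis=0, keepdims=True)

    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    pc1 = PCA(n_components=n_comp, svd_solver="randomized", random_state=0).fit_transform(X)[:, 0]

    is_naive = np.array([c.celltype == naive_label for c in cd8])
    if is_naive.any():
        if pc1[is_naive].mean() > pc1[~is_naive].mean():
            pc1 = -pc1
    else:
        logger.warning("no %s cells; orienting PC1 by cytotoxicity-gene correlation",
                       naive_label)
        cyto_rows = [i for i, g in enumerate(sub.genes) if g in CYTOTOXICITY_GENES]
        if not cyto_rows:
            raise UsageError("cannot orient effectorness: no naive cells and no "
                             "cytotoxicity genes present")
        cyto_mean = X[:, cyto_rows].mean(axis=1)
        if np.corrcoef(pc1, cyto_mean)[0, 1] < 0:
            pc1 = -pc1

    order = np.argsort(np.argsort(pc1, kind="stable"), kind="stable").astype(float)
    score = order / max(len(order) - 1, 1)
    return pd.Series(score, index=pd.MultiIndex.from_tuples(
        [c.cell_id for c in cd8], names=["sample_id", "barcode"]
    ), name="effectorness")


# --------------------------------------------------------------------------
# Pseudobulk clustering (descriptive layer)


def cluster_pseudobulk(
    pb_counts: pd.DataFrame, n_clusters: int = 6
) -> pd.Series:
    """Hierarchical clustering of pseudobulk profiles.

    Correlation distance on log-CPM, average linkage; returns integer
    cluster labels per group column.
    """
    log_pb = _log_cpm(pb_counts)
    corr = np.corrcoef(log_pb.to_numpy().T)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    labels = fcluster(linkage(dist, method="average"), t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=pb_counts.columns, name="cluster")
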