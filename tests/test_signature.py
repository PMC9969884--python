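"""Pseudobulk, differential expression and scoring tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrpersist.errors import UsageError
from tcrpersist.io_model import CellRecord, CountMatrix, Sample
from tcrpersist.signature import (
    DEResult,
    PseudobulkMatrix,
    benjamini_hochberg,
    build_reference_projection,
    cluster_pseudobulk,
    cytotoxicity_score,
    effectorness_score,
    fit_paired_de,
    make_synthetic_reference,
    pseudobulk_aggregate,
    select_signature,
    size_factors_median_of_ratios,
)
import scipy.sparse as sp


def _mini_counts(matrix, genes=None, samples=("S1",), cells_per_sample=None):
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    n = matrix.shape[1]
    cells_per_sample = cells_per_sample or {samples[0]: n}
    barcodes = []
    for sid in samples:
        for i in range(cells_per_sample[sid]):
            barcodes.append((sid, f"B{i}"))
    return CountMatrix(genes=genes, barcodes=barcodes, matrix=sp.csr_matrix(matrix))


def _cell(bc, sid="S1", ct="CD8 TEM"):
    return CellRecord(barcode=bc, sample_id=sid, celltype=ct,
                      l1_prediction_score=0.9, pct_mito=5.0, n_genes=500)


SAMPLES = [Sample("S1", "A", "donor", "pre")]


class TestPseudobulk:
    def test_two_cells_sum(self):
        cm = _mini_counts([[2, 3]])
        pb = pseudobulk_aggregate(cm, [_cell("B0"), _cell("B1")], SAMPLES)
        assert pb.counts.iloc[0, 0] == 5

    def test_singleton_group_equals_cell_vector(self):
        cm = _mini_counts([[4], [7]])
        pb = pseudobulk_aggregate(cm, [_cell("B0")], SAMPLES)
        assert pb.counts.iloc[:, 0].tolist() == [4, 7]

    def test_conservation_on_cohort(self, small_run):
        """Pseudobulk totals equal the summed counts of the included cells
        (exact integer conservation)."""
        run = small_run
        pb = pseudobulk_aggregate(run.cohort.counts, run.kept, run.cohort.samples)
        included = run.cohort.counts.subset_cells([c.cell_id for c in run.kept])
        assert pb.counts.to_numpy().sum() == included.matrix.sum()
        # per-group cell counts add up too
        assert pb.groups["n_cells"].sum() == len(run.kept)

    def test_strata_split_groups(self):
        cm = _mini_counts([[1, 2, 4]])
        cells = [_cell("B0"), _cell("B1"), _cell("B2")]
        strata = {("S1", "B0"): "persisting", ("S1", "B1"): "other", ("S1", "B2"): "other"}
        pb = pseudobulk_aggregate(cm, cells, SAMPLES, strata=strata)
        assert pb.counts["S1|CD8 TEM|persisting"].tolist() == [1]
        assert pb.counts["S1|CD8 TEM|other"].tolist() == [6]


class TestBenjaminiHochberg:
    @staticmethod
    def _bh_oracle(p):
        """Brute-force BH: p_adj(i) = min over j with p(j) >= p(i) of m*p(j)/rank(j)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running_min = 1.0
        for rank_from_top in range(m, 0, -1):
            idx = order[rank_from_top - 1]
            running_min = min(running_min, m * p[idx] / rank_from_top)
            adj[idx] = running_min
        return adj

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for n in (1, 2, 10, 100):
            p = rng.uniform(size=n)
            assert np.allclose(benjamini_hochberg(p), self._bh_oracle(p), atol=1e-12)

    def test_ties_and_extremes(self):
        p = np.array([0.01, 0.01, 1.0, 0.5, 0.0])
        assert np.allclose(benjamini_hochberg(p), self._bh_oracle(p), atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


def _paired_pb(counts_by_group: dict, pairs: dict) -> PseudobulkMatrix:
    meta = []
    for gid in counts_by_group:
        sid, stratum = gid.split("|")
        meta.append({"group": gid, "sample_id": sid, "celltype": "CD8 TEM",
                     "stratum": stratum, "pair_id": pairs[sid], "role": "donor",
                     "timepoint": "pre", "n_cells": 10})
    genes = [f"g{i}" for i in range(len(next(iter(counts_by_group.values()))))]
    return PseudobulkMatrix(
        counts=pd.DataFrame(counts_by_group, index=pd.Index(genes, name="gene")),
        groups=pd.DataFrame(meta).set_index("group"),
    )


class TestPairedDE:
    def test_identical_counts_give_null_result(self):
        rng = np.random.default_rng(0)
        base = rng.integers(20, 200, size=40)
        groups = {}
        for s in range(4):
            for stratum in ("persisting", "other"):
                groups[f"S{s}|{stratum}"] = base
        pb = _paired_pb(groups, {f"S{s}": f"P{s}" for s in range(4)})
        de = fit_paired_de(pb)
        assert np.allclose(de.table["log2FC"], 0.0, atol=1e-6)
        assert (de.table["p"] > 0.9).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        mu = rng.integers(50, 150, size=60).astype(float)
        groups = {}
        for s in range(4):
            for stratum in ("persisting", "other"):
                m = mu.copy()
                if stratum == "persisting":
                    m[:10] *= 4.0  # 2 log2 units
                groups[f"S{s}|{stratum}"] = rng.poisson(m)
        pb = _paired_pb(groups, {f"S{s}": f"P{s}" for s in range(4)})
        de = fit_paired_de(pb)
        hits = set(select_signature(de, p_adj_max=0.05, lfc_min=0.5))
        assert {f"g{i}" for i in range(10)} <= hits

    def test_pair_without_both_strata_dropped(self):
        rng = np.random.default_rng(2)
        base = rng.integers(20, 200, size=30)
        groups = {f"S{s}|{st}": rng.poisson(base)
                  for s in range(3) for st in ("persisting", "other")}
        groups["S3|other"] = rng.poisson(base)  # S3 lacks the persisting stratum
        pb = _paired_pb(groups, {f"S{s}": f"P{s}" for s in range(4)})
        de = fit_paired_de(pb)  # succeeds on the 3 usable pairs
        assert len(de.table) > 0

    def test_fewer_than_two_pairs_errors(self):
        rng = np.random.default_rng(3)
        base = rng.integers(20, 200, size=30)
        groups = {f"S0|{st}": rng.poisson(base) for st in ("persisting", "other")}
        pb = _paired_pb(groups, {"S0": "P0"})
        with pytest.raises(UsageError):
            fit_paired_de(pb)

    def test_size_factors_track_depth(self):
        rng = np.random.default_rng(4)
        base = rng.integers(50, 500, size=200)
        counts = pd.DataFrame({"a": base, "b": base * 3, "c": base})
        sf = size_factors_median_of_ratios(counts)
        assert sf["b"] / sf["a"] == pytest.approx(3.0, rel=1e-6)


class TestSelectSignature:
    def _de(self, rows):
        table = pd.DataFrame(rows).set_index("gene")
        table["p"] = table["p_adj"]
        return DEResult(table=table)

    def test_threshold_boundaries(self):
        de = self._de([
            {"gene": "hit", "log2FC": 0.6, "p_adj": 0.005},
            {"gene": "low_fc", "log2FC": 0.4, "p_adj": 0.005},
            {"gene": "weak_p", "log2FC": 0.8, "p_adj": 0.02},
        ])
        assert select_signature(de) == ["hit"]

    def test_ordered_by_adjusted_p(self):
        de = self._de([
            {"gene": "b", "log2FC": 1.0, "p_adj": 0.004},
            {"gene": "a", "log2FC": 1.0, "p_adj": 0.001},
        ])
        assert select_signature(de) == ["a", "b"]

    def test_empty_selection_is_empty_list(self):
        de = self._de([{"gene": "x", "log2FC": 0.1, "p_adj": 0.9}])
        assert select_signature(de) == []


class TestReferenceProjection:
    @pytest.fixture(scope="class")
    def reference(self):
        genes = [f"g{i}" for i in range(40)]
        return make_synthetic_reference(
            ["NKG7", "GZMB", "PRF1", "GNLY"] + genes, seed=3
        )

    def test_projection_reproduces_reference_coordinates(self, reference):
        proj = build_reference_projection(reference, ["NKG7", "GZMB", "PRF1", "GNLY"])
        scores = cytotoxicity_score(reference, proj)
        assert np.allclose(scores.to_numpy(), proj.reference_scores.to_numpy(), atol=1e-9)

    def test_nk_scores_above_naive(self, reference):
        proj = build_reference_projection(reference, ["NKG7", "GZMB", "PRF1", "GNLY"])
        s = proj.reference_scores
        nk = s[[c for c in s.index if c.startswith("NK")]].mean()
        naive = s[[c for c in s.index if "Naive" in c]].mean()
        assert nk > naive

    def test_loading_is_unit_norm(self, reference):
        proj = build_reference_projection(reference, ["NKG7", "GZMB", "PRF1", "GNLY"])
        assert np.linalg.norm(proj.loading) == pytest.approx(1.0)

    def test_too_few_shared_genes_errors(self, reference):
        with pytest.raises(UsageError, match="MISSING1"):
            build_reference_projection(
                reference, ["NKG7", "MISSING1", "MISSING2", "MISSING3"]
            )

    def test_recovers_planted_factor_direction(self):
        """One-factor reference data: PC1 loadings align with the loadings a
        noise-free evaluation of the same generative model produces
        (|cosine| >= 0.95 despite Poisson sampling noise)."""
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(30)]
        direction = rng.normal(size=30)
        direction /= np.linalg.norm(direction)
        z_draws = rng.normal(scale=3.0, size=12)
        profiles = {
            f"ref{j}": rng.poisson(np.exp2(10.0 + z * direction))
            for j, z in enumerate(z_draws)
        }
        ref = pd.DataFrame(profiles, index=genes)
        proj = build_reference_projection(ref, genes)

        # independent oracle: exact expected counts, no sampling noise
        exact = pd.DataFrame(
            {f"ref{j}": np.exp2(10.0 + z * direction) for j, z in enumerate(z_draws)},
            index=genes,
        )
        oracle = build_reference_projection(exact, genes)
        cos = abs(np.dot(proj.loading, oracle.loading))
        assert cos >= 0.95

    def test_query_at_reference_mean_scores_zero(self, reference):
        proj = build_reference_projection(reference, ["NKG7", "GZMB", "PRF1", "GNLY"])
        # build a query whose full-library log2-CPM equals the reference
        # center on every panel gene
        cpm = np.zeros(len(reference.index))
        pos = {g: i for i, g in enumerate(reference.index)}
        for g, c in zip(proj.genes, proj.center):
            cpm[pos[g]] = np.exp2(c) - 1.0
        remainder = 1e6 - cpm.sum()
        query = pd.DataFrame({"q": cpm}, index=reference.index)
        query.loc["filler"] = remainder
        score = cytotoxicity_score(query, build_reference_projection(
            pd.concat([reference, pd.DataFrame(
                {c: [0] for c in reference.columns}, index=["filler"])]),
            ["NKG7", "GZMB", "PRF1", "GNLY"]))
        assert abs(score["q"]) < 1e-6


class TestEffectorness:
    def test_scores_bounded_and_ordered(self, small_run):
        run = small_run
        eff = effectorness_score(run.cohort.counts, run.kept)
        assert eff.between(0.0, 1.0).all()
        ct_of = {c.cell_id: c.celltype for c in run.kept}
        by_ct = eff.groupby(lambda cid: ct_of[cid]).median()
        assert by_ct["CD8 Naive"] < by_ct["CD8 TCM"] < by_ct["CD8 TEM"]

    def test_requires_multiple_subtypes(self):
        cm = _mini_counts(np.ones((5, 3), dtype=int))
        cells = [_cell(f"B{i}") for i in range(3)]
        with pytest.raises(UsageError):
            effectorness_score(cm, cells)


class TestGeneUnionPca:
    def _two_contrast_pb(self):
        rng = np.random.default_rng(21)
        mu = rng.integers(40, 200, size=80).astype(float)
        cols, meta = {}, []
        for s in range(4):
            role = "donor" if s < 2 else "recipient"
            for stratum in ("persisting", "other"):
                m = mu.copy()
                # the donor-recipient axis dominates, as in the study
                if role == "recipient":
                    m[:20] *= 4.0
                if stratum == "persisting":
                    m[20:30] *= 2.5
                gid = f"S{s}|{stratum}"
                cols[gid] = rng.poisson(m)
                meta.append({"group": gid, "sample_id": f"S{s}", "celltype": "CD8 TEM",
                             "stratum": stratum, "pair_id": f"P{s % 2}", "role": role,
                             "timepoint": "pre", "n_cells": 10})
        genes = [f"g{i}" for i in range(80)]
        return PseudobulkMatrix(
            counts=pd.DataFrame(cols, index=pd.Index(genes, name="gene")),
            groups=pd.DataFrame(meta).set_index("group"),
        )

    def test_role_contrast_and_union(self):
        from tcrpersist.signature import de_gene_union, pseudobulk_pca

        pb = self._two_contrast_pb()
        de_role = fit_paired_de(pb, contrast_col="role", level_test="recipient",
                                level_ref="donor")
        de_stratum = fit_paired_de(pb)
        union = de_gene_union([de_role, de_stratum], p_adj_max=0.05)
        assert {f"g{i}" for i in range(30)} <= set(union)
        coords = pseudobulk_pca(pb.counts, union)
        # the dominant axis separates donors from recipients
        donors = coords.loc[[g for g in coords.index if g.startswith(("S0", "S1"))], "PC1"]
        recipients = coords.loc[[g for g in coords.index if g.startswith(("S2", "S3"))], "PC1"]
        assert min(donors.min(), recipients.min()) != max(donors.max(), recipients.max())
        assert (donors.max() < recipients.min()) or (recipients.max() < donors.min())


def test_cluster_pseudobulk_separates_profiles():
    rng = np.random.default_rng(5)
    a = rng.poisson(100, size=50)
    b = rng.poisson(100, size=50)
    cols = {f"a{i}": rng.poisson(np.maximum(a, 1)) for i in range(3)}
    cols |= {f"b{i}": rng.poisson(np.maximum(b, 1)) for i in range(3)}
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
    labels = cluster_pseudobulk(counts, n_clusters=2)
    assert labels[["a0", "a1", "a2"]].nunique() == 1
    assert labels[["b0", "b1", "b2"]].nunique() == 1
    assert labels["a0"] != labels["b0"]
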