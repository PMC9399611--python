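"""NMF factorization, consensus clustering, rank selection, naming, and
pseudo-bulk aggregation."""

import numpy as np
import pandas as pd
import pytest

from tmephenotype.infiltration import InfiltrationMatrix
from tmephenotype.subtyping import (
    PseudoBulkMatrix,
    SubtypingResult,
    assign_and_name,
    consensus_cluster,
    consensus_from_assignments,
    cophenetic_coefficient,
    nmf_factorize,
    posneg_fold,
    pseudobulk_aggregate,
    select_rank,
)


class TestNmf:
    def test_exact_rank_one_recovery(self, rng):
        u = rng.random(15) + 0.5
        v = rng.random(20) + 0.5
        X = np.outer(u, v)
        run = nmf_factorize(X, 1, seed=0, max_iter=2000, tol=1e-12)
        assert run.objective_trace[-1] < 1e-6

    def test_objective_non_increasing(self, rng):
        X = rng.random((20, 30))
        run = nmf_factorize(X, 4, seed=1, max_iter=500, tol=0.0)
        trace = np.array(run.objective_trace)
        assert (np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1.0)).all()

    def test_frobenius_objective_non_increasing(self, rng):
        X = rng.random((15, 25))
        run = nmf_factorize(X, 3, seed=2, objective="frobenius", tol=0.0, max_iter=300)
        trace = np.array(run.objective_trace)
        assert (np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1.0)).all()

    def test_factors_non_negative_and_deterministic(self, rng):
        X = rng.random((10, 12))
        a = nmf_factorize(X, 3, seed=5)
        b = nmf_factorize(X, 3, seed=5)
        assert (a.W >= 0).all() and (a.H >= 0).all()
        np.testing.assert_array_equal(a.H, b.H)

    def test_block_structure_recovered_across_seeds(self, rng):
        B1 = rng.random((10, 12)) + 1.0
        B2 = rng.random((8, 15)) + 1.0
        X = np.zeros((18, 27))
        X[:10, :12] = B1
        X[10:, 12:] = B2
        X += 1e-6  # avoid all-zero columns
        truth = np.array([0] * 12 + [1] * 15)
        hits = 0
        for seed in range(20):
            a = nmf_factorize(X, 2, seed=seed).assignments()
            agree = max((a == truth).mean(), (a == 1 - truth).mean())
            hits += agree == 1.0
        assert hits >= 19  # >= 95% of 20 seeds

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            nmf_factorize(np.array([[-1.0, 2.0], [1.0, 1.0]]), 1)
        with pytest.raises(ValueError, match="all-zero column"):
            nmf_factorize(np.array([[1.0, 0.0], [2.0, 0.0]]), 1)
        with pytest.raises(ValueError, match="rank"):
            nmf_factorize(rng.random((4, 6)), 4)


class TestPosnegFold:
    def test_definition(self):
        out = posneg_fold(np.array([[-1.0, 0.0, 2.0]]))
        np.testing.assert_array_equal(out, [[0.0, 0.0, 2.0], [1.0, 0.0, 0.0]])

    def test_non_negative_input_identity_branch(self, rng):
        Z = rng.random((4, 5))
        out = posneg_fold(Z)
        np.testing.assert_array_equal(out[:4], Z)
        assert (out[4:] == 0).all()

    def test_pos_plus_neg_is_abs(self, rng):
        Z = rng.normal(size=(6, 7))
        out = posneg_fold(Z)
        np.testing.assert_allclose(out[:6] + out[6:], np.abs(Z))

    def test_dataframe_preserves_columns(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["r"], columns=["a", "b"])
        out = posneg_fold(df)
        assert list(out.index) == ["r+", "r-"]
        assert list(out.columns) == ["a", "b"]


class TestConsensus:
    def test_co_assignment_counting(self):
        together = [np.array([0, 0, 1])] * 15 + [np.array([0, 1, 1])] * 15
        C = consensus_from_assignments(together)
        assert C[0, 1] == pytest.approx(0.5)
        assert C[0, 0] == 1.0

    def test_permutation_equivariance(self, rng):
        assignments = [rng.integers(0, 3, 12) for _ in range(10)]
        C = consensus_from_assignments(assignments)
        perm = rng.permutation(12)
        C_perm = consensus_from_assignments([a[perm] for a in assignments])
        np.testing.assert_array_equal(C[np.ix_(perm, perm)], C_perm)

    def test_perfect_consensus_block_structure_and_unit_cophenetic(self, rng):
        # well-separated blocks: every restart recovers the same partition
        X = np.vstack([
            np.hstack([rng.random((5, 10)) + 5.0, rng.random((5, 12)) + 0.01]),
            np.hstack([rng.random((5, 10)) + 0.01, rng.random((5, 12)) + 5.0]),
        ])
        res = consensus_cluster(X, ranks=(2,), n_runs=8, seed=0, subsample=None)
        C = res.consensus[2].to_numpy()
        assert set(np.unique(C)) <= {0.0, 1.0}
        np.testing.assert_array_equal(np.diag(C), 1.0)
        np.testing.assert_allclose(C, C.T)
        assert res.cophenetic[2] == pytest.approx(1.0)

    def test_consensus_matrix_contract_under_subsampling(self, rng):
        X = rng.random((8, 30)) + 0.1
        res = consensus_cluster(X, ranks=(2, 3), n_runs=10, seed=3, subsample=0.8)
        for k, C in res.consensus.items():
            arr = C.to_numpy()
            np.testing.assert_allclose(arr, arr.T)
            np.testing.assert_array_equal(np.diag(arr), 1.0)
            assert arr.min() >= 0.0 and arr.max() <= 1.0
            assert -1.0 <= res.cophenetic[k] <= 1.0

    def test_planted_rank_orders_cophenetic(self, rng):
        # 60 samples from 3 archetypes: consensus at the true rank is more
        # stable than at a clearly over-fitted one
        archetypes = rng.random((10, 3)) * 3.0
        labels = rng.integers(0, 3, 60)
        X = archetypes[:, labels] + rng.normal(0, 0.6, (10, 60))
        folded = posneg_fold(X - X.mean(axis=1, keepdims=True))
        res = consensus_cluster(folded, ranks=(3, 4, 5), n_runs=15, seed=1)
        assert res.cophenetic[3] > res.cophenetic[5]

    def test_deterministic_given_seed(self, rng):
        X = rng.random((6, 20)) + 0.1
        a = consensus_cluster(X, ranks=(2, 3), n_runs=6, seed=9)
        b = consensus_cluster(X, ranks=(2, 3), n_runs=6, seed=9)
        for k in (2, 3):
            pd.testing.assert_frame_equal(a.consensus[k], b.consensus[k])
            assert a.cophenetic[k] == b.cophenetic[k]


class TestSelectRank:
    @pytest.mark.parametrize(
        "rho, expected",
        [
            ({2: 0.995, 3: 0.990, 4: 0.900, 5: 0.895, 6: 0.890}, 3),
            ({2: 0.5, 3: 0.6, 4: 0.7, 5: 0.8}, 2),  # increasing: first pair wins
            ({2: 1.0, 3: 0.9, 4: 0.9, 5: 0.8, 6: 0.8}, 2),  # tie at 2 and 4 -> 2
            ({3: 0.9, 4: 0.85, 5: 0.6}, 4),
        ],
    )
    def test_drop_rule(self, rho, expected):
        assert select_rank(rho) == expected

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            select_rank({3: 0.9})


def _named_result(act_means, stro_means, n_per=4):
    """Build a SubtypingResult + InfiltrationMatrix with 3 clusters whose
    activated-adaptive / stromal aggregates have the given cluster means."""
    n = 3 * n_per
    samples = [f"s{i}" for i in range(n)]
    labels = np.repeat([0, 1, 2], n_per)
    act_cells = ["Activated CD4 T cell", "Activated CD8 T cell", "Activated B cell",
                 "Effector memory CD4 T cell", "Effector memory CD8 T cell"]
    stro_cells = ["Fibroblast", "Endothelial cell"]
    rows = {}
    for c in act_cells:
        rows[c] = np.array(act_means)[labels].astype(float)
    for c in stro_cells:
        rows[c] = np.array(stro_means)[labels].astype(float)
    im = InfiltrationMatrix(pd.DataFrame(rows, index=samples).T,
                            normalized=True, stages=("minmax", "zscore"))
    H = np.zeros((3, n))
    H[labels, np.arange(n)] = 1.0
    from tmephenotype.subtyping import NMFRun

    run = NMFRun(W=np.eye(3), H=H, objective_trace=[1.0], seed=0, converged=True)
    C = pd.DataFrame(np.eye(n), index=samples, columns=samples)
    return SubtypingResult(
        consensus={3: C}, cophenetic={3: 1.0}, ranks=[3],
        best_runs={3: run}, selected_rank=3,
    ), im


class TestAssignAndName:
    def test_three_cluster_naming_rule(self):
        res, im = _named_result(act_means=(1.2, -0.8, 0.1), stro_means=(-0.5, -0.9, 1.4))
        out = assign_and_name(res, im)
        assert out.cluster_names == {
            1: "immune-active", 2: "immune-desert", 3: "stroma-rich"
        }

    def test_non_three_rank_gets_generic_names(self, rng):
        X = rng.random((6, 16)) + 0.1
        res = consensus_cluster(X, ranks=(2,), n_runs=5, seed=0)
        res.selected_rank = 2
        im = InfiltrationMatrix(pd.DataFrame(
            rng.random((3, 16)),
            index=["Activated CD4 T cell", "Fibroblast", "x"],
            columns=res.consensus[2].index,
        ))
        out = assign_and_name(res, im)
        assert set(out.phenotypes.unique()) <= {"cluster-1", "cluster-2"}

    def test_conflicting_top_cluster_resolved_by_margin(self):
        # cluster 1 tops both aggregates; activated margin is larger
        res, im = _named_result(act_means=(2.0, -1.0, 0.0), stro_means=(1.5, -0.5, 1.0))
        out = assign_and_name(res, im)
        assert out.cluster_names[1] == "immune-active"
        assert out.cluster_names[3] == "stroma-rich"

    def test_synthetic_cohort_names_match_planted(self, small_cohort):
        from tmephenotype import phenotype_pipeline

        im, res = phenotype_pipeline(
            small_cohort.expression, small_cohort.signatures,
            ranks=(2, 3, 4), n_runs=10, seed=5,
        )
        res3 = assign_and_name(res, im, rank=3)
        acc = (res3.phenotypes == small_cohort.truth.phenotype).mean()
        assert acc >= 0.9


class TestPseudoBulk:
    def _counts(self):
        counts = pd.DataFrame(
            {"c1": [2, 0, 0], "c2": [3, 0, 49], "c3": [5, 50, 0]},
            index=["g_sum", "g_kept", "g_dropped"],
        )
        meta = pd.DataFrame({"cell_id": ["c1", "c2", "c3"],
                             "sample_id": ["sa", "sa", "sa"]})
        return counts, meta

    def test_summation_and_read_filter(self):
        counts, meta = self._counts()
        unfiltered = pseudobulk_aggregate(counts, meta, min_total_reads=0)
        assert unfiltered.values.loc["g_sum", "sa"] == 10
        pb = pseudobulk_aggregate(counts, meta, min_total_reads=50)
        assert "g_kept" in pb.values.index  # exactly 50 reads: retained
        assert "g_dropped" not in pb.values.index  # 49 reads: dropped

    def test_group_split_associativity(self, rng):
        counts = pd.DataFrame(rng.integers(0, 20, (15, 8)),
                              index=[f"g{i}" for i in range(15)],
                              columns=[f"c{i}" for i in range(8)])
        meta = pd.DataFrame({"cell_id": counts.columns,
                             "sample_id": ["x"] * 8})
        whole = pseudobulk_aggregate(counts, meta, min_total_reads=0).values["x"]
        part1 = counts.iloc[:, :3].sum(axis=1)
        part2 = counts.iloc[:, 3:].sum(axis=1)
        pd.testing.assert_series_equal(whole, part1 + part2, check_names=False)

    def test_unknown_cell_and_non_integer_rejected(self):
        counts, meta = self._counts()
        with pytest.raises(ValueError, match="c3"):
            pseudobulk_aggregate(counts, meta.iloc[:2], min_total_reads=0)
        bad = counts.astype(float)
        bad.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="integer"):
            pseudobulk_aggregate(bad, meta, min_total_reads=0)

    def test_mean_expression_feeds_log_cpm(self):
        counts, meta = self._counts()
        pb = pseudobulk_aggregate(counts, meta, min_total_reads=0)
        from tmephenotype.io_preprocess import log_cpm_transform

        m = log_cpm_transform(pb.mean_expression())
        assert m.log_scale
        assert m.shape == (3, 1)


def test_cophenetic_coefficient_matches_scipy_reference(rng):
    """Independent re-derivation: correlation between consensus
    dissimilarities and tree distances computed directly."""
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import squareform

    C = rng.random((10, 10))
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    mine = cophenetic_coefficient(C)
    cond = squareform(1 - C, checks=False)
    coph_d = cophenet(average(cond))
    expected = np.corrcoef(cond, coph_d)[0, 1]
    assert mine == pytest.approx(expected, abs=1e-12)
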