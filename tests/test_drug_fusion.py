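"""Collective tri-factorization: assembly, optimization and prediction."""

import numpy as np
import pytest
from scipy.optimize import nnls
from sklearn.metrics import roc_auc_score

from netrepurpose.drug_fusion import (
    assemble_system,
    default_rank,
    factorize,
    merge_candidates,
    predict_associations,
    read_labeled_matrix,
    reconstruct_relation,
    write_labeled_matrix,
)
from netrepurpose.synthetic_fixtures import FusionSpec, gen_fusion


def labels(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


def small_relation(seed=0, shape=(12, 9), rank=2):
    rng = np.random.default_rng(seed)
    g1 = rng.uniform(0.1, 1.0, (shape[0], rank))
    g2 = rng.uniform(0.1, 1.0, (shape[1], rank))
    s = np.diag(rng.uniform(0.5, 1.5, rank))
    return g1 @ s @ g2.T


class TestAssembleSystem:
    def test_shapes_and_ranks_validated(self):
        R = small_relation()
        sys_ = assemble_system({(2, 3): (R, labels("d", 12), labels("p", 9))},
                               ranks={2: 2, 3: 2})
        assert sys_.sizes == {2: 12, 3: 9}
        assert sys_.relations[(2, 3)].shape == (12, 9)

    def test_negative_entries_rejected(self):
        R = small_relation()
        R[0, 0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            assemble_system({(2, 3): (R, labels("d", 12), labels("p", 9))})

    def test_label_mismatch_resolved_by_intersection(self):
        R = small_relation()
        theta = np.eye(10)  # only 10 of the 12 drug labels
        sys_ = assemble_system(
            {(2, 3): (R, labels("d", 12), labels("p", 9))},
            constraints={2: [(theta, labels("d", 10))]},
            ranks={2: 2, 3: 2},
        )
        assert sys_.sizes[2] == 10
        assert sys_.relations[(2, 3)].shape == (10, 9)

    def test_asymmetric_constraint_rejected(self):
        R = small_relation()
        theta = np.triu(np.ones((12, 12)))
        with pytest.raises(ValueError, match="symmetric"):
            assemble_system({(2, 3): (R, labels("d", 12), labels("p", 9))},
                            constraints={2: [(theta, labels("d", 12))]})

    def test_rank_must_be_below_size(self):
        R = small_relation()
        with pytest.raises(ValueError, match="rank"):
            assemble_system({(2, 3): (R, labels("d", 12), labels("p", 9))},
                            ranks={2: 12, 3: 2})

    def test_default_rank_scaling(self):
        assert default_rank(100) == 5
        assert default_rank(2) == 1


class TestFactorize:
    def test_planted_rank_one_recovery(self):
        rng = np.random.default_rng(3)
        R = rng.uniform(0.2, 1.0, (20, 1)) @ rng.uniform(0.2, 1.0, (1, 15)) * 2
        sys_ = assemble_system({(1, 2): (R, labels("a", 20), labels("b", 15))},
                               ranks={1: 1, 2: 1})
        fac = factorize(sys_, max_iter=300, tol=1e-10, seed=1)
        R_in = sys_.relations[(1, 2)]
        resid = np.linalg.norm(R_in - reconstruct_relation(fac, sys_, 1, 2),
                               "fro") / np.linalg.norm(R_in, "fro")
        assert resid < 1e-3

    def test_objective_trace_monotone_with_constraints(self):
        fx = gen_fusion(FusionSpec(sizes={1: 20, 2: 25, 3: 30}), seed=4)
        sys_ = assemble_system(fx["relations"], fx["constraints"])
        fac = factorize(sys_, max_iter=150, tol=1e-8, seed=2)
        tr = fac.objective_trace
        assert all(tr[i + 1] <= tr[i] * (1 + 1e-9) for i in range(len(tr) - 1))

    def test_factors_stay_non_negative(self):
        fx = gen_fusion(FusionSpec(sizes={1: 15, 2: 20, 3: 25}), seed=5)
        sys_ = assemble_system(fx["relations"], fx["constraints"])
        fac = factorize(sys_, max_iter=80, seed=3)
        assert all((fac.G[i] >= 0).all() for i in fac.G)

    def test_unconstrained_matches_nnls_oracle_objective(self):
        """Without Θ the fit should be no worse than a direct alternating
        non-negative least-squares oracle on the same relation (within 1%)."""
        rng = np.random.default_rng(9)
        R = small_relation(seed=9, shape=(15, 12), rank=2)
        sys_ = assemble_system({(1, 2): (R, labels("a", 15), labels("b", 12))},
                               ranks={1: 2, 2: 2})
        R_in = sys_.relations[(1, 2)]
        fac = factorize(sys_, max_iter=500, tol=1e-12, seed=0)

        # oracle: alternating NNLS on R ≈ A Bᵀ at the same total rank
        A = rng.uniform(0.1, 1.0, (15, 2))
        B = rng.uniform(0.1, 1.0, (12, 2))
        for _ in range(200):
            B = np.vstack([nnls(A, R_in[:, j])[0] for j in range(12)])
            A = np.vstack([nnls(B, R_in[i, :])[0] for i in range(15)])
        oracle_obj = np.linalg.norm(R_in - A @ B.T, "fro") ** 2
        scale = np.linalg.norm(R_in, "fro") ** 2
        assert fac.objective_trace[-1] - oracle_obj <= 0.01 * scale


class TestPrediction:
    def test_exact_rank_input_reconstructs_losslessly(self):
        R = small_relation(seed=2, shape=(14, 10), rank=2)
        sys_ = assemble_system({(1, 2): (R, labels("a", 14), labels("b", 10))},
                               ranks={1: 2, 2: 2})
        fac = factorize(sys_, max_iter=600, tol=1e-13, seed=4, n_restarts=5)
        R_in = sys_.relations[(1, 2)]
        assert np.allclose(reconstruct_relation(fac, sys_, 1, 2), R_in,
                           atol=1e-3)

    def test_unknown_pair_rejected(self):
        R = small_relation()
        sys_ = assemble_system({(2, 3): (R, labels("d", 12), labels("p", 9))},
                               ranks={2: 2, 3: 2})
        fac = factorize(sys_, max_iter=10, seed=0)
        with pytest.raises(ValueError):
            reconstruct_relation(fac, sys_, 1, 2)

    def test_masked_entries_score_above_random_zeros(self):
        fx = gen_fusion(FusionSpec(sizes={1: 30, 2: 40, 3: 50},
                                   density=0.08, n_masked=15), seed=6)
        sys_ = assemble_system(fx["relations"], fx["constraints"])
        fac = factorize(sys_, max_iter=150, seed=1)
        R_hat = reconstruct_relation(fac, sys_, 2, 3)
        R = sys_.relations[(2, 3)]
        lab2, lab3 = sys_.labels[2], sys_.labels[3]
        masked = {(lab2.index(d), lab3.index(p)) for d, p in fx["masked"]}
        zeros = [(r, c) for r, c in zip(*np.where(R == 0))
                 if (r, c) not in masked]
        rng = np.random.default_rng(0)
        neg = [zeros[i] for i in rng.choice(len(zeros), 200, replace=False)]
        y = [1] * len(masked) + [0] * len(neg)
        s = [R_hat[r, c] for r, c in list(masked) + neg]
        assert roc_auc_score(y, s) > 0.8

    def test_planted_hidden_association_ranks_high(self):
        """A held-out entry of a coherent drug block beats the per-column
        threshold and tops the prediction list.

        Five hub drugs share all six proteins; the hidden entry
        (hub0, q) is zeroed while two singleton drugs supply weak known
        entries in column q, dragging its threshold below the hub
        block's reconstruction level.
        """
        drugs = [f"hub{i}" for i in range(5)] + ["solo0", "solo1"]
        prots = [f"p{i}" for i in range(5)] + ["q"]
        R = np.zeros((7, 6))
        R[:5, :5] = 1.0          # hub block
        R[1:5, 5] = 1.0          # hubs 1-4 known in column q
        R[5, 5] = R[6, 5] = 1.0  # singleton drugs only in column q
        # hidden truth: (hub0, q) = 1, presented as 0
        sys_ = assemble_system({(2, 3): (R, drugs, prots)}, ranks={2: 1, 3: 1})
        fac = factorize(sys_, max_iter=300, tol=1e-12, seed=2)
        preds = predict_associations(fac, sys_)
        assert preds, "no candidate cleared the per-column threshold"
        top5 = {(d, t) for d, t, _, _ in preds[:5]}
        assert ("hub0", "q") in top5

    def test_all_known_yields_no_predictions(self):
        R = np.ones((6, 5))
        sys_ = assemble_system({(2, 3): (R, labels("d", 6), labels("p", 5))},
                               ranks={2: 1, 3: 1})
        fac = factorize(sys_, max_iter=100, seed=0)
        assert predict_associations(fac, sys_) == []

    def test_label_permutation_equivariance(self):
        """Permuting object labels permutes predictions identically."""
        fx = gen_fusion(FusionSpec(sizes={1: 12, 2: 15, 3: 18}, n_masked=3),
                        seed=10)
        sys_ = assemble_system(fx["relations"], fx["constraints"])
        fac = factorize(sys_, max_iter=80, seed=5)
        preds = predict_associations(fac, sys_)

        # rename drugs with a prefix that reverses the sort order
        mapping = {lab: f"z{lab}" for lab in fx["labels"][2]}
        relations = {}
        for (i, j), (mat, rows, cols) in fx["relations"].items():
            rows = [mapping.get(r, r) for r in rows] if i == 2 else rows
            cols = [mapping.get(c, c) for c in cols] if j == 2 else cols
            relations[(i, j)] = (mat, rows, cols)
        constraints = {
            i: [(m, [mapping.get(x, x) for x in labs] if i == 2 else labs)]
            for i, [(m, labs)] in fx["constraints"].items()
        }
        sys_p = assemble_system(relations, constraints)
        fac_p = factorize(sys_p, max_iter=80, seed=5)
        preds_p = predict_associations(fac_p, sys_p)
        assert {(mapping[d], t) for d, t, _, _ in preds} == {
            (d, t) for d, t, _, _ in preds_p}


class TestMergeAndIO:
    def test_merge_tags_and_dedups(self):
        rows = merge_candidates({"MAP2K2": ["Bosutinib"]},
                                {"MAP2K2": ["Mercaptopurine", "Bosutinib"]})
        (row,) = rows
        assert row["known_drugs"] == ["Bosutinib"]
        assert row["predicted_drugs"] == ["Mercaptopurine"]

    def test_empty_target_gets_no_drugs_row(self):
        (row,) = merge_candidates({}, {}, targets=["ORPHAN"])
        assert row["status"] == "No drugs"

    def test_matrix_market_round_trip(self, tmp_path):
        R = small_relation(seed=1, shape=(7, 5))
        write_labeled_matrix(R, tmp_path / "R.mtx", labels("r", 7),
                             labels("c", 5))
        back, rows, cols = read_labeled_matrix(tmp_path / "R.mtx")
        assert np.allclose(back, R, atol=1e-9)
        assert rows == labels("r", 7) and cols == labels("c", 5)
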