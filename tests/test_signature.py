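"""ΔCt arithmetic, paired testing, ROC/AUC, logistic fit, CV, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from p53lnc.signature import (
    CohortTable,
    cluster_samples,
    crossval_signature,
    delta_ct,
    fit_logistic,
    fold_change,
    marker_statistics,
    paired_differential,
    roc_auc,
    select_signature,
)
from p53lnc.simulate import SimulationConfig, simulate_cohort


def concordance_oracle(scores, labels):
    """Tie-corrected all-pairs concordance statistic."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestDeltaCt:
    def test_subtraction_rule(self):
        assert delta_ct(30.0, 20.0) == 10.0

    def test_equal_cts_give_zero(self):
        assert delta_ct(21.5, 21.5) == 0.0

    def test_missing_ct_stays_flagged_not_zero(self):
        out = delta_ct([30.0, np.nan], [20.0, 20.0])
        assert out[0] == 10.0 and np.isnan(out[1])

    def test_delta_delta_ct_fold_change_identity(self):
        # ΔΔCt = −1 → fold change 2
        assert fold_change(9.0, 10.0) == pytest.approx(2.0)


class TestPairedTest:
    def test_identical_tissues_give_zero_and_p_one(self):
        x = np.arange(10, dtype=float)
        mean, p = paired_differential(x, x)
        assert mean == 0.0 and p == 1.0

    def test_constant_nonzero_difference_reported_at_floor(self):
        x = np.arange(10, dtype=float)
        mean, p = paired_differential(x + 2.0, x)
        assert mean == 2.0 and 0 < p < 1e-300

    def test_matches_scipy_on_random_pairs(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            mean, p = paired_differential(a, b)
            assert p == pytest.approx(float(stats.ttest_rel(a, b).pvalue))

    def test_requires_two_complete_pairs(self):
        with pytest.raises(ValueError):
            paired_differential([1.0], [2.0])


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_identical_scores_give_half(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_worked_example_three_of_four_pairs_concordant(self):
        # positives score {2, 4}, negatives {1, 3}: 3 of 4 pairs concordant
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_auc_equals_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            r = roc_auc(scores, labels)
            assert abs(r.auc - concordance_oracle(scores, labels)) < 1e-12
            assert r.fpr[0] == 0 and r.tpr[0] == 0
            assert r.fpr[-1] == 1 and r.tpr[-1] == 1

    def test_negating_scores_complements_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        assert roc_auc(-scores, labels).auc == pytest.approx(
            1 - roc_auc(scores, labels).auc, abs=1e-12
        )


class TestSelect:
    def test_strictly_greater_selection(self):
        aucs = {"m1": 0.9, "m2": 0.65, "m3": 0.72}
        assert select_signature(aucs, cutoff=0.7) == ["m1", "m3"]

    def test_exactly_at_cutoff_excluded(self):
        assert select_signature({"m": 0.70}, cutoff=0.7) == []

    def test_empty_selection_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_signature({"m": 0.6}, cutoff=0.7) == []
        assert "cutoff" in caplog.text


def nll_and_grad(beta, x, y):
    design = np.c_[np.ones(len(x)), x]
    eta = design @ beta
    mu = special.expit(eta)
    nll = -np.sum(y * np.log(mu + 1e-320) + (1 - y) * np.log(1 - mu + 1e-320))
    grad = design.T @ (mu - y)
    return nll, grad


class TestLogistic:
    def test_zero_variance_feature_gets_zero_weight_and_logit_intercept(self):
        y = np.r_[np.ones(30), np.zeros(10)]
        x = np.full((40, 1), 3.7)
        m = fit_logistic(x, y)
        # any (w, b) with 3.7w + b = logit(0.75) is an MLE; IRLS from zero
        # keeps the linear predictor at the class log-odds
        assert m.coef[0] * 3.7 + m.intercept == pytest.approx(np.log(3.0), abs=1e-6)

    def test_perfectly_separable_data_raises_flag(self):
        x = np.r_[np.full(20, -1.0), np.full(20, 1.0)].reshape(-1, 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        m = fit_logistic(x, y)
        assert m.separation and not m.converged

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))

    def test_matches_direct_newton_maximization(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n, p = 200, 2
            x = rng.normal(size=(n, p))
            beta_true = rng.uniform(-1, 1, p + 1)
            probs = special.expit(np.c_[np.ones(n), x] @ beta_true)
            y = (rng.uniform(size=n) < probs).astype(float)
            if y.min() == y.max():
                continue
            m = fit_logistic(x, y)
            res = optimize.minimize(
                nll_and_grad, np.zeros(p + 1), args=(x, y), jac=True,
                method="BFGS", options={"gtol": 1e-12, "maxiter": 500},
            )
            assert np.allclose(np.r_[m.intercept, m.coef], res.x, atol=1e-6)


def cohort_from_arrays(tumour, normal, markers=None):
    n, m = tumour.shape
    markers = markers or [f"g{j}" for j in range(m)]
    idx = pd.MultiIndex.from_product(
        [[f"P{i:03d}" for i in range(n)], ["tumour", "normal"]],
        names=["patient", "tissue"],
    )
    data = np.empty((2 * n, m))
    data[0::2] = tumour
    data[1::2] = normal
    return CohortTable(pd.DataFrame(data, index=idx, columns=markers))


class TestCohortAndCv:
    def test_paired_design_enforced(self):
        idx = pd.MultiIndex.from_tuples(
            [("P1", "tumour"), ("P1", "normal"), ("P2", "tumour")],
            names=["patient", "tissue"],
        )
        with pytest.raises(ValueError, match="paired"):
            CohortTable(pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=idx))

    def test_ct_table_round_trip_through_reader(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_patients=12)
        table, truth = simulate_cohort(cfg)
        path = tmp_path / "ct.tsv"
        table.to_csv(path, sep="\t", index=False)
        from p53lnc.signature import read_ct_table

        cohort = read_ct_table(path)
        assert len(cohort.patients) == 12
        assert cohort.markers == list(truth.markers["marker"])
        # ΔCt reconstructed from raw Ct pairs
        row = table.iloc[0]
        assert cohort.delta_ct.loc[(row.patient, row.tissue), row.marker] == (
            pytest.approx(row.ct - row.reference_ct)
        )

    def test_folds_partition_patients_and_are_deterministic(self):
        rng = np.random.default_rng(6)
        cohort = cohort_from_arrays(
            rng.normal(2, 1, size=(25, 3)), rng.normal(0, 1, size=(25, 3))
        )
        r1 = crossval_signature(cohort, k=5, seed=42, auc_cutoff=0.5)
        r2 = crossval_signature(cohort, k=5, seed=42, auc_cutoff=0.5)
        assert r1.fold_of_patient == r2.fold_of_patient
        assert r1.pooled_auc == r2.pooled_auc
        counts = pd.Series(list(r1.fold_of_patient.values())).value_counts()
        assert counts.sum() == 25 and counts.max() == 5

    def test_k_larger_than_cohort_is_error(self):
        rng = np.random.default_rng(7)
        cohort = cohort_from_arrays(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            crossval_signature(cohort, k=10, seed=0, auc_cutoff=0.0)

    def test_uninformative_markers_give_chance_level_cv_auc(self):
        rng = np.random.default_rng(8)
        cohort = cohort_from_arrays(
            rng.normal(size=(500, 3)), rng.normal(size=(500, 3))
        )
        r = crossval_signature(cohort, k=10, seed=1, auc_cutoff=0.0, use_all_when_empty=True)
        assert abs(r.pooled_auc - 0.5) < 0.05

    def test_marker_statistics_flags_planted_shifts(self):
        rng = np.random.default_rng(9)
        tumour = np.c_[rng.normal(3, 1, 40), rng.normal(0, 1, 40)]
        normal = rng.normal(0, 1, size=(40, 2))
        stats_df = marker_statistics(cohort_from_arrays(tumour, normal, ["hit", "null"]))
        hit = stats_df.set_index("marker")
        assert bool(hit.loc["hit", "significant"])
        assert not bool(hit.loc["null", "significant"])
        assert hit.loc["hit", "auc"] > 0.9


class TestClustering:
    def test_identical_patient_columns_merge_first(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(4, 6))
        data[:, 3] = data[:, 0]  # duplicate patient
        df = pd.DataFrame(data, index=list("abcd"), columns=[f"P{i}" for i in range(6)])
        rows, cols = cluster_samples(df)
        i, j = cols.index("P0"), cols.index("P3")
        assert abs(i - j) == 1  # adjacent leaves

    def test_leaf_sets_invariant_under_permutation(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(5, 7)),
                          index=[f"m{i}" for i in range(5)],
                          columns=[f"P{i}" for i in range(7)])
        rows1, cols1 = cluster_samples(df)
        perm = df.iloc[[3, 1, 4, 0, 2], [6, 2, 0, 5, 1, 4, 3]]
        rows2, cols2 = cluster_samples(perm)
        assert set(rows1) == set(rows2) and set(cols1) == set(cols2)

    def test_pairwise_distances_match_direct_recomputation(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(12)
        x = rng.normal(size=(6, 4))
        direct = [
            np.sqrt(((x[i] - x[j]) ** 2).sum())
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        assert np.allclose(pdist(x), direct)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            cluster_samples(df)

    def test_single_row_axis_keeps_input_order(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["only"], columns=list("xyz"))
        rows, cols = cluster_samples(df)
        assert rows == ["only"]
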