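"""Standardization, clustering summaries, CV classification, correlation and
FDR, survival screening, gene association, and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score

from nucmorph.cohort_stats import (
    bh_fdr,
    cv_binary_auroc,
    gene_association,
    km_median_split,
    mann_whitney_auroc,
    median_z_heatmap,
    one_vs_all_cv,
    overlap_enrichment,
    pearson,
    predict_wgd,
    prepare_umap_input,
    robust_zscore,
    select_gene_sets,
    spearman,
    survival_screen,
    wgd_binarize,
    zscore_columns,
)
from nucmorph.synthetic import CohortSimParams, simulate_cohort


class TestStandardization:
    def test_constant_column_flagged_not_divided(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        z, flagged = zscore_columns(df)
        assert flagged == ["b"]
        assert (z["b"] == 5.0).all()
        assert z["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["a"].std(ddof=1) == pytest.approx(1.0)

    def test_value_at_median_maps_to_zero(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 100.0])
        z = robust_zscore(x)
        assert z[2] == 0.0

    def test_robust_z_sd_calibrated_on_normal_draws(self):
        rng = np.random.default_rng(0)
        z = robust_zscore(rng.normal(size=10_000))
        assert 0.95 <= z.std(ddof=1) <= 1.05

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="interquartile"):
            robust_zscore(np.array([1.0, 1.0, 1.0, 1.0]))


class TestMedianZHeatmap:
    def test_mirrored_groups_give_antisymmetric_medians(self):
        rng = np.random.default_rng(1)
        n = 300
        base = rng.normal(size=(2 * n, 3))
        base[:n] += 1.0
        base[n:] -= 1.0
        df = pd.DataFrame(base, columns=["f1", "f2", "f3"])
        df["grp"] = ["A"] * n + ["B"] * n
        out = median_z_heatmap(df, "grp")
        med = out["matrix"]
        assert np.allclose(med.loc["A"], -med.loc["B"], atol=0.1)

    def test_30_feature_columns_in_30_out(self):
        cohort, _, _ = simulate_cohort(
            CohortSimParams(n_slides_per_group=20, classes=("CANCER",),
                            n_genes=5, n_planted_genes=1, seed=0))
        cols = [c for c in cohort.columns if "_NUCLEUS_" in c]
        assert len(cols) == 30
        out = median_z_heatmap(cohort, "cancer_type", cols)
        assert out["matrix"].shape == (3, 30)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0], "grp": ["A", "A"]})
        with pytest.raises(ValueError, match="2 groups"):
            median_z_heatmap(df, "grp")

    def test_average_linkage_merge_order_matches_hand_computation(self):
        # 1-D points 0, 1, 4, 10: merges (0,1) at d=1, then {0,1}+{4} at
        # average distance (4+3)/2=3.5, then all at (10+9+6)/3 ≈ 8.33
        pts = np.array([[0.0], [1.0], [4.0], [10.0]])
        link = hierarchy.linkage(pts, method="average", metric="euclidean")
        assert link[0][2] == pytest.approx(1.0)
        assert link[1][2] == pytest.approx(3.5)
        assert link[2][2] == pytest.approx((10 + 9 + 6) / 3)


class TestAUROC:
    def test_perfect_ranking_gives_one(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        assert mann_whitney_auroc(scores, y) == 1.0

    def test_matches_brute_force_pair_counting_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(6, 50))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            pos = scores[y == 1]
            neg = scores[y == 0]
            wins = sum((p > q) + 0.5 * (p == q)
                       for p in pos for q in neg)
            assert mann_whitney_auroc(scores, y) == pytest.approx(
                wins / (len(pos) * len(neg)))

    def test_matches_sklearn_reference(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=200)
        scores = rng.normal(size=200) + y
        assert mann_whitney_auroc(scores, y) == pytest.approx(
            roc_auc_score(y, scores))


@pytest.fixture(scope="module")
def planted_cohort():
    cols = [f"f{i}" for i in range(10)]
    rng = np.random.default_rng(7)
    n = 400
    X = pd.DataFrame(rng.normal(size=(2 * n, 10)), columns=cols)
    X.iloc[:n, :5] += 1.5
    y = np.array([1] * n + [0] * n)
    return X, y


class TestCVBinaryAUROC:

    def test_null_labels_give_chance_auroc(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(800, 10)))
        y = np.array([1, 0] * 400)
        res = cv_binary_auroc(X, y, seed=0)
        assert 0.42 <= res.mean_auroc <= 0.58

    def test_planted_shift_detected(self, planted_cohort):
        X, y = planted_cohort
        res = cv_binary_auroc(X, y, seed=0)
        assert res.mean_auroc >= 0.9
        assert len(res.fold_aurocs) == 5
        assert res.mean_auroc == pytest.approx(np.mean(res.fold_aurocs))
        # shifted features dominate importances
        top5 = {f for f, _ in res.top_importances(5)}
        assert top5 == {"f0", "f1", "f2", "f3", "f4"}

    def test_deterministic_given_seed(self, planted_cohort):
        X, y = planted_cohort
        r1 = cv_binary_auroc(X, y, seed=3)
        r2 = cv_binary_auroc(X, y, seed=3)
        assert r1.fold_aurocs == r2.fold_aurocs
        assert r1.feature_importances == r2.feature_importances

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError, match="minority"):
            cv_binary_auroc(X, y, k=5)

    def test_nonfinite_features_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan] * 10})
        with pytest.raises(ValueError, match="non-finite"):
            cv_binary_auroc(X, [0, 1] * 10)


class TestOneVsAll:
    def test_three_subtypes_give_three_results(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(150, 5)))
        labels = np.repeat(["a", "b", "c"], 50)
        out = one_vs_all_cv(X, labels, seed=0)
        assert set(out) == {"a", "b", "c"}

    def test_rare_subtype_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(63, 4)))
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 3)
        with pytest.warns(UserWarning, match="skipped"):
            out = one_vs_all_cv(X, labels, seed=0)
        assert "c" not in out

    def test_shift_in_cancer_features_raises_cancer_auroc_only(self):
        col = "MEAN[CANCER_NUCLEUS_AREA]_H&E"
        cohort, _, _ = simulate_cohort(CohortSimParams(
            n_slides_per_group=100, n_genes=5, n_planted_genes=1,
            subtype_effects={"BASAL": {col: 2.0,
                                       "STD[CANCER_NUCLEUS_AREA]_H&E": 1.5}},
            seed=11))
        cancer_cols = [c for c in cohort.columns if "[CANCER_" in c]
        fib_cols = [c for c in cohort.columns if "[FIBROBLAST_" in c]
        res_cancer = one_vs_all_cv(cohort[cancer_cols],
                                   cohort["molecular_subtype"], seed=0)
        res_fib = one_vs_all_cv(cohort[fib_cols],
                                cohort["molecular_subtype"], seed=0)
        assert res_cancer["BASAL"].mean_auroc > res_fib["BASAL"].mean_auroc
        assert res_cancer["BASAL"].mean_auroc > 0.8


class TestWGD:
    def test_binarization_rule(self):
        assert wgd_binarize([0, 1, 2]).tolist() == [0, 1, 1]
        with pytest.raises(ValueError, match="wgd_count"):
            wgd_binarize([3])

    def test_planted_atypia_signal_recovered_in_importances(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort, _, _ = simulate_cohort(CohortSimParams(
                n_slides_per_group=120, group_labels=("BRCA",),
                classes=("CANCER",), wgd_beta=1.5, n_genes=5,
                n_planted_genes=1, seed=seed))
            X = cohort[[c for c in cohort.columns if "_NUCLEUS_" in c]]
            res, top5 = predict_wgd(X, cohort["wgd_count"], seed=seed)
            if any("STD[CANCER_NUCLEUS_AREA]" in name for name, _ in top5):
                hits += 1
        assert hits >= 0.8 * n_seeds
        assert res.mean_auroc > 0.5


class TestCorrelationAndFDR:
    def test_monotone_transform_gives_unit_spearman(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        rho, p = spearman(x, x**3)
        assert rho == 1.0

    def test_exact_permutation_p_for_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        rho, p = spearman(x, y)
        # enumerate all 5! permutations directly
        rx = stats.rankdata(x)
        count = 0
        for perm in itertools.permutations(stats.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120)

    def test_t_approximation_matches_scipy_for_large_n(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))

    def test_pearson_on_linear_data(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_bh_hand_computed_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        assert (q <= 1.0).all()

    def test_type_one_error_calibration_of_spearman_p(self):
        rng = np.random.default_rng(14)
        rejections = 0
        trials = 40
        for _ in range(trials):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            _, p = spearman(x, y)
            rejections += p < 0.05
        assert 0.02 * trials <= rejections <= 0.09 * trials or rejections <= 4


class TestSurvival:
    @staticmethod
    def cohort_with_hazard(beta, seed, n_per_group=270):
        return simulate_cohort(CohortSimParams(
            n_slides_per_group=n_per_group, group_labels=("BRCA",),
            classes=("FIBROBLAST",), survival_beta=beta, n_genes=5,
            n_planted_genes=1, seed=seed))[0]

    def test_null_cohort_hazard_ratios_near_one(self):
        cohort = self.cohort_with_hazard(0.0, seed=1, n_per_group=500)
        feats = [c for c in cohort.columns if "_NUCLEUS_" in c][:10]
        screen, n_excl = survival_screen(cohort, feats)
        assert n_excl == 0
        assert screen["converged"].all()
        assert screen["hazard_ratio"].between(0.85, 1.18).all()

    def test_planted_hazard_recovered_with_ci_coverage(self):
        # small-n version of the 100-seed recovery check in the acceptance
        # suite; at 20 seeds the binomial floor for a true >=90% coverage
        # rate is 15/20
        feature = "MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E"
        covered = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = self.cohort_with_hazard(np.log(1.8), seed=seed, n_per_group=800)
            screen, _ = survival_screen(cohort, [feature])
            row = screen.iloc[0]
            assert 1.5 <= row["hazard_ratio"] <= 2.2
            covered += row["ci_low"] <= 1.8 <= row["ci_high"]
        assert covered >= 15

    def test_unrelated_feature_ranks_behind_planted_one(self):
        feature = "MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E"
        other = "MEAN[FIBROBLAST_NUCLEUS_SOLIDITY]_H&E"
        wins = 0
        for seed in range(10):
            cohort = self.cohort_with_hazard(np.log(1.8), seed=100 + seed)
            screen, _ = survival_screen(cohort, [feature, other])
            s = screen.set_index("feature")
            wins += s.loc[feature, "q_value"] <= s.loc[other, "q_value"]
        assert wins >= 9

    def test_rows_missing_stage_excluded_and_counted(self):
        cohort = self.cohort_with_hazard(0.0, seed=2)
        cohort.loc[cohort.index[:17], "stage"] = np.nan
        feats = [c for c in cohort.columns if "_NUCLEUS_" in c][:2]
        _, n_excl = survival_screen(cohort, feats)
        assert n_excl == 17

    def test_km_median_split_properties(self):
        feature = "MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E"
        cohort = self.cohort_with_hazard(np.log(1.8), seed=3, n_per_group=800)
        out = km_median_split(cohort, feature)
        for grp in ("high", "low"):
            surv = out["curves"][grp]["survival"]
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()
        assert out["hazard_ratio"] > 1.0
        assert out["ci_low"] > 1.0  # CI excludes 1 at this n and effect

    def test_km_null_split_hr_near_one(self):
        feature = "MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E"
        cohort = self.cohort_with_hazard(0.0, seed=4, n_per_group=500)
        out = km_median_split(cohort, feature)
        assert 0.8 <= out["hazard_ratio"] <= 1.25

    # the 4-row toy intentionally produces a near-separated Cox fit
    @pytest.mark.filterwarnings(
        "ignore::lifelines.exceptions.ConvergenceWarning")
    def test_median_ties_assigned_to_high_group(self):
        df = pd.DataFrame({
            "f": [1.0, 2.0, 2.0, 3.0],
            "surv_time": [5.0, 6.0, 7.0, 8.0],
            "surv_event": [1, 1, 1, 1],
        })
        out = km_median_split(df, "f")
        # median = 2.0; ties go high -> high group has 3 members; the KM
        # curve of the high group then steps at 3 event times
        assert len(out["curves"]["high"]["times"]) >= 3


class TestGeneAssociation:
    @staticmethod
    def planted(seed=0, rho=0.4, n_genes=400, n_planted=40, n=800):
        cohort, expr, sets = simulate_cohort(CohortSimParams(
            n_slides_per_group=n, group_labels=("BRCA",),
            classes=("FIBROBLAST",), n_genes=n_genes,
            n_planted_genes=n_planted, planted_gene_rho=rho, seed=seed))
        feat = cohort.set_index("slide_id")["MEAN[FIBROBLAST_NUCLEUS_AREA]_H&E"]
        return feat, expr, sets

    def test_null_expression_yields_empty_sets(self):
        empty_both = 0
        for seed in range(10):
            feat, expr, _ = self.planted(seed=seed, rho=0.0, n_genes=200,
                                         n_planted=1, n=200)
            assoc = gene_association(feat, expr)
            pos, neg = select_gene_sets(assoc)
            empty_both += (not pos) and (not neg)
        assert empty_both >= 9

    def test_planted_block_lands_in_positive_set(self):
        feat, expr, _ = self.planted()
        assoc = gene_association(feat, expr)
        pos, neg = select_gene_sets(assoc)
        planted = {f"GENE_{i:05d}" for i in range(40)}
        assert len(planted & set(pos)) >= 32  # >= 80% recovered
        false_pos = set(pos) - planted
        assert len(false_pos) <= 5
        assert not planted & set(neg)

    def test_boundary_rho_excluded_by_strict_inequality(self):
        assoc = pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "spearman_rho": [0.15, 0.16, -0.15],
            "p": [1e-4, 1e-4, 1e-4],
            "q": [1e-3, 1e-3, 1e-3],
        })
        pos, neg = select_gene_sets(assoc)
        assert pos == ["g2"] and neg == []

    def test_sample_mismatch_rejected(self):
        feat, expr, _ = self.planted(n_genes=20, n_planted=2, n=50)
        with pytest.raises(ValueError, match="sample ids"):
            gene_association(feat.iloc[:-1], expr.iloc[1:])

    def test_vectorized_rho_matches_scipy_per_gene(self):
        feat, expr, _ = self.planted(n_genes=25, n_planted=5, n=60)
        assoc = gene_association(feat, expr).set_index("gene")
        for g in list(expr.columns)[:10]:
            ref_rho, ref_p = stats.spearmanr(feat, expr[g])
            assert assoc.loc[g, "spearman_rho"] == pytest.approx(ref_rho)
            assert assoc.loc[g, "p"] == pytest.approx(ref_p, rel=1e-6)


class TestEnrichment:
    def test_whole_pathway_query_ranks_first(self):
        universe = [f"g{i}" for i in range(1000)]
        sets = {"target": universe[:50], "other": universe[500:550]}
        out = overlap_enrichment(universe[:50], sets, universe)
        assert out.iloc[0]["set_name"] == "target"
        assert out.iloc[0]["overlap"] == 50

    def test_hypergeometric_tail_matches_direct_summation(self):
        from math import comb

        universe = [f"g{i}" for i in range(100)]
        query = universe[:10]
        pathway = universe[6:16]  # overlap = 4
        out = overlap_enrichment(query, {"pw": pathway}, universe,
                                 q_cutoff=1.1)
        # P(X >= 4) for X ~ Hypergeom(M=100, K=10, n=10) by summation
        p_direct = sum(
            comb(10, k) * comb(90, 10 - k) / comb(100, 10)
            for k in range(4, 11)
        )
        assert out.iloc[0]["p"] == pytest.approx(p_direct, rel=1e-12)
        assert out.iloc[0]["overlap"] == 4

    def test_empty_query_gives_no_enrichment(self):
        universe = [f"g{i}" for i in range(100)]
        out = overlap_enrichment([], {"pw": universe[:10]}, universe)
        assert len(out) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(["g1"], {"pw": ["g1"]}, [])

    def test_at_most_ten_rows_reported(self):
        rng = np.random.default_rng(15)
        universe = [f"g{i}" for i in range(200)]
        query = universe[:40]
        sets = {f"pw{i}": universe[:40] for i in range(15)}  # all identical
        out = overlap_enrichment(query, sets, universe)
        assert len(out) <= 10


class TestUMAPInput:
    def test_recorded_parameters(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)))
        _, params = prepare_umap_input(df)
        assert params == {"n_neighbors": 100, "n_components": 2,
                          "metric": "euclidean"}

    def test_zscored_columns_and_row_count(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(50, 3)),
                          columns=["a", "b", "c"])
        z, _ = prepare_umap_input(df)
        assert len(z) == 50
        assert np.allclose(z.mean(), 0.0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-9)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            prepare_umap_input(df)
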