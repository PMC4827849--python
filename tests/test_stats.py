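"""Hotelling's T^2 / Mahalanobis group inference and permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from hippomorph import stats as st


def brute_force_mahalanobis(S, T):
    """Independent evaluation of M = [pq/(p+q)] d^T Sigma^-1 d with the
    pooled covariance assembled entry by entry."""
    S = np.atleast_2d(np.asarray(S, float))
    T = np.atleast_2d(np.asarray(T, float))
    p, q = len(S), len(T)
    d = S.mean(0) - T.mean(0)
    k = S.shape[1]
    sigma = np.zeros((k, k))
    for grp in (S, T):
        m = grp.mean(0)
        for row in grp:
            sigma += np.outer(row - m, row - m)
    sigma /= p + q - 2
    return p * q / (p + q) * d @ np.linalg.inv(sigma) @ d


class TestMahalanobis:
    def test_printed_hand_example(self):
        S = np.array([[-1.0], [1.0]])
        T = np.array([[1.0], [3.0]])
        assert st.mahalanobis_group_distance(S, T) == pytest.approx(2.0)
        assert brute_force_mahalanobis(S, T) == pytest.approx(2.0)

    def test_agrees_with_brute_force_on_random_data(self):
        rng = np.random.default_rng(7)
        S = rng.standard_normal((9, 4))
        T = rng.standard_normal((12, 4)) + 0.3
        assert st.mahalanobis_group_distance(S, T) == pytest.approx(
            brute_force_mahalanobis(S, T), rel=1e-10
        )

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((6, 4))
        T = rng.standard_normal((8, 4))
        assert st.mahalanobis_group_distance(S, T) == pytest.approx(
            st.mahalanobis_group_distance(T, S)
        )

    def test_zero_for_equal_means(self):
        S = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        assert st.mahalanobis_group_distance(S, S.copy()) == pytest.approx(0.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            st.mahalanobis_group_distance(np.zeros((1, 4)), np.zeros((5, 4)))


class TestVertexPermutationTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        S = rng.standard_normal((10, 30, 4))
        T = rng.standard_normal((10, 30, 4))
        p1, _ = st.vertex_permutation_test(S, T, n_perm=200, seed=5)
        p2, _ = st.vertex_permutation_test(S, T, n_perm=200, seed=5)
        assert np.array_equal(p1, p2)

    def test_p_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(3)
        n_perm = 200
        S = rng.standard_normal((15, 5, 4)) + 6.0  # overwhelming effect
        T = rng.standard_normal((15, 5, 4))
        p, _ = st.vertex_permutation_test(S, T, n_perm=n_perm, seed=1)
        assert np.all(p > 0)
        assert p.min() == pytest.approx(1.0 / (n_perm + 1))

    def test_matches_hotelling_f_under_null(self):
        rng = np.random.default_rng(11)
        S = rng.standard_normal((20, 150, 4))
        T = rng.standard_normal((20, 150, 4))
        p_perm, obs = st.vertex_permutation_test(S, T, n_perm=400, seed=2)
        p_f = np.array([st.hotelling_f_pvalue(m, 20, 20, 4) for m in obs])
        from scipy.stats import ks_2samp

        assert ks_2samp(p_perm, p_f).pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            st.vertex_permutation_test(
                np.zeros((3, 2, 4)), np.zeros((3, 2, 4)), n_perm=10
            )


class TestOverallMapSignificance:
    def test_duplicated_groups_give_null_map(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 40, 4))
        pm = st.overall_map_significance(A, A.copy(), np.ones(40), n_perm=150, seed=0)
        assert pm.overall_p == 1.0
        assert pm.suprathreshold_area == 0.0
        assert pm.note == "zero suprathreshold area"
        assert np.abs(pm.m_value).max() < 1e-12

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(4)
        S = rng.standard_normal((20, 40, 4))
        S[:, :20] += 2.0  # effect on half the vertices
        T = rng.standard_normal((20, 40, 4))
        areas = np.ones(40)
        pm = st.overall_map_significance(S, T, areas, n_perm=500, seed=0)
        assert pm.overall_p <= 0.01
        assert 0 < pm.suprathreshold_area <= areas.sum()

    def test_area_uses_vertex_weights(self):
        rng = np.random.default_rng(4)
        S = rng.standard_normal((20, 40, 4))
        S[:, :20] += 2.0
        T = rng.standard_normal((20, 40, 4))
        pm1 = st.overall_map_significance(S, T, np.ones(40), n_perm=120, seed=0)
        pm2 = st.overall_map_significance(S, T, 2 * np.ones(40), n_perm=120, seed=0)
        assert pm2.suprathreshold_area == pytest.approx(2 * pm1.suprathreshold_area)


class TestPvalueCdf:
    def test_uniform_grid_lies_on_diagonal(self):
        n = 200
        p = np.arange(1, n + 1) / n
        curve = st.pvalue_cdf(p)
        assert np.allclose(curve.cum_fraction, curve.p_sorted)
        assert curve.cum_fraction[-1] == 1.0

    def test_degenerate_map_is_left_step(self):
        p = np.full(50, 1.0 / 501.0)
        curve = st.pvalue_cdf(p)
        assert curve.value_at(0.05) == 1.0
        assert curve.value_at(1.0 / 502.0) == 0.0

    def test_frame_has_reference_lines(self):
        curve = st.pvalue_cdf(np.linspace(0.01, 1, 50))
        df = curve.to_frame()
        assert {"p", "cdf", "null_line", "fdr_line"} <= set(df.columns)
        assert np.allclose(df["fdr_line"], df["p"] / 0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            st.pvalue_cdf(np.array([np.nan]))


class TestRunGroupContrast:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(9)
        rows = []
        stats = {}
        for dose, n in ((0, 8), (1, 5), (2, 5)):
            for j in range(n):
                sid = f"sub-{dose}{j:03d}"
                rows.append({"subject_id": sid, "group": str(dose), "dose": dose,
                             "seed": 0})
                x = rng.standard_normal((30, 4))
                x[:, 3] -= 0.8 * dose  # dose-graded radial deficit
                stats[sid] = x
        return pd.DataFrame(rows), stats

    def test_pooled_carrier_selector(self, cohort):
        table, stats = cohort
        pm, cdf, report = st.run_group_contrast(
            table, stats, {1, 2}, {0}, np.ones(30), n_perm=150, seed=0
        )
        assert report["n_s"] == 10 and report["n_t"] == 8
        assert set(report["subjects_s"]) == {
            s for s in stats if not s.startswith("sub-0")
        }
        assert report["n_perm"] == 150
        assert np.isfinite(pm.p_uncorrected).all()

    def test_callable_selector_and_exclusion(self, cohort):
        table, stats = cohort
        pm, _, report = st.run_group_contrast(
            table, stats,
            lambda df: df["dose"] == 2,
            lambda df: df["dose"] == 0,
            np.ones(30), n_perm=150, seed=0,
        )
        assert report["n_s"] == 5 and report["n_t"] == 8

    def test_empty_selection_lists_available(self, cohort):
        table, stats = cohort
        with pytest.raises(ValueError, match="available dose levels"):
            st.run_group_contrast(
                table, stats, {7}, {0}, np.ones(30), n_perm=150, seed=0
            )

    def test_masked_vertices_propagate(self, cohort):
        table, stats = cohort
        sid = next(iter(stats))
        stats[sid] = stats[sid].copy()
        stats[sid][3] = np.nan  # one unusable vertex in one subject
        pm, _, report = st.run_group_contrast(
            table, stats, {2}, {0}, np.ones(30), n_perm=150, seed=0
        )
        assert report["n_vertices_masked"] == 1
        assert np.isnan(pm.p_uncorrected[3])

    def test_split_halves_of_null_group_not_significant(self):
        rng = np.random.default_rng(30)
        rows, stats = [], {}
        for j in range(16):
            sid = f"sub-0{j:03d}"
            rows.append({"subject_id": sid, "group": "ctl", "dose": 0, "seed": 0})
            stats[sid] = rng.standard_normal((20, 4))
        table = pd.DataFrame(rows)
        ids = sorted(stats)
        pm, _, _ = st.run_group_contrast(
            table, stats,
            lambda df: df["subject_id"].isin(ids[:8]),
            lambda df: df["subject_id"].isin(ids[8:]),
            np.ones(20), n_perm=300, seed=1,
        )
        assert pm.overall_p > 0.05
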