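"""Pairwise PCA, confidence ellipses, and the concordance statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cytoprofile.concordance import (
    BCPConcordance,
    concordance,
    confidence_ellipse,
    fit_pairwise_pca,
    pairwise_concordance,
    rank_references,
)
from cytoprofile.feature_table import parameter_columns
from cytoprofile.synthetic import (
    TreatmentSpec,
    default_parameter_names,
    gen_feature_table,
)


def _gauss_table(name, n, mean, seed, cov=None):
    mean = np.asarray(mean, dtype=float)
    cov = np.eye(len(mean)) if cov is None else cov
    spec = TreatmentSpec(name, n, mean, cov)
    return gen_feature_table([spec], default_parameter_names(len(mean)), seed=seed)


class TestPairwisePCA:
    def test_duplicated_table_scores_coincide(self, two_treatment_table):
        t = two_treatment_table
        a = t[t["treatment"] == "ctrl"]
        b = a.copy()
        _, sa, sb = fit_pairwise_pca(a, b)
        assert np.allclose(sa, sb)

    def test_perfectly_correlated_pair_is_rank_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(100)],
                "treatment": ["A"] * 50 + ["B"] * 50,
                "replicate": 1,
                "p1": x,
                "p2": 3.0 * x - 1.0,
            }
        )
        model, _, _ = fit_pairwise_pca(
            df[df["treatment"] == "A"], df[df["treatment"] == "B"]
        )
        ev = model.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_shift_drives_pc1_loading(self):
        # the between-group shift makes the shifted parameters mutually
        # correlated in the pooled data, so PC1 concentrates on them
        p = 39
        mean = np.zeros(p)
        mean[[7, 8]] = 4.0
        a = _gauss_table("a", 400, np.zeros(p), seed=1)
        b = _gauss_table("b", 400, mean, seed=2)
        model, _, _ = fit_pairwise_pca(a, b)
        pc1 = np.abs(model.loadings[:, 0])
        top_two = {model.parameters[i] for i in pc1.argsort()[-2:]}
        assert top_two == {"p08", "p09"}
        # oracle: leading eigenvector of the pooled correlation matrix
        x = np.vstack([
            a[parameter_columns(a)].to_numpy(),
            b[parameter_columns(b)].to_numpy(),
        ])
        corr = np.corrcoef(x, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        lead = np.abs(evecs[:, -1])
        assert np.allclose(pc1 / np.linalg.norm(pc1), lead / np.linalg.norm(lead),
                           atol=1e-6)

    def test_loading_columns_orthonormal_and_variance_sorted(self, two_treatment_table):
        t = two_treatment_table
        model, _, _ = fit_pairwise_pca(
            t[t["treatment"] == "ctrl"], t[t["treatment"] == "drug"]
        )
        L = model.loadings
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        assert np.all(np.diff(model.explained_variance) <= 1e-9)

    def test_zero_variance_parameter_dropped_with_warning(self):
        a = _gauss_table("a", 50, [0.0, 0.0], seed=1)
        b = _gauss_table("b", 50, [0.0, 0.0], seed=2)
        a["p02"] = 1.0
        b["p02"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model, _, _ = fit_pairwise_pca(a, b)
        assert model.parameters == ["p01"]

    def test_too_few_cells_rejected(self):
        a = _gauss_table("a", 1, [0.0], seed=1)
        b = _gauss_table("b", 1, [0.0], seed=2)
        with pytest.raises(ValueError, match="3 cells"):
            fit_pairwise_pca(a, b)


class TestConfidenceEllipse:
    def test_chi2_coverage_on_standard_normal(self):
        rng = np.random.default_rng(123)
        pts = rng.standard_normal((10_000, 2))
        ell = confidence_ellipse(pts, level=0.95, method="normal")
        assert ell.contains(pts).mean() == pytest.approx(0.95, abs=0.01)

    def test_center_is_always_a_member(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((30, 2))
        ell = confidence_ellipse(pts)
        assert ell.contains(ell.center[None, :])[0]

    def test_t_radius_approaches_chi2_radius(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((200_000, 2))
        t_ell = confidence_ellipse(pts, method="t")
        n_ell = confidence_ellipse(pts, method="normal")
        assert t_ell.radius2 / n_ell.radius2 == pytest.approx(1.0, abs=1e-4)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            confidence_ellipse(pts)

    def test_membership_matches_polygon_winding_oracle(self):
        """Quadratic-form membership equals a brute-force geometric test
        against a densely sampled boundary polygon of the same ellipse."""
        from matplotlib.path import Path as MplPath

        rng = np.random.default_rng(8)
        pts = rng.standard_normal((400, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        ell = confidence_ellipse(pts, method="normal")
        evals, evecs = np.linalg.eigh(ell.shape)
        a = np.sqrt(evals[-1] * ell.radius2)
        b = np.sqrt(evals[0] * ell.radius2)
        theta = np.arctan2(evecs[1, -1], evecs[0, -1])
        t = np.linspace(0.0, 2 * np.pi, 20_001)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        boundary = (rot @ np.stack([a * np.cos(t), b * np.sin(t)])).T + ell.center
        inside_oracle = MplPath(boundary).contains_points(pts)
        inside = ell.contains(pts)
        # the polygon chord falls short of the true boundary by ~(pi/n)^2;
        # compare only points clear of that discretisation band
        m2 = ell.mahalanobis2(pts)
        clear = np.abs(m2 - ell.radius2) > 1e-6 * ell.radius2
        assert np.array_equal(inside[clear], inside_oracle[clear])


class TestConcordance:
    def test_identical_clouds_give_exactly_one(self):
        rng = np.random.default_rng(5)
        sc = rng.standard_normal((300, 2))
        ell = confidence_ellipse(sc)
        res = concordance(ell, ell, sc, sc.copy())
        assert res.proportion == 1.0
        assert res.n_both == res.n_either

    def test_distant_clusters_give_exactly_zero(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((300, 2))
        b = rng.standard_normal((300, 2)) + np.array([100.0, 0.0])
        res = concordance(confidence_ellipse(a), confidence_ellipse(b), a, b)
        assert res.proportion == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((200, 2))
        b = rng.standard_normal((200, 2)) + 1.0
        ea, eb = confidence_ellipse(a), confidence_ellipse(b)
        r1 = concordance(ea, eb, a, b)
        r2 = concordance(eb, ea, b, a)
        assert r1.proportion == r2.proportion
        assert 0.0 <= r1.proportion <= 1.0
        assert r1.n_both <= r1.n_either

    def test_matches_monte_carlo_oracle_over_distance_grid(self):
        """Fitted-ellipse concordance vs analytic-ellipse Monte Carlo, and
        monotone decline with the distance between treatment means."""
        n = 5000
        r2 = stats.chi2.ppf(0.95, 2)
        props = []
        for d in (0.0, 2.0, 4.0):
            rng_fit = np.random.default_rng(21)
            sa = rng_fit.standard_normal((n, 2))
            sb = rng_fit.standard_normal((n, 2)) + np.array([d, 0.0])
            res = concordance(
                confidence_ellipse(sa, method="normal"),
                confidence_ellipse(sb, method="normal"),
                sa,
                sb,
            )
            # oracle: fresh draws, true centers, unit covariance, chi2 radius
            rng = np.random.default_rng(99)
            oa = rng.standard_normal((n, 2))
            ob = rng.standard_normal((n, 2)) + np.array([d, 0.0])
            pts = np.vstack([oa, ob])
            in_a = ((pts - [0.0, 0.0]) ** 2).sum(axis=1) <= r2
            in_b = ((pts - [d, 0.0]) ** 2).sum(axis=1) <= r2
            oracle = (in_a & in_b).sum() / (in_a | in_b).sum()
            assert res.proportion == pytest.approx(oracle, abs=0.02)
            props.append(res.proportion)
        assert props[0] > props[1] > props[2]

    def test_invariant_to_parameter_rescaling_and_permutation(self):
        a = _gauss_table("a", 300, np.zeros(5), seed=31)
        b = _gauss_table("b", 300, np.full(5, 1.0), seed=32)

        def prop(ta, tb):
            _, sa, sb = fit_pairwise_pca(ta, tb)
            return concordance(
                confidence_ellipse(sa), confidence_ellipse(sb), sa, sb
            ).proportion

        base = prop(a, b)
        # affine rescale of one parameter is absorbed by standardisation
        a2, b2 = a.copy(), b.copy()
        for t in (a2, b2):
            t["p03"] = 40.0 * t["p03"] - 7.0
        assert prop(a2, b2) == pytest.approx(base, abs=1e-12)
        # permuting parameter columns changes nothing
        perm = ["p04", "p01", "p05", "p02", "p03"]
        meta = ["cell_id", "treatment", "replicate"]
        assert prop(a[meta + perm], b[meta + perm]) == pytest.approx(base, abs=1e-12)


class TestRanking:
    def _panel(self, seed):
        p = 10
        names = default_parameter_names(p)
        query = _gauss_table("query", 260, np.zeros(p), seed=seed)
        query["treatment"] = "query"
        refs = {}
        refs["ref_same"] = _gauss_table("ref_same", 260, np.zeros(p), seed=seed + 1)
        for k in range(3):
            mean = np.zeros(p)
            mean[k] = 2.5
            refs[f"ref_{k}"] = _gauss_table(f"ref_{k}", 260, mean, seed=seed + 2 + k)
        return query, refs

    def test_duplicate_distribution_ranks_first(self):
        query, refs = self._panel(seed=50)
        results = rank_references(query, refs, seed=1)
        assert results[0].treatment_b == "ref_same"
        assert results[0].proportion > 0.8
        assert [r.proportion for r in results] == sorted(
            (r.proportion for r in results), reverse=True
        )

    def test_empty_reference_map(self):
        query, _ = self._panel(seed=51)
        assert rank_references(query, {}, seed=0) == []

    def test_model_results_frame_and_summary(self):
        query, refs = self._panel(seed=52)
        res = BCPConcordance(query, refs).fit(seed=2)
        frame = res.to_frame()
        assert list(frame["rank"]) == [1, 2, 3, 4]
        assert frame["proportion"].is_monotonic_decreasing
        text = res.summary()
        assert "concordance" in text and "ref_same" in text
        scores = res.scores_frame()
        assert {"pair", "treatment", "pc1", "pc2"} <= set(scores.columns)

    def test_plot_pair_draws_both_ellipses(self):
        import matplotlib

        matplotlib.use("Agg")
        query, refs = self._panel(seed=53)
        res = BCPConcordance(query, refs).fit(seed=3)
        ax = res.plot_pair("ref_same")
        assert len(ax.patches) == 2

    def test_subsampling_balances_each_pair(self):
        query, refs = self._panel(seed=54)
        pr = pairwise_concordance(query, refs["ref_0"], seed=5)
        assert len(pr.scores_a) == len(pr.scores_b) == 260
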