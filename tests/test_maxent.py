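"""Maxent engine: features, fitting vs an independent optimizer, metrics,
model selection, contributions, response curves and the niche envelope."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

from paleoniche import maxent as mx


def lbfgs_oracle(Xp, Xb, reg, tol=1e-16):
    """Direct numerical maximization of the penalized objective.

    Independent of the package's proximal-gradient path: the lasso problem is
    rewritten exactly as a smooth bound-constrained problem via the split
    beta = u - v with u, v >= 0 and solved with L-BFGS-B.
    """
    k = Xp.shape[1]

    def f(uv):
        u, v = uv[:k], uv[k:]
        beta = u - v
        return (
            -(Xp @ beta).mean()
            + logsumexp(Xb @ beta)
            - np.log(len(Xb))
            + reg @ (u + v)
        )

    res = minimize(
        f,
        np.zeros(2 * k),
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * k),
        options={"maxiter": 50_000, "ftol": tol, "gtol": 1e-12},
    )
    beta = res.x[:k] - res.x[k:]

    # refine on the identified orthant (smooth there) to machine precision
    active = np.abs(beta) > 1e-10
    if active.any():
        signs = np.sign(beta[active])
        Xpa, Xba = Xp[:, active], Xb[:, active]
        rega = reg[active] * signs

        def g(b):
            return (-(Xpa @ b).mean() + logsumexp(Xba @ b) - np.log(len(Xba))
                    + rega @ b)

        def g_grad(b):
            eta = Xba @ b
            q = np.exp(eta - logsumexp(eta))
            return -Xpa.mean(axis=0) + q @ Xba + rega

        def g_hess(b):
            eta = Xba @ b
            q = np.exp(eta - logsumexp(eta))
            mu = q @ Xba
            return (Xba * q[:, None]).T @ Xba - np.outer(mu, mu)

        res2 = minimize(g, beta[active], method="trust-exact", jac=g_grad,
                        hess=g_hess, options={"gtol": 1e-14, "maxiter": 1000})
        if np.all(np.sign(res2.x) * signs >= 0):
            beta = np.zeros(k)
            beta[active] = res2.x
    return beta


def gaussian_niche_sample(seed, n_pres=500, n_bg=2000, opt=8.0, sd_true=4.0):
    """Presences thinned from a uniform environment by a Gaussian niche."""
    rng = np.random.default_rng(seed)
    pres = []
    while len(pres) < n_pres:
        x = rng.uniform(-10, 25, 4 * n_pres)
        keep = rng.random(len(x)) < np.exp(-0.5 * ((x - opt) / sd_true) ** 2)
        pres.extend(x[keep].tolist())
    return (
        pd.DataFrame({"t": pres[:n_pres]}),
        pd.DataFrame({"t": rng.uniform(-10, 25, n_bg)}),
    )


def recovered_optimum(model):
    """Climate-space optimum implied by an LQ fit: -bL/(2 bQ), unscaled."""
    bl = bq = 0.0
    for j, f in enumerate(model.meta):
        if f.kind == "L":
            bl = model.coef[j]
        elif f.kind == "Q":
            bq = model.coef[j]
    if bq >= 0:
        return None
    lo, hi = model.normalization[model.variables[0]]
    return lo + (-bl / (2 * bq)) * (hi - lo)


@pytest.fixture(scope="module")
def tiny_data():
    rng = np.random.default_rng(7)
    pres = pd.DataFrame({"a": rng.normal(1.0, 0.5, 8), "b": rng.normal(0.0, 1.0, 8)})
    bg = pd.DataFrame({"a": rng.normal(0.0, 1.0, 22), "b": rng.normal(0.0, 1.0, 22)})
    return pres, bg


class TestFeatures:
    def test_linear_feature_is_minmax_scaled(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        X, meta = mx.build_features(df, ["x"], mx.FeatureSpec("L"), {"x": (2.0, 6.0)})
        assert np.allclose(X[:, 0], [0.0, 0.5, 1.0])
        assert meta[0].kind == "L"

    def test_quadratic_is_square_of_linear(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.uniform(0, 10, 50)})
        X, meta = mx.build_features(df, ["x"], mx.FeatureSpec("LQ"), {"x": (0.0, 10.0)})
        assert np.allclose(X[:, 1], X[:, 0] ** 2)

    def test_hinge_values_match_hand_computation(self):
        spec = mx.FeatureSpec("H", hinge_knots=3)
        df = pd.DataFrame({"x": [0.5]})
        X, meta = mx.build_features(df, ["x"], spec, {"x": (0.0, 1.0)})
        # knots at 0, 1/3, 2/3: h(0.5) = 0.5, (0.5-1/3)/(2/3), 0
        assert np.allclose(X[0], [0.5, (0.5 - 1 / 3) / (2 / 3), 0.0])
        assert [m.knot for m in meta] == pytest.approx([0.0, 1 / 3, 2 / 3])

    def test_zero_variance_variable_skipped_with_warning(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero variance"):
            X, meta = mx.build_features(
                df, ["x", "y"], mx.FeatureSpec("L"), {"x": (1.0, 1.0), "y": (0.0, 9.0)}
            )
        assert [m.variable for m in meta] == ["y"]


class TestFitMaxent:
    def test_huge_penalty_zeroes_all_coefficients(self, tiny_data):
        pres, bg = tiny_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ", rm=1e6))
        assert m.n_nonzero == 0
        raw = mx.predict(m, bg, "raw")
        assert np.allclose(raw, raw[0])
        assert np.allclose(mx.predict(m, bg, "logistic"), 0.5)

    @pytest.mark.parametrize("fclass", ["L", "LQ", "LQH", "H"])
    def test_coefficients_match_direct_maximization(self, tiny_data, fclass):
        pres, bg = tiny_data
        spec = mx.FeatureSpec(fclass, hinge_knots=5, rm=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mx.fit_maxent(pres, bg, spec, kkt_tol=1e-8)
        Xp, _ = mx.build_features(pres, m.variables, spec, m.normalization)
        Xb0, _ = mx.build_features(bg, m.variables, spec, m.normalization)
        Xb = np.vstack([Xb0, Xp])  # samples added to background, as in the fit
        beta_oracle = lbfgs_oracle(Xp, Xb, m.reg)
        assert np.max(np.abs(beta_oracle - m.coef)) < 1e-4

    def test_kkt_conditions_hold_at_the_solution(self, tiny_data):
        pres, bg = tiny_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"), kkt_tol=1e-8)
        Xp, _ = mx.build_features(pres, m.variables, m.spec, m.normalization)
        Xb0, _ = mx.build_features(bg, m.variables, m.spec, m.normalization)
        Xb = np.vstack([Xb0, Xp])
        _, grad, _ = mx._smooth_value_grad(m.coef, Xp, Xb)
        assert mx._kkt_violation(grad, m.coef, m.reg) < 1e-7

    def test_gaussian_niche_optimum_recovered(self):
        hits = 0
        for s in range(20):
            pres, bg = gaussian_niche_sample(s)
            m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ", rm=1.0))
            est = recovered_optimum(m)
            hits += est is not None and abs(est - 8.0) <= 0.2 * 4.0
        assert hits >= 18

    def test_sparsity_weakly_monotone_in_rm(self, tiny_data):
        pres, bg = tiny_data
        nnz = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rm in (1, 2, 3, 4, 5):
                nnz.append(mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ", rm=rm)).n_nonzero)
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_no_background_raises(self, tiny_data):
        pres, _ = tiny_data
        with pytest.raises(mx.FittingError):
            mx.fit_maxent(pres, pres.iloc[:0], mx.FeatureSpec("L"))

    def test_model_json_roundtrip(self, tiny_data):
        pres, bg = tiny_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        back = mx.MaxentModel.from_json(m.to_json())
        assert np.allclose(back.coef, m.coef)
        assert np.allclose(mx.predict(back, bg, "logistic"), mx.predict(m, bg, "logistic"))


class TestPredict:
    def test_raw_sums_to_one_over_normalization_set(self, fitted_lq_model):
        model, table, _ = fitted_lq_model
        from paleoniche.sampling import split_presence_background

        pres, bg = split_presence_background(table)
        total = mx.predict(model, bg, "raw").sum() + mx.predict(model, pres, "raw").sum()
        assert abs(total - 1.0) < 1e-6

    def test_logistic_is_monotone_in_raw(self, fitted_lq_model):
        model, table, _ = fitted_lq_model
        rows = table.sample(300, random_state=0)
        raw = mx.predict(model, rows, "raw")
        logi = mx.predict(model, rows, "logistic")
        rho, _ = spearmanr(raw, logi)
        assert rho == pytest.approx(1.0)
        assert np.all((logi >= 0) & (logi <= 1))

    def test_cloglog_in_unit_interval(self, fitted_lq_model):
        model, table, _ = fitted_lq_model
        cll = mx.predict(model, table, "cloglog")
        assert np.all((cll >= 0) & (cll <= 1))

    def test_missing_variable_raises(self, fitted_lq_model):
        model, _, _ = fitted_lq_model
        with pytest.raises(KeyError):
            mx.predict(model, pd.DataFrame({"temperature": [1.0]}), "logistic")


class TestMetrics:
    def test_auc_equals_all_pairs_count(self):
        rng = np.random.default_rng(3)
        pres = rng.normal(0.6, 0.3, 17)
        bg = rng.normal(0.4, 0.3, 29)
        wins = sum(
            1.0 if p > b else 0.5 if p == b else 0.0 for p in pres for b in bg
        )
        assert mx.auc_score(pres, bg) == pytest.approx(wins / (17 * 29))

    def test_separable_scores_reach_perfect_metrics(self):
        pres = np.array([0.8, 0.9, 0.95])
        bg = np.array([0.1, 0.2, 0.3])
        assert mx.auc_score(pres, bg) == 1.0
        t = mx.youden_threshold(pres, bg)
        tss, _ = mx.tss_kappa(*mx.confusion_rates(pres, bg, t))
        assert tss == 1.0
        assert t == 0.8  # tie rule: lower edge of the separating gap

    def test_tss_and_kappa_from_hand_computed_table(self):
        # TP=40 FN=10 TN=70 FP=30 -> TPR .8, TNR .7, TSS .5
        tss, kappa = mx.tss_kappa(40, 10, 70, 30)
        assert tss == pytest.approx(0.5)
        po = 110 / 150
        pe = (70 * 50 + 80 * 100) / 150**2
        assert kappa == pytest.approx((po - pe) / (1 - pe))

    def test_omission_rules(self):
        train = np.arange(0.0, 1.01, 0.05)
        assert mx.omission_threshold(train, "mtp") == 0.0
        cut = mx.omission_threshold(train, "or10p")
        assert 0.05 <= cut <= 0.15
        with pytest.raises(ValueError):
            mx.omission_threshold(train, "nope")

    def test_aicc_undefined_when_presences_too_few(self, tiny_data):
        pres, bg = tiny_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQH", hinge_knots=10))
        if m.n_nonzero + 1 >= len(pres):
            assert np.isnan(mx.aicc_score(m, pres, bg))
        else:
            assert np.isfinite(mx.aicc_score(m, pres, bg))

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        pres = rng.uniform(0, 1, 30)
        bg = rng.uniform(0, 1, 60)
        a1 = mx.auc_score(pres, bg)
        a2 = mx.auc_score(np.exp(3 * pres), np.exp(3 * bg))
        assert a1 == pytest.approx(a2)


class TestSelection:
    def test_singleton_grid_selects_that_candidate(self, fitted_lq_model):
        _, table, _ = fitted_lq_model
        spec = mx.FeatureSpec("L", rm=2.0)
        sel = mx.cross_validate_select(table, grid=[spec], folds=5, seed=0)
        assert sel.selected == spec
        assert len(sel.grid) == 1
        assert any("selected" in line for line in sel.trace)

    def test_informative_model_beats_null_candidate(self, fitted_lq_model):
        _, table, _ = fitted_lq_model
        good = mx.FeatureSpec("LQ", rm=1.0)
        null = mx.FeatureSpec("L", rm=1e6)  # all-zero coefficients
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = mx.cross_validate_select(table, grid=[null, good], folds=5, seed=1)
        assert sel.selected == good
        # null model fails the AICc screen by construction: uniform density
        null_row = sel.grid[sel.grid["rm"] == 1e6].iloc[0]
        assert null_row["delta_aicc"] > 2.0 or np.isnan(null_row["aicc"])

    def test_selection_is_deterministic_under_seed(self, fitted_lq_model):
        _, table, _ = fitted_lq_model
        grid = [mx.FeatureSpec("L", rm=1.0), mx.FeatureSpec("LQ", rm=1.0)]
        a = mx.cross_validate_select(table, grid=grid, folds=5, seed=3)
        b = mx.cross_validate_select(table, grid=grid, folds=5, seed=3)
        pd.testing.assert_frame_equal(a.grid, b.grid)
        assert a.selected == b.selected

    def test_too_few_presences_for_folds_raises(self, tiny_data):
        pres, bg = tiny_data
        table = pd.concat(
            [pres.assign(label="presence"), bg.assign(label="background")],
            ignore_index=True,
        )
        with pytest.raises(ValueError):
            mx.cross_validate_select(table, folds=50, variables=["a", "b"])

    def test_empty_grid_rejected(self, fitted_lq_model):
        _, table, _ = fitted_lq_model
        with pytest.raises(ValueError):
            mx.cross_validate_select(table, grid=[])


class TestInterpretation:
    def test_single_variable_contribution_is_total(self):
        pres, bg = gaussian_niche_sample(1, n_pres=200, n_bg=500)
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        table = pd.concat(
            [pres.assign(label="presence"), bg.assign(label="background")],
            ignore_index=True,
        )
        contrib = mx.variable_contribution(m, table)
        assert contrib["drop_pct"].iloc[0] == pytest.approx(100.0)
        assert contrib["permutation_pct"].iloc[0] == pytest.approx(100.0)

    def test_contributions_sum_to_hundred(self, fitted_lq_model):
        model, table, _ = fitted_lq_model
        contrib = mx.variable_contribution(model, table, seed=1)
        assert contrib["drop_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert contrib["permutation_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_coefficient_variable_contributes_nothing_by_drop(self, fitted_lq_model):
        model, table, _ = fitted_lq_model
        import copy

        m2 = copy.deepcopy(model)
        victim = m2.variables[-1]
        for j, f in enumerate(m2.meta):
            if f.variable == victim:
                m2.coef[j] = 0.0
        contrib = mx.variable_contribution(m2, table, method="drop")
        assert contrib.set_index("variable").loc[victim, "drop_pct"] == pytest.approx(0.0)

    def test_positive_linear_model_has_increasing_response(self):
        pres, bg = gaussian_niche_sample(2, n_pres=300)
        pres["t"] += 10.0  # push presences to the high end: positive slope
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("L"))
        curve = mx.response_curve(m, "t")
        assert (np.diff(curve["suitability"]) >= -1e-12).all()
        assert curve["suitability"].between(0, 1).all()

    def test_lq_response_peaks_at_analytic_optimum(self):
        pres, bg = gaussian_niche_sample(4)
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        opt = recovered_optimum(m)
        curve = mx.response_curve(m, "t", grid=200)
        peak = curve["t"].iloc[curve["suitability"].idxmax()]
        step = curve["t"].iloc[1] - curve["t"].iloc[0]
        assert abs(peak - opt) <= step

    def test_unknown_variable_rejected(self, fitted_lq_model):
        model, _, _ = fitted_lq_model
        with pytest.raises(KeyError):
            mx.response_curve(model, "nope")


class TestNicheEnvelope:
    def test_subthreshold_response_gives_empty_envelope(self):
        pres, bg = gaussian_niche_sample(5)
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        env = mx.niche_envelope(m, cut=0.999999)
        assert env["intervals"]["t"] == []

    def test_gaussian_niche_envelope_contains_true_optimum(self):
        pres, bg = gaussian_niche_sample(6)
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        env = mx.niche_envelope(m, cut=0.5)
        assert any(lo <= 8.0 <= hi for lo, hi in env["intervals"]["t"])

    def test_envelope_endpoints_match_dense_crossing_search(self):
        pres, bg = gaussian_niche_sample(8)
        m = mx.fit_maxent(pres, bg, mx.FeatureSpec("LQ"))
        env = mx.niche_envelope(m, cut=0.5, grid=512)
        dense = mx.response_curve(m, "t", grid=20_000)
        above = dense["suitability"].values >= 0.5
        x = dense["t"].values
        lo_dense = x[above][0]
        hi_dense = x[above][-1]
        (lo, hi) = env["intervals"]["t"][0]
        gap = (x[-1] - x[0]) / 512
        assert abs(lo - lo_dense) < gap and abs(hi - hi_dense) < gap

    def test_pairwise_surfaces_cover_variable_pairs(self, fitted_lq_model):
        model, _, _ = fitted_lq_model
        env = mx.niche_envelope(model, pair_grid=15)
        n = len(model.variables)
        assert len(env["surfaces"]) == n * (n - 1) // 2
        for surf in env["surfaces"].values():
            assert surf["suitability"].shape == (15, 15)
            assert ((surf["suitability"] >= 0) & (surf["suitability"] <= 1)).all()
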