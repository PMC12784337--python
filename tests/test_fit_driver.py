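import numpy as np
import pytest

from gmr3 import FitOptions, fit, gen_study1, initialize, predict, rmse
from gmr3.fit_driver import FitResult, build_phi, classify_ordinal, identify, transform_new
from gmr3.model_spec import DataError, Dataset, VariableSpec
from gmr3.optimal_scaling import Quantification

from conftest import make_numeric_dataset


def closed_form_rrr(Phi, Y, S):
    """Classical reduced-rank regression on centered responses."""
    Yc = Y - Y.mean(axis=0)
    C = np.linalg.lstsq(Phi, Yc, rcond=None)[0]
    _, _, Qt = np.linalg.svd(Phi @ C, full_matrices=False)
    V = Qt[:S].T
    return C @ V @ V.T


class TestInitialize:
    def test_all_numeric_start_is_classical_rrr(self, rng):
        ds, _ = make_numeric_dataset(rng, N=150, P=5, R=4, S=2)
        start = initialize(ds, 2)
        Phi = build_phi(ds, start.quantifications, start.train_stats)
        Ystd = (ds.Y - ds.Y.mean(0)) / ds.Y.std(0)
        A_expected = closed_form_rrr(Phi, Ystd, 2)
        np.testing.assert_allclose(start.A, A_expected, atol=1e-8)

    def test_pure_noise_has_small_singular_values(self, rng):
        X = rng.standard_normal((3000, 4))
        Y = rng.standard_normal((3000, 3))
        ds = Dataset(
            X=X, Y=Y,
            predictor_specs=[VariableSpec(f"x{j}", "predictor", "numeric") for j in range(4)],
            response_specs=[VariableSpec(f"y{r}", "response", "numeric") for r in range(3)],
        )
        start = initialize(ds, 2)
        assert np.linalg.svd(start.A, compute_uv=False)[0] < 0.1

    def test_ordinal_threshold_start_is_cumulative_logit(self):
        Y = np.repeat([1, 2, 3, 4], 10).astype(float)[:, None]
        X = np.linspace(-1, 1, 40)[:, None] + np.arange(40)[:, None] * 0.01
        ds = Dataset(
            X=X, Y=Y,
            predictor_specs=[VariableSpec("x", "predictor", "numeric")],
            response_specs=[VariableSpec("y", "response", "ordinal", 4)],
        )
        start = initialize(ds, 1)
        np.testing.assert_allclose(start.thresholds[0], [-1.0986123, 0, 1.0986123], atol=1e-6)

    def test_underdetermined_rejected(self, rng):
        ds, _ = make_numeric_dataset(rng, N=150, P=5, R=4)
        ds_small = Dataset(X=ds.X[:5], Y=ds.Y[:5],
                           predictor_specs=ds.predictor_specs,
                           response_specs=ds.response_specs)
        with pytest.raises(DataError):
            initialize(ds_small, 2)


class TestFit:
    def test_all_numeric_matches_closed_form_rrr(self, rng):
        ds, _ = make_numeric_dataset(rng, N=200, P=5, R=4, S=2)
        res = fit(ds, FitOptions(rank=2, tol=1e-12, max_iter=5000))
        Phi = build_phi(ds, res.quantifications, res.train_stats)
        np.testing.assert_allclose(res.A, closed_form_rrr(Phi, ds.Y, 2), atol=1e-6)

    def test_full_rank_numeric_equals_multivariate_regression(self, rng):
        ds, _ = make_numeric_dataset(rng, N=120, P=3, R=3, S=2)
        res = fit(ds, FitOptions(rank=3, tol=1e-12, max_iter=5000))
        Phi = build_phi(ds, res.quantifications, res.train_stats)
        C = np.linalg.lstsq(Phi, ds.Y - ds.Y.mean(0), rcond=None)[0]
        np.testing.assert_allclose(res.A, C, atol=1e-6)

    def test_single_binary_response_is_logistic_regression(self, rng):
        import statsmodels.api as sm

        N = 250
        X = rng.standard_normal((N, 3))
        eta = 0.4 + X @ np.array([0.9, -0.6, 0.2])
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        ds = Dataset(
            X=X, Y=y[:, None],
            predictor_specs=[VariableSpec(f"x{j}", "predictor", "numeric") for j in range(3)],
            response_specs=[VariableSpec("y", "response", "binary", 2)],
        )
        res = fit(ds, FitOptions(rank=1, tol=1e-10, max_iter=5000))
        Phi = build_phi(ds, res.quantifications, res.train_stats)
        ref = sm.Logit(y, sm.add_constant(Phi)).fit(disp=0)
        assert res.nll == pytest.approx(-ref.llf, abs=1e-6)

    def test_single_ordinal_response_is_proportional_odds(self, rng):
        from scipy.special import expit
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        N = 250
        X = rng.standard_normal((N, 3))
        eta = X @ np.array([0.9, -0.6, 0.2])
        cum = expit(np.array([-1.0, 0.0, 1.0])[None, :] - eta[:, None])
        y = (rng.uniform(size=N)[:, None] > cum).sum(axis=1) + 1.0
        ds = Dataset(
            X=X, Y=y[:, None],
            predictor_specs=[VariableSpec(f"x{j}", "predictor", "numeric") for j in range(3)],
            response_specs=[VariableSpec("y", "response", "ordinal", 4)],
        )
        res = fit(ds, FitOptions(rank=1, tol=1e-11, max_iter=8000))
        Phi = build_phi(ds, res.quantifications, res.train_stats)
        ref = OrderedModel(y, Phi, distr="logit").fit(method="bfgs", disp=0, gtol=1e-10)
        assert res.nll == pytest.approx(-ref.llf, abs=1e-5)

    @pytest.mark.parametrize("scenario", ["cond1", "gmr3-p2", "gmr3-r1", "gmr3-pr"])
    def test_monotone_descent_across_scenarios(self, scenario):
        sim = gen_study1(scenario, N=200, seed=11)
        res = fit(sim.dataset, FitOptions(rank=2))
        trace = np.asarray(res.nll_trace)
        assert np.all(np.diff(trace) <= 1e-8)
        assert res.converged

    def test_recovery_improves_with_sample_size(self):
        medians = []
        for N in (250, 1000):
            errs = [
                rmse(sim.A_true, fit(sim.dataset, FitOptions(rank=2)).A)
                for sim in (gen_study1("cond1", N=N, seed=500 + i) for i in range(20))
            ]
            medians.append(np.median(errs))
        assert medians[1] < medians[0]

    def test_warm_start_reaches_same_solution(self, rng):
        sim = gen_study1("gmr3-pr", N=200, seed=21)
        cold = fit(sim.dataset, FitOptions(rank=2, tol=1e-9))
        warm = fit(sim.dataset, FitOptions(rank=2, tol=1e-9), start=cold)
        assert warm.nll == pytest.approx(cold.nll, abs=1e-6)
        assert warm.n_iter <= cold.n_iter


class TestIdentify:
    def test_invariants_after_fit(self):
        sim = gen_study1("gmr3-pr", N=200, seed=31)
        res = fit(sim.dataset, FitOptions(rank=2))
        Phi = build_phi(sim.dataset, res.quantifications, res.train_stats)
        U = Phi @ res.B
        UtU = U.T @ U
        np.testing.assert_allclose(res.V.T @ res.V, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(UtU - np.diag(np.diag(UtU)), 0, atol=1e-8)
        assert np.diff(np.diag(UtU)).max() <= 1e-8  # non-increasing

    def test_rotation_leaves_A_invariant(self, rng):
        B = rng.standard_normal((4, 2))
        V = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        res = FitResult(m=np.zeros(5), B=B.copy(), V=V.copy(), thresholds={},
                        sigma2=None, quantifications=[])
        Phi = rng.standard_normal((30, 4))
        A_old = res.A.copy()
        identify(res, Phi)
        np.testing.assert_allclose(res.A, A_old, atol=1e-12)
        for s in range(2):
            assert res.V[np.argmax(np.abs(res.V[:, s])), s] > 0

    def test_multistart_agreement(self):
        """Different generated starts land on the same identified solution."""
        sim = gen_study1("gmr3-pr", N=300, seed=41)
        res1 = fit(sim.dataset, FitOptions(rank=2, tol=1e-11, max_iter=5000))
        # perturbed warm start: same data, different initial rotation
        start = initialize(sim.dataset, 2)
        rng = np.random.default_rng(5)
        Q = np.linalg.qr(rng.standard_normal((2, 2)))[0]
        start.B, start.V = start.B @ Q, start.V @ Q
        start.B += 0.1 * rng.standard_normal(start.B.shape)
        res2 = fit(sim.dataset, FitOptions(rank=2, tol=1e-11, max_iter=5000), start=start)
        np.testing.assert_allclose(res1.B, res2.B, atol=1e-4)
        np.testing.assert_allclose(res1.V, res2.V, atol=1e-4)


class TestPredict:
    def worked_example_fit(self):
        """A FitResult carrying the published survey coefficients."""
        A = np.array([
            [-0.16, -0.27, -0.05, 0.06, 0.17, 0.50, 0.23],
            [-0.63, -0.28, -0.60, -0.22, -0.38, 0.11, -0.31],
            [-0.06, 0.06, -0.10, -0.07, -0.15, -0.19, -0.16],
            [0.21, 0.08, 0.21, 0.08, 0.14, -0.01, 0.12],
            [0.34, 0.17, 0.31, 0.11, 0.18, -0.10, 0.14],
        ])
        # factor A exactly via its SVD (the printed matrix has full numerical
        # rank; the factorization only serves the prediction interface here)
        P_, lam, Qt = np.linalg.svd(A)
        B = P_[:, :5] * lam[:5]
        V = Qt[:5].T
        m = np.array([0.45, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        resp = [
            VariableSpec("T", "response", "binary", 2),
            VariableSpec("FE", "response", "binary", 2),
        ] + [VariableSpec(n, "response", "ordinal", 4) for n in ("CI", "MW", "FS", "DI", "RE")]
        pred = [
            VariableSpec("A", "predictor", "numeric"),
            VariableSpec("PA", "predictor", "ordinal", 3),
            VariableSpec("G", "predictor", "binary", 2),
            VariableSpec("U", "predictor", "ordinal", 3),
            VariableSpec("E", "predictor", "ordinal", 9),
        ]
        quants = [
            None,
            Quantification(np.array([-1.13, 0.36, 1.31]), "ordinal", "increasing"),
            Quantification(np.array([-0.72, 1.39]), "binary"),
            Quantification(np.array([-0.64, -0.44, 1.82]), "ordinal", "increasing"),
            Quantification(np.array([-1.4, -1.3, -0.8, -0.7, 0.2, 0.25, 0.32, 0.4, 2.0]),
                           "ordinal", "increasing"),
        ]
        thresholds = {2: np.array([-2.57, -0.91, 1.80])}
        for r in (3, 4, 5, 6):
            thresholds[r] = np.array([-1.0, 0.0, 1.0])
        return FitResult(
            m=m, B=B, V=V, thresholds=thresholds, sigma2=None,
            quantifications=quants, predictor_specs=pred, response_specs=resp,
            train_stats=[(47.0, 18.0), None, None, None, None],
        )

    def test_worked_profile_class_and_probability(self):
        res = self.worked_example_fit()
        # 70-year-old woman, left, rural, bachelor: age standardizes to 1.2778
        # with the synthetic training stats; the published quantifications give
        # the rest of the profile directly
        X_new = np.array([[70.0, 1, 2, 1, 7]])
        out = predict(res, X_new)
        phi = transform_new(res, X_new)
        np.testing.assert_allclose(phi[0, 1:], [-1.13, 1.39, -0.64, 0.32], atol=1e-12)
        theta_T = float(out["theta"][0, 0])
        assert abs(theta_T - (0.45 + phi[0] @ res.A[:, 0])) < 1e-10
        ci = out["responses"]["CI"]
        theta_ci = float(out["theta"][0, 2])
        expected_class = 1 + int(np.sum(np.array([-2.57, -0.91, 1.80]) <= theta_ci))
        assert ci["class"][0] == expected_class

    def test_unseen_category_rejected(self):
        res = self.worked_example_fit()
        with pytest.raises(DataError, match="PA"):
            predict(res, np.array([[30.0, 4, 1, 1, 1]]))

    def test_classification_boundary_is_half_open(self):
        t = np.array([-1.0, 0.5, 2.0])
        assert classify_ordinal(-1.0, t)[0] == 2  # theta == t_1 -> class 2
        assert classify_ordinal(-1.0 - 1e-12, t)[0] == 1
        assert classify_ordinal(5.0, t)[0] == 4
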