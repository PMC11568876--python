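"""Functional network: spline properties, exact reductions, gradients."""

import numpy as np
import pytest

from kfnet import fnn, simulate
from kfnet.basis import BasisSystem
from kfnet.fnn import FunctionalCurve


@pytest.fixture(scope="module")
def gene():
    return simulate.sim_genotypes(120, 30, (0.1, 0.5), ld_rho=0.3, seed=55)


@pytest.fixture(scope="module")
def input_basis():
    return BasisSystem(knots=8, order=4)


@pytest.fixture(scope="module")
def curves(gene, input_basis):
    return fnn.smooth_genotypes(gene, input_basis, 1e-6)


class TestBasisSystem:
    @pytest.mark.parametrize("knots,order", [(0, 4), (5, 4), (12, 3), (7, 2)])
    def test_partition_of_unity(self, knots, order):
        b = BasisSystem(knots=knots, order=order)
        t = np.linspace(0, 1, 301)
        np.testing.assert_allclose(b.evaluate(t).sum(axis=1), 1.0, atol=1e-10)

    def test_local_support(self):
        b = BasisSystem(knots=10, order=4)
        t = np.linspace(0, 1, 400)
        B = b.evaluate(t)
        # each basis function is supported on at most `order` knot spans
        span = 1.0 / 11
        for j in range(b.dim):
            nz = t[B[:, j] > 1e-12]
            assert nz.max() - nz.min() <= 4 * span + 1e-9

    def test_dimension_is_knots_plus_order(self):
        assert BasisSystem(knots=100, order=4).dim == 104

    def test_second_derivative_gram_vs_numerical_quadrature(self):
        """Penalty Gram matrices against direct numerical integration."""
        from scipy.integrate import quad
        b = BasisSystem(knots=3, order=4)
        G = b.gram(2, 2)
        for i in [0, 2, 4]:
            for j in [0, 2, 4]:
                val, _ = quad(
                    lambda t: b.evaluate(np.array([t]), 2)[0, i]
                    * b.evaluate(np.array([t]), 2)[0, j],
                    0, 1, limit=200,
                )
                assert G[i, j] == pytest.approx(val, abs=1e-8)

    def test_affine_functions_have_zero_penalty(self):
        b = BasisSystem(knots=6, order=4)
        t = np.linspace(0, 1, 200)
        B = b.evaluate(t)
        # project 2 + 3t onto the basis (exact: affine is in the span)
        c, *_ = np.linalg.lstsq(B, 2 + 3 * t, rcond=None)
        assert c @ b.gram(2, 2) @ c == pytest.approx(0.0, abs=1e-8)


class TestSmoothGenotypes:
    def test_constant_row_fits_constant_curve(self, input_basis):
        x = simulate.sim_genotypes(2, 30, seed=1)
        d = np.full_like(x.dosages, 2.0)
        x = type(x)(x.samples, x.variants, d)
        curves = fnn.smooth_genotypes(x, input_basis, 1e-8)
        grid = np.linspace(0, 1, 50)
        np.testing.assert_allclose(curves(grid), 2.0, atol=1e-6)

    def test_huge_penalty_forces_straight_line(self, gene, input_basis):
        curves = fnn.smooth_genotypes(gene, input_basis, 1e8)
        grid = np.linspace(0.05, 0.95, 60)
        vals = curves(grid)
        # second differences of an affine function vanish
        d2 = np.diff(vals, n=2, axis=1)
        assert np.abs(d2).max() < 1e-3

    def test_richer_basis_reduces_approximation_error(self):
        """Nested-model oracle: more basis functions fit a smooth dosage
        trend better in integrated squared error."""
        rng = np.random.default_rng(3)
        n, p = 2000, 30
        x = simulate.sim_genotypes(n, p, seed=4)
        bp = np.array([v.bp_pos for v in x.variants], dtype=float)
        t = (bp - bp[0]) / (bp[-1] - bp[0])
        prob = 0.5 + 0.4 * np.sin(2 * np.pi * t)
        d = rng.binomial(2, np.tile(prob, (n, 1))).astype(float)
        x = type(x)(x.samples, x.variants, d)
        grid = np.linspace(0, 1, 200)
        target = 2 * (0.5 + 0.4 * np.sin(2 * np.pi * grid))
        err = {}
        for knots in (0, 8):
            cur = fnn.smooth_genotypes(x, BasisSystem(knots=knots, order=4),
                                       1e-9)
            # mean of fitted curves = fit of the mean dosage (linear smoother)
            err[knots] = np.mean((cur(grid).mean(axis=0) - target) ** 2)
        assert err[8] < err[0]

    def test_missing_dosages_omitted_from_fit(self, input_basis):
        x = simulate.sim_genotypes(5, 30, seed=6)
        d = x.dosages.copy()
        d[2, 10:13] = np.nan
        xm = type(x)(x.samples, x.variants, d)
        cm = fnn.smooth_genotypes(xm, input_basis, 1e-4)
        c0 = fnn.smooth_genotypes(x, input_basis, 1e-4)
        # other samples unaffected; sample 2 still finite
        np.testing.assert_allclose(cm.coefs[0], c0.coefs[0], atol=1e-12)
        assert np.isfinite(cm.coefs[2]).all()

    def test_underdetermined_without_penalty_rejected(self):
        x = simulate.sim_genotypes(3, 5, seed=7)
        with pytest.raises(ValueError, match="underdetermined"):
            fnn.smooth_genotypes(x, BasisSystem(knots=8), 0.0)


class TestForward:
    def test_zero_parameters_give_zero_output(self, curves, input_basis):
        model = fnn.init_fnn(input_basis, hidden_knots=(5, 4), seed=0)
        for d in range(len(model.W)):
            model.W[d] = np.zeros_like(model.W[d])
            model.a0[d] = np.zeros_like(model.a0[d])
        model.w_out = np.zeros_like(model.w_out)
        model.a0_out = 0.0
        np.testing.assert_allclose(fnn.forward(model, curves), 0.0, atol=1e-14)

    def test_constant_intercept_ignores_input(self, curves, input_basis):
        """With zero weight kernels the output is the same for every
        sample, regardless of its genotype curve."""
        model = fnn.init_fnn(input_basis, hidden_knots=(5,), seed=1,
                             activation="identity")
        model.W[0] = np.zeros_like(model.W[0])
        f = fnn.forward(model, curves)
        np.testing.assert_allclose(f, f[0], atol=1e-10)

    def test_single_linear_layer_equals_functional_linear_model(
        self, curves, input_basis
    ):
        """Exact reduction: embed a fitted FLM into a one-layer
        identity-activation network and compare predictions."""
        rng = np.random.default_rng(8)
        y = rng.standard_normal(curves.coefs.shape[0])
        flm = fnn.fit_flm(curves, y, lam=1e-6)
        oracle = fnn.predict_flm(flm, curves)

        model = fnn.init_fnn(input_basis, hidden_knots=(6,), seed=2,
                             activation="identity")
        b1 = model.bases[1]
        J1 = b1.gram(0, 0)
        # pick u with <u, w_out>_J = 1, then W = u alpha^T reproduces
        # f = a0_out + <alpha, J0 c> for every input curve
        w = model.w_out
        u = w / float(w @ J1 @ w)
        alpha = flm["coef"][1 : 1 + input_basis.dim]
        model.W[0] = np.outer(u, alpha)
        model.a0[0] = np.zeros(b1.dim)
        model.a0_out = float(flm["coef"][0])
        got = fnn.forward(model, curves)
        np.testing.assert_allclose(got, oracle, atol=1e-6)


class TestLossAndPenalty:
    def test_zero_lambda_is_pure_data_loss(self, curves, input_basis):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(curves.coefs.shape[0])
        model = fnn.init_fnn(input_basis, hidden_knots=(5,), seed=3)
        f = fnn.forward(model, curves)
        assert fnn.loss(model, curves, y, lam=0.0) == pytest.approx(
            np.mean((f - y) ** 2)
        )

    def test_perfect_prediction_zero_loss(self, curves, input_basis):
        model = fnn.init_fnn(input_basis, hidden_knots=(5,), seed=4)
        y = fnn.forward(model, curves)
        assert fnn.loss(model, curves, y, lam=0.0) == pytest.approx(0.0)

    def test_affine_parameter_functions_have_zero_penalty(self, input_basis):
        model = fnn.init_fnn(input_basis, hidden_knots=(5, 4), seed=5)
        for d in range(len(model.W)):
            bs, bt = model.bases[d + 1], model.bases[d]
            ts = np.linspace(0, 1, 200)
            Bs, Bt = bs.evaluate(ts), bt.evaluate(ts)
            cs, *_ = np.linalg.lstsq(Bs, 1 + 2 * ts, rcond=None)
            ct, *_ = np.linalg.lstsq(Bt, 3 - ts, rcond=None)
            model.W[d] = np.outer(cs, ct)  # affine x affine surface
            model.a0[d] = cs
        blast = model.bases[-1]
        Bl = blast.evaluate(np.linspace(0, 1, 200))
        cl, *_ = np.linalg.lstsq(Bl, np.linspace(0, 1, 200), rcond=None)
        model.w_out = cl
        assert fnn.penalty(model) == pytest.approx(0.0, abs=1e-7)

    def test_cross_entropy_label_domain(self, curves, input_basis):
        model = fnn.init_fnn(input_basis, hidden_knots=(5,), binary=True,
                             seed=6)
        with pytest.raises(ValueError, match="0/1"):
            fnn.loss(model, curves, np.full(curves.coefs.shape[0], 2.0))


class TestGradient:
    @pytest.mark.parametrize("binary", [False, True])
    def test_matches_central_finite_differences(self, curves, input_basis,
                                                binary):
        rng = np.random.default_rng(10)
        n = curves.coefs.shape[0]
        y = (rng.standard_normal(n) > 0).astype(float) if binary \
            else rng.standard_normal(n)
        Z = rng.standard_normal((n, 2))
        model = fnn.init_fnn(input_basis, hidden_knots=(5, 4),
                             n_covariates=2, binary=binary, seed=7)
        lam = 0.03
        _, grads = fnn.grad(model, curves, y, Z, lam=lam)
        params = model.parameters()
        checked = 0
        for name, p in params.items():
            arr = np.atleast_1d(np.asarray(p, float))
            for ii in rng.choice(arr.size, size=min(5, arr.size),
                                 replace=False):
                eps = 1e-6
                for sign, store in ((1, "lp"), (-2, "lm")):
                    arr.flat[ii] += sign * eps
                    pp = dict(params)
                    pp[name] = arr if np.ndim(p) else float(arr[0])
                    model.set_parameters(pp)
                    if store == "lp":
                        lp = fnn.loss(model, curves, y, Z, lam)
                    else:
                        lm = fnn.loss(model, curves, y, Z, lam)
                arr.flat[ii] += eps
                model.set_parameters(params)
                fd = (lp - lm) / (2 * eps)
                an = np.atleast_1d(np.asarray(grads[name], float)).flat[ii]
                assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an), 1e-6)
                checked += 1
        assert checked >= 25


class TestTrain:
    def _data(self, gene, input_basis, signal="linear", n=120):
        y = simulate.sim_fnn_phenotype(gene, signal, snr=1.0, seed=77)
        y = (y - y.mean()) / y.std()
        curves = fnn.smooth_genotypes(gene, input_basis, 1e-6)
        C = curves.coefs
        tr = FunctionalCurve(input_basis, C[:80])
        va = FunctionalCurve(input_basis, C[80:])
        return (tr, y[:80]), (va, y[80:])

    def test_training_reduces_loss_and_is_deterministic(self, gene,
                                                        input_basis):
        train_d, valid_d = self._data(gene, input_basis)
        kw = dict(lambdas=(1e-3,), epochs=120, lr=1e-2, seed=5)
        factory = lambda s: fnn.init_fnn(input_basis, hidden_knots=(5, 4),
                                         seed=s)  # noqa: E731
        _, lam1, h1 = fnn.train(factory, train_d, valid_d, **kw)
        _, lam2, h2 = fnn.train(factory, train_d, valid_d, **kw)
        rec1 = h1["lambdas"][1e-3]
        rec2 = h2["lambdas"][1e-3]
        assert rec1["final_train_loss"] <= rec1["initial_train_loss"]
        assert rec1["final_train_loss"] == rec2["final_train_loss"]
        assert lam1 == lam2

    def test_lambda_selected_by_validation_loss(self, gene, input_basis):
        train_d, valid_d = self._data(gene, input_basis)
        _, lam, hist = fnn.train(
            lambda s: fnn.init_fnn(input_basis, hidden_knots=(5,), seed=s),
            train_d, valid_d, lambdas=(1e-4, 1e0), epochs=80, lr=1e-2, seed=3,
        )
        losses = {k: v["valid_loss"] for k, v in hist["lambdas"].items()}
        assert lam == min(losses, key=losses.get)

    def test_large_lambda_flattens_learned_functions(self, gene, input_basis):
        """Curvature of the learned parameter functions decreases along an
        increasing penalty grid."""
        train_d, valid_d = self._data(gene, input_basis)
        curv = []
        for lam in (1e-3, 1e-1, 1e1, 1e3):
            res = fnn._train_one(
                lambda s: fnn.init_fnn(input_basis, hidden_knots=(5,), seed=s),
                train_d[0].coefs, None, train_d[1], lam, 150, 1e-2, 4,
            )
            m = res["model"]
            grid = np.linspace(0, 1, 120)
            mx = 0.0
            for d in range(len(m.W)):
                B2s = m.bases[d + 1].evaluate(grid, 2)
                B2t = m.bases[d].evaluate(grid, 2)
                mx = max(mx, np.abs(B2s @ m.a0[d]).max())
                mx = max(mx, np.abs(B2s @ m.W[d] @
                                    m.bases[d].evaluate(grid).T).max())
                mx = max(mx, np.abs(m.bases[d + 1].evaluate(grid) @ m.W[d]
                                    @ B2t.T).max())
            mx = max(mx, np.abs(m.bases[-1].evaluate(grid, 2)
                                @ m.w_out).max())
            curv.append(mx)
        assert all(b <= a * 1.05 for a, b in zip(curv, curv[1:]))

    def test_linear_signal_matches_flm_oracle(self, input_basis):
        """On a purely linear functional signal the trained 1-layer network
        reaches the closed-form FLM's test correlation within sampling
        error."""
        diffs = []
        for seed in range(5):
            x = simulate.sim_genotypes(300, 30, seed=200 + seed)
            y = simulate.sim_fnn_phenotype(x, "linear", snr=1.0,
                                           seed=300 + seed)
            y = (y - y.mean()) / y.std()
            curves = fnn.smooth_genotypes(x, input_basis, 1e-6)
            C = curves.coefs
            cv = lambda sl: FunctionalCurve(input_basis, C[sl])  # noqa: E731
            model, _, _ = fnn.train(
                lambda s: fnn.init_fnn(input_basis, hidden_knots=(6,),
                                       seed=s),
                (cv(slice(0, 160)), y[:160]),
                (cv(slice(160, 220)), y[160:220]),
                lambdas=(1e-3,), epochs=800, lr=2e-2, seed=seed,
            )
            f_fnn = fnn.forward(model, cv(slice(220, 300)))
            flm = fnn.fit_flm(cv(slice(0, 160)), y[:160], lam=1e-4)
            f_flm = fnn.predict_flm(flm, cv(slice(220, 300)))
            c_fnn = np.corrcoef(f_fnn, y[220:])[0, 1]
            c_flm = np.corrcoef(f_flm, y[220:])[0, 1]
            diffs.append(c_fnn - c_flm)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert diffs.mean() >= -3 * se - 0.05
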