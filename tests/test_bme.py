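"""Maximum-entropy reweighting: objective, solver, scans, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpens import bme, forward
from idpens.core import ObservableSet, ValidationError
from idpens.forward import ForwardMatrix


def linear_problem(n, m, rng, sigma=0.5, kind="CS"):
    F = rng.normal(size=(n, m))
    y = rng.normal(size=m)
    meta = pd.DataFrame({"resid": range(m), "atom": ["CA"] * m})
    obs = ObservableSet(kind, y, np.full(m, sigma), meta)
    return ForwardMatrix(kind, F, obs), obs


class TestChi2:
    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(0)
        fm, obs = linear_problem(4, 3, rng)
        w = np.full(4, 0.25)
        obs.values[:] = w @ fm.matrix
        assert bme.chi2(w, fm, obs) == pytest.approx(0.0, abs=1e-20)

    def test_unit_residual(self):
        meta = pd.DataFrame({"resid": [0], "atom": ["CA"]})
        obs = ObservableSet("CS", np.array([1.0]), np.array([0.5]), meta)
        fm = ForwardMatrix("CS", np.array([[1.5]]), obs)
        assert bme.chi2(np.array([1.0]), fm, obs) == pytest.approx(1.0)

    def test_against_brute_force_summation(self):
        rng = np.random.default_rng(3)
        fm, obs = linear_problem(6, 4, rng)
        w = rng.dirichlet(np.ones(6))
        brute = 0.0
        for mcol in range(4):
            avg = sum(w[i] * fm.matrix[i, mcol] for i in range(6))
            brute += ((avg - obs.values[mcol]) / obs.sigmas[mcol]) ** 2
        assert bme.chi2(w, fm, obs) == pytest.approx(brute, abs=1e-10)

    def test_misaligned_shapes(self):
        rng = np.random.default_rng(0)
        fm, obs = linear_problem(4, 3, rng)
        _, obs2 = linear_problem(4, 2, rng)
        with pytest.raises(ValidationError):
            bme.chi2(np.full(4, 0.25), fm, obs2)


class TestSrel:
    def test_identity(self):
        w = np.array([0.2, 0.8])
        assert bme.srel(w, w) == pytest.approx(0.0)

    def test_hand_case_collapse_to_one(self):
        s = bme.srel([1.0, 0.0], [0.5, 0.5])
        assert s == pytest.approx(-np.log(2))
        assert np.exp(s) == pytest.approx(0.5)

    def test_support_violation(self):
        with pytest.raises(ValidationError):
            bme.srel([0.5, 0.5], [1.0, 0.0])

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_gibbs_inequality(self, n, seed):
        """S_rel <= 0 with equality only at w = w0."""
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(n))
        w0 = rng.dirichlet(np.ones(n))
        s = bme.srel(w, w0)
        assert s <= 1e-12
        if np.abs(w - w0).max() > 1e-6:
            assert s < 0


def grid_min_L(fm, obs, w0, theta, step=0.001):
    """Exhaustive simplex grid search of the BME objective (n <= 3)."""
    n = w0.size
    k = int(round(1.0 / step))
    if n == 2:
        a = np.arange(k + 1) / k
        W = np.stack([a, 1 - a], axis=1)
    elif n == 3:
        pairs = [(i, j) for i in range(k + 1) for j in range(k + 1 - i)]
        W = np.array([[i / k, j / k, (k - i - j) / k] for i, j in pairs])
    else:
        raise ValueError("grid oracle supports n <= 3")
    avg = W @ fm.matrix
    chi2 = np.sum(((avg - obs.values) / obs.sigmas) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(W > 0, W * np.log(W / w0[None, :]), 0.0)
    srel = -terms.sum(axis=1)
    return float(np.min(0.5 * chi2 - theta * srel))


class TestBmeSolve:
    def test_matches_simplex_grid_search(self):
        rng = np.random.default_rng(11)
        for _ in range(4):
            n = int(rng.integers(2, 4))
            m = int(rng.integers(1, 4))
            fm, obs = linear_problem(n, m, rng)
            w0 = np.full(n, 1.0 / n)
            theta = float(rng.uniform(0.3, 3.0))
            res = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, bme.ReweightConfig(theta=theta))
            d = res.diagnostics
            L = 0.5 * d.chi2_total - theta * d.srel
            assert L <= grid_min_L(fm, obs, w0, theta) + 1e-4

    def test_prior_dominated_limit(self):
        rng = np.random.default_rng(2)
        fm, obs = linear_problem(30, 5, rng)
        w0 = np.full(30, 1 / 30)
        res = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, bme.ReweightConfig(theta=1e6))
        assert np.abs(res.weights - w0).max() < 1e-3
        assert res.diagnostics.neff > 0.999

    def test_self_consistent_data_keeps_prior(self):
        rng = np.random.default_rng(5)
        fm, obs = linear_problem(20, 6, rng)
        w0 = np.full(20, 0.05)
        obs.values[:] = w0 @ fm.matrix  # zero-noise prior-generated data
        res = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, bme.ReweightConfig(theta=10.0))
        assert res.diagnostics.neff >= 0.999
        assert res.diagnostics.chi2_total < 1e-6

    def test_posterior_has_exponential_form(self):
        """log(w*/w0) lies in the row space of F (plus a constant)."""
        rng = np.random.default_rng(8)
        fm, obs = linear_problem(25, 3, rng)
        w0 = rng.dirichlet(np.ones(25))
        cfg = bme.ReweightConfig(theta=2.0, tol=1e-16, gtol=1e-13, max_iter=20_000)
        res = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, cfg)
        y = np.log(res.weights / w0)
        X = np.column_stack([fm.matrix, np.ones(25)])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-6

    def test_neff_srel_identity(self):
        rng = np.random.default_rng(9)
        fm, obs = linear_problem(10, 2, rng)
        res = bme.bme_solve(
            {"CS": fm}, {"CS": obs}, np.full(10, 0.1), bme.ReweightConfig(theta=1.0)
        )
        d = res.diagnostics
        assert d.neff == pytest.approx(np.exp(d.srel), abs=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        fm, obs = linear_problem(12, 3, rng)
        w0 = np.full(12, 1 / 12)
        cfg = bme.ReweightConfig(theta=1.0)
        a = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, cfg)
        b = bme.bme_solve({"CS": fm}, {"CS": obs}, w0, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_rejects_validation_kind_as_restraint(self):
        rng = np.random.default_rng(0)
        fm, obs = linear_problem(4, 2, rng, kind="CS")
        fm_pre = ForwardMatrix("CS", fm.matrix, obs)
        with pytest.raises(ValidationError):
            bme.bme_solve({"PRE": fm_pre}, {"PRE": obs}, np.full(4, 0.25), bme.ReweightConfig())


def toy_scan_problem(seed=0, n=40):
    """Small reweighting problem with informative data away from the prior."""
    rng = np.random.default_rng(seed)
    feature = rng.normal(size=n)
    F = np.column_stack([feature, feature**2, rng.normal(size=n)])
    w0 = np.full(n, 1.0 / n)
    w_true = np.exp(0.8 * feature)
    w_true /= w_true.sum()
    y = w_true @ F + rng.normal(size=3) * 0.02
    meta = pd.DataFrame({"resid": range(3), "atom": ["CA"] * 3})
    obs = ObservableSet("CS", y, np.full(3, 0.02), meta)
    return {"CS": ForwardMatrix("CS", F, obs)}, {"CS": obs}, w0


class TestThetaScan:
    def test_chi2_and_neff_nonincreasing(self):
        forwards, observables, w0 = toy_scan_problem()
        cfg = bme.ReweightConfig(theta_grid=np.geomspace(100, 0.01, 10))
        curve = bme.theta_scan(forwards, observables, w0, cfg)
        chi = curve.column("chi2_total")
        neff = np.array([d.neff for d in curve.diagnostics])
        assert np.all(np.diff(chi) <= np.abs(chi[:-1]) * 1e-6 + 1e-9)
        assert np.all(np.diff(neff) <= neff[:-1] * 1e-6 + 1e-9)

    def test_largest_theta_near_prior(self):
        forwards, observables, w0 = toy_scan_problem()
        cfg = bme.ReweightConfig(theta_grid=np.geomspace(1e5, 1.0, 6))
        curve = bme.theta_scan(forwards, observables, w0, cfg)
        assert curve.diagnostics[0].neff > 0.999

    def test_ascending_grid_rejected(self):
        forwards, observables, w0 = toy_scan_problem()
        with pytest.raises(ValidationError):
            bme.ReweightConfig(theta_grid=np.array([1.0, 10.0]))


def synthetic_curve(thetas, chi2s, neffs, pre=None):
    diags = []
    for i in range(len(thetas)):
        d = bme.FitDiagnostics(
            chi2_by_kind={"CS": float(chi2s[i])},
            n_points={"CS": 1},
            omega=1.0,
            srel=float(np.log(neffs[i])),
            pre_score=None if pre is None else float(pre[i]),
        )
        diags.append(d)
    return bme.ScanCurve(thetas=np.asarray(thetas, float), diagnostics=diags, results=[None] * len(thetas))


class TestSelectTheta:
    def test_constructed_corner_found(self):
        # sharp L: chi2 falls fast then flattens; neff flat then falls
        thetas = np.array([1000, 300, 100, 30, 10, 3, 1], dtype=float)
        chi2s = np.array([1e4, 2e3, 4e2, 1e2, 80, 70, 65])
        neffs = np.array([0.95, 0.93, 0.9, 0.85, 0.5, 0.2, 0.05])
        curve = synthetic_curve(thetas, chi2s, neffs)
        assert bme.select_theta(curve, "elbow") == pytest.approx(30.0)

    def test_straight_tradeoff_warns(self):
        thetas = np.geomspace(100, 1, 6)
        chi2s = np.geomspace(1e4, 1e2, 6)
        neffs = np.geomspace(0.9, 0.1, 6)
        curve = synthetic_curve(thetas, chi2s, neffs)
        with pytest.warns(UserWarning, match="weak elbow"):
            bme.select_theta(curve, "elbow")

    def test_validation_minimum_mode(self):
        # PRE-score valley shaped like the published a03ws scan: minimum at 150
        thetas = np.array([1200, 600, 300, 150, 75, 30, 10], dtype=float)
        chi2s = np.geomspace(5e3, 1e2, 7)
        neffs = np.geomspace(0.95, 0.2, 7)
        pre = np.array([0.40, 0.36, 0.33, 0.31, 0.33, 0.38, 0.45])
        curve = synthetic_curve(thetas, chi2s, neffs, pre)
        assert bme.select_theta(curve, "validation-minimum") == pytest.approx(150.0)

    def test_ties_break_toward_larger_theta(self):
        thetas = np.array([100, 50, 25, 10], dtype=float)
        pre = np.array([0.5, 0.3, 0.3, 0.6])
        curve = synthetic_curve(thetas, np.geomspace(10, 1, 4), np.geomspace(0.9, 0.3, 4), pre)
        assert bme.select_theta(curve, "validation-minimum") == pytest.approx(50.0)

    def test_too_few_points(self):
        curve = synthetic_curve([10, 5, 1], np.ones(3), [0.9, 0.5, 0.1])
        with pytest.raises(ValidationError):
            bme.select_theta(curve, "elbow")


class TestPreValidationScore:
    def _pre_forward(self, ratios_calc, sites, weights_n=3):
        params = forward.PREParams()
        r6 = forward.r6_from_ratio(np.asarray(ratios_calc), params)
        F = np.tile(r6, (weights_n, 1))
        meta = pd.DataFrame({"label_site": sites, "resid": range(len(sites))})
        obs = ObservableSet("PRE", np.asarray(ratios_calc), np.full(len(sites), 0.05), meta)
        return ForwardMatrix("PRE", F, obs)

    def test_exact_match_scores_zero(self):
        fm = self._pre_forward([0.3, 0.6, 0.8, 0.5], [0, 0, 1, 1])
        w = np.full(3, 1 / 3)
        assert bme.pre_validation_score(w, fm) == pytest.approx(0.0, abs=1e-9)

    def test_single_site_uniform_residuals(self):
        fm = self._pre_forward([0.3, 0.5, 0.7], [0, 0, 0])
        fm.observables.values[:] += 0.1  # all residuals 0.1
        w = np.full(3, 1 / 3)
        assert bme.pre_validation_score(w, fm) == pytest.approx(0.1, abs=1e-9)

    def test_two_site_rms_of_rmsds(self):
        fm = self._pre_forward([0.4, 0.4, 0.6, 0.6], [0, 0, 1, 1])
        fm.observables.values[:2] += 0.3
        fm.observables.values[2:] += 0.4
        w = np.full(3, 1 / 3)
        expected = np.sqrt((0.09 + 0.16) / 2)
        assert bme.pre_validation_score(w, fm) == pytest.approx(expected, abs=1e-9)


class TestOmegaScan:
    def test_default_grid_contains_published_value(self):
        assert 75.0 in bme.ReweightConfig().omega_grid

    def test_fret_chi2_nonincreasing_in_omega(self):
        rng = np.random.default_rng(21)
        n = 30
        feature = rng.normal(size=n)
        w0 = np.full(n, 1 / n)
        F_cs = rng.normal(size=(n, 4))
        meta_cs = pd.DataFrame({"resid": range(4), "atom": ["CA"] * 4})
        obs_cs = ObservableSet("CS", w0 @ F_cs + 0.3, np.full(4, 0.1), meta_cs)
        F_fr = 1 / (1 + np.exp(-feature))[:, None]
        meta_fr = pd.DataFrame({"site_a": [0], "site_b": [1], "R0_nm": [5.0]})
        obs_fr = ObservableSet("FRET", np.array([float(w0 @ F_fr[:, 0]) + 0.05]), np.array([0.02]), meta_fr)
        forwards = {
            "CS": ForwardMatrix("CS", F_cs, obs_cs),
            "FRET": ForwardMatrix("FRET", F_fr, obs_fr),
        }
        observables = {"CS": obs_cs, "FRET": obs_fr}
        cfg = bme.ReweightConfig(theta=5.0, omega_grid=(1.0, 5.0, 25.0, 75.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bme.omega_scan(forwards, observables, w0, cfg)
        chis = [d.chi2_by_kind["FRET"] for d in res.diagnostics]
        assert np.all(np.diff(chis) <= np.abs(np.array(chis[:-1])) * 1e-6 + 1e-9)

    def test_no_fret_returns_one(self):
        rng = np.random.default_rng(0)
        fm, obs = linear_problem(5, 2, rng)
        res = bme.omega_scan({"CS": fm}, {"CS": obs}, np.full(5, 0.2), bme.ReweightConfig())
        assert res.chosen_omega == 1.0
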