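"""The three model families: compositional LM, iso-temporal substitution,
and partitioning-index regression, with their effect-evaluation helpers."""

import numpy as np
import pytest

from actipart import models as mdl
from actipart.composition import (
    IlrBasis,
    clr,
    close,
    ilr,
    neutral,
    pivot_basis,
)
from actipart.simulate import SimulationTruth, generate_cohort, generate_outcomes
from conftest import GEOMETRIC_MEAN, PROFILES, TRIG_DIRECTION, TRIG_NORM


def helmert_like_basis(D):
    """A second valid ilr basis, different from the pivot basis."""
    M = np.zeros((D - 1, D))
    for r in range(1, D):
        M[r - 1, :r] = 1.0 / r
        M[r - 1, r] = -1.0
        M[r - 1] *= np.sqrt(r / (r + 1.0))
    return IlrBasis(M)


def noiseless_cohort(n=80, seed=3, beta_norm=0.29, gamma=None):
    gamma = np.zeros(6) if gamma is None else gamma
    truth = SimulationTruth(sigma_eps=0.0, beta_norm=beta_norm, gamma=gamma, alpha=5.0)
    cohort = generate_cohort(truth, n, seed=seed, with_streams=False)
    X = cohort.compositions.iloc[:, 1:].to_numpy(float)
    Z = cohort.covariates.iloc[:, 1:].to_numpy(float)
    y = cohort.outcomes["outcome"].to_numpy(float)
    return truth, X, Z, y


class TestCompositionalLM:
    def test_noiseless_exact_recovery(self):
        gamma = np.array([1.2, -0.05, 0.4, 0.0, 0.7, -0.3])
        truth, X, Z, y = noiseless_cohort(gamma=gamma)
        fit = mdl.fit_compositional_lm(y, X, Z)
        assert fit.alpha == pytest.approx(5.0, abs=1e-8)
        assert fit.beta_norm == pytest.approx(0.29, abs=1e-8)
        np.testing.assert_allclose(fit.beta_direction, truth.beta_direction, atol=1e-8)
        np.testing.assert_allclose(fit.gamma, gamma, atol=1e-8)

    def test_basis_invariance(self):
        truth, X, Z, y = noiseless_cohort()
        f1 = mdl.fit_compositional_lm(y, X, Z, pivot_basis(5))
        f2 = mdl.fit_compositional_lm(y, X, Z, helmert_like_basis(5))
        assert f1.beta_norm == pytest.approx(f2.beta_norm, abs=1e-10)
        np.testing.assert_allclose(f1.beta_direction, f2.beta_direction, atol=1e-10)
        assert f1.model_p == pytest.approx(f2.model_p, abs=1e-10)
        x = close(np.array([1, 2, 3, 4, 5.0]))
        z = np.zeros(6)
        assert mdl.predict_outcome(f1, x, z) == pytest.approx(
            mdl.predict_outcome(f2, x, z), abs=1e-10
        )

    def test_null_model_type_one_error(self):
        """With beta_norm = 0 the joint F-test rejects ~5% of the time."""
        truth = SimulationTruth(sigma_eps=1.0, beta_norm=0.0, alpha=0.0)
        rejections = 0
        reps = 400
        root = np.random.SeedSequence(77)
        for i, child in enumerate(root.spawn(reps)):
            rng = np.random.default_rng(child)
            X = rng.dirichlet(np.ones(5) * 8, size=60)
            y = generate_outcomes(X, np.zeros((60, 1)), truth, rng)
            fit = mdl.fit_compositional_lm(y, X)
            rejections += fit.model_p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_prediction_matches_ilr_route(self):
        _, X, Z, y = noiseless_cohort()
        basis = pivot_basis(5)
        fit = mdl.fit_compositional_lm(y, X, Z, basis)
        x = close(np.array([0.1, 0.5, 0.2, 0.1, 0.1]))
        z = np.ones(6)
        via_ilr = fit.alpha + fit.ilr_coefs @ ilr(x, basis) + fit.gamma @ z
        assert mdl.predict_outcome(fit, x, z) == pytest.approx(via_ilr, abs=1e-10)

    def test_neutral_composition_prediction(self):
        _, X, Z, y = noiseless_cohort()
        fit = mdl.fit_compositional_lm(y, X, Z)
        z = np.zeros(6)
        assert mdl.predict_outcome(fit, neutral(5), z) == pytest.approx(fit.alpha)

    def test_rank_deficiency_rejected(self):
        _, X, Z, y = noiseless_cohort(n=40)
        Zbad = np.hstack([Z, Z[:, :1]])  # duplicated column
        with pytest.raises(ValueError, match="rank"):
            mdl.fit_compositional_lm(y, X, Zbad)


class TestProfileContrast:
    def test_identity_profile(self):
        gm = close(GEOMETRIC_MEAN)
        assert mdl.profile_contrast((TRIG_DIRECTION, TRIG_NORM), gm, gm) == pytest.approx(0.0)
        assert mdl.profile_contrast(
            (TRIG_DIRECTION, TRIG_NORM), gm, gm, log_outcome=True
        ) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "profile, printed",
        [("couch potato", 1.35), ("office worker", 1.12), ("doorman", 0.86), ("active", 0.80)],
    )
    def test_published_triglycerides_ratios(self, profile, printed):
        ratio = mdl.profile_contrast(
            (TRIG_DIRECTION, TRIG_NORM), PROFILES[profile], GEOMETRIC_MEAN, log_outcome=True
        )
        assert ratio == pytest.approx(printed, abs=0.02)

    def test_accepts_fitted_model(self):
        _, X, Z, y = noiseless_cohort()
        fit = mdl.fit_compositional_lm(y, X, Z)
        direct = mdl.profile_contrast(fit, PROFILES["active"], GEOMETRIC_MEAN)
        manual = fit.beta_clr @ (clr(close(PROFILES["active"])) - clr(close(GEOMETRIC_MEAN)))
        assert direct == pytest.approx(manual, abs=1e-12)


class TestIsotemporal:
    names = ("lie", "sit", "stand", "lpa", "mvpa")

    def make_data(self, rng, n=100, effects=(0.0, 3.0, -1.0, 2.0, 5.0), noise=0.0):
        P = rng.dirichlet(np.ones(5) * 6, size=n)
        y = P @ np.array(effects) + noise * rng.normal(size=n)
        return P, y

    def test_noiseless_exact_recovery(self, rng):
        # y = sum_b e_b p_b; with 'lie' displaced the coefficient of b is e_b - e_lie
        effects = np.array([1.0, 3.0, -1.0, 2.0, 5.0])
        P, y = self.make_data(rng, effects=effects)
        fit = mdl.fit_isotemporal(y, P, self.names, displaced="lie")
        for i, b in enumerate(self.names[1:], start=1):
            assert fit.estimates[b] == pytest.approx(effects[i] - effects[0], abs=1e-8)

    def test_reparametrization_antisymmetry(self, rng):
        P, y = self.make_data(rng, noise=1.0)
        f_a = mdl.fit_isotemporal(y, P, self.names, displaced="sit")
        f_b = mdl.fit_isotemporal(y, P, self.names, displaced="stand")
        assert f_a.estimates["stand"] == pytest.approx(-f_b.estimates["sit"], abs=1e-8)
        assert f_a.p_values["stand"] == pytest.approx(f_b.p_values["sit"], abs=1e-8)

    def test_published_effect_arithmetic(self):
        """One percent of the time budget from sitting to standing at the
        published coefficient 23.93 gives ~0.24 mg/dL."""
        assert mdl.reallocation_effect(23.93, 0.01) == pytest.approx(0.24, abs=0.005)

    def test_unclosed_proportions_rejected(self, rng):
        P, y = self.make_data(rng)
        with pytest.raises(ValueError):
            mdl.fit_isotemporal(y, P * 1.01, self.names, displaced="lie")

    def test_significance_tiers(self):
        assert mdl.significance_tier(0.0005) == "***"
        assert mdl.significance_tier(0.03) == "*"
        assert mdl.significance_tier(0.07) == "†"
        assert mdl.significance_tier(0.5) == ""


class TestReallocationMatrix:
    def test_grid_identities(self, rng):
        P = rng.dirichlet(np.ones(5) * 6, size=120)
        y = P @ np.array([1.0, -2.0, 0.5, 3.0, 4.0]) + rng.normal(size=120)
        names = ("lie", "sit", "stand", "lpa", "mvpa")
        M = mdl.reallocation_matrix(y, P, names)
        np.testing.assert_allclose(np.diag(M.estimate), 0.0)
        np.testing.assert_allclose(M.estimate, -M.estimate.T, atol=1e-8)
        # transitivity: A->C = A->B + B->C (one underlying linear model)
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    assert M.estimate[c, a] == pytest.approx(
                        M.estimate[b, a] + M.estimate[c, b], abs=1e-8
                    )

    def test_sign_agrees_with_compositional_contrast(self, rng):
        """Moving a little time from sitting to standing changes the
        predicted outcome in the same direction under both models."""
        truth = SimulationTruth(sigma_eps=0.0, alpha=0.0)
        X = rng.dirichlet(np.ones(5) * 8, size=150)
        y = generate_outcomes(X, np.zeros((150, 1)), truth, rng)
        names = ("lie", "sit", "stand", "lpa", "mvpa")
        M = mdl.reallocation_matrix(y, X, names)
        base = close(GEOMETRIC_MEAN)
        shifted = base.copy()
        shifted[1] -= 0.01
        shifted[2] += 0.01
        delta = mdl.profile_contrast((truth.beta_direction, truth.beta_norm), shifted, base)
        assert np.sign(M.estimate[2, 1]) == np.sign(delta)


class TestPartitioning:
    def simulate_once(self, rng, n=150, b1=2.0, b2=0.0, noise=1.0):
        X = rng.dirichlet(np.ones(5) * 8, size=n)
        idx = rng.normal(5.0, 2.0, size=n)
        y = b1 * idx + b2 * idx**2 + noise * rng.normal(size=n)
        return X, idx, y

    def test_quadratic_type_one_error(self):
        """Under a purely linear truth the auto rule admits the quadratic
        term at about the nominal 5% rate."""
        root = np.random.SeedSequence(123)
        included = 0
        reps = 400
        for child in root.spawn(reps):
            rng = np.random.default_rng(child)
            X, idx, y = self.simulate_once(rng)
            fit = mdl.fit_partitioning(y, idx, X, quadratic="auto")
            included += fit.quadratic_included
        assert included / reps == pytest.approx(0.05, abs=0.03)

    def test_strong_quadratic_detected_and_vertex_recovered(self):
        root = np.random.SeedSequence(321)
        vertices = []
        for child in root.spawn(30):
            rng = np.random.default_rng(child)
            X, idx, y = self.simulate_once(rng, b1=-4.8, b2=0.4, noise=0.5)
            fit = mdl.fit_partitioning(y, idx, X, quadratic="auto")
            assert fit.quadratic_included
            vertices.append(mdl.vertex(fit))
        assert np.median(vertices) == pytest.approx(6.0, rel=0.10)

    def test_null_index_ci_coverage(self):
        """An index unrelated to outcome and composition: the 95% CI
        covers zero in about 95% of replicates."""
        root = np.random.SeedSequence(55)
        covered = 0
        reps = 300
        for child in root.spawn(reps):
            rng = np.random.default_rng(child)
            X = rng.dirichlet(np.ones(5) * 8, size=120)
            idx = rng.normal(size=120)
            y = rng.normal(size=120)
            fit = mdl.fit_partitioning(y, idx, X, quadratic="off")
            covered += fit.ci_index[0] <= 0.0 <= fit.ci_index[1]
        assert covered / reps == pytest.approx(0.95, abs=0.035)

    def test_nan_indices_dropped(self, rng):
        X, idx, y = self.simulate_once(rng, n=100)
        idx[:7] = np.nan
        fit = mdl.fit_partitioning(y, idx, X)
        assert fit.n == 93 and fit.n_dropped == 7

    def test_constant_index_rejected(self, rng):
        X, idx, y = self.simulate_once(rng, n=50)
        with pytest.raises(ValueError, match="constant"):
            mdl.fit_partitioning(y, np.ones(50), X)


class TestEffectHelpers:
    def test_published_gini_effect(self):
        # linear coefficient -29.8 per Gini unit, shift of +0.1
        assert mdl.effect_delta((-29.8, None), 0.6, 0.7) == pytest.approx(-2.98)

    def test_published_quadratic_ratio_shift(self):
        delta = mdl.effect_delta((-3944.26, 2047.4), 0.9707, 0.9892)
        assert abs(delta) == pytest.approx(1.3, abs=0.05)

    def test_published_median_effect(self):
        assert mdl.effect_delta((-1.61, None), 3.0, 6.0) == pytest.approx(-4.83)

    def test_published_vertex(self):
        assert mdl.vertex((-4.75, 0.39)) == pytest.approx(6.09, abs=0.01)

    def test_vertex_requires_quadratic(self):
        with pytest.raises(ValueError):
            mdl.vertex((-4.75, None))

    def test_effect_delta_from_fit(self, rng):
        X = rng.dirichlet(np.ones(5) * 8, size=80)
        idx = rng.normal(size=80)
        y = 2.0 * idx + 0.01 * rng.normal(size=80)
        fit = mdl.fit_partitioning(y, idx, X, quadratic="off")
        assert mdl.effect_delta(fit, 0.0, 1.0) == pytest.approx(2.0, abs=0.05)
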