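import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from geoadditive.mcmc import MCMCConfig, run_chain, update_block, update_variance
from geoadditive.models import build_model
from geoadditive.polya_gamma import draw_polya_gamma
from geoadditive.records import Dataset


def _intercept_only_dataset(rng, n, p):
    y = (rng.random(n) < p).astype(float)
    frame = pd.DataFrame({"district_id": 1, "y": y})
    return Dataset(frame=frame, district_index={1: 0})


class _BareModel:
    """Minimal duck-typed model for driving run_chain directly."""

    def __init__(self, y, X, labels):
        self.y = y
        self.X_fixed = X
        self.fixed_labels = labels
        self.smooth_terms = []
        self.structured = False
        self.unstructured = False
        self.graph = None
        self.district_positions = None
        self.level = "M0"
        self.outcome = "y"


class TestUpdateBlock:
    def test_one_parameter_normal_normal_algebra(self, rng):
        # closed form: precision = sum omega x^2 + 1/v0, mean = kappa'x / precision
        x = rng.standard_normal(50)
        omega = rng.uniform(0.1, 1.0, 50)
        kappa = rng.standard_normal(50)
        v0 = 2.0
        prec = (omega * x * x).sum() + 1.0 / v0
        mean = (x * kappa).sum() / prec
        draws = np.array(
            [
                update_block(kappa, x[:, None], omega, np.array([[1.0 / v0]]), rng)[0]
                for _ in range(4000)
            ]
        )
        assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(1 / prec / 4000) + 1e-9)
        assert draws.var(ddof=1) == pytest.approx(1.0 / prec, rel=0.15)

    def test_infinite_prior_precision_pins_to_zero(self, rng):
        x = rng.standard_normal(30)
        draw = update_block(
            np.ones(30), x[:, None], np.ones(30), np.array([[1e12]]), rng
        )
        assert abs(draw[0]) < 1e-4

    def test_singular_precision_raises(self, rng):
        X = np.zeros((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match="constraint"):
            update_block(np.ones(10), X, np.ones(10), np.zeros((2, 2)), rng)


class TestUpdateVariance:
    def test_zero_block_reduces_to_prior_rate(self, rng):
        K = np.eye(4)
        draws = np.array(
            [update_variance(np.zeros(4), K, 2.0, 3.0, rng, rank=4) for _ in range(20_000)]
        )
        # IG(2 + 2, 3): mean 3/(4-1) = 1
        assert draws.mean() == pytest.approx(3.0 / 3.0, rel=0.05)
        assert np.all(draws > 0)

    def test_moment_oracle(self, rng):
        f = np.array([1.0, -1.0, 2.0])
        K = np.eye(3)
        a, b = 3.0, 1.0
        quad = f @ K @ f
        draws = np.array([update_variance(f, K, a, b, rng, rank=3) for _ in range(20_000)])
        a_p, b_p = a + 1.5, b + quad / 2
        exact = b_p / (a_p - 1)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - exact) < 3 * se

    def test_invalid_hyperparameters(self, rng):
        with pytest.raises(ValueError):
            update_variance(np.zeros(3), np.eye(3), 0.0, 1.0, rng)


class TestRunChain:
    def test_stored_draw_count(self, rng):
        y = (rng.random(200) < 0.3).astype(float)
        model = _BareModel(y, np.ones((200, 1)), ["(Intercept)"])
        chain = run_chain(model, MCMCConfig(iterations=2000, burn_in=500, seed=1))
        assert chain.n_stored == 1500
        assert chain.fixed.shape == (1500, 1)

    def test_intercept_recovers_logit_prevalence(self, rng):
        # large-n Bernoulli MLE oracle: posterior mean ~ logit(0.3)
        y = (rng.random(3000) < 0.3).astype(float)
        model = _BareModel(y, np.ones((3000, 1)), ["(Intercept)"])
        chain = run_chain(model, MCMCConfig(iterations=1500, burn_in=300, seed=2))
        mle = logit(y.mean())
        assert abs(chain.fixed[:, 0].mean() - mle) < 0.1

    def test_same_seed_identical_chains(self, small_sim):
        truth = small_sim.truth
        model = build_model(
            "M4", small_sim.dataset, "hypertension", ["sex"], graph=small_sim.graph,
            n_interior_knots=6,
        )
        cfg = MCMCConfig(iterations=120, burn_in=20, seed=99)
        c1, c2 = run_chain(model, cfg), run_chain(model, cfg)
        np.testing.assert_array_equal(c1.fixed, c2.fixed)
        np.testing.assert_array_equal(c1.deviance, c2.deviance)
        np.testing.assert_array_equal(c1.f_unstructured, c2.f_unstructured)

    def test_variances_positive_and_deviance_finite(self, m5_chain):
        for name, v in m5_chain.variances.items():
            assert np.all(v > 0), name
        assert np.all(np.isfinite(m5_chain.deviance))

    def test_fixed_effect_consistency_with_n(self):
        # posterior mean approaches the truth as n grows (RMS over 3 seeds)
        beta_true = 0.8
        errs = {}
        for n in (500, 4000):
            sq = []
            for seed in (5, 6, 7):
                rng = np.random.default_rng(seed)
                x = (rng.random(n) < 0.5).astype(float)
                y = (rng.random(n) < expit(-1.0 + beta_true * x)).astype(float)
                model = _BareModel(
                    y, np.column_stack([np.ones(n), x]), ["(Intercept)", "x"]
                )
                chain = run_chain(model, MCMCConfig(iterations=800, burn_in=200, seed=60 + seed))
                sq.append((chain.fixed[:, 1].mean() - beta_true) ** 2)
            errs[n] = np.sqrt(np.mean(sq))
        assert errs[4000] < 0.15
        assert errs[4000] < errs[500]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)

    def test_hyperprior_sensitivity(self, small_sim):
        # the even-vaguer IG(1e-5, 1e-5) setting must leave fixed effects
        # essentially unchanged (variance hyperpriors act on smooths/fields)
        truth = small_sim.truth
        model = build_model(
            "M5", small_sim.dataset, "hypertension", ["sex", "residence"],
            graph=small_sim.graph, n_interior_knots=6,
        )
        base = run_chain(model, MCMCConfig(iterations=600, burn_in=200, seed=21))
        vague = run_chain(
            model,
            MCMCConfig(iterations=600, burn_in=200, seed=21, hyper_a=1e-5, hyper_b=1e-5),
        )
        for chain in (base, vague):
            assert all(np.all(v > 0) for v in chain.variances.values())
        diff = np.abs(base.fixed.mean(axis=0) - vague.fixed.mean(axis=0))
        assert diff.max() < 0.25


class TestGewekeStyle:
    def test_successive_conditional_simulator_matches_prior(self, rng):
        """Joint correctness of the PG conditional updates.

        Alternate (theta -> y -> theta | y) transitions leave the prior
        invariant when the conditionals are correct, so the long-run draws
        of beta must match its N(0, v0) prior (intercept-only model with a
        tight prior to keep the check well conditioned).
        """
        n, v0 = 40, 0.5
        X = np.ones((n, 1))
        beta = 0.0
        draws = []
        for _ in range(4000):
            y = (rng.random(n) < expit(beta)).astype(float)
            eta = np.full(n, beta)
            omega = draw_polya_gamma(1.0, eta, rng)
            kappa = y - 0.5
            beta = update_block(kappa, X, omega, np.array([[1.0 / v0]]), rng)[0]
            draws.append(beta)
        draws = np.asarray(draws[500:])
        # autocorrelation-inflated standard error for the mean test
        m = draws.size
        acf1 = np.corrcoef(draws[1:], draws[:-1])[0, 1]
        ess = m * (1 - acf1) / (1 + acf1)
        assert abs(draws.mean()) < 4 * np.sqrt(v0 / ess)
        assert draws.var(ddof=1) == pytest.approx(v0, rel=0.2)
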