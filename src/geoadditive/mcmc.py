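"""Gibbs sampler for the Bernoulli-logit structured additive model.

Pólya-Gamma data augmentation makes every conditional exact: given latent
omega_i ~ PG(1, eta_i), each coefficient block (fixed effects, P-spline
coefficients, structured and unstructured district effects) is multivariate
Gaussian, and each smoothing / spatial variance is inverse-Gamma.  The
sampler performs a systematic scan

    omega | rest  ->  each coefficient block | rest  ->  each variance | rest

and records the Bernoulli deviance -2 sum[y log p + (1-y) log(1-p)] at every
stored draw, plus the running mean of the linear predictor (the plug-in for
the DIC effective-parameter count).

Identifiability: smooth blocks are pre-centered (sum-to-zero over the
sample, see :mod:`geoadditive.smooths`); the structured ICAR field is
re-centered to component-wise mean zero after each update, with the removed
level absorbed into the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit

from .polya_gamma import draw_polya_gamma

log = logging.getLogger(__name__)

__all__ = ["MCMCConfig", "ChainResult", "update_block", "update_variance", "run_chain"]

_P_CLIP = 1e-12


@dataclass
class MCMCConfig:
    """Chain length and priors.

    Defaults follow the analysis scale (40,000 iterations, 10,000 burn-in);
    tests and the synthetic pipeline use shorter chains via this config.
    Variance hyperpriors are IG(a, b), weakly informative at the
    conventional (0.001, 0.001); fixed effects get diffuse mean-zero
    Gaussians (variance 1e6) so every conditional stays proper.
    """

    iterations: int = 40000
    burn_in: int = 10000
    thinning: int = 1
    seed: int = 0
    hyper_a: float = 0.001
    hyper_b: float = 0.001
    fixed_prior_var: float = 1.0e6
    pg_trunc: int = 16

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in + self.thinning - 1) // self.thinning


@dataclass
class ChainResult:
    """Stored posterior draws for one fitted model."""

    fixed: np.ndarray  # (M, p)
    fixed_labels: list
    smooth_coefs: dict  # name -> (M, k) in the centered parameterisation
    smooth_terms: dict  # name -> SmoothTerm (centered)
    f_structured: np.ndarray | None  # (M, S)
    f_unstructured: np.ndarray | None
    variances: dict  # name -> (M,)
    deviance: np.ndarray  # (M,)
    eta_mean: np.ndarray  # (n,) posterior mean linear predictor
    y: np.ndarray
    district_labels: list | None
    config: MCMCConfig
    level: str = ""
    outcome: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return len(self.deviance)


def update_block(kappa_adj, X, omega, prior_precision, rng) -> np.ndarray:
    """Draw one Gaussian coefficient block under PG augmentation.

    ``kappa_adj`` is (y - 1/2) - Omega * eta_rest, i.e. the working residual
    with every other block's contribution removed.  The conditional has
    precision X' Omega X + prior_precision and mean solving it against
    X' kappa_adj.
    """
    A = X.T @ (X * omega[:, None]) + prior_precision
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular conditional precision; review constraints/hyperpriors"
        ) from exc
    rhs = X.T @ kappa_adj
    mean = cho_solve((L, True), rhs, check_finite=False)
    z = rng.standard_normal(len(rhs))
    return mean + solve_triangular(L, z, lower=True, trans="T", check_finite=False)


def update_variance(f, K, a: float, b: float, rng, rank: int | None = None) -> float:
    """Conjugate inverse-Gamma draw for a smoothing or spatial variance.

    tau^2 | f ~ IG(a + rank(K)/2, b + f'Kf/2).
    """
    if a <= 0 or b <= 0:
        raise ValueError("hyperparameters a, b must be > 0")
    f = np.asarray(f, dtype=float)
    quad = float(f @ K @ f)
    if quad < 0:
        log.warning("negative quadratic form %.3e clipped to 0", quad)
        quad = 0.0
    if rank is None:
        rank = int(np.linalg.matrix_rank(K))
    shape = a + rank / 2.0
    rate = b + quad / 2.0
    return rate / rng.standard_gamma(shape)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    p = np.clip(expit(eta), _P_CLIP, 1.0 - _P_CLIP)
    return float(-2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


def run_chain(model, config: MCMCConfig) -> ChainResult:
    """Run the systematic-scan Gibbs sampler for one built model.

    ``model`` is a :class:`geoadditive.models.ModelSpec` (duck-typed: needs
    y, X_fixed, fixed_labels, smooth terms, district positions / graph and
    the structured/unstructured flags).  Fixed seed implies bit-reproducible
    chains.
    """
    rng = np.random.default_rng(config.seed)
    y = np.asarray(model.y, dtype=float)
    n = len(y)
    kappa = y - 0.5

    X = np.asarray(model.X_fixed, dtype=float)
    p = X.shape[1]
    prior_prec_fixed = np.eye(p) / config.fixed_prior_var
    beta = np.zeros(p)

    terms = list(model.smooth_terms)
    gammas = [np.zeros(t.design.shape[1]) for t in terms]
    tau2_smooth = [0.1] * len(terms)
    term_ranks = [
        t.penalty_rank if t.penalty_rank is not None else int(np.linalg.matrix_rank(t.penalty))
        for t in terms
    ]

    has_str = bool(getattr(model, "structured", False))
    has_unstr = bool(getattr(model, "unstructured", False))
    d = model.district_positions if (has_str or has_unstr) else None
    S = model.graph.n if model.graph is not None else 0
    if has_str:
        from .spatial import icar_precision

        K_s = icar_precision(model.graph)
        comp = model.graph.components()
        rank_str = S - (int(comp.max()) + 1)
        f_str = np.zeros(S)
        tau2_str = 0.1
    if has_unstr:
        f_unstr = np.zeros(S)
        tau2_unstr = 0.1

    eta = X @ beta
    for t_, g_ in zip(terms, gammas):
        eta = eta + t_.design @ g_
    if has_str:
        eta = eta + f_str[d]
    if has_unstr:
        eta = eta + f_unstr[d]

    M = config.n_stored
    store_fixed = np.empty((M, p))
    store_smooth = {t.name: np.empty((M, t.design.shape[1])) for t in terms}
    store_fstr = np.empty((M, S)) if has_str else None
    store_funstr = np.empty((M, S)) if has_unstr else None
    store_var = {f"tau2_{t.name}": np.empty(M) for t in terms}
    if has_str:
        store_var["tau2_structured"] = np.empty(M)
    if has_unstr:
        store_var["tau2_unstructured"] = np.empty(M)
    store_dev = np.empty(M)
    eta_sum = np.zeros(n)

    a, b = config.hyper_a, config.hyper_b
    m_idx = 0
    for it in range(config.iterations):
        if not np.all(np.isfinite(eta)):
            raise FloatingPointError(f"non-finite linear predictor at iteration {it}")
        omega = draw_polya_gamma(1.0, eta, rng, trunc=config.pg_trunc)

        # fixed effects
        contrib = X @ beta
        kadj = kappa - omega * (eta - contrib)
        beta_new = update_block(kadj, X, omega, prior_prec_fixed, rng)
        eta += X @ (beta_new - beta)
        beta = beta_new

        # smooth blocks
        for j, t_ in enumerate(terms):
            B = t_.design
            contrib = B @ gammas[j]
            kadj = kappa - omega * (eta - contrib)
            g_new = update_block(kadj, B, omega, t_.penalty / tau2_smooth[j], rng)
            eta += B @ (g_new - gammas[j])
            gammas[j] = g_new

        if has_str or has_unstr:
            omega_d = np.bincount(d, weights=omega, minlength=S)

        # Both fields present: draw them as one 2S Gaussian block.  They are
        # strongly negatively correlated given the data (only their sum is
        # well identified), so separate scans mix the attribution far too
        # slowly.
        if has_str and has_unstr:
            contrib = f_str[d] + f_unstr[d]
            r = kappa - omega * (eta - contrib)
            rhs_half = np.bincount(d, weights=r, minlength=S)
            Dw = np.diag(omega_d)
            A = np.block(
                [[Dw + K_s / tau2_str, Dw], [Dw, Dw + np.eye(S) / tau2_unstr]]
            )
            L = np.linalg.cholesky(A)
            rhs = np.concatenate([rhs_half, rhs_half])
            mean = cho_solve((L, True), rhs, check_finite=False)
            draw = mean + solve_triangular(
                L, rng.standard_normal(2 * S), lower=True, trans="T", check_finite=False
            )
            f_new, f_unstr = draw[:S], draw[S:]
            removed = np.zeros(S)
            for c in range(int(comp.max()) + 1):
                mask = comp == c
                mc = f_new[mask].mean()
                f_new[mask] -= mc
                removed[mask] = mc
            shift = float(removed[d].mean())
            beta[0] += shift
            eta += f_new[d] + f_unstr[d] - contrib + shift
            f_str = f_new
            tau2_str = update_variance(f_str, K_s, a, b, rng, rank=rank_str)
            tau2_unstr = update_variance(f_unstr, np.eye(S), a, b, rng, rank=S)

        # structured ICAR field
        elif has_str:
            contrib = f_str[d]
            r = kappa - omega * (eta - contrib)
            rhs = np.bincount(d, weights=r, minlength=S)
            A = np.diag(omega_d) + K_s / tau2_str
            L = np.linalg.cholesky(A)
            mean = cho_solve((L, True), rhs, check_finite=False)
            f_new = mean + solve_triangular(
                L, rng.standard_normal(S), lower=True, trans="T", check_finite=False
            )
            # component-wise sum-to-zero; the intercept absorbs the level
            removed = np.zeros(S)
            for c in range(int(comp.max()) + 1):
                mask = comp == c
                mc = f_new[mask].mean()
                f_new[mask] -= mc
                removed[mask] = mc
            shift = float(removed[d].mean())
            beta[0] += shift
            eta += f_new[d] - contrib + shift
            f_str = f_new
            tau2_str = update_variance(f_str, K_s, a, b, rng, rank=rank_str)

        # unstructured exchangeable field alone (diagonal conditional)
        elif has_unstr:
            contrib = f_unstr[d]
            r = kappa - omega * (eta - contrib)
            rhs = np.bincount(d, weights=r, minlength=S)
            var = 1.0 / (omega_d + 1.0 / tau2_unstr)
            f_unstr = var * rhs + np.sqrt(var) * rng.standard_normal(S)
            eta += f_unstr[d] - contrib
            tau2_unstr = update_variance(
                f_unstr, np.eye(S), a, b, rng, rank=S
            )

        # smoothing variances
        for j, t_ in enumerate(terms):
            tau2_smooth[j] = update_variance(
                gammas[j], t_.penalty, a, b, rng, rank=term_ranks[j]
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            store_fixed[m_idx] = beta
            for j, t_ in enumerate(terms):
                store_smooth[t_.name][m_idx] = gammas[j]
            if has_str:
                store_fstr[m_idx] = f_str
                store_var["tau2_structured"][m_idx] = tau2_str
            if has_unstr:
                store_funstr[m_idx] = f_unstr
                store_var["tau2_unstructured"][m_idx] = tau2_unstr
            for j, t_ in enumerate(terms):
                store_var[f"tau2_{t_.name}"][m_idx] = tau2_smooth[j]
            store_dev[m_idx] = _deviance(y, eta)
            eta_sum += eta
            m_idx += 1

    return ChainResult(
        fixed=store_fixed,
        fixed_labels=list(model.fixed_labels),
        smooth_coefs=store_smooth,
        smooth_terms={t.name: t for t in terms},
        f_structured=store_fstr,
        f_unstructured=store_funstr,
        variances=store_var,
        deviance=store_dev,
        eta_mean=eta_sum / max(m_idx, 1),
        y=y,
        district_labels=list(model.graph.labels) if model.graph is not None else None,
        config=config,
        level=getattr(model, "level", ""),
        outcome=getattr(model, "outcome", ""),
    )
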