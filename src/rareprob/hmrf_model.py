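"""Probability components of the hidden Markov random field.

Two latent binary fields are attached to the M variants: X (causal status)
and R (elevated-region status).  The pieces defined here:

* emission marginals — Beta-Binomial likelihoods of the observed carrier
  counts under the causal model (distinct case/control carrier frequencies,
  each integrated over its own Beta prior) and under the null model (a single
  pooled frequency).  The displayed per-vector likelihoods omit the binomial
  coefficient consistently in both branches, so their ratio is a proper Bayes
  factor.
* local conditionals — Gibbs-form conditional probabilities of X_s and R_s
  given the neighborhood, with own-term/pair-term potentials weighted by the
  collapsing weights omega.
* transition probabilities — the causal rates inside elevated (xi) and
  background (zeta) regions, with conjugate Beta posteriors.
* Beta posterior modes — the MAP update shared by theta, rho, xi and zeta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .site_stats import NeighborWeights


@dataclass
class HiddenStates:
    """Latent binary vectors: X (1 = causal), R (1 = elevated region)."""

    X: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.R = np.asarray(self.R, dtype=np.int8)
        for name, v in (("X", self.X), ("R", self.R)):
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        if self.X.size != self.R.size:
            raise ValueError("X and R must have equal length")

    def copy(self) -> "HiddenStates":
        return HiddenStates(self.X.copy(), self.R.copy())


@dataclass
class MRFParams:
    """Field parameters: (gamma, eta) for X, (tau, upsilon) for R.

    gamma and tau scale the own-state potentials; eta and upsilon scale the
    pairwise neighbor potentials and are constrained positive so that the
    collapsing weights act with their intended sign.
    """

    gamma: float = 0.0
    eta: float = 1.0
    tau: float = 0.0
    upsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.upsilon <= 0:
            raise ValueError("eta and upsilon must be strictly positive")


@dataclass
class BetaHyper:
    """Beta hyperparameters for all conjugate pieces of the model."""

    alpha_theta: float = 1.0
    beta_theta: float = 1.0
    alpha_rho: float = 1.0
    beta_rho: float = 1.0
    alpha_null: float = 1.0
    beta_null: float = 1.0
    alpha_xi: float = 1.0
    beta_xi: float = 1.0
    alpha_zeta: float = 1.0
    beta_zeta: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")


@dataclass
class TransitionState:
    """Causal rates by region and the counts they are estimated from.

    xi = P(X=1 | R=1), zeta = P(X=1 | R=0); c_E / c_B are the elevated /
    background site counts and c_X_plus / c_X_minus the causal counts within
    them.
    """

    xi: float = 0.5
    zeta: float = 0.5
    c_X_plus: int = 0
    c_E: int = 0
    c_X_minus: int = 0
    c_B: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0 and 0.0 <= self.zeta <= 1.0):
            raise ValueError("xi and zeta must lie in [0, 1]")
        if self.c_X_plus > self.c_E or self.c_X_minus > self.c_B:
            raise ValueError("causal counts cannot exceed region sizes")

    def rate_for_region(self, R: np.ndarray) -> np.ndarray:
        """Per-site P(X=1 | R_s): xi where elevated, zeta where background."""
        return np.where(np.asarray(R) == 1, self.xi, self.zeta)


# ---------------------------------------------------------------------------
# emission marginals


def _beta_binom_logmarg(c, n, alpha: float, beta: float):
    """log B(alpha + c, beta + n - c) - log B(alpha, beta) (no C(n, c))."""
    c = np.asarray(c, dtype=float)
    return betaln(alpha + c, beta + n - c) - betaln(alpha, beta)


def emission_loglik_causal(c_plus, c_minus, n_case: int, n_ctrl: int, hyper: BetaHyper):
    """Log marginal likelihood of the counts under the causal model.

    Case and control carrier frequencies are distinct, each with its own Beta
    prior; integrating them out gives the product of two Beta-function
    ratios.
    """
    return _beta_binom_logmarg(c_plus, n_case, hyper.alpha_theta, hyper.beta_theta) + (
        _beta_binom_logmarg(c_minus, n_ctrl, hyper.alpha_rho, hyper.beta_rho)
    )


def emission_loglik_null(c_total, N: int, hyper: BetaHyper):
    """Log marginal likelihood under the null model (theta = rho).

    All N genotypes share one carrier frequency with a Beta prior; the count
    is the pooled c = c_plus + c_minus.
    """
    return _beta_binom_logmarg(c_total, N, hyper.alpha_null, hyper.beta_null)


# ---------------------------------------------------------------------------
# local conditionals

_RATE_FLOOR = 1e-6  # keeps logits of xi/zeta finite


def _normalize_pair(log_score1: float, log_score0: float) -> float:
    """P(state = 1) from two log-scores, guarded against overflow."""
    m = max(log_score1, log_score0)
    e1 = np.exp(log_score1 - m)
    e0 = np.exp(log_score0 - m)
    return float(e1 / (e1 + e0))


def local_conditional_X(
    s: int,
    X: np.ndarray,
    R: np.ndarray,
    W: NeighborWeights,
    params: MRFParams,
    trans: TransitionState,
) -> float:
    """P(X_s = 1 | X_n(s), R) under the Gibbs potentials.

    Unnormalized log-score of state x: gamma * log P(X_s = x | R_s)
    + eta * sum_{s'} omega(s, s') P(X_s' | R_s') X_s'.  The own term is the
    Bayesian-classifier prior for the site's region (tempered by gamma); the
    pair term collects the collapsing-weighted neighbor field and is shared
    by both states, so the normalized probability is a logistic function of
    gamma * logit P(X_s = 1 | R_s).
    """
    X = np.asarray(X)
    R = np.asarray(R)
    q = np.clip(trans.rate_for_region(R), _RATE_FLOOR, 1.0 - _RATE_FLOOR)
    nb = W.neighbors[s]
    pair = params.eta * float(np.sum(W.omega[s, nb] * q[nb] * X[nb]))
    return _normalize_pair(
        params.gamma * np.log(q[s]) + pair,
        params.gamma * np.log1p(-q[s]) + pair,
    )


def region_neighbor_sum(R: np.ndarray, halfwidth: int = 5) -> np.ndarray:
    """Signed neighbor sums sum_{0 < |s' - s| <= h} (2 R_s' - 1) per site.

    The region field lives on the genomic variant order: each site's
    neighbors are the ``halfwidth`` sites on either flank.
    """
    spins = 2.0 * np.asarray(R, dtype=float) - 1.0
    m = spins.size
    kernel = np.ones(2 * halfwidth + 1)
    kernel[halfwidth] = 0.0  # exclude self
    full = np.convolve(spins, kernel, mode="full")
    return full[halfwidth:halfwidth + m]


def local_conditional_R(
    s: int,
    R: np.ndarray,
    params: MRFParams,
    halfwidth: int = 5,
) -> float:
    """P(R_s = 1 | R_n(s)) for the genomic region field.

    Log-score of state r: tau * r + upsilon * r * sum_{|s'-s| <= h}
    (2 R_s' - 1): an Ising-style smoothing potential on the variant axis, so
    elevated regions form contiguous stretches.  Normalized probability is
    logistic in tau + upsilon * neighbor sum.
    """
    R = np.asarray(R)
    lo = max(0, s - halfwidth)
    hi = min(R.size, s + halfwidth + 1)
    t = float(np.sum(2.0 * R[lo:hi] - 1.0) - (2.0 * R[s] - 1.0))
    return _normalize_pair(params.tau + params.upsilon * t, 0.0)


def field_logodds_X(R: np.ndarray, params: MRFParams, trans: TransitionState) -> np.ndarray:
    """Vectorized log-odds of X_s = 1 under the field: gamma * logit(q_s)."""
    q = np.clip(trans.rate_for_region(R), _RATE_FLOOR, 1.0 - _RATE_FLOOR)
    return params.gamma * (np.log(q) - np.log1p(-q))


def field_prob_X(R: np.ndarray, params: MRFParams, trans: TransitionState) -> np.ndarray:
    """Vectorized P(X_s = 1 | neighborhood) for every site."""
    return 1.0 / (1.0 + np.exp(-field_logodds_X(R, params, trans)))


# ---------------------------------------------------------------------------
# transitions


def transition_counts(X: np.ndarray, R: np.ndarray) -> TransitionState:
    """Count causal sites inside and outside elevated regions."""
    X = np.asarray(X)
    R = np.asarray(R)
    if X.size != R.size:
        raise ValueError("X and R must have equal length")
    c_E = int(R.sum())
    c_B = int(R.size - c_E)
    c_X_plus = int((X * R).sum())
    c_X_minus = int((X * (1 - R)).sum())
    xi = c_X_plus / c_E if c_E else 0.5
    zeta = c_X_minus / c_B if c_B else 0.5
    return TransitionState(xi=xi, zeta=zeta, c_X_plus=c_X_plus, c_E=c_E,
                           c_X_minus=c_X_minus, c_B=c_B)


def transition_loglik(counts: TransitionState, hyper: BetaHyper) -> float:
    """log P(X | R): product of the two Beta-Binomial marginals.

    A region class with zero sites contributes an empty product (log 0
    contribution), which the Beta-function ratio yields automatically since
    its count is forced to zero.
    """
    elevated = _beta_binom_logmarg(counts.c_X_plus, counts.c_E, hyper.alpha_xi, hyper.beta_xi)
    background = _beta_binom_logmarg(
        counts.c_X_minus, counts.c_B, hyper.alpha_zeta, hyper.beta_zeta
    )
    return float(elevated + background)


def beta_posterior_mode(c, n, alpha: float, beta: float):
    """MAP estimate under a Beta(alpha, beta) prior and Binomial(n) count.

    (alpha + c - 1) / (alpha + beta + n - 2), clamped to [0, 1]; when the
    posterior has no interior mode (alpha + beta + n = 2) falls back to the
    empirical rate c/n (or 1/2 when n = 0).
    """
    c = np.asarray(c, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    denom = alpha + beta + n - 2.0
    if denom <= 0:
        out = c / n if n > 0 else np.full_like(c, 0.5)
    else:
        out = np.clip((alpha + c - 1.0) / denom, 0.0, 1.0)
    return float(out[0]) if scalar else out
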