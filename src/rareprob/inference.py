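"""Pseudo-likelihood estimation cycle and the final collapsing test.

The fit alternates four steps until the causal-state vector stops moving:

1. empirical-Bayes re-estimation of the Beta hyperparameters from the
   current per-site rate estimates, followed by MAP updates of the case and
   control carrier frequencies (theta, rho);
2. MAP updates of the causal rates by region (xi, zeta) from the current
   hidden-state counts;
3. maximum pseudo-likelihood fit of the field parameters (gamma, eta) and
   (tau, upsilon);
4. an ICM sweep setting each X_s (and then each R_s) to the state maximizing
   emission log-likelihood plus log local conditional.

Convergence is the Euclidean distance between successive causal-state
vectors; the default tolerance of 1 stops as soon as a sweep flips nothing.
The selected variants are then collapsed — separately for risk (z > 0) and
protective (z < 0) directions — into per-individual carrier indicators and
tested with the pooled two-proportion z statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .core_io import GenotypeMatrix, Phenotypes, PriorScores, RunConfig, RATE_CLAMP
from .site_stats import SiteStats, NeighborWeights, carrier_counts, build_neighborhood, z_statistic
from .hmrf_model import (
    BetaHyper,
    HiddenStates,
    MRFParams,
    TransitionState,
    beta_posterior_mode,
    emission_loglik_causal,
    emission_loglik_null,
    field_logodds_X,
    field_prob_X,
    region_neighbor_sum,
    transition_counts,
)

logger = logging.getLogger("rareprob")

_PARAM_BOUND = 30.0  # gamma cap; keeps the tempered prior finite
_TAU_BOUND = 12.0  # |tau|, upsilon cap for the region field (separation guard)
_TRANSITION_PRIOR = (2.0, 2.0)  # Beta prior for xi and zeta
_R_RELAX_SWEEPS = 20  # inner relaxation passes of the region field per cycle


@dataclass
class FitResult:
    """Everything a completed fit produced."""

    variant_ids: list[str]
    X_hat: np.ndarray
    R_hat: np.ndarray
    theta_hat: np.ndarray
    rho_hat: np.ndarray
    z: np.ndarray
    params: MRFParams
    trans: TransitionState
    hyper: BetaHyper
    selected_risk: set[str]
    selected_protective: set[str]
    statistic: float
    p_value: float
    significant: bool
    n_iterations: int
    converged: bool
    trace: list[dict] = dc_field(default_factory=list)


def init_states(
    stats: SiteStats,
    priors: Optional[PriorScores] = None,
    z_init: float = 1.0,
    region_window: int = 10,
) -> HiddenStates:
    """Seed the hidden states from the marginal statistics (or prior scores).

    X0 flags sites with |z| >= ``z_init``.  R0 smooths X0 with a centered
    moving average of width ``region_window`` (zero-padded at the edges) and
    thresholds it at 0.5, so the initial elevated regions are stretches
    where flagged sites cluster.  Prior scores, when given, override either
    vector (hint >= 0.5).
    """
    m = stats.n_variants
    if priors is not None and priors.causal_hint is not None:
        X0 = (priors.causal_hint >= 0.5).astype(np.int8)
    else:
        X0 = (np.abs(stats.z) >= z_init).astype(np.int8)
    if priors is not None and priors.region_hint is not None:
        R0 = (priors.region_hint >= 0.5).astype(np.int8)
    else:
        w = max(1, int(region_window))
        full = np.convolve(X0.astype(float), np.ones(w) / w, mode="full")
        start = (w - 1) // 2
        smooth = full[start:start + m]
        R0 = (smooth >= 0.5).astype(np.int8)
    if X0.size != m or R0.size != m:
        raise ValueError("prior score length does not match variant count")
    return HiddenStates(X0, R0)


def estimate_beta_hyper(estimates, sizes=None) -> tuple[float, float]:
    """Method-of-moments Beta fit to a vector of per-site rate estimates.

    With mean m and variance v, k = m(1-m)/v - 1, alpha = m k, beta =
    (1-m) k.  When ``sizes`` (the per-site count denominators) is given, v
    is first corrected for binomial sampling noise — the observed spread of
    c/n overstates the spread of the underlying rates by about
    m(1-m) E[1/n] — which is what makes the fit a proper Beta-Binomial
    moment estimator rather than a fit to noise.  Falls back to the flat
    prior (1, 1) whenever the fit is undefined: empty input, a single
    value, or non-positive (corrected) variance or k — i.e. rates
    indistinguishable from homogeneous.
    """
    values = np.asarray(estimates, dtype=float)
    if values.size < 2:
        return (1.0, 1.0)
    values = np.clip(values, RATE_CLAMP, 1.0 - RATE_CLAMP)
    m = float(values.mean())
    v = float(values.var())
    if sizes is not None:
        inv_n = float(np.mean(1.0 / np.asarray(sizes, dtype=float)))
        v -= m * (1.0 - m) * inv_n
    if v <= 0.0:
        return (1.0, 1.0)
    k = m * (1.0 - m) / v - 1.0
    if k <= 0.0:
        return (1.0, 1.0)
    if sizes is not None and k > 1.0 / inv_n:
        # implied prior is tighter than the per-site sampling noise can
        # resolve: rates indistinguishable from homogeneous
        return (1.0, 1.0)
    return (m * k, (1.0 - m) * k)


def _pl_objective_X(gamma: float, X: np.ndarray, logit_q: np.ndarray) -> float:
    """Pseudo-log-likelihood of X: logistic in the tempered prior log-odds."""
    own = gamma * logit_q
    return float(np.sum(X * own - np.logaddexp(0.0, own)))


def _pl_objective_R(tau: float, upsilon: float, R: np.ndarray, t: np.ndarray) -> float:
    """Pseudo-log-likelihood of R: logistic in tau + upsilon * neighbor sum."""
    a = tau + upsilon * t
    return float(np.sum(R * a - np.logaddexp(0.0, a)))


def fit_mrf_params(
    states: HiddenStates,
    W: NeighborWeights,
    trans: TransitionState,
    current: Optional[MRFParams] = None,
    region_halfwidth: int = 5,
) -> MRFParams:
    """Maximize the pseudo-likelihoods over the field parameters.

    gamma (tempering of the region-conditional causal prior) is maximized on
    a bounded interval; (tau, upsilon) of the genomic region field are
    maximized jointly with upsilon > 0.  The causal-field pair weight eta
    does not enter the normalized conditionals (the pair term is shared by
    both states) and is carried through unchanged.  If an optimizer fails or
    would return a lower objective than the incoming parameters, the
    incoming values are kept.
    """
    from scipy.optimize import minimize

    if current is None:
        current = MRFParams()
    X = states.X.astype(float)
    R = states.R.astype(float)
    q = np.clip(trans.rate_for_region(states.R), RATE_CLAMP, 1.0 - RATE_CLAMP)
    logit_q = np.log(q) - np.log1p(-q)

    if X.sum() == 0:
        gamma = 0.0  # degenerate: no selected sites, prior weight unidentified
    elif X.sum() == X.size:
        gamma = _PARAM_BOUND
    else:
        res = minimize_scalar(
            lambda g: -_pl_objective_X(g, X, logit_q),
            bounds=(0.0, _PARAM_BOUND),
            method="bounded",
        )
        gamma = float(res.x)
        if not res.success or (
            _pl_objective_X(gamma, X, logit_q) < _pl_objective_X(current.gamma, X, logit_q)
        ):
            gamma = current.gamma

    t = region_neighbor_sum(states.R, region_halfwidth)
    r_count = float(R.sum())
    tau0 = float(np.log((r_count + 1.0) / (R.size - r_count + 1.0)))  # add-one base rate
    if r_count == 0.0 or r_count == R.size:
        tau, upsilon = tau0, current.upsilon
    else:
        x0 = np.array([np.clip(current.tau, -_TAU_BOUND, _TAU_BOUND),
                       np.clip(current.upsilon, 1e-6, _TAU_BOUND)])
        res = minimize(
            lambda p: -_pl_objective_R(p[0], p[1], R, t),
            x0=x0,
            bounds=[(-_TAU_BOUND, _TAU_BOUND), (1e-6, _TAU_BOUND)],
            method="L-BFGS-B",
        )
        tau, upsilon = float(res.x[0]), float(res.x[1])
        if not res.success or (
            _pl_objective_R(tau, upsilon, R, t)
            < _pl_objective_R(current.tau, current.upsilon, R, t)
        ):
            tau, upsilon = current.tau, current.upsilon

    return MRFParams(gamma=gamma, eta=current.eta, tau=tau, upsilon=max(upsilon, 1e-6))


def icm_update_states(
    stats: SiteStats,
    states: HiddenStates,
    params: MRFParams,
    trans: TransitionState,
    hyper: BetaHyper,
    W: NeighborWeights,
    order: Optional[np.ndarray] = None,
    region_halfwidth: int = 5,
) -> HiddenStates:
    """One full ICM sweep over all sites.

    First every X_s is set to argmax_x emission(x) + log P(X_s = x | field)
    (the causal-field contrast does not involve the other sites' current
    states, so this part is order-free).  Then the region field is swept in
    ``order`` (ascending by default): R_s <- argmax_r log Bern(X_s; xi or
    zeta) + log P(R_s = r | region neighbors), with neighbor sums updated
    in place so each site sees its predecessors' new labels.  Exact ties
    keep the previous state.
    """
    X_prev = states.X
    R_prev = states.R
    e1 = emission_loglik_causal(stats.c_plus, stats.c_minus, stats.n_case, stats.n_ctrl, hyper)
    e0 = emission_loglik_null(stats.c_plus + stats.c_minus, stats.n_case + stats.n_ctrl, hyper)
    contrast = (e1 - e0) + field_logodds_X(R_prev, params, trans)
    X_new = np.where(contrast > 0, 1, np.where(contrast < 0, 0, X_prev)).astype(np.int8)

    xi = float(np.clip(trans.xi, RATE_CLAMP, 1.0 - RATE_CLAMP))
    zeta = float(np.clip(trans.zeta, RATE_CLAMP, 1.0 - RATE_CLAMP))
    Xf = X_new.astype(float)
    data_term = (
        Xf * (np.log(xi) - np.log(zeta))
        + (1 - Xf) * (np.log1p(-xi) - np.log1p(-zeta))
    )
    R_new = R_prev.copy()
    t = region_neighbor_sum(R_new, region_halfwidth)
    m = R_new.size
    if order is None:
        order = np.arange(m)
    # relax the region field to a stable configuration: repeated sweeps let
    # contiguous blocks consolidate (or noise patches dissolve) fully before
    # the next parameter update
    for _ in range(_R_RELAX_SWEEPS):
        changed = False
        for s in order:
            delta = data_term[s] + params.tau + params.upsilon * t[s]
            new = R_new[s] if delta == 0.0 else (1 if delta > 0 else 0)
            if new != R_new[s]:
                step = 2.0 * (new - R_new[s])  # +-2 change of the spin 2R-1
                lo, hi = max(0, s - region_halfwidth), min(m, s + region_halfwidth + 1)
                t[lo:hi] += step
                t[s] -= step  # a site is not its own neighbor
                R_new[s] = new
                changed = True
        if not changed:
            break
    return HiddenStates(X_new, R_new)


def converged(X_prev: np.ndarray, X_new: np.ndarray, tol: float = 1.0) -> bool:
    """True iff the Euclidean distance between state vectors is below tol."""
    X_prev = np.asarray(X_prev, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_prev.size != X_new.size:
        raise ValueError("state vectors must have equal length")
    return bool(np.sqrt(np.sum((X_prev - X_new) ** 2)) < tol)


def association_test(
    X_hat: np.ndarray,
    z: np.ndarray,
    G: GenotypeMatrix,
    P: Phenotypes,
    threshold: float = 2.5e-6,
):
    """Collapsing test of the selected variants.

    The selected set is split by effect direction: risk (z > 0) and
    protective (z < 0).  Each non-empty subset is collapsed to a
    per-individual indicator of carrying >= 1 mutant across the subset and
    tested with the pooled two-proportion z (two-sided normal p).  With both
    subsets present the two p-values are Bonferroni-combined
    (p = min(1, 2 min(p+, p-))); an empty selection gives p = 1.

    Returns (statistic, p_value, significant, risk_idx, protective_idx).
    """
    X_hat = np.asarray(X_hat)
    z = np.asarray(z)
    risk_idx = np.flatnonzero((X_hat == 1) & (z > 0))
    prot_idx = np.flatnonzero((X_hat == 1) & (z < 0))

    def _collapsed_test(idx: np.ndarray) -> tuple[float, float]:
        carrier = G.values[idx].any(axis=0)
        c_case = int(carrier[P.case_mask].sum())
        c_ctrl = int(carrier[~P.case_mask].sum())
        stat = float(z_statistic(c_case, c_ctrl, P.n_case, P.n_ctrl))
        p = float(2.0 * norm.sf(abs(stat))) if stat != 0.0 else 1.0
        return stat, p

    results = []
    for idx in (risk_idx, prot_idx):
        if idx.size:
            results.append(_collapsed_test(idx))
    if not results:
        return 0.0, 1.0, False, risk_idx, prot_idx
    stats_, pvals = zip(*results)
    best = int(np.argmin(pvals))
    p_value = min(1.0, len(results) * min(pvals)) if len(results) > 1 else pvals[0]
    statistic = stats_[best]
    return statistic, p_value, bool(p_value < threshold), risk_idx, prot_idx


def run_rareprob(
    G: GenotypeMatrix,
    P: Phenotypes,
    priors: Optional[PriorScores] = None,
    config: Optional[RunConfig] = None,
) -> FitResult:
    """Full pipeline: statistics, neighborhood, initialization, the four-step
    estimation cycle, and the final collapsing test.

    Deterministic given the inputs and ``config.seed``.
    """
    if config is None:
        config = RunConfig()
    stats = carrier_counts(G, P)
    W = build_neighborhood(stats.z, mode=config.neighborhood_mode,
                           min_abs_omega=config.min_abs_omega)
    states = init_states(stats, priors, z_init=config.z_init,
                         region_window=config.region_window)
    rng = np.random.default_rng(config.seed)

    theta_hat = stats.theta_hat.astype(float).copy()
    rho_hat = stats.rho_hat.astype(float).copy()
    pooled_rate = (stats.c_plus + stats.c_minus) / (stats.n_case + stats.n_ctrl)
    params = MRFParams()
    hyper = BetaHyper()
    trace: list[dict] = []
    did_converge = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        # Step 1: empirical-Bayes hyperparameters for the emission pieces,
        # fitted to the raw across-site rate spread (fitting them to the
        # MAP-shrunken estimates instead would collapse the prior variance
        # each cycle and with it the marginal-likelihood Occam penalty),
        # followed by the MAP rate updates
        a_th, b_th = estimate_beta_hyper(stats.theta_hat, sizes=stats.n_case)
        a_rh, b_rh = estimate_beta_hyper(stats.rho_hat, sizes=stats.n_ctrl)
        a_nu, b_nu = estimate_beta_hyper(pooled_rate, sizes=stats.n_case + stats.n_ctrl)
        # the emission Bayes factor compares the split model against the
        # pooled one; an adaptive prior on one side against a flat fallback
        # on the other would bias that comparison, so a fallback in any
        # component reverts all three to the flat prior
        if (1.0, 1.0) in ((a_th, b_th), (a_rh, b_rh), (a_nu, b_nu)):
            a_th = b_th = a_rh = b_rh = a_nu = b_nu = 1.0
        # Step 2: region-wise causal rates.  A single (c, n) pair carries no
        # replicate structure to fit hyperparameters from, and the flat
        # prior's MAP sits on the boundary whenever a region class holds no
        # causal site (the generic case), collapsing the transition
        # evidence; a weakly informative Beta(2, 2) keeps it finite.
        counts = transition_counts(states.X, states.R)
        a_xi, b_xi = _TRANSITION_PRIOR
        a_ze, b_ze = _TRANSITION_PRIOR
        # identifiability: "elevated" is by definition the region class with
        # the higher causal rate; relabel if the counts say otherwise
        if beta_posterior_mode(counts.c_X_minus, counts.c_B, a_ze, b_ze) > (
            beta_posterior_mode(counts.c_X_plus, counts.c_E, a_xi, b_xi)
        ):
            states = HiddenStates(states.X, 1 - states.R)
            counts = transition_counts(states.X, states.R)
        hyper = BetaHyper(
            alpha_theta=a_th, beta_theta=b_th,
            alpha_rho=a_rh, beta_rho=b_rh,
            alpha_null=a_nu, beta_null=b_nu,
            alpha_xi=a_xi, beta_xi=b_xi,
            alpha_zeta=a_ze, beta_zeta=b_ze,
        )
        theta_hat = np.clip(
            beta_posterior_mode(stats.c_plus, stats.n_case, a_th, b_th),
            RATE_CLAMP, 1.0 - RATE_CLAMP,
        )
        rho_hat = np.clip(
            beta_posterior_mode(stats.c_minus, stats.n_ctrl, a_rh, b_rh),
            RATE_CLAMP, 1.0 - RATE_CLAMP,
        )
        xi = beta_posterior_mode(counts.c_X_plus, counts.c_E, a_xi, b_xi)
        zeta = beta_posterior_mode(counts.c_X_minus, counts.c_B, a_ze, b_ze)
        trans = TransitionState(
            xi=float(np.clip(xi, RATE_CLAMP, 1.0 - RATE_CLAMP)),
            zeta=float(np.clip(zeta, RATE_CLAMP, 1.0 - RATE_CLAMP)),
            c_X_plus=counts.c_X_plus, c_E=counts.c_E,
            c_X_minus=counts.c_X_minus, c_B=counts.c_B,
        )
        # Step 3: field parameters by maximum pseudo-likelihood
        halfwidth = max(1, config.region_window // 2)
        params = fit_mrf_params(states, W, trans, current=params,
                                region_halfwidth=halfwidth)
        # Step 4: ICM sweep
        order = rng.permutation(states.X.size) if config.random_sweep_order else None
        new_states = icm_update_states(stats, states, params, trans, hyper, W, order,
                                       region_halfwidth=halfwidth)

        e1 = emission_loglik_causal(stats.c_plus, stats.c_minus, stats.n_case,
                                    stats.n_ctrl, hyper)
        e0 = emission_loglik_null(stats.c_plus + stats.c_minus,
                                  stats.n_case + stats.n_ctrl, hyper)
        Xf = new_states.X.astype(float)
        pX = np.clip(field_prob_X(new_states.R, params, trans), RATE_CLAMP, 1 - RATE_CLAMP)
        objective = float(
            np.sum(Xf * e1 + (1 - Xf) * e0)
            + np.sum(Xf * np.log(pX) + (1 - Xf) * np.log1p(-pX))
        )
        n_flips = int(np.sum(new_states.X != states.X))
        trace.append({
            "iteration": n_iter,
            "objective": objective,
            "n_flips": n_flips,
            "n_selected": int(new_states.X.sum()),
            "gamma": params.gamma,
            "tau": params.tau,
            "xi": trans.xi,
            "zeta": trans.zeta,
        })
        conv = converged(states.X, new_states.X, config.convergence_tol) and bool(
            np.array_equal(states.R, new_states.R)
        )
        states = new_states
        if conv:
            did_converge = True
            break
        if states.X.sum() == 0:
            # empty selection is terminal: the collapsing test of an empty
            # set is p = 1, and the causal-prior weight is unidentified, so
            # further sweeps could only oscillate
            did_converge = True
            break

    if not did_converge:
        logger.warning("fit reached max_iter=%d without converging", config.max_iter)

    statistic, p_value, significant, risk_idx, prot_idx = association_test(
        states.X, stats.z, G, P, config.significance_threshold
    )
    vid = np.asarray(G.variant_ids)
    return FitResult(
        variant_ids=list(G.variant_ids),
        X_hat=states.X.copy(),
        R_hat=states.R.copy(),
        theta_hat=theta_hat,
        rho_hat=rho_hat,
        z=stats.z,
        params=params,
        trans=trans,
        hyper=hyper,
        selected_risk=set(vid[risk_idx]),
        selected_protective=set(vid[prot_idx]),
        statistic=statistic,
        p_value=p_value,
        significant=significant,
        n_iterations=n_iter,
        converged=did_converge,
        trace=trace,
    )
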