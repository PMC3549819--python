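"""Synthetic case-control generators with fully labeled ground truth.

Three frameworks, mirroring the study designs this package is evaluated on:

* ``sim_fixed`` — a fixed number K of causal variants.  Control carrier
  frequencies follow Wright's stationary distribution under purifying
  selection; each causal site receives a marginal population attributable
  risk delta = Delta / K which maps to a relative risk and thence a case
  frequency.  Case and control genotypes are drawn independently.
* ``sim_par`` — the causal set grows until the group PAR budget Delta is
  exhausted by the stopping product prod(1 - theta_s Pr / P_D) > 1 - Delta;
  non-causal sites get the coalescent-motivated null frequency 5.0 / N.
  Phenotypes arise mechanistically: a carrier of any causal variant is
  affected with penetrance Pr, a non-carrier with the baseline rate solving
  marginal prevalence P_D; cases and controls are rejection-sampled to
  quota.
* ``sim_regions`` — elevated/background region labels (preset blocks or a
  two-state Markov chain), per-region causal probabilities, then the same
  mechanistic phenotype model.

Every dataset carries its genotypes, phenotypes, true causal vector, true
region vector and the per-site frequencies used, so power, per-site type-I
error and region recovery can all be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import GenotypeMatrix, Phenotypes, ValidationError

#: Wright's-distribution settings for the fixed-causal-count framework
WRIGHT_FIXED = dict(sigma=12.0, beta_s=0.001, beta_n=0.00033)
#: Wright's-distribution settings for the PAR- and region-driven frameworks
WRIGHT_SELECTION = dict(sigma=30.0, beta_s=0.2, beta_n=0.002)

#: default Wright settings per framework name
FRAMEWORK_WRIGHT = {
    "fixed": WRIGHT_FIXED,
    "par": WRIGHT_SELECTION,
    "regions": WRIGHT_SELECTION,
}

_GRID_POINTS = 4096


@dataclass
class WrightParams:
    """Wright's stationary MAF distribution under purifying selection.

    Density proportional to rho^(beta_s - 1) (1 - rho)^(beta_n - 1)
    e^(sigma (1 - rho)), truncated to [maf_lo, maf_hi].  sigma is the
    selection coefficient, beta_s the forward (normal -> causal) and beta_n
    the back mutation probability.  The default truncation [1e-5, 0.01]
    keeps draws in the rare range (the density is improper at 0 for
    beta_s < 1).
    """

    sigma: float = 12.0
    beta_s: float = 0.001
    beta_n: float = 0.00033
    maf_lo: float = 1e-5
    maf_hi: float = 0.01

    def __post_init__(self) -> None:
        if self.beta_s <= 0 or self.beta_n <= 0:
            raise ValidationError("beta_s and beta_n must be positive")
        if not (0.0 < self.maf_lo < self.maf_hi <= 0.5):
            raise ValidationError("need 0 < maf_lo < maf_hi <= 0.5")


@dataclass
class SimConfig:
    """Shared simulator configuration.

    m: total variants; k: causal count (fixed framework); n: genotypes
    (n_case = n_ctrl = n / 2 unless overridden); delta: group PAR; pr:
    penetrance of the causal set; p_d: disease prevalence; region layout
    (count, length, mode) and Markov-chain stay/switch rates; per-region
    causal probabilities; seed.
    """

    m: int = 100
    k: int = 50
    n: int = 2000
    delta: float = 0.05
    pr: float = 0.1
    p_d: float = 0.01
    n_regions: int = 1
    region_length: int = 50
    region_mode: str = "preset"
    stay_prob: float = 0.8
    switch_prob: float = 0.2
    p_causal_elevated: float = 0.1
    p_causal_background: float = 0.001
    n_case: Optional[int] = None
    n_ctrl: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValidationError("delta must lie in [0, 1)")
        if not (0.0 < self.pr <= 1.0 and 0.0 < self.p_d <= 1.0):
            raise ValidationError("pr and p_d must lie in (0, 1]")
        if abs(self.stay_prob + self.switch_prob - 1.0) > 1e-12:
            raise ValidationError("stay_prob + switch_prob must equal 1")
        if self.k > self.m:
            raise ValidationError("k cannot exceed m")
        if self.region_mode not in ("preset", "markov"):
            raise ValidationError("region_mode must be 'preset' or 'markov'")
        if self.n_case is None:
            self.n_case = self.n // 2
        if self.n_ctrl is None:
            self.n_ctrl = self.n - self.n // 2

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_ctrl


@dataclass
class SimDataset:
    """A generated dataset plus its ground truth."""

    genotypes: GenotypeMatrix
    phenotypes: Phenotypes
    truth_causal: np.ndarray
    truth_region: np.ndarray
    theta: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        m = self.genotypes.n_variants
        for name in ("truth_causal", "truth_region", "theta", "rho"):
            v = np.asarray(getattr(self, name))
            if v.size != m:
                raise ValidationError(f"{name} length must equal variant count")
            setattr(self, name, v)


# ---------------------------------------------------------------------------
# Wright's distribution


def _wright_grid_cdf(params: WrightParams) -> tuple[np.ndarray, np.ndarray]:
    grid = np.geomspace(params.maf_lo, params.maf_hi, _GRID_POINTS)
    logf = (
        (params.beta_s - 1.0) * np.log(grid)
        + (params.beta_n - 1.0) * np.log1p(-grid)
        - params.sigma * grid  # e^{sigma(1 - rho)} up to a constant
    )
    f = np.exp(logf - logf.max())
    # trapezoid cumulative over the (uneven) grid
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    return grid, cdf


def sample_wright(
    params: WrightParams, rng: np.random.Generator, size: Optional[int] = None
):
    """Draw carrier frequencies from the truncated Wright's distribution.

    Inverse-CDF sampling on a log-spaced grid of 4096 points; deterministic
    given the generator state.
    """
    grid, cdf = _wright_grid_cdf(params)
    u = rng.random(size if size is not None else 1)
    draws = np.interp(u, cdf, grid)
    return draws if size is not None else float(draws[0])


def wright_mean(params: WrightParams) -> float:
    """Numeric-quadrature mean of the truncated density (oracle use)."""
    grid, _ = _wright_grid_cdf(params)
    logf = (
        (params.beta_s - 1.0) * np.log(grid)
        + (params.beta_n - 1.0) * np.log1p(-grid)
        - params.sigma * grid
    )
    f = np.exp(logf - logf.max())
    num = np.trapezoid(grid * f, grid)
    den = np.trapezoid(f, grid)
    return float(num / den)


def case_maf(delta: float, rho) -> tuple:
    """Relative risk and case carrier frequency from a marginal PAR.

    RR = delta / ((1 - delta) rho) + 1 and theta = RR rho / ((RR - 1) rho
    + 1), which simplifies to theta = delta + rho (1 - delta): theta >= rho
    with equality iff delta = 0.
    """
    if not (0.0 <= delta < 1.0):
        raise ValidationError("delta must lie in [0, 1)")
    rho = np.asarray(rho, dtype=float)
    scalar = rho.ndim == 0
    rho = np.atleast_1d(rho)
    if ((rho <= 0) | (rho >= 1)).any():
        raise ValidationError("rho must lie in (0, 1)")
    rr = delta / ((1.0 - delta) * rho) + 1.0
    theta = rr * rho / ((rr - 1.0) * rho + 1.0)
    if scalar:
        return float(rr[0]), float(theta[0])
    return rr, theta


# ---------------------------------------------------------------------------
# framework 1: fixed number of causal variants


def sim_fixed(
    config: SimConfig,
    wright: Optional[WrightParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimDataset:
    """Fixed-causal-count generator.

    K causal sites (a contiguous block at a seeded random offset, recorded as
    the elevated region) receive control frequencies from Wright's
    distribution and case frequencies from the per-site PAR delta = Delta /
    K; the remaining sites are null (theta = rho).  Case and control
    genotype entries are independent Bernoulli draws.
    """
    if wright is None:
        wright = WrightParams(**WRIGHT_FIXED)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, k = config.m, config.k
    n_case, n_ctrl = config.n_case, config.n_ctrl

    rho = sample_wright(wright, rng, size=m)
    theta = rho.copy()
    offset = int(rng.integers(0, m - k + 1)) if k < m else 0
    causal = np.zeros(m, dtype=np.int8)
    causal[offset:offset + k] = 1
    if k > 0:
        delta_marginal = config.delta / k
        _, theta_causal = case_maf(delta_marginal, rho[causal == 1])
        theta[causal == 1] = theta_causal

    cases = rng.random((m, n_case)) < theta[:, None]
    ctrls = rng.random((m, n_ctrl)) < rho[:, None]
    values = np.concatenate([cases, ctrls], axis=1).astype(np.int8)
    G = GenotypeMatrix(
        values,
        variant_ids=[f"v{s}" for s in range(m)],
        sample_ids=[f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)],
    )
    P = Phenotypes(np.concatenate([np.ones(n_case, dtype=np.int8),
                                   np.zeros(n_ctrl, dtype=np.int8)]))
    return SimDataset(G, P, causal, causal.copy(), theta, rho)


# ---------------------------------------------------------------------------
# frameworks 2 and 3: mechanistic phenotypes with rejection sampling


def draw_causal_mafs(
    wright: WrightParams,
    pr: float,
    p_d: float,
    delta: float,
    rng: np.random.Generator,
    theta_source=None,
    max_causal: int = 100_000,
) -> np.ndarray:
    """Grow the causal set until the group-PAR budget is spent.

    Frequencies are appended while prod(1 - theta_s Pr / P_D) > 1 - Delta;
    the draw that breaks the inequality is the last member.  ``theta_source``
    (an iterator of frequencies) replaces the Wright draws when supplied.
    """
    thetas: list[float] = []
    product = 1.0
    while len(thetas) < max_causal:
        th = float(next(theta_source)) if theta_source is not None else sample_wright(wright, rng)
        if th * pr / p_d >= 1.0:
            raise ValidationError("theta * Pr / P_D >= 1; lower Pr or raise P_D")
        thetas.append(th)
        product *= 1.0 - th * pr / p_d
        if product <= 1.0 - delta:
            break
    return np.asarray(thetas)


def _sample_case_control(
    theta_causal: np.ndarray,
    pr: float,
    p_d: float,
    n_case: int,
    n_ctrl: int,
    rng: np.random.Generator,
    max_draws: int = 20_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample genotype carriers at the causal sites.

    An individual carrying >= 1 causal mutant is affected with probability
    Pr; a non-carrier with the baseline rate p0 solving the prevalence
    identity P_D = q Pr + (1 - q) p0, q = P(any causal carrier).  Returns
    the causal-site carrier blocks (k x n_case, k x n_ctrl).
    """
    k = theta_causal.size
    q = 1.0 - float(np.prod(1.0 - theta_causal)) if k else 0.0
    p0 = (p_d - q * pr) / (1.0 - q) if q < 1.0 else 0.0
    if p0 < 0.0 or p0 > 1.0:
        raise ValidationError(
            f"no baseline affection rate solves prevalence {p_d} with "
            f"carrier mass {q:.4g} and penetrance {pr}"
        )
    case_cols: list[np.ndarray] = []
    ctrl_cols: list[np.ndarray] = []
    need_case, need_ctrl = n_case, n_ctrl
    drawn = 0
    batch = max(10_000, n_case + n_ctrl)
    while (need_case > 0 or need_ctrl > 0) and drawn < max_draws:
        g = (rng.random((batch, k)) < theta_causal[None, :]) if k else np.zeros((batch, 0), bool)
        carrier = g.any(axis=1)
        p_aff = np.where(carrier, pr, p0)
        affected = rng.random(batch) < p_aff
        drawn += batch
        if need_case > 0:
            take = np.flatnonzero(affected)[:need_case]
            case_cols.append(g[take])
            need_case -= take.size
        if need_ctrl > 0:
            take = np.flatnonzero(~affected)[:need_ctrl]
            ctrl_cols.append(g[take])
            need_ctrl -= take.size
    if need_case > 0 or need_ctrl > 0:
        raise ValidationError(
            f"could not fill case/control quotas within {max_draws} draws "
            f"(prevalence {p_d} too extreme?)"
        )
    case_block = np.concatenate(case_cols, axis=0).T.astype(np.int8)
    ctrl_block = np.concatenate(ctrl_cols, axis=0).T.astype(np.int8)
    return case_block, ctrl_block


def _assemble_mechanistic(
    config: SimConfig,
    causal: np.ndarray,
    theta_causal: np.ndarray,
    truth_region: np.ndarray,
    rng: np.random.Generator,
) -> SimDataset:
    """Shared assembly for frameworks 2-3: causal blocks via rejection
    sampling, null sites at the coalescent frequency 5 / N."""
    m = causal.size
    n_case, n_ctrl = config.n_case, config.n_ctrl
    n_total = n_case + n_ctrl
    rho_null = 5.0 / n_total

    case_block, ctrl_block = _sample_case_control(
        theta_causal, config.pr, config.p_d, n_case, n_ctrl, rng
    )
    values = np.empty((m, n_total), dtype=np.int8)
    causal_idx = np.flatnonzero(causal == 1)
    null_idx = np.flatnonzero(causal == 0)
    values[causal_idx, :n_case] = case_block
    values[causal_idx, n_case:] = ctrl_block
    values[null_idx, :] = (rng.random((null_idx.size, n_total)) < rho_null).astype(np.int8)

    theta = np.full(m, rho_null)
    rho = np.full(m, rho_null)
    theta[causal_idx] = theta_causal
    rho[causal_idx] = theta_causal  # population carrier frequency at causal sites

    G = GenotypeMatrix(
        values,
        variant_ids=[f"v{s}" for s in range(m)],
        sample_ids=[f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)],
    )
    P = Phenotypes(np.concatenate([np.ones(n_case, dtype=np.int8),
                                   np.zeros(n_ctrl, dtype=np.int8)]))
    return SimDataset(G, P, causal, truth_region, theta, rho)


def sim_par(
    config: SimConfig,
    wright: Optional[WrightParams] = None,
    rng: Optional[np.random.Generator] = None,
    theta_source=None,
) -> SimDataset:
    """PAR-driven generator: the causal count follows from the group PAR.

    Causal frequencies come from Wright's distribution under strong
    selection until the stopping product crosses 1 - Delta; the causal set
    is placed as one contiguous block (recorded as the elevated region).
    """
    if wright is None:
        wright = WrightParams(**WRIGHT_SELECTION)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    theta_causal = draw_causal_mafs(
        wright, config.pr, config.p_d, config.delta, rng, theta_source=theta_source
    )
    k = theta_causal.size
    if k > config.m:
        raise ValidationError(f"causal set ({k}) exceeds total variants ({config.m})")
    offset = int(rng.integers(0, config.m - k + 1)) if k < config.m else 0
    causal = np.zeros(config.m, dtype=np.int8)
    causal[offset:offset + k] = 1
    return _assemble_mechanistic(config, causal, theta_causal, causal.copy(), rng)


def region_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Elevated/background labels: preset blocks or a two-state Markov chain.

    Preset mode lays ``n_regions`` elevated blocks of ``region_length`` sites
    at the starts of equal chunks of the variant axis.  Markov mode starts in
    a fair coin flip and stays in the current region type with probability
    ``stay_prob``.
    """
    m = config.m
    labels = np.zeros(m, dtype=np.int8)
    if config.region_mode == "preset":
        if config.n_regions * config.region_length > m:
            raise ValidationError("elevated regions do not fit in m variants")
        chunk = m // config.n_regions
        for r in range(config.n_regions):
            start = r * chunk
            labels[start:start + config.region_length] = 1
    else:
        state = int(rng.random() < 0.5)
        for s in range(m):
            labels[s] = state
            if rng.random() >= config.stay_prob:
                state = 1 - state
    return labels


def sim_regions(
    config: SimConfig,
    wright: Optional[WrightParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimDataset:
    """Region-structured generator.

    Causal status is Bernoulli per region class (elevated vs background
    rates); causal carrier frequencies come from Wright's distribution under
    strong selection, null sites from 5 / N; phenotypes follow the
    penetrance mechanism.
    """
    if wright is None:
        wright = WrightParams(**WRIGHT_SELECTION)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = region_labels(config, rng)
    p_causal = np.where(labels == 1, config.p_causal_elevated, config.p_causal_background)
    causal = (rng.random(config.m) < p_causal).astype(np.int8)
    theta_causal = sample_wright(wright, rng, size=int(causal.sum()))
    return _assemble_mechanistic(config, causal, theta_causal, labels, rng)
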