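"""Per-variant carrier statistics and the pairwise collapsing-weight system.

For each variant the carrier counts among cases (``c_plus``) and controls
(``c_minus``) give carrier-frequency estimates ``theta_hat`` and ``rho_hat``
and a pooled two-proportion statistic ``z``.  The collapsing weight

    omega(s, s') = 2 z_s z_s' / (z_s^2 + z_s'^2)

measures how alike two variants' case-control signals are (1 for identical
non-zero statistics, -1 for exactly opposed ones) and defines the
neighborhood system of the Markov random field: variants pulling the
phenotype in the same direction reinforce each other, risk and protective
variants repel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GenotypeMatrix, Phenotypes


@dataclass
class SiteStats:
    """Per-variant counts, frequency estimates and z statistics."""

    c_plus: np.ndarray
    c_minus: np.ndarray
    n_case: int
    n_ctrl: int
    theta_hat: np.ndarray
    rho_hat: np.ndarray
    z: np.ndarray

    @property
    def n_variants(self) -> int:
        return self.z.size


@dataclass
class NeighborWeights:
    """Symmetric pairwise collapsing weights and per-site neighbor lists."""

    omega: np.ndarray
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        masked = np.zeros_like(self.omega)
        for s, nb in enumerate(self.neighbors):
            masked[s, nb] = self.omega[s, nb]
        self._masked_omega = masked

    def neighbor_term(self, values: np.ndarray) -> np.ndarray:
        """Vector of sum_{s' in n(s)} omega[s, s'] * values[s'] for all s."""
        return self._masked_omega @ np.asarray(values, dtype=float)


def carrier_counts(G: GenotypeMatrix, P: Phenotypes) -> SiteStats:
    """Count carriers per variant in cases and controls and form z."""
    if G.n_samples != P.status.size:
        raise ValueError("genotype and phenotype sample counts differ")
    case = P.case_mask
    c_plus = G.values[:, case].sum(axis=1).astype(np.int64)
    c_minus = G.values[:, ~case].sum(axis=1).astype(np.int64)
    n_case, n_ctrl = P.n_case, P.n_ctrl
    theta_hat = c_plus / n_case
    rho_hat = c_minus / n_ctrl
    z = z_statistic(c_plus, c_minus, n_case, n_ctrl)
    return SiteStats(c_plus, c_minus, n_case, n_ctrl, theta_hat, rho_hat, z)


def z_statistic(c_plus, c_minus, n_case: int, n_ctrl: int) -> np.ndarray:
    """Pooled two-proportion standardized difference of carrier frequencies.

    z = (theta_hat - rho_hat) / sqrt(p(1-p)(1/n_case + 1/n_ctrl)) with the
    pooled proportion p = (c_plus + c_minus) / (n_case + n_ctrl).  Defined as
    0 whenever the two proportions are equal, including the degenerate pooled
    p in {0, 1} where the denominator vanishes.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("group sizes must be positive")
    c_plus = np.asarray(c_plus, dtype=float)
    c_minus = np.asarray(c_minus, dtype=float)
    theta = c_plus / n_case
    rho = c_minus / n_ctrl
    pbar = (c_plus + c_minus) / (n_case + n_ctrl)
    var = pbar * (1.0 - pbar) * (1.0 / n_case + 1.0 / n_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (theta - rho) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z if z.ndim else float(z)


def collapse_weight(z1, z2):
    """omega = 2 z1 z2 / (z1^2 + z2^2), with omega = 0 at z1 = z2 = 0.

    Bounded by |omega| <= 1 (AM-GM); sign follows sign(z1 * z2); invariant to
    scaling both statistics by a common positive factor.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    denom = z1 * z1 + z2 * z2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 2.0 * z1 * z2 / np.where(denom > 0, denom, 1.0), 0.0)
    return w if w.ndim else float(w)


def build_neighborhood(
    z: np.ndarray, mode: str = "dense", min_abs_omega: float = 0.0
) -> NeighborWeights:
    """Build the full omega matrix and per-site neighbor lists.

    dense mode: every other site is a neighbor.  threshold mode: only pairs
    with |omega| >= ``min_abs_omega``.  The diagonal is never a neighbor.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if m < 2:
        raise ValueError("need at least two variants for a neighborhood system")
    omega = collapse_weight(z[:, None], z[None, :])
    np.fill_diagonal(omega, 1.0)  # self-weight, never used as a neighbor
    neighbors: list[np.ndarray] = []
    for s in range(m):
        others = np.delete(np.arange(m), s)
        if mode == "dense":
            neighbors.append(others)
        elif mode == "threshold":
            keep = np.abs(omega[s, others]) >= min_abs_omega
            neighbors.append(others[keep])
        else:
            raise ValueError(f"unknown neighborhood mode {mode!r}")
    return NeighborWeights(omega=omega, neighbors=neighbors)
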