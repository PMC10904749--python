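"""Weighted-histogram (WHAM) reweighting of replica-exchange samples.

Combines samples collected at several ladder temperatures into weights
appropriate for a single target temperature. The implementation is the
binless self-consistent form: with inverse temperatures beta_m, sample
energies U_j, and N_k samples at ladder state k, iterate

    f_m = -ln sum_j exp(-beta_m U_j) / sum_k N_k exp(f_k - beta_k U_j)

to convergence, then weight sample j at the target by

    w_j  propto  exp(-beta_t U_j) / sum_k N_k exp(f_k - beta_k U_j).

Everything is evaluated in log space. Solute-tempering ensembles are
accepted through user-supplied reduced energies: pass per-sample
energies already expressed in kcal/mol for the state Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL
from .errors import ConfigError, ConvergenceError, EmptySampleError


@dataclass
class ReplicaEnsemble:
    """Pooled samples from a replica ladder.

    ``temperatures``/``energies`` are per sample; ``payload`` carries any
    per-sample observable (or frame reference) to be reweighted.
    """

    temperatures: np.ndarray
    energies: np.ndarray
    ladder: np.ndarray
    payload: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.ladder = np.asarray(self.ladder, dtype=float)
        if self.temperatures.shape != self.energies.shape:
            raise ConfigError("temperatures and energies must align")
        on_ladder = np.isin(self.temperatures, self.ladder)
        if not on_ladder.all():
            raise ConfigError("every sample temperature must be on the ladder")


def wham_weights(
    ensemble: ReplicaEnsemble,
    T_target: float,
    tol: float = 1e-7,
    max_iter: int = 10000,
):
    """Per-sample weights at ``T_target`` plus converged offsets f_m.

    Returns ``(weights, f)`` with weights normalized to sum to 1 and
    ``f`` ordered as ``ensemble.ladder``.
    """
    if T_target <= 0:
        raise ConfigError("target temperature must be positive")
    if T_target > ensemble.ladder.max() + 1e-9:
        raise ConfigError("target temperature must be on or below the ladder maximum")
    U = ensemble.energies
    if len(U) == 0:
        raise EmptySampleError("ensemble has no samples")
    ladder = ensemble.ladder
    betas = 1.0 / (R_KCAL * ladder)
    beta_t = 1.0 / (R_KCAL * T_target)
    N_k = np.array([(ensemble.temperatures == T).sum() for T in ladder], dtype=float)
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)

    # (M, n): -beta_m * U_j
    neg_bu = -np.outer(betas, U)
    f = np.zeros(len(ladder))
    if len(ladder) > 1:
        f = _solve_offsets(neg_bu, logN, f, tol, max_iter)

    log_denom = logsumexp(neg_bu + (logN + f)[:, None], axis=0)
    logw = -beta_t * U - log_denom
    logw -= logsumexp(logw)
    return np.exp(logw), f


def _solve_offsets(neg_bu, logN, f, tol, max_iter):
    for _ in range(max_iter):
        # log denominator per sample: logsumexp_k [ logN_k + f_k - beta_k U_j ]
        log_denom = logsumexp(neg_bu + (logN + f)[:, None], axis=0)
        new_f = -logsumexp(neg_bu - log_denom[None, :], axis=1)
        new_f = new_f - new_f[0]  # gauge: f_0 = 0
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            return f
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations (last change {delta:.3e})"
    )


def reweighted_mean(values: np.ndarray, weights: np.ndarray):
    """Weighted mean plus a standard-error estimate from the weight spread."""
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mean = float((w * values).sum())
    se = float(np.sqrt((w**2 * (values - mean) ** 2).sum()))
    return mean, se
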