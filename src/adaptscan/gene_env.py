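"""Bayes-factor test for allele-frequency/environment correlation.

Population allele frequencies are standardized per SNP,
``y_l = (p_l - p̄) / sqrt(p̄ (1 - p̄))`` with the unweighted
across-population mean p̄, and the shared demographic structure is
captured by an L×L covariance Ω estimated from putatively neutral control
SNPs (moment estimate, shrunk toward its diagonal). For a candidate SNP
the Bayes factor compares a model in which ``y ~ N(β·env, Ω)`` with β
averaged over a uniform grid on (-beta_bound, beta_bound) against the
covariance-only null β = 0. This is a deterministic Gaussian
approximation of the MCMC-based environmental-correlation test; rank
behaviour, not the published Bayes-factor magnitudes, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import EnvTable, ValidationError

__all__ = [
    "CovarianceModel",
    "BfResult",
    "standardize_freqs",
    "estimate_covariance",
    "env_bayes_factor",
    "env_scan",
    "EnvScanConfig",
]


@dataclass
class CovarianceModel:
    """Across-population covariance of standardized frequencies."""

    populations: list[str]
    omega: np.ndarray
    shrinkage: float

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[0] != self.omega.shape[1]:
            raise ValidationError("omega must be square")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValidationError("omega must be symmetric")
        w = np.linalg.eigvalsh(self.omega)
        if w.min() <= 0:
            raise ValidationError(f"omega not positive definite (smallest eigenvalue {w.min():.3g})")


@dataclass
class BfResult:
    snp: str
    environment: str
    bf: float
    beta_grid: np.ndarray
    log_likelihood: np.ndarray  # per grid point, log density of y


@dataclass
class EnvScanConfig:
    beta_bound: float = 0.3
    grid_points: int = 201
    shrinkage: float = 0.05
    absolute_latitude: bool = True


def standardize_freqs(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize an (L pops × m SNPs) frequency matrix per SNP.

    Returns ``(Y, kept)`` where ``kept`` indexes the columns whose
    across-population mean was neither 0 nor 1.
    """
    F = np.asarray(freqs, dtype=float)
    pbar = F.mean(axis=0)
    kept = np.flatnonzero((pbar > 0.0) & (pbar < 1.0))
    Fk = F[:, kept]
    pk = pbar[kept]
    return (Fk - pk[None, :]) / np.sqrt(pk * (1.0 - pk))[None, :], kept


def estimate_covariance(
    standardized: np.ndarray,
    populations: list[str] | None = None,
    shrinkage: float = 0.05,
) -> CovarianceModel:
    """Moment estimate of Ω from standardized control SNPs.

    ``omega = (1 - λ)·Ŝ + λ·diag(Ŝ)`` with Ŝ the empirical covariance
    across SNPs. Requires at least 10·L control SNPs.
    """
    Y = np.asarray(standardized, dtype=float)
    L, m = Y.shape
    if m < 10 * L:
        raise ValidationError(f"need >= {10 * L} control SNPs for {L} populations, got {m}")
    S = np.cov(Y, bias=False)
    S = np.atleast_2d(S)
    omega = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    if populations is None:
        populations = [f"POP{i}" for i in range(L)]
    return CovarianceModel(populations, omega, shrinkage)


def _grid_loglik(Y: np.ndarray, env: np.ndarray, omega: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """log N(y_j; β_g·env, Ω) for every SNP column j and grid point g.

    Returns an (n_grid, m) matrix of log densities (constants included).
    """
    L = omega.shape[0]
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(omega)
        raise ValidationError(f"singular omega (smallest eigenvalue {w.min():.3g})") from None
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    const = -0.5 * (L * np.log(2.0 * np.pi) + logdet)
    # whitened residuals: solve chol z = (y - β e) for each β
    from scipy.linalg import solve_triangular

    Zy = solve_triangular(chol, Y, lower=True)          # (L, m)
    Ze = solve_triangular(chol, env, lower=True)        # (L,)
    # ||Zy - β Ze||² = ||Zy||² - 2β Ze·Zy + β² ||Ze||²
    yy = (Zy**2).sum(axis=0)                            # (m,)
    ey = Ze @ Zy                                        # (m,)
    ee = float(Ze @ Ze)
    b = grid[:, None]
    quad = yy[None, :] - 2.0 * b * ey[None, :] + (b**2) * ee
    return const - 0.5 * quad


def env_bayes_factor(
    y: np.ndarray,
    env: np.ndarray,
    model: CovarianceModel,
    beta_bound: float = 0.3,
    grid_points: int = 201,
    snp: str = "",
    environment: str = "",
) -> BfResult:
    """Bayes factor for one standardized SNP vector against one environment.

    ``bf`` is the mean over an equally spaced, symmetric β grid on
    [-beta_bound, beta_bound] of the MVN density of ``y`` with mean
    ``β·env`` and covariance Ω, divided by the density at β = 0. ``env``
    must be standardized (mean 0, sd 1 across populations).
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    env = np.asarray(env, dtype=float)
    grid = np.linspace(-beta_bound, beta_bound, grid_points)
    ll = _grid_loglik(y, env, model.omega, grid)[:, 0]
    ll0 = _grid_loglik(y, env, model.omega, np.array([0.0]))[0, 0]
    log_bf = logsumexp(ll) - np.log(len(grid)) - ll0
    return BfResult(snp, environment, float(np.exp(log_bf)), grid, ll)


def env_scan(
    freqs: np.ndarray,
    env_table: EnvTable,
    control: np.ndarray,
    populations: list[str] | None = None,
    snp_ids: list[str] | None = None,
    config: EnvScanConfig | None = None,
) -> pd.DataFrame:
    """Bayes factor for every (SNP, environmental variable) pair.

    ``freqs``: (L × m) candidate-SNP frequencies; ``control``: (L × m0)
    putatively neutral frequencies used once to estimate Ω (shared across
    the scan). Environment variables are z-standardized across
    populations; latitude enters as absolute degrees when
    ``config.absolute_latitude`` (the sunlight-exposure reading). Output
    is sorted by descending Bayes factor.
    """
    cfg = config or EnvScanConfig()
    F = np.asarray(freqs, dtype=float)
    L, m = F.shape
    if populations is None:
        populations = [f"POP{i}" for i in range(L)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    Yc, _ = standardize_freqs(np.asarray(control, dtype=float))
    model = estimate_covariance(Yc, populations, shrinkage=cfg.shrinkage)
    Y, kept = standardize_freqs(F)
    E = env_table.matrix(populations)  # (L, n_vars)
    grid = np.linspace(-cfg.beta_bound, cfg.beta_bound, cfg.grid_points)
    rows = []
    for v, var in enumerate(env_table.variables):
        e = E[:, v].astype(float)
        if cfg.absolute_latitude and var.lower().startswith("lat"):
            e = np.abs(e)
        e = (e - e.mean()) / e.std()
        ll = _grid_loglik(Y, e, model.omega, grid)          # (n_grid, m_kept)
        ll0 = _grid_loglik(Y, e, model.omega, np.array([0.0]))[0]
        log_bf = logsumexp(ll, axis=0) - np.log(len(grid)) - ll0
        for j, col in enumerate(kept):
            rows.append((snp_ids[col], var, float(np.exp(log_bf[j]))))
    df = pd.DataFrame(rows, columns=["snp", "env", "bf"])
    return df.sort_values("bf", ascending=False, kind="mergesort").reset_index(drop=True)
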