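"""The embedded Markov chain over 2M strains and its stationary distribution.

Each off-diagonal entry of the 2M x 2M chain is the strain-replacement rate
scaled by the uniform mutant-appearance probability 1/(2M); the diagonal
absorbs the remainder so rows are stochastic. Because each rate is at most
1/2, diagonals are always non-negative. The stationary distribution is the
left eigenvector at eigenvalue one; its mass on even-labeled (cooperative)
states is the overall cooperation level, and the cooperative strain carrying
the most mass defines the optimal repertoire size K_C*. Any uniform rescaling
of the off-diagonal rates leaves the stationary vector unchanged, which is
why the omitted mutation rate never matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import minimize_scalar

from .core import ModelParams, StrainSpace
from .transitions import rate_matrix

__all__ = [
    "DegenerateChainError",
    "TransitionMatrix",
    "StationaryResult",
    "BetaPeak",
    "build_chain",
    "stationary_distribution",
    "sweep",
    "find_beta_peak",
]

_RESIDUAL_TOL = 1e-10
_EIGENVALUE_GAP = 1e-9


class DegenerateChainError(RuntimeError):
    """The chain has no unique stationary distribution (eigenvalue-1 multiplicity > 1
    or the eigen-solve failed to meet the residual tolerance)."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic embedded chain plus its strain labeling."""

    A: np.ndarray
    space: StrainSpace
    params: ModelParams

    def rescaled(self, kappa: float) -> "TransitionMatrix":
        """Rebuild with all off-diagonal entries multiplied by kappa in (0, 1]."""
        if not (0.0 < kappa <= 1.0):
            raise ValueError("kappa must lie in (0, 1]")
        B = self.A * kappa
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, 1.0 - B.sum(axis=1))
        return TransitionMatrix(B, self.space, self.params)


@dataclass(frozen=True)
class StationaryResult:
    """Stationary vector with the derived summaries."""

    pi: np.ndarray
    space: StrainSpace
    params: ModelParams
    cooperation_level: float
    K_C_star: int
    K_D_star: int
    residual: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": np.arange(1, len(self.space) + 1),
                "strategy": [st.strategy.name for st in self.space.strains],
                "K": [st.K for st in self.space.strains],
                "pi": self.pi,
            }
        )


def build_chain(params: ModelParams, space: StrainSpace | None = None) -> TransitionMatrix:
    """Assemble the 2M x 2M embedded chain from the pairwise transition rates."""
    if space is None:
        space = StrainSpace(params.M)
    n = len(space)
    A = rate_matrix(params, space) / n
    np.fill_diagonal(A, 0.0)
    diag = 1.0 - A.sum(axis=1)
    if np.any(diag < 0):
        raise DegenerateChainError("negative diagonal: off-diagonal rates exceed 1")
    np.fill_diagonal(A, diag)
    return TransitionMatrix(A, space, params)


def stationary_distribution(tm: TransitionMatrix) -> StationaryResult:
    """Left eigenvector of the chain at eigenvalue one, with summaries.

    Computed as the right eigenvector of A^T; the real part is taken, the
    sign fixed, entries clipped at zero and renormalized, and the residual
    ``max |pi A - pi|`` is required to be below 1e-10. Ties for K_C* / K_D*
    resolve to the smallest repertoire size.
    """
    A = tm.A
    eigvals, eigvecs = linalg.eig(A.T)
    close = np.abs(eigvals - 1.0) < _EIGENVALUE_GAP
    if close.sum() > 1:
        raise DegenerateChainError(
            f"eigenvalue 1 has multiplicity {int(close.sum())}; chain is reducible"
        )
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    pi = np.real(eigvecs[:, idx])
    if pi.sum() < 0:
        pi = -pi
    if np.min(pi) < -1e-9:
        raise DegenerateChainError("stationary eigenvector has significantly negative entries")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.max(np.abs(pi @ A - pi)))
    if residual > _RESIDUAL_TOL:
        raise DegenerateChainError(f"stationary residual {residual:.2e} exceeds tolerance")

    coop = tm.space.coop_mask
    K = tm.space.repertoire
    cooperation_level = float(pi[coop].sum())
    def argmax_smallest_K(values: np.ndarray, Ks: np.ndarray) -> int:
        # ties (within eigen-solve noise) break toward the smallest repertoire
        top = values.max()
        return int(Ks[values >= top - 1e-12].min())

    K_C_star = argmax_smallest_K(pi[coop], K[coop])
    K_D_star = argmax_smallest_K(pi[~coop], K[~coop])
    return StationaryResult(pi, tm.space, tm.params, cooperation_level, K_C_star, K_D_star, residual)


def solve(params: ModelParams, space: StrainSpace | None = None) -> StationaryResult:
    """Convenience: build the chain and return its stationary distribution."""
    return stationary_distribution(build_chain(params, space))


def sweep(params: ModelParams, vary: str, grid) -> pd.DataFrame:
    """Stationary summaries along a parameter grid.

    ``vary`` is ``"theta"`` or ``"beta"``. Degenerate chains at individual
    grid points are recorded (``error`` column) without aborting the sweep.
    """
    if vary not in ("theta", "beta"):
        raise ValueError(f"vary must be 'theta' or 'beta', got {vary!r}")
    space = StrainSpace(params.M)
    rows = []
    for value in grid:
        row = {vary: float(value)}
        try:
            res = solve(params.replace(**{vary: float(value)}), space)
            row.update(
                cooperation_level=res.cooperation_level,
                K_C_star=res.K_C_star,
                K_D_star=res.K_D_star,
                error="",
            )
        except DegenerateChainError as exc:
            row.update(cooperation_level=np.nan, K_C_star=-1, K_D_star=-1, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BetaPeak:
    """Result of maximizing the cooperation level over selection intensity."""

    beta_c: float
    cooperation_level: float
    interior: bool  # False when the maximum sits on the search-range boundary


def find_beta_peak(
    params: ModelParams,
    beta_range: tuple = (1e-3, 0.2),
    n_grid: int = 40,
) -> BetaPeak:
    """Locate the selection intensity maximizing the overall cooperation level.

    A coarse grid scan over ``beta_range`` brackets the maximum, then a
    bounded golden-section-type refinement polishes it; the result is
    reported to 4 decimal places. If the grid argmax falls on a boundary of
    the range there is no interior peak within it: the boundary point is
    returned with ``interior=False`` and a warning.
    """
    lo, hi = beta_range
    if not (0.0 <= lo < hi):
        raise ValueError(f"invalid beta range {beta_range!r}")
    space = StrainSpace(params.M)

    def level(beta: float) -> float:
        return solve(params.replace(beta=float(beta)), space).cooperation_level

    grid = np.linspace(lo, hi, n_grid)
    values = np.array([level(g) for g in grid])
    j = int(np.argmax(values))
    if j in (0, n_grid - 1):
        warnings.warn("no interior peak: cooperation level is maximal at the range boundary")
        return BetaPeak(round(float(grid[j]), 4), float(values[j]), interior=False)

    res = minimize_scalar(
        lambda b: -level(b),
        bounds=(grid[j - 1], grid[j + 1]),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return BetaPeak(round(float(res.x), 4), float(-res.fun), interior=True)
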