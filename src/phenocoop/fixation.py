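"""Exact fixation probabilities for one mutant strain invading a resident.

For a birth-death (Moran) chain over the mutant count i = 0..N with
transition probabilities T_{i,i+1}, T_{i,i-1}, the probability that a single
mutant reaches fixation is the standard product formula

    phi_1 = ( 1 + sum_{l=1}^{N-1} prod_{k=1}^{l} T_{k,k-1} / T_{k,k+1} )^{-1}.

Under exponential fitness the ratio simplifies to
``T_{k,k-1}/T_{k,k+1} = exp(beta * (P_B(k) - P_A(k)))`` (the sampling factors
cancel), so the whole sum is accumulated in log space: the formula stays
finite for arbitrarily strong selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import ModelParams, Strain, StrainSpace, state_payoffs, fitness

__all__ = [
    "FixationQuery",
    "fixation_probability",
    "brute_force_fixation",
    "dvsd_closed_form",
    "fixation_matrices",
]

_BRUTE_FORCE_N_MAX = 12


@dataclass(frozen=True)
class FixationQuery:
    """A single-mutant invasion: mutant strain vs resident strain at fixed delta.

    ``delta`` is 1 when mutant and resident lineages express the same
    phenotype, 0 otherwise; it is frozen for the whole invasion (expressed
    phenotypes are inherited clonally between mutation events).
    """

    mutant: Strain
    resident: Strain
    delta: int
    params: ModelParams

    def __post_init__(self) -> None:
        if self.delta not in (0, 1):
            raise ValueError(f"delta must be 0 or 1, got {self.delta!r}")
        if self.params.N < 2:
            raise ValueError("fixation requires N >= 2")


def _log_backward_forward_ratios(query: FixationQuery) -> np.ndarray:
    """log(T_{k,k-1}/T_{k,k+1}) = beta * (P_B(k) - P_A(k)) for k = 1..N-1."""
    p = query.params
    k = np.arange(1, p.N)
    P_A, P_B = state_payoffs(k, query.mutant, query.resident, query.delta, p)
    return p.beta * (np.asarray(P_B) - np.asarray(P_A))


def fixation_probability(query: FixationQuery) -> float:
    """Fixation probability phi_1 of a single mutant, via the product formula.

    Evaluated entirely in log space (cumulative sums of the log payoff
    differences, then a log-sum-exp), so it is numerically exact from the
    neutral limit beta = 0 (returning 1/N) up to effectively infinite
    selection intensity. Result lies in (0, 1).
    """
    log_ratios = _log_backward_forward_ratios(query)
    log_terms = np.cumsum(log_ratios)  # log prod_{k<=l} for l = 1..N-1
    log_sum = logsumexp(log_terms)
    return float(np.exp(-np.logaddexp(0.0, log_sum)))


def brute_force_fixation(query: FixationQuery) -> float:
    """Independent oracle: solve the absorbing-chain linear system directly.

    Builds the full Moran transition probabilities T_{i,i+1} and T_{i,i-1}
    from the payoff kernel and fitness map, and solves

        phi_i = T_{i,i+1} phi_{i+1} + T_{i,i-1} phi_{i-1} + T_{i,i} phi_i,
        phi_0 = 0, phi_N = 1

    with a dense linear solve. Restricted to N <= 12: it exists to check
    :func:`fixation_probability` at small N, not to be fast.
    """
    p = query.params
    if p.N > _BRUTE_FORCE_N_MAX:
        raise ValueError(f"brute-force solve is restricted to N <= {_BRUTE_FORCE_N_MAX}")
    N = p.N
    i = np.arange(1, N)
    P_A, P_B = state_payoffs(i, query.mutant, query.resident, query.delta, p)
    P_A, P_B = np.atleast_1d(P_A), np.atleast_1d(P_B)
    # Shared shift keeps exp() finite; it cancels in the selection probabilities.
    shift = np.maximum(P_A, P_B)
    f_A = fitness(P_A - shift, p)
    g_B = fitness(P_B - shift, p)
    f_A, g_B = np.atleast_1d(f_A), np.atleast_1d(g_B)
    total = i * f_A + (N - i) * g_B
    T_up = (i * f_A / total) * ((N - i) / N)
    T_down = ((N - i) * g_B / total) * (i / N)

    # Unknowns phi_1..phi_{N-1}: -T_down*phi_{i-1} + (T_up+T_down)*phi_i - T_up*phi_{i+1} = rhs
    n = N - 1
    mat = np.zeros((n, n))
    rhs = np.zeros(n)
    for row in range(n):
        mat[row, row] = T_up[row] + T_down[row]
        if row > 0:
            mat[row, row - 1] = -T_down[row]
        if row < n - 1:
            mat[row, row + 1] = -T_up[row]
    rhs[-1] = T_up[-1]  # phi_N = 1
    phi = np.linalg.solve(mat, rhs)
    return float(phi[0])


def dvsd_closed_form(K_mutant: int, K_resident: int, params: ModelParams) -> float:
    """Fixation probability of a defector mutant in a defector resident population.

    Defectors earn only their maintenance cost, so fitnesses are constant in
    the mutant count and the product formula collapses to

        rho = (1 - e^{beta theta (K_mut - K_res)}) / (1 - e^{N beta theta (K_mut - K_res)})

    independent of the phenotype match. The neutral point
    ``beta * theta * (K_mut - K_res) = 0`` returns the limit value 1/N.
    Evaluated with expm1 (and a log-space factor for the positive-exponent
    branch) so it is accurate for both tiny and huge selection differentials.
    """
    x = params.beta * params.theta * (K_mutant - K_resident)
    N = params.N
    if x == 0.0:
        return 1.0 / N
    if x < 0:
        return float(np.expm1(x) / np.expm1(N * x))
    # x > 0: factor out the dominant exponentials to avoid overflow.
    return float(np.exp((1.0 - N) * x) * np.expm1(-x) / np.expm1(-N * x))


def fixation_matrices(params: ModelParams, space: StrainSpace | None = None):
    """Vectorized fixation probabilities over the whole 2M-strain space.

    Returns ``(rho_same, rho_diff)``, each of shape (2M, 2M), where entry
    ``[y, x]`` is the probability that a single mutant of the strain at
    position y fixates in a resident population of the strain at position x,
    with matching (rho_same) or non-matching (rho_diff) expressed phenotypes.
    Diagonal entries are the neutral 1/N (identical strains).

    This is the same arithmetic as :func:`fixation_probability`, broadcast
    over all ordered strain pairs at once; the embedded-chain builder depends
    on it for speed.
    """
    if space is None:
        space = StrainSpace(params.M)
    N, b, c, beta, theta = params.N, params.b, params.c, params.beta, params.theta
    s = space.coop_indicator
    K = space.repertoire
    i = np.arange(1, N, dtype=float)

    sA = s[:, None, None]  # mutant axis
    sB = s[None, :, None]  # resident axis
    KA = K[:, None, None]
    KB = K[None, :, None]
    ii = i[None, None, :]

    out = []
    for delta in (1, 0):
        P_A = (ii - 1) * (b - c) * sA + (N - ii) * (b * sB - c * sA) * delta - theta * KA
        P_B = ii * (b * sA - c * sB) * delta + (N - ii - 1) * (b - c) * sB - theta * KB
        log_terms = np.cumsum(beta * (P_B - P_A), axis=2)
        log_sum = logsumexp(log_terms, axis=2)
        out.append(np.exp(-np.logaddexp(0.0, log_sum)))
    return out[0], out[1]
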