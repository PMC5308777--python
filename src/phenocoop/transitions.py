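"""Expected transition rates between homogeneous strain states.

In the rare-mutation limit the population hops between the 2M homogeneous
strain states. The rate of leaving resident state X for mutant state Y
combines the chance that the mutant's first expressed phenotype matches the
residents' with the corresponding fixation probabilities (mutation rate
omitted as a common factor):

    r(X, Y) = H(K_Y - K_X) * (1/2) [ a_Y rho_s + (1 - a_Y) rho_d ]
            + (1 - H(K_Y - K_X)) * (1/2) [ (K_X - K_Y)/K_X * rho_d
                                           + K_Y/K_X * (a_Y rho_s + (1 - a_Y) rho_d) ]

with a_Y = 1/K_Y (random phenotypic switching), H the Heaviside step
(H(0) = 1), and rho_s / rho_d the fixation probabilities of a single Y mutant
in an X resident population with matching / non-matching phenotype. The 1/2
is the equal chance that a mutant is a cooperator or a defector.

Phenotype labels form a nested universe {1..K}: a strain with repertoire K
expresses a uniform label from {1..K}. A mutant with K_Y >= K_X then covers
the residents' label surely and matches it with probability 1/K_Y; a mutant
with K_Y < K_X covers it with probability K_Y/K_X first. This is the labeling
convention that both branches of the rate formula encode.
"""

from __future__ import annotations

import numpy as np

from .core import ModelParams, Strain, StrainSpace
from .fixation import FixationQuery, fixation_probability, fixation_matrices

__all__ = ["match_probability", "transition_rate", "rate_matrix"]


def match_probability(strain: Strain) -> float:
    """Probability alpha = 1/K that a strain's first expression matches a given label."""
    return 1.0 / strain.K


def _combine(rho_s: float, rho_d: float, K_X, K_Y) -> float:
    """Apply the two Heaviside branches of the rate formula."""
    alpha_Y = 1.0 / np.asarray(K_Y, dtype=float)
    inner = alpha_Y * rho_s + (1.0 - alpha_Y) * rho_d
    K_X = np.asarray(K_X, dtype=float)
    K_Y = np.asarray(K_Y, dtype=float)
    low = (K_X - K_Y) / K_X * rho_d + K_Y / K_X * inner
    return 0.5 * np.where(K_Y >= K_X, inner, low)


def transition_rate(resident: Strain, mutant: Strain, params: ModelParams) -> float:
    """Expected rate r(X -> Y) of the resident strain X being replaced by mutant Y.

    Probability per mutation event, in [0, 1/2]. The diagonal X = Y is the
    chain builder's business and is rejected here.
    """
    if resident == mutant:
        raise ValueError("transition_rate is defined between distinct strains")
    rho_s = fixation_probability(FixationQuery(mutant, resident, 1, params))
    rho_d = fixation_probability(FixationQuery(mutant, resident, 0, params))
    return float(_combine(rho_s, rho_d, resident.K, mutant.K))


def rate_matrix(
    params: ModelParams,
    space: StrainSpace | None = None,
    include_self: bool = False,
) -> np.ndarray:
    """All pairwise rates at once: R[x, y] = r(resident x -> mutant y).

    By default the diagonal is zeroed (in the embedded chain a same-strain
    mutant changes nothing). With ``include_self=True`` the diagonal instead
    carries the rate at which a distinct but identical-strain lineage would
    take over — the equal-coordinate points of an invasion surface, e.g. the
    neutral (1/2)(1/N) for a defector pair of equal repertoire.
    """
    if space is None:
        space = StrainSpace(params.M)
    rho_s, rho_d = fixation_matrices(params, space)  # [mutant, resident]
    K = space.repertoire
    K_X = K[:, None]  # resident (row = from-state)
    K_Y = K[None, :]  # mutant (column = to-state)
    R = _combine(rho_s.T, rho_d.T, K_X, K_Y)
    if not include_self:
        np.fill_diagonal(R, 0.0)
    return R
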