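"""Domain types and the pairwise payoff kernel.

The model couples a donation game to an evolvable phenotypic repertoire.
Each individual carries a triplet (G, S, K): the phenotype G it currently
expresses, its behavioral strategy S, and the number K of phenotypes it could
express. Contingent cooperators donate (pay ``c``, deliver ``b``) only to
partners expressing the same phenotype; everyone pays a maintenance cost
``theta * K`` for keeping K phenotypes expressible. Payoff maps to fitness
exponentially, ``f = exp(beta * payoff)``, and the population evolves by a
frequency-dependent Moran process.

This module holds the parameter container, the strategy/strain/individual
types, and the two-type payoff kernel that both the exact fixation analytics
and the stochastic simulator are built on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "Strategy",
    "ModelParams",
    "Strain",
    "Individual",
    "StrainSpace",
    "phenotype_cost",
    "state_payoffs",
    "fitness",
]


class Strategy(enum.Enum):
    """Behavioral strategy as a point (p, q) in the unit square.

    ``p`` is the probability of cooperating with a same-phenotype partner,
    ``q`` with a different-phenotype partner. Only the two discrete corners
    are constructible here: the contingent cooperator C = (1, 0) and the
    unconditional defector D = (0, 0).
    """

    C = (1.0, 0.0)
    D = (0.0, 0.0)

    @property
    def p(self) -> float:
        return self.value[0]

    @property
    def q(self) -> float:
        return self.value[1]

    @property
    def s(self) -> int:
        """Cooperation indicator used in the payoff formulas (1 for C, 0 for D)."""
        return 1 if self is Strategy.C else 0

    @classmethod
    def parse(cls, text: Union[str, "Strategy"]) -> "Strategy":
        if isinstance(text, Strategy):
            return text
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown strategy {text!r}; expected 'C' or 'D'") from None


@dataclass(frozen=True)
class ModelParams:
    """All scalar model constants.

    Parameters
    ----------
    N : population size (Moran process keeps it constant), integer >= 2.
    b : donation benefit, payoff units. Must exceed ``c``.
    c : donation cost, payoff units, > 0.
    beta : selection intensity (per payoff unit); 0 is neutral drift.
    theta : maintenance cost per potentially expressible phenotype.
    mu : mutation probability per birth, in [0, 1].
    M : maximum repertoire size, integer >= 1.

    Defaults are the model's standard parameter set (N=20, b=1, c=0.3,
    beta=0.1, theta=0.1, mu=0.002, M=50).
    """

    N: int = 20
    b: float = 1.0
    c: float = 0.3
    beta: float = 0.1
    theta: float = 0.1
    mu: float = 0.002
    M: int = 50

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ValueError(f"N must be an integer >= 2, got {self.N!r}")
        if not (self.b > self.c > 0):
            raise ValueError(f"donation game requires b > c > 0, got b={self.b}, c={self.c}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not (isinstance(self.M, (int, np.integer)) and self.M >= 1):
            raise ValueError(f"M must be an integer >= 1, got {self.M!r}")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for key, value in data.items():
            if key not in known:
                continue
            if key in ("N", "M"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelParams":
        """Load parameters from a flat YAML mapping (keys N, b, c, beta, theta, mu, M).

        Unknown keys (e.g. ``seed``) are ignored so a single config file can
        also drive the simulator.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class Strain:
    """A homogeneous type: behavioral strategy plus repertoire size K.

    Strains are the states of the rare-mutation embedded Markov chain.
    """

    strategy: Strategy
    K: int

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError(f"repertoire size K must be an integer >= 1, got {self.K!r}")
        object.__setattr__(self, "K", int(self.K))

    @property
    def s(self) -> int:
        return self.strategy.s

    @property
    def label(self) -> int:
        """1-based chain label: cooperative strains are even (2K), defective odd (2K-1)."""
        return 2 * self.K if self.strategy is Strategy.C else 2 * self.K - 1

    def __str__(self) -> str:  # e.g. "C(K=8)"
        return f"{self.strategy.name}(K={self.K})"


@dataclass(frozen=True)
class Individual:
    """Agent triplet (G, S, K): expressed phenotype, strategy, repertoire size."""

    phenotype: int
    strategy: Strategy
    K: int

    def __post_init__(self) -> None:
        if not (1 <= self.phenotype <= self.K):
            raise ValueError(
                f"expressed phenotype must lie in the individual's repertoire "
                f"[1, {self.K}], got {self.phenotype}"
            )

    @property
    def strain(self) -> Strain:
        return Strain(self.strategy, self.K)


@dataclass(frozen=True)
class StrainSpace:
    """The ordered set of all 2M strains and its labeling.

    Chain label convention: the cooperative strain with repertoire K_C gets
    even label 2*K_C, the defective strain with K_D the odd label 2*K_D - 1.
    Array position = label - 1 (0-based), so positions 0, 2, 4, ... hold
    defectors with K = 1, 2, 3, ... and positions 1, 3, 5, ... cooperators.
    """

    M: int
    strains: tuple = field(repr=False, default=())

    def __post_init__(self) -> None:
        if not self.strains:
            ordered = []
            for label in range(1, 2 * self.M + 1):
                if label % 2 == 0:
                    ordered.append(Strain(Strategy.C, label // 2))
                else:
                    ordered.append(Strain(Strategy.D, (label + 1) // 2))
            object.__setattr__(self, "strains", tuple(ordered))

    def __len__(self) -> int:
        return 2 * self.M

    def position(self, strain: Strain) -> int:
        """0-based array position of a strain (its chain label minus one)."""
        if strain.K > self.M:
            raise ValueError(f"strain K={strain.K} exceeds the repertoire cap M={self.M}")
        return strain.label - 1

    @property
    def coop_indicator(self) -> np.ndarray:
        """Vector s over positions: 1 for cooperative strains, 0 for defective."""
        return np.array([st.s for st in self.strains], dtype=float)

    @property
    def repertoire(self) -> np.ndarray:
        """Vector K over positions."""
        return np.array([st.K for st in self.strains], dtype=float)

    @property
    def coop_mask(self) -> np.ndarray:
        return self.coop_indicator.astype(bool)


def phenotype_cost(strain: Strain, params: ModelParams) -> float:
    """Maintenance cost of a repertoire: kappa(K) = theta * K, in payoff units."""
    return params.theta * strain.K


def state_payoffs(i, A: Strain, B: Strain, delta: int, params: ModelParams):
    """Total payoffs of an A and a B individual when i copies of A face N-i of B.

    During an invasion all A's express one phenotype and all B's another (or
    the same): ``delta`` is 1 if the two expressed phenotypes match, else 0.
    Payoffs are totals over all pairwise interactions, self-interaction
    excluded::

        P_A = (i-1)(b-c) s_A + (N-i)(b s_B - c s_A) delta - theta K_A
        P_B = i (b s_A - c s_B) delta + (N-i-1)(b-c) s_B - theta K_B

    ``i`` may be a scalar or an integer array in [1, N-1]; payoffs broadcast.
    """
    if delta not in (0, 1):
        raise ValueError(f"delta must be 0 or 1, got {delta!r}")
    i = np.asarray(i)
    if np.any(i < 1) or np.any(i > params.N - 1):
        raise ValueError(f"i must lie in [1, N-1] = [1, {params.N - 1}]")
    b, c, theta, N = params.b, params.c, params.theta, params.N
    sA, sB = A.s, B.s
    P_A = (i - 1) * (b - c) * sA + (N - i) * (b * sB - c * sA) * delta - theta * A.K
    P_B = i * (b * sA - c * sB) * delta + (N - i - 1) * (b - c) * sB - theta * B.K
    if P_A.ndim == 0:
        return float(P_A), float(P_B)
    return P_A.astype(float), P_B.astype(float)


def fitness(payoff, params: ModelParams):
    """Exponential payoff-to-fitness map f = exp(beta * payoff).

    Neutral selection (beta = 0) gives fitness 1 for any payoff. Downstream
    code works with payoff *differences* in log space, never with raw fitness
    ratios, so strong selection does not overflow; call this only on payoffs
    of moderate magnitude.
    """
    out = np.exp(params.beta * np.asarray(payoff, dtype=float))
    return float(out) if out.ndim == 0 else out
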