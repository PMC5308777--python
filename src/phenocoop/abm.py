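"""Stochastic agent-based Moran simulator with combinational mutation.

Each of the N agents carries (G, S, K): expressed phenotype, strategy,
repertoire size. One update step: every agent's total payoff over all
pairwise encounters is computed from scratch (a cooperator pays c to every
same-phenotype partner and receives b from every same-phenotype cooperator;
everyone pays theta*K; no self-interaction); a parent is drawn with
probability proportional to exp(beta * payoff); a uniformly random agent
among the N present dies; the offspring takes its slot. With probability mu
the offspring is a combinational mutant — strategy uniform over {C, D},
repertoire K' uniform over {1..M}, expressed phenotype uniform over {1..K'} —
otherwise it inherits the parent's triplet verbatim (clonal expression).

Phenotype labels live in the nested universe {1..K}, so the chance that a
fresh mutant matches a resident's label reproduces the analytic match
probabilities. The long-run loops are jit-compiled with numba; the
step-by-step Python API (:class:`Population`, :func:`moran_step`) exists for
inspection and small-scale work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .core import ModelParams, Strain, Strategy, StrainSpace

__all__ = [
    "Population",
    "SimulationResult",
    "FixationEstimate",
    "payoffs",
    "moran_step",
    "run_simulation",
    "fixation_frequency",
]

_MAX_INVASION_STEPS = 50_000_000


# ---------------------------------------------------------------------------
# Python-level population and single step
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """N agents as parallel arrays plus the generator driving their updates."""

    phenotype: np.ndarray
    is_coop: np.ndarray
    repertoire: np.ndarray
    rng: np.random.Generator

    def __post_init__(self) -> None:
        n = len(self.phenotype)
        if not (len(self.is_coop) == len(self.repertoire) == n):
            raise ValueError("population arrays must have equal length")
        if np.any(self.phenotype < 1) or np.any(self.phenotype > self.repertoire):
            raise ValueError("every expressed phenotype must lie in [1, K] of its carrier")

    @property
    def N(self) -> int:
        return len(self.phenotype)

    @classmethod
    def random(cls, params: ModelParams, seed) -> "Population":
        """Uniformly random initial population: S ~ U{C,D}, K ~ U{1..M}, G ~ U{1..K}."""
        rng = np.random.default_rng(seed)
        K = rng.integers(1, params.M + 1, size=params.N)
        G = rng.integers(1, K + 1)
        S = rng.integers(0, 2, size=params.N)
        return cls(G.astype(np.int64), S.astype(np.int64), K.astype(np.int64), rng)

    @classmethod
    def homogeneous(cls, strain: Strain, phenotype: int, N: int, seed) -> "Population":
        rng = np.random.default_rng(seed)
        return cls(
            np.full(N, phenotype, dtype=np.int64),
            np.full(N, strain.s, dtype=np.int64),
            np.full(N, strain.K, dtype=np.int64),
            rng,
        )

    def strain_counts(self, M: int) -> np.ndarray:
        """Counts per chain position (length 2M): cooperators at 2K-1, defectors at 2K-2."""
        pos = np.where(self.is_coop == 1, 2 * self.repertoire - 1, 2 * self.repertoire - 2)
        return np.bincount(pos, minlength=2 * M).astype(np.int64)

    def strains_present(self) -> set:
        return {
            Strain(Strategy.C if s else Strategy.D, int(k))
            for s, k in zip(self.is_coop, self.repertoire)
        }


def payoffs(pop: Population, params: ModelParams) -> np.ndarray:
    """Total payoff of every agent over all pairwise interactions."""
    g, s, K = pop.phenotype, pop.is_coop, pop.repertoire
    size = int(g.max()) + 1
    n_pheno = np.bincount(g, minlength=size)
    n_coop = np.bincount(g[s == 1], minlength=size)
    return (
        params.b * (n_coop[g] - s)
        - params.c * s * (n_pheno[g] - 1)
        - params.theta * K
    ).astype(float)


def moran_step(pop: Population, params: ModelParams) -> Population:
    """One in-place birth-death update; returns the same population object."""
    pay = payoffs(pop, params)
    w = np.exp(params.beta * (pay - pay.max()))
    parent = int(pop.rng.choice(pop.N, p=w / w.sum()))
    dead = int(pop.rng.integers(pop.N))
    if pop.rng.random() < params.mu:
        s_new = int(pop.rng.integers(2))
        k_new = int(pop.rng.integers(1, params.M + 1))
        g_new = int(pop.rng.integers(1, k_new + 1))
    else:
        s_new = int(pop.is_coop[parent])
        k_new = int(pop.repertoire[parent])
        g_new = int(pop.phenotype[parent])
    pop.phenotype[dead] = g_new
    pop.is_coop[dead] = s_new
    pop.repertoire[dead] = k_new
    return pop


# ---------------------------------------------------------------------------
# jit-compiled long-run kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _one_step(G, S, K, N, M, b, c, theta, beta, mu, pay, n_pheno, n_coop):
    for g in range(M + 1):
        n_pheno[g] = 0
        n_coop[g] = 0
    for i in range(N):
        n_pheno[G[i]] += 1
        if S[i] == 1:
            n_coop[G[i]] += 1
    pmax = -1.0e300
    for i in range(N):
        p = b * (n_coop[G[i]] - S[i]) - c * S[i] * (n_pheno[G[i]] - 1) - theta * K[i]
        pay[i] = p
        if p > pmax:
            pmax = p
    total = 0.0
    for i in range(N):
        pay[i] = np.exp(beta * (pay[i] - pmax))
        total += pay[i]
    u = np.random.random() * total
    parent = N - 1
    acc = 0.0
    for i in range(N):
        acc += pay[i]
        if u <= acc:
            parent = i
            break
    dead = np.random.randint(0, N)
    if np.random.random() < mu:
        s_new = 1 if np.random.random() < 0.5 else 0
        k_new = 1 + np.random.randint(0, M)
        g_new = 1 + np.random.randint(0, k_new)
    else:
        s_new = S[parent]
        k_new = K[parent]
        g_new = G[parent]
    G[dead] = g_new
    S[dead] = s_new
    K[dead] = k_new


@njit(cache=True)
def _run_kernel(G, S, K, N, M, b, c, theta, beta, mu, steps, record_every, seed, store_counts):
    np.random.seed(seed)
    n_rec = steps // record_every
    occupancy = np.zeros(2 * M)
    t_arr = np.empty(n_rec, dtype=np.int64)
    n_coop_arr = np.empty(n_rec, dtype=np.int64)
    mean_kc = np.full(n_rec, np.nan)
    mean_kd = np.full(n_rec, np.nan)
    counts = np.zeros((n_rec if store_counts else 1, 2 * M), dtype=np.int64)
    pay = np.empty(N)
    n_pheno = np.zeros(M + 1, dtype=np.int64)
    n_coop_ph = np.zeros(M + 1, dtype=np.int64)
    rec = 0
    for t in range(steps):
        _one_step(G, S, K, N, M, b, c, theta, beta, mu, pay, n_pheno, n_coop_ph)
        if (t + 1) % record_every == 0:
            nc = 0
            sum_kc = 0
            sum_kd = 0
            for i in range(N):
                pos = 2 * K[i] - 1 if S[i] == 1 else 2 * K[i] - 2
                occupancy[pos] += 1.0 / N
                if store_counts:
                    counts[rec, pos] += 1
                if S[i] == 1:
                    nc += 1
                    sum_kc += K[i]
                else:
                    sum_kd += K[i]
            t_arr[rec] = t + 1
            n_coop_arr[rec] = nc
            if nc > 0:
                mean_kc[rec] = sum_kc / nc
            if nc < N:
                mean_kd[rec] = sum_kd / (N - nc)
            rec += 1
    return occupancy, t_arr, n_coop_arr, mean_kc, mean_kd, counts


@njit(cache=True)
def _invasion_kernel(
    g_mut, s_mut, k_mut, g_res, s_res, k_res,
    N, M, b, c, theta, beta, replicates, seed, max_steps,
):
    np.random.seed(seed)
    G = np.empty(N, dtype=np.int64)
    S = np.empty(N, dtype=np.int64)
    K = np.empty(N, dtype=np.int64)
    pay = np.empty(N)
    n_pheno = np.zeros(M + 1, dtype=np.int64)
    n_coop_ph = np.zeros(M + 1, dtype=np.int64)
    fixed = 0
    for _ in range(replicates):
        G[0] = g_mut
        S[0] = s_mut
        K[0] = k_mut
        for i in range(1, N):
            G[i] = g_res
            S[i] = s_res
            K[i] = k_res
        for _step in range(max_steps):
            _one_step(G, S, K, N, M, b, c, theta, beta, 0.0, pay, n_pheno, n_coop_ph)
            count = 0
            for i in range(N):
                if G[i] == g_mut and S[i] == s_mut and K[i] == k_mut:
                    count += 1
            if count == 0:
                break
            if count == N:
                fixed += 1
                break
    return fixed


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory summaries plus the strain-occupancy histogram.

    ``occupancy`` sums to one over the 2M chain positions: at each recording
    point every agent contributes 1/N to its strain's bin, so mixed snapshots
    are assigned fractionally by strain counts.
    """

    trajectory: pd.DataFrame
    occupancy: np.ndarray
    counts: Optional[np.ndarray]
    params: ModelParams
    seed: int
    steps: int
    record_every: int

    def occupancy_frame(self) -> pd.DataFrame:
        space = StrainSpace(self.params.M)
        return pd.DataFrame(
            {
                "label": np.arange(1, 2 * self.params.M + 1),
                "strategy": [st.strategy.name for st in space.strains],
                "K": [st.K for st in space.strains],
                "occupancy": self.occupancy,
            }
        )


def run_simulation(
    params: ModelParams,
    steps: int,
    seed: int,
    record_every: int = 100,
    init: Optional[Population] = None,
    store_counts: Optional[bool] = None,
) -> SimulationResult:
    """Run the Moran process for ``steps`` birth-death updates.

    Starts from a uniformly random population unless ``init`` is given.
    Identical seeds yield identical trajectories. Full per-record strain
    counts are kept only when small enough to be cheap (or when forced with
    ``store_counts=True``).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if record_every < 1 or record_every > steps:
        raise ValueError("record_every must lie in [1, steps]")
    pop = Population.random(params, seed) if init is None else init
    if pop.N != params.N:
        raise ValueError(f"initial population size {pop.N} != params.N {params.N}")
    n_rec = steps // record_every
    if store_counts is None:
        store_counts = n_rec * 2 * params.M <= 2_000_000
    G = pop.phenotype.copy()
    S = pop.is_coop.copy()
    K = pop.repertoire.copy()
    occ, t_arr, n_coop, mean_kc, mean_kd, counts = _run_kernel(
        G, S, K, params.N, params.M,
        params.b, params.c, params.theta, params.beta, params.mu,
        int(steps), int(record_every), int(seed) % 2**31, bool(store_counts),
    )
    occ = occ / n_rec
    traj = pd.DataFrame(
        {
            "time": t_arr,
            "n_coop": n_coop,
            "coop_fraction": n_coop / params.N,
            "mean_K_C": mean_kc,
            "mean_K_D": mean_kd,
        }
    )
    return SimulationResult(
        traj, occ, counts if store_counts else None,
        params, int(seed), int(steps), int(record_every),
    )


@dataclass(frozen=True)
class FixationEstimate:
    """Replicate fixation frequency of a single mutant, with its standard error."""

    frequency: float
    std_error: float
    replicates: int
    fixed: int


def _phenotypes_for_delta(mutant: Strain, resident: Strain, delta: int):
    """Pick concrete expressed labels realizing the requested match indicator."""
    if delta == 1:
        return 1, 1
    if mutant.K > 1:
        return 2, 1
    if resident.K > 1:
        return 1, 2
    raise ValueError("delta=0 needs at least one repertoire with K >= 2")


def fixation_frequency(
    mutant: Strain,
    resident: Strain,
    params: ModelParams,
    replicates: int,
    seed: int,
    delta: Optional[int] = None,
) -> FixationEstimate:
    """Estimate a single mutant's fixation probability by replicated invasions.

    Each replicate seeds one mutant into N-1 residents and runs the process
    (mu = 0) until one lineage owns the population. With ``delta`` in {0, 1}
    the expressed phenotypes are pinned to realize that match indicator; with
    ``delta=None`` both lineages draw their labels uniformly from their own
    repertoires, replicating how a fresh mutant meets a resident strain.
    """
    rng = np.random.default_rng(seed)
    if delta is None:
        g_res = rng.integers(1, resident.K + 1, size=replicates)
        g_mut = rng.integers(1, mutant.K + 1, size=replicates)
        n_match = int(np.sum(g_mut == g_res))
        groups = [(1, n_match), (0, replicates - n_match)]
    else:
        groups = [(int(delta), replicates)]
    fixed = 0
    for d, reps in groups:
        if reps == 0:
            continue
        if d == 1 and mutant == resident:
            raise ValueError("mutant and resident are indistinguishable at delta=1")
        g_m, g_r = _phenotypes_for_delta(mutant, resident, d)
        sub_seed = int(rng.integers(2**31))
        fixed += int(
            _invasion_kernel(
                g_m, mutant.s, mutant.K, g_r, resident.s, resident.K,
                params.N, params.M, params.b, params.c, params.theta, params.beta,
                int(reps), sub_seed, _MAX_INVASION_STEPS,
            )
        )
    freq = fixed / replicates
    se = float(np.sqrt(max(freq * (1.0 - freq), 1e-12) / replicates))
    return FixationEstimate(freq, se, int(replicates), int(fixed))
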