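"""Canned reproduction pipelines tying the modules together.

Three studies: the pairwise invasion-rate surfaces over repertoire sizes for
each mutant/resident strategy combination; the stationary distribution and
overall cooperation level across maintenance costs, optionally overlaid with
agent-based occupancy; and the cost/selection sweeps with the optimal
cooperative repertoire K_C* and the cooperation-maximizing selection
intensity. CSV/JSON tables are the canonical outputs; every file embeds the
full parameter set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import ModelParams, Strategy, StrainSpace
from .transitions import rate_matrix
from .markov import solve, sweep, find_beta_peak
from .abm import run_simulation

__all__ = [
    "invasion_surfaces",
    "stationary_vs_cost",
    "diversity_sweeps",
    "write_csv",
]

STRATEGY_PAIRS = [("D", "D"), ("C", "D"), ("D", "C"), ("C", "C")]


def _provenance(params: ModelParams, **extra) -> dict:
    meta = {"version": __version__, **params.to_dict(), **extra}
    return meta


def write_csv(df: pd.DataFrame, path: Path, params: ModelParams, **extra) -> None:
    """Write a CSV with the full parameter set embedded as comment header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in _provenance(params, **extra).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def invasion_surfaces(
    params: ModelParams,
    k_max: Optional[int] = None,
    out_dir: Optional[Path] = None,
) -> dict:
    """Transition-rate surfaces r(resident -> mutant) over repertoire grids.

    Returns one long-format table (K_resident, K_mutant, rate) per
    (mutant strategy, resident strategy) combination, evaluated on
    K in {1..k_max}^2 (k_max defaults to M).
    """
    k_max = params.M if k_max is None else int(k_max)
    work = params.replace(M=k_max)
    space = StrainSpace(k_max)
    # equal-coordinate points carry the identical-strain (neutral-lineage) rate
    R = rate_matrix(work, space, include_self=True)  # R[x, y] = resident x -> mutant y
    coop = space.coop_mask
    K = space.repertoire.astype(int)
    surfaces = {}
    for mut_strat, res_strat in STRATEGY_PAIRS:
        rows = coop if res_strat == "C" else ~coop
        cols = coop if mut_strat == "C" else ~coop
        sub = R[np.ix_(rows, cols)]
        kr, km = np.meshgrid(K[rows], K[cols], indexing="ij")
        df = pd.DataFrame(
            {"K_resident": kr.ravel(), "K_mutant": km.ravel(), "rate": sub.ravel()}
        )
        surfaces[(mut_strat, res_strat)] = df
        if out_dir is not None:
            write_csv(
                df,
                Path(out_dir) / f"invasion_{mut_strat}_into_{res_strat}.csv",
                work,
                mutant_strategy=mut_strat,
                resident_strategy=res_strat,
            )
    return surfaces


def stationary_vs_cost(
    theta_list: Sequence[float],
    params: Optional[ModelParams] = None,
    out_dir: Optional[Path] = None,
    simulate: bool = False,
    steps: int = 2_000_000,
    seed: int = 0,
    record_every: int = 100,
) -> pd.DataFrame:
    """Stationary distribution per maintenance cost, optionally with ABM overlay.

    Returns a summary table (theta, cooperation_level, K_C_star, K_D_star and,
    when ``simulate`` is set, the occupancy-derived cooperation level and the
    total-variation distance between analytic and simulated distributions).
    Per-theta stationary vectors (and occupancy histograms) go to ``out_dir``.
    """
    params = ModelParams() if params is None else params
    rows = []
    for j, theta in enumerate(theta_list):
        p = params.replace(theta=float(theta))
        res = solve(p)
        row = {
            "theta": float(theta),
            "cooperation_level": res.cooperation_level,
            "K_C_star": res.K_C_star,
            "K_D_star": res.K_D_star,
        }
        frame = res.to_frame()
        if simulate:
            sim = run_simulation(p, steps=steps, seed=seed + j, record_every=record_every)
            frame["occupancy"] = sim.occupancy
            row["sim_cooperation_level"] = float(
                sim.occupancy[StrainSpace(p.M).coop_mask].sum()
            )
            row["tv_distance"] = 0.5 * float(np.abs(sim.occupancy - res.pi).sum())
        if out_dir is not None:
            write_csv(frame, Path(out_dir) / f"stationary_theta_{theta}.csv", p)
        rows.append(row)
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        write_csv(summary, Path(out_dir) / "stationary_summary.csv", params)
    return summary


def diversity_sweeps(
    params: Optional[ModelParams] = None,
    theta_grid: Optional[Sequence[float]] = None,
    beta_grid: Optional[Sequence[float]] = None,
    out_dir: Optional[Path] = None,
) -> dict:
    """Cost and selection-intensity sweeps plus the cooperation-maximizing beta.

    The theta sweep runs at the parameter set's beta; the beta sweep and the
    peak search run at its theta. Returns the two sweep tables and the peak.
    """
    params = ModelParams() if params is None else params
    theta_grid = np.linspace(0.0, 1.0, 21) if theta_grid is None else theta_grid
    beta_grid = np.linspace(1e-3, 0.2, 41) if beta_grid is None else beta_grid
    theta_table = sweep(params, "theta", theta_grid)
    beta_table = sweep(params, "beta", beta_grid)
    peak = find_beta_peak(params)
    if out_dir is not None:
        write_csv(theta_table, Path(out_dir) / "sweep_theta.csv", params)
        write_csv(beta_table, Path(out_dir) / "sweep_beta.csv", params)
        out = Path(out_dir) / "beta_peak.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(
            json.dumps(
                {
                    **_provenance(params),
                    "beta_c": peak.beta_c,
                    "cooperation_level": peak.cooperation_level,
                    "interior": peak.interior,
                },
                indent=2,
            )
        )
    return {"theta": theta_table, "beta": beta_table, "beta_peak": peak}
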