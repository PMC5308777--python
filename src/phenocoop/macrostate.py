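"""Coarse-graining of trajectories into macro-states.

A snapshot is labeled by which strategy class dominates and by that class's
mean repertoire size, banded into Low (0, 3], Middle (3, 38] and High
(38, M] diversity (right-closed as printed on the band edges). If neither
class reaches the dominance threshold but both hold at least 1 - threshold
of the population, the snapshot is a coexistence state such as ``C_M+D_L``;
anything else is ``mixed``. Persistence and switching between macro-states
are estimated empirically as row-normalized transition counts at a chosen
lag, in units of recording intervals — the model itself fixes no natural
time unit for these frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["diversity_band", "classify", "classify_trajectory", "empirical_transitions"]

DEFAULT_BANDS = (3.0, 38.0)
DEFAULT_THRESHOLD = 0.95


def diversity_band(mean_K: float, bands=DEFAULT_BANDS) -> str:
    """Band label for a mean repertoire size: L for (0, 3], M for (3, 38], H above."""
    low, mid = bands
    if not np.isfinite(mean_K) or mean_K <= 0:
        raise ValueError(f"mean repertoire size must be positive, got {mean_K!r}")
    if mean_K <= low:
        return "L"
    if mean_K <= mid:
        return "M"
    return "H"


def classify(
    n_coop: int,
    n_def: int,
    mean_K_C: float,
    mean_K_D: float,
    threshold: float = DEFAULT_THRESHOLD,
    bands=DEFAULT_BANDS,
) -> str:
    """Macro-state label of one snapshot. Total function: always returns a label."""
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"dominance threshold must lie in (0.5, 1], got {threshold}")
    N = n_coop + n_def
    if N <= 0:
        raise ValueError("empty snapshot")
    fc = n_coop / N
    fd = n_def / N
    if fc >= threshold:
        return f"C_{diversity_band(mean_K_C, bands)}"
    if fd >= threshold:
        return f"D_{diversity_band(mean_K_D, bands)}"
    if fc >= 1.0 - threshold and fd >= 1.0 - threshold:
        return f"C_{diversity_band(mean_K_C, bands)}+D_{diversity_band(mean_K_D, bands)}"
    return "mixed"


def classify_trajectory(
    trajectory: pd.DataFrame,
    N: int,
    threshold: float = DEFAULT_THRESHOLD,
    bands=DEFAULT_BANDS,
) -> pd.Series:
    """Label every record of a simulator trajectory (columns n_coop, mean_K_C, mean_K_D)."""
    labels = [
        classify(
            int(row.n_coop), N - int(row.n_coop),
            float(row.mean_K_C), float(row.mean_K_D),
            threshold, bands,
        )
        for row in trajectory.itertuples()
    ]
    return pd.Series(labels, index=trajectory.index, name="macrostate")


def empirical_transitions(labels, lag: int = 1) -> pd.DataFrame:
    """Row-normalized macro-state transition frequencies at the given lag.

    Rows/columns are the visited macro-states; entry (a, b) is the fraction
    of times state a was followed, ``lag`` recording intervals later, by
    state b. A ``visits`` column counts outgoing observations per state.
    """
    labels = list(labels)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(labels) < lag + 1:
        raise ValueError("trajectory must span at least one lag")
    states = sorted(set(labels))
    index = {s: k for k, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for a, b in zip(labels[:-lag], labels[lag:]):
        counts[index[a], index[b]] += 1
    visits = counts.sum(axis=1)
    freq = np.divide(counts, visits[:, None], out=np.zeros_like(counts), where=visits[:, None] > 0)
    out = pd.DataFrame(freq, index=states, columns=states)
    out["visits"] = visits.astype(int)
    return out
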