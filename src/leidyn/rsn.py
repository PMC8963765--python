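"""Spatial overlap of state prototypes with reference resting-state
networks.

Each prototype is rectified (negative elements set to zero, keeping only
the regions that split away from the global mode) and correlated with each
reference network's parcel-composition vector: entry (r, n) of the
reference table is the fraction of parcel n's voxels assigned to network
r.  A prototype whose rectified form is constant (notably the globally
synchronized state, all elements non-positive) has no defined correlation
and is reported as overlapping with no network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import StateRepertoire

__all__ = [
    "YEO7_NAMES",
    "rectify",
    "overlap",
    "read_rsn_table",
    "synthetic_rsn_table",
]

YEO7_NAMES = [
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
]


def rectify(prototype: np.ndarray) -> np.ndarray:
    """Elementwise ``max(v, 0)``: keep only regions split from the global
    mode."""
    return np.maximum(np.asarray(prototype, dtype=float), 0.0)


def read_rsn_table(path) -> pd.DataFrame:
    """Read a networks x parcels fraction table (TSV, network names as the
    first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("RSN fractions must lie in [0, 1]")
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("RSN table has an all-zero network row")
    return df


def synthetic_rsn_table(
    N: int = 90, names: list[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in for a reference-network composition table.

    Assigns each parcel a dominant network (contiguous blocks) with a high
    voxel fraction and spreads small fractions over the remaining networks.
    Purely synthetic: it reproduces the format and the row/column
    invariants of a real atlas-derived table, not its anatomy.
    """
    names = names or YEO7_NAMES
    r = len(names)
    rng = np.random.default_rng(seed)
    table = rng.uniform(0.0, 0.08, size=(r, N))
    dominant = np.repeat(np.arange(r), int(np.ceil(N / r)))[:N]
    table[dominant, np.arange(N)] = rng.uniform(0.6, 0.95, size=N)
    return pd.DataFrame(table, index=names)


def overlap(repertoire: StateRepertoire, rsn: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between each rectified prototype and each
    reference network.

    Returns a tidy table (``state, network, r, p, best_match,
    no_overlap``); ``best_match`` flags the network maximizing r for each
    state, and ``no_overlap`` flags states whose rectified prototype has
    zero variance (correlation undefined).
    """
    networks = rsn.to_numpy(dtype=float)
    if networks.shape[1] != repertoire.n_regions:
        raise ValueError(
            f"RSN table has {networks.shape[1]} parcels, repertoire has "
            f"{repertoire.n_regions}"
        )
    rows = []
    for a in range(1, repertoire.K + 1):
        v = rectify(repertoire.prototypes[a - 1])
        degenerate = np.ptp(v) == 0
        rs = np.full(networks.shape[0], np.nan)
        ps = np.full(networks.shape[0], np.nan)
        if not degenerate:
            for j, net in enumerate(networks):
                if np.ptp(net) == 0:
                    continue
                rs[j], ps[j] = scipy.stats.pearsonr(v, net)
        best = int(np.nanargmax(rs)) if not degenerate and np.any(np.isfinite(rs)) else None
        for j, name in enumerate(rsn.index):
            rows.append(
                {
                    "state": a,
                    "network": name,
                    "r": rs[j],
                    "p": ps[j],
                    "best_match": best is not None and j == best,
                    "no_overlap": bool(degenerate),
                }
            )
    return pd.DataFrame(rows)
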