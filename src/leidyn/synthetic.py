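"""Synthetic two-group cohorts with planted phase-coherence states.

Each scan is generated from a hidden per-group Markov chain over a small
repertoire of planted states.  A planted state is a community of regions in
anti-phase (pi offset) with the rest of the brain; the all-false mask is the
globally synchronized state.  Regional signals are cosines of a shared slow
carrier plus independent Wiener phase noise, plus additive Gaussian
observation noise.  Because the community offset is exactly pi, the leading
eigenvector of the noiseless phase-coherence matrix is the (sign-convention
oriented) indicator contrast of the community mask, so every downstream
stage has analytic ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ParcellatedScan

__all__ = [
    "PlantedState",
    "CohortSpec",
    "ScanTruth",
    "CohortTruth",
    "global_state",
    "community_state",
    "stationary_of_tpm",
    "generate_scan",
    "generate_cohort",
    "write_cohort",
    "default_cohort_spec",
    "two_state_cohort_spec",
]


@dataclass(frozen=True)
class PlantedState:
    """A planted phase-coherence pattern.

    ``community_mask`` flags the regions in anti-phase with the rest; the
    all-false mask is the global-coherence state.  The community is the
    minority by construction (at most N/2 regions), matching the downstream
    eigenvector sign convention.
    """

    community_mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "community_mask", np.asarray(self.community_mask, dtype=bool))
        n = self.community_mask.size
        if self.community_mask.sum() > n // 2:
            raise ValueError(
                f"planted state {self.label!r}: community must cover at most N/2 regions"
            )


def global_state(n_regions: int, label: str = "global") -> PlantedState:
    """The globally synchronized state (empty community)."""
    return PlantedState(np.zeros(n_regions, dtype=bool), label)


def community_state(n_regions: int, regions: Sequence[int], label: str) -> PlantedState:
    """A state with the given regions in anti-phase with the rest."""
    mask = np.zeros(n_regions, dtype=bool)
    mask[np.asarray(regions, dtype=int)] = True
    return PlantedState(mask, label)


def _validate_tpm(tpm: np.ndarray, k: int, name: str) -> np.ndarray:
    tpm = np.asarray(tpm, dtype=float)
    if tpm.shape != (k, k):
        raise ValueError(f"TPM for group {name!r} must be {k}x{k}, got {tpm.shape}")
    if np.any(tpm < 0):
        raise ValueError(f"TPM for group {name!r} has negative entries")
    rows = tpm.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ValueError(f"TPM for group {name!r}: rows must sum to 1 within 1e-9")
    return tpm


def stationary_of_tpm(tpm: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solved via ``pi = 1 (I - P + ONE)^-1``; falls back to the uniform
    distribution if the linear system is singular (reducible chain).
    """
    tpm = np.asarray(tpm, dtype=float)
    k = tpm.shape[0]
    a = np.eye(k) - tpm + np.ones((k, k))
    try:
        pi = np.linalg.solve(a.T, np.ones(k))
    except np.linalg.LinAlgError:
        return np.full(k, 1.0 / k)
    return pi


@dataclass
class CohortSpec:
    """Generation parameters for a two-group synthetic cohort.

    ``group_tpms`` maps each group label to a row-stochastic hidden-state
    transition matrix over the planted ``states``; ``n_per_group`` maps the
    same labels to scan counts.  The hidden state is piecewise-constant over
    volumes (one state per TR).
    """

    n_per_group: Mapping[str, int]
    states: Sequence[PlantedState]
    group_tpms: Mapping[str, np.ndarray]
    N: int = 90
    T: int = 150
    TR: float = 2.0
    carrier_freq_hz: float = 0.05
    phase_noise_sd: float = 0.05
    obs_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if not self.states:
            raise ValueError("at least one planted state required")
        for st in self.states:
            if st.community_mask.size != self.N:
                raise ValueError(f"state {st.label!r} mask length != N={self.N}")
        if set(self.n_per_group) != set(self.group_tpms):
            raise ValueError("n_per_group and group_tpms must share group labels")
        k = len(self.states)
        self.group_tpms = {
            g: _validate_tpm(tpm, k, g) for g, tpm in self.group_tpms.items()
        }
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative scan count for group {g!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)


@dataclass
class ScanTruth:
    """Ground truth for one generated scan: the hidden state sequence
    (1-based, length T) and the generating group chain."""

    subject_id: str
    group: str
    hidden_states: np.ndarray
    tpm: np.ndarray
    stationary: np.ndarray

    def hidden_occupancy(self, n_states: int) -> np.ndarray:
        """Empirical fractional occupancy of the hidden sequence."""
        counts = np.bincount(self.hidden_states, minlength=n_states + 1)[1:]
        return counts / self.hidden_states.size


@dataclass
class CohortTruth:
    """Per-scan hidden sequences plus per-group generating chains."""

    scans: list[ScanTruth] = field(default_factory=list)
    group_tpms: dict = field(default_factory=dict)
    group_stationary: dict = field(default_factory=dict)


def _simulate_chain(tpm: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    k = tpm.shape[0]
    pi0 = stationary_of_tpm(tpm)
    pi0 = np.clip(pi0, 0, None)
    pi0 = pi0 / pi0.sum()
    states = np.empty(t, dtype=int)
    cdf = np.cumsum(tpm, axis=1)
    u = rng.random(t)
    states[0] = np.searchsorted(np.cumsum(pi0), u[0], side="right")
    for i in range(1, t):
        states[i] = np.searchsorted(cdf[states[i - 1]], u[i], side="right")
    return np.minimum(states, k - 1) + 1  # 1-based labels


def generate_scan(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> tuple[ParcellatedScan, ScanTruth]:
    """Generate one scan of the given group.

    The regional phase is ``2*pi*f*TR*t`` (shared carrier) plus an
    independent per-region Wiener walk with per-volume standard deviation
    ``phase_noise_sd``, plus a pi offset for regions inside the active
    planted state's community.  The observed signal is the cosine of that
    phase plus i.i.d. Gaussian noise.
    """
    if group not in spec.group_tpms:
        raise ValueError(f"unknown group {group!r}")
    tpm = spec.group_tpms[group]
    hidden = _simulate_chain(tpm, spec.T, rng)

    t_idx = np.arange(spec.T)
    carrier = 2.0 * np.pi * spec.carrier_freq_hz * spec.TR * t_idx  # (T,)
    if spec.phase_noise_sd > 0:
        wiener = np.cumsum(
            rng.normal(0.0, spec.phase_noise_sd, size=(spec.N, spec.T)), axis=1
        )
    else:
        wiener = np.zeros((spec.N, spec.T))
    masks = np.stack([st.community_mask for st in spec.states])  # (K, N)
    offsets = np.pi * masks[hidden - 1].T  # (N, T)
    theta = carrier[None, :] + wiener + offsets
    signal = np.cos(theta)
    if spec.obs_noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.obs_noise_sd, size=signal.shape)

    scan = ParcellatedScan(signal, spec.TR, subject_id, group)
    truth = ScanTruth(subject_id, group, hidden, tpm, stationary_of_tpm(tpm))
    return scan, truth


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ParcellatedScan], CohortTruth, pd.DataFrame]:
    """Generate all scans of the cohort, reproducibly for a fixed seed.

    A single cohort seed deterministically spawns one RNG substream per
    scan, so generation order (or parallelism) cannot change the output.
    Returns the scans, the ground truth, and a manifest table with columns
    ``subject_id, group, tr_seconds``.
    """
    total = sum(spec.n_per_group.values())
    if total == 0:
        raise ValueError("empty cohort: all group counts are zero")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(total)
    scans: list[ParcellatedScan] = []
    truth = CohortTruth(
        group_tpms={g: np.asarray(t) for g, t in spec.group_tpms.items()},
        group_stationary={g: stationary_of_tpm(t) for g, t in spec.group_tpms.items()},
    )
    rows = []
    i = 0
    for group in spec.groups:
        for j in range(spec.n_per_group[group]):
            subject_id = f"sub-{group}-{j:03d}"
            rng = np.random.default_rng(children[i])
            scan, st = generate_scan(spec, group, rng, subject_id)
            scans.append(scan)
            truth.scans.append(st)
            rows.append({"subject_id": subject_id, "group": group, "tr_seconds": spec.TR})
            i += 1
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "tr_seconds"])
    return scans, truth, manifest


def write_cohort(
    scans: Sequence[ParcellatedScan],
    truth: CohortTruth,
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write scans (one TSV per scan), manifest, hidden sequences and the
    generating chains to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for scan in scans:
        p = out / f"{scan.subject_id}.tsv"
        np.savetxt(p, scan.signal, delimiter="\t", fmt="%.17g")
        paths.append(p.name)
    man = manifest.copy()
    man["path"] = paths
    manifest_path = out / "manifest.tsv"
    man.to_csv(manifest_path, sep="\t", index=False)
    with open(out / "hidden_states.tsv", "w") as fh:
        for st in truth.scans:
            fh.write(st.subject_id + "\t" + "\t".join(map(str, st.hidden_states)) + "\n")
    with open(out / "group_chains.json", "w") as fh:
        json.dump(
            {
                g: {
                    "tpm": truth.group_tpms[g].tolist(),
                    "stationary": truth.group_stationary[g].tolist(),
                }
                for g in truth.group_tpms
            },
            fh,
            indent=2,
        )
    return manifest_path


def two_state_cohort_spec(
    n_per_group: tuple[int, int] = (30, 30),
    occupancy: tuple[float, float] = (0.425, 0.375),
    switching_rate: float = 0.6,
    community_size: int = 30,
    N: int = 90,
    T: int = 150,
    seed: int = 0,
    groups: tuple[str, str] = ("A", "B"),
    **kwargs,
) -> CohortSpec:
    """Two planted states (global + one community) with a controlled group
    difference in community-state occupancy.

    The hidden chain of group ``g`` is ``[[1-a, a], [b, 1-b]]`` with
    ``a = s * pi_g`` and ``b = s * (1 - pi_g)``, where ``s`` is the
    switching rate and ``pi_g`` the community-state stationary mass, so the
    asymptotic occupancy variance ``pi(1-pi)(2-s)/(s T)`` is matched across
    groups up to the occupancy difference.  The default occupancies
    (0.425 vs 0.375, s = 0.6, T = 150) give a planted between-scan effect
    of Hedges' g ~= 0.8 on community-state fractional occupancy.  Setting
    ``occupancy`` equal in both groups yields a null cohort.
    """
    states = [
        global_state(N),
        community_state(N, range(community_size), "community"),
    ]
    tpms = {}
    for g, pi in zip(groups, occupancy):
        a = switching_rate * pi
        b = switching_rate * (1.0 - pi)
        tpms[g] = np.array([[1.0 - a, a], [b, 1.0 - b]])
    return CohortSpec(
        n_per_group={groups[0]: n_per_group[0], groups[1]: n_per_group[1]},
        states=states,
        group_tpms=tpms,
        N=N,
        T=T,
        seed=seed,
        **kwargs,
    )


def default_cohort_spec(
    n_per_group: tuple[int, int] = (10, 10),
    N: int = 90,
    T: int = 150,
    seed: int = 0,
    groups: tuple[str, str] = ("A", "B"),
    **kwargs,
) -> CohortSpec:
    """Three planted states (global + two communities) with a moderate group
    difference in global-state occupancy; convenient for smoke tests and
    examples."""
    third = N // 3
    states = [
        global_state(N),
        community_state(N, range(third), "community-1"),
        community_state(N, range(third, 2 * third), "community-2"),
    ]
    tpm_a = np.array(
        [
            [0.70, 0.15, 0.15],
            [0.30, 0.60, 0.10],
            [0.30, 0.10, 0.60],
        ]
    )
    tpm_b = np.array(
        [
            [0.55, 0.225, 0.225],
            [0.40, 0.50, 0.10],
            [0.40, 0.10, 0.50],
        ]
    )
    return CohortSpec(
        n_per_group={groups[0]: n_per_group[0], groups[1]: n_per_group[1]},
        states=states,
        group_tpms={groups[0]: tpm_a, groups[1]: tpm_b},
        N=N,
        T=T,
        seed=seed,
        **kwargs,
    )
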