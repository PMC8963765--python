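"""End-to-end orchestration: scans -> eigenvectors -> states -> dynamics ->
group statistics, with a serialized run record.

``run_pipeline`` ties the stages together for a whole cohort and a range
of K, writing tidy TSV tables into an output directory.  Transition and
limiting-probability statistics, which the state-trajectory analysis only
interprets at a chosen partition, are computed for ``optimal_k`` when set.
All randomness derives from the single config seed, so two runs with the
same config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import cluster
from .dynamics import (
    assign_trajectory,
    chain_diagnostics_table,
    measures_table,
    transition_model,
    transitions_table,
)
from .io import read_cohort, write_table
from .phase import eigenseries, pool_eigenvectors
from .rsn import overlap, read_rsn_table
from .stats import TestSpec, compare_all
from .validation import validation_report

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline"]

log = logging.getLogger("leidyn")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    manifest: str
    out_dir: str
    rsn_table: str | None = None
    K_range: list[int] = field(default_factory=lambda: list(range(2, 21)))
    algorithm: str = "kmeans"
    n_restarts: int = 1000
    optimal_k: int | None = None
    B: int = 10_000
    n_boot: int = 500
    tails: str = "two"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs are
        written and how verbosely is not part of the analysis identity)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("out_dir", "log_level")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one run: config snapshot, software version, seeds,
    per-stage timings and collected warnings; serialized next to the
    outputs."""

    config: dict
    config_hash: str
    version: str
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Per K: a ranked state repertoire, per-scan trajectories, the tidy
    measures table and occupancy/dwell group tests.  For ``optimal_k``
    (when set): per-scan transition models, chain diagnostics, transition
    and limiting-probability group tests.  A validation report (silhouette
    and Dunn per K) and, when an RSN table is configured, per-K overlap
    tables are also written.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(
        config=config.to_dict(), config_hash=config.config_hash(), version=__version__
    )
    t0 = time.perf_counter()

    scans = read_cohort(config.manifest)
    log.info("read %d scans", len(scans))
    record.timings["read"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        series = [eigenseries(s) for s in scans]
    record.warnings.extend(str(w.message) for w in caught)
    pool, meta = pool_eigenvectors(series)
    pooled = meta.copy()
    pooled[[f"v{i + 1}" for i in range(pool.shape[1])]] = pool
    write_table(pooled, out / "pooled_eigenvectors.tsv")
    record.timings["leida"] = time.perf_counter() - t1

    rsn = read_rsn_table(config.rsn_table) if config.rsn_table else None
    ss = np.random.SeedSequence(config.seed)
    test_seed = int(ss.generate_state(1)[0] % (2**31))
    solutions = {}
    for K in config.K_range:
        tk = time.perf_counter()
        rep = cluster(
            pool,
            K,
            algorithm=config.algorithm,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        solutions[K] = rep
        np.savetxt(out / f"prototypes_K{K}.tsv", rep.prototypes, delimiter="\t", fmt="%.17g")
        np.savetxt(out / f"assignments_K{K}.tsv", rep.assignments, fmt="%d")

        trajectories = [assign_trajectory(es, rep) for es in series]
        measures = measures_table(trajectories, K)
        measures.insert(0, "config_hash", record.config_hash)
        write_table(measures, out / f"measures_K{K}.tsv")

        spec = TestSpec(B=config.B, n_boot=config.n_boot, tails=config.tails, seed=test_seed)
        for measure in ("fo", "dt"):
            res = compare_all(measures, measure, K, spec)
            res.insert(0, "config_hash", record.config_hash)
            write_table(res, out / f"stats_{measure}_K{K}.tsv")

        if config.optimal_k == K:
            models = [transition_model(tr, K) for tr in trajectories]
            trans = transitions_table(models)
            diag = chain_diagnostics_table(models)
            write_table(trans, out / f"transitions_K{K}.tsv")
            write_table(diag, out / f"chain_diagnostics_K{K}.tsv")
            res = compare_all(trans, "transition", K, spec)
            res.insert(0, "config_hash", record.config_hash)
            write_table(res, out / f"stats_transition_K{K}.tsv")
            res = compare_all(diag, "limiting", K, spec)
            res.insert(0, "config_hash", record.config_hash)
            write_table(res, out / f"stats_limiting_K{K}.tsv")

        if rsn is not None:
            write_table(overlap(rep, rsn), out / f"overlap_K{K}.tsv")
        record.timings[f"K={K}"] = time.perf_counter() - tk
        log.info("finished K=%d", K)

    report = validation_report(pool, solutions)
    report.insert(0, "config_hash", record.config_hash)
    write_table(report, out / "validation_report.tsv")
    record.timings["total"] = time.perf_counter() - t0
    record.save(out / "run_record.json")
    return out
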