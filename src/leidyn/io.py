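"""Plain-text I/O for scans, manifests and result tables.

The canonical scan format is a tab-separated numeric table with regions as
rows and volumes as columns; the cohort manifest is a TSV with columns
``subject_id, group, tr_seconds, path`` (paths relative to the manifest's
directory).  Numeric tables are written with 17 significant digits so that
a read/write round trip is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ParcellatedScan

__all__ = ["read_scan", "write_scan", "read_manifest", "read_cohort", "write_table"]

MANIFEST_COLUMNS = ["subject_id", "group", "tr_seconds", "path"]


def _locate_bad_cell(path: Path) -> tuple[int, int, str]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            for j, cell in enumerate(line.rstrip("\n").split("\t"), start=1):
                try:
                    float(cell)
                except ValueError:
                    return i, j, cell
    return -1, -1, ""


def read_scan(
    path, subject_id: str = "", group: str = "", tr: float = 1.0
) -> ParcellatedScan:
    """Read one regions x volumes TSV into a :class:`ParcellatedScan`.

    Malformed numeric cells raise a ``ValueError`` naming the offending row
    and column.
    """
    path = Path(path)
    try:
        signal = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as err:
        i, j, cell = _locate_bad_cell(path)
        if i > 0:
            raise ValueError(
                f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
            ) from err
        raise ValueError(f"{path}: malformed scan table: {err}") from err
    return ParcellatedScan(signal, tr, subject_id or path.stem, group)


def write_scan(scan: ParcellatedScan, path) -> Path:
    path = Path(path)
    np.savetxt(path, scan.signal, delimiter="\t", fmt="%.17g")
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read and schema-check a cohort manifest TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: manifest has no scans")
    return df


def read_cohort(manifest_path) -> list[ParcellatedScan]:
    """Read every scan listed in a manifest; aborts naming the file on the
    first unreadable scan, and on inconsistent region counts."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    scans = []
    n_regions = None
    for row in manifest.itertuples(index=False):
        p = base / row.path
        if not p.exists():
            raise FileNotFoundError(f"scan file not found: {p}")
        scan = read_scan(p, row.subject_id, row.group, float(row.tr_seconds))
        if n_regions is None:
            n_regions = scan.n_regions
        elif scan.n_regions != n_regions:
            raise ValueError(
                f"{p}: has {scan.n_regions} regions, expected {n_regions}"
            )
        scans.append(scan)
    return scans


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a tidy result table as TSV (full float precision)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
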