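"""CSV/JSON readers and writers for every pipeline artifact.

All tables round-trip losslessly: writers emit labeled CSV with an index
column, readers restore the same frame (binary matrices come back as
integers, distance matrices as :class:`DistanceMatrix`).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import grids
from .distances import DistanceMatrix


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="host_id")


def read_environment(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


def read_incidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="parasite_id")
    return df.astype(np.int8)


def write_pam(pam: grids.PresenceAbsenceMatrix, path) -> None:
    pam.to_frame().to_csv(path)


def read_pam(path, grid: grids.GridSpec) -> grids.PresenceAbsenceMatrix:
    df = pd.read_csv(path, index_col="host_id")
    return grids.PresenceAbsenceMatrix(list(df.index), grid, df.to_numpy())


def write_distance_matrix(dm: DistanceMatrix, path, report_path=None,
                          report: dict | None = None) -> None:
    dm.to_frame().to_csv(path)
    if report_path is not None:
        payload = {"kind": dm.kind, "normalized": dm.normalized}
        payload.update(report or {})
        write_json(payload, report_path)


def read_distance_matrix(path, kind: str, normalized: bool = True) -> DistanceMatrix:
    df = pd.read_csv(path, index_col="host_id")
    return DistanceMatrix(list(df.index), df.to_numpy(float), kind=kind,
                          normalized=normalized)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
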