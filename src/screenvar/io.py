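"""Reading and writing the pipeline's delimited-text formats.

All interchange is lowest-common-denominator text: UTF-8 comma-separated
CSV with a header row for tables, a GAL-style neighbor list for adjacency
(``area_id: n1 n2 ...`` per line), and JSON for the synthetic ground truth
and run provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .adjacency import Adjacency
from .standardization import AGE_BANDS, ScreeningCounts, band_column
from .synthetic import TrueParameters

__all__ = [
    "read_counts", "write_counts", "read_areas", "write_areas",
    "read_adjacency", "write_adjacency", "read_truth", "write_truth",
]

AREA_COUNT_COLUMNS = ["area_id", "period", "invitees", "screened"]
NATIONAL_COUNT_COLUMNS = ["age", "year", "invitees", "screened"]
AREA_COLUMNS = ["area_id", "state", "remoteness", "disadvantage",
                "centroid_x", "centroid_y"] + [band_column(lo, hi) for lo, hi in AGE_BANDS]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_counts(area_path: str | Path, national_path: str | Path | None = None) -> ScreeningCounts:
    """Load area-level (and optionally national age/year) screening counts,
    validating the schema; violations are reported with file line numbers
    (header = line 1)."""
    area_path = Path(area_path)
    area = pd.read_csv(area_path)
    _require_columns(area, AREA_COUNT_COLUMNS, area_path)
    bad = area["screened"] > area["invitees"]
    if bad.any():
        lines = (area.index[bad] + 2).tolist()[:5]
        raise ValueError(f"{area_path}: screened > invitees at line(s) {lines}")
    neg = (area[["invitees", "screened"]] < 0).any(axis=1)
    if neg.any():
        lines = (area.index[neg] + 2).tolist()[:5]
        raise ValueError(f"{area_path}: negative counts at line(s) {lines}")
    national = pd.DataFrame()
    if national_path is not None:
        national_path = Path(national_path)
        national = pd.read_csv(national_path)
        _require_columns(national, NATIONAL_COUNT_COLUMNS, national_path)
    return ScreeningCounts(area=area, national=national)


def write_counts(counts: ScreeningCounts, area_path: str | Path,
                 national_path: str | Path | None = None) -> None:
    counts.area.to_csv(area_path, index=False)
    if national_path is not None and len(counts.national):
        counts.national.to_csv(national_path, index=False)


def read_areas(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    areas = pd.read_csv(path)
    _require_columns(areas, AREA_COLUMNS, path)
    if areas["area_id"].duplicated().any():
        dup = areas.loc[areas["area_id"].duplicated(), "area_id"].tolist()[:5]
        raise ValueError(f"{path}: duplicate area ids {dup}")
    return areas


def write_areas(areas: pd.DataFrame, path: str | Path) -> None:
    areas.to_csv(path, index=False)


def read_adjacency(path: str | Path) -> Adjacency:
    return Adjacency.from_gal(path)


def write_adjacency(adj: Adjacency, path: str | Path) -> None:
    adj.to_gal(path)


def write_truth(truth: TrueParameters, ids: list, path: str | Path) -> None:
    """Ground-truth sidecar for parameter-recovery tests."""
    payload = {
        "area_id": [str(a) for a in ids],
        "psi": np.asarray(truth.psi, float).tolist(),
        "theta": np.asarray(truth.theta, float).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> tuple[list, TrueParameters]:
    payload = json.loads(Path(path).read_text())
    truth = TrueParameters(psi=np.array(payload["psi"]), theta=np.array(payload["theta"]))
    return payload["area_id"], truth
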