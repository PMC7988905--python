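"""Readers and writers for the canonical delimited-text microdata schema.

Data dictionary (header row required, comma-delimited):

    country     string  country name
    cluster_id  string  primary sampling unit id, nested within country
    rural       0/1     1 = rural residence (group A)
    weight      float   positive sampling weight
    outcome     0/1     1 = outcome event (e.g. recent illness episode)
    <other>     number  every additional column is kept as a covariate
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import REQUIRED_COLUMNS, SurveyDataset
from .errors import ParseError, SchemaError


def read_microdata(path) -> SurveyDataset:
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"country": str, "cluster_id": str},
        float_precision="round_trip",
    )
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    for col in ("rural", "outcome"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = ~vals.isin((0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"{path.name}: non-binary {col} value "
                f"{frame[col].iloc[row - 1]!r} on row {row}"
            )
        frame[col] = vals.astype(np.int64)
    w = pd.to_numeric(frame["weight"], errors="coerce")
    bad = ~(w > 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path.name}: invalid weight on row {row}")
    frame["weight"] = w.astype(float)
    for col in frame.columns:
        if col not in REQUIRED_COLUMNS:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
            if frame[col].isna().any():
                row = int(np.flatnonzero(frame[col].isna().to_numpy())[0]) + 1
                raise ParseError(
                    f"{path.name}: non-numeric covariate {col!r} on row {row}"
                )
    return SurveyDataset(frame=frame, provenance=str(path))


def write_microdata(data: SurveyDataset, path) -> None:
    data.frame.to_csv(path, index=False)
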