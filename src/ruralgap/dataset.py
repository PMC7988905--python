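"""Canonical child-level microdata container.

One row per under-five child with the columns

    country, cluster_id, rural, weight, outcome, <covariate columns...>

``rural`` and ``outcome`` are 0/1 integers, ``weight`` is a positive
sampling weight, and every column not in the required set is treated as a
covariate. The container is a thin typed wrapper around a
:class:`pandas.DataFrame`; all downstream computation is columnar.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ParseError

REQUIRED_COLUMNS = ("country", "cluster_id", "rural", "weight", "outcome")


@dataclass(frozen=True)
class ChildRecord:
    """A single child row (a convenience view, not the storage format)."""

    country: str
    cluster_id: str
    rural: int
    weight: float
    outcome: int
    covariates: Mapping[str, float]


@dataclass
class SurveyDataset:
    """Ordered collection of child records plus a provenance string."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_COLUMNS]

    @property
    def n_children(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(self.frame) == 0:
            raise SchemaError("dataset is empty")
        f = self.frame
        for col in ("rural", "outcome"):
            bad = ~f[col].isin((0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ParseError(
                    f"non-binary {col} value {f[col].iloc[row - 1]!r} on row {row}"
                )
        if (f["weight"] <= 0).any():
            row = int(np.flatnonzero((f["weight"] <= 0).to_numpy())[0]) + 1
            raise ParseError(f"non-positive weight on row {row}")
        # no cluster may span countries
        span = f.groupby("cluster_id")["country"].nunique()
        multi = span[span > 1]
        if len(multi):
            raise ParseError(
                f"cluster {multi.index[0]!r} spans more than one country"
            )

    def records(self) -> Iterator[ChildRecord]:
        covs = self.covariate_names
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            yield ChildRecord(
                country=d["country"],
                cluster_id=d["cluster_id"],
                rural=int(d["rural"]),
                weight=float(d["weight"]),
                outcome=int(d["outcome"]),
                covariates={c: d[c] for c in covs},
            )

    def equals(self, other: "SurveyDataset") -> bool:
        return self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )
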