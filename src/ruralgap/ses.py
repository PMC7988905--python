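"""Neighbourhood socioeconomic index.

Clusters are profiled by three weighted deprivation proportions — children
of mothers with no education, of poor households (bottom two wealth
quintiles), and of unemployed mothers — and scored on the first principal
component of the standardised proportions. The score is oriented so that
higher means more disadvantaged, then clusters are cut into quintiles
weighted by child count (quintile 1 = highest SES, 5 = lowest).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import SurveyDataset
from .errors import DegenerateInputError, SchemaError

#: covariate columns the profiler looks for
EDUCATION_COL = "no_education"
WEALTH_COL = "wealth"
POOR_COL = "poor_household"
EMPLOYMENT_COL = "unemployed"

#: wealth quintile values counted as "poor" when WEALTH_COL is used
POOR_WEALTH_LEVELS = (1, 2)


@dataclass(frozen=True)
class ClusterProfile:
    country: str
    cluster_id: str
    n_children: int
    prop_no_education: float
    prop_poor_household: float
    prop_unemployed: float


@dataclass
class SESIndex:
    """First-component scores keyed by (country, cluster_id)."""

    scores: dict[tuple[str, str], float]
    loadings: np.ndarray
    explained_variance_share: float
    quintile: dict[tuple[str, str], int]


def cluster_profiles(data: SurveyDataset) -> list[ClusterProfile]:
    """One weighted deprivation profile per (country, cluster)."""
    f = data.frame
    for col in (EDUCATION_COL, EMPLOYMENT_COL):
        if col not in f.columns:
            raise SchemaError(f"missing required covariate {col!r}")
    if POOR_COL in f.columns:
        poor = f[POOR_COL].to_numpy(dtype=float)
    elif WEALTH_COL in f.columns:
        poor = f[WEALTH_COL].isin(POOR_WEALTH_LEVELS).to_numpy(dtype=float)
    else:
        raise SchemaError(
            f"missing required covariate {WEALTH_COL!r} (or {POOR_COL!r})"
        )
    work = pd.DataFrame(
        {
            "country": f["country"],
            "cluster_id": f["cluster_id"],
            "w": f["weight"].to_numpy(dtype=float),
            "edu": f[EDUCATION_COL].to_numpy(dtype=float),
            "poor": poor,
            "unemp": f[EMPLOYMENT_COL].to_numpy(dtype=float),
        }
    )
    for c in ("edu", "poor", "unemp"):
        work[c] = work[c] * work["w"]
    g = work.groupby(["country", "cluster_id"], sort=True)
    agg = g[["w", "edu", "poor", "unemp"]].sum()
    n = g.size()
    out = []
    for (country, cid), row in agg.iterrows():
        out.append(
            ClusterProfile(
                country=country,
                cluster_id=cid,
                n_children=int(n.loc[(country, cid)]),
                prop_no_education=row["edu"] / row["w"],
                prop_poor_household=row["poor"] / row["w"],
                prop_unemployed=row["unemp"] / row["w"],
            )
        )
    return out


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    mu = x.mean(axis=0)
    z = np.zeros_like(x)
    nz = sd > 0
    z[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return z


def compute_ses_index(profiles: Sequence[ClusterProfile]) -> SESIndex:
    """First principal component of the standardised deprivation proportions.

    PCA is on the correlation matrix (columns standardised to mean 0,
    SD 1); a zero-variance column contributes nothing. The component sign
    is fixed so the score correlates nonnegatively with the no-education
    proportion (falling back to the other proportions if it is constant).
    """
    if len(profiles) < 5:
        raise DegenerateInputError("need at least 5 cluster profiles")
    x = np.array(
        [
            [p.prop_no_education, p.prop_poor_household, p.prop_unemployed]
            for p in profiles
        ],
        dtype=float,
    )
    if np.allclose(x.std(axis=0), 0.0):
        raise DegenerateInputError(
            "all cluster profiles identical: zero variance in every proportion"
        )
    z = _standardise(x)
    cov = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    loading = eigvec[:, -1]
    share = float(eigval[-1] / eigval.sum())
    score = z @ loading
    # orient: more deprivation => higher score
    for col in range(3):
        c = float(np.dot(score - score.mean(), z[:, col]))
        if abs(c) > 1e-12:
            if c < 0:
                loading = -loading
                score = -score
            break
    keys = [(p.country, p.cluster_id) for p in profiles]
    counts = np.array([p.n_children for p in profiles], dtype=float)
    quint = _child_weighted_quintiles(score, counts, keys)
    return SESIndex(
        scores=dict(zip(keys, score.tolist())),
        loadings=loading,
        explained_variance_share=share,
        quintile=quint,
    )


def _child_weighted_quintiles(
    score: np.ndarray, counts: np.ndarray, keys: list[tuple[str, str]]
) -> dict[tuple[str, str], int]:
    """Cut clusters into 5 bins so ~20% of children land in each.

    Clusters are ranked by score ascending (ties broken by key, so the
    assignment is deterministic); each cluster is placed by the midpoint
    of its child-count interval. Quintile 1 = lowest score = highest SES.
    """
    order = sorted(range(len(score)), key=lambda i: (score[i], keys[i]))
    total = counts.sum()
    quint: dict[tuple[str, str], int] = {}
    cum = 0.0
    for i in order:
        mid = cum + counts[i] / 2.0
        q = int(math.floor(5.0 * mid / total)) + 1
        quint[keys[i]] = min(max(q, 1), 5)
        cum += counts[i]
    return quint


def ses_by_country(data: SurveyDataset, pooled: bool = False) -> dict[str, SESIndex]:
    """SES index per country (default) or one pooled index for all clusters.

    Returns a map country -> SESIndex; under ``pooled=True`` the single
    index is stored under the key ``"__pooled__"``.
    """
    profiles = cluster_profiles(data)
    if pooled:
        return {"__pooled__": compute_ses_index(profiles)}
    out: dict[str, SESIndex] = {}
    for country in sorted({p.country for p in profiles}):
        out[country] = compute_ses_index(
            [p for p in profiles if p.country == country]
        )
    return out


def attach_ses(
    data: SurveyDataset, indexes: dict[str, SESIndex], column: str = "ses_quintile"
) -> SurveyDataset:
    """Return a copy of the dataset with each child's cluster SES quintile."""
    quint: dict[tuple[str, str], int] = {}
    for idx in indexes.values():
        quint.update(idx.quintile)
    f = data.frame.copy()
    keys = list(zip(f["country"], f["cluster_id"]))
    f[column] = [quint[k] for k in keys]
    return SurveyDataset(frame=f, provenance=data.provenance + "+ses")


def ses_table(indexes: dict[str, SESIndex]) -> pd.DataFrame:
    rows = []
    for idx in indexes.values():
        for (country, cid), s in sorted(idx.scores.items()):
            rows.append(
                {
                    "country": country,
                    "cluster_id": cid,
                    "score": s,
                    "quintile": idx.quintile[(country, cid)],
                }
            )
    return pd.DataFrame(rows)
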