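"""Group prevalences, risk differences and meta-analytic pooling.

Conventions (logged in pipeline manifests):

* point estimates use sampling weights; variances use unweighted group
  sizes unless Kish effective sample sizes are requested;
* risk differences are rural minus non-rural, scaled per 1000 children,
  with Wald normal confidence intervals and no continuity correction;
* chi-square association tests run on unweighted counts;
* all tests are two-sided at alpha = 0.05 with no multiplicity adjustment;
* random-effects pooling uses the DerSimonian-Laird moment estimator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurveyDataset
from .errors import (
    DegenerateTableError,
    DegenerateTestError,
    EstimationError,
    PoolingError,
)

Z975 = stats.norm.ppf(0.975)

PRO_RURAL = "pro-rural"
PRO_NONRURAL = "pro-non-rural"
NOT_SIGNIFICANT = "not-significant"


@dataclass(frozen=True)
class PrevalenceEstimate:
    group: str
    p: float
    n_unweighted: int
    sum_weights: float


@dataclass(frozen=True)
class RiskDifference:
    """Rural minus non-rural prevalence difference per 1000 children."""

    country: str
    rd_per_1000: float
    se_per_1000: float
    ci95: tuple[float, float]
    z: float
    p_value: float


@dataclass(frozen=True)
class MetaEstimate:
    rd_per_1000: float
    se_per_1000: float
    ci95: tuple[float, float]
    z: float
    p_value: float


@dataclass(frozen=True)
class MetaResult:
    fixed_effect: MetaEstimate
    random_effect: MetaEstimate
    tau2: float
    q: float
    df: int
    weights_percent: dict[str, float]


@dataclass(frozen=True)
class InequalityClass:
    country: str
    category: str


def weighted_prevalence(
    data: SurveyDataset | pd.DataFrame,
    group_filter=None,
    label: str = "all",
) -> PrevalenceEstimate:
    """Weighted outcome prevalence p = sum(w*y)/sum(w) over a subset.

    ``group_filter`` may be None (everyone), a boolean mask aligned to the
    frame, or a callable mapping the frame to such a mask.
    """
    f = data.frame if isinstance(data, SurveyDataset) else data
    if group_filter is not None:
        mask = group_filter(f) if callable(group_filter) else group_filter
        f = f[np.asarray(mask, dtype=bool)]
    if len(f) == 0:
        raise EstimationError(f"group {label!r}: empty subset")
    w = f["weight"].to_numpy(dtype=float)
    y = f["outcome"].to_numpy(dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise EstimationError(f"group {label!r}: zero total weight")
    return PrevalenceEstimate(
        group=label, p=float((w * y).sum() / sw), n_unweighted=len(f),
        sum_weights=float(sw),
    )


def risk_difference(
    p_rural: float,
    n_rural: float,
    p_nonrural: float,
    n_nonrural: float,
    country: str = "",
) -> RiskDifference:
    if n_rural < 1 or n_nonrural < 1:
        raise EstimationError(f"{country or 'risk_difference'}: empty group")
    for p in (p_rural, p_nonrural):
        if not 0.0 <= p <= 1.0:
            raise EstimationError(f"prevalence {p} outside [0, 1]")
    rd = 1000.0 * (p_rural - p_nonrural)
    se = 1000.0 * np.sqrt(
        p_rural * (1 - p_rural) / n_rural
        + p_nonrural * (1 - p_nonrural) / n_nonrural
    )
    if se == 0.0:
        if rd == 0.0:
            return RiskDifference(country, 0.0, 0.0, (0.0, 0.0), 0.0, 1.0)
        raise EstimationError(f"{country}: zero SE with nonzero risk difference")
    z = rd / se
    p = 2.0 * stats.norm.sf(abs(z))
    return RiskDifference(
        country=country,
        rd_per_1000=float(rd),
        se_per_1000=float(se),
        ci95=(float(rd - Z975 * se), float(rd + Z975 * se)),
        z=float(z),
        p_value=float(p),
    )


def two_proportion_z(
    p1: float, n1: float, p2: float, n2: float
) -> tuple[float, float]:
    """Pooled-variance two-sided z-test for equality of two proportions."""
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateTestError(
            f"pooled proportion {pooled} is degenerate (0 or 1)"
        )
    se = np.sqrt(pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def chisq_association(
    data: SurveyDataset | pd.DataFrame, covariate: str
) -> tuple[float, int, float]:
    """Pearson chi-square of covariate level x outcome, unweighted counts."""
    f = data.frame if isinstance(data, SurveyDataset) else data
    if covariate not in f.columns:
        raise DegenerateTableError(f"covariate {covariate!r} not in dataset")
    table = pd.crosstab(f[covariate], f["outcome"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"covariate {covariate!r}: fewer than 2 observed levels in table"
        )
    obs = table.to_numpy(dtype=float)
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise DegenerateTableError(
            f"covariate {covariate!r}: zero expected cell in contingency table"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def meta_analysis(
    rds: Sequence[RiskDifference], method: str = "DL"
) -> MetaResult:
    """Inverse-variance fixed effect + DerSimonian-Laird random effects."""
    if method != "DL":
        raise PoolingError(f"unsupported meta-analysis method {method!r}")
    if len(rds) < 2:
        raise PoolingError("need at least 2 countries to pool")
    theta = np.array([r.rd_per_1000 for r in rds])
    se = np.array([r.se_per_1000 for r in rds])
    if (se <= 0).any():
        bad = rds[int(np.flatnonzero(se <= 0)[0])].country
        raise PoolingError(f"country {bad!r} has non-positive SE")
    v = se**2
    w = 1.0 / v
    fe = float((w * theta).sum() / w.sum())
    q = float((w * (theta - fe) ** 2).sum())
    df = len(rds) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    wr = 1.0 / (v + tau2)
    re = float((wr * theta).sum() / wr.sum())

    def _summ(est: float, weights: np.ndarray) -> MetaEstimate:
        s = float(np.sqrt(1.0 / weights.sum()))
        z = est / s
        return MetaEstimate(
            rd_per_1000=est,
            se_per_1000=s,
            ci95=(est - Z975 * s, est + Z975 * s),
            z=float(z),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
        )

    wp = 100.0 * wr / wr.sum()
    return MetaResult(
        fixed_effect=_summ(fe, w),
        random_effect=_summ(re, wr),
        tau2=float(tau2),
        q=q,
        df=df,
        weights_percent={r.country: float(p) for r, p in zip(rds, wp)},
    )


def classify_inequality(
    estimate: float, p_value: float, alpha: float = 0.05, country: str = ""
) -> InequalityClass:
    if not 0.0 <= p_value <= 1.0:
        raise EstimationError(f"p_value {p_value} outside [0, 1]")
    if p_value < alpha and estimate > 0:
        cat = PRO_RURAL
    elif p_value < alpha and estimate < 0:
        cat = PRO_NONRURAL
    else:
        cat = NOT_SIGNIFICANT
    return InequalityClass(country=country, category=cat)


def _group_sizes(f: pd.DataFrame, kish: bool) -> tuple[float, float]:
    def n(sub: pd.DataFrame) -> float:
        if not kish:
            return float(len(sub))
        w = sub["weight"].to_numpy(dtype=float)
        return float(w.sum() ** 2 / (w**2).sum())

    return n(f[f["rural"] == 1]), n(f[f["rural"] == 0])


def country_risk_differences(
    data: SurveyDataset, kish: bool = False
) -> list[RiskDifference]:
    """Per-country rural-minus-non-rural RD per 1000 with weighted points.

    Countries missing either group are skipped (nothing to compare).
    """
    out = []
    for country, sub in data.frame.groupby("country", sort=True):
        if sub["rural"].nunique() < 2:
            continue
        pr = weighted_prevalence(sub, sub["rural"] == 1, label="rural")
        pn = weighted_prevalence(sub, sub["rural"] == 0, label="nonrural")
        n_r, n_n = _group_sizes(sub, kish)
        out.append(risk_difference(pr.p, n_r, pn.p, n_n, country=country))
    return out


def forest_table(
    rds: Sequence[RiskDifference], meta: MetaResult, alpha: float = 0.05
) -> pd.DataFrame:
    """Plot-ready per-country forest table (country, rd, ci, weight, class)."""
    rows = []
    for r in rds:
        cls = classify_inequality(r.rd_per_1000, r.p_value, alpha, r.country)
        rows.append(
            {
                "country": r.country,
                "rd_per_1000": r.rd_per_1000,
                "se_per_1000": r.se_per_1000,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_value": r.p_value,
                "weight_percent": meta.weights_percent.get(r.country, np.nan),
                "category": cls.category,
            }
        )
    return pd.DataFrame(rows)
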