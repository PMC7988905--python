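"""Per-country odds ratios and Mantel-Haenszel pooling across countries.

Each country contributes a 2x2 table (rural/non-rural x case/non-case).
The pooled odds ratio is Mantel-Haenszel with a Robins-Breslow-Greenland
standard error for its log; heterogeneity across countries is Cochran's Q
over stratum log odds ratios with inverse-variance weights, summarised as
I-squared = max(0, (Q - df)/Q).

Counts are unweighted by default; a weighted variant rounds weighted sums
to integer counts and is labelled approximate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataset import SurveyDataset
from .errors import EstimationError, FittingError, PoolingError

log = logging.getLogger(__name__)

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class StratumTable:
    """2x2 counts: a = rural cases, b = rural non-cases,
    c = non-rural cases, d = non-rural non-cases."""

    country: str
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)

    def is_informative(self) -> bool:
        return (
            self.a + self.b >= 1
            and self.c + self.d >= 1
            and self.a + self.c >= 1
            and self.b + self.d >= 1
        )


@dataclass(frozen=True)
class PooledORResult:
    or_mh: float
    ci95: tuple[float, float]
    z: float
    p_value: float
    q: float
    df: int
    i2: float
    n_strata: int
    continuity_corrected: tuple[str, ...] = ()


def stratum_tables(
    data: SurveyDataset, weighted: bool = False
) -> list[StratumTable]:
    """One 2x2 per country; countries lacking a group are excluded (warned)."""
    out = []
    for country, sub in data.frame.groupby("country", sort=True):
        if sub["rural"].nunique() < 2:
            log.warning(
                "country %s excluded from stratified tables: "
                "only one residence group present", country,
            )
            continue
        w = sub["weight"].to_numpy(dtype=float) if weighted else np.ones(len(sub))
        rural = sub["rural"].to_numpy()
        y = sub["outcome"].to_numpy()
        a = w[(rural == 1) & (y == 1)].sum()
        b = w[(rural == 1) & (y == 0)].sum()
        c = w[(rural == 0) & (y == 1)].sum()
        d = w[(rural == 0) & (y == 0)].sum()
        if weighted:  # approximate: weighted sums rounded to pseudo-counts
            a, b, c, d = (float(round(x)) for x in (a, b, c, d))
        out.append(StratumTable(country, float(a), float(b), float(c), float(d)))
    return out


def i_squared(q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q); zero when Q is 0."""
    if q <= 0.0:
        return 0.0
    return max(0.0, (q - df) / q)


def _log_or_and_var(t: StratumTable) -> tuple[float, float, bool]:
    """Woolf log-OR and variance, 0.5 continuity correction on zero cells."""
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    return float(np.log(a * d / (b * c))), float(1 / a + 1 / b + 1 / c + 1 / d), corrected


def cochran_q(tables: Sequence[StratumTable]) -> tuple[float, int, tuple[str, ...]]:
    """Cochran's Q over stratum log odds ratios, inverse-variance weights."""
    logs, ws, corrected = [], [], []
    for t in tables:
        lo, var, cc = _log_or_and_var(t)
        logs.append(lo)
        ws.append(1.0 / var)
        if cc:
            corrected.append(t.country)
    logs_a = np.array(logs)
    ws_a = np.array(ws)
    center = (ws_a * logs_a).sum() / ws_a.sum()
    q = float((ws_a * (logs_a - center) ** 2).sum())
    return q, len(tables) - 1, tuple(corrected)


def mh_pooled_or(tables: Sequence[StratumTable]) -> PooledORResult:
    """Mantel-Haenszel pooled OR with RBG SE, z-test of OR = 1, Q and I^2."""
    informative = [t for t in tables if t.is_informative()]
    if not informative:
        raise PoolingError("no informative stratum (a margin is empty everywhere)")
    a = np.array([t.a for t in informative])
    b = np.array([t.b for t in informative])
    c = np.array([t.c for t in informative])
    d = np.array([t.d for t in informative])
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    rs, ss = r.sum(), s.sum()
    if ss == 0 or rs == 0:
        raise PoolingError("Mantel-Haenszel OR undefined: zero cross-product sum")
    or_mh = rs / ss
    # Robins-Breslow-Greenland variance of log(OR_MH)
    p = (a + d) / n
    q_ = (b + c) / n
    var = (
        (p * r).sum() / (2 * rs**2)
        + ((p * s + q_ * r)).sum() / (2 * rs * ss)
        + (q_ * s).sum() / (2 * ss**2)
    )
    se = float(np.sqrt(var))
    lo = float(np.log(or_mh))
    z = lo / se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    q, df, corrected = cochran_q(informative)
    return PooledORResult(
        or_mh=float(or_mh),
        ci95=(float(np.exp(lo - Z975 * se)), float(np.exp(lo + Z975 * se))),
        z=float(z),
        p_value=pval,
        q=q,
        df=df,
        i2=i_squared(q, df),
        n_strata=len(informative),
        continuity_corrected=corrected,
    )


def homogeneity_subset_test(
    tables: Sequence[StratumTable], subset: Sequence[str]
) -> tuple[float, int, float]:
    """Cochran's Q restricted to a named subset of countries."""
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 countries")
    by_country = {t.country: t for t in tables}
    missing = [s for s in subset if s not in by_country]
    if missing:
        raise ValueError(f"subset countries absent from tables: {missing}")
    q, df, _ = cochran_q([by_country[s] for s in subset])
    return q, df, float(stats.chi2.sf(q, df))


def country_logit_or(
    data: SurveyDataset,
    country: str,
    adjust: Sequence[str] = (),
    weighted: bool = False,
) -> tuple[float, tuple[float, float], float]:
    """Country-level logistic OR of outcome on the rural flag.

    With no adjustment covariates the model is saturated and the estimate
    equals the crude 2x2 cross-product OR. Returns (or, ci95, p_value).
    """
    sub = data.frame[data.frame["country"] == country]
    if len(sub) == 0:
        raise EstimationError(f"country {country!r} absent from dataset")
    if sub["rural"].nunique() < 2:
        raise EstimationError(f"country {country!r}: only one residence group")
    if sub["outcome"].nunique() < 2:
        raise EstimationError(f"country {country!r}: outcome has no variation")
    cols = ["rural", *adjust]
    x = sm.add_constant(sub[cols].to_numpy(dtype=float), has_constant="add")
    y = sub["outcome"].to_numpy(dtype=float)
    kwargs = {}
    if weighted:
        kwargs["var_weights"] = sub["weight"].to_numpy(dtype=float)
    try:
        model = sm.GLM(y, x, family=sm.families.Binomial(), **kwargs)
        res = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FittingError(f"country {country!r}: logit fit failed: {exc}") from exc
    beta = res.params[1]
    se = res.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 25 or se > 50:
        raise FittingError(
            f"country {country!r}: separation or non-identifiable rural effect"
        )
    z = beta / se
    return (
        float(np.exp(beta)),
        (float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se))),
        float(2.0 * stats.norm.sf(abs(z))),
    )


def or_table(
    data: SurveyDataset,
    alpha: float = 0.05,
    adjust: Sequence[str] = (),
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-country OR report (country, or, ci, p, category)."""
    from .inequality import classify_inequality

    rows = []
    for country in sorted(data.frame["country"].unique()):
        sub = data.frame[data.frame["country"] == country]
        if sub["rural"].nunique() < 2 or sub["outcome"].nunique() < 2:
            log.warning("country %s excluded from OR table", country)
            continue
        orr, ci, p = country_logit_or(data, country, adjust=adjust, weighted=weighted)
        cls = classify_inequality(np.log(orr), p, alpha, country)
        rows.append(
            {
                "country": country,
                "odds_ratio": orr,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_value": p,
                "category": cls.category,
            }
        )
    return pd.DataFrame(rows)
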