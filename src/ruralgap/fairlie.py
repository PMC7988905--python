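"""Nonlinear decomposition of a binary-outcome group gap.

The gap in mean outcome between group A (rural, disadvantaged) and group B
(non-rural) is split into an "explained" part driven by differences in
covariate distributions and an "unexplained" remainder, using the
logistic inverse link F(u) = 1/(1 + exp(-u)).

Mechanics per replication:

1. the larger group is randomly subsampled without replacement down to the
   smaller group's size;
2. both equal-size samples are sorted by predicted probability under the
   reference coefficients and paired by rank (ties keep original order);
3. starting from the group-B rows, covariate blocks are switched to the
   matched group-A rows one block at a time, recording the change in the
   mean predicted probability after each switch.

The sequential switch deltas telescope exactly to that replication's
explained term; block order is randomized per replication by default to
average out path dependence. Final contributions are means over
replications; their SEs are SDs over replications.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ConfigurationError, FittingError, SchemaError

GROUP_A = "A"  # rural
GROUP_B = "B"  # non-rural

#: name of the optional group-membership dummy in a pooled fit; it is held
#: fixed (never switched) during decomposition
GROUP_DUMMY = "_group"


@dataclass
class LogitModel:
    """Fitted logistic coefficients with the fixed logistic inverse link."""

    intercept: float
    coefficients: dict[str, float]
    n_obs: int = 0
    loglike: float = float("nan")
    converged: bool = True
    bse: dict[str, float] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(design), self.intercept, dtype=float)
        for term, beta in self.coefficients.items():
            lp += beta * design[term].to_numpy(dtype=float)
        return lp

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        """Mean response F(alpha + X beta), always inside (0, 1)."""
        return expit(self.linear_predictor(design))


@dataclass
class GroupSample:
    label: str
    design: pd.DataFrame
    outcomes: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        if len(self.design) != len(self.outcomes):
            raise SchemaError("design rows and outcomes are misaligned")
        if len(self.design) < 1:
            raise SchemaError(f"group {self.label}: empty sample")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.outcomes):
                raise SchemaError("weights misaligned with outcomes")
            if (self.weights <= 0).any():
                raise SchemaError(f"group {self.label}: non-positive weight")

    @property
    def size(self) -> int:
        return len(self.design)

    def mean_outcome(self) -> float:
        if self.weights is None:
            return float(self.outcomes.mean())
        return float((self.weights * self.outcomes).sum() / self.weights.sum())


@dataclass
class DecompositionConfig:
    replications: int = 1000
    seed: int = 0
    variable_groups: dict[str, tuple[str, ...]] | None = None
    randomize_order: bool = True
    coefficient_source: str = "pooled"  # pooled | groupA | groupB

    def validate(self) -> None:
        if self.replications < 1:
            raise ConfigurationError("replications must be >= 1")
        if self.coefficient_source not in ("pooled", "groupA", "groupB"):
            raise ConfigurationError(
                f"coefficient_source {self.coefficient_source!r} invalid"
            )


@dataclass(frozen=True)
class BlockContribution:
    mean: float
    se: float
    percent_of_gap: float


@dataclass
class DecompositionResult:
    total_gap: float
    explained_total: float
    unexplained: float
    contributions: dict[str, BlockContribution]
    R_used: int
    explained_se: float


def _design_matrix(designs: Sequence[pd.DataFrame]) -> tuple[np.ndarray, list[str]]:
    cols = list(designs[0].columns)
    for d in designs[1:]:
        if list(d.columns) != cols:
            raise SchemaError("group designs have mismatched covariate columns")
    x = np.vstack([d.to_numpy(dtype=float) for d in designs])
    return x, cols


def _check_rank(x: np.ndarray, cols: list[str]) -> None:
    xc = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        for j, name in enumerate(cols):
            if np.ptp(x[:, j]) == 0:
                raise FittingError(f"term {name!r} is constant (rank deficient)")
        raise FittingError(
            f"design is rank deficient (collinear terms among {cols})"
        )


def _fit_logit(
    designs: Sequence[pd.DataFrame],
    outcomes: Sequence[np.ndarray],
    weights: Sequence[np.ndarray | None] | None,
) -> LogitModel:
    x, cols = _design_matrix(designs)
    y = np.concatenate([np.asarray(o, dtype=float) for o in outcomes])
    if len(np.unique(y)) < 2:
        raise FittingError("outcome has no variation in the fitting sample")
    _check_rank(x, cols)
    kwargs = {}
    if weights is not None and any(w is not None for w in weights):
        ws = [
            w if w is not None else np.ones(len(d))
            for w, d in zip(weights, designs)
        ]
        kwargs["var_weights"] = np.concatenate(ws)
    xc = sm.add_constant(x, has_constant="add")
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, xc, family=sm.families.Binomial(), **kwargs).fit(
                maxiter=200
            )
    except PerfectSeparationWarning as exc:
        raise FittingError(f"perfect separation detected: {exc}") from exc
    except Exception as exc:
        raise FittingError(f"logit fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise FittingError("logit fit produced non-finite coefficients")
    big = np.abs(params[1:]) > 25
    if big.any():
        raise FittingError(
            f"term {cols[int(np.flatnonzero(big)[0])]!r}: "
            "perfect separation suspected (|coefficient| > 25)"
        )
    bse = np.asarray(res.bse, dtype=float)
    return LogitModel(
        intercept=float(params[0]),
        coefficients={c: float(b) for c, b in zip(cols, params[1:])},
        n_obs=len(y),
        loglike=float(res.llf),
        converged=bool(res.converged),
        bse={c: float(s) for c, s in zip(cols, bse[1:])},
    )


def fit_pooled_logit(
    A: GroupSample,
    B: GroupSample,
    weights: str = "on",
    include_group_dummy: bool = False,
) -> LogitModel:
    """Maximum-likelihood logistic fit on the pooled A+B sample.

    The pooled model excludes a group-membership dummy by default;
    ``include_group_dummy=True`` adds one under the reserved name
    ``_group`` (1 = group A), which the decomposition holds fixed.
    """
    da, db = A.design, B.design
    if include_group_dummy:
        da = da.assign(**{GROUP_DUMMY: 1.0})
        db = db.assign(**{GROUP_DUMMY: 0.0})
    w = [A.weights, B.weights] if weights == "on" else None
    return _fit_logit([da, db], [A.outcomes, B.outcomes], w)


def fit_group_logit(sample: GroupSample, weights: str = "on") -> LogitModel:
    w = [sample.weights] if weights == "on" else None
    return _fit_logit([sample.design], [sample.outcomes], w)


def match_subsample(
    A: GroupSample, B: GroupSample, model: LogitModel, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equal-size rank-matched row sets (A rows first, B rows second).

    The larger group is subsampled without replacement to the smaller
    group's size; both sets are sorted by predicted probability under
    ``model`` (stable sort, so ties fall back to original row order) and
    paired by rank.
    """
    rng = np.random.default_rng(seed)
    n = min(A.size, B.size)

    def take(sample: GroupSample) -> pd.DataFrame:
        if sample.size > n:
            idx = np.sort(rng.choice(sample.size, size=n, replace=False))
            return sample.design.iloc[idx].reset_index(drop=True)
        return sample.design.reset_index(drop=True)

    da, db = take(A), take(B)
    order_a = np.argsort(model.predict(da), kind="stable")
    order_b = np.argsort(model.predict(db), kind="stable")
    return (
        da.iloc[order_a].reset_index(drop=True),
        db.iloc[order_b].reset_index(drop=True),
    )


def _resolve_blocks(
    config: DecompositionConfig, model: LogitModel, design_cols: Sequence[str]
) -> dict[str, tuple[str, ...]]:
    switchable = [c for c in design_cols if c != GROUP_DUMMY]
    if config.variable_groups is None:
        return {c: (c,) for c in switchable}
    blocks = {k: tuple(v) for k, v in config.variable_groups.items()}
    flat = [c for cols in blocks.values() for c in cols]
    if sorted(flat) != sorted(set(flat)):
        raise SchemaError("variable_groups assigns a term to multiple blocks")
    if set(flat) != set(switchable):
        raise SchemaError(
            "variable_groups must partition the switchable design terms "
            f"exactly; expected {sorted(switchable)}, got {sorted(flat)}"
        )
    missing = [c for c in flat if c not in model.coefficients]
    if missing:
        raise SchemaError(f"terms {missing} absent from the fitted model")
    return blocks


def decompose(
    A: GroupSample,
    B: GroupSample,
    model: LogitModel,
    config: DecompositionConfig,
) -> DecompositionResult:
    """Replicated sequential-switch decomposition of the A-B outcome gap.

    Per replication the block switch deltas telescope exactly to that
    replication's explained term; the unexplained remainder is defined as
    total_gap - explained_total, so the decomposition identity holds by
    construction on every run. Replication r draws from an independent
    stream seeded by (config.seed, r), making results reproducible under
    any execution order.
    """
    config.validate()
    if list(A.design.columns) != list(B.design.columns):
        raise SchemaError("group designs have mismatched covariate columns")
    model_terms = [t for t in model.terms]
    extra = [c for c in A.design.columns if c not in model_terms]
    if extra:
        raise SchemaError(f"design terms {extra} absent from the fitted model")
    blocks = _resolve_blocks(config, model, list(A.design.columns))
    names = list(blocks)
    k = len(names)
    total_gap = A.mean_outcome() - B.mean_outcome()

    intercept = model.intercept
    beta = np.array(
        [model.coefficients[c] for c in A.design.columns], dtype=float
    )
    col_idx = {c: j for j, c in enumerate(A.design.columns)}
    block_cols = {
        name: np.array([col_idx[c] for c in cols], dtype=int)
        for name, cols in blocks.items()
    }

    deltas = np.empty((config.replications, k))
    explained = np.empty(config.replications)
    for r in range(config.replications):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(r,))
        )
        da, db = match_subsample(A, B, model, rng)
        xa = da.to_numpy(dtype=float)
        x = db.to_numpy(dtype=float).copy()
        order = rng.permutation(k) if config.randomize_order else np.arange(k)
        prev = float(expit(intercept + x @ beta).mean())
        start = prev
        for pos in order:
            cols = block_cols[names[pos]]
            x[:, cols] = xa[:, cols]
            cur = float(expit(intercept + x @ beta).mean())
            deltas[r, pos] = cur - prev
            prev = cur
        explained[r] = prev - start

    means = deltas.mean(axis=0)
    ses = deltas.std(axis=0, ddof=1) if config.replications > 1 else np.zeros(k)
    explained_total = float(explained.mean())
    explained_se = (
        float(explained.std(ddof=1)) if config.replications > 1 else 0.0
    )
    contributions = {}
    for j, name in enumerate(names):
        pct = 100.0 * means[j] / total_gap if total_gap != 0 else float("nan")
        contributions[name] = BlockContribution(
            mean=float(means[j]), se=float(ses[j]), percent_of_gap=float(pct)
        )
    return DecompositionResult(
        total_gap=float(total_gap),
        explained_total=explained_total,
        unexplained=float(total_gap - explained_total),
        contributions=contributions,
        R_used=config.replications,
        explained_se=explained_se,
    )


def run_fairlie(
    A: GroupSample,
    B: GroupSample,
    config: DecompositionConfig,
    weights: str = "on",
    include_group_dummy: bool = False,
) -> tuple[DecompositionResult, LogitModel]:
    """Fit the reference model per ``config.coefficient_source``, decompose."""
    config.validate()
    if config.coefficient_source == "pooled":
        model = fit_pooled_logit(A, B, weights, include_group_dummy)
    elif config.coefficient_source == "groupA":
        model = fit_group_logit(A, weights)
    else:
        model = fit_group_logit(B, weights)
    if include_group_dummy and config.coefficient_source == "pooled":
        A = GroupSample(A.label, A.design.assign(**{GROUP_DUMMY: 1.0}),
                        A.outcomes, A.weights)
        B = GroupSample(B.label, B.design.assign(**{GROUP_DUMMY: 0.0}),
                        B.outcomes, B.weights)
    return decompose(A, B, model, config), model


def contribution_table(result: DecompositionResult) -> pd.DataFrame:
    """One row per block, sorted by |percent_of_gap| descending.

    Positive contributions widen the pro-rural gap. When the total gap is
    zero, percentages are undefined: the table carries absolute
    contributions and an ``absolute_only`` flag instead of dividing.
    """
    absolute_only = result.total_gap == 0
    rows = []
    for name, c in result.contributions.items():
        rows.append(
            {
                "block": name,
                "mean": c.mean,
                "se": c.se,
                "percent_of_gap": None if absolute_only else c.percent_of_gap,
                "absolute_only": absolute_only,
            }
        )
    key = (lambda r: abs(r["mean"])) if absolute_only else (
        lambda r: abs(r["percent_of_gap"])
    )
    rows.sort(key=key, reverse=True)
    return pd.DataFrame(rows)


def group_samples_from_frame(
    frame: pd.DataFrame, covariates: Sequence[str]
) -> tuple[GroupSample, GroupSample]:
    """Split a microdata frame into rural (A) and non-rural (B) samples."""
    a = frame[frame["rural"] == 1]
    b = frame[frame["rural"] == 0]
    if len(a) == 0 or len(b) == 0:
        raise SchemaError("both residence groups must be nonempty")
    return (
        GroupSample(GROUP_A, a[list(covariates)].reset_index(drop=True),
                    a["outcome"].to_numpy(), a["weight"].to_numpy()),
        GroupSample(GROUP_B, b[list(covariates)].reset_index(drop=True),
                    b["outcome"].to_numpy(), b["weight"].to_numpy()),
    )
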