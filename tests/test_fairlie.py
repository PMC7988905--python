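import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ruralgap.errors import ConfigurationError, FittingError, SchemaError
from ruralgap.fairlie import (
    GROUP_DUMMY,
    DecompositionConfig,
    GroupSample,
    LogitModel,
    contribution_table,
    decompose,
    fit_pooled_logit,
    group_samples_from_frame,
    match_subsample,
    run_fairlie,
)
from ruralgap.synthetic import SimulationConfig, generate_survey

from conftest import make_country


def _group(label, x, y, weights=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    design = pd.DataFrame(x, columns=[f"x{i+1}" for i in range(x.shape[1])])
    return GroupSample(label, design, np.asarray(y, dtype=float), weights)


def _simulate_groups(rng, n_a, n_b, alpha, beta, p_a, p_b):
    """Two groups, binary covariates with group-specific prevalences."""
    xa = (rng.random((n_a, len(p_a))) < np.asarray(p_a)).astype(float)
    xb = (rng.random((n_b, len(p_b))) < np.asarray(p_b)).astype(float)
    ya = (rng.random(n_a) < expit(alpha + xa @ beta)).astype(float)
    yb = (rng.random(n_b) < expit(alpha + xb @ beta)).astype(float)
    return _group("A", xa, ya), _group("B", xb, yb)


class TestFitPooledLogit:
    def test_null_recovery(self):
        rng = np.random.default_rng(0)
        A, B = _simulate_groups(
            rng, 25_000, 25_000, alpha=-1.0,
            beta=np.zeros(2), p_a=[0.5, 0.3], p_b=[0.5, 0.3],
        )
        m = fit_pooled_logit(A, B, weights="off")
        for term, b in m.coefficients.items():
            assert abs(b) < 3 * m.bse[term]

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        beta = np.array([0.8, -0.5])
        A, B = _simulate_groups(
            rng, 25_000, 25_000, alpha=-2.0, beta=beta,
            p_a=[0.5, 0.4], p_b=[0.4, 0.5],
        )
        m = fit_pooled_logit(A, B, weights="off")
        for term, truth in zip(("x1", "x2"), beta):
            assert abs(m.coefficients[term] - truth) < 3 * m.bse[term]
        assert m.converged

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = x.copy()
        A = _group("A", x, y)
        B = _group("B", x, y)
        with pytest.raises(FittingError):
            fit_pooled_logit(A, B, weights="off")

    def test_constant_term_named_in_error(self):
        A = _group("A", np.ones(40), np.r_[np.zeros(20), np.ones(20)])
        B = _group("B", np.ones(40), np.r_[np.zeros(20), np.ones(20)])
        with pytest.raises(FittingError, match="x1"):
            fit_pooled_logit(A, B, weights="off")

    def test_group_dummy_added(self):
        rng = np.random.default_rng(2)
        A, B = _simulate_groups(
            rng, 2000, 2000, alpha=-1.0, beta=np.array([0.5]),
            p_a=[0.6], p_b=[0.4],
        )
        m = fit_pooled_logit(A, B, weights="off", include_group_dummy=True)
        assert GROUP_DUMMY in m.coefficients


class TestMatchSubsample:
    def _model(self, betas, intercept=-1.0):
        return LogitModel(intercept=intercept, coefficients=betas)

    def test_equal_sizes_rank_sorted(self):
        rng = np.random.default_rng(3)
        A = _group("A", rng.random(50), np.zeros(50))
        B = _group("B", rng.random(50), np.zeros(50))
        m = self._model({"x1": 1.0})
        da, db = match_subsample(A, B, m, seed=0)
        assert len(da) == len(db) == 50
        assert np.all(np.diff(m.predict(da)) >= 0)
        assert np.all(np.diff(m.predict(db)) >= 0)
        assert sorted(da["x1"]) == sorted(A.design["x1"])

    def test_all_tied_keeps_original_order(self):
        A = _group("A", np.arange(10.0), np.zeros(10))
        B = _group("B", np.arange(10.0)[::-1].copy(), np.zeros(10))
        m = self._model({"x1": 0.0})  # all predictions tied
        da, db = match_subsample(A, B, m, seed=1)
        assert list(da["x1"]) == list(A.design["x1"])
        assert list(db["x1"]) == list(B.design["x1"])

    def test_subsample_unique_and_sized(self):
        m = self._model({"x1": 1.0})
        A = _group("A", np.arange(1000.0), np.zeros(1000))
        B = _group("B", np.arange(100.0), np.zeros(100))
        for seed in range(100):
            da, db = match_subsample(A, B, m, seed=seed)
            assert len(da) == len(db) == 100
            assert da["x1"].nunique() == 100  # drawn without replacement
            assert set(da["x1"]) <= set(A.design["x1"])


class TestDecompose:
    def test_identical_covariates_all_zero(self):
        rng = np.random.default_rng(4)
        x = rng.random(400)
        ya = (rng.random(400) < 0.4).astype(float)
        yb = (rng.random(400) < 0.2).astype(float)
        A, B = _group("A", x, ya), _group("B", x.copy(), yb)
        m = fit_pooled_logit(A, B, weights="off")
        res = decompose(A, B, m, DecompositionConfig(replications=5, seed=0))
        for c in res.contributions.values():
            assert c.mean == pytest.approx(0.0, abs=1e-12)
        assert res.explained_total == pytest.approx(0.0, abs=1e-12)
        assert res.unexplained == pytest.approx(res.total_gap, abs=1e-12)

    def test_single_covariate_matches_direct_evaluation(self):
        # equal sizes, one covariate: no subsampling, so the contribution
        # must equal the direct rank-matched switch evaluated by hand
        rng = np.random.default_rng(5)
        A, B = _simulate_groups(
            rng, 800, 800, alpha=-1.5, beta=np.array([1.0]),
            p_a=[0.7], p_b=[0.3],
        )
        m = fit_pooled_logit(A, B, weights="off")
        res = decompose(
            A, B, m,
            DecompositionConfig(replications=1, seed=0, randomize_order=False),
        )
        a0, b1 = m.intercept, m.coefficients["x1"]
        xa = np.sort(A.design["x1"].to_numpy())
        xb = np.sort(B.design["x1"].to_numpy())
        if b1 < 0:  # rank order follows predicted probability
            xa, xb = xa[::-1], xb[::-1]
        oracle = float(
            np.mean(expit(a0 + b1 * xa)) - np.mean(expit(a0 + b1 * xb))
        )
        assert res.contributions["x1"].mean == pytest.approx(oracle, abs=1e-12)
        assert res.explained_total == pytest.approx(oracle, abs=1e-12)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(6)
        A, B = _simulate_groups(
            rng, 700, 500, alpha=-1.0, beta=np.array([0.6, -0.4, 0.8]),
            p_a=[0.6, 0.5, 0.4], p_b=[0.4, 0.5, 0.6],
        )
        m = fit_pooled_logit(A, B, weights="off")
        res = decompose(A, B, m, DecompositionConfig(replications=40, seed=1))
        total_block = sum(c.mean for c in res.contributions.values())
        assert total_block == pytest.approx(res.explained_total, abs=1e-10)
        assert res.explained_total + res.unexplained == pytest.approx(
            res.total_gap, abs=1e-12
        )

    def test_group_a_coefficients_same_rows_all_zero(self):
        rng = np.random.default_rng(7)
        x = rng.random((300, 2))
        y = (rng.random(300) < 0.3).astype(float)
        A = _group("A", x, y)
        B = _group("B", x.copy(), y.copy())
        cfg = DecompositionConfig(
            replications=3, seed=0, coefficient_source="groupA"
        )
        res, _ = run_fairlie(A, B, cfg, weights="off")
        assert res.total_gap == 0.0
        assert res.explained_total == pytest.approx(0.0, abs=1e-12)
        assert res.unexplained == pytest.approx(0.0, abs=1e-12)
        for c in res.contributions.values():
            assert c.mean == pytest.approx(0.0, abs=1e-12)

    def test_replication_count_and_errors(self):
        rng = np.random.default_rng(8)
        A, B = _simulate_groups(
            rng, 100, 100, alpha=0.0, beta=np.array([0.5]), p_a=[0.6], p_b=[0.4]
        )
        m = fit_pooled_logit(A, B, weights="off")
        with pytest.raises(ConfigurationError):
            decompose(A, B, m, DecompositionConfig(replications=0))
        with pytest.raises(SchemaError, match="partition"):
            decompose(
                A, B, m,
                DecompositionConfig(
                    replications=1, variable_groups={"block": ("nope",)}
                ),
            )

    def test_blocks_switch_together(self):
        rng = np.random.default_rng(9)
        A, B = _simulate_groups(
            rng, 400, 400, alpha=-1.0, beta=np.array([0.7, 0.7, -0.3]),
            p_a=[0.7, 0.7, 0.5], p_b=[0.3, 0.3, 0.5],
        )
        m = fit_pooled_logit(A, B, weights="off")
        cfg = DecompositionConfig(
            replications=10,
            seed=2,
            variable_groups={"pair": ("x1", "x2"), "solo": ("x3",)},
        )
        res = decompose(A, B, m, cfg)
        assert set(res.contributions) == {"pair", "solo"}
        assert sum(c.mean for c in res.contributions.values()) == pytest.approx(
            res.explained_total, abs=1e-10
        )

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(10)
        A, B = _simulate_groups(
            rng, 500, 300, alpha=-1.0, beta=np.array([0.8]), p_a=[0.6], p_b=[0.4]
        )
        m = fit_pooled_logit(A, B, weights="off")
        cfg = DecompositionConfig(replications=10, seed=77)
        r1 = decompose(A, B, m, cfg)
        r2 = decompose(A, B, m, cfg)
        assert r1.contributions["x1"].mean == r2.contributions["x1"].mean
        assert r1.explained_total == r2.explained_total


class TestKnownDGPRecovery:
    def _dataset(self, edu_shift, rural_effect, seed, n_clusters=150,
                 children=100):
        cfg = SimulationConfig(
            countries=[
                make_country(
                    "K",
                    n_clusters=n_clusters,
                    children_per_cluster=children,
                    rural_effect=rural_effect,
                    intercept=-2.2,
                    covariate_effects={"no_education": 1.8, "unemployed": 0.3},
                    covariate_rural_shift={"no_education": edu_shift},
                    covariate_base={"no_education": 0.2, "unemployed": 0.4},
                    covariate_kind={},
                    cluster_sd=0.0,
                    weight_cv=0.0,
                )
            ],
            seed=seed,
        )
        return generate_survey(cfg)

    def test_compositional_gap_mostly_explained(self):
        ds = self._dataset(edu_shift=0.45, rural_effect=0.0, seed=13)
        A, B = group_samples_from_frame(ds.frame, ds.covariate_names)
        cfg = DecompositionConfig(replications=50, seed=3)
        res, _ = run_fairlie(A, B, cfg, weights="off")
        assert res.total_gap > 0.05
        assert res.contributions["no_education"].percent_of_gap >= 90.0
        # unexplained within binomial Monte-Carlo error of zero
        p = 0.5 * (A.mean_outcome() + B.mean_outcome())
        mc_se = np.sqrt(p * (1 - p) * (1 / A.size + 1 / B.size))
        assert abs(res.unexplained) <= 3 * mc_se

    def test_structural_gap_mostly_unexplained(self):
        ds = self._dataset(edu_shift=0.0, rural_effect=0.6, seed=14)
        A, B = group_samples_from_frame(ds.frame, ds.covariate_names)
        cfg = DecompositionConfig(replications=50, seed=4)
        res, _ = run_fairlie(A, B, cfg, weights="off")
        assert res.total_gap > 0.05
        assert abs(res.explained_total) <= 0.1 * abs(res.total_gap)

    def test_contribution_monotone_in_shift(self):
        means = []
        for shift in (0.1, 0.25, 0.45):
            ds = self._dataset(edu_shift=shift, rural_effect=0.0, seed=15,
                               n_clusters=120)
            A, B = group_samples_from_frame(ds.frame, ds.covariate_names)
            cfg = DecompositionConfig(replications=30, seed=5)
            res, _ = run_fairlie(A, B, cfg, weights="off")
            means.append(res.contributions["no_education"].mean)
        assert means[0] < means[1] < means[2]


class TestOrderRandomization:
    def _case(self, seed):
        # three correlated blocks so sequential switching is path dependent
        rng = np.random.default_rng(seed)
        n = 1500
        za = rng.random(n)
        zb = rng.random(n)
        xa = np.column_stack(
            [(za < 0.7), (za < 0.6) ^ (rng.random(n) < 0.1), (za < 0.5)]
        ).astype(float)
        xb = np.column_stack(
            [(zb < 0.3), (zb < 0.35) ^ (rng.random(n) < 0.1), (zb < 0.5)]
        ).astype(float)
        beta = np.array([1.2, 0.8, -0.6])
        ya = (rng.random(n) < expit(-1.5 + xa @ beta)).astype(float)
        yb = (rng.random(n) < expit(-1.5 + xb @ beta)).astype(float)
        return _group("A", xa, ya), _group("B", xb, yb)

    def test_randomization_shrinks_order_dependence(self):
        from itertools import permutations

        A, B = self._case(20)
        m = fit_pooled_logit(A, B, weights="off")
        cols = ("x1", "x2", "x3")
        fixed = []
        for perm in permutations(cols):
            cfg = DecompositionConfig(
                replications=20, seed=30, randomize_order=False,
                variable_groups={c: (c,) for c in perm},
            )
            fixed.append(decompose(A, B, m, cfg).contributions["x1"].mean)
        randomized = []
        for s in range(12):
            cfg = DecompositionConfig(replications=20, seed=100 + s,
                                      randomize_order=True)
            randomized.append(decompose(A, B, m, cfg).contributions["x1"].mean)
        assert np.std(randomized) <= np.std(fixed) + 1e-12


class TestContributionTable:
    def _result(self, gap, means):
        from ruralgap.fairlie import BlockContribution, DecompositionResult

        contribs = {
            name: BlockContribution(
                mean=m, se=0.0,
                percent_of_gap=100.0 * m / gap if gap else float("nan"),
            )
            for name, m in means.items()
        }
        explained = sum(means.values())
        return DecompositionResult(
            total_gap=gap, explained_total=explained,
            unexplained=gap - explained, contributions=contribs,
            R_used=1, explained_se=0.0,
        )

    def test_percent_arithmetic(self):
        table = contribution_table(
            self._result(0.02, {"a": 0.02, "b": -0.01})
        )
        assert list(table["block"]) == ["a", "b"]
        assert list(table["percent_of_gap"]) == pytest.approx([100.0, -50.0])

    def test_zero_gap_guarded(self):
        table = contribution_table(self._result(0.0, {"a": 0.0, "b": 0.0}))
        assert table["absolute_only"].all()
        assert table["percent_of_gap"].isna().all()

    def test_dominant_block_ranks_first(self):
        table = contribution_table(
            self._result(0.05, {"small": 0.005, "big": 0.04, "mid": -0.01})
        )
        assert table.iloc[0]["block"] == "big"
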