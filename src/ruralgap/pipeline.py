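"""One-command analysis pipeline.

Chains simulate (or read) -> neighbourhood SES -> prevalence/risk-difference
inequality -> Mantel-Haenszel pooled ORs -> Fairlie decomposition of the
countries classified pro-rural by the OR test, and writes delimited-text +
JSON reports plus a machine-readable run manifest.

Selection into the decomposition is keyed on the OR-based classification;
the RD-based classification is reported alongside so discrepancies between
the two are visible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import SurveyDataset
from .errors import ConfigurationError, PipelineError, RuralGapError
from .fairlie import (
    DecompositionConfig,
    contribution_table,
    group_samples_from_frame,
    run_fairlie,
)
from .inequality import (
    PRO_RURAL,
    country_risk_differences,
    forest_table,
    meta_analysis,
    weighted_prevalence,
)
from .io import read_microdata, write_microdata
from .pooled_or import homogeneity_subset_test, mh_pooled_or, or_table, stratum_tables
from .ses import attach_ses, ses_by_country, ses_table
from .synthetic import SimulationConfig, generate_survey

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str
    input: str = "simulate"  # path to microdata CSV, or the word "simulate"
    simulation: SimulationConfig | None = None
    alpha: float = 0.05
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    ses_pooled: bool = False
    use_weights: str = "on"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input == "simulate":
            if self.simulation is None:
                raise ConfigurationError(
                    "input='simulate' requires a simulation section"
                )
        elif not Path(self.input).exists():
            raise ConfigurationError(f"input file {self.input!r} does not exist")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        self.decomposition.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.get("simulation")
        dec = d.get("decomposition", {})
        return cls(
            output_dir=d["output_dir"],
            input=d.get("input", "simulate"),
            simulation=SimulationConfig.from_dict(sim) if sim else None,
            alpha=float(d.get("alpha", 0.05)),
            decomposition=DecompositionConfig(**dec),
            ses_pooled=bool(d.get("ses_pooled", False)),
            use_weights=d.get("use_weights", "on"),
            log_level=d.get("log_level", "INFO"),
        )


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict. Deterministic per seed."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "alpha": config.alpha,
        "decomposition_seed": config.decomposition.seed,
        "decomposition_replications": config.decomposition.replications,
        "decisions": {
            "point_estimates_weighted": True,
            "test_variances_use_unweighted_n": True,
            "chi_square_on_unweighted_counts": True,
            "two_sided_alpha_no_multiplicity_adjustment": config.alpha,
            "meta_method": "DerSimonian-Laird",
            "mh_counts_unweighted": True,
            "fairlie_block_order_randomized": config.decomposition.randomize_order,
            "fairlie_coefficient_source": config.decomposition.coefficient_source,
            "selection_into_decomposition": "OR-based pro-rural classification",
        },
    }

    # ---- stage: data -------------------------------------------------
    try:
        if config.input == "simulate":
            data = generate_survey(config.simulation)
            manifest["root_seed"] = config.simulation.seed
            write_microdata(data, out / "microdata.csv")
        else:
            data = read_microdata(config.input)
            manifest["input"] = str(config.input)
        manifest["n_children"] = data.n_children
        manifest["n_countries"] = int(data.frame["country"].nunique())
    except RuralGapError as exc:
        raise PipelineError("data", str(exc)) from exc

    # ---- stage: ses --------------------------------------------------
    try:
        indexes = ses_by_country(data, pooled=config.ses_pooled)
        data = attach_ses(data, indexes)
        ses_table(indexes).to_csv(out / "ses_index.csv", index=False)
    except RuralGapError as exc:
        raise PipelineError("ses", str(exc)) from exc

    # ---- stage: inequality -------------------------------------------
    try:
        prev_rows = []
        for country, sub in data.frame.groupby("country", sort=True):
            for label, mask in (
                ("all", None),
                ("rural", sub["rural"] == 1),
                ("nonrural", sub["rural"] == 0),
            ):
                try:
                    est = weighted_prevalence(sub, mask, label=label)
                except RuralGapError:
                    continue
                prev_rows.append(
                    {
                        "country": country,
                        "group": label,
                        "prevalence": est.p,
                        "n_unweighted": est.n_unweighted,
                        "sum_weights": est.sum_weights,
                    }
                )
        for label, mask in (
            ("all", None),
            ("rural", data.frame["rural"] == 1),
            ("nonrural", data.frame["rural"] == 0),
        ):
            est = weighted_prevalence(data.frame, mask, label=label)
            prev_rows.append(
                {
                    "country": "__pooled__",
                    "group": label,
                    "prevalence": est.p,
                    "n_unweighted": est.n_unweighted,
                    "sum_weights": est.sum_weights,
                }
            )
        pd.DataFrame(prev_rows).to_csv(out / "prevalence.csv", index=False)

        rds = country_risk_differences(data)
        if len(rds) >= 2:
            meta = meta_analysis(rds)
            forest = forest_table(rds, meta, alpha=config.alpha)
            forest.to_csv(out / "risk_differences.csv", index=False)
            _dump_json(
                _round_floats(
                    {
                        "fixed_effect": dataclasses.asdict(meta.fixed_effect),
                        "random_effect": dataclasses.asdict(meta.random_effect),
                        "tau2": meta.tau2,
                        "q": meta.q,
                        "df": meta.df,
                        "weights_percent": meta.weights_percent,
                    }
                ),
                out / "meta_analysis.json",
            )
            _dump_json(
                _round_floats(forest.to_dict(orient="records")),
                out / "risk_differences.json",
            )
    except RuralGapError as exc:
        raise PipelineError("inequality", str(exc)) from exc

    # ---- stage: pooled OR --------------------------------------------
    try:
        tables = stratum_tables(data)
        ors = or_table(data, alpha=config.alpha)
        ors.to_csv(out / "odds_ratios.csv", index=False)
        _dump_json(
            _round_floats(ors.to_dict(orient="records")),
            out / "odds_ratios.json",
        )
        het: dict = {}
        if len(tables) >= 1:
            pooled = mh_pooled_or(tables)
            het["all"] = {
                "or_mh": pooled.or_mh,
                "ci95": list(pooled.ci95),
                "z": pooled.z,
                "p_value": pooled.p_value,
                "q": pooled.q,
                "df": pooled.df,
                "i2": pooled.i2,
                "continuity_corrected": list(pooled.continuity_corrected),
            }
        selected = sorted(
            ors.loc[ors["category"] == PRO_RURAL, "country"].tolist()
        )
        table_countries = {t.country for t in tables}
        subset = [c for c in selected if c in table_countries]
        if len(subset) >= 2:
            sub_tables = [t for t in tables if t.country in subset]
            pooled_sub = mh_pooled_or(sub_tables)
            q, df, p = homogeneity_subset_test(tables, subset)
            het["pro_rural_subset"] = {
                "countries": subset,
                "or_mh": pooled_sub.or_mh,
                "ci95": list(pooled_sub.ci95),
                "q": q,
                "df": df,
                "p_value": p,
            }
        _dump_json(_round_floats(het), out / "heterogeneity.json")
        manifest["pro_rural_countries"] = selected
    except RuralGapError as exc:
        raise PipelineError("pooled_or", str(exc)) from exc

    # ---- stage: decomposition ----------------------------------------
    try:
        covs = data.covariate_names
        dec_reports = {}
        for country in selected:
            sub = data.frame[data.frame["country"] == country]
            A, B = group_samples_from_frame(sub, covs)
            cfg = dataclasses.replace(config.decomposition)
            result, model = run_fairlie(A, B, cfg, weights=config.use_weights)
            table = contribution_table(result)
            dec_reports[country] = {
                "total_gap": result.total_gap,
                "explained_total": result.explained_total,
                "unexplained": result.unexplained,
                "replications": result.R_used,
                "contributions": _round_floats(
                    table.to_dict(orient="records")
                ),
            }
        _dump_json(_round_floats(dec_reports), out / "decomposition.json")
        rows = []
        for country, rep in dec_reports.items():
            for c in rep["contributions"]:
                rows.append({"country": country, **c})
        pd.DataFrame(rows).to_csv(out / "decomposition.csv", index=False)
        manifest["n_decomposed"] = len(dec_reports)
    except RuralGapError as exc:
        raise PipelineError("decomposition", str(exc)) from exc

    _dump_json(_round_floats(manifest), out / "manifest.json")
    return manifest
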