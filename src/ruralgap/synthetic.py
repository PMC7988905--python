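"""Multi-country, cluster-structured survey microdata generator.

The generator emulates the structure of a pooled multi-country household
survey: each country contributes a set of primary sampling units
(clusters), each cluster is labelled rural or non-rural, children nest in
clusters, covariates are drawn with rural/non-rural mean shifts, and the
binary outcome follows a logistic model with known coefficients plus a
cluster-level random intercept. Sampling weights are log-normal with a
configurable coefficient of variation and mean one per country.

Because every data-generating parameter is known, downstream estimators
can be tested against closed-form or Monte-Carlo oracles
(:func:`expected_prevalence`) without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .dataset import SurveyDataset
from .errors import ConfigurationError

# latent-normal cut points that split N(0,1) into 5 equal bins
_QUINTILE_CUTS = norm.ppf([0.2, 0.4, 0.6, 0.8])

_KINDS = ("binary", "ordinal5")


@dataclass
class CountryConfig:
    """Data-generating parameters for one country.

    ``rural_effect`` is the structural gap gamma on the logit scale;
    ``covariate_rural_shift`` is the compositional gap: the difference in
    covariate mean (binary: prevalence; ordinal5: latent-normal mean)
    between rural and non-rural clusters.
    """

    name: str
    n_clusters: int
    children_per_cluster: int
    rural_cluster_fraction: float
    intercept: float
    rural_effect: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    covariate_rural_shift: dict[str, float] = field(default_factory=dict)
    covariate_base: dict[str, float] = field(default_factory=dict)
    covariate_kind: dict[str, str] = field(default_factory=dict)
    cluster_sd: float = 0.0
    weight_cv: float = 0.0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError(f"{self.name}: n_clusters must be >= 1")
        if self.children_per_cluster < 1:
            raise ConfigurationError(
                f"{self.name}: children_per_cluster must be >= 1"
            )
        if not 0.0 <= self.rural_cluster_fraction <= 1.0:
            raise ConfigurationError(
                f"{self.name}: rural_cluster_fraction must be in [0, 1]"
            )
        if self.cluster_sd < 0:
            raise ConfigurationError(f"{self.name}: cluster_sd must be >= 0")
        if self.weight_cv < 0:
            raise ConfigurationError(f"{self.name}: weight_cv must be >= 0")
        extra = set(self.covariate_rural_shift) - set(self.covariate_effects)
        if extra:
            raise ConfigurationError(
                f"{self.name}: covariate_rural_shift names "
                f"{sorted(extra)} absent from covariate_effects"
            )
        for cov, kind in self.covariate_kind.items():
            if kind not in _KINDS:
                raise ConfigurationError(
                    f"{self.name}: covariate_kind[{cov!r}] must be one of {_KINDS}"
                )
        for cov, base in self.covariate_base.items():
            if self.kind_of(cov) == "binary" and not 0.0 < base < 1.0:
                raise ConfigurationError(
                    f"{self.name}: covariate_base[{cov!r}] must be in (0, 1)"
                )

    def kind_of(self, cov: str) -> str:
        return self.covariate_kind.get(cov, "binary")

    def base_of(self, cov: str) -> float:
        if cov in self.covariate_base:
            return self.covariate_base[cov]
        return 0.5 if self.kind_of(cov) == "binary" else 0.0


@dataclass
class SimulationConfig:
    countries: list[CountryConfig]
    seed: int = 0

    def validate(self) -> None:
        if not self.countries:
            raise ConfigurationError("countries must be a nonempty list")
        for c in self.countries:
            c.validate()
        names = [c.name for c in self.countries]
        if len(set(names)) != len(names):
            raise ConfigurationError("countries: duplicate country names")
        # covariate names must be identical across countries so the pooled
        # dataset has one schema
        first = set(self.countries[0].covariate_effects)
        for c in self.countries[1:]:
            if set(c.covariate_effects) != first:
                raise ConfigurationError(
                    f"covariate_effects: country {c.name!r} names "
                    f"{sorted(set(c.covariate_effects))} but country "
                    f"{self.countries[0].name!r} names {sorted(first)}"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        countries = [CountryConfig(**c) for c in d["countries"]]
        return cls(countries=countries, seed=int(d.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _covariate_names(cc: CountryConfig) -> list[str]:
    return list(cc.covariate_effects)


def _draw_covariate(
    rng: np.random.Generator, cc: CountryConfig, cov: str, rural: np.ndarray
) -> np.ndarray:
    """Draw one covariate for a vector of children given cluster rurality."""
    shift = cc.covariate_rural_shift.get(cov, 0.0)
    base = cc.base_of(cov)
    if cc.kind_of(cov) == "binary":
        p = np.clip(base + shift * rural, 1e-3, 1 - 1e-3)
        return (rng.random(rural.shape) < p).astype(np.int64)
    # ordinal5: latent normal, rural mean shifted, cut at N(0,1) quintiles
    z = rng.standard_normal(rural.shape) + base + shift * rural
    return np.searchsorted(_QUINTILE_CUTS, z).astype(np.int64) + 1


def generate_survey(config: SimulationConfig) -> SurveyDataset:
    """Simulate the full multi-country dataset. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    frames = []
    for cc in config.countries:
        n_rural = int(round(cc.rural_cluster_fraction * cc.n_clusters))
        rural_flags = np.zeros(cc.n_clusters, dtype=np.int64)
        rural_flags[:n_rural] = 1
        rng.shuffle(rural_flags)
        sizes = np.maximum(rng.poisson(cc.children_per_cluster, cc.n_clusters), 1)
        effects = rng.normal(0.0, cc.cluster_sd, cc.n_clusters)

        child_cluster = np.repeat(np.arange(cc.n_clusters), sizes)
        rural = rural_flags[child_cluster]
        lp = np.full(len(rural), cc.intercept, dtype=float)
        lp += cc.rural_effect * rural
        lp += effects[child_cluster]
        data: dict[str, np.ndarray] = {}
        for cov in _covariate_names(cc):
            x = _draw_covariate(rng, cc, cov, rural)
            data[cov] = x
            lp += cc.covariate_effects[cov] * x
        outcome = (rng.random(len(rural)) < expit(lp)).astype(np.int64)

        if cc.weight_cv > 0:
            sigma2 = np.log1p(cc.weight_cv**2)
            w = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), len(rural))
            w = w / w.mean()  # renormalise to mean 1 per country
        else:
            w = np.ones(len(rural))

        frame = pd.DataFrame(
            {
                "country": cc.name,
                "cluster_id": np.array(
                    [f"{cc.name}-c{i:05d}" for i in range(cc.n_clusters)]
                )[child_cluster],
                "rural": rural,
                "weight": w,
                "outcome": outcome,
                **data,
            }
        )
        frames.append(frame)
    frame = pd.concat(frames, ignore_index=True)
    return SurveyDataset(frame=frame, provenance=f"simulated(seed={config.seed})")


def expected_prevalence(
    config: SimulationConfig,
    group: str = "all",
    n_draws: int = 200_000,
    seed: int = 12345,
) -> float:
    """Plug-in expected outcome prevalence by Monte-Carlo integration.

    This is a test oracle, not a fit: it integrates the inverse-logit of
    the configured linear predictor over the covariate and cluster-effect
    distributions (``n_draws`` draws per country/stratum) and weights
    strata by their expected child counts. Independent of
    :func:`generate_survey`'s sampling path.
    """
    if group not in ("rural", "nonrural", "all"):
        raise ConfigurationError(
            f"group must be 'rural', 'nonrural' or 'all', got {group!r}"
        )
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    total_w = 0.0
    total = 0.0
    for cc in config.countries:
        # expected children per cluster for Poisson truncated below at 1
        lam = cc.children_per_cluster
        esize = lam + np.exp(-lam)
        for rural, frac in ((1, cc.rural_cluster_fraction),
                            (0, 1.0 - cc.rural_cluster_fraction)):
            if group == "rural" and rural == 0:
                continue
            if group == "nonrural" and rural == 1:
                continue
            if frac <= 0:
                continue
            flag = np.full(n_draws, rural, dtype=np.int64)
            lp = np.full(n_draws, cc.intercept + cc.rural_effect * rural)
            lp += rng.normal(0.0, cc.cluster_sd, n_draws)
            for cov in _covariate_names(cc):
                lp += cc.covariate_effects[cov] * _draw_covariate(
                    rng, cc, cov, flag
                )
            w = cc.n_clusters * frac * esize
            total += w * float(expit(lp).mean())
            total_w += w
    if total_w == 0:
        raise ConfigurationError(f"no clusters in group {group!r}")
    return total / total_w
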