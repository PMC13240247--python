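"""National disturbance–demography model.

Expected adult-female survival S̄ and recruitment R̄ are beta-regression
predictions from disturbance covariates (percent anthropogenic footprint
buffered 500 m, percent recent fire outside that footprint); the expected
population growth rate is the Hatter–Bergerud female-only form

    λ̄ = S̄ · (1 + R̄/2),

with R̄ in calves per cow and a 50 % calf sex ratio.  Among-population
variation is represented by a beta distribution around each mean with a
precision parameter φ (α = μφ, β = (1−μ)φ): a population is a quantile of
that distribution, and it keeps its quantile as disturbance changes, so
per-population rate trajectories over disturbance never cross.

The published coefficient and precision values of the national model are
not reproduced here; models load from a small YAML schema and the package
ships an illustrative default set with the qualitative structure of the
national fits (both rates declining with anthropogenic disturbance).

External I/O reports recruitment in calves per 100 cows; all internal
math is in calves per cow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats
from scipy.special import expit

logger = logging.getLogger(__name__)

LINKS = ("logit", "log", "identity")


def _inverse_link(eta: float, link: str) -> float:
    if link == "logit":
        return float(expit(eta))
    if link == "log":
        return float(np.exp(eta))
    if link == "identity":
        return float(eta)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


@dataclass(frozen=True)
class RegressionTerms:
    """One rate's linear predictor: intercept + coefficients per covariate."""

    link: str
    intercept: float
    coef_anthro: float
    coef_fire: float = 0.0

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}, got {self.link!r}")

    def predict(self, anthro: float, fire_excl_anthro: float) -> float:
        eta = (
            self.intercept
            + self.coef_anthro * anthro
            + self.coef_fire * fire_excl_anthro
        )
        return _inverse_link(eta, self.link)


@dataclass(frozen=True)
class DemographicModel:
    """Beta-regression models for survival and recruitment plus precisions.

    ``recruitment_scale`` is the divisor converting the recruitment
    prediction to calves per cow (100 when coefficients are calibrated in
    calves per 100 cows, 1 when already per cow).
    """

    survival: RegressionTerms
    recruitment: RegressionTerms
    precision_survival: float
    precision_recruitment: float
    recruitment_scale: float = 1.0
    model_id_survival: str = "M4"
    model_id_recruitment: str = "M1"

    def __post_init__(self) -> None:
        if self.precision_survival <= 0 or self.precision_recruitment <= 0:
            raise ValueError("beta precisions must be > 0")
        if self.recruitment_scale <= 0:
            raise ValueError("recruitment_scale must be > 0")


@dataclass(frozen=True)
class DisturbanceCovariates:
    """Model covariates: both percentages on the 0–100 scale."""

    anthro: float
    fire_excl_anthro: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("anthro", self.anthro), ("fire_excl_anthro", self.fire_excl_anthro)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class ExpectedRates:
    S_bar: float
    R_bar: float          # calves per cow
    lambda_bar: float

    def __post_init__(self) -> None:
        if not 0.0 < self.S_bar < 1.0:
            raise ValueError(f"S_bar must be in (0,1), got {self.S_bar}")
        if self.R_bar < 0:
            raise ValueError(f"R_bar must be >= 0, got {self.R_bar}")


@dataclass(frozen=True)
class PopulationQuantile:
    """A population's persistent position in the among-population beta."""

    q_S: float
    q_R: float
    population_id: str

    def __post_init__(self) -> None:
        if not (0.0 < self.q_S < 1.0 and 0.0 < self.q_R < 1.0):
            raise ValueError("quantiles must lie strictly in (0, 1)")


def expected_rates(model: DemographicModel, cov: DisturbanceCovariates) -> ExpectedRates:
    """Predict (S̄, R̄, λ̄) at the given disturbance covariates.

    Survival predictions outside (0, 1) (possible under identity or log
    links) are clamped into the open interval with a warning; negative
    recruitment is an error.
    """
    S = model.survival.predict(cov.anthro, cov.fire_excl_anthro)
    if not 0.0 < S < 1.0:
        clamped = float(np.clip(S, 1e-9, 1.0 - 1e-9))
        logger.warning("survival prediction %.4f outside (0,1); clamped to %.4g", S, clamped)
        S = clamped
    R = model.recruitment.predict(cov.anthro, cov.fire_excl_anthro) / model.recruitment_scale
    if R < 0:
        raise ValueError(f"negative recruitment prediction {R}")
    lam = S * (1.0 + R / 2.0)
    return ExpectedRates(S_bar=S, R_bar=R, lambda_bar=lam)


def sample_population_quantiles(
    n: int, seed: int, stratified: bool = True, shared: bool = False
) -> list[PopulationQuantile]:
    """Draw n populations' beta quantiles, deterministically for a seed.

    Stratified mode places exactly one quantile uniformly inside each of n
    equal-probability bins (so small ensembles still span the national
    distribution); otherwise quantiles are i.i.d. uniform(0, 1).  With
    ``shared=True`` a population uses one quantile for both rates
    (q_S = q_R); by default the two are independent.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    if stratified:
        edges = np.arange(n) / n
        q_S = edges + rng.uniform(0.0, 1.0 / n, size=n)
        q_R = edges + rng.uniform(0.0, 1.0 / n, size=n)
        perm = rng.permutation(n)   # decouple the two stratifications
        q_R = q_R[perm]
    else:
        q_S = rng.uniform(0.0, 1.0, size=n)
        q_R = rng.uniform(0.0, 1.0, size=n)
    if shared:
        q_R = q_S.copy()
    eps = 1e-12
    q_S = np.clip(q_S, eps, 1 - eps)
    q_R = np.clip(q_R, eps, 1 - eps)
    return [
        PopulationQuantile(float(a), float(b), population_id=f"pop_{i:04d}")
        for i, (a, b) in enumerate(zip(q_S, q_R))
    ]


def beta_ppf_mean_precision(q: float, mu: float, phi: float) -> float:
    """Inverse CDF of Beta(α = μφ, β = (1−μ)φ) at quantile q."""
    if not 0.0 < mu < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mu}")
    if phi <= 0:
        raise ValueError(f"beta precision must be > 0, got {phi}")
    return float(stats.beta.ppf(q, mu * phi, (1.0 - mu) * phi))


def beta_draw(mu: float, phi: float, rng: np.random.Generator) -> float:
    """One random draw from Beta parameterized by (mean, precision)."""
    if not 0.0 < mu < 1.0:
        raise ValueError(f"beta mean must be in (0,1), got {mu}")
    return float(rng.beta(mu * phi, (1.0 - mu) * phi))


def rates_at_quantile(
    model: DemographicModel, cov: DisturbanceCovariates, pq: PopulationQuantile
) -> tuple[float, float]:
    """Population-level (S, R) at the population's persistent quantiles.

    R̄ (calves per cow) serves directly as the beta mean, so it must lie in
    (0, 1) — recruitment above one calf per cow is outside this model's
    among-population distribution.  Returns R in calves per cow.
    """
    exp = expected_rates(model, cov)
    S = beta_ppf_mean_precision(pq.q_S, exp.S_bar, model.precision_survival)
    R = beta_ppf_mean_precision(pq.q_R, exp.R_bar, model.precision_recruitment)
    return S, R


# ---------------------------------------------------------------------------
# YAML model schema


def model_from_dict(doc: Mapping) -> DemographicModel:
    """Build a DemographicModel from the documented mapping schema.

    Schema::

        survival:    {link, intercept, coef_anthro, coef_fire?, precision}
        recruitment: {link, intercept, coef_anthro, coef_fire?, precision,
                      scale?}   # scale=100 for calves-per-100-cows fits
    """
    def terms(block: Mapping) -> RegressionTerms:
        return RegressionTerms(
            link=block["link"],
            intercept=float(block["intercept"]),
            coef_anthro=float(block["coef_anthro"]),
            coef_fire=float(block.get("coef_fire", 0.0)),
        )

    surv = doc["survival"]
    rec = doc["recruitment"]
    return DemographicModel(
        survival=terms(surv),
        recruitment=terms(rec),
        precision_survival=float(surv["precision"]),
        precision_recruitment=float(rec["precision"]),
        recruitment_scale=float(rec.get("scale", 1.0)),
        model_id_survival=str(doc.get("model_id_survival", "M4")),
        model_id_recruitment=str(doc.get("model_id_recruitment", "M1")),
    )


def load_model(path: str | Path) -> DemographicModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def default_model() -> DemographicModel:
    """The illustrative default model shipped with the package."""
    from importlib.resources import files

    text = files("boreal").joinpath("data/demographic_model.yaml").read_text()
    return model_from_dict(yaml.safe_load(text))
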