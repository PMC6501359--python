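"""Allometric longevity baseline and longevity quotients.

Maximum lifespan scales with body mass across placental mammals. Fitting
``log10(longevity) = a + b * log10(body mass)`` to a reference table of
non-flying placental mammals gives a size-specific prediction; dividing a
species' observed maximum lifespan by that prediction yields its longevity
quotient (LQ). LQ = 1 means a typical lifespan for the species' size.

The packaged default baseline is the published mammalian fit
(a = 0.5609, b = 0.1868, n = 804), so LQs can be computed without any
reference table. Because maximum lifespan is an order statistic that creeps
upward with sampling effort, reference fitting filters to acceptable-quality
records with medium or large sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "AllometricModel",
    "DEFAULT_MODEL",
    "filter_reference",
    "fit_allometry",
    "predict_longevity",
    "longevity_quotient",
    "lq_table",
]


@dataclass(frozen=True)
class AllometricModel:
    """OLS fit of log10(longevity, years) on log10(body mass, g)."""

    intercept: float
    slope: float
    n_reference: int

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("non-finite allometric coefficients")
        if self.n_reference < 3:
            raise ValueError("reference fit needs at least 3 species")


#: published mammalian baseline: 804 non-flying placental mammals
DEFAULT_MODEL = AllometricModel(intercept=0.5609, slope=0.1868, n_reference=804)


def filter_reference(table: pd.DataFrame) -> pd.DataFrame:
    """Keep acceptable-quality records with medium or large sample sizes."""
    for col in ("quality", "sample_size"):
        if col not in table.columns:
            raise ValueError(f"reference table lacks column {col!r}")
    mask = (table["quality"] == "acceptable") & table["sample_size"].isin(["medium", "large"])
    out = table.loc[mask].copy()
    logger.info("reference filter kept %d of %d records", len(out), len(table))
    if out.empty:
        raise ValueError("no reference records pass the quality/sample-size filter")
    return out


def fit_allometry(table: pd.DataFrame) -> AllometricModel:
    """Least-squares fit of log10(longevity) on log10(mass)."""
    longevity = np.asarray(table["longevity_years"], dtype=float)
    mass = np.asarray(table["body_mass_g"], dtype=float)
    if len(table) < 3:
        raise ValueError("need at least 3 reference species")
    if np.any(longevity <= 0) or np.any(mass <= 0):
        raise ValueError("longevity and mass must be positive")
    x = np.log10(mass)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(mass); slope undefined")
    y = np.log10(longevity)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return AllometricModel(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                           n_reference=len(table))


def predict_longevity(mass_g, model: AllometricModel = DEFAULT_MODEL):
    """Predicted maximum lifespan (years) for a body mass in grams."""
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("body mass must be positive")
    out = 10.0 ** (model.intercept + model.slope * np.log10(mass_g))
    return float(out) if out.ndim == 0 else out


def longevity_quotient(observed_years, predicted_years):
    """Observed / predicted lifespan (unitless)."""
    obs = np.asarray(observed_years, dtype=float)
    pred = np.asarray(predicted_years, dtype=float)
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("observed and predicted longevity must be positive")
    out = obs / pred
    return float(out) if out.ndim == 0 else out


def lq_table(traits: pd.DataFrame, model: AllometricModel = DEFAULT_MODEL) -> pd.DataFrame:
    """Per-species LQ table: species, observed, predicted, LQ."""
    pred = predict_longevity(np.asarray(traits["body_mass_g"], dtype=float), model)
    obs = np.asarray(traits["longevity_years"], dtype=float)
    return pd.DataFrame({
        "species": traits["species"].to_numpy(),
        "observed": obs,
        "predicted": pred,
        "LQ": longevity_quotient(obs, pred),
    })
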