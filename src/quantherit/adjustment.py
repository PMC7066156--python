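"""Age and sex adjustment of the phenotype, one value per individual.

Within each cohort the (optionally log-transformed) phenotype is regressed by
ordinary least squares on female, age, age^2, female*age and female*age^2,
pooling all exam records.  Each exam's adjusted value is its residual plus the
cohort grand mean — residual centering keeps the phenotype on its original
scale so downstream regression slopes stay in concentration units — and an
individual's final value is the mean of their adjusted exams.

Single-sex or constant-age cohorts make some covariate columns collinear;
those columns are dropped (with a warning) rather than failing the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["AdjustmentModel", "fit_adjustment_model", "adjust_and_average", "adjust_cohorts"]

COVARIATES = ["intercept", "female", "age", "age2", "female_age", "female_age2"]


@dataclass
class AdjustmentModel:
    cohort: str
    coefficients: pd.Series  # indexed by COVARIATES; dropped columns get 0.0
    grand_mean: float
    transform: str
    n_obs: int
    dropped: tuple[str, ...] = ()

    def design(self, female: np.ndarray, age: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [
                np.ones_like(age),
                female,
                age,
                age**2,
                female * age,
                female * age**2,
            ]
        )

    def predict(self, female, age) -> np.ndarray:
        return self.design(np.asarray(female, float), np.asarray(age, float)) @ (
            self.coefficients[COVARIATES].to_numpy()
        )


def _transform_values(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


def _cohort_frame(exams: pd.DataFrame, individuals: pd.DataFrame, cohort: str) -> pd.DataFrame:
    info = individuals.set_index("individual_id")[["female", "cohort"]]
    merged = exams.join(info, on="individual_id")
    merged = merged[merged["cohort"] == cohort]
    if len(merged) == 0:
        raise ValueError(f"no exam records for cohort {cohort!r}")
    return merged


def fit_adjustment_model(
    exams: pd.DataFrame,
    individuals: pd.DataFrame,
    cohort: str,
    transform: str = "identity",
) -> AdjustmentModel:
    """OLS of the (transformed) phenotype on the five age/sex covariates."""
    merged = _cohort_frame(exams, individuals, cohort)
    yv = _transform_values(merged["value"].to_numpy(float), transform)
    female = merged["female"].to_numpy(float)
    age = merged["age"].to_numpy(float)

    X = np.column_stack(
        [np.ones_like(age), female, age, age**2, female * age, female * age**2]
    )
    # drop collinear columns (pivoted QR rank reveal), keep the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    dropped = tuple(COVARIATES[j] for j in range(X.shape[1]) if j not in keep)
    if dropped:
        log.warning("cohort %s: dropping collinear covariate(s) %s", cohort, dropped)
    beta_kept, *_ = np.linalg.lstsq(X[:, keep], yv, rcond=None)
    beta = pd.Series(0.0, index=COVARIATES)
    beta.iloc[keep] = beta_kept

    return AdjustmentModel(
        cohort=cohort,
        coefficients=beta,
        grand_mean=float(yv.mean()),
        transform=transform,
        n_obs=len(yv),
        dropped=dropped,
    )


def adjust_and_average(
    exams: pd.DataFrame, individuals: pd.DataFrame, model: AdjustmentModel
) -> pd.DataFrame:
    """Residual + grand mean per exam, then the mean over each individual's exams.

    Returns columns ``individual_id, value, n_exams, cohort``.
    """
    merged = _cohort_frame(exams, individuals, model.cohort)
    yv = _transform_values(merged["value"].to_numpy(float), model.transform)
    pred = model.predict(merged["female"].to_numpy(float), merged["age"].to_numpy(float))
    adjusted = yv - pred + model.grand_mean
    out = (
        pd.DataFrame(
            {"individual_id": merged["individual_id"].to_numpy(), "adjusted": adjusted}
        )
        .groupby("individual_id", sort=True)["adjusted"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n_exams"})
    )
    out["cohort"] = model.cohort
    return out


def adjust_cohorts(
    exams: pd.DataFrame, individuals: pd.DataFrame, transform: str = "identity"
) -> tuple[pd.DataFrame, dict[str, AdjustmentModel]]:
    """Fit and apply adjustment separately per cohort; pool adjusted values."""
    models = {}
    parts = []
    for cohort in sorted(individuals["cohort"].unique()):
        present = individuals[individuals["cohort"] == cohort]["individual_id"]
        if not exams["individual_id"].isin(set(present)).any():
            continue
        model = fit_adjustment_model(exams, individuals, cohort, transform)
        models[cohort] = model
        parts.append(adjust_and_average(exams, individuals, model))
    adjusted = pd.concat(parts, ignore_index=True)
    return adjusted, models
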