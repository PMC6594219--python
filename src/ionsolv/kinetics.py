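"""Kinetic solvent parameter and the correlative descriptor models.

The kinetic solvent parameter sigma = ln(k_org / k_water) compares the
apparent rate constant of an acid-catalyzed reaction in a water/organic
mixture against pure water (positive sigma: faster in the mixture).  Two
simulation-derived descriptors predict it: the sign-corrected preferential
exclusion coefficient Gamma' and the hydronium solvation free-energy ratio
dG_k / dG_H2O.  The single-descriptor model sigma_pred = A * Gamma' has no
intercept; the two-descriptor model is ordinary least squares on
standardized descriptors, sigma_pred = A z(Gamma') + B z(dG_ratio) + C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidSpecError, IonsolvError


class CollinearityError(IonsolvError):
    """Raised when the standardized descriptors are effectively collinear."""


class DegenerateError(IonsolvError):
    """Raised on zero-variance input to standardization or fitting."""


def sigma(k_org: float, k_water: float) -> float:
    """Kinetic solvent parameter sigma = ln(k_org / k_water).

    Natural-log scale: a rate ratio is strictly positive, while observed
    solvent effects can slow reactions, so the parameter must be able to
    go negative; the log of the ratio is the conventional choice.
    """
    if k_org <= 0 or k_water <= 0:
        raise InvalidSpecError("rate constants must be positive")
    return math.log(k_org / k_water)


def dg_ratio(delta_g_k: float, delta_g_water: float) -> float:
    """Hydronium solvation free-energy ratio, system k over pure water."""
    if delta_g_water == 0:
        raise InvalidSpecError("water solvation free energy must be non-zero")
    return delta_g_k / delta_g_water


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Z-scores with sample standard deviation (divisor n-1).

    Returns (z, mean, sd); the output has mean 0 and SD 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidSpecError("need at least 2 values to standardize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise DegenerateError("cannot standardize a constant vector")
    return (v - mean) / sd, mean, sd


@dataclass
class KineticDataset:
    """Per-composition rates and descriptors for the correlative model."""

    solvent: list[str]
    wt_pct: np.ndarray
    sigma: np.ndarray
    gamma_prime: np.ndarray
    dg_ratio: np.ndarray
    k_org: Optional[np.ndarray] = None
    k_water: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wt_pct = np.asarray(self.wt_pct, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.gamma_prime = np.asarray(self.gamma_prime, dtype=float)
        self.dg_ratio = np.asarray(self.dg_ratio, dtype=float)
        n = len(self.solvent)
        for name in ("wt_pct", "sigma", "gamma_prime", "dg_ratio"):
            if len(getattr(self, name)) != n:
                raise InvalidSpecError(f"column {name} length mismatch")
        if not np.isfinite(self.sigma).all():
            raise InvalidSpecError("sigma values must be finite")
        for rates in (self.k_org, self.k_water):
            if rates is not None and (np.asarray(rates) <= 0).any():
                raise InvalidSpecError("rate constants must be positive")

    def __len__(self) -> int:
        return len(self.solvent)

    @classmethod
    def from_rates(cls, solvent, wt_pct, k_org, k_water, gamma_prime, dg_ratio):
        k_org = np.asarray(k_org, dtype=float)
        k_water = np.asarray(k_water, dtype=float)
        sig = np.array([sigma(o, w) for o, w in zip(k_org, k_water)])
        return cls(
            solvent=list(solvent), wt_pct=wt_pct, sigma=sig,
            gamma_prime=gamma_prime, dg_ratio=dg_ratio,
            k_org=k_org, k_water=k_water,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "solvent": self.solvent,
                "wt_pct": self.wt_pct,
                "sigma": self.sigma,
                "gamma_prime": self.gamma_prime,
                "dg_ratio": self.dg_ratio,
            }
        )


@dataclass
class ModelFit:
    """Fitted correlative model with its standardization frozen in.

    ``coefficients`` maps descriptor names (plus "intercept" for the
    two-descriptor model) to values; prediction on new data reuses the
    training means/SDs so the model is a fixed function of raw descriptors.
    """

    kind: str                                   # "single" or "multilinear"
    coefficients: dict[str, float]
    standardization: Optional[dict[str, tuple[float, float]]]
    coefficient_se: Optional[dict[str, float]] = None
    n_obs: int = 0

    def predict(self, dataset: KineticDataset) -> np.ndarray:
        if self.kind == "single":
            return self.coefficients["gamma_prime"] * dataset.gamma_prime
        zg = (dataset.gamma_prime - self.standardization["gamma_prime"][0]) / \
            self.standardization["gamma_prime"][1]
        zd = (dataset.dg_ratio - self.standardization["dg_ratio"][0]) / \
            self.standardization["dg_ratio"][1]
        return (
            self.coefficients["gamma_prime"] * zg
            + self.coefficients["dg_ratio"] * zd
            + self.coefficients["intercept"]
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": dict(self.coefficients),
            "coefficient_se": dict(self.coefficient_se or {}),
            "standardization": {
                k: list(v) for k, v in (self.standardization or {}).items()
            },
            "n_obs": self.n_obs,
        }


@dataclass
class ModelEvaluation:
    """Parity-plot quality metrics for a fitted model on a dataset."""

    parity_slope: float
    rmse: float
    pearson_r: float
    pearson_by_solvent: dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.parity_slope, self.rmse, self.pearson_r))

    def to_dict(self) -> dict:
        return {
            "parity_slope": self.parity_slope,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "pearson_by_solvent": dict(self.pearson_by_solvent),
        }


def fit_single(dataset: KineticDataset) -> ModelFit:
    """No-intercept least squares of sigma on raw Gamma'."""
    if len(dataset) < 2:
        raise InvalidSpecError("need at least 2 rows")
    x = dataset.gamma_prime
    denom = float(x @ x)
    if denom == 0:
        raise DegenerateError("Gamma' is identically zero; slope undefined")
    a = float(x @ dataset.sigma) / denom
    resid = dataset.sigma - a * x
    dof = max(len(dataset) - 1, 1)
    se = math.sqrt(float(resid @ resid) / dof / denom)
    return ModelFit(
        kind="single",
        coefficients={"gamma_prime": a},
        standardization=None,
        coefficient_se={"gamma_prime": se},
        n_obs=len(dataset),
    )


def fit_multilinear(dataset: KineticDataset) -> ModelFit:
    """OLS of sigma on standardized Gamma' and dG ratio plus an intercept."""
    if len(dataset) < 4:
        raise InvalidSpecError("need at least 4 rows for the two-descriptor fit")
    zg, mg, sg = standardize(dataset.gamma_prime)
    zd, md, sd = standardize(dataset.dg_ratio)
    r = float(np.corrcoef(zg, zd)[0, 1])
    if abs(r) > 0.999:
        raise CollinearityError(
            f"standardized descriptors are collinear (|r| = {abs(r):.4f})"
        )
    x = np.column_stack([zg, zd, np.ones(len(dataset))])
    coef, _, _, _ = np.linalg.lstsq(x, dataset.sigma, rcond=None)
    resid = dataset.sigma - x @ coef
    dof = max(len(dataset) - 3, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    names = ["gamma_prime", "dg_ratio", "intercept"]
    return ModelFit(
        kind="multilinear",
        coefficients=dict(zip(names, map(float, coef))),
        standardization={"gamma_prime": (mg, sg), "dg_ratio": (md, sd)},
        coefficient_se=dict(zip(names, map(float, np.sqrt(np.diag(cov))))),
        n_obs=len(dataset),
    )


def evaluate_model(fit: ModelFit, dataset: KineticDataset) -> ModelEvaluation:
    """Parity slope, RMSE, and Pearson r of predicted vs observed sigma.

    The parity slope is the least-squares slope (with intercept) of
    observed sigma regressed on predicted sigma; RMSE is the root mean
    squared prediction residual; Pearson r is reported overall and per
    solvent subset with at least two rows.
    """
    if len(dataset) < 2:
        raise InvalidSpecError("need at least 2 rows to evaluate")
    pred = fit.predict(dataset)
    obs = dataset.sigma
    if np.ptp(pred) == 0:
        raise DegenerateError("constant predictions; parity slope undefined")
    slope = float(np.polyfit(pred, obs, 1)[0])
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(obs) == 0:
        r_all = float("nan")
    else:
        r_all = float(stats.pearsonr(pred, obs).statistic)
    by_solvent = {}
    for name in sorted(set(dataset.solvent)):
        mask = np.array([s == name for s in dataset.solvent])
        if mask.sum() >= 2 and np.ptp(pred[mask]) > 0 and np.ptp(obs[mask]) > 0:
            by_solvent[name] = float(
                stats.pearsonr(pred[mask], obs[mask]).statistic
            )
    return ModelEvaluation(
        parity_slope=slope, rmse=rmse, pearson_r=r_all,
        pearson_by_solvent=by_solvent,
    )
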