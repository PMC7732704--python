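"""Polynomial repeated-measures regression of mindfulness scores on engagement.

One model per predictor (predictors are strongly collinear): a linear mixed
model with a per-installation random intercept and fixed effects that are a
degree-1..3 polynomial of a single predictor (weeks since install, total
active minutes, total visits, total events, or highest level achieved).

The polynomial is fitted on an orthonormal basis (QR of the Vandermonde
matrix) for numerical stability and independent per-term tests; coefficients
are reported back on the raw power basis. The reported ``r_squared`` is a
marginal pseudo-R²: the squared correlation between observed outcomes and
the fixed-effects prediction (a variance-decomposition alternative is also
available). Restricted maximum likelihood throughout; when fewer than two
installations contribute repeated occasions the random intercept is not
identifiable and the fit falls back to OLS with a warning.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .engagement_metrics import MS_PER_DAY
from .ffmq import SUBSCALE_LABELS, FFMQScore

log = logging.getLogger("mhengage.outcome_model")

OUTCOMES: tuple[str, ...] = ("total", "Obs", "AA", "NJIE", "NRIE")
PREDICTORS: tuple[str, ...] = (
    "weeks_since_install",
    "active_minutes",
    "n_visits",
    "n_events",
    "level_achieved",
)

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log1p": np.log1p,
}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "total"
    predictor: str = "active_minutes"
    degree: int = 3
    transform: str = "identity"  # applied to the predictor before the polynomial

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ModelFit:
    """Fitted polynomial mixed model, coefficients on the raw power basis."""

    spec: ModelSpec
    coefficients: np.ndarray  # beta_0 .. beta_d on the (transformed) raw scale
    se: np.ndarray
    cov: np.ndarray
    term_pvalues: np.ndarray  # per polynomial term, from the orthogonal basis
    r_squared: float
    n_occasions: int
    n_users: int
    random_intercept_var: float
    residual_var: float
    method: str  # "mixed" | "ols"
    converged: bool

    def predict(self, x: np.ndarray | Sequence[float]) -> np.ndarray:
        """Fixed-effects prediction at raw predictor values."""
        z = TRANSFORMS[self.spec.transform](np.asarray(x, dtype=float))
        V = np.vander(z, len(self.coefficients), increasing=True)
        return V @ self.coefficients

    def derivative(self, x: np.ndarray | Sequence[float]) -> np.ndarray:
        """Derivative of the fitted curve w.r.t. the *transformed* predictor."""
        z = TRANSFORMS[self.spec.transform](np.asarray(x, dtype=float))
        d = np.polynomial.polynomial.polyder(self.coefficients)
        return np.polynomial.polynomial.polyval(z, d)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zcrit = sps.norm.ppf(1 - alpha / 2)
        lo = self.coefficients - zcrit * self.se
        hi = self.coefficients + zcrit * self.se
        return np.column_stack([lo, hi])


def assemble_long_table(
    scores: Iterable[FFMQScore],
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """One row per assessment occasion, joining facet scores to the user's
    engagement totals (the replication default: end-of-study totals as
    predictors).

    Raises if any score belongs to an installation without a profile; users
    with a profile but no scores are simply absent (count logged).
    """
    rows = []
    for s in scores:
        row = {
            "install_id": s.install_id,
            "occasion_ts": s.timestamp,
            "weeks_since_install": s.weeks_since_install,
            "level_at_assessment": s.level_at_assessment,
            "total": s.total,
        }
        row.update(s.labeled)
        rows.append(row)
    if not rows:
        raise ValueError("no scored occasions")
    long = pd.DataFrame(rows)
    prof_cols = ["install_id", "active_minutes", "n_visits", "n_events", "level_achieved"]
    merged = long.merge(profiles[prof_cols], on="install_id", how="left", validate="m:1")
    orphans = merged.loc[merged["active_minutes"].isna(), "install_id"].unique()
    if len(orphans):
        raise ValueError(f"scores without profiles: {sorted(orphans)[:10]}")
    n_without = profiles["install_id"].nunique() - merged["install_id"].nunique()
    if n_without:
        log.info("assemble_long_table: %d user(s) have no scored occasion", n_without)
    return merged


def _orthonormal_basis(x: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """QR of the increasing-power Vandermonde matrix, signs normalized so the
    diagonal of R is positive. Returns (Q, R) with ``Q @ R = V``."""
    V = np.vander(x, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    s = np.sign(np.diag(R))
    s[s == 0] = 1.0
    return Q * s, R * s[:, None]


def fit_polynomial(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the repeated-measures polynomial model described by *spec*."""
    outcome_col = spec.outcome
    data = table.dropna(subset=[outcome_col, spec.predictor])
    y = data[outcome_col].to_numpy(dtype=float)
    x = TRANSFORMS[spec.transform](data[spec.predictor].to_numpy(dtype=float))
    groups = data["install_id"].to_numpy()
    n = y.size
    if np.unique(x).size < spec.degree + 2:
        raise ValueError(
            f"{spec}: needs at least degree+2={spec.degree + 2} distinct predictor values"
        )
    if np.var(y) == 0:
        raise ValueError(f"{spec}: outcome has zero variance")
    Q, R = _orthonormal_basis(x, spec.degree)
    k = spec.degree + 1

    counts = pd.Series(groups).value_counts()
    n_users = int(counts.size)
    n_multi = int((counts >= 2).sum())
    method = "mixed" if n_multi >= 2 else "ols"
    converged = True
    if method == "mixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = sm.MixedLM(y, Q, groups=groups)
                res = model.fit(reml=True)
                converged = bool(res.converged)
            except Exception as exc:  # singular / non-converging fit
                raise RuntimeError(f"singular mixed fit for {spec}: {exc}") from exc
        gamma = np.asarray(res.fe_params)
        cov_gamma = np.asarray(res.cov_params())[:k, :k]
        tau2 = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        sigma2 = float(res.scale)
        pvals = np.asarray(res.pvalues)[:k]
    else:
        log.warning("%s: <2 users with repeated occasions; single-level OLS fallback", spec)
        res = sm.OLS(y, Q).fit()
        gamma = np.asarray(res.params)
        cov_gamma = np.asarray(res.cov_params())
        tau2 = 0.0
        sigma2 = float(res.mse_resid)
        pvals = np.asarray(res.pvalues)

    Rinv = np.linalg.inv(R)
    beta = Rinv @ gamma
    cov_beta = Rinv @ cov_gamma @ Rinv.T
    yhat = Q @ gamma
    r2 = marginal_r_squared(y, yhat)
    return ModelFit(
        spec=spec,
        coefficients=beta,
        se=np.sqrt(np.clip(np.diag(cov_beta), 0, None)),
        cov=cov_beta,
        term_pvalues=pvals,
        r_squared=r2,
        n_occasions=int(n),
        n_users=n_users,
        random_intercept_var=tau2,
        residual_var=sigma2,
        method=method,
        converged=converged,
    )


def marginal_r_squared(observed: np.ndarray, fixed_pred: np.ndarray) -> float:
    """Squared correlation between observed outcomes and the fixed-effects
    prediction (marginal pseudo-R²). Zero when the prediction is constant."""
    observed = np.asarray(observed, dtype=float)
    fixed_pred = np.asarray(fixed_pred, dtype=float)
    if np.var(observed) == 0:
        raise ValueError("outcome has zero variance")
    if np.var(fixed_pred) == 0:
        return 0.0
    r = np.corrcoef(observed, fixed_pred)[0, 1]
    return float(r * r)


def variance_r_squared(
    y: np.ndarray, fixed_pred: np.ndarray, tau2: float, sigma2: float
) -> float:
    """Alternative R²: fixed-effect variance over total (fixed + random +
    residual) variance."""
    vf = float(np.var(fixed_pred))
    return vf / (vf + tau2 + sigma2)


def fit_battery(
    table: pd.DataFrame,
    degree: int = 3,
    time_outcomes: Sequence[str] = OUTCOMES,
    engagement_predictors: Sequence[str] = (
        "active_minutes",
        "n_visits",
        "n_events",
        "level_achieved",
    ),
    engagement_transform: str = "identity",
) -> pd.DataFrame:
    """Run the full reported model grid: time (weeks since install) on the
    total score and each facet, plus each engagement predictor on the total.
    Per-cell failures are recorded, not raised. Returns a tidy frame with one
    row per model x term."""
    specs = [
        ModelSpec(outcome=o, predictor="weeks_since_install", degree=degree)
        for o in time_outcomes
    ] + [
        ModelSpec(outcome="total", predictor=p, degree=degree, transform=engagement_transform)
        for p in engagement_predictors
    ]
    rows = []
    for spec in specs:
        base = {
            "outcome": spec.outcome,
            "predictor": spec.predictor,
            "degree": spec.degree,
            "transform": spec.transform,
        }
        try:
            fit = fit_polynomial(table, spec)
        except (ValueError, RuntimeError) as exc:
            rows.append({**base, "term": None, "error": str(exc)})
            continue
        for t in range(spec.degree + 1):
            rows.append(
                {
                    **base,
                    "term": t,
                    "coefficient": fit.coefficients[t],
                    "se": fit.se[t],
                    "p_value": fit.term_pvalues[t],
                    "r_squared": fit.r_squared,
                    "n_occasions": fit.n_occasions,
                    "n_users": fit.n_users,
                    "method": fit.method,
                    "error": "",
                }
            )
    return pd.DataFrame(rows)
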