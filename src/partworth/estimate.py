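"""Aggregate logit estimation of part-worth utilities.

Each respondent-profile evaluation is one independent Bernoulli observation
(aggregate model — no respondent clustering, matching a pooled conjoint
analysis).  The linear predictor is the effects-coded main-effects design, so
decoded per-level utilities are zero-sum within each attribute.

The monitoring outcome is recoded to binary first: "increase" vs
no-increase ("maintain" and the sparse "decrease" combined).

Fitting is Newton-Raphson on the Bernoulli log-likelihood with step-halving,
converging when the gradient's max-norm falls below ``tol`` (1e-8 by
default).  The coefficient covariance is the inverse observed information at
the optimum.  Complete or quasi-separation — a coefficient diverging while
the likelihood keeps improving — is detected and reported as an error naming
the offending column rather than returned as a huge finite estimate.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .attributes import AttributeSpec, Profile
from .design import effects_decode_matrix, encode_effects

logger = logging.getLogger(__name__)

#: Threshold on |coefficient| beyond which the MLE is treated as divergent.
_SEPARATION_BOUND = 15.0


class FitError(RuntimeError):
    """The logit fit could not be computed."""


class SeparationError(FitError):
    """The MLE is infinite: some column perfectly predicts the outcome."""


class ResponseParseError(ValueError):
    """A response value could not be interpreted; names the offending row."""


_MONITORING_RECODE = {"increase": 1, "maintain": 0, "decrease": 0}
_YESNO = {"yes": 1, "no": 0}


def recode_monitoring(value: str) -> int:
    """Binary monitoring outcome: increase -> 1; maintain/decrease -> 0."""
    try:
        return _MONITORING_RECODE[value]
    except KeyError:
        raise ResponseParseError(
            f"unknown monitoring category {value!r}"
        ) from None


def _binary_outcome(series: pd.Series, outcome: str) -> np.ndarray:
    mapping = _MONITORING_RECODE if outcome == "monitoring" else _YESNO
    values = series.to_numpy()
    y = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, float) and np.isnan(v):
            y[i] = np.nan
            continue
        try:
            y[i] = mapping[v]
        except (KeyError, TypeError):
            raise ResponseParseError(
                f"row {series.index[i]}: unknown {outcome} value {v!r}"
            ) from None
    return y


@dataclasses.dataclass
class FittedLogit:
    """A converged (or explicitly failed) aggregate logit fit."""

    outcome: str
    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    column_map: list[tuple[str | None, str | None]]
    llf: float
    n_obs: int
    n_iter: int
    converged: bool
    attrs: list[AttributeSpec]

    def summary_frame(self) -> pd.DataFrame:
        """term, estimate, SE, z, p — one row per model coefficient."""
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.cov))
        z = self.params / se
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.params,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_aggregate_logit(
    responses: pd.DataFrame,
    profiles: Sequence[Profile],
    attrs: Sequence[AttributeSpec],
    outcome: str,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    cluster_robust: bool = False,
) -> FittedLogit:
    """Fit one outcome's aggregate logit on effects-coded main effects.

    ``responses`` must carry ``profile_id`` and the outcome column; profile
    attribute levels are looked up from ``profiles``.  Rows with a missing
    outcome value are dropped for this model only (logged).  With
    ``cluster_robust=True`` the covariance is a respondent-clustered
    sandwich instead of the inverse observed information.
    """
    if outcome not in responses.columns:
        raise FitError(f"responses have no column {outcome!r}")
    design = encode_effects(profiles, attrs)
    row_of = {pid: i for i, pid in enumerate(design.profile_ids)}
    unknown = set(responses["profile_id"]) - set(row_of)
    if unknown:
        raise FitError(f"responses reference unknown profile_ids: {sorted(unknown)[:5]}")

    y = _binary_outcome(responses[outcome], outcome)
    keep = ~np.isnan(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("outcome %s: dropped %d rows with missing values", outcome, n_dropped)
    y = y[keep]
    pid = responses["profile_id"].to_numpy()[keep]
    X = design.X[[row_of[p] for p in pid]]
    n, p = X.shape
    if n == 0:
        raise FitError(f"no usable observations for outcome {outcome!r}")

    # every level of every attribute must be observed at least once
    pid_set = set(pid)
    observed = [prof for prof in profiles if prof.profile_id in pid_set]
    for a in attrs:
        seen = {prof.assignment[a.name] for prof in observed}
        missing = set(a.levels) - seen
        if missing:
            raise FitError(
                f"outcome {outcome!r}: no observations for {a.name} level(s) "
                f"{sorted(missing)}"
            )

    ybar = y.mean()
    beta = np.zeros(p)
    beta[0] = np.log((ybar + 1e-6) / (1 - ybar + 1e-6))
    ll = _loglik(X, y, beta)
    converged = False
    H = np.eye(p)
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise FitError(
                f"outcome {outcome!r}: singular information matrix"
            ) from None
        t = 1.0
        for _ in range(40):
            beta_new = beta + t * step
            ll_new = _loglik(X, y, beta_new)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = beta_new, ll_new
        worst = int(np.argmax(np.abs(beta)))
        if abs(beta[worst]) > _SEPARATION_BOUND:
            raise SeparationError(
                f"outcome {outcome!r}: coefficient for column "
                f"{['intercept', *design.columns[1:]][worst]!r} diverging "
                f"(|beta|>{_SEPARATION_BOUND:g}); data are separated or degenerate"
            )
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise FitError(f"outcome {outcome!r}: singular information at optimum") from None
    if cluster_robust:
        resid = y - mu
        meat = np.zeros((p, p))
        for _, idx in responses.loc[keep].groupby("respondent_id").indices.items():
            s = X[idx].T @ resid[idx]
            meat += np.outer(s, s)
        cov = cov @ meat @ cov
    if not converged:
        logger.warning("outcome %s: Newton did not converge in %d iterations", outcome, max_iter)
    return FittedLogit(
        outcome=outcome,
        params=beta,
        cov=cov,
        columns=design.columns,
        column_map=design.column_map,
        llf=ll,
        n_obs=n,
        n_iter=it,
        converged=converged,
        attrs=list(attrs),
    )


def utility_table(fit: FittedLogit, attrs: Sequence[AttributeSpec] | None = None) -> pd.DataFrame:
    """Decode a fit into one zero-sum utility (and SE) per attribute level.

    The omitted level of each attribute is reconstructed as minus the sum of
    the others; its standard error comes from the delta method applied to the
    coefficient covariance.
    """
    if not fit.converged:
        raise FitError(f"outcome {fit.outcome!r}: fit did not converge; refusing to decode")
    attrs = list(attrs) if attrs is not None else fit.attrs
    D, row_map = effects_decode_matrix(attrs)
    u = D @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, fit.cov, D))
    return pd.DataFrame(
        {
            "attribute": [a for a, _ in row_map],
            "level": [lvl for _, lvl in row_map],
            "utility": u,
            "se": se,
        }
    )


def utilities_by_attribute(fit: FittedLogit) -> dict[str, np.ndarray]:
    """Decoded utilities grouped per attribute, in level order."""
    table = utility_table(fit)
    return {
        a.name: table.loc[table["attribute"] == a.name, "utility"].to_numpy()
        for a in fit.attrs
    }
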