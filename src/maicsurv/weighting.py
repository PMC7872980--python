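"""Matching-adjusted indirect comparison (MAIC) weighting.

The index trial's patients are reweighted so that the weighted means of the
chosen effect modifiers equal the comparator publication's reported
proportions. Weights take the exponential-tilting (entropy-balancing) form
``w_i = exp(alpha' (x_i - x*))`` where ``x*`` is the target vector; the
tilting coefficients minimise the convex objective
``Q(alpha) = sum_i exp(alpha' (x_i - x*))``, whose stationarity condition is
exactly the moment-matching constraint. Weight concentration is summarised by
Kish's effective sample size ``(sum w)^2 / sum w^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

MOMENT_TOL = 1e-8
FEAS_EPS = 1e-9


@dataclass
class TargetMoments:
    """Published comparator proportions for the matched covariates (0-1 scale)."""

    targets: dict  # covariate name -> proportion

    def __post_init__(self):
        for k, v in self.targets.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"target for {k} outside [0, 1]: {v}")

    @classmethod
    def from_aggregate_baseline(cls, baseline: dict, names=None) -> "TargetMoments":
        """Build targets from an AggregateTrial baseline block (percent scale)."""
        names = list(baseline) if names is None else names
        return cls({k: baseline[k] / 100.0 for k in names})


@dataclass
class WeightSet:
    """Solved MAIC weights with diagnostics."""

    alpha: np.ndarray
    weights: np.ndarray
    ess: float
    covariates: list
    residuals: dict = field(default_factory=dict)  # covariate -> weighted mean - target

    def summary(self) -> dict:
        return {
            "alpha": dict(zip(self.covariates, np.asarray(self.alpha).tolist())),
            "ess": self.ess,
            "n": int(len(self.weights)),
            "moment_residuals": {k: float(v) for k, v in self.residuals.items()},
        }

    def to_csv(self, path, ids=None) -> None:
        ids = np.arange(len(self.weights)) if ids is None else ids
        pd.DataFrame({"id": ids, "weight": self.weights}).to_csv(path, index=False)


def restrict_ipd(ipd: pd.DataFrame, criteria) -> tuple[pd.DataFrame, dict]:
    """Apply eligibility criteria sequentially; returns (subset, provenance).

    ``criteria`` is a list of ``(label, predicate)`` pairs (predicate maps the
    DataFrame to a boolean mask) or a dict ``column -> required value``.
    Raises if the subset becomes empty, naming the first criterion that
    excluded everyone.
    """
    if isinstance(criteria, dict):
        criteria = [(f"{col} == {val}", (lambda df, c=col, v=val: df[c] == v))
                    for col, val in criteria.items()]
    provenance = {"n_before": int(len(ipd)), "steps": []}
    out = ipd
    for label, pred in criteria:
        mask = np.asarray(pred(out), dtype=bool)
        out = out[mask]
        provenance["steps"].append({"criterion": label, "n_after": int(len(out))})
        if len(out) == 0:
            raise ValueError(f"restriction left no patients; first fully exclusionary "
                             f"criterion: {label}")
    provenance["n_after"] = int(len(out))
    return out.reset_index(drop=True), provenance


def solve_weights(ipd: pd.DataFrame, targets: TargetMoments | dict,
                  rescale_to_n: bool = True) -> WeightSet:
    """Estimate exponential-tilting weights matching the target moments.

    The weighted mean of every matched covariate equals its target to within
    1e-8 at the solution. Weights are rescaled to sum to the (restricted)
    sample size for reporting; all downstream estimators are invariant to
    that scale.
    """
    if isinstance(targets, dict):
        targets = TargetMoments(targets)
    names = list(targets.targets)
    missing = [c for c in names if c not in ipd.columns]
    if missing:
        raise ValueError(f"covariates not in IPD: {missing}")
    X = ipd[names].to_numpy(dtype=float)
    xstar = np.array([targets.targets[c] for c in names])
    lo, hi = X.min(axis=0), X.max(axis=0)
    bad = [c for c, l, h, x in zip(names, lo, hi, xstar)
           if not (l + FEAS_EPS < x < h - FEAS_EPS)]
    if bad:
        raise ValueError(f"targets outside the observed covariate support: {bad}")

    Z = X - xstar  # centring on the target anchors the tilt

    def objective(alpha):
        w = np.exp(Z @ alpha)
        return w.sum(), Z.T @ w, Z.T @ (Z * w[:, None])

    def fun(a):
        return objective(a)[0]

    def jac(a):
        return objective(a)[1]

    def hess(a):
        return objective(a)[2]

    res = minimize(fun, np.zeros(len(names)), jac=jac, hess=hess,
                   method="trust-exact", options={"gtol": 1e-12, "maxiter": 500})
    alpha = res.x
    w = np.exp(Z @ alpha)
    resid = (Z * w[:, None]).sum(axis=0) / w.sum()
    if np.max(np.abs(resid)) > MOMENT_TOL:
        raise RuntimeError(
            f"weight solver did not converge: max moment residual "
            f"{np.max(np.abs(resid)):.2e}, gradient norm {np.linalg.norm(res.jac):.2e}")
    if rescale_to_n:
        w = w * len(w) / w.sum()
    return WeightSet(alpha=alpha, weights=w, ess=kish_ess(w), covariates=names,
                     residuals=dict(zip(names, resid)))


def kish_ess(weights) -> float:
    """Kish's effective sample size, ``(sum w)^2 / sum w^2``; scale-invariant."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    sw2 = (w**2).sum()
    if sw2 == 0:
        raise ValueError("all weights are zero")
    return float(w.sum() ** 2 / sw2)
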