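"""Synthetic two-trial scenarios: index-trial IPD and comparator "publications".

The index trial yields one row per patient (binary baseline covariates,
overall-survival and progression-free-survival times with event indicators, a
grade-3/4 treatment-related adverse-event flag, and an analysis weight). The
comparator trial is simulated the same way but only aggregate artefacts
survive — a baseline-percentage table, Kaplan–Meier curves sampled on a grid
with digitization-style rounding, numbers-at-risk tables, and adverse-event
counts — emulating the published evidence base an indirect comparison has to
work from.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq
from scipy.stats import norm

from .config import ScenarioConfig, HazardSpec
from .fpbasis import fp_basis

_T_EPS = 1e-4
_GRID_N = 4096

IPD_COLUMNS = ("id", "os_time", "os_event", "pfs_time", "pfs_event", "trae_grade34", "weight")


def _cumulative_hazard_grid(spec: HazardSpec, t_max: float):
    """Baseline cumulative hazard H(t) tabulated on a fine grid for inversion."""
    grid = np.linspace(_T_EPS, t_max, _GRID_N)
    h = spec.hazard(grid)
    if not np.all(np.isfinite(h)):
        raise ValueError("hazard is not finite on (0, censor_time]; reject config")
    H = cumulative_trapezoid(h, grid, initial=0.0)
    if H[-1] <= 0:
        raise ValueError("cumulative hazard is identically zero; reject config")
    return grid, H


def _draw_covariates(n, prevalences, correlation, rng):
    names = list(prevalences)
    if not names:
        return pd.DataFrame(index=range(n))
    if correlation == 0.0:
        data = {c: (rng.random(n) < prevalences[c]).astype(int) for c in names}
        return pd.DataFrame(data)
    # exchangeable Gaussian copula: latent z with common correlation,
    # thresholded at the marginal quantile so marginals are preserved
    k = len(names)
    shared = rng.standard_normal(n)
    own = rng.standard_normal((n, k))
    r = correlation
    z = np.sqrt(abs(r)) * np.sign(r) * shared[:, None] + np.sqrt(1 - abs(r)) * own
    data = {c: (z[:, j] < norm.ppf(prevalences[c])).astype(int) for j, c in enumerate(names)}
    return pd.DataFrame(data)


def _sample_event_times(n, spec, log_multipliers, censor_time, rng):
    """Inverse-transform sampling of event times from the cumulative hazard.

    Returns (time, event); draws with total hazard below the exponential
    deviate at the censoring horizon are administratively censored there.
    """
    grid, H = _cumulative_hazard_grid(spec, censor_time)
    e = rng.exponential(size=n)
    target = e / np.exp(log_multipliers)
    censored = target > H[-1]
    t = np.interp(target, H, grid)
    t[censored] = censor_time
    return t, (~censored).astype(int)


def _simulate_arm(config: ScenarioConfig, arm: str, rng) -> pd.DataFrame:
    prev = config.covariate_prevalences.get(arm, {})
    cov = _draw_covariates(getattr(config, f"n_{arm}"), prev, config.covariate_correlation, rng)
    n = len(cov)
    log_mult = np.zeros(n)
    for name, eff in config.covariate_log_hazard_effects.items():
        if name in cov.columns:
            log_mult += eff * cov[name].to_numpy()
    spec = config.hazards[arm]
    grid, H = _cumulative_hazard_grid(spec, config.censor_time)

    # raw (pre-censoring) death times are needed to truncate progression
    e_death = rng.exponential(size=n)
    target_death = e_death / np.exp(log_mult)
    death_raw = np.interp(target_death, H, grid)
    death_raw[target_death > H[-1]] = np.inf

    # progression hazard = death hazard * multiplier, so its cumulative
    # hazard is multiplier * H on the same grid
    e_prog = rng.exponential(size=n)
    target_prog = e_prog / (np.exp(log_mult) * config.pfs_hazard_multiplier)
    prog_raw = np.interp(target_prog, H, grid)
    prog_raw[target_prog > H[-1]] = np.inf

    os_time = np.minimum(death_raw, config.censor_time)
    os_event = (death_raw <= config.censor_time).astype(int)
    pfs_raw = np.minimum(prog_raw, death_raw)
    pfs_time = np.minimum(pfs_raw, config.censor_time)
    pfs_event = (pfs_raw <= config.censor_time).astype(int)

    trae = (rng.random(n) < config.trae_probs.get(arm, 0.0)).astype(int)
    out = pd.DataFrame({
        "id": np.arange(n),
        "os_time": os_time,
        "os_event": os_event,
        "pfs_time": pfs_time,
        "pfs_event": pfs_event,
        "trae_grade34": trae,
        "weight": np.ones(n),
    })
    return pd.concat([out, cov], axis=1)


def generate_index_ipd(config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Simulate the index-trial IPD table (one row per patient)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate_arm(config, "index", rng)


def generate_comparator_ipd(config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Simulate the comparator arm's subject-level data.

    ``publish_comparator`` discards this table after aggregation; it is
    exposed so studies can compare against the estimates an analyst would
    get with full access to the comparator IPD.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    return _simulate_arm(config, "comparator", rng)


@dataclass
class AggregateTrial:
    """The published face of a comparator trial.

    Only aggregates: baseline covariate percentages, digitized KM curves per
    endpoint, numbers-at-risk tables, total event counts, and the grade-3/4
    TRAE two-by-two margin.
    """

    name: str
    n: int
    baseline: dict  # covariate -> percent (0-100)
    km_curves: dict  # endpoint -> {"time": [...], "survival": [...]}
    risk_tables: dict  # endpoint -> {"time": [...], "n_risk": [...]}
    event_totals: dict = field(default_factory=dict)  # endpoint -> count
    safety: dict | None = None  # {"events": int, "total": int}

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "AggregateTrial":
        if hasattr(src, "read"):
            d = json.load(src)
        elif isinstance(src, str) and src.lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(**d)


def _km_step(times, events):
    """Plain product-limit estimate; returns event times and survival after each."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    uniq = np.unique(t[e == 1])
    n = len(t)
    surv, s = [], 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.asarray(surv)


def publish_comparator(config: ScenarioConfig, rng=None, name: str = "comparator") -> AggregateTrial:
    """Simulate the comparator arm internally and emit only its publication.

    Survival probabilities are sampled on the curve grid and rounded to three
    decimals (plus optional uniform jitter) to emulate plot digitization.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ipd = _simulate_arm(config, "comparator", rng)
    n = len(ipd)

    cov_cols = [c for c in ipd.columns if c not in IPD_COLUMNS]
    baseline = {c: round(100.0 * float(ipd[c].mean()), 1) for c in cov_cols}

    grid = np.arange(0.0, config.censor_time + 1e-9, config.curve_grid_step)
    km_curves, risk_tables, event_totals = {}, {}, {}
    for endpoint in ("os", "pfs"):
        t = ipd[f"{endpoint}_time"].to_numpy()
        e = ipd[f"{endpoint}_event"].to_numpy()
        et, es = _km_step(t, e)
        # step function: survival at g is the value after the last event <= g
        surv = np.array([1.0 if len(et) == 0 or g < et[0]
                         else es[np.searchsorted(et, g, side="right") - 1] for g in grid])
        if config.digitization_jitter > 0:
            surv = surv + rng.uniform(-config.digitization_jitter,
                                      config.digitization_jitter, size=surv.shape)
        surv = np.clip(np.round(surv, 3), 0.0, 1.0)
        surv[0] = 1.0
        km_curves[endpoint] = {"time": grid.tolist(), "survival": surv.tolist()}
        rt = np.arange(0.0, config.censor_time + 1e-9, config.risk_table_spacing)
        risk_tables[endpoint] = {
            "time": rt.tolist(),
            "n_risk": [int(np.sum(t >= x)) for x in rt],
        }
        event_totals[endpoint] = int(e.sum())

    safety = {"events": int(ipd["trae_grade34"].sum()), "total": n}
    return AggregateTrial(name=name, n=n, baseline=baseline, km_curves=km_curves,
                          risk_tables=risk_tables, event_totals=event_totals, safety=safety)


def powerlaw_hr_components(hr_early: float, hr_late: float, powers=(0.0, 0.0),
                           term: int = 0, early=(1, 12), late=(13, 60)):
    """Solve for (d_scale, d_shape) so ``HR(t) = exp(d_scale + d_shape*g(t))``
    hits two interval targets, where ``g`` is FP basis term ``term`` of
    ``powers``.

    Targets are arithmetic means of monthly HRs over the two month ranges
    (inclusive). Used to build scenarios with a flat-then-diverging hazard
    ratio, as seen when durable responders separate late. Requires ``g``
    monotone over the months spanned (true for every single FP term).
    """
    from scipy.special import logsumexp

    g_e = fp_basis(np.arange(early[0], early[1] + 1, dtype=float), powers)[term]
    g_l = fp_basis(np.arange(late[0], late[1] + 1, dtype=float), powers)[term]
    target = np.log(hr_late / hr_early)

    def log_ratio(b):
        return (logsumexp(b * g_l) - np.log(len(g_l))
                - logsumexp(b * g_e) + np.log(len(g_e)) - target)

    lo, hi = -1.0, 1.0
    while log_ratio(lo) * log_ratio(hi) > 0 and hi < 1e3:
        lo, hi = lo * 2, hi * 2
    b = brentq(log_ratio, lo, hi)
    d0 = np.log(hr_early) - (logsumexp(b * g_e) - np.log(len(g_e)))
    return float(d0), float(b)
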