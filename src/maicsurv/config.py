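"""Scenario configuration for two-trial simulation studies.

A scenario fully specifies an index trial (individual patient data are kept)
and a comparator trial (only aggregate summaries are "published"), together
with the data-generating hazards so that every downstream estimate can be
checked against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .fpbasis import fp_basis


@dataclass(frozen=True)
class HazardSpec:
    """Log-hazard model ``ln h(t) = b0 + b1*f0(t) + b2*f1(t)`` in months.

    ``powers`` are fractional-polynomial powers; a constant hazard is
    ``powers=(0, 0), beta=(ln lambda, 0, 0)``.
    """

    powers: tuple[float, float] = (0.0, 0.0)
    beta: tuple[float, float, float] = (np.log(0.05), 0.0, 0.0)

    def log_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        f0, f1 = fp_basis(t, self.powers)
        b0, b1, b2 = self.beta
        return b0 + b1 * f0 + b2 * f1

    def hazard(self, t) -> np.ndarray:
        return np.exp(self.log_hazard(t))


ARMS = ("index", "comparator")


@dataclass
class ScenarioConfig:
    """Complete description of a two-trial scenario.

    Covariates are binary indicators drawn independently per arm with the
    stated prevalences (an optional exchangeable Gaussian-copula correlation
    can be switched on); event times follow the arm hazard shifted
    multiplicatively by covariate effects, with administrative censoring.
    """

    n_index: int = 103
    n_comparator: int = 563
    covariate_prevalences: dict = field(default_factory=dict)  # arm -> {name: p}
    hazards: dict = field(default_factory=lambda: {a: HazardSpec() for a in ARMS})
    covariate_log_hazard_effects: dict = field(default_factory=dict)
    censor_time: float = 60.0
    trae_probs: dict = field(default_factory=lambda: {"index": 0.66, "comparator": 0.48})
    risk_table_spacing: float = 6.0
    curve_grid_step: float = 1.0
    pfs_hazard_multiplier: float = 2.0
    digitization_jitter: float = 0.0
    covariate_correlation: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_index < 2 or self.n_comparator < 2:
            raise ValueError("each arm needs n >= 2")
        if not (self.censor_time > 0):
            raise ValueError("censor_time must be positive")
        if not (self.curve_grid_step > 0 and self.risk_table_spacing > 0):
            raise ValueError("grid step and risk-table spacing must be positive")
        if not (self.pfs_hazard_multiplier > 1):
            raise ValueError("pfs_hazard_multiplier must exceed 1 so PFS <= OS")
        for arm in ARMS:
            for name, p in self.covariate_prevalences.get(arm, {}).items():
                if not (0 <= p <= 1):
                    raise ValueError(f"prevalence of {name} in {arm} arm outside [0, 1]")
            if not (0 <= self.trae_probs.get(arm, 0.0) <= 1):
                raise ValueError(f"trae_prob for {arm} arm outside [0, 1]")
        if not (-1 < self.covariate_correlation < 1):
            raise ValueError("covariate_correlation must lie in (-1, 1)")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hazards"] = {
            arm: {"powers": list(h.powers), "beta": list(h.beta)}
            for arm, h in self.hazards.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "hazards" in d:
            d["hazards"] = {
                arm: h if isinstance(h, HazardSpec) else HazardSpec(
                    powers=tuple(h["powers"]), beta=tuple(h["beta"])
                )
                for arm, h in d["hazards"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class TruthRecord:
    """Ground truth of the treatment effect implied by a scenario.

    ``true_log_hr_components`` are the differences of index minus comparator
    log-hazard coefficients (defined only when both arms share FP powers);
    interval HRs are arithmetic means of the monthly hazard ratios, matching
    the reporting convention of the time-varying analysis.
    """

    true_log_hr_components: tuple[float, float, float] | None
    true_interval_hr: dict
    generating_powers: tuple[float, float]


def scenario_truth(config: ScenarioConfig, intervals=((0, 12), (12, 60))) -> TruthRecord:
    """Summarise the true (conditional) hazard ratio of a scenario.

    Covariate effects are shared across arms, so the hazard ratio conditional
    on covariates is the ratio of the two arm hazards.
    """
    hi, hc = config.hazards["index"], config.hazards["comparator"]
    d = None
    if hi.powers == hc.powers:
        d = tuple(bi - bc for bi, bc in zip(hi.beta, hc.beta))
    interval_hr = {}
    for t0, t1 in intervals:
        months = np.arange(np.floor(t0) + 1, np.floor(t1) + 1)
        hr = np.exp(hi.log_hazard(months) - hc.log_hazard(months))
        if np.any(hr <= 0):
            raise ValueError("interval HR must be positive")
        interval_hr[(t0, t1)] = float(np.mean(hr))
    return TruthRecord(d, interval_hr, hc.powers)
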