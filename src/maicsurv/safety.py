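"""Weighted comparison of grade 3/4 treatment-related adverse-event incidence.

The index arm contributes a weighted 2x2 margin: the weighted TRAE proportion
applied to the Kish effective sample size gives fractional "effective events"
over an ESS total, which is compared to the comparator's published count/total
through an odds ratio. Credible intervals come from independent Jeffreys
Beta(events + 0.5, non-events + 0.5) posteriors on each arm's rate (the Beta
accepts fractional counts directly), with the OR formed per draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .weighting import kish_ess


@dataclass
class SafetyTable:
    """Weighted two-by-two margin: index (fractional) vs comparator counts."""

    index_events: float
    index_total: float
    comp_events: float
    comp_total: float

    def __post_init__(self):
        for events, total, side in ((self.index_events, self.index_total, "index"),
                                    (self.comp_events, self.comp_total, "comparator")):
            if total <= 0:
                raise ValueError(f"{side} total must be positive")
            if not (0 <= events <= total):
                raise ValueError(f"{side} events outside [0, total]")

    @classmethod
    def from_json(cls, src) -> "SafetyTable":
        if hasattr(src, "read"):
            d = json.load(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(**d)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


@dataclass
class ORResult:
    or_point: float
    cri95: tuple[float, float]
    index_rate: float
    comp_rate: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cri95"] = list(self.cri95)
        return d


def weighted_safety_counts(records) -> tuple[float, float]:
    """Effective event count and ESS of the weighted index arm.

    The weighted TRAE proportion ``sum(w*y)/sum(w)`` is applied to Kish's
    effective sample size, so the pair behaves like a (fractional) 2x2 margin
    carrying the true precision of the weighted sample.
    """
    w = records["weight"].to_numpy(dtype=float)
    y = records["trae_grade34"].to_numpy(dtype=float)
    sw = w.sum()
    if sw <= 0:
        raise ValueError("total weight is zero")
    p_hat = float((w * y).sum() / sw)
    ess = kish_ess(w)
    return p_hat * ess, ess


def odds_ratio(table: SafetyTable, draws: int = 200_000, seed: int = 0) -> ORResult:
    """Point odds ratio and 95% credible interval for a (fractional) 2x2 table."""
    a, ta = table.index_events, table.index_total
    b, tb = table.comp_events, table.comp_total
    if min(a, ta - a, b, tb - b) <= 0:
        raise ValueError("zero cell in the 2x2 table; apply a continuity correction "
                         "to the inputs before comparing")
    point = (a / (ta - a)) / (b / (tb - b))
    rng = np.random.default_rng(seed)
    pa = rng.beta(a + 0.5, ta - a + 0.5, size=draws)
    pb = rng.beta(b + 0.5, tb - b + 0.5, size=draws)
    ors = (pa / (1 - pa)) / (pb / (1 - pb))
    lo, hi = np.percentile(ors, [2.5, 97.5])
    return ORResult(
        or_point=float(point),
        cri95=(float(lo), float(hi)),
        index_rate=float(a / ta),
        comp_rate=float(b / tb),
    )
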