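"""Pseudo-IPD reconstruction from digitized Kaplan–Meier curves.

Published survival figures carry (almost) all the information of the
underlying time-to-event data: the step positions locate events and the
numbers-at-risk table pins down how much censoring happened between steps.
Within each inter-risk-table interval the reconstruction solves for event and
censoring counts so that (a) the product-limit estimate through the digitized
steps is matched and (b) the at-risk count at the next risk-table time is
matched; censoring is spread inside the interval. This is the standard
iterative inversion used to rebuild per-subject data from published curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.exceptions import StatisticalWarning
from sklearn.isotonic import IsotonicRegression


@dataclass
class DigitizedCurve:
    """Digitized survival curve: ordered (time, survival) coordinates."""

    time: np.ndarray
    survival: np.ndarray
    endpoint_label: str = "os"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.time.size == 0:
            raise ValueError("empty digitized curve")
        if self.time[0] != 0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("curve times must strictly increase from 0")
        if np.any((self.survival < 0) | (self.survival > 1)) or self.survival[0] != 1.0:
            raise ValueError("survival must start at 1 and stay within [0, 1]")

    def repaired(self) -> "DigitizedCurve":
        """Return a copy with monotonicity restored by pool-adjacent-violators.

        Digitization noise can make the extracted survival sequence tick
        upward; isotonic (decreasing) regression projects it back onto the
        feasible set before inversion.
        """
        if np.all(np.diff(self.survival) <= 0):
            return self
        iso = IsotonicRegression(increasing=False)
        s = iso.fit_transform(self.time, self.survival)
        s = np.clip(s, 0.0, 1.0)
        s[0] = 1.0
        return DigitizedCurve(self.time.copy(), s, self.endpoint_label)

    @classmethod
    def from_csv(cls, path, endpoint_label: str = "os") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(), endpoint_label)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.time, "survival": self.survival}).to_csv(path, index=False)


@dataclass
class RiskTable:
    """Numbers-at-risk table accompanying a published KM figure."""

    time: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.time.size == 0 or self.time[0] != 0:
            raise ValueError("risk table must start at t = 0")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")

    @classmethod
    def from_csv(cls, path, total_events=None) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["n_risk"].to_numpy(), total_events)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.time, "n_risk": self.n_risk}).to_csv(path, index=False)


@dataclass
class PseudoIPD:
    """Reconstructed per-subject (time, event) pairs for one arm."""

    data: pd.DataFrame  # columns: time, event
    arm_label: str = ""
    provenance: list = field(default_factory=list)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm_label: str = "") -> "PseudoIPD":
        return cls(pd.read_csv(path)[["time", "event"]], arm_label)


def _censor_times(count: int, t0: float, t1: float) -> list[float]:
    # few censorings land at the interval midpoint; many are spread uniformly
    if count <= 0:
        return []
    if count < 5:
        return [0.5 * (t0 + t1)] * count
    return list(t0 + (np.arange(1, count + 1) / (count + 1)) * (t1 - t0))


def reconstruct(curve: DigitizedCurve, risk: RiskTable, arm_label: str = "") -> PseudoIPD:
    """Invert a digitized KM curve + risk table into pseudo-IPD.

    Events are placed exactly at digitized step times. Within each interval
    between risk-table times the censoring count is iterated until the implied
    number at risk at the next risk-table time matches the published one;
    infeasible intervals (implied negative counts) are clamped to zero and a
    warning is recorded in the result's provenance.
    """
    curve = curve.repaired()
    t, s = curve.time, curve.survival
    rt, rn = risk.time, risk.n_risk
    n0 = int(rn[0])
    provenance: list[str] = []

    events: list[tuple[float, int]] = []  # (time, count)
    censors: list[float] = []
    n_cur = n0
    s_cur = 1.0

    # a digitized step exactly at a risk-table time aggregates events from just
    # before it, so it is processed before that at-risk count applies: intervals
    # are (t0, t1] with the count at t1 matched after the step at t1
    boundaries = list(rt) + [max(t[-1], rt[-1]) + 1e-9]
    for j in range(len(rt)):
        t0, t1 = boundaries[j], boundaries[j + 1]
        target_next = int(rn[j + 1]) if j + 1 < len(rt) else None
        mask = (t > t0) & (t <= t1)
        pts = list(zip(t[mask], s[mask]))

        c_guess, best = 0, None
        for _ in range(40):
            n_i, s_i = n_cur, s_cur
            ev_i: list[tuple[float, int]] = []
            ctimes = _censor_times(c_guess, t0, t1)
            ci = 0
            for tk, sk in pts:
                while ci < len(ctimes) and ctimes[ci] < tk:
                    n_i -= 1
                    ci += 1
                d = 0
                if n_i > 0 and s_i > 0:
                    d = int(round(n_i * (1.0 - sk / s_i)))
                    d = max(0, min(d, n_i))
                    if d > 0:
                        s_i *= 1.0 - d / n_i
                        n_i -= d
                        ev_i.append((tk, d))
            n_i -= len(ctimes) - ci  # censorings after the last step
            n_i = max(n_i, 0)
            best = (ev_i, ctimes, n_i, s_i)
            if target_next is None:
                break
            gap = n_i - target_next
            if gap == 0:
                break
            new_guess = c_guess + gap
            if new_guess < 0:
                provenance.append(
                    f"interval [{t0:g}, {t1:g}): implied censor count {new_guess} clamped to 0"
                )
                new_guess = 0
            if new_guess == c_guess:
                break
            c_guess = new_guess
        ev_i, ctimes, n_i, s_i = best
        events.extend(ev_i)
        censors.extend(ctimes)
        n_cur, s_cur = n_i, s_i

    # whoever is still at risk at the end of follow-up is censored there
    t_end = max(t[-1], rt[-1])
    censors.extend([t_end] * n_cur)

    if risk.total_events is not None:
        events, censors, notes = _rescale_events(events, censors, risk.total_events)
        provenance.extend(notes)

    times = [tk for tk, d in events for _ in range(d)] + censors
    flags = [1] * sum(d for _, d in events) + [0] * len(censors)
    df = pd.DataFrame({"time": times, "event": flags}).sort_values(
        ["time", "event"], kind="stable").reset_index(drop=True)
    if len(df) != n0:
        provenance.append(f"subject count {len(df)} != initial at-risk {n0}")
    return PseudoIPD(df, arm_label, provenance)


def _rescale_events(events, censors, total_events):
    """Final pass: nudge event counts to match a published total event count.

    Conversions swap events with censorings at the same step times so the
    subject count is preserved.
    """
    notes = []
    current = sum(d for _, d in events)
    if current == total_events or not events:
        return events, censors, notes
    events = sorted(events)
    diff = total_events - current
    if diff > 0:
        # promote censorings (latest first) into events at the nearest earlier step
        censors = sorted(censors)
        step_times = [tk for tk, _ in events]
        moved = 0
        while moved < diff and censors:
            c = censors.pop()
            idx = int(np.searchsorted(step_times, c, side="right")) - 1
            idx = max(idx, 0)
            tk, d = events[idx]
            events[idx] = (tk, d + 1)
            moved += 1
        if moved < diff:
            notes.append(f"could only add {moved} of {diff} events to match total_events")
    else:
        # demote events (largest steps first) into censorings at the step time
        for _ in range(-diff):
            idx = int(np.argmax([d for _, d in events]))
            tk, d = events[idx]
            if d == 0:
                notes.append("ran out of events while matching total_events")
                break
            events[idx] = (tk, d - 1)
            censors.append(tk)
    return events, censors, notes


@dataclass
class KMEstimate:
    """Weighted product-limit estimate with Greenwood variance."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else float(out[0])

    def variance_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 0.0, self.variance[np.clip(idx, 0, None)])
        return out if out.size > 1 else float(out[0])


def km_estimate(times, events, weights=None) -> KMEstimate:
    """Weighted Kaplan–Meier estimator (unit weights give the classical KM)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("no subjects")
    if np.all((times == 0) & (events == 0)):
        raise ValueError("all subjects censored at time 0")
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        kmf.fit(times, events, weights=weights)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    # weighted Greenwood: var(S) = S^2 * sum d_i / (n_i (n_i - d_i))
    w = np.ones_like(times) if weights is None else np.asarray(weights, dtype=float)
    terms = np.zeros_like(t)
    for i, ti in enumerate(t):
        n_i = w[times >= ti].sum()
        d_i = w[(times == ti) & (events == 1)].sum()
        if d_i > 0 and n_i > d_i:
            terms[i] = d_i / (n_i * (n_i - d_i))
        elif d_i > 0:
            terms[i] = np.nan  # variance undefined once the last subject fails
    var = s**2 * np.nancumsum(terms)
    return KMEstimate(t, s, var)
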