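"""Aalen–Johansen non-parametric cumulative incidence.

With a single initial state and absorbing competing outcomes the
Aalen–Johansen estimator reduces to

    CIF_j(t) = sum_{t_i <= t} S(t_i-) * d_ij / n_i,

where ``S`` is the all-cause Kaplan–Meier survivor function, ``d_ij`` the
number of cause-j events at the distinct event time ``t_i`` and ``n_i`` the
number at risk.  It is the model-free sense check for the parametric
cumulative incidence: crude curves are computed within sex x smoking x
symptom groups without conditioning on age.

Ties between causes at one time share the same at-risk set and ``S(t-)``;
censoring tied with an event time is processed after the events (the
standard survival convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .vocab import CENSORED

__all__ = ["AJEstimate", "aalen_johansen"]


@dataclass
class AJEstimate:
    """Step-function CIF per outcome plus the all-cause survivor curve."""

    times: NDArray                  # distinct event times, ascending
    cif: dict[str, NDArray]         # CIF_j evaluated just after each event time
    survival: NDArray               # all-cause KM just after each event time
    at_risk: NDArray                # n_i at each event time
    n: int
    group: str = ""

    def cif_at(self, outcome: str, t: float) -> float:
        """Right-continuous evaluation of CIF_j at time t."""
        if outcome not in self.cif:
            return 0.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cif[outcome][idx]) if idx >= 0 else 0.0

    def se_at(self, outcome: str, t: float) -> float:
        """Greenwood-style binomial approximation sqrt(p (1-p) / n)."""
        p = self.cif_at(outcome, t)
        return float(np.sqrt(p * (1.0 - p) / self.n))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for outcome, values in self.cif.items():
            for t, c in zip(self.times, values):
                rows.append({"group": self.group, "outcome": outcome, "t": t, "cif": c})
        return pd.DataFrame(rows, columns=["group", "outcome", "t", "cif"])


def aalen_johansen(
    records: pd.DataFrame, horizon: float | None = None, group: str = ""
) -> AJEstimate:
    """Aalen–Johansen cumulative incidence for one homogeneous group.

    ``records`` needs ``time_months`` and ``outcome`` columns; rows with any
    non-censored outcome are events of that cause.  Follow-up beyond
    ``horizon`` (if given) is administratively censored first.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate cumulative incidence from an empty group")
    times = records["time_months"].to_numpy(float)
    outcomes = records["outcome"].to_numpy(object)
    if np.any(times <= 0):
        raise ValueError("all follow-up times must be positive")
    if horizon is not None:
        over = times > horizon
        times = np.where(over, horizon, times)
        outcomes = np.where(over, CENSORED, outcomes)

    n = times.size
    is_event = outcomes != CENSORED
    causes = sorted(set(outcomes[is_event]))
    event_times = np.unique(times[is_event])

    # at risk just before t: everyone with follow-up >= t (events and
    # censorings exactly at t still count: censoring is processed after events)
    order = np.argsort(times, kind="stable")
    sorted_times = times[order]

    surv = 1.0
    cif_now = {c: 0.0 for c in causes}
    cif_steps = {c: np.empty(event_times.size) for c in causes}
    surv_steps = np.empty(event_times.size)
    n_risk = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk = n - int(np.searchsorted(sorted_times, t, side="left"))
        d_total = 0
        for c in causes:
            d = int(np.sum((times == t) & (outcomes == c)))
            cif_now[c] += surv * d / at_risk
            d_total += d
        surv *= 1.0 - d_total / at_risk
        for c in causes:
            cif_steps[c][i] = cif_now[c]
        surv_steps[i] = surv
        n_risk[i] = at_risk

    return AJEstimate(
        times=event_times, cif=cif_steps, survival=surv_steps,
        at_risk=n_risk, n=n, group=group,
    )
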