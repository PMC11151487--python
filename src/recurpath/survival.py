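"""Disease-free survival comparison between altered and unaltered groups.

Kaplan–Meier product-limit curves per group with the group median
(smallest time at which survival drops to <= 0.5; "not reached" if the curve
stays above 0.5) and the two-group log-rank test, via lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival
    medians: dict[str, float | None]  # None = not reached
    n: dict[str, int]
    events: dict[str, int]
    logrank_statistic: float | None
    logrank_p: float | None

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "n": self.n[g],
                "events": self.events[g],
                "median_months": self.medians[g] if self.medians[g] is not None else "NR",
            }
            for g in sorted(self.curves)
        ]
        return pd.DataFrame(rows)


def validate_survival(data: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    if not required <= set(data.columns):
        raise SurvivalError(f"survival table needs columns {sorted(required)}")
    if (data["time"] <= 0).any() or not np.isfinite(data["time"]).all():
        raise SurvivalError("survival times must be finite and > 0")
    if not set(data["event"].astype(int)) <= {0, 1}:
        raise SurvivalError("event flags must be 0/1")
    return data


def km_analysis(data: pd.DataFrame) -> KMResult:
    """Kaplan–Meier curves, group medians, and the two-group log-rank test.

    With zero events overall the log-rank statistic is undefined and reported
    as None.
    """
    data = validate_survival(data)
    groups = sorted(data["group"].unique())
    if len(groups) != 2:
        raise SurvivalError(f"expected exactly 2 groups, got {groups}")
    curves, medians, n, events = {}, {}, {}, {}
    for g in groups:
        sub = data[data["group"] == g]
        if len(sub) == 0:
            raise SurvivalError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"].astype(int))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[g] = curve
        med = kmf.median_survival_time_
        medians[g] = None if np.isinf(med) else float(med)
        n[g] = int(len(sub))
        events[g] = int(sub["event"].astype(int).sum())
    total_events = sum(events.values())
    if total_events == 0:
        logger.info("km_analysis: zero events; log-rank undefined")
        stat = p = None
    else:
        a, b = groups
        da, db = data[data["group"] == a], data[data["group"] == b]
        res = logrank_test(
            da["time"], db["time"],
            event_observed_A=da["event"].astype(int),
            event_observed_B=db["event"].astype(int),
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return KMResult(curves, medians, n, events, stat, p)
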