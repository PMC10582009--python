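"""Genetic-diversity indicators with Acceptable / Warning / Alarm status.

Three indicator families, after the CBD-style monitoring framework:

* Delta-H — annualised percent change of a within-population diversity
  metric (heterozygosity, pi, or F_ROH) between two time points, gated on
  statistical significance.  Annual loss <= 0.05 %/yr is Acceptable,
  0.05-0.3 Warning, > 0.3 Alarm.
* Ne — effective population size against the 50/500 rule: >= 500
  Acceptable, between 50 and 500 Warning, <= 50 Alarm.
* Delta-F_ST — change in between-population differentiation, translated to
  expected migrants per generation under Wright's island model
  Nm = (1 - F_ST) / (4 F_ST).  Migration reduced by >= 25 % (or inflated by
  >= 50 %) is a Warning; reduced by >= 50 % (or inflated by >= 100 %), or any
  population extinct, an Alarm.

Changes that are not statistically significant are always Acceptable: the
t-test decides, with a flag recording whether the Wilcoxon test concurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .diversity import DiversityTrack


class Status(str, Enum):
    ACCEPTABLE = "Acceptable"
    WARNING = "Warning"
    ALARM = "Alarm"


@dataclass
class IndicatorThresholds:
    """Classification bands; defaults follow the monitoring framework."""

    annual_warning_pct: float = 0.05  # loss above this is at least Warning
    annual_alarm_pct: float = 0.3  # loss above this is Alarm
    ne_low: float = 50.0
    ne_high: float = 500.0
    migration_warning_decrease_pct: float = 25.0
    migration_alarm_decrease_pct: float = 50.0
    migration_warning_increase_pct: float = 50.0
    migration_alarm_increase_pct: float = 100.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.annual_warning_pct < self.annual_alarm_pct):
            raise ValueError("annual bands must satisfy 0 < warning < alarm")
        if not (0 < self.ne_low < self.ne_high):
            raise ValueError("Ne bounds must satisfy 0 < low < high")


@dataclass
class IndicatorReport:
    indicator: str
    populations: tuple[str, ...]
    period_years: float
    value_t1: float
    value_t2: float
    annual_pct_change: float | None
    p_ttest: float | None
    p_wilcoxon: float | None
    concordant: bool | None
    significant: bool | None
    status: Status
    nm_t1: float | None = None
    nm_t2: float | None = None

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["status"] = self.status.value
        d["populations"] = ",".join(self.populations)
        return d


def annual_change(m1: float, m2: float, years: float) -> float:
    """Percent change per year: 100 * (m2 - m1) / (m1 * years)."""
    if m1 <= 0:
        raise ValueError("baseline metric must be positive")
    if years <= 0:
        raise ValueError("period must be positive")
    return 100.0 * (m2 - m1) / (m1 * years)


_REL_EPS = 1e-9  # losses equal to a threshold at working precision take the milder band


def _band(loss_pct_per_year: float, th: IndicatorThresholds) -> Status:
    if loss_pct_per_year <= th.annual_warning_pct * (1 + _REL_EPS):
        return Status.ACCEPTABLE
    if loss_pct_per_year <= th.annual_alarm_pct * (1 + _REL_EPS):
        return Status.WARNING
    return Status.ALARM


def classify_delta_h(
    values_t1: Sequence[float],
    values_t2: Sequence[float],
    years: float,
    direction: str = "loss-when-decreasing",
    indicator: str = "dHET",
    populations: tuple[str, ...] = (),
    thresholds: IndicatorThresholds | None = None,
) -> IndicatorReport:
    """Classify temporal change in a per-sample diversity metric.

    Only statistically significant changes count: an unpaired t-test decides
    at alpha, a Wilcoxon rank-sum test is run alongside and a concordance
    flag records whether the two agree.  For heterozygosity and pi a
    decrease is a loss (``loss-when-decreasing``); for F_ROH an increase is
    (``loss-when-increasing``).
    """
    th = thresholds or IndicatorThresholds()
    if direction not in ("loss-when-decreasing", "loss-when-increasing"):
        raise ValueError(f"unknown direction {direction!r}")
    x1 = np.asarray(values_t1, dtype=float)
    x2 = np.asarray(values_t2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 samples per time point")
    t_res = stats.ttest_ind(x1, x2, equal_var=False)
    try:
        w_res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
        p_w = float(w_res.pvalue)
    except ValueError:  # e.g. all values identical
        p_w = 1.0
    p_t = float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0
    significant = p_t < th.alpha
    concordant = significant == (p_w < th.alpha)
    m1, m2 = float(x1.mean()), float(x2.mean())
    ac = annual_change(m1, m2, years)
    loss = -ac if direction == "loss-when-decreasing" else ac
    status = Status.ACCEPTABLE if not significant else _band(loss, th)
    return IndicatorReport(
        indicator=indicator,
        populations=populations,
        period_years=years,
        value_t1=m1,
        value_t2=m2,
        annual_pct_change=ac,
        p_ttest=p_t,
        p_wilcoxon=p_w,
        concordant=concordant,
        significant=significant,
        status=status,
    )


def classify_ne(ne: float, thresholds: IndicatorThresholds | None = None) -> Status:
    """Classify an (externally estimated) effective population size.

    Ne >= 500 Acceptable; 50 < Ne < 500 Warning; Ne <= 50 Alarm — the
    boundaries follow the strict inequalities of the 50/500 rule, so
    Ne = 50 itself falls to Alarm and Ne = 500 to Acceptable.
    """
    th = thresholds or IndicatorThresholds()
    if ne <= 0:
        raise ValueError("Ne must be positive")
    if ne >= th.ne_high:
        return Status.ACCEPTABLE
    if ne > th.ne_low:
        return Status.WARNING
    return Status.ALARM


def fst_to_migrants(fst: float) -> float:
    """Expected migrants per generation under Wright's island model:
    Nm = (1 - F_ST) / (4 F_ST)."""
    if not 0 < fst < 1:
        raise ValueError("F_ST must lie strictly between 0 and 1")
    return (1.0 - fst) / (4.0 * fst)


def classify_delta_fst(
    track_t1: DiversityTrack,
    track_t2: DiversityTrack,
    populations_maintained: bool = True,
    statistic: str = "mean",
    populations: tuple[str, ...] = (),
    thresholds: IndicatorThresholds | None = None,
) -> IndicatorReport:
    """Classify temporal change in between-population differentiation.

    Windows are paired by coordinates and compared with a Wilcoxon
    signed-rank test; if any population went extinct the status is Alarm
    outright; a non-significant change is Acceptable; otherwise genome-wide
    F_ST at each time point is converted to expected migrants Nm and the
    percent change in Nm is classified against the migration bands.
    """
    th = thresholds or IndicatorThresholds()
    key = ["chrom", "start", "end"]
    merged = track_t1.frame[key + ["value"]].merge(
        track_t2.frame[key + ["value"]], on=key, suffixes=("_1", "_2")
    )
    merged = merged.dropna(subset=["value_1", "value_2"])
    if len(merged) < 10:
        raise ValueError("fewer than 10 shared windows")
    v1 = merged["value_1"].to_numpy()
    v2 = merged["value_2"].to_numpy()
    diffs = v2 - v1
    if np.allclose(diffs, 0):
        p_w = 1.0
    else:
        p_w = float(stats.wilcoxon(v1, v2, zero_method="wilcox").pvalue)
    agg = np.mean if statistic == "mean" else np.median
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    f1, f2 = float(agg(v1)), float(agg(v2))
    significant = p_w < th.alpha
    nm1 = fst_to_migrants(f1) if 0 < f1 < 1 else None
    nm2 = fst_to_migrants(f2) if 0 < f2 < 1 else None
    if not populations_maintained:
        status = Status.ALARM
    elif not significant:
        status = Status.ACCEPTABLE
    elif nm1 is None or nm2 is None:
        status = Status.ALARM  # differentiation at or beyond the model's domain
    else:
        pct = 100.0 * (nm2 - nm1) / nm1
        eps = _REL_EPS
        if (
            pct <= -th.migration_alarm_decrease_pct * (1 - eps)
            or pct >= th.migration_alarm_increase_pct * (1 - eps)
        ):
            status = Status.ALARM
        elif (
            pct <= -th.migration_warning_decrease_pct * (1 - eps)
            or pct >= th.migration_warning_increase_pct * (1 - eps)
        ):
            status = Status.WARNING
        else:
            status = Status.ACCEPTABLE
    return IndicatorReport(
        indicator="dFST",
        populations=populations or track_t1.populations,
        period_years=float("nan"),
        value_t1=f1,
        value_t2=f2,
        annual_pct_change=None,
        p_ttest=None,
        p_wilcoxon=p_w,
        concordant=None,
        significant=significant,
        status=status,
        nm_t1=nm1,
        nm_t2=nm2,
    )
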