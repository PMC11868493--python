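"""Median-cutoff stratification and survival statistics.

Cohort analyses follow the standard tissue-biomarker workflow: continuous
per-patient scores (e.g. intratumoral G9 density, intratumoral CD8 density)
are dichotomized at the cohort median, the Kaplan–Meier product-limit
estimator gives the overall survival rate (OSR) at 5 years (= 60 months
exactly), groups are compared with the two-tailed log-rank test, and
frequency tables with Pearson's chi-square (no continuity correction, as is
conventional for these cohort sizes; a Yates-corrected variant is available
via ``correction=True``).

Estimation is delegated to ``lifelines`` (Kaplan–Meier, log-rank) and
``scipy`` (chi-square); this module owns the stratification semantics:
values strictly above the median are "high", ties at the median go to
"low", so the high group is strictly above the cutoff.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import InputError

FIVE_YEARS_MONTHS = 60.0


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def median_split(values, labels: tuple[str, str] = ("low", "high")) -> np.ndarray:
    """Dichotomize at the sample median: value > median -> high, <= -> low.

    The median is the standard even/odd sample median. If every value is
    identical the whole cohort is "low" and a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InputError("median_split requires >= 2 values")
    if not np.isfinite(v).all():
        raise InputError("median_split requires finite values")
    med = np.median(v)
    out = np.where(v > med, labels[1], labels[0])
    if (out == labels[0]).all():
        warnings.warn("all values <= median (constant input?); entire cohort is low",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class KMCurve:
    """Product-limit survival estimate with its risk table.

    Wraps a fitted ``lifelines.KaplanMeierFitter``; ``table`` lists the
    distinct observed times with at-risk counts, deaths, and the stepwise
    survival estimate. At tied times events are processed before censorings
    (the standard convention, which lifelines follows).
    """

    def __init__(self, fitter: KaplanMeierFitter, table: pd.DataFrame):
        self._fitter = fitter
        self.table = table

    @property
    def times(self) -> np.ndarray:
        return self.table["time_months"].to_numpy()

    def survival_at(self, t_months: float) -> float:
        """Step value of S(t) at ``t_months`` (right-continuous)."""
        if t_months < 0:
            raise InputError("survival_at requires t >= 0")
        return float(self._fitter.predict(t_months, interpolate=False))


def km_fit(records: pd.DataFrame) -> KMCurve:
    """Fit the Kaplan–Meier estimator to (time_months, event) records."""
    if len(records) == 0:
        raise InputError("km_fit requires at least one record")
    t = records["time_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if (t < 0).any():
        raise InputError("negative time_months in survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    table = pd.DataFrame(
        {
            "time_months": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "deaths": ev["observed"].to_numpy(dtype=int),
            "censored": ev["censored"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    )
    return KMCurve(kmf, table)


def survival_at(curve: KMCurve, t_months: float) -> float:
    """Functional form of :meth:`KMCurve.survival_at`."""
    return curve.survival_at(t_months)


def osr_percent(records: pd.DataFrame, t_months: float = FIVE_YEARS_MONTHS) -> float:
    """Overall survival rate at ``t_months`` as a percentage (KM estimate)."""
    return 100.0 * km_fit(records).survival_at(t_months)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def logrank(groups) -> tuple[float, float]:
    """Two-tailed log-rank test across >= 2 groups of survival records.

    Returns (chi-square statistic, p) with df = n_groups - 1.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise InputError("logrank requires >= 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise InputError(f"logrank group {i} has zero patients")
    times = np.concatenate([g["time_months"].to_numpy(dtype=float) for g in groups])
    events = np.concatenate([g["event"].to_numpy(dtype=int) for g in groups])
    if events.sum() == 0:
        raise InputError("logrank requires at least one event overall")
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table of counts.

    No continuity correction by default. Raises :class:`InputError` when any
    expected count is zero (degenerate margins).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise InputError("contingency table must be 2-D with nonnegative counts")
    total = obs.sum()
    if total == 0:
        raise InputError("contingency table is empty")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise InputError("chi-square undefined: a cell has expected count zero")
    res = stats.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# joint stratification
# ---------------------------------------------------------------------------

def joint_strata(
    labels_a: pd.Series,
    labels_b: pd.Series,
    records: pd.DataFrame,
    t_months: float = FIVE_YEARS_MONTHS,
    pairwise: bool = False,
    names: tuple[str, str] = ("A", "B"),
):
    """Cross two binary labelings into up-to-4 joint groups with per-group OSR.

    ``labels_a``/``labels_b`` are high/low Series indexed by patient_id;
    ``records`` must carry the same patients. Returns a report DataFrame
    (group, n, events, OSR% at ``t_months``) and, when ``pairwise`` is true,
    a dict of pairwise log-rank (statistic, p) keyed by group-name pairs.
    """
    ia, ib = set(labels_a.index), set(labels_b.index)
    if ia != ib:
        raise InputError("labelings cover different patients")
    rec = records.set_index("patient_id") if "patient_id" in records.columns else records
    if set(rec.index) != ia:
        raise InputError("survival records cover different patients than the labelings")
    joint = labels_a.astype(str) + "-" + names[0] + "/" + labels_b.astype(str) + "-" + names[1]
    rows = []
    group_records: dict[str, pd.DataFrame] = {}
    for group in sorted(joint.unique()):
        patients = joint.index[joint == group]
        g = rec.loc[patients].reset_index()
        group_records[group] = g
        events = int(((g["event"] == 1) & (g["time_months"] <= t_months)).sum())
        rows.append(
            {
                "group": group,
                "n": len(g),
                "events_before_t": events,
                "osr_pct": osr_percent(g, t_months),
            }
        )
    report = pd.DataFrame(rows)
    if not pairwise:
        return report
    tests = {}
    for g1, g2 in itertools.combinations(sorted(group_records), 2):
        try:
            tests[(g1, g2)] = logrank([group_records[g1], group_records[g2]])
        except InputError:
            tests[(g1, g2)] = (float("nan"), float("nan"))
    return report, tests
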