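"""Genotype–phenotype analytics for retinoblastoma cohorts.

Implements the descriptive and model-based summaries used to compare REC
classes: contingency tables with within-group percentages, group summaries
(median/range of age at diagnosis and tumour counts, laterality split),
empirical log-survival curves, closed-form exponential onset-model fits
with Wald rate comparisons, the incomplete-penetrance stratification, and
the Knudson-style Poisson link between tumour number and laterality.

Under the two-hit model the fraction S of predisposed children not yet
diagnosed declines exponentially with age (log S linear in t), so each
group's onset is summarised by a single rate λ (per month).  Every cohort
member is a diagnosed case — there is no censoring — so the maximum
likelihood estimate is the closed form λ̂ = n / Σ t.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


class CohortDataError(ValueError):
    """Invalid or insufficient phenotype data."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as in clinical tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------

class Laterality(enum.Enum):
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"


class FamilyHistory(enum.Enum):
    ISOLATED = "isolated"
    FAMILIAL = "familial"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PatientRecord:
    """One phenotype observation: a diagnosed retinoblastoma patient."""

    patient_id: str
    variant_id: str
    laterality: Laterality
    age_at_dx: float                       # months
    tumors_less_affected_eye: Optional[int] = None
    family_history: FamilyHistory = FamilyHistory.UNKNOWN
    ip_variant: bool = False               # variant seen in an unaffected carrier

    def __post_init__(self) -> None:
        if not (self.age_at_dx > 0):
            raise CohortDataError(
                f"{self.patient_id}: age_at_dx must be positive months, got {self.age_at_dx}"
            )
        if self.tumors_less_affected_eye is not None and self.tumors_less_affected_eye < 0:
            raise CohortDataError(f"{self.patient_id}: negative tumour count")


Grouping = Callable[[PatientRecord], str]


# ---------------------------------------------------------------------------
# Contingency tables and group summaries
# ---------------------------------------------------------------------------

def contingency(patients: Sequence[PatientRecord], grouping: Grouping) -> pd.DataFrame:
    """Group × laterality counts with within-group (row-wise) percentages.

    Returns a DataFrame indexed by group label with columns
    ``unilateral``, ``bilateral``, ``n``, ``unilateral_pct``,
    ``bilateral_pct`` (half-up, one decimal) plus a ``TOTAL`` margin row.
    Empty groups never arise from a total grouping; groups with n=0 after
    restriction carry NaN percentages.
    """
    rows: dict[str, dict[str, int]] = {}
    for p in patients:
        g = grouping(p)
        cell = rows.setdefault(g, {"unilateral": 0, "bilateral": 0})
        cell[p.laterality.value] += 1
    if not rows:
        raise CohortDataError("contingency requires at least one patient")
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.loc["TOTAL"] = df.sum()
    df["n"] = df["unilateral"] + df["bilateral"]
    for col in ("unilateral", "bilateral"):
        df[f"{col}_pct"] = [
            round_half_up(100.0 * c / n, 1) if n > 0 else float("nan")
            for c, n in zip(df[col], df["n"])
        ]
    return df


@dataclass(frozen=True)
class GroupSummary:
    """One row of a class-summary table."""

    label: str
    n: int
    percent_of_cohort: float
    unilateral_n: int
    unilateral_pct: float
    bilateral_n: int
    bilateral_pct: float
    age_median: float
    age_range: tuple[float, float]
    tumors_median: Optional[float]
    tumors_range: Optional[tuple[int, int]]

    def __post_init__(self) -> None:
        assert self.unilateral_n + self.bilateral_n == self.n


def _median(values: Sequence[float]) -> float:
    # even-n convention: mean of the central pair
    return float(np.median(np.asarray(values, dtype=float)))


def summarize_by_group(
    patients: Sequence[PatientRecord], grouping: Grouping
) -> list[GroupSummary]:
    """Per-group phenotype summary in the style of a clinical class table."""
    if not patients:
        raise CohortDataError("summarize_by_group requires at least one patient")
    total = len(patients)
    groups: dict[str, list[PatientRecord]] = {}
    for p in patients:
        groups.setdefault(grouping(p), []).append(p)
    out = []
    for label in sorted(groups):
        members = groups[label]
        n = len(members)
        uni = sum(1 for p in members if p.laterality is Laterality.UNILATERAL)
        bil = n - uni
        ages = [p.age_at_dx for p in members]
        tumors = [
            p.tumors_less_affected_eye
            for p in members
            if p.tumors_less_affected_eye is not None
        ]
        out.append(GroupSummary(
            label=label,
            n=n,
            percent_of_cohort=round_half_up(100.0 * n / total, 1),
            unilateral_n=uni,
            unilateral_pct=round_half_up(100.0 * uni / n, 1),
            bilateral_n=bil,
            bilateral_pct=round_half_up(100.0 * bil / n, 1),
            age_median=_median(ages),
            age_range=(min(ages), max(ages)),
            tumors_median=_median(tumors) if tumors else None,
            tumors_range=(min(tumors), max(tumors)) if tumors else None,
        ))
    return out


def summary_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": s.label,
            "n": s.n,
            "percent_of_cohort": s.percent_of_cohort,
            "unilateral_n": s.unilateral_n,
            "unilateral_pct": s.unilateral_pct,
            "bilateral_n": s.bilateral_n,
            "bilateral_pct": s.bilateral_pct,
            "age_median": s.age_median,
            "age_min": s.age_range[0],
            "age_max": s.age_range[1],
            "tumors_median": s.tumors_median,
            "tumors_min": None if s.tumors_range is None else s.tumors_range[0],
            "tumors_max": None if s.tumors_range is None else s.tumors_range[1],
        }
        for s in summaries
    ])


def penetrance_split(patients: Sequence[PatientRecord]) -> dict[str, Optional[GroupSummary]]:
    """Compare carriers of incomplete-penetrance-associated variants vs the rest.

    Returns ``{"incomplete_penetrance": ..., "regular_penetrance": ...}``;
    a side with no patients is None (flagged rather than fabricated).
    """
    if not patients:
        raise CohortDataError("penetrance_split requires at least one patient")
    label = lambda p: "incomplete_penetrance" if p.ip_variant else "regular_penetrance"
    summaries = {s.label: s for s in summarize_by_group(patients, label)}
    return {
        "incomplete_penetrance": summaries.get("incomplete_penetrance"),
        "regular_penetrance": summaries.get("regular_penetrance"),
    }


# ---------------------------------------------------------------------------
# Exponential onset model
# ---------------------------------------------------------------------------

def empirical_log_survival(ages: Sequence[float]) -> np.ndarray:
    """Empirical (t, log S(t)) step points from uncensored ages at diagnosis.

    S after the i-th order statistic is (n − i)/n; tied ages collapse into a
    single step and the terminal S = 0 point is omitted (log undefined).
    Returns an array of shape (k, 2) with log S monotone non-increasing.
    """
    ages = np.asarray(list(ages), dtype=float)
    if ages.size < 2:
        raise CohortDataError("empirical_log_survival needs at least two ages")
    n = ages.size
    t, counts = np.unique(ages, return_counts=True)
    events = np.cumsum(counts)
    s = (n - events) / n
    keep = s > 0
    return np.column_stack([t[keep], np.log(s[keep])])


@dataclass(frozen=True)
class ExponentialFit:
    rate_lambda: float       # per-month hazard
    n: int
    log_likelihood: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        assert self.rate_lambda > 0
        assert self.ci95[0] <= self.rate_lambda <= self.ci95[1]

    @property
    def median_months(self) -> float:
        return math.log(2.0) / self.rate_lambda


def fit_exponential(ages: Sequence[float]) -> ExponentialFit:
    """Closed-form exponential MLE for uncensored ages: λ̂ = n / Σt.

    The 95% CI comes from the normal approximation on log λ
    (SE(log λ̂) = 1/√n).
    """
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise CohortDataError("fit_exponential needs at least one age")
    if np.any(ages <= 0):
        raise CohortDataError("ages must be positive")
    n = int(ages.size)
    lam = n / float(ages.sum())
    ll = n * math.log(lam) - lam * float(ages.sum())
    half = 1.959963984540054 / math.sqrt(n)
    ci = (lam * math.exp(-half), lam * math.exp(half))
    return ExponentialFit(rate_lambda=lam, n=n, log_likelihood=ll, ci95=ci)


@dataclass(frozen=True)
class RateComparison:
    rate_ratio: float
    percent_increase: float
    wald_z: float
    p_value: float

    def __post_init__(self) -> None:
        assert self.rate_ratio > 0
        assert abs(self.percent_increase - 100.0 * (self.rate_ratio - 1.0)) < 1e-9
        assert 0.0 < self.p_value <= 1.0


def compare_rates(ages_a: Sequence[float], ages_b: Sequence[float]) -> RateComparison:
    """Two-group exponential rate contrast with a Wald test on log λ.

    rate_ratio = λ̂_a / λ̂_b; Var(log ratio) = 1/n_a + 1/n_b.  A ratio above
    1 means group a is diagnosed at a higher rate (earlier) than group b.
    """
    fa, fb = fit_exponential(ages_a), fit_exponential(ages_b)
    rr = fa.rate_lambda / fb.rate_lambda
    se = math.sqrt(1.0 / fa.n + 1.0 / fb.n)
    z = math.log(rr) / se
    p = float(2.0 * sps.norm.sf(abs(z))) if z != 0.0 else 1.0
    p = min(p, 1.0)
    return RateComparison(
        rate_ratio=rr,
        percent_increase=100.0 * (rr - 1.0),
        wald_z=z,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Knudson Poisson laterality link
# ---------------------------------------------------------------------------

def poisson_laterality(m: float) -> tuple[float, float, float]:
    """(p_unaffected, p_unilateral, p_bilateral) for mean tumour count m.

    Model: tumour foci per individual ~ Poisson(m), split independently
    between two eyes with per-eye mean m/2.  Then
    p_unaffected = e^(−m), p_bilateral = (1 − e^(−m/2))², and unilateral is
    the remainder 2·e^(−m/2)(1 − e^(−m/2)).  The triple sums to one.
    """
    if m < 0:
        raise CohortDataError(f"Poisson mean must be non-negative, got {m}")
    q = math.exp(-m / 2.0)           # P(one eye tumour-free)
    p_un = q * q                     # = e^(−m)
    p_bi = (1.0 - q) ** 2
    p_uni = 1.0 - p_un - p_bi
    return (p_un, max(p_uni, 0.0), p_bi)


@dataclass(frozen=True)
class PoissonMEstimate:
    m: float
    unbounded: bool = False


def estimate_poisson_m(
    unilateral_n: int,
    bilateral_n: int,
    unaffected_n: int = 0,
    rtol: float = 1e-8,
) -> PoissonMEstimate:
    """Multinomial MLE of the Poisson tumour-count mean from laterality counts.

    Maximises the likelihood of (unaffected, unilateral, bilateral) counts
    under :func:`poisson_laterality` by root-finding on the score in
    q = e^(−m/2).  All-bilateral data with no unilateral/unaffected
    observations push m to infinity; that case is returned flagged
    ``unbounded`` with a finite upper-limit value.
    """
    u, b, n0 = int(unilateral_n), int(bilateral_n), int(unaffected_n)
    if min(u, b, n0) < 0:
        raise CohortDataError("counts must be non-negative")
    if u + b == 0 and n0 == 0:
        raise CohortDataError("at least one individual required")
    if u + b == 0:
        return PoissonMEstimate(0.0)
    a = u + 2 * n0       # weight on log q
    c = u + 2 * b        # weight on log(1 − q)
    if a == 0:
        # q → 0, m → ∞: report the resolution limit, flagged
        return PoissonMEstimate(-2.0 * math.log(rtol), unbounded=True)
    # score in q: a/q − c/(1−q) = 0 (closed root a/(a+c)); solved numerically
    score = lambda q: a / q - c / (1.0 - q)
    q_hat = optimize.brentq(score, 1e-15, 1.0 - 1e-15, xtol=1e-15, rtol=max(rtol, 1e-15))
    return PoissonMEstimate(-2.0 * math.log(q_hat))
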