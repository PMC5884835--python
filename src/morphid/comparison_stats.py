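"""Matched-binary-outcome statistics: Cochran's Q, McNemar, Holm.

Identification runs on the same cohort yield, per condition (engine,
feature set, noise level), a dichotomous correct/incorrect flag per
subject.  Equality of the correct-identification proportions across k
matched conditions is tested with Cochran's Q (which reduces to the
uncorrected McNemar statistic at k = 2); engine-vs-engine contrasts use
the exact binomial McNemar test; and the family of tests is controlled
with the Bonferroni–Holm step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .identification import IdentificationReport

#: canonical order of the five feature sets in battery output
_SET_ORDER = {"ALL": 0, "AREA": 1, "THICKNESS": 2, "VOLUME": 3, "11LBR": 4}


@dataclass
class BinaryOutcomeMatrix:
    """Subjects × conditions matrix of correct/incorrect flags."""

    values: np.ndarray               # (N, k) of {0, 1}
    condition_labels: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValidationError("need a 2-D matrix with at least 2 conditions")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("cells must be binary (0/1)")
        if len(self.condition_labels) != self.values.shape[1]:
            raise ValidationError("one label per condition required")

    @classmethod
    def from_reports(cls, reports: list[IdentificationReport], labels: list[str] | None = None):
        subjects = reports[0].subjects
        for r in reports[1:]:
            if r.subjects != subjects:
                raise ValidationError("reports cover different subject sets")
        return cls(
            values=np.column_stack([r.correct.astype(int) for r in reports]),
            condition_labels=labels
            or [f"{r.engine}/{r.dataset}/noise={r.noise_level:g}" for r in reports],
            subject_ids=list(subjects),
        )


@dataclass
class TestResult:
    test_name: str
    conditions: list[str]
    statistic: float | None
    df: int | None
    p_value: float
    p_adjusted: float | None = None
    reject: bool | None = None
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "conditions": list(self.conditions),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "reject": self.reject,
            "flag": self.flag,
        }


def cochran_q(m: BinaryOutcomeMatrix) -> TestResult:
    """Cochran's Q over k matched binary conditions.

    Q = (k−1)·[k·ΣC_j² − N²] / (k·ΣR_i − ΣR_i²) with C_j the condition
    totals, R_i the subject (row) totals and N the grand total; df = k−1,
    p from the upper chi-square tail.  Rows constant across conditions
    carry no information; if *all* rows are constant the statistic is
    undefined and p = 1 is returned with a flag.
    """
    X = m.values
    k = X.shape[1]
    C = X.sum(axis=0)
    R = X.sum(axis=1)
    N = X.sum()
    denom = k * N - (R**2).sum()
    if denom == 0:
        return TestResult(
            "cochran_q", m.condition_labels, None, k - 1, 1.0, flag="all rows constant"
        )
    Q = (k - 1) * (k * (C**2).sum() - N**2) / denom
    p = float(stats.chi2.sf(Q, k - 1))
    return TestResult("cochran_q", m.condition_labels, float(Q), k - 1, p)


def mcnemar(m: BinaryOutcomeMatrix, method: str = "exact") -> TestResult:
    """McNemar's test for two matched binary conditions.

    ``exact``: two-sided binomial on the discordant pairs, p = min(1,
    2·P(X ≤ min(b,c))) with X ~ Binomial(b+c, ½); ``chi2_cc``: the
    continuity-corrected statistic (|b−c|−1)²/(b+c) on 1 df.  With no
    discordant pairs p = 1 (flagged).
    """
    if m.values.shape[1] != 2:
        raise ValidationError("McNemar requires exactly 2 conditions")
    x, y = m.values[:, 0], m.values[:, 1]
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if b + c == 0:
        return TestResult(
            "mcnemar_" + method, m.condition_labels, None, None, 1.0, flag="no discordance"
        )
    if method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), b + c, 0.5)))
        return TestResult("mcnemar_exact", m.condition_labels, float(min(b, c)), None, p)
    if method == "chi2_cc":
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, 1))
        return TestResult("mcnemar_chi2_cc", m.condition_labels, float(statistic), 1, p)
    raise ValidationError(f"unknown McNemar method {method!r}")


def holm_adjust(
    p_values: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni–Holm step-down adjustment.

    Returns (adjusted p-values, reject flags) in the input order.  The
    smallest p is compared against α/m, the next against α/(m−1), and so
    on; adjusted p_(i) = max_{j≤i} min(1, (m−j+1)·p_(j)), which makes
    rejections contiguous from the smallest p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    reject = adjusted <= alpha
    return adjusted, reject


def comparison_battery(
    reports: list[IdentificationReport],
    alpha: float = 0.05,
    mcnemar_method: str = "exact",
) -> list[TestResult]:
    """The full cross-engine / cross-dataset / cross-noise test battery.

    From identification reports covering two engines × the five feature
    sets (× optionally the nine noise levels) on the same subjects and
    split, assembles: one Cochran's Q across datasets per engine (2 tests),
    one Cochran's Q across noise levels per engine-dataset pair (10 tests
    with the full noise grid), and one engine-vs-engine McNemar per dataset
    at zero noise (5 tests) — 17 tests on the full grid — then applies the
    Holm correction across the whole family.
    """
    by_key: dict[tuple[str, str, float], IdentificationReport] = {}
    for r in reports:
        by_key[(r.engine, r.dataset, float(r.noise_level))] = r
    engines = sorted({k[0] for k in by_key})
    datasets = sorted({k[1] for k in by_key}, key=lambda d: (_SET_ORDER.get(d, 99), d))
    if len(engines) != 2:
        raise ValidationError(f"battery needs exactly 2 engines, got {engines}")
    missing = [
        (e, d, 0.0) for e in engines for d in datasets if (e, d, 0.0) not in by_key
    ]
    if missing:
        raise ValidationError(f"missing zero-noise reports for: {missing}")

    results: list[TestResult] = []
    # Q across datasets, per engine (zero-noise cells)
    for e in engines:
        cells = [by_key[(e, d, 0.0)] for d in datasets]
        m = BinaryOutcomeMatrix.from_reports(cells, labels=[f"{e}/{d}" for d in datasets])
        res = cochran_q(m)
        res.test_name = f"cochran_q[{e}: datasets]"
        results.append(res)
    # Q across noise levels, per engine × dataset (when a sweep is present)
    partial = False
    for e in engines:
        for d in datasets:
            levels = sorted(l for (ee, dd, l) in by_key if ee == e and dd == d)
            if len(levels) < 2:
                partial = True
                continue
            cells = [by_key[(e, d, l)] for l in levels]
            m = BinaryOutcomeMatrix.from_reports(
                cells, labels=[f"{e}/{d}/noise={l:g}" for l in levels]
            )
            res = cochran_q(m)
            res.test_name = f"cochran_q[{e}/{d}: noise]"
            results.append(res)
    # McNemar engine vs engine, per dataset (zero noise)
    for d in datasets:
        cells = [by_key[(e, d, 0.0)] for e in engines]
        m = BinaryOutcomeMatrix.from_reports(cells, labels=[f"{e}/{d}" for e in engines])
        res = mcnemar(m, method=mcnemar_method)
        res.test_name = f"mcnemar[{d}: {engines[0]} vs {engines[1]}]"
        results.append(res)

    adjusted, reject = holm_adjust([r.p_value for r in results], alpha=alpha)
    for r, pa, rej in zip(results, adjusted, reject):
        r.p_adjusted = float(pa)
        r.reject = bool(rej)
        if partial:
            r.flag = (r.flag + "; " if r.flag else "") + "partial battery (no noise sweep)"
    return results


def battery_to_dataframe(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
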