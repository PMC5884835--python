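"""The identification experiment harness.

Implements the repeated-scan protocol: for a cohort scanned at T annual
timepoints, one timepoint per subject is held out for testing and the
rest train the engine; the engine must then assign each held-out scan to
the correct subject out of all N.  Per-subject one-vs-rest confusion
counts are macro-averaged into accuracy / sensitivity / specificity / F1,
and two robustness sweeps degrade the conditions: additive white Gaussian
noise on the test scans (0–40% of the training SD in nine steps) and
cohort subsampling (10, 20, …, 190 subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers
from .errors import ValidationError
from .feature_tables import (
    FeatureSchema,
    FeatureTable,
    apply_scaler,
    fit_scaler,
    select_feature_set,
)

NOISE_LEVELS = tuple(round(0.05 * i, 2) for i in range(9))   # 0, 0.05, …, 0.40
SIZE_STEPS = tuple(range(10, 191, 10))                       # 10, 20, …, 190

SPLIT_MODES = ("per_subject_random", "global_random", "fixed")


@dataclass
class SplitPlan:
    """Per-subject assignment of timepoints to train/test roles."""

    test_timepoint: dict[str, int]   # subject -> held-out timepoint
    train_timepoints: dict[str, list[int]]
    mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        for s, tp in self.test_timepoint.items():
            train = self.train_timepoints.get(s, [])
            if len(train) < 1:
                raise ValidationError(f"subject {s} has no training timepoints")
            if tp in train:
                raise ValidationError(f"subject {s}: test timepoint also in training")


def split_timepoints(
    table: FeatureTable,
    plan_mode: str = "per_subject_random",
    seed: int = 0,
    test_timepoint: int | None = None,
) -> SplitPlan:
    """Choose one test timepoint per subject (the rest train).

    ``per_subject_random`` draws each subject's test point independently;
    ``global_random`` draws a single test point shared by all subjects;
    ``fixed`` uses the given ``test_timepoint``.
    """
    if plan_mode not in SPLIT_MODES:
        raise ValidationError(f"unknown split mode {plan_mode!r}; use one of {SPLIT_MODES}")
    tps_by_subject: dict[str, set[int]] = {}
    for s, t in zip(table.subject_ids, table.timepoints):
        tps_by_subject.setdefault(s, set()).add(int(t))
    short = [s for s, v in tps_by_subject.items() if len(v) < 2]
    if short:
        raise ValidationError(f"subjects with <2 timepoints cannot be split: {short[:10]}")
    if len({frozenset(v) for v in tps_by_subject.values()}) > 1:
        raise ValidationError("subjects do not share an identical timepoint set")
    tps = sorted(next(iter(tps_by_subject.values())))
    subjects = sorted(tps_by_subject)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B11]))
    if plan_mode == "fixed":
        if test_timepoint is None or test_timepoint not in tps:
            raise ValidationError(f"fixed mode needs a test timepoint among {tps}")
        chosen = {s: int(test_timepoint) for s in subjects}
    elif plan_mode == "global_random":
        t = int(rng.choice(tps))
        chosen = {s: t for s in subjects}
    else:
        draws = rng.choice(tps, size=len(subjects))
        chosen = {s: int(t) for s, t in zip(subjects, draws)}
    return SplitPlan(
        test_timepoint=chosen,
        train_timepoints={s: [t for t in tps if t != chosen[s]] for s in subjects},
        mode=plan_mode,
        seed=int(seed),
    )


def apply_split(table: FeatureTable, plan: SplitPlan) -> tuple[FeatureTable, FeatureTable]:
    """Materialize (train, test) tables from a plan."""
    is_test = np.array(
        [plan.test_timepoint[s] == int(t) for s, t in zip(table.subject_ids, table.timepoints)]
    )
    train = table.take_rows(np.flatnonzero(~is_test)).sorted_by_row()
    test = table.take_rows(np.flatnonzero(is_test)).sorted_by_row()
    return train, test


def add_gaussian_noise(
    test: FeatureTable,
    level: float,
    reference: FeatureTable,
    seed: int = 0,
) -> FeatureTable:
    """Add white Gaussian noise scaled to the training SD of each feature.

    Noise SD for feature ``j`` is ``level * s_j`` where ``s_j`` is the sample
    SD (n−1) of feature ``j`` over the ``reference`` (training) rows.  A
    constant reference feature is passed through unperturbed with a warning.
    ``level = 0`` returns an identical copy.
    """
    if level < 0:
        raise ValidationError("noise level must be non-negative")
    if reference.feature_names != test.feature_names:
        raise ValidationError("reference and test tables must share feature columns")
    if level == 0:
        return test.take_rows(np.arange(test.n_rows))
    s = reference.values.std(axis=0, ddof=1)
    if np.any(s == 0):
        bad = [test.feature_names[j] for j in np.nonzero(s == 0)[0]]
        warnings.warn(
            f"constant reference features passed through without noise: {bad[:5]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAD0]))
    eta = rng.normal(0.0, 1.0, size=test.values.shape) * (level * s)
    out = test.take_rows(np.arange(test.n_rows))
    out.values = out.values + eta
    return out


@dataclass
class IdentificationReport:
    """Macro-averaged metrics plus the per-subject correctness vector."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    subjects: list[str]
    correct: np.ndarray                      # bool per subject, sorted by id
    confusion: dict[str, dict[str, int]]     # per class: TP/FN/FP/TN
    engine: str = ""
    dataset: str = ""
    noise_level: float = 0.0
    seed: int | None = None
    n_subjects: int = 0

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }

    def to_dict(self) -> dict:
        return {
            **self.metrics(),
            "subjects": self.subjects,
            "correct": [int(c) for c in self.correct],
            "engine": self.engine,
            "dataset": self.dataset,
            "noise_level": self.noise_level,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IdentificationReport":
        return cls(
            accuracy=d["accuracy"],
            sensitivity=d["sensitivity"],
            specificity=d["specificity"],
            f1=d["f1"],
            subjects=list(d["subjects"]),
            correct=np.array(d["correct"], dtype=bool),
            confusion=d.get("confusion", {}),
            engine=d.get("engine", ""),
            dataset=d.get("dataset", ""),
            noise_level=d.get("noise_level", 0.0),
            seed=d.get("seed"),
            n_subjects=d.get("n_subjects", len(d["subjects"])),
        )


def compute_metrics(truth: list[str], predicted: list[str]) -> IdentificationReport:
    """One-vs-rest confusion per subject, macro-averaged.

    Each subject contributes exactly one test scan, so per class ``c``:
    TP_c ∈ {0,1}; FP_c counts other subjects' scans attributed to ``c``;
    TN_c = (N−1) − FP_c.  Sensitivity is TP_c, specificity TN_c/(N−1),
    accuracy (TP_c+TN_c)/N, and F1 the harmonic mean of precision
    TP_c/(TP_c+FP_c) and sensitivity (0 where undefined).  The macro
    averages are the unweighted means over all N classes.
    """
    if len(truth) != len(predicted):
        raise ValidationError("truth and prediction lengths differ")
    if len(set(truth)) != len(truth):
        raise ValidationError("identification requires exactly one test row per class")
    classes = sorted(truth)
    N = len(classes)
    pred_of = dict(zip(truth, predicted))
    fp = {c: 0 for c in classes}
    for t, p in zip(truth, predicted):
        if p != t:
            if p in fp:
                fp[p] += 1
    sens = np.empty(N)
    spec = np.empty(N)
    acc = np.empty(N)
    f1 = np.empty(N)
    confusion: dict[str, dict[str, int]] = {}
    for i, c in enumerate(classes):
        tp = int(pred_of[c] == c)
        fn = 1 - tp
        fpc = fp[c]
        tn = (N - 1) - fpc
        sens[i] = tp
        spec[i] = tn / (N - 1) if N > 1 else 1.0
        acc[i] = (tp + tn) / N
        prec = tp / (tp + fpc) if (tp + fpc) > 0 else 0.0
        f1[i] = 2 * prec * tp / (prec + tp) if (prec + tp) > 0 else 0.0
        confusion[c] = {"TP": tp, "FN": fn, "FP": fpc, "TN": tn}
    correct = np.array([pred_of[c] == c for c in classes])
    return IdentificationReport(
        accuracy=float(acc.mean()),
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        f1=float(f1.mean()),
        subjects=classes,
        correct=correct,
        confusion=confusion,
        n_subjects=N,
    )


def _fit_predict(engine: str, engine_params: dict, train: FeatureTable, test: FeatureTable):
    params = dict(engine_params or {})
    if engine == "lda":
        model = classifiers.fit_lda(
            train, shrinkage=params.get("shrinkage", classifiers.DEFAULT_SHRINKAGE)
        )
        return classifiers.predict_lda(model, test)
    if engine == "wknn":
        model = classifiers.fit_wknn(train, k=params.get("k", classifiers.DEFAULT_K))
        return classifiers.predict_wknn(model, test)
    raise ValidationError(f"unknown engine {engine!r}; use 'lda' or 'wknn'")


def run_identification(
    table: FeatureTable,
    schema: FeatureSchema | None,
    set_name: str,
    engine: str = "lda",
    engine_params: dict | None = None,
    plan_mode: str = "per_subject_random",
    noise_level: float = 0.0,
    seed: int = 0,
    scale: bool = True,
    test_timepoint: int | None = None,
) -> IdentificationReport:
    """One full identification experiment.

    Pipeline: feature-set selection → train/test timepoint split → z-scoring
    fit on the training rows and applied to both → Gaussian noise on the
    test rows → engine fit/predict → macro metrics.  Fully seeded; pass
    ``schema=None`` to use all columns of ``table`` as the feature set.
    """
    sub = table if schema is None else select_feature_set(table, schema, set_name)
    plan = split_timepoints(sub, plan_mode, seed=seed, test_timepoint=test_timepoint)
    train, test = apply_split(sub, plan)
    if scale:
        scaler = fit_scaler(train)
        train = apply_scaler(scaler, train)
        test = apply_scaler(scaler, test)
    if noise_level > 0:
        test = add_gaussian_noise(test, noise_level, reference=train, seed=seed)
    predicted = _fit_predict(engine, engine_params or {}, train, test)
    report = compute_metrics(list(test.subject_ids), predicted)
    report.engine = engine
    report.dataset = set_name
    report.noise_level = float(noise_level)
    report.seed = int(seed)
    return report


@dataclass
class SweepResult:
    """Reports collected along a robustness axis (noise level or cohort size)."""

    axis_name: str
    axis_values: list
    reports: list[IdentificationReport] = field(default_factory=list)
    axis_of_report: list = field(default_factory=list)
    replicate_of_report: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for val, rep, r in zip(self.axis_of_report, self.replicate_of_report, self.reports):
            rows.append(
                {
                    self.axis_name: val,
                    "replicate": rep,
                    "engine": r.engine,
                    "dataset": r.dataset,
                    **r.metrics(),
                    "n_subjects": r.n_subjects,
                    "seed": r.seed,
                }
            )
        return pd.DataFrame(rows)


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    return [int(s) for s in ss.generate_state(replicates) >> 1]  # keep < 2^31


def noise_sweep(
    table: FeatureTable,
    schema: FeatureSchema | None,
    set_name: str,
    engine: str = "lda",
    engine_params: dict | None = None,
    plan_mode: str = "per_subject_random",
    seed: int = 0,
    levels: tuple = NOISE_LEVELS,
    replicates: int = 1,
    scale: bool = True,
) -> SweepResult:
    """Identification at each noise level (default nine: 0%, 5%, …, 40%).

    Within a replicate the split (and hence training data) is held fixed
    across levels so that only the test-scan degradation varies.
    """
    out = SweepResult("noise_level", list(levels))
    for rep, rep_seed in enumerate(_replicate_seeds(seed, replicates)):
        for level in levels:
            r = run_identification(
                table, schema, set_name, engine, engine_params,
                plan_mode, noise_level=level, seed=rep_seed, scale=scale,
            )
            out.reports.append(r)
            out.axis_of_report.append(level)
            out.replicate_of_report.append(rep)
    return out


def size_sweep(
    table: FeatureTable,
    schema: FeatureSchema | None,
    set_name: str,
    engine: str = "lda",
    engine_params: dict | None = None,
    plan_mode: str = "per_subject_random",
    seed: int = 0,
    sizes: tuple = SIZE_STEPS,
    replicates: int = 1,
    scale: bool = True,
    noise_level: float = 0.0,
) -> SweepResult:
    """Identification at increasing cohort sizes (default 10, 20, …, 190).

    Subjects are subsampled without replacement (seeded); sizes above the
    available cohort are clipped out of the axis.
    """
    subjects = np.array(table.subjects)
    usable = [s for s in sizes if s <= len(subjects)]
    out = SweepResult("n_subjects", list(usable))
    for rep, rep_seed in enumerate(_replicate_seeds(seed, replicates)):
        rng = np.random.default_rng(np.random.SeedSequence([rep_seed, 0x517E]))
        for size in usable:
            chosen = set(rng.choice(subjects, size=size, replace=False).tolist())
            keep = np.flatnonzero(np.array([s in chosen for s in table.subject_ids]))
            sub = table.take_rows(keep)
            r = run_identification(
                sub, schema, set_name, engine, engine_params,
                plan_mode, noise_level=noise_level, seed=rep_seed, scale=scale,
            )
            out.reports.append(r)
            out.axis_of_report.append(size)
            out.replicate_of_report.append(rep)
    return out
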