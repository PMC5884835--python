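"""Wide-format morphometric feature tables.

The pipeline's universal currency is a :class:`FeatureTable`: one row per
subject-scan, one column per anatomical measure, in the dialect emitted by
FreeSurfer's ``aparcstats2table``/``asegstats2table`` (first column an
identifier, remaining columns numeric).  A :class:`FeatureSchema` names the
five canonical feature sets (11LBR, THICKNESS, AREA, VOLUME, ALL) and a
:class:`Scaler` carries training-set z-scoring parameters.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .destrieux import EXTRA_NAMES, LBR_NAMES, regional_names
from .errors import ParseError, ValidationError

FEATURE_SET_NAMES = ("11LBR", "THICKNESS", "AREA", "VOLUME", "ALL")

_TP_SUFFIX = re.compile(r"^(?P<subject>.+)_t(?P<tp>\d+)$")
_TP_COLUMNS = {"tp", "timepoint", "time_point", "visit"}


@dataclass
class FeatureTable:
    """Subject × timepoint × feature matrix.

    Rows are subject-scans; ``subject_ids[i]`` and ``timepoints[i]`` label row
    ``i`` of ``values``.  Every ``(subject, timepoint)`` pair is unique, all
    values are finite, and every subject carries the same timepoint set.
    """

    subject_ids: list[str]
    timepoints: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    units: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=int)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.values.shape if self.values.ndim == 2 else (len(self.values), -1)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if p != len(self.feature_names):
            raise ValidationError(
                f"column count {p} != number of feature names {len(self.feature_names)}"
            )
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValidationError("duplicate feature names")
        if len(self.subject_ids) != n or len(self.timepoints) != n:
            raise ValidationError("row labels and value matrix disagree in length")
        pairs = list(zip(self.subject_ids, self.timepoints.tolist()))
        if len(pairs) != len(set(pairs)):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValidationError(f"duplicate (subject, timepoint) rows: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            offenders = [
                f"row {i + 1} ({self.subject_ids[i]}, t{self.timepoints[i]}), "
                f"column {self.feature_names[j]}"
                for i, j in bad[:10]
            ]
            raise ValidationError("non-finite/missing values: " + "; ".join(offenders))

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> list[str]:
        """Unique subject identifiers in sorted order."""
        return sorted(set(self.subject_ids))

    @property
    def timepoint_set(self) -> list[int]:
        return sorted(set(self.timepoints.tolist()))

    def sorted_by_row(self) -> "FeatureTable":
        order = sorted(
            range(self.n_rows), key=lambda i: (self.subject_ids[i], self.timepoints[i])
        )
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in order],
            timepoints=self.timepoints[order],
            values=self.values[order],
        )

    def take_rows(self, idx: np.ndarray | list[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in idx],
            timepoints=self.timepoints[idx],
            values=self.values[idx],
        )

    def select_columns(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise ValidationError(f"features absent from table: {missing}")
        pos = {n: j for j, n in enumerate(self.feature_names)}
        cols = [pos[n] for n in names]
        units = (
            {n: self.units[n] for n in names if n in self.units}
            if self.units
            else None
        )
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            timepoints=self.timepoints.copy(),
            feature_names=list(names),
            values=self.values[:, cols].copy(),
            units=units,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "timepoint", self.timepoints)
        df.insert(0, "subject", self.subject_ids)
        return df


@dataclass
class FeatureSchema:
    """Names of the five canonical morphometric feature sets.

    ``ALL`` is the concatenation of the three 148-region modality sets
    (Destrieux parcellation, lh/rh) with the global/subcortical extras;
    ``11LBR`` (eleven large-brain-region composites) is a subset of the
    extras.  The packaged default reconstructs the extras from standard
    FreeSurfer aseg/global names.
    """

    regional: dict[str, list[str]] = field(
        default_factory=lambda: {m: regional_names(m) for m in ("thickness", "area", "volume")}
    )
    extra_names: list[str] = field(default_factory=lambda: list(EXTRA_NAMES))
    lbr_names: list[str] = field(default_factory=lambda: list(LBR_NAMES))

    def __post_init__(self) -> None:
        for m, names in self.regional.items():
            if len(names) != len(set(names)):
                raise ValidationError(f"duplicate names in modality {m}")
        if not set(self.lbr_names) <= set(self.extra_names):
            raise ValidationError("11LBR names must be a subset of the extras")

    @property
    def set_definitions(self) -> dict[str, list[str]]:
        return {
            "11LBR": list(self.lbr_names),
            "THICKNESS": list(self.regional["thickness"]),
            "AREA": list(self.regional["area"]),
            "VOLUME": list(self.regional["volume"]),
            "ALL": (
                list(self.regional["thickness"])
                + list(self.regional["area"])
                + list(self.regional["volume"])
                + list(self.extra_names)
            ),
        }

    def feature_set(self, name: str) -> list[str]:
        try:
            return self.set_definitions[name]
        except KeyError:
            raise ValidationError(
                f"unknown feature set {name!r}; choose from {FEATURE_SET_NAMES}"
            ) from None

    def units(self) -> dict[str, str]:
        """Per-feature unit tags (mm, mm2, mm3)."""
        u: dict[str, str] = {}
        for m, tag in (("thickness", "mm"), ("area", "mm2"), ("volume", "mm3")):
            u.update({n: tag for n in self.regional[m]})
        for n in self.extra_names:
            if n.endswith("_area"):
                u[n] = "mm2"
            elif n.endswith("_thickness"):
                u[n] = "mm"
            elif n.endswith("-to-eTIV"):
                u[n] = "dimensionless"
            else:
                u[n] = "mm3"
        return u

    def to_json(self) -> str:
        return json.dumps(
            {
                "regional": self.regional,
                "extra_names": self.extra_names,
                "lbr_names": self.lbr_names,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            regional=d["regional"],
            extra_names=d["extra_names"],
            lbr_names=d["lbr_names"],
        )


def default_schema() -> FeatureSchema:
    """The packaged 510-feature schema."""
    return FeatureSchema()


# -- I/O -----------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def read_table(path, dialect: str = "tsv") -> FeatureTable:
    """Read a wide feature table.

    The first column holds either ``subject_tN`` identifiers or plain subject
    identifiers accompanied by a dedicated timepoint column (named one of
    ``tp``/``timepoint``/``time_point``/``visit``).  All remaining columns
    must be numeric; missing cells are rejected, not imputed.
    """
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("table needs an identifier column and at least one feature")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)

    tp_col = next((c for c in df.columns[1:] if c.lower() in _TP_COLUMNS), None)
    if tp_col is not None:
        subjects = ids.tolist()
        try:
            timepoints = df[tp_col].astype(int).to_numpy()
        except (TypeError, ValueError) as e:
            raise ParseError(f"non-integer timepoint in column {tp_col}: {e}") from None
        feat_cols = [c for c in df.columns[1:] if c != tp_col]
    else:
        subjects, tps = [], []
        for i, ident in enumerate(ids):
            m = _TP_SUFFIX.match(ident)
            if not m:
                raise ParseError(
                    f"row {i + 1}: identifier {ident!r} lacks a _tN timepoint suffix "
                    "and no timepoint column is present"
                )
            subjects.append(m.group("subject"))
            tps.append(int(m.group("tp")))
        timepoints = np.array(tps, dtype=int)
        feat_cols = list(df.columns[1:])

    raw = df[feat_cols]
    missing = raw.isna()
    if missing.to_numpy().any():
        offenders = [
            f"row {i + 1}, column {c}"
            for i, c in zip(*np.nonzero(missing.to_numpy()))
            for c in [feat_cols[c]]
        ]
        raise ValidationError("missing values: " + "; ".join(offenders[:10]))
    values = np.empty(raw.shape, dtype=float)
    for j, c in enumerate(feat_cols):
        try:
            # numpy's parser is correctly rounded (pd.to_numeric's is not)
            values[:, j] = raw[c].to_numpy(dtype="U").astype(np.float64)
        except (TypeError, ValueError):
            bad = pd.to_numeric(raw[c], errors="coerce")
            i = int(np.nonzero(bad.isna().to_numpy())[0][0])
            raise ParseError(
                f"non-numeric cell at row {i + 1}, column {c}: {raw[c].iloc[i]!r}"
            ) from None

    return FeatureTable(
        subject_ids=subjects,
        timepoints=timepoints,
        feature_names=feat_cols,
        values=values,
    ).sorted_by_row()


def write_table(table: FeatureTable, path, dialect: str = "tsv") -> None:
    """Write a table readable back by :func:`read_table` (lossless round trip)."""
    sep = _sep(dialect)
    if table.n_features == 0:
        raise ValidationError("refusing to write a table with no feature columns")
    ids = [f"{s}_t{t}" for s, t in zip(table.subject_ids, table.timepoints)]
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "subject", ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def table_to_string(table: FeatureTable, dialect: str = "tsv") -> str:
    buf = io.StringIO()
    write_table(table, buf, dialect=dialect)
    return buf.getvalue()


def select_feature_set(
    table: FeatureTable, schema: FeatureSchema, set_name: str
) -> FeatureTable:
    """Column-subset ``table`` to one of the five canonical feature sets."""
    names = schema.feature_set(set_name)
    missing = [n for n in names if n not in table.feature_names]
    if missing:
        raise ValidationError(
            f"feature set {set_name} needs columns absent from the table: {missing[:10]}"
        )
    return table.select_columns(names)


# -- scaling -------------------------------------------------------------

@dataclass
class Scaler:
    """Per-feature z-scoring parameters (training mean, sample SD with n−1)."""

    feature_names: list[str]
    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            bad = [self.feature_names[j] for j in np.nonzero(self.scale <= 0)[0]]
            raise ValidationError(f"non-positive scale for features: {bad[:10]}")


def fit_scaler(table: FeatureTable) -> Scaler:
    if table.n_rows < 2:
        raise ValidationError("need at least 2 rows to fit a scaler")
    loc = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [table.feature_names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"constant feature columns cannot be scaled: {bad[:10]}")
    return Scaler(list(table.feature_names), loc, sd)


def apply_scaler(scaler: Scaler, table: FeatureTable) -> FeatureTable:
    if scaler.feature_names != table.feature_names:
        raise ValidationError("scaler and table feature names disagree")
    return replace(table, values=(table.values - scaler.location) / scaler.scale)


def invert_scaler(scaler: Scaler, table: FeatureTable) -> FeatureTable:
    if scaler.feature_names != table.feature_names:
        raise ValidationError("scaler and table feature names disagree")
    return replace(table, values=table.values * scaler.scale + scaler.location)
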