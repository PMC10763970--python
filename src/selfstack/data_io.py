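"""Reading, validation and numeric encoding of thyroid-style tabular cohorts.

The supported input dialect is the UCI ``thyroid0387`` format: comma-separated
rows, ``?`` for a missing value, and a final field of the form
``"<codes>|<record id>"`` holding the diagnosis (one or more single-letter
condition codes, or ``-`` for a healthy record) together with a record
identifier.  A plain CSV with a header naming every schema column is accepted
as well, so cohorts written by this package round-trip through the reader.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Column",
    "FeatureSchema",
    "Cohort",
    "DiagnosisCode",
    "EncodedMatrix",
    "SplitPair",
    "EncodingPolicy",
    "FeatureEncoder",
    "ParseError",
    "ValidationError",
    "DIAGNOSIS_DESCRIPTIONS",
    "THYROID_SCHEMA",
    "parse_diagnosis",
    "read_thyroid_table",
    "write_cohort",
    "encode_features",
    "split_train_test",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed against the schema."""


class ValidationError(ValueError):
    """A value violates the closed vocabulary of the schema."""


#: Single-letter thyroid diagnosis codes and the conditions they denote.
#: ``-`` marks the record of a healthy person ("no condition").
DIAGNOSIS_DESCRIPTIONS: dict[str, str] = {
    "A": "hyperthyroid",
    "B": "T3 toxic",
    "C": "toxic goitre",
    "D": "secondary toxic",
    "E": "hypothyroid",
    "F": "primary hypothyroid",
    "G": "compensated hypothyroid",
    "H": "secondary hypothyroid",
    "I": "increased binding protein",
    "J": "decreased binding protein",
    "K": "concurrent non-thyroidal illness",
    "L": "consistent with replacement therapy",
    "M": "under replaced",
    "N": "over replaced",
    "O": "antithyroid drugs",
    "P": "I131 treatment",
    "Q": "surgery",
    "R": "discordant assay results",
    "S": "elevated TBG",
    "T": "elevated thyroid hormones",
    "-": "no condition",
}


@dataclass(frozen=True)
class DiagnosisCode:
    """One diagnosis code from the closed set ``A``–``T`` plus ``-``."""

    code: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.code not in DIAGNOSIS_DESCRIPTIONS:
            raise ValidationError(f"unknown diagnosis code {self.code!r}")
        if not self.description:
            object.__setattr__(
                self, "description", DIAGNOSIS_DESCRIPTIONS[self.code]
            )


KINDS = ("binary", "continuous", "categorical", "identifier", "target")


@dataclass(frozen=True)
class Column:
    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered column layout of a cohort table.

    Exactly one column must have kind ``target``; ``identifier`` columns are
    carried through reading but never emitted as model features.
    """

    columns: tuple[Column, ...]
    missing_token: str = "?"

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique")
        targets = [c for c in self.columns if c.kind == "target"]
        if len(targets) != 1:
            raise ValueError("schema must have exactly one target column")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def target_index(self) -> int:
        return next(i for i, c in enumerate(self.columns) if c.kind == "target")

    @property
    def feature_columns(self) -> tuple[tuple[int, Column], ...]:
        return tuple(
            (i, c)
            for i, c in enumerate(self.columns)
            if c.kind not in ("identifier", "target")
        )


def _thyroid_columns() -> tuple[Column, ...]:
    binary = [
        "on_thyroxine",
        "query_on_thyroxine",
        "on_antithyroid_meds",
        "sick",
        "pregnant",
        "thyroid_surgery",
        "I131_treatment",
        "query_hypothyroid",
        "query_hyperthyroid",
        "lithium",
        "goitre",
        "tumor",
        "hypopituitary",
        "psych",
    ]
    cols: list[Column] = [Column("age", "continuous"), Column("sex", "binary")]
    cols += [Column(n, "binary") for n in binary]
    for hormone in ("TSH", "T3", "TT4", "T4U", "FTI", "TBG"):
        cols.append(Column(f"{hormone}_measured", "binary"))
        cols.append(Column(hormone, "continuous"))
    cols.append(Column("referral_source", "categorical"))
    cols.append(Column("target", "target"))
    cols.append(Column("patient_id", "identifier"))
    return tuple(cols)


#: 31-column layout of the thyroid0387 table: 29 clinical features (age, sex,
#: treatment/history flags, six serum measurements with their "was measured"
#: indicator flags, referral source), the diagnosis target and the patient id.
THYROID_SCHEMA = FeatureSchema(_thyroid_columns())


@dataclass
class Cohort:
    """Raw labelled records: values kept as text, missing token untouched."""

    schema: FeatureSchema
    records: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ncol = len(self.schema.columns)
        for i, rec in enumerate(self.records):
            if len(rec) != ncol:
                raise ValidationError(
                    f"record {i} has {len(rec)} values, expected {ncol}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    def labels(self) -> list[str]:
        """Normalized diagnosis strings (possibly compound, e.g. ``"AK"``)."""
        t = self.schema.target_index
        return [rec[t] for rec in self.records]

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(self.schema, [self.records[i] for i in indices])


def parse_diagnosis(raw: str) -> list[DiagnosisCode]:
    """Split a raw diagnosis field into its constituent codes.

    The thyroid0387 dialect stores ``"<codes>|<record id>"``; the suffix is
    stripped.  A compound string such as ``"AK"`` decomposes per character;
    ``"-"`` yields the single no-condition code.
    """
    codes = raw.split("|", 1)[0].strip()
    if not codes:
        raise ValidationError("empty diagnosis field")
    out = []
    for ch in codes:
        if ch not in DIAGNOSIS_DESCRIPTIONS:
            raise ValidationError(
                f"diagnosis code {ch!r} (in {codes!r}) is not a recognized code"
            )
        out.append(DiagnosisCode(ch))
    return out


def _normalize_row(
    fields: list[str], schema: FeatureSchema, lineno: int
) -> tuple[str, ...]:
    ncol = len(schema.columns)
    has_id = any(c.kind == "identifier" for c in schema.columns)
    if len(fields) == ncol - 1 and has_id and "|" in fields[-1]:
        # thyroid0387 dialect: diagnosis and record id share the last field
        codes, _, rid = fields[-1].partition("|")
        fields = fields[:-1] + [codes.strip(), rid.strip()]
    if len(fields) != ncol:
        raise ParseError(
            f"line {lineno}: expected {ncol} fields, found {len(fields)}"
        )
    t = schema.target_index
    try:
        codes = parse_diagnosis(fields[t])
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from exc
    fields = list(fields)
    fields[t] = "".join(c.code for c in codes)
    return tuple(v.strip() for v in fields)


_BINARY_TOKENS = {"t", "f", "F", "M"}


def infer_schema_from_header(
    names: Sequence[str], rows: Sequence[Sequence[str]], missing_token: str = "?"
) -> FeatureSchema:
    """Build a schema from a CSV header by inspecting column values.

    ``target`` names the target; ``patient_id``/``pid`` an identifier.  A
    feature column whose non-missing values are all t/f (or F/M) tokens is
    binary, all-numeric columns are continuous, anything else categorical.
    """
    cols = []
    for j, name in enumerate(names):
        if name == "target":
            cols.append(Column(name, "target"))
            continue
        if name in ("patient_id", "pid"):
            cols.append(Column(name, "identifier"))
            continue
        values = {r[j] for r in rows if len(r) > j} - {missing_token}
        if values and values <= _BINARY_TOKENS:
            kind = "binary"
        else:
            try:
                for v in values:
                    float(v)
                kind = "continuous"
            except ValueError:
                kind = "categorical"
        cols.append(Column(name, kind))
    return FeatureSchema(tuple(cols), missing_token=missing_token)


def read_thyroid_table(
    path: str | Path, schema: FeatureSchema = THYROID_SCHEMA
) -> Cohort:
    """Read a cohort table, validating every row against the schema.

    Accepts the raw thyroid0387 dialect (no header, ``codes|id`` final
    field) and plain CSV with a header row.  A header matching the given
    schema's names uses that schema; any other header naming a ``target``
    column has its schema inferred from the header and the data, so CSVs
    written by `write_cohort` for any schema round-trip.  Rows are never
    dropped silently: any malformed line raises with its number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        raw = [
            (lineno, fields)
            for lineno, fields in enumerate(csv.reader(fh), start=1)
            if fields and any(f.strip() for f in fields)
        ]
    if raw:
        first = tuple(f.strip() for f in raw[0][1])
        if first == schema.names:
            raw = raw[1:]
        elif "target" in first:
            schema = infer_schema_from_header(
                first, [r for _, r in raw[1:]], schema.missing_token
            )
            raw = raw[1:]
    records = [_normalize_row(fields, schema, lineno) for lineno, fields in raw]
    return Cohort(schema, records)


def write_cohort(
    cohort: Cohort, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a cohort as normalized CSV (with header) or thyroid0387 text."""
    path = Path(path)
    schema = cohort.schema
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "csv":
            writer.writerow(schema.names)
            writer.writerows(cohort.records)
        elif dialect == "thyroid0387":
            t = schema.target_index
            ident = next(
                i for i, c in enumerate(schema.columns) if c.kind == "identifier"
            )
            for rec in cohort.records:
                fields = [v for i, v in enumerate(rec) if i not in (t, ident)]
                fields.append(f"{rec[t]}|{rec[ident]}")
                writer.writerow(fields)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class EncodedMatrix:
    """Fully numeric feature matrix with integer class labels."""

    X: np.ndarray
    y: np.ndarray
    class_map: dict[str, int]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X and y shapes are inconsistent")
        if np.isnan(self.X).any():
            raise ValueError("encoded matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return len(self.class_map)

    def subset(self, indices: np.ndarray) -> "EncodedMatrix":
        return EncodedMatrix(
            self.X[indices], self.y[indices], self.class_map, self.feature_names
        )

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: Sequence[int]) -> "EncodedMatrix":
        """Wrap plain arrays of already-encoded features and integer labels.

        The class map spans 0..max(y) so that a subset missing some class
        (e.g. a cross-validation fold) keeps the full index space.
        """
        y = np.asarray(y, dtype=int)
        if y.size and y.min() < 0:
            raise ValueError("labels must be non-negative integers")
        n_classes = int(y.max()) + 1 if y.size else 0
        class_map = {str(c): c for c in range(n_classes)}
        names = [f"x{j}" for j in range(np.asarray(X).shape[1])]
        return cls(np.asarray(X, dtype=float), y, class_map, names)


@dataclass(frozen=True)
class EncodingPolicy:
    """How raw text columns become numbers.

    Binary tokens map via `binary_map` (t/f flags and F/M sex); categorical
    columns are integer-coded in first-appearance order; missing continuous
    values take the column median, missing binary/categorical the column mode;
    constant ``*_measured`` indicator flags are dropped (they carry no signal
    and exist only to mirror the serum columns' missingness).
    """

    binary_map: tuple[tuple[str, int], ...] = (("t", 1), ("f", 0), ("F", 1), ("M", 0))
    drop_columns: tuple[str, ...] = ()
    drop_constant_indicators: bool = True


class FeatureEncoder:
    """Fit a numeric encoding on one cohort and apply it to others.

    Fitting learns, per column, the imputation statistic (median or mode),
    the categorical code book, and which columns are dropped; `transform`
    re-applies exactly those choices so train and test matrices are aligned.
    Records whose diagnosis decomposes to more than one code are excluded
    (the task is single-label multi-class) and counted in `n_multilabel`.
    """

    def __init__(self, policy: EncodingPolicy | None = None) -> None:
        self.policy = policy or EncodingPolicy()
        self.fitted_ = False

    def fit(self, cohort: Cohort) -> "FeatureEncoder":
        policy = self.policy
        schema = cohort.schema
        missing = schema.missing_token
        keep = self._single_label_indices(cohort)
        binary_map = dict(policy.binary_map)

        self.columns_: list[Column] = []
        self.fill_: dict[str, float] = {}
        self.codebooks_: dict[str, dict[str, int]] = {}
        dropped: list[str] = []
        for ci, col in schema.feature_columns:
            if col.name in policy.drop_columns:
                dropped.append(col.name)
                continue
            values = [cohort.records[i][ci] for i in keep]
            present = [v for v in values if v != missing]
            if not present:
                raise ValidationError(
                    f"column {col.name!r} is entirely missing; nothing to impute"
                )
            if col.kind == "binary":
                encoded = [self._binary(v, col.name, binary_map) for v in present]
                if (
                    policy.drop_constant_indicators
                    and col.name.endswith("_measured")
                    and len(set(encoded)) == 1
                ):
                    dropped.append(col.name)
                    continue
                # mode, ties to the smaller code for determinism
                ones = sum(encoded)
                self.fill_[col.name] = float(ones * 2 > len(encoded))
            elif col.kind == "continuous":
                vals = [self._float(v, col.name) for v in present]
                self.fill_[col.name] = float(np.median(vals))
            else:  # categorical: first-appearance integer coding
                book: dict[str, int] = {}
                for v in present:
                    book.setdefault(v, len(book))
                self.codebooks_[col.name] = book
                counts = {v: present.count(v) for v in book}
                self.fill_[col.name] = float(
                    book[max(book, key=lambda v: (counts[v], -book[v]))]
                )
            self.columns_.append(col)
        if dropped:
            logger.info("dropped columns: %s", ", ".join(dropped))
        self.class_map_ = {
            code: idx for idx, code in enumerate(sorted({
                cohort.records[i][schema.target_index] for i in keep
            }))
        }
        self.fitted_ = True
        return self

    def transform(self, cohort: Cohort) -> EncodedMatrix:
        if not self.fitted_:
            raise RuntimeError("encoder is not fitted")
        schema = cohort.schema
        missing = schema.missing_token
        keep = self._single_label_indices(cohort)
        binary_map = dict(self.policy.binary_map)
        col_index = {c.name: i for i, c in enumerate(schema.columns)}

        X = np.empty((len(keep), len(self.columns_)), dtype=float)
        for j, col in enumerate(self.columns_):
            ci = col_index[col.name]
            for r, i in enumerate(keep):
                v = cohort.records[i][ci]
                if v == missing:
                    X[r, j] = self.fill_[col.name]
                elif col.kind == "binary":
                    X[r, j] = self._binary(v, col.name, binary_map)
                elif col.kind == "continuous":
                    X[r, j] = self._float(v, col.name)
                else:
                    book = self.codebooks_[col.name]
                    X[r, j] = book.get(v, self.fill_[col.name])
        t = schema.target_index
        y = np.empty(len(keep), dtype=int)
        for r, i in enumerate(keep):
            label = cohort.records[i][t]
            if label not in self.class_map_:
                raise ValidationError(f"label {label!r} was not seen at fit time")
            y[r] = self.class_map_[label]
        return EncodedMatrix(
            X, y, dict(self.class_map_), [c.name for c in self.columns_]
        )

    def fit_transform(self, cohort: Cohort) -> EncodedMatrix:
        return self.fit(cohort).transform(cohort)

    def _single_label_indices(self, cohort: Cohort) -> list[int]:
        t = cohort.schema.target_index
        keep, skipped = [], 0
        for i, rec in enumerate(cohort.records):
            if len(parse_diagnosis(rec[t])) == 1:
                keep.append(i)
            else:
                skipped += 1
        self.n_multilabel = skipped
        if skipped:
            logger.info("excluded %d multi-label records", skipped)
        return keep

    @staticmethod
    def _binary(v: str, name: str, binary_map: dict[str, int]) -> int:
        if v not in binary_map:
            raise ValidationError(
                f"unknown token {v!r} in binary column {name!r}"
            )
        return binary_map[v]

    @staticmethod
    def _float(v: str, name: str) -> float:
        try:
            return float(v)
        except ValueError as exc:
            raise ValidationError(
                f"non-numeric value {v!r} in continuous column {name!r}"
            ) from exc


def encode_features(
    cohort: Cohort, policy: EncodingPolicy | None = None
) -> EncodedMatrix:
    """Encode a cohort with statistics computed on that same cohort."""
    return FeatureEncoder(policy).fit_transform(cohort)


@dataclass
class SplitPair:
    train: EncodedMatrix
    test: EncodedMatrix
    ratio: float
    seed: int
    shuffled: bool
    train_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    test_indices: np.ndarray = field(default=None)  # type: ignore[assignment]


def split_train_test(
    data: EncodedMatrix,
    ratio: float = 0.2,
    seed: int = 0,
    shuffle: bool = True,
) -> SplitPair:
    """Hold out ``round(ratio * n)`` rows as a test set.

    With ``shuffle`` the rows are permuted by a generator seeded with ``seed``
    before cutting; without it the tail of the file order becomes the test
    set.  The split is not stratified: per-class test counts vary with the
    seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = data.n
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_test = int(np.floor(ratio * n + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"ratio {ratio} yields an empty partition for n={n}"
        )
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)
    test_idx = order[n - n_test:]
    train_idx = order[: n - n_test]
    return SplitPair(
        train=data.subset(train_idx),
        test=data.subset(test_idx),
        ratio=ratio,
        seed=seed,
        shuffled=shuffle,
        train_indices=train_idx,
        test_indices=test_idx,
    )
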