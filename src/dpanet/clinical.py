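"""Clinical variable dichotomization, chi-square screening and binary encoding.

The clinical arm of the model works on routinely collected preoperative
variables (age, tumor size, portal vein invasion, liver-function labs, BCLC
stage, ...).  Each variable is dichotomized at an established clinical cutoff
(or kept categorical), screened against the early-recurrence outcome with a
Pearson chi-square test of independence, and the significant variables are
packed into a fixed 9-element binary vector that feeds the fusion network:

    [c1..c6] = age>=60, size>=5cm, portal vein invasion, NLR>=2.8,
               TB>=20.5, AFP>=9
    [c7,c8,c9] = one-hot-ish BCLC code: 0->(0,0,0), A->(0,0,1),
                 B->(0,1,0), C->(1,0,0)

The chi-square test is Pearson's, WITHOUT Yates continuity correction, with
df = r - 1 for an r x 2 table; this is the variant that reproduces every
reference contingency-table p-value, including tables with small or zero
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableDefinition",
    "ClinicalRecord",
    "ContingencyTable",
    "ChiSquareResult",
    "CLINICAL_VARIABLES",
    "VECTOR_ORDER",
    "BCLC_CODE",
    "TABLE1_COUNTS",
    "dichotomize_record",
    "build_contingency_table",
    "pearson_chi_square",
    "select_significant_variables",
    "encode_clinical_vector",
    "decode_clinical_vector",
    "chi_square_report",
    "encode_cohort",
    "cohort_report",
    "read_clinical_csv",
    "records_from_reference_counts",
]

LABELS = {"NER": 0, "ER": 1}


class ClinicalDataError(ValueError):
    """Schema or value problem in clinical input."""


@dataclass(frozen=True)
class VariableDefinition:
    name: str
    kind: str  # "binary-cutoff" | "categorical"
    cutoff: float | None = None
    unit: str = ""
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "binary-cutoff" and self.cutoff is None:
            raise ValueError(f"{self.name}: binary-cutoff variable needs a cutoff")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"{self.name}: categorical variable needs categories")

    @property
    def n_categories(self) -> int:
        return 2 if self.kind == "binary-cutoff" else len(self.categories)

    def category_labels(self) -> list[str]:
        if self.kind == "binary-cutoff":
            return [f"<{self.cutoff:g}", f">={self.cutoff:g}"]
        return list(self.categories)


# Canonical variable set and CSV schema (column order).
CLINICAL_VARIABLES: tuple[VariableDefinition, ...] = (
    VariableDefinition("sex", "categorical", categories=("female", "male")),
    VariableDefinition("age", "binary-cutoff", cutoff=60, unit="years"),
    VariableDefinition("tumor_size_mm", "binary-cutoff", cutoff=50, unit="mm"),
    VariableDefinition("tumor_number", "binary-cutoff", cutoff=2, unit="count"),
    VariableDefinition("portal_vein_invasion", "categorical", categories=("no", "yes")),
    VariableDefinition("cirrhosis", "categorical", categories=("no", "yes")),
    VariableDefinition("hbv", "categorical", categories=("no", "yes")),
    VariableDefinition("nlr", "binary-cutoff", cutoff=2.8, unit="ratio"),
    VariableDefinition("alt", "binary-cutoff", cutoff=40, unit="U/L"),
    VariableDefinition("ast", "binary-cutoff", cutoff=50, unit="U/L"),
    VariableDefinition("akp", "binary-cutoff", cutoff=125, unit="U/L"),
    VariableDefinition("ggt", "binary-cutoff", cutoff=45, unit="U/L"),
    VariableDefinition("alb", "binary-cutoff", cutoff=40, unit="g/L"),
    VariableDefinition("tb", "binary-cutoff", cutoff=20.5, unit="umol/L"),
    VariableDefinition("afp", "binary-cutoff", cutoff=9, unit="ug/L"),
    VariableDefinition("cp_level", "categorical", categories=("A", "B")),
    VariableDefinition("bclc", "categorical", categories=("0", "A", "B", "C")),
)

_DEFS = {d.name: d for d in CLINICAL_VARIABLES}

# Order of the seven encoded variables (c1..c9); BCLC expands to three bits.
VECTOR_ORDER: tuple[str, ...] = (
    "age", "tumor_size_mm", "portal_vein_invasion", "nlr", "tb", "afp", "bclc",
)

# Canonical reporting order: encoded variables first, then the rest in schema order.
CANONICAL_ORDER: tuple[str, ...] = VECTOR_ORDER + tuple(
    d.name for d in CLINICAL_VARIABLES if d.name not in VECTOR_ORDER
)

BCLC_CODE = {"0": (0, 0, 0), "A": (0, 0, 1), "B": (0, 1, 0), "C": (1, 0, 0)}
_BCLC_DECODE = {v: k for k, v in BCLC_CODE.items()}

# Reference class-conditional contingency counts (rows = ordered categories,
# columns = [NER, ER]) for a 167-patient cohort with 65 early recurrences.
# These drive both the statistical fixtures and the synthetic cohort generator.
TABLE1_COUNTS: dict[str, list[list[int]]] = {
    "sex": [[17, 10], [85, 55]],
    "age": [[55, 47], [47, 18]],
    "tumor_size_mm": [[74, 28], [28, 37]],
    "tumor_number": [[97, 58], [5, 7]],
    "portal_vein_invasion": [[95, 48], [7, 17]],
    "cirrhosis": [[31, 21], [71, 44]],
    "hbv": [[25, 8], [77, 57]],
    "nlr": [[71, 35], [31, 30]],
    "alt": [[66, 38], [36, 27]],
    "ast": [[77, 46], [25, 19]],
    "akp": [[85, 46], [17, 19]],
    "ggt": [[46, 20], [56, 45]],
    "alb": [[100, 65], [2, 0]],  # row 0 is ">=40", the clinically normal side
    "tb": [[81, 41], [21, 24]],
    "afp": [[39, 11], [63, 54]],
    "cp_level": [[89, 51], [13, 14]],
    "bclc": [[17, 5], [78, 39], [1, 3], [6, 18]],
}
# The reference table lists ALB with the ">=40" row first; internally category
# index 0 is always the "< cutoff" side, so flip that variable's rows when
# comparing against the reference.
_REVERSED_ROWS = {"alb"}


@dataclass
class ClinicalRecord:
    patient_id: str
    raw: dict[str, object]
    label: int  # NER=0, ER=1
    dichotomized: dict[str, int] = field(default_factory=dict)


@dataclass
class ContingencyTable:
    variable: str
    counts: np.ndarray  # (r, 2) ints, columns = [NER, ER]
    row_labels: list[str]
    col_labels: tuple[str, str] = ("NER", "ER")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


# -- operations ------------------------------------------------------------

def dichotomize_record(
    record: ClinicalRecord,
    defs: tuple[VariableDefinition, ...] = CLINICAL_VARIABLES,
) -> ClinicalRecord:
    """Map each raw value to its category index (cutoff rule: value < cutoff -> 0)."""
    out: dict[str, int] = {}
    for d in defs:
        if d.name not in record.raw:
            raise ClinicalDataError(
                f"patient {record.patient_id}: missing variable '{d.name}'"
            )
        v = record.raw[d.name]
        if d.kind == "binary-cutoff":
            try:
                x = float(v)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ClinicalDataError(
                    f"patient {record.patient_id}: non-numeric value {v!r} for '{d.name}'"
                ) from None
            if not np.isfinite(x):
                raise ClinicalDataError(
                    f"patient {record.patient_id}: non-finite value for '{d.name}'"
                )
            out[d.name] = 0 if x < d.cutoff else 1
        else:
            label = str(v)
            if label not in d.categories:
                raise ClinicalDataError(
                    f"patient {record.patient_id}: unknown category {label!r} for "
                    f"'{d.name}' (expected one of {list(d.categories)})"
                )
            out[d.name] = d.categories.index(label)
    return replace(record, dichotomized=out)


def build_contingency_table(cohort: list[ClinicalRecord], variable: str) -> ContingencyTable:
    if not cohort:
        raise ClinicalDataError("empty cohort")
    if variable not in _DEFS:
        raise ClinicalDataError(f"unknown variable '{variable}'")
    d = _DEFS[variable]
    counts = np.zeros((d.n_categories, 2), dtype=int)
    for rec in cohort:
        if variable not in rec.dichotomized:
            raise ClinicalDataError(
                f"patient {rec.patient_id}: record not dichotomized for '{variable}'"
            )
        counts[rec.dichotomized[variable], rec.label] += 1
    return ContingencyTable(variable, counts, d.category_labels())


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square of independence on an r x 2 table, no continuity correction."""
    obs = np.asarray(table.counts, dtype=float)
    if obs.shape[0] < 2:
        raise ClinicalDataError(
            f"variable '{table.variable}': degenerate table with a single category"
        )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ClinicalDataError(
            f"variable '{table.variable}': zero row/column marginal in contingency table"
        )
    exp = np.outer(row, col) / obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.shape[0] - 1
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p)


def select_significant_variables(
    results: dict[str, ChiSquareResult], alpha: float = 0.05
) -> list[str]:
    """Variables with p < alpha, returned in the fixed canonical (c1..c9) order."""
    if not results:
        raise ClinicalDataError("no chi-square results to select from")
    if not 0.0 < alpha <= 1.0:
        raise ClinicalDataError(f"alpha must be in (0, 1], got {alpha}")
    order = [v for v in CANONICAL_ORDER if v in results]
    order += [v for v in results if v not in CANONICAL_ORDER]
    return [v for v in order if results[v].p_value < alpha]


def encode_clinical_vector(record: ClinicalRecord) -> np.ndarray:
    """9-element binary vector [c1..c9] from a dichotomized record."""
    for v in VECTOR_ORDER:
        if v not in record.dichotomized:
            raise ClinicalDataError(
                f"patient {record.patient_id}: missing selected variable '{v}'"
            )
    d = record.dichotomized
    bits = [d[v] for v in VECTOR_ORDER[:-1]]
    bclc_label = _DEFS["bclc"].categories[d["bclc"]]
    bits.extend(BCLC_CODE[bclc_label])
    return np.array(bits, dtype=np.int64)


def decode_clinical_vector(vector: np.ndarray) -> dict[str, int]:
    """Inverse of :func:`encode_clinical_vector` (category indices)."""
    vector = np.asarray(vector)
    if vector.shape != (9,) or not np.isin(vector, (0, 1)).all():
        raise ClinicalDataError("clinical vector must be 9 binary elements")
    code = tuple(int(b) for b in vector[6:])
    if code not in _BCLC_DECODE:
        raise ClinicalDataError(f"illegal BCLC code {code}")
    out = {v: int(vector[i]) for i, v in enumerate(VECTOR_ORDER[:-1])}
    out["bclc"] = _DEFS["bclc"].categories.index(_BCLC_DECODE[code])
    return out


# -- cohort-level helpers --------------------------------------------------

def chi_square_report(cohort: list[ClinicalRecord], alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable chi-square screening as a tidy frame (variable, statistic, df, p, selected).

    Variables whose table is degenerate in this cohort (an empty category row
    or class column, possible in small samples) get NaN statistics and are
    never selected, rather than aborting the whole report.
    """
    results: dict[str, ChiSquareResult] = {}
    degenerate: list[str] = []
    for name in _DEFS:
        try:
            results[name] = pearson_chi_square(build_contingency_table(cohort, name))
        except ClinicalDataError:
            degenerate.append(name)
    selected = set(select_significant_variables(results, alpha)) if results else set()
    rows = []
    for v in CANONICAL_ORDER:
        if v in results:
            rows.append({
                "variable": v,
                "statistic": results[v].statistic,
                "df": results[v].df,
                "p_value": results[v].p_value,
                "selected": v in selected,
            })
        else:
            rows.append({
                "variable": v, "statistic": np.nan, "df": 0,
                "p_value": np.nan, "selected": False,
            })
    return pd.DataFrame(rows)


def encode_cohort(cohort: list[ClinicalRecord]) -> pd.DataFrame:
    """Encoded 9-bit vectors, one row per patient (columns c1..c9)."""
    data = {
        rec.patient_id: encode_clinical_vector(rec) for rec in cohort
    }
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=[f"c{i}" for i in range(1, 10)]
    )
    df.index.name = "patient_id"
    return df


def cohort_report(cohort: list[ClinicalRecord]) -> dict:
    """Cohort composition summary (class sizes and ER prevalence in percent)."""
    n = len(cohort)
    if n == 0:
        raise ClinicalDataError("empty cohort")
    n_er = sum(r.label for r in cohort)
    return {
        "n_patients": n,
        "n_er": n_er,
        "n_ner": n - n_er,
        "er_prevalence_pct": round(100.0 * n_er / n, 1),
    }


# -- I/O -------------------------------------------------------------------

CSV_COLUMNS = ["patient_id", "label"] + [d.name for d in CLINICAL_VARIABLES]


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Read and validate the clinical CSV; returns dichotomized records."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ClinicalDataError(f"clinical CSV missing columns: {missing_cols}")
    if df[CSV_COLUMNS].isna().any().any():
        bad = df[CSV_COLUMNS].isna().any()
        raise ClinicalDataError(
            f"clinical CSV has missing values in columns: {list(bad[bad].index)}"
        )
    records = []
    for _, row in df.iterrows():
        label = str(row["label"])
        if label not in LABELS:
            raise ClinicalDataError(
                f"patient {row['patient_id']}: label must be ER or NER, got {label!r}"
            )
        raw = {d.name: row[d.name] for d in CLINICAL_VARIABLES}
        rec = ClinicalRecord(str(row["patient_id"]), raw, LABELS[label])
        records.append(dichotomize_record(rec))
    return records


def records_from_reference_counts(seed: int = 0) -> list[ClinicalRecord]:
    """Reconstruct a 167-patient cohort whose per-variable class-conditional
    category counts equal the reference contingency tables exactly.

    Within each class, category assignments are shuffled independently per
    variable, so joint cross-variable structure is arbitrary — the marginal
    r x 2 tables (all that the chi-square screening sees) are exact.
    """
    rng = np.random.default_rng(seed)
    class_sizes = {0: 102, 1: 65}
    per_class_assign: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for name, rows in TABLE1_COUNTS.items():
        arr = np.asarray(rows)
        if name in _REVERSED_ROWS:
            arr = arr[::-1]
        for cls in (0, 1):
            cats = np.repeat(np.arange(arr.shape[0]), arr[:, cls])
            assert cats.size == class_sizes[cls]
            rng.shuffle(cats)
            per_class_assign[cls][name] = cats
    records = []
    idx = 0
    for cls in (0, 1):
        for i in range(class_sizes[cls]):
            raw: dict[str, object] = {}
            for d in CLINICAL_VARIABLES:
                cat = int(per_class_assign[cls][d.name][i])
                if d.kind == "categorical":
                    raw[d.name] = d.categories[cat]
                else:
                    # any raw value on the right side of the cutoff
                    raw[d.name] = d.cutoff - 1.0 if cat == 0 else d.cutoff + 1.0
            records.append(
                dichotomize_record(
                    ClinicalRecord(f"P{idx:03d}", raw, cls)
                )
            )
            idx += 1
    return records
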