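"""Data model for multi-cancer, multi-dataset expression and clinical data.

A study is a :class:`CohortCollection`: per cancer type, several independent
cohorts, each an :class:`ExpressionDataset` (log-scale expression, features x
samples, with probe-level annotations) paired with a :class:`ClinicalTable`
whose columns follow a closed controlled vocabulary (sample type, receptor
status, survival endpoints, subtype labels).  Unknown clinical codes are
coerced to missing rather than rejected, mirroring the tolerant curation
style of large multi-study compendia.

On-disk formats are plain text: expression and annotation as TSV, clinical
as CSV, "NA" for missing throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Controlled vocabulary

CLINICAL_COLUMNS = [
    "sample_id", "dataset_id", "sample_type", "age_at_diagnosis", "grade",
    "stage", "er_status", "pgr_status", "her2_status", "subtype",
    "days_to_death", "vital_status", "days_to_recurrence",
    "recurrence_status", "treatment",
]

VOCABULARY: dict[str, set[str]] = {
    "sample_type": {"tumor", "healthy"},
    "er_status": {"positive", "negative"},
    "pgr_status": {"positive", "negative"},
    "her2_status": {"positive", "negative"},
    "vital_status": {"deceased", "living"},
    "recurrence_status": {"recurred", "norecurrence"},
    "treatment": {"yes", "no"},
}

#: factors applied to time columns at read time to express them in days
TIME_UNIT_FACTORS = {"days": 1.0, "months": 30.4375, "years": 365.25}


class FormatError(ValueError):
    """A file does not conform to the declared on-disk dialect."""


class ReconciliationError(ValueError):
    """Expression and clinical tables disagree on the sample set."""


class SurvivalEndpoint(NamedTuple):
    """One sample's follow-up: time in days (> 0) and event indicator (0/1)."""

    time: float
    event: int


@dataclass
class ExpressionDataset:
    """One cohort's feature x sample log-expression matrix with annotations.

    ``values`` is a DataFrame indexed by probe/feature id with sample-id
    columns; missing measurements are NaN.  ``features`` is indexed by
    probe_id with columns ``gene_symbol`` and ``entrez_id`` (either may be
    missing; a feature is gene-mappable when at least one is present).
    """

    dataset_id: str
    cancer_type: str
    values: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise FormatError(f"{self.dataset_id}: duplicate feature ids")
        if not self.values.columns.is_unique:
            raise FormatError(f"{self.dataset_id}: duplicate sample ids")
        if not self.values.index.equals(self.features.index):
            raise FormatError(
                f"{self.dataset_id}: expression rows and annotation rows disagree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return ExpressionDataset(self.dataset_id, self.cancer_type,
                                 self.values[keep], self.features.copy())


@dataclass
class ClinicalTable:
    """Standardized per-sample clinical records for one dataset.

    ``df`` is indexed by sample_id and carries the controlled-vocabulary
    columns; coded values outside the vocabulary have already been coerced
    to missing at construction time.
    """

    dataset_id: str
    df: pd.DataFrame
    n_coerced: int = 0

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            raise FormatError(f"{self.dataset_id}: duplicate clinical sample ids")
        has_dtd = self.df["days_to_death"].notna()
        missing_vs = self.df["vital_status"].isna()
        if (has_dtd & missing_vs).any():
            raise FormatError(
                f"{self.dataset_id}: days_to_death present without vital_status")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return ClinicalTable(self.dataset_id, self.df.loc[keep])


@dataclass
class CohortCollection:
    """All cohorts of a study, grouped by cancer type."""

    datasets: list[tuple[ExpressionDataset, ClinicalTable]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e, _ in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_ids must be unique")
        for expr, clin in self.datasets:
            if set(expr.sample_ids) != set(clin.sample_ids):
                raise ReconciliationError(
                    f"{expr.dataset_id}: expression/clinical sample mismatch")

    @property
    def grouping(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for expr, _ in self.datasets:
            out.setdefault(expr.cancer_type, []).append(expr.dataset_id)
        return out

    @property
    def cancer_types(self) -> list[str]:
        return list(self.grouping)

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def get(self, dataset_id: str) -> tuple[ExpressionDataset, ClinicalTable]:
        for pair in self.datasets:
            if pair[0].dataset_id == dataset_id:
                return pair
        raise KeyError(dataset_id)

    def by_cancer_type(self, cancer_type: str) -> "CohortCollection":
        return CohortCollection(
            [p for p in self.datasets if p[0].cancer_type == cancer_type])

    def subset(self, dataset_ids: Iterable[str]) -> "CohortCollection":
        wanted = set(dataset_ids)
        return CohortCollection(
            [p for p in self.datasets if p[0].dataset_id in wanted])


# ---------------------------------------------------------------------------
# Vocabulary coercion

def coerce_vocabulary(df: pd.DataFrame, dataset_id: str = "?") -> tuple[pd.DataFrame, int]:
    """Replace out-of-vocabulary codes with missing; return the coercion count."""
    df = df.copy()
    n_coerced = 0
    for col, allowed in VOCABULARY.items():
        if col not in df:
            continue
        vals = df[col]
        bad = vals.notna() & ~vals.isin(allowed)
        if bad.any():
            n_coerced += int(bad.sum())
            logger.warning("%s: %d value(s) in %r outside the controlled "
                           "vocabulary coerced to missing", dataset_id,
                           int(bad.sum()), col)
            df.loc[bad, col] = np.nan
    return df, n_coerced


# ---------------------------------------------------------------------------
# Readers / writers

def read_dataset(expression_path: str | Path,
                 annotation_path: str | Path,
                 clinical_path: str | Path,
                 cancer_type: str = "unknown",
                 dataset_id: str | None = None,
                 time_unit: Literal["days", "months", "years"] = "days",
                 ) -> tuple[ExpressionDataset, ClinicalTable]:
    """Read one cohort from disk and validate it.

    ``time_unit`` converts the survival time columns to days at read time.
    Raises :class:`FormatError` for malformed headers and
    :class:`ReconciliationError` when expression and clinical sample ids
    do not match (the message lists the orphans).
    """
    expression_path = Path(expression_path)
    dataset_id = dataset_id or expression_path.stem

    expr = pd.read_csv(expression_path, sep="\t", na_values=["NA"])
    if expr.columns[0] != "feature_id":
        raise FormatError(
            f"{expression_path}: first expression column must be 'feature_id', "
            f"got {expr.columns[0]!r}")
    expr = expr.set_index("feature_id")
    expr = expr.astype(float)

    ann = pd.read_csv(annotation_path, sep="\t", na_values=["NA"],
                      dtype={"probe_id": str, "gene_symbol": str})
    for col in ("probe_id", "gene_symbol", "entrez_id"):
        if col not in ann.columns:
            raise FormatError(f"{annotation_path}: missing column {col!r}")
    ann = ann.set_index("probe_id")[["gene_symbol", "entrez_id"]]
    ann = ann.reindex(expr.index)

    clin = pd.read_csv(clinical_path, na_values=["NA"], dtype={"sample_id": str})
    for col in CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise FormatError(f"{clinical_path}: missing column {col!r}")
    clin = clin.set_index("sample_id")
    factor = TIME_UNIT_FACTORS[time_unit]
    if factor != 1.0:
        for col in ("days_to_death", "days_to_recurrence"):
            clin[col] = clin[col] * factor
    clin, n_coerced = coerce_vocabulary(clin, dataset_id)

    expr_ids, clin_ids = set(expr.columns), set(clin.index)
    if expr_ids != clin_ids:
        raise ReconciliationError(
            f"{dataset_id}: sample mismatch; expression-only="
            f"{sorted(expr_ids - clin_ids)}, clinical-only="
            f"{sorted(clin_ids - expr_ids)}")

    ds = ExpressionDataset(dataset_id, cancer_type, expr, ann)
    ct = ClinicalTable(dataset_id, clin.loc[list(expr.columns)], n_coerced)
    return ds, ct


def write_dataset(dataset: ExpressionDataset, clinical: ClinicalTable,
                  expression_path: str | Path, annotation_path: str | Path,
                  clinical_path: str | Path) -> None:
    """Write a cohort in the TSV/CSV on-disk dialect (inverse of read_dataset).

    Matrix values are written with 17 significant digits so that a
    write-then-read round trip reproduces them exactly.
    """
    out = dataset.values.copy()
    out.index.name = "feature_id"
    out.to_csv(expression_path, sep="\t", na_rep="NA", float_format="%.17g")
    ann = dataset.features.copy()
    ann.index.name = "probe_id"
    ann.to_csv(annotation_path, sep="\t", na_rep="NA")
    clin = clinical.df.copy()
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Survival endpoints

ENDPOINTS = {
    "overall_survival": ("days_to_death", "vital_status", "deceased"),
    "recurrence_free": ("days_to_recurrence", "recurrence_status", "recurred"),
}


def extract_endpoint(clinical: ClinicalTable,
                     endpoint: str = "overall_survival",
                     ) -> dict[str, SurvivalEndpoint]:
    """Map sample_id -> (time, event) for one survival endpoint.

    Only samples with both a positive time and a status code are returned;
    for overall survival the event fires iff vital_status is "deceased".
    """
    try:
        time_col, status_col, event_code = ENDPOINTS[endpoint]
    except KeyError:
        raise ValueError(f"unsupported endpoint {endpoint!r}") from None
    df = clinical.df
    ok = df[time_col].notna() & df[status_col].notna() & (df[time_col] > 0)
    sub = df.loc[ok]
    return {
        sid: SurvivalEndpoint(float(t), int(s == event_code))
        for sid, t, s in zip(sub.index, sub[time_col], sub[status_col])
    }


def save_collection(collection: CohortCollection, directory: str | Path) -> None:
    """Write every cohort of a collection under one directory.

    Produces ``<id>.expr.tsv``, ``<id>.ann.tsv`` and ``<id>.clin.csv`` per
    cohort plus an ``index.json`` recording ids and cancer types.
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for expr, clin in collection:
        base = directory / expr.dataset_id
        write_dataset(expr, clin, f"{base}.expr.tsv", f"{base}.ann.tsv",
                      f"{base}.clin.csv")
        index.append({"dataset_id": expr.dataset_id,
                      "cancer_type": expr.cancer_type})
    (directory / "index.json").write_text(json.dumps({"datasets": index}, indent=1))


def load_collection(directory: str | Path) -> CohortCollection:
    """Read a collection written by :func:`save_collection`."""
    import json

    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    pairs = []
    for entry in index["datasets"]:
        base = directory / entry["dataset_id"]
        pairs.append(read_dataset(f"{base}.expr.tsv", f"{base}.ann.tsv",
                                  f"{base}.clin.csv",
                                  cancer_type=entry["cancer_type"],
                                  dataset_id=entry["dataset_id"]))
    return CohortCollection(pairs)


def endpoint_arrays(endpoints: dict[str, SurvivalEndpoint],
                    sample_ids: Iterable[str] | None = None,
                    ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Align an endpoint map to an ordered sample list -> (ids, time, event)."""
    if sample_ids is None:
        ids = list(endpoints)
    else:
        ids = [s for s in sample_ids if s in endpoints]
    time = np.array([endpoints[s].time for s in ids], dtype=float)
    event = np.array([endpoints[s].event for s in ids], dtype=int)
    return ids, time, event
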