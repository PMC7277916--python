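"""Sample sheets, count matrices and cohort summaries.

A *cohort* is an ordered collection of tumor specimens, each carrying the
clinical annotation and ordinal immunohistochemistry (IHC) scores needed by
the concordance analysis: HER2 on a 0-3 scale and ER/PR on 0-8 scales for
breast cancer (BC), and a three-level PD-L1 staining category for lung
cancer (LC), plus per-sample sequencing coverage (uniquely mapped reads)
and RNA integrity number (RIN).

Sample sheets are plain TSV; coverage is carried in millions of mapped
reads on disk (the convention of clinical annotation tables) and stored
internally as an absolute read count, which the downsampling analysis
needs. Count matrices are gene-by-sample TSVs of raw non-negative integer
counts keyed by HGNC gene symbols.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "CountMatrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "summarize_cohort",
    "read_count_matrix",
    "write_count_matrix",
    "load_breast_cohort",
    "load_lung_cohort",
]


class CohortValidationError(ValueError):
    """Raised when a sample sheet or count matrix violates its contract."""


#: categories for the PD-L1 tumor-cell staining fraction: 0 = "<1% cells",
#: 1 = "1%-50%", 2 = ">50%".
PDL1_CATEGORIES = {0: "<1%", 1: "1%-50%", 2: ">50%"}

_PDL1_ALIASES = {
    "0": 0,
    "<1%": 0,
    "0%": 0,
    "1%-50%": 1,
    "1%–50%": 1,  # en dash, as printed in annotation tables
    "1-50%": 1,
    ">50%": 2,
    "50%-100%": 2,
    "50%–100%": 2,
}

# site labels are matched case-insensitively; spellings that denote the same
# site category are folded together ("relapse in the scar" is a scar
# metastasis).
_SITE_ALIASES = {
    "relapse in the scar": "scar metastasis",
}


def _normalize_site(raw: str) -> str:
    s = " ".join(raw.strip().lower().split())
    return _SITE_ALIASES.get(s, s)


@dataclass
class SampleRecord:
    """Clinical/QC annotation and IHC scores for one tumor specimen.

    ``coverage_reads`` is the absolute number of uniquely mapped reads.
    Ordinal scores are ``None`` when not assessed. Cohort-specific markers
    are enforced: PD-L1 belongs to LC specimens, HER2/ER/PR to BC.
    """

    sample_id: str
    cohort: str  # "BC" | "LC"
    coverage_reads: int
    site: str | None = None
    age: int | None = None
    sex: str | None = None
    stage: str | None = None
    histology: str | None = None
    her2_score: int | None = None
    er_score: int | None = None
    pr_score: int | None = None
    pdl1_category: int | None = None
    rin: float | None = None
    days_in_paraffin: int | None = None

    def validate(self) -> None:
        if self.cohort not in ("BC", "LC"):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: cohort must be 'BC' or 'LC', got {self.cohort!r}"
            )
        if not (isinstance(self.coverage_reads, (int, np.integer)) and self.coverage_reads > 0):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: coverage_reads must be a positive integer, "
                f"got {self.coverage_reads!r}"
            )
        for name, value, lo, hi in (
            ("her2_score", self.her2_score, 0, 3),
            ("er_score", self.er_score, 0, 8),
            ("pr_score", self.pr_score, 0, 8),
            ("pdl1_category", self.pdl1_category, 0, 2),
        ):
            if value is not None and not (lo <= value <= hi):
                raise CohortValidationError(
                    f"sample {self.sample_id!r}: {name}={value} outside [{lo}, {hi}]"
                )
        if self.rin is not None and not (1.0 <= self.rin <= 10.0):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: rin={self.rin} outside [1, 10]"
            )
        if self.cohort == "BC" and self.pdl1_category is not None:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: PD-L1 category on a BC sample"
            )
        if self.cohort == "LC" and any(
            s is not None for s in (self.her2_score, self.er_score, self.pr_score)
        ):
            raise CohortValidationError(
                f"sample {self.sample_id!r}: HER2/ER/PR score on an LC sample"
            )

    def score(self, protein: str) -> int | None:
        """Ordinal IHC score for ``protein`` ("HER2", "ER", "PR", "PD-L1")."""
        key = protein.upper().replace("-", "")
        mapping = {
            "HER2": self.her2_score,
            "ER": self.er_score,
            "PR": self.pr_score,
            "PDL1": self.pdl1_category,
        }
        if key not in mapping:
            raise KeyError(f"unknown protein {protein!r}")
        return mapping[key]


@dataclass
class Cohort:
    """Ordered collection of :class:`SampleRecord` with unique sample ids."""

    records: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(f"duplicate sample ids: {sorted(dupes)}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids) -> "Cohort":
        wanted = set(sample_ids)
        return Cohort(
            [r for r in self.records if r.sample_id in wanted],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Annotation as a DataFrame indexed by sample id (internal units)."""
        rows = [{f.name: getattr(r, f.name) for f in fields(SampleRecord)} for r in self.records]
        return pd.DataFrame(rows).set_index("sample_id")

    @staticmethod
    def concat(*cohorts: "Cohort") -> "Cohort":
        records = [r for c in cohorts for r in c.records]
        provenance = "+".join(c.provenance for c in cohorts)
        return Cohort(records, provenance=provenance)


@dataclass
class CohortSummary:
    """Descriptive statistics over a cohort; missing fields excluded pairwise."""

    n: int
    mean_age: float | None
    age_range: tuple[int, int] | None
    sex_counts: dict[str, int]
    site_counts: dict[str, int]
    histology_counts: dict[str, int]
    coverage_range: tuple[int, int]
    rin_range: tuple[float, float] | None
    n_passing_coverage: int
    coverage_threshold: int


#: default mapping from :class:`SampleRecord` fields to sample-sheet columns.
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "cohort": "cohort",
    "site": "site",
    "age": "age",
    "sex": "sex",
    "stage": "stage",
    "histology": "histology",
    "her2_score": "her2_score",
    "er_score": "er_score",
    "pr_score": "pr_score",
    "pdl1_category": "pdl1_positive_cells",
    "coverage_reads": "coverage_mln",
    "rin": "rin",
    "days_in_paraffin": "days_in_paraffin",
}

_MISSING = {"", "na", "nan", "none", "not assessed"}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().lower() in _MISSING


def _parse_int(value, row: str, column: str, what: str = "integer") -> int:
    try:
        f = float(str(value).strip())
    except ValueError:
        raise CohortValidationError(
            f"row {row!r}, column {column!r}: expected {what}, got {value!r}"
        ) from None
    if not f.is_integer():
        raise CohortValidationError(
            f"row {row!r}, column {column!r}: expected {what}, got {value!r}"
        )
    return int(f)


def _parse_pdl1(value, row: str, column: str) -> int:
    s = str(value).strip()
    if s in _PDL1_ALIASES:
        return _PDL1_ALIASES[s]
    return _parse_int(value, row, column, what="PD-L1 category (0/1/2 or '%' range)")


def read_sample_sheet(path, dialect: dict[str, str] | None = None) -> Cohort:
    """Read a TSV sample sheet into a :class:`Cohort`.

    ``dialect`` maps :class:`SampleRecord` field names to column names in
    the file, overriding :data:`DEFAULT_DIALECT` entry-wise. The coverage
    column carries millions of mapped reads (e.g. ``3.96``) and is
    converted to an absolute read count on read. Empty cells and the
    literal ``NA`` both parse as missing. Unknown columns are ignored.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for required in ("sample_id", "cohort", "coverage_reads"):
        if colmap[required] not in df.columns:
            raise CohortValidationError(
                f"{path}: missing required column {colmap[required]!r}"
            )

    records = []
    for _, row in df.iterrows():
        sid = str(row[colmap["sample_id"]]).strip()
        kwargs: dict = {"sample_id": sid}

        def get(fname: str):
            col = colmap[fname]
            if col not in df.columns:
                return None
            v = row[col]
            return None if _is_missing(v) else v

        kwargs["cohort"] = str(get("cohort") or "").strip().upper()
        cov = get("coverage_reads")
        if cov is None:
            raise CohortValidationError(
                f"row {sid!r}, column {colmap['coverage_reads']!r}: coverage is required"
            )
        try:
            cov_mln = float(str(cov).strip())
        except ValueError:
            raise CohortValidationError(
                f"row {sid!r}, column {colmap['coverage_reads']!r}: "
                f"non-numeric coverage {cov!r}"
            ) from None
        kwargs["coverage_reads"] = int(round(cov_mln * 1_000_000))

        for fname in ("site",):
            v = get(fname)
            kwargs[fname] = _normalize_site(str(v)) if v is not None else None
        for fname in ("sex", "stage", "histology"):
            v = get(fname)
            kwargs[fname] = str(v).strip() if v is not None else None
        if kwargs.get("sex") is not None:
            kwargs["sex"] = kwargs["sex"].lower()

        v = get("age")
        kwargs["age"] = _parse_int(v, sid, colmap["age"]) if v is not None else None
        for fname in ("her2_score", "er_score", "pr_score"):
            v = get(fname)
            kwargs[fname] = _parse_int(v, sid, colmap[fname]) if v is not None else None
        v = get("pdl1_category")
        kwargs["pdl1_category"] = (
            _parse_pdl1(v, sid, colmap["pdl1_category"]) if v is not None else None
        )
        v = get("rin")
        if v is not None:
            try:
                kwargs["rin"] = float(str(v).strip())
            except ValueError:
                raise CohortValidationError(
                    f"row {sid!r}, column {colmap['rin']!r}: non-numeric RIN {v!r}"
                ) from None
        v = get("days_in_paraffin")
        kwargs["days_in_paraffin"] = (
            _parse_int(v, sid, colmap["days_in_paraffin"]) if v is not None else None
        )

        rec = SampleRecord(**kwargs)
        try:
            rec.validate()
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path}: {exc}") from None
        records.append(rec)

    return Cohort(records, provenance=str(path))


def write_sample_sheet(cohort: Cohort, path) -> None:
    """Write a cohort back to TSV in the default dialect (round-trippable)."""
    rows = []
    for r in cohort:
        rows.append(
            {
                "sample_id": r.sample_id,
                "cohort": r.cohort,
                "site": r.site if r.site is not None else "",
                "age": r.age if r.age is not None else "",
                "sex": r.sex if r.sex is not None else "",
                "stage": r.stage if r.stage is not None else "",
                "histology": r.histology if r.histology is not None else "",
                "her2_score": r.her2_score if r.her2_score is not None else "",
                "er_score": r.er_score if r.er_score is not None else "",
                "pr_score": r.pr_score if r.pr_score is not None else "",
                "pdl1_positive_cells": (
                    PDL1_CATEGORIES[r.pdl1_category] if r.pdl1_category is not None else ""
                ),
                "coverage_mln": repr(r.coverage_reads / 1_000_000),
                "rin": r.rin if r.rin is not None else "",
                "days_in_paraffin": (
                    r.days_in_paraffin if r.days_in_paraffin is not None else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize_cohort(cohort: Cohort, coverage_threshold: int = 2_500_000) -> CohortSummary:
    """Descriptive statistics for a cohort.

    Mean age is the arithmetic mean over records with a non-missing age,
    reported to one decimal place; categorical counts are over exact
    values; coverage is summarized over all records. Missing fields are
    excluded pairwise and never imputed.
    """
    if len(cohort) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    ages = [r.age for r in cohort if r.age is not None]
    rins = [r.rin for r in cohort if r.rin is not None]
    coverages = [r.coverage_reads for r in cohort]

    def counts(values) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in values:
            if v is not None:
                out[v] = out.get(v, 0) + 1
        return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))

    return CohortSummary(
        n=len(cohort),
        mean_age=round(float(np.mean(ages)), 1) if ages else None,
        age_range=(min(ages), max(ages)) if ages else None,
        sex_counts=counts(r.sex for r in cohort),
        site_counts=counts(r.site for r in cohort),
        histology_counts=counts(r.histology for r in cohort),
        coverage_range=(min(coverages), max(coverages)),
        rin_range=(min(rins), max(rins)) if rins else None,
        n_passing_coverage=sum(c >= coverage_threshold for c in coverages),
        coverage_threshold=coverage_threshold,
    )


@dataclass
class CountMatrix:
    """Raw gene-by-sample counts (genes on rows, HGNC symbols as index)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise CohortValidationError(f"duplicate gene symbols: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise CohortValidationError(f"duplicate sample columns: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)) or np.isnan(values).any():
                raise CohortValidationError("counts must be integers")
            self.counts = df.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise CohortValidationError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)].copy())

    def equals(self, other: "CountMatrix") -> bool:
        return self.counts.equals(other.counts)


def read_count_matrix(path) -> CountMatrix:
    """Read a genes-by-samples TSV of raw counts (first column: gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise CohortValidationError(f"{path}: duplicate gene symbols {dupes}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise CohortValidationError(f"{path}: non-numeric counts")
    if np.isnan(arr.astype(float)).any():
        raise CohortValidationError(f"{path}: missing count values")
    if not np.allclose(arr, np.round(arr)):
        bad = df.columns[np.where(~np.isclose(arr, np.round(arr)))[1][0]]
        raise CohortValidationError(f"{path}: non-integer count in column {bad!r}")
    if (arr < 0).any():
        bad = df.columns[np.where(arr < 0)[1][0]]
        raise CohortValidationError(f"{path}: negative count in column {bad!r}")
    df.index.name = "gene"
    return CountMatrix(df.astype(np.int64))


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("rnaconcord.data") / name)


def load_breast_cohort() -> Cohort:
    """The packaged 39-sample breast-cancer annotation table."""
    return read_sample_sheet(_fixture_path("table1_bc.tsv"))


def load_lung_cohort() -> Cohort:
    """The packaged 19-sample lung-cancer annotation table."""
    return read_sample_sheet(_fixture_path("table2_lc.tsv"))
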