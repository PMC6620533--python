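"""Reading and writing the pipeline's external file formats.

The pipeline consumes three delimited inputs — a cohort manifest, per-subject
region morphometry tables and per-subject region time-course matrices — and
emits a JSON diagnosis report.  All readers validate against an
:class:`~neurofuse.atlas.AtlasDefinition` and reorder rows into canonical
atlas order, so downstream numerics never see a permuted region axis.

Delimiters are auto-detected from the file extension: ``.tsv`` is
tab-separated, anything else comma-separated.  Files are UTF-8 with ``.`` as
the decimal separator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition, dk_atlas

__all__ = [
    "ValidationError",
    "SubjectRecord",
    "CohortManifest",
    "TimecourseMatrix",
    "FEATURE_COLUMNS",
    "read_cohort_manifest",
    "read_region_features",
    "read_time_courses",
    "write_diagnosis_report",
    "read_diagnosis_report",
]

#: Canonical morphometric feature column order: surface area, volume, mean
#: cortical thickness, thickness SD, mean-curvature index, Gaussian
#: curvature, intrinsic curvature index, folding index.
FEATURE_COLUMNS: tuple[str, ...] = ("A", "V", "T_mean", "T_sd", "MCI", "K", "ICI", "FI")

MANIFEST_COLUMNS = (
    "subject_id",
    "label",
    "sex",
    "age",
    "ados_total",
    "ados_sa",
    "ados_rrb",
    "has_smri",
    "has_fmri",
)

_VALID_LABELS = {"ASD", "TD"}
_VALID_SEX = {"M", "F", "unknown"}


class ValidationError(ValueError):
    """Input failed validation; ``errors`` collects every problem found."""

    def __init__(self, errors: Iterable[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's identity, diagnosis and covariates.

    ``ados_total`` is the cumulative ADOS severity score (1–24 in this
    cohort); ``ados_sa`` and ``ados_rrb`` are the social-affect and
    restricted/repetitive-behaviour sub-scores.  All three are optional —
    only a subset of subjects have an ADOS report.
    """

    subject_id: str
    label: str
    sex: str = "unknown"
    age: float = float("nan")
    ados_total: int | None = None
    ados_sa: int | None = None
    ados_rrb: int | None = None

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be ASD or TD, got {self.label!r}")
        if self.sex not in _VALID_SEX:
            raise ValueError(f"sex must be M, F or unknown, got {self.sex!r}")
        if self.ados_total is not None and not (0 <= self.ados_total <= 30):
            raise ValueError(f"ados_total out of range [0, 30]: {self.ados_total}")

    @property
    def has_severity(self) -> bool:
        return self.ados_total is not None


@dataclass
class CohortManifest:
    """Validated cohort: subject records plus per-subject modality flags."""

    subjects: list[SubjectRecord]
    modality_availability: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([f"duplicate subject_id: {d}" for d in dupes])
        for s in self.subjects:
            self.modality_availability.setdefault(s.subject_id, (True, True))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    def subset(self, subject_ids: Iterable[str]) -> "CohortManifest":
        keep = set(subject_ids)
        return CohortManifest(
            [s for s in self.subjects if s.subject_id in keep],
            {k: v for k, v in self.modality_availability.items() if k in keep},
        )

    def with_severity(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.has_severity]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            smri, fmri = self.modality_availability[s.subject_id]
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "label": s.label,
                    "sex": s.sex,
                    "age": s.age,
                    "ados_total": s.ados_total,
                    "ados_sa": s.ados_sa,
                    "ados_rrb": s.ados_rrb,
                    "has_smri": smri,
                    "has_fmri": fmri,
                }
            )
        return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


@dataclass
class TimecourseMatrix:
    """A subject's 68 × T region time courses in canonical atlas order.

    ``constant_regions`` lists regions whose time course has zero variance;
    their Pearson correlations are undefined downstream and are handled by
    :func:`neurofuse.connectivity.connectivity_matrix`.
    """

    values: np.ndarray
    t_points: int
    constant_regions: list[str] = field(default_factory=list)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _parse_optional_int(raw: Any, what: str, row: int, errors: list[str]) -> int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None
    try:
        val = float(s)
    except ValueError:
        errors.append(f"row {row}: unparseable {what}: {raw!r}")
        return None
    if not val.is_integer():
        errors.append(f"row {row}: non-integer {what}: {raw!r}")
        return None
    return int(val)


def read_cohort_manifest(
    path: str | Path, atlas: AtlasDefinition | None = None
) -> CohortManifest:
    """Read and validate a cohort manifest CSV/TSV.

    Required columns are ``subject_id`` and ``label``; ``sex``, ``age``, the
    three ADOS columns and the ``has_smri``/``has_fmri`` modality flags are
    optional.  All validation problems in the file are collected and raised
    together as one :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    errors: list[str] = []
    for col in ("subject_id", "label"):
        if col not in df.columns:
            errors.append(f"missing required column: {col}")
    if errors:
        raise ValidationError(errors)

    seen: set[str] = set()
    records: list[SubjectRecord] = []
    availability: dict[str, tuple[bool, bool]] = {}
    for row_no, row in enumerate(df.to_dict("records"), start=2):  # 1 = header
        sid = str(row["subject_id"]).strip()
        if sid in seen:
            errors.append(f"duplicate subject_id: {sid}")
            continue
        seen.add(sid)
        label = str(row.get("label", "")).strip()
        if label not in _VALID_LABELS:
            errors.append(f"row {row_no}: subject {sid} has missing/invalid label {label!r}")
            continue
        sex = str(row.get("sex", "unknown") or "unknown").strip() or "unknown"
        if sex not in _VALID_SEX:
            errors.append(f"row {row_no}: invalid sex {sex!r}")
            continue
        age_raw = row.get("age")
        try:
            age = float(age_raw) if age_raw not in (None, "") else float("nan")
        except (TypeError, ValueError):
            errors.append(f"row {row_no}: unparseable age: {age_raw!r}")
            continue
        ados_total = _parse_optional_int(row.get("ados_total"), "ados_total", row_no, errors)
        ados_sa = _parse_optional_int(row.get("ados_sa"), "ados_sa", row_no, errors)
        ados_rrb = _parse_optional_int(row.get("ados_rrb"), "ados_rrb", row_no, errors)
        if ados_total is not None and not (0 <= ados_total <= 30):
            errors.append(f"row {row_no}: ados_total out of range [0, 30]: {ados_total}")
            continue

        def _flag(raw: Any) -> bool:
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return True
            return str(raw).strip().lower() in {"1", "true", "yes", "y"}

        availability[sid] = (_flag(row.get("has_smri")), _flag(row.get("has_fmri")))
        records.append(
            SubjectRecord(
                subject_id=sid,
                label=label,
                sex=sex,
                age=age,
                ados_total=ados_total,
                ados_sa=ados_sa,
                ados_rrb=ados_rrb,
            )
        )
    if errors:
        raise ValidationError(errors)
    return CohortManifest(records, availability)


def read_region_features(
    path: str | Path, atlas: AtlasDefinition | None = None
) -> pd.DataFrame:
    """Read a subject's 68 × 8 region morphometry table.

    The ``region`` column may hold region names or integer atlas codes, in
    any order; the returned frame is indexed by region name in canonical
    atlas order with columns :data:`FEATURE_COLUMNS`.
    """
    atlas = atlas or dk_atlas()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    errors: list[str] = []
    if "region" not in df.columns:
        raise ValidationError(["missing 'region' column"])
    missing_cols = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError([f"missing feature column: {c}" for c in missing_cols])

    positions: dict[int, int] = {}
    for row_no, region in enumerate(df["region"]):
        try:
            idx = atlas.index_of(region if isinstance(region, str) else int(region))
        except KeyError:
            errors.append(f"unknown region {region!r} (row {row_no + 2})")
            continue
        if idx in positions:
            errors.append(f"duplicate region {region!r}")
        positions[idx] = row_no
    missing = [atlas.region_names[i] for i in range(atlas.n_regions) if i not in positions]
    errors.extend(f"missing region: {name}" for name in missing)
    if errors:
        raise ValidationError(errors)

    values = np.empty((atlas.n_regions, len(FEATURE_COLUMNS)))
    for idx in range(atlas.n_regions):
        row = df.iloc[positions[idx]]
        for col_no, col in enumerate(FEATURE_COLUMNS):
            try:
                values[idx, col_no] = float(row[col])
            except (TypeError, ValueError):
                errors.append(
                    f"non-numeric value at region {atlas.region_names[idx]!r},"
                    f" column {col!r}: {row[col]!r}"
                )
                values[idx, col_no] = np.nan
    if errors:
        raise ValidationError(errors)
    return pd.DataFrame(values, index=list(atlas.region_names), columns=list(FEATURE_COLUMNS))


def read_time_courses(
    path: str | Path, atlas: AtlasDefinition | None = None
) -> TimecourseMatrix:
    """Read a subject's 68 × T time-course CSV (first column = region).

    Rows are reordered to atlas order.  Fewer than 3 time points is an
    error; constant rows are loaded but flagged in the result's metadata.
    """
    atlas = atlas or dk_atlas()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None)
    regions = df.iloc[:, 0]
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    if data.shape[1] < 3:
        raise ValidationError(
            [f"too few time points: T={data.shape[1]} (need at least 3)"]
        )
    errors: list[str] = []
    out = np.full((atlas.n_regions, data.shape[1]), np.nan)
    seen: set[int] = set()
    for row_no, region in enumerate(regions):
        try:
            idx = atlas.index_of(region if isinstance(region, str) else int(region))
        except KeyError:
            errors.append(f"unknown region {region!r}")
            continue
        if idx in seen:
            errors.append(f"duplicate region {region!r}")
        seen.add(idx)
        out[idx] = data[row_no]
    errors.extend(
        f"missing region: {atlas.region_names[i]}"
        for i in range(atlas.n_regions)
        if i not in seen
    )
    if errors:
        raise ValidationError(errors)
    constant = [
        atlas.region_names[i]
        for i in range(atlas.n_regions)
        if np.ptp(out[i]) == 0.0
    ]
    return TimecourseMatrix(values=out, t_points=out.shape[1], constant_regions=constant)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_diagnosis_report(
    results: Mapping[str, Any],
    maps: Mapping[str, Mapping[str, Any]] | None,
    path: str | Path,
) -> Path:
    """Write the machine-readable diagnosis report as JSON.

    ``results`` holds cohort-level metrics and per-subject predictions;
    ``maps`` maps subject id to its personalized-map vectors (``V_f``,
    ``V_s``), either of which may be ``None`` for a single-modality run.
    The report round-trips exactly through :func:`read_diagnosis_report`.
    """
    path = Path(path)
    payload = {
        "results": _jsonable(dict(results)),
        "maps": _jsonable(dict(maps)) if maps is not None else None,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path


def read_diagnosis_report(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
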