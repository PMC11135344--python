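"""Domain types and CSV readers/writers for region-level cohort tables.

A cohort couples a subject metadata table (diagnosis, sex, age, and the
three cognitive scores) with one subjects x regions feature matrix per
biomarker.  Matrices may cover different subject subsets, mirroring studies
where not every participant undergoes every imaging modality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regions import CANONICAL_REGION_COUNTS

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "Sex",
    "Target",
    "SubjectRecord",
    "BiomarkerMatrix",
    "Cohort",
    "GroupSpec",
    "GROUP_MEMBERS",
    "SCORE_RANGES",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "select_group",
]


class CohortValidationError(ValueError):
    """Raised when cohort tables violate a structural or range invariant."""


class Diagnosis(str, Enum):
    HC = "HC"
    MCI = "MCI"
    AD = "AD"


class Sex(str, Enum):
    M = "M"
    F = "F"


class Target(str, Enum):
    """Cognitive scores used as regression targets."""

    MMSE = "MMSE"
    CDRSB = "CDRSB"
    ADAS = "ADAS"


#: Legal (inclusive) ranges of the cognitive scores.  MMSE: 0-30 with higher
#: better; CDRSB: 0-18 and ADAS: 0-70 with higher worse.
SCORE_RANGES: dict[Target, tuple[float, float]] = {
    Target.MMSE: (0.0, 30.0),
    Target.CDRSB: (0.0, 18.0),
    Target.ADAS: (0.0, 70.0),
}

#: Analysis groups pool diagnostic cohorts.
GROUP_MEMBERS: dict[str, frozenset[Diagnosis]] = {
    "HC_MCI": frozenset({Diagnosis.HC, Diagnosis.MCI}),
    "HC_AD": frozenset({Diagnosis.HC, Diagnosis.AD}),
    "MCI_AD": frozenset({Diagnosis.MCI, Diagnosis.AD}),
    "HC_MCI_AD": frozenset({Diagnosis.HC, Diagnosis.MCI, Diagnosis.AD}),
}


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    diagnosis: Diagnosis
    sex: Sex
    age: float
    mmse: float
    cdrsb: float
    adas: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: age must be positive, got {self.age}"
            )
        for target, value in (
            (Target.MMSE, self.mmse),
            (Target.CDRSB, self.cdrsb),
            (Target.ADAS, self.adas),
        ):
            lo, hi = SCORE_RANGES[target]
            if not (lo <= value <= hi) or not np.isfinite(value):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: {target.value} score {value} "
                    f"outside [{lo:g}, {hi:g}]"
                )

    def score(self, target: Target) -> float:
        return {
            Target.MMSE: self.mmse,
            Target.CDRSB: self.cdrsb,
            Target.ADAS: self.adas,
        }[target]


@dataclass
class BiomarkerMatrix:
    """Subjects x regions feature matrix for one biomarker panel.

    ``biomarker`` is a free string; the nine canonical panels (VGM, ATH, SA,
    VWM, FA, MD, RD, LD, ABETA) have their region counts enforced.  Synthetic
    panels may use any other name and region count.
    """

    biomarker: str
    region_names: list[str]
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.biomarker = str(self.biomarker).upper()
        self.values = np.asarray(self.values, dtype=float)
        expected = CANONICAL_REGION_COUNTS.get(self.biomarker)
        if expected is not None and len(self.region_names) != expected:
            raise CohortValidationError(
                f"{self.biomarker} expects {expected} regions, "
                f"got {len(self.region_names)}"
            )
        if self.values.ndim != 2 or self.values.shape != (
            len(self.subject_ids),
            len(self.region_names),
        ):
            raise CohortValidationError(
                f"{self.biomarker}: values shape {self.values.shape} does not "
                f"match {len(self.subject_ids)} subjects x "
                f"{len(self.region_names)} regions"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise CohortValidationError(
                f"{self.biomarker}: duplicate region names"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise CohortValidationError(
                f"{self.biomarker}: duplicate subject ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise CohortValidationError(
                f"{self.biomarker}: matrix contains missing/non-finite values"
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    matrices: dict[str, BiomarkerMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate subject ids in metadata")
        known = set(ids)
        for name, mat in self.matrices.items():
            extra = set(mat.subject_ids) - known
            if extra:
                raise CohortValidationError(
                    f"{name}: subject ids absent from metadata: "
                    f"{sorted(extra)[:5]}"
                )

    def subject_by_id(self) -> dict[str, SubjectRecord]:
        return {s.subject_id: s for s in self.subjects}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class GroupSpec:
    """A named pooling of diagnostic cohorts, e.g. HC_AD = {HC, AD}."""

    name: str
    members: frozenset[Diagnosis]

    def __post_init__(self) -> None:
        expected = GROUP_MEMBERS.get(self.name)
        if expected is None:
            raise CohortValidationError(
                f"unknown group {self.name!r}; expected one of "
                f"{sorted(GROUP_MEMBERS)}"
            )
        if frozenset(self.members) != expected:
            raise CohortValidationError(
                f"group {self.name}: members {sorted(d.value for d in self.members)} "
                f"do not match the name"
            )

    @classmethod
    def from_name(cls, name: str) -> "GroupSpec":
        name = name.upper()
        if name not in GROUP_MEMBERS:
            raise CohortValidationError(
                f"unknown group {name!r}; expected one of {sorted(GROUP_MEMBERS)}"
            )
        return cls(name=name, members=GROUP_MEMBERS[name])


METADATA_COLUMNS = ["subject_id", "diagnosis", "sex", "age", "mmse", "cdrsb", "adas"]


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise CohortValidationError(f"malformed CSV {path}: {exc}") from exc


def load_cohort(
    metadata_path: str | Path,
    matrix_paths: Mapping[str, str | Path],
) -> Cohort:
    """Load and validate a cohort from a metadata CSV plus matrix CSVs.

    Matrix rows containing any missing value are dropped from that matrix
    only (with a logged count), matching an inclusion criterion of complete
    data per modality.
    """
    metadata_path = Path(metadata_path)
    meta = _read_csv(metadata_path)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise CohortValidationError(
            f"{metadata_path}: missing metadata columns {missing_cols}"
        )
    subjects = []
    for row in meta.itertuples(index=False):
        try:
            diagnosis = Diagnosis(str(row.diagnosis))
            sex = Sex(str(row.sex))
        except ValueError as exc:
            raise CohortValidationError(
                f"subject {row.subject_id!r}: {exc}"
            ) from exc
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                diagnosis=diagnosis,
                sex=sex,
                age=float(row.age),
                mmse=float(row.mmse),
                cdrsb=float(row.cdrsb),
                adas=float(row.adas),
            )
        )

    matrices: dict[str, BiomarkerMatrix] = {}
    for biomarker, path in matrix_paths.items():
        biomarker = str(biomarker).upper()
        df = _read_csv(Path(path))
        if "subject_id" not in df.columns:
            raise CohortValidationError(f"{path}: missing subject_id column")
        region_names = [c for c in df.columns if c != "subject_id"]
        values = df[region_names].to_numpy(dtype=float)
        keep = np.all(np.isfinite(values), axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d subject rows with missing values",
                biomarker,
                n_dropped,
            )
        matrices[biomarker] = BiomarkerMatrix(
            biomarker=biomarker,
            region_names=region_names,
            subject_ids=[str(s) for s in df.loc[keep, "subject_id"]],
            values=values[keep],
        )
    return Cohort(subjects=subjects, matrices=matrices)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write metadata + per-biomarker matrix CSVs; returns written paths.

    Floats are written with Python's shortest round-trip repr, so
    ``load_cohort(write_cohort(...))`` reproduces finite values bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.subjects],
            "diagnosis": [s.diagnosis.value for s in cohort.subjects],
            "sex": [s.sex.value for s in cohort.subjects],
            "age": [s.age for s in cohort.subjects],
            "mmse": [s.mmse for s in cohort.subjects],
            "cdrsb": [s.cdrsb for s in cohort.subjects],
            "adas": [s.adas for s in cohort.subjects],
        }
    )
    meta_path = out_dir / "metadata.csv"
    meta.to_csv(meta_path, index=False, float_format="%.17g")
    paths["metadata"] = meta_path
    for name, mat in cohort.matrices.items():
        df = pd.DataFrame(mat.values, columns=mat.region_names)
        df.insert(0, "subject_id", mat.subject_ids)
        path = out_dir / f"{name.lower()}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths[name] = path
    return paths


def select_group(
    cohort: Cohort,
    group: GroupSpec | str,
    biomarker: str,
    target: Target | str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract (X, y, subject_ids) for one prediction task.

    Rows are restricted to subjects whose diagnosis belongs to the group and
    who have a row in the biomarker's matrix; ``y`` is the chosen cognitive
    score aligned to the rows of ``X``.
    """
    if isinstance(group, str):
        group = GroupSpec.from_name(group)
    if isinstance(target, str):
        target = Target(target.upper())
    biomarker = biomarker.upper()
    if biomarker not in cohort.matrices:
        raise CohortValidationError(
            f"biomarker {biomarker} not present in cohort "
            f"(has {sorted(cohort.matrices)})"
        )
    mat = cohort.matrices[biomarker]
    by_id = cohort.subject_by_id()
    rows = []
    ids = []
    y = []
    for i, sid in enumerate(mat.subject_ids):
        rec = by_id[sid]
        if rec.diagnosis in group.members:
            rows.append(i)
            ids.append(sid)
            y.append(rec.score(target))
    if not rows:
        raise CohortValidationError(
            f"no subjects in group {group.name} for biomarker {biomarker}"
        )
    return mat.values[rows], np.asarray(y, dtype=float), ids


def diagnoses_of(cohort: Cohort, ids: Iterable[str]) -> np.ndarray:
    """Diagnosis labels (as strings) aligned to the given subject ids."""
    by_id = cohort.subject_by_id()
    return np.asarray([by_id[s].diagnosis.value for s in ids])
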