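"""Patient-level data model, cohort CSV I/O, subgroup membership and
eligibility filtering, and design-matrix construction with standardization.

One row / record is one coronary intervention (consecutive interventions of
the same patient are treated as independent; a ``patient_id`` is carried for
optional grouped analyses but not used by default). Records hold the three
mandatory stratification variables (age, sex, diabetes), the treatment
received (bare-metal stent BMS or drug-eluting stent DES), clinical and
biomarker feature values with missingness, and binary endpoint labels at
fixed horizons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import NONE_SET, FeatureCatalog

logger = logging.getLogger(__name__)

#: Endpoint label columns: 6-month angiographic restenosis, 1-/3-year
#: clinical restenosis (target lesion revascularization) and 1-/3-year
#: hazardous events (death, myocardial infarction, stent thrombosis).
ENDPOINTS = (
    "angio_restenosis_6m",
    "clin_restenosis_1y",
    "clin_restenosis_3y",
    "hazard_1y",
    "hazard_3y",
)

TREATMENTS = ("BMS", "DES")

META_COLUMNS = (
    "record_id",
    "patient_id",
    "age",
    "sex",
    "diabetes",
    "era_tag",
    "treatment",
    "three_vessel",
    "followed_up",
) + ENDPOINTS

#: Columns that must be present and parseable in any cohort CSV.
MANDATORY_COLUMNS = ("age", "sex", "diabetes", "treatment")

EVENT, NO_EVENT = "event", "no_event"


class MissingColumnError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

AGE_LEVELS = ("ALL", "LE60", "GT60")
SEX_LEVELS = ("ALL", "FEMALE", "MALE")
DIABETES_LEVELS = ("ALL", "NO", "YES")


@dataclass(frozen=True, order=True)
class SubgroupSpec:
    """A conjunction of constraints on age (<=60 / >60), sex and diabetes.

    ``ALL`` leaves a variable unconstrained. A record belongs to the subgroup
    iff it satisfies every non-ALL constraint; the age split is inclusive on
    the young side (age 60 satisfies ``LE60``).
    """

    age: str = "ALL"
    sex: str = "ALL"
    diabetes: str = "ALL"

    def __post_init__(self) -> None:
        if self.age not in AGE_LEVELS:
            raise ValueError(f"age constraint must be one of {AGE_LEVELS}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex constraint must be one of {SEX_LEVELS}")
        if self.diabetes not in DIABETES_LEVELS:
            raise ValueError(f"diabetes constraint must be one of {DIABETES_LEVELS}")

    def matches(self, age: float, sex: str, diabetes: str) -> bool:
        if age is None or (isinstance(age, float) and math.isnan(age)) or sex is None or diabetes is None:
            raise ValueError("age, sex and diabetes are mandatory for subgroup membership")
        if self.age == "LE60" and not age <= 60:
            return False
        if self.age == "GT60" and not age > 60:
            return False
        if self.sex == "FEMALE" and sex != "female":
            return False
        if self.sex == "MALE" and sex != "male":
            return False
        if self.diabetes == "NO" and diabetes != "no":
            return False
        if self.diabetes == "YES" and diabetes != "yes":
            return False
        return True

    def mask(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorized membership over a cohort frame."""
        if frame["age"].isna().any() or frame["sex"].isna().any() or frame["diabetes"].isna().any():
            raise ValueError("age, sex and diabetes are mandatory for subgroup membership")
        m = np.ones(len(frame), dtype=bool)
        if self.age == "LE60":
            m &= (frame["age"] <= 60).to_numpy()
        elif self.age == "GT60":
            m &= (frame["age"] > 60).to_numpy()
        if self.sex != "ALL":
            m &= (frame["sex"] == self.sex.lower()).to_numpy()
        if self.diabetes != "ALL":
            m &= (frame["diabetes"] == self.diabetes.lower()).to_numpy()
        return m

    @property
    def label(self) -> str:
        return f"{self.age}/{self.sex}/{self.diabetes}"

    @property
    def is_leaf_of_full_tree(self) -> bool:
        """True if all three variables are constrained (8 such subgroups)."""
        return "ALL" not in (self.age, self.sex, self.diabetes)


def subgroup_membership(record: "PatientRecord", spec: SubgroupSpec) -> bool:
    """Does a record satisfy every non-ALL constraint of ``spec``?"""
    return spec.matches(record.age, record.sex, record.diabetes)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """One intervention: demographics, features, treatment, endpoint labels."""

    record_id: str
    age: float
    sex: str  # "female" | "male"
    diabetes: str  # "no" | "yes"
    treatment: str  # "BMS" | "DES"
    patient_id: str = ""
    era_tag: str = ""
    three_vessel: str = "no"
    followed_up: bool = True
    clinical: dict = field(default_factory=dict)
    biomarkers: dict = field(default_factory=dict)
    endpoints: dict = field(default_factory=dict)

    def validate(self, catalog: FeatureCatalog | None = None) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if catalog is not None:
            for name in list(self.clinical) + list(self.biomarkers):
                if name not in catalog:
                    raise ValueError(f"feature {name!r} not in catalogue")
        if not self.followed_up:
            for ep, val in self.endpoints.items():
                if val is not None:
                    raise ValueError(
                        f"record {self.record_id}: endpoint {ep} set but not followed up"
                    )

    def feature_value(self, name: str):
        if name in self.clinical:
            return self.clinical[name]
        return self.biomarkers.get(name)


def cohort_to_frame(cohort: Sequence[PatientRecord] | pd.DataFrame, catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Canonical tabular view of a cohort (records x columns).

    Accepts a DataFrame (returned as-is) so pipeline stages can take either
    representation.
    """
    if isinstance(cohort, pd.DataFrame):
        return cohort
    catalog = catalog or FeatureCatalog.default()
    rows = []
    for r in cohort:
        row = {
            "record_id": r.record_id,
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "diabetes": r.diabetes,
            "era_tag": r.era_tag,
            "treatment": r.treatment,
            "three_vessel": r.three_vessel,
            "followed_up": r.followed_up,
        }
        for ep in ENDPOINTS:
            row[ep] = r.endpoints.get(ep)
        for name in catalog.features:
            row[name] = r.feature_value(name)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(catalog.features))
    return _coerce_frame(frame, catalog)


def frame_to_cohort(frame: pd.DataFrame, catalog: FeatureCatalog | None = None) -> list[PatientRecord]:
    catalog = catalog or FeatureCatalog.default()
    out = []
    for _, row in frame.iterrows():
        clinical = {n: _opt(row[n]) for n in catalog.clinical_names if n in frame.columns}
        biomarkers = {n: _opt(row[n]) for n in catalog.biomarker_names if n in frame.columns}
        endpoints = {ep: _opt(row[ep]) for ep in ENDPOINTS if ep in frame.columns}
        out.append(
            PatientRecord(
                record_id=str(row["record_id"]),
                patient_id=str(row.get("patient_id", "")),
                age=float(row["age"]),
                sex=row["sex"],
                diabetes=row["diabetes"],
                era_tag=str(row.get("era_tag", "")),
                treatment=row["treatment"],
                three_vessel=row.get("three_vessel", "no"),
                followed_up=bool(row.get("followed_up", True)),
                clinical=clinical,
                biomarkers=biomarkers,
                endpoints=endpoints,
            )
        )
    return out


def _opt(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def _coerce_frame(frame: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Coerce column dtypes; unparseable cells become missing with a warning."""
    frame = frame.copy()
    frame["age"] = pd.to_numeric(frame["age"], errors="raise")
    numeric = [
        n
        for n in catalog.features
        if n in frame.columns and catalog.kind(n) in ("continuous", "binary")
    ]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str).str.strip() != "") & (frame[col].astype(str) != "NA")
        if bad.any():
            logger.warning(
                "column %s: %d unparseable values set to missing", col, int(bad.sum())
            )
        frame[col] = coerced
    for col in ("sex", "diabetes", "treatment", "three_vessel", "era_tag") + ENDPOINTS:
        if col in frame.columns:
            frame[col] = frame[col].where(frame[col].notna(), None)
    return frame


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA"}


def read_cohort(path: str | Path, catalog: FeatureCatalog | None = None) -> list[PatientRecord]:
    """Read a cohort CSV (UTF-8, comma-separated, header row).

    Empty cells and ``NA`` are read as missing. Unparseable numeric cells
    become missing with a logged warning; the row count is preserved.
    Raises :class:`MissingColumnError` naming the first absent mandatory
    column (age, sex, diabetes, treatment).
    """
    catalog = catalog or FeatureCatalog.default()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise MissingColumnError(f"cohort CSV is missing mandatory column {col!r}")
    frame = frame.replace(list(_MISSING_TOKENS), None)
    if "followed_up" in frame.columns:
        frame["followed_up"] = frame["followed_up"].map(
            lambda v: v if v is None else v.strip().lower() in ("yes", "true", "1")
        )
    frame = _coerce_frame(frame, catalog)
    return frame_to_cohort(frame, catalog)


def write_cohort(
    cohort: Sequence[PatientRecord] | pd.DataFrame,
    path: str | Path,
    catalog: FeatureCatalog | None = None,
) -> None:
    """Write a cohort CSV; missing values are written as ``NA``."""
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame(cohort, catalog).copy()
    frame["followed_up"] = frame["followed_up"].map(lambda b: "yes" if b else "no")
    frame.to_csv(path, index=False, na_rep="NA", encoding="utf-8")


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

#: Subgroup/feature-set eligibility thresholds: a design matrix is usable
#: only with at least 100 complete rows of which at least 10 are positive.
MIN_SAMPLES = 100
MIN_POSITIVES = 10


@dataclass
class EligibleSample:
    """Complete-case design data for one (subgroup, feature pair, arm, endpoint)."""

    features: pd.DataFrame  # complete rows x selected feature columns
    y: np.ndarray  # binary endpoint labels, 1 = event
    subgroup: SubgroupSpec
    feature_pair: tuple[str, str]
    treatment_arm: str
    endpoint: str
    index: np.ndarray  # positional indices into the source frame

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())


class CohortIndex:
    """Precomputed masks over a cohort frame, shared across the many
    (subgroup, feature pair, arm, endpoint) eligibility queries of a training
    run."""

    def __init__(self, frame: pd.DataFrame, catalog: FeatureCatalog):
        self.frame = frame
        self.catalog = catalog
        self.feature_names = [n for n in catalog.features if n in frame.columns]
        self.col = {n: i for i, n in enumerate(self.feature_names)}
        self.notna = frame[self.feature_names].notna().to_numpy()
        self.arm = {t: (frame["treatment"] == t).to_numpy() for t in TREATMENTS}
        self.endpoint_ok = {ep: frame[ep].notna().to_numpy() for ep in ENDPOINTS}
        self.event = {ep: (frame[ep] == EVENT).to_numpy() for ep in ENDPOINTS}
        self._subgroup_masks: dict[SubgroupSpec, np.ndarray] = {}

    def subgroup_mask(self, spec: SubgroupSpec) -> np.ndarray:
        if spec not in self._subgroup_masks:
            self._subgroup_masks[spec] = spec.mask(self.frame)
        return self._subgroup_masks[spec]


def filter_eligible(
    cohort: Sequence[PatientRecord] | pd.DataFrame,
    spec: SubgroupSpec,
    feature_pair: tuple[str, str],
    treatment_arm: str,
    endpoint: str,
    catalog: FeatureCatalog | None = None,
    min_samples: int = MIN_SAMPLES,
    min_positives: int = MIN_POSITIVES,
    index: CohortIndex | None = None,
) -> EligibleSample | None:
    """Complete-case sample for a candidate classifier, or ``None`` if ineligible.

    Keeps records in the subgroup and treatment arm with a non-missing
    endpoint label and no missing value among the selected features. Returns
    ``None`` (ineligible) when fewer than ``min_samples`` rows or
    ``min_positives`` positive labels survive, or when the feature pair is
    (NONE, NONE) so the design matrix would be empty.
    """
    catalog = catalog or FeatureCatalog.default()
    if treatment_arm not in TREATMENTS:
        raise ValueError(f"treatment arm must be one of {TREATMENTS}")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    names = catalog.pair_members(feature_pair)
    if not names:
        return None
    if index is None:
        index = CohortIndex(cohort_to_frame(cohort, catalog), catalog)
    mask = index.subgroup_mask(spec) & index.arm[treatment_arm] & index.endpoint_ok[endpoint]
    cols = [index.col[n] for n in names]
    mask &= index.notna[:, cols].all(axis=1)
    idx = np.flatnonzero(mask)
    if len(idx) < min_samples:
        return None
    y = index.event[endpoint][idx].astype(int)
    if y.sum() < min_positives:
        return None
    return EligibleSample(
        features=index.frame.iloc[idx][names],
        y=y,
        subgroup=spec,
        feature_pair=feature_pair,
        treatment_arm=treatment_arm,
        endpoint=endpoint,
        index=idx,
    )


# ---------------------------------------------------------------------------
# Standardization and design-matrix encoding
# ---------------------------------------------------------------------------


def standardize(matrix: np.ndarray) -> tuple[dict, np.ndarray]:
    """Zero-mean unit-variance scaling fitted on training data.

    Zero-variance columns are mapped to zero with a logged warning. Returns
    the fitted parameters and the transformed matrix.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot standardize an empty matrix")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance column(s) mapped to 0", int(zero_var.sum()))
    params = {"mean": mean, "sd": np.where(zero_var, 1.0, sd), "zero_var": zero_var}
    return params, apply_standardization(params, matrix)


def apply_standardization(params: dict, matrix: np.ndarray) -> np.ndarray:
    """Apply training-set scaling parameters to a (possibly new) matrix."""
    matrix = np.asarray(matrix, dtype=float)
    out = (matrix - params["mean"]) / params["sd"]
    out[:, params["zero_var"]] = 0.0
    return out


@dataclass
class DesignSpec:
    """Fitted encoding: continuous columns z-scored with training parameters,
    binary columns passed through as 0/1, categorical columns one-hot encoded
    against the most frequent training level (left unscaled)."""

    feature_names: list[str]
    kinds: dict[str, str]
    cont_params: dict  # standardize() params over the continuous block
    cont_names: list[str]
    binary_names: list[str]
    cat_encodings: dict[str, tuple[str, tuple[str, ...]]]  # name -> (reference, other levels)
    column_names: list[str]

    @classmethod
    def fit(cls, features: pd.DataFrame, catalog: FeatureCatalog) -> "DesignSpec":
        if features.shape[1] == 0 or len(features) == 0:
            raise ValueError("cannot fit a design on an empty feature frame")
        names = list(features.columns)
        kinds = {n: catalog.kind(n) for n in names}
        cont = [n for n in names if kinds[n] == "continuous"]
        binary = [n for n in names if kinds[n] == "binary"]
        cats = [n for n in names if kinds[n] == "categorical"]
        cont_params, _ = (
            standardize(features[cont].to_numpy(dtype=float))
            if cont
            else ({"mean": np.zeros(0), "sd": np.ones(0), "zero_var": np.zeros(0, bool)}, None)
        )
        cat_encodings = {}
        for n in cats:
            counts = features[n].value_counts()
            reference = counts.index[0]
            others = tuple(lv for lv in catalog.levels(n) if lv != reference)
            cat_encodings[n] = (reference, others)
        columns = list(cont) + list(binary)
        for n in cats:
            columns += [f"{n}={lv}" for lv in cat_encodings[n][1]]
        return cls(
            feature_names=names,
            kinds=kinds,
            cont_params=cont_params,
            cont_names=cont,
            binary_names=binary,
            cat_encodings=cat_encodings,
            column_names=columns,
        )

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        blocks = []
        if self.cont_names:
            blocks.append(
                apply_standardization(self.cont_params, features[self.cont_names].to_numpy(dtype=float))
            )
        if self.binary_names:
            blocks.append(features[self.binary_names].to_numpy(dtype=float))
        for n, (_, others) in self.cat_encodings.items():
            col = features[n]
            blocks.append(np.column_stack([(col == lv).to_numpy(dtype=float) for lv in others]) if others else np.zeros((len(features), 0)))
        if not blocks:
            return np.zeros((len(features), 0))
        return np.hstack(blocks)

    # -- JSON round-trip ----------------------------------------------------
    def to_jsonable(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "kinds": self.kinds,
            "cont_params": {
                "mean": self.cont_params["mean"].tolist(),
                "sd": self.cont_params["sd"].tolist(),
                "zero_var": self.cont_params["zero_var"].tolist(),
            },
            "cont_names": self.cont_names,
            "binary_names": self.binary_names,
            "cat_encodings": {k: [v[0], list(v[1])] for k, v in self.cat_encodings.items()},
            "column_names": self.column_names,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "DesignSpec":
        return cls(
            feature_names=list(d["feature_names"]),
            kinds=dict(d["kinds"]),
            cont_params={
                "mean": np.asarray(d["cont_params"]["mean"], dtype=float),
                "sd": np.asarray(d["cont_params"]["sd"], dtype=float),
                "zero_var": np.asarray(d["cont_params"]["zero_var"], dtype=bool),
            },
            cont_names=list(d["cont_names"]),
            binary_names=list(d["binary_names"]),
            cat_encodings={k: (v[0], tuple(v[1])) for k, v in d["cat_encodings"].items()},
            column_names=list(d["column_names"]),
        )
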