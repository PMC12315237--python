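"""Longitudinal cohort ingestion, cleaning, visit merging and splitting.

The unit of analysis is the :class:`ParticipantHistory`: a set of baseline
covariates plus a time-ordered list of visits, each carrying possibly-missing
cognitive scores (MMSE, CDR global), a clinical diagnosis (CN/MCI/DEM) and six
FreeSurfer ROI volumes (five regions plus intracranial volume, ICV).  Time is
expressed throughout as real-valued months since the participant's first
(baseline) visit.

All participant-level splitting (k-fold partitioning, first-half/second-half
splits) lives here so that no downstream stage can leak information across
participants.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered diagnosis codes, mildest first.  The ordering is semantic: CN < MCI
#: < DEM is the severity order used by "best"/"worst"/"milder" features.
DIAGNOSES = ("CN", "MCI", "DEM")
DX_SEVERITY = {dx: i for i, dx in enumerate(DIAGNOSES)}

#: The five ROI volumes that are normalized by ICV.
ROI_NAMES = ("hippocampus", "fusiform", "midtemp", "ventricle", "wholebrain")
#: All raw volumetric columns, including ICV itself.
VOLUME_COLUMNS = ROI_NAMES + ("icv",)

#: Default sentinel integers that some source tables use to code missingness.
DEFAULT_SENTINELS = frozenset({-1, -4, 999})

#: Phenotype columns that sentinel cleaning may touch.  Engineered feature
#: columns (where 999 is a legitimate constant) must never be listed here.
PHENOTYPE_COLUMNS = (
    "age", "education_years", "apoe4_count", "mmse", "cdr_global",
) + VOLUME_COLUMNS

COHORT_COLUMNS = [
    "participant_id", "month", "age", "sex", "education_years", "marital",
    "apoe4_count", "mmse", "cdr_global", "diagnosis",
    "hippocampus", "fusiform", "midtemp", "ventricle", "wholebrain", "icv",
]


class ConfigurationError(ValueError):
    """Raised when a configuration references unknown columns or invalid rates."""


@dataclass(frozen=True)
class BaselineProfile:
    """Time-invariant covariates measured at enrolment."""

    sex: str | None = None            # "male" | "female" | None
    education_years: float | None = None
    marital: str | None = None        # "married" | "not_married" | None
    apoe4_count: int | None = None    # 0 | 1 | 2 | None

    def __post_init__(self) -> None:
        if self.sex not in (None, "male", "female"):
            raise ValueError(f"invalid sex: {self.sex!r}")
        if self.marital not in (None, "married", "not_married"):
            raise ValueError(f"invalid marital status: {self.marital!r}")
        if self.apoe4_count not in (None, 0, 1, 2):
            raise ValueError(f"invalid APOE-e4 count: {self.apoe4_count!r}")


@dataclass(frozen=True)
class VisitRecord:
    """One (possibly incomplete) participant-visit.

    ``roi_volumes`` holds raw volumes in mm^3; ``roi_normalized`` holds the
    five non-ICV volumes divided by ICV (present only when both the raw volume
    and ICV are present).
    """

    participant_id: str
    month: float
    age: float | None = None
    mmse: float | None = None
    cdr_global: float | None = None
    diagnosis: str | None = None
    roi_volumes: dict = field(default_factory=dict)
    roi_normalized: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.month < 0:
            raise ValueError("visit month must be non-negative")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE out of range: {self.mmse}")
        if self.cdr_global is not None and self.cdr_global not in (0, 0.5, 1, 2, 3):
            raise ValueError(f"CDR global not on the 5-level grid: {self.cdr_global}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis code: {self.diagnosis!r}")

    def has_recurring_feature(self) -> bool:
        """True if any recurring feature (cognitive, MRI, diagnosis) is observed."""
        return (
            self.mmse is not None
            or self.cdr_global is not None
            or self.diagnosis is not None
            or any(v is not None for v in self.roi_volumes.values())
        )


@dataclass(frozen=True)
class ParticipantHistory:
    """Baseline covariates plus a strictly time-ordered visit list."""

    participant_id: str
    baseline: BaselineProfile
    visits: tuple

    def __post_init__(self) -> None:
        months = [v.month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit months must be strictly increasing")
        if any(v.participant_id != self.participant_id for v in self.visits):
            raise ValueError("all visits must share the participant id")

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class FoldSplit:
    """One fold of a cyclic k-fold participant partition."""

    fold_index: int
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset

    def __post_init__(self) -> None:
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ValueError("train/val/test id sets must be pairwise disjoint")


# ---------------------------------------------------------------------------
# Table-level cleaning
# ---------------------------------------------------------------------------

def clean_sentinels(
    table: pd.DataFrame,
    sentinel_values: set | frozenset = DEFAULT_SENTINELS,
    columns: tuple | list | None = None,
) -> pd.DataFrame:
    """Replace sentinel integers with NaN in raw phenotype columns.

    Only the configured phenotype columns are touched; engineered feature
    columns (where e.g. 999 is a legitimate constant) are never cleaned.
    Returns a new table with identical shape.
    """
    if columns is None:
        columns = [c for c in PHENOTYPE_COLUMNS if c in table.columns]
    else:
        unknown = [c for c in columns if c not in table.columns]
        if unknown:
            raise ConfigurationError(f"sentinel config references unknown columns: {unknown}")
    out = table.copy()
    sentinels = list(sentinel_values)
    for col in columns:
        out[col] = out[col].where(~out[col].isin(sentinels), np.nan)
    return out


def merge_visits(pheno_rows, mri_rows, window_months: float = 6.0):
    """Merge MRI-only rows into nearby phenotype rows for one participant.

    Each MRI row attaches to the nearest phenotype row within
    ``window_months``; the merged visit keeps the phenotype row's month.  A
    tie (two equidistant phenotype rows) is broken toward the earlier row.
    Unmatched MRI rows become MRI-only visits.  Rows are dicts with a
    ``month`` key plus feature keys.
    """
    pheno = sorted(pheno_rows, key=lambda r: r["month"])
    mris = sorted(mri_rows, key=lambda r: r["month"])
    attached: dict[int, list] = {i: [] for i in range(len(pheno))}
    leftover = []
    for mri in mris:
        best_i, best_d = None, None
        for i, p in enumerate(pheno):
            d = abs(mri["month"] - p["month"])
            if d <= window_months and (best_d is None or d < best_d):
                best_i, best_d = i, d  # strict < keeps the earlier row on ties
        if best_i is None:
            leftover.append(mri)
        else:
            attached[best_i].append(mri)
    merged = []
    for i, p in enumerate(pheno):
        row = dict(p)
        for mri in attached[i]:
            for k, v in mri.items():
                if k == "month" or v is None:
                    continue
                if row.get(k) is None:  # phenotype value wins on conflict
                    row[k] = v
        merged.append(row)
    merged.extend(dict(m) for m in leftover)
    merged.sort(key=lambda r: r["month"])
    return merged


def normalize_by_icv(visit: VisitRecord) -> VisitRecord:
    """Divide each present ROI volume by ICV; missing values propagate."""
    icv = visit.roi_volumes.get("icv")
    if icv is None:
        return replace(visit, roi_normalized={})
    if icv <= 0:
        raise ValueError(f"ICV must be positive, got {icv}")
    normalized = {
        roi: visit.roi_volumes[roi] / icv
        for roi in ROI_NAMES
        if visit.roi_volumes.get(roi) is not None
    }
    return replace(visit, roi_normalized=normalized)


def filter_eligible(cohort):
    """Keep participants with recurring features at two or more time points.

    The recurring features need not co-occur: MRI-only at one visit plus
    cognition-only at another qualifies.  Order-preserving and idempotent.
    """
    return [
        h for h in cohort
        if sum(v.has_recurring_feature() for v in h.visits) >= 2
    ]


MODALITIES = ("cognitive", "mri", "diagnosis")


def blank_modality(visit: VisitRecord, modality: str) -> VisitRecord:
    """Return the visit with one recurring-feature block set to missing."""
    if modality == "cognitive":
        return replace(visit, mmse=None, cdr_global=None)
    if modality == "mri":
        return replace(visit, roi_volumes={}, roi_normalized={})
    if modality == "diagnosis":
        return replace(visit, diagnosis=None)
    raise ValueError(f"unknown modality: {modality}")


# ---------------------------------------------------------------------------
# Participant-level splitting
# ---------------------------------------------------------------------------

def kfold_partition(ids, k: int, seed: int) -> list:
    """Cyclic k-fold participant partition.

    Participants are shuffled once and split into ``k`` partitions; fold ``i``
    uses partition ``i`` as test, partition ``i+1`` (cyclic) as validation and
    the remaining ``k-2`` as training, so test sets are disjoint and jointly
    exhaustive.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    if k < 3:
        raise ValueError("k must be at least 3 (train/val/test roles)")
    if len(ids) < k:
        raise ValueError("need at least k participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    partitions = [
        [ids[j] for j in chunk] for chunk in np.array_split(order, k)
    ]
    folds = []
    for i in range(k):
        test = frozenset(partitions[i])
        val = frozenset(partitions[(i + 1) % k])
        train = frozenset(
            pid for j, part in enumerate(partitions)
            if j not in (i, (i + 1) % k) for pid in part
        )
        folds.append(FoldSplit(i + 1, train, val, test))
    return folds


def split_half(history: ParticipantHistory):
    """First-half/second-half protocol split of one participant's visits.

    The first ``ceil(m/2)`` visits are the observed input; the remainder are
    the unobserved targets.  With 10 visits the first 5 are input.  Odd m
    gives the extra visit to the input side.
    """
    m = history.n_visits
    if m < 2:
        raise ValueError("need at least 2 visits to split")
    n_in = math.ceil(m / 2)
    return history.visits[:n_in], history.visits[n_in:]


# ---------------------------------------------------------------------------
# Tabular round trip
# ---------------------------------------------------------------------------

def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def histories_from_table(table: pd.DataFrame):
    """Build :class:`ParticipantHistory` objects from a tidy visit table.

    Expects one row per participant-visit with the documented column
    dictionary; unknown extra columns are ignored with a logged warning.
    Missing cells are empty/NaN.  ROI volumes are ICV-normalized on load.
    """
    extra = [c for c in table.columns if c not in COHORT_COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns: %s", extra)
    histories = []
    for pid, grp in table.groupby("participant_id", sort=True):
        grp = grp.sort_values("month")
        first = grp.iloc[0]
        apoe = _opt(first.get("apoe4_count"))
        baseline = BaselineProfile(
            sex=_opt(first.get("sex")),
            education_years=_opt(first.get("education_years")),
            marital=_opt(first.get("marital")),
            apoe4_count=int(apoe) if apoe is not None else None,
        )
        visits = []
        for _, row in grp.iterrows():
            volumes = {c: _opt(row.get(c)) for c in VOLUME_COLUMNS}
            visit = VisitRecord(
                participant_id=str(pid),
                month=float(row["month"]),
                age=_opt(row.get("age")),
                mmse=_opt(row.get("mmse")),
                cdr_global=_opt(row.get("cdr_global")),
                diagnosis=_opt(row.get("diagnosis")),
                roi_volumes={k: v for k, v in volumes.items() if v is not None},
            )
            visits.append(normalize_by_icv(visit))
        histories.append(ParticipantHistory(str(pid), baseline, tuple(visits)))
    return histories


def histories_to_table(cohort) -> pd.DataFrame:
    """Inverse of :func:`histories_from_table` (one row per visit)."""
    rows = []
    for h in cohort:
        for v in h.visits:
            row = {
                "participant_id": h.participant_id,
                "month": v.month,
                "age": v.age,
                "sex": h.baseline.sex,
                "education_years": h.baseline.education_years,
                "marital": h.baseline.marital,
                "apoe4_count": h.baseline.apoe4_count,
                "mmse": v.mmse,
                "cdr_global": v.cdr_global,
                "diagnosis": v.diagnosis,
            }
            for c in VOLUME_COLUMNS:
                row[c] = v.roi_volumes.get(c)
            rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> list:
    """Read the documented cohort CSV and return eligible-ready histories."""
    table = pd.read_csv(path)
    return histories_from_table(table)


def write_cohort_csv(cohort, path) -> None:
    histories_to_table(cohort).to_csv(path, index=False)


def save_folds(folds, path) -> None:
    payload = {
        str(f.fold_index): {
            "train": sorted(f.train_ids),
            "val": sorted(f.val_ids),
            "test": sorted(f.test_ids),
        }
        for f in folds
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_folds(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        FoldSplit(int(i), frozenset(d["train"]), frozenset(d["val"]),
                  frozenset(d["test"]))
        for i, d in sorted(payload.items(), key=lambda kv: int(kv[0]))
    ]
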