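"""Longitudinal-to-cross-sectional (L2C) feature engineering.

A participant's variable-length visit history plus a forecast time ``tf`` is
collapsed into a fixed-length named feature vector: each of the 8 continuous
modalities (MMSE, CDR global, five ICV-normalized ROI volumes, ICV) yields 7
temporal summaries (most recent value and its recency, most recent change
rate, historical extremes and their recency) and the categorical diagnosis
yields 8, for 8*7 + 8 = 64 engineered features.  Six covariates (age at
``tf``, sex, education, marital status, APOE-e4 count, months since
baseline) are appended, for 70 named fields in total.

All ``time_since_*`` quantities are measured from ``tf`` in months.  A value
of 999 in ``time_since_milder`` is a semantic sentinel meaning "no strictly
milder diagnosis in history", not a missing value.  Missing fields are NaN.

Training samples are enumerated by the prefix-target augmentation: the first
``p`` visits predict each later visit ``q``, for every ``1 <= p < q <= m``,
giving m(m-1)/2 samples per participant before dropping samples whose target
visit has no observed target variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DX_SEVERITY, ParticipantHistory

NO_MILDER_SENTINEL = 999.0

#: Continuous modalities in fixed order.  ROI entries refer to ICV-normalized
#: volumes; ``icv`` is the raw intracranial volume.
CONTINUOUS_MODALITIES = (
    "mmse", "cdr_global", "hippocampus", "fusiform", "midtemp",
    "ventricle", "wholebrain", "icv",
)

TABLE_PREFIXES = (
    "mr_", "time_since_mr_", "mr_change_",
    "low_", "time_since_low_", "high_", "time_since_high_",
)

DX_FEATURE_NAMES = (
    "mr_dx", "time_since_mr_dx", "best_dx", "time_since_best_dx",
    "worst_dx", "time_since_worst_dx", "milder", "time_since_milder",
)

AUGMENT_FEATURE_NAMES = (
    "age_at_tf", "sex", "education_years", "marital", "apoe4_count",
    "months_since_baseline",
)

ENGINEERED_FEATURE_NAMES = tuple(
    f"{prefix}{mod}" for mod in CONTINUOUS_MODALITIES for prefix in TABLE_PREFIXES
) + DX_FEATURE_NAMES

#: The full 70-field schema, in canonical column order.
FEATURE_NAMES = ENGINEERED_FEATURE_NAMES + AUGMENT_FEATURE_NAMES

#: Columns that downstream preprocessing treats as categorical.
CATEGORICAL_FEATURES = ("mr_dx", "best_dx", "worst_dx", "milder",
                        "sex", "marital", "apoe4_count")

SEX_CODES = {"male": 0.0, "female": 1.0}
MARITAL_CODES = {"not_married": 0.0, "married": 1.0}


def continuous_features(series, tf: float) -> dict:
    """Seven temporal summaries of one continuous modality.

    ``series`` is an iterable of ``(month, value)`` pairs with months strictly
    before ``tf``; an empty series yields all-NaN.  Ties in the historical
    extremes resolve to the most recent occurrence.
    """
    pts = sorted(series, key=lambda p: p[0])
    if any(not math.isfinite(v) for _, v in pts):
        raise ValueError("non-finite value in series")
    if pts and pts[-1][0] >= tf:
        raise ValueError("series months must precede the forecast time")
    out = {p: math.nan for p in TABLE_PREFIXES}
    if not pts:
        return out
    mr_month, mr_value = pts[-1]
    out["mr_"] = mr_value
    out["time_since_mr_"] = tf - mr_month
    if len(pts) >= 2:
        (m0, v0), (m1, v1) = pts[-2], pts[-1]
        out["mr_change_"] = (v1 - v0) / (m1 - m0)
    lo_m, lo_v = pts[0]
    hi_m, hi_v = pts[0]
    for m, v in pts[1:]:
        if v <= lo_v:  # ties -> most recent occurrence
            lo_m, lo_v = m, v
        if v >= hi_v:
            hi_m, hi_v = m, v
    out["low_"] = lo_v
    out["time_since_low_"] = tf - lo_m
    out["high_"] = hi_v
    out["time_since_high_"] = tf - hi_m
    return out


def diagnosis_features(dx_series, tf: float) -> dict:
    """Eight summaries of the categorical diagnosis history.

    Diagnoses are encoded ordinally (CN=0 < MCI=1 < DEM=2).  ``best`` is the
    mildest and ``worst`` the most severe historical diagnosis, each dated by
    its most recent occurrence.  ``milder`` flags any historical diagnosis
    strictly milder than the most recent one; its recency is 999 when no such
    diagnosis exists.  An empty history yields all-NaN.
    """
    pts = sorted(dx_series, key=lambda p: p[0])
    out = {name: math.nan for name in DX_FEATURE_NAMES}
    if not pts:
        return out
    if pts[-1][0] >= tf:
        raise ValueError("diagnosis months must precede the forecast time")
    try:
        coded = [(m, DX_SEVERITY[dx]) for m, dx in pts]
    except KeyError as exc:
        raise ValueError(f"unknown diagnosis code: {exc.args[0]!r}") from None
    mr_month, mr_sev = coded[-1]
    out["mr_dx"] = float(mr_sev)
    out["time_since_mr_dx"] = tf - mr_month
    best_m, best_s = coded[0]
    worst_m, worst_s = coded[0]
    for m, s in coded[1:]:
        if s <= best_s:
            best_m, best_s = m, s
        if s >= worst_s:
            worst_m, worst_s = m, s
    out["best_dx"] = float(best_s)
    out["time_since_best_dx"] = tf - best_m
    out["worst_dx"] = float(worst_s)
    out["time_since_worst_dx"] = tf - worst_m
    milder_months = [m for m, s in coded if s < mr_sev]
    if milder_months:
        out["milder"] = 1.0
        out["time_since_milder"] = tf - max(milder_months)
    else:
        out["milder"] = 0.0
        out["time_since_milder"] = NO_MILDER_SENTINEL
    return out


def _modality_series(visits, modality: str):
    series = []
    for v in visits:
        if modality == "mmse":
            value = v.mmse
        elif modality == "cdr_global":
            value = v.cdr_global
        elif modality == "icv":
            value = v.roi_volumes.get("icv")
        else:
            value = v.roi_normalized.get(modality)
        if value is not None:
            series.append((v.month, float(value)))
    return series


def assemble_features(history: ParticipantHistory, tf: float,
                      input_visits=None) -> dict:
    """Full 70-field L2C vector for one (history, forecast time) pair.

    ``input_visits`` restricts the observed history (defaults to all visits);
    ``tf`` must lie strictly after the last input visit.  Age at ``tf`` is
    extrapolated linearly from the last observed age.
    """
    visits = history.visits if input_visits is None else tuple(input_visits)
    if not visits:
        raise ValueError("history has no input visits")
    if tf <= visits[-1].month:
        raise ValueError("forecast time must be after the last input visit")

    out = {}
    for mod in CONTINUOUS_MODALITIES:
        feats = continuous_features(_modality_series(visits, mod), tf)
        for prefix in TABLE_PREFIXES:
            out[f"{prefix}{mod}"] = feats[prefix]
    dx_series = [(v.month, v.diagnosis) for v in visits if v.diagnosis is not None]
    out.update(diagnosis_features(dx_series, tf))

    ages = [(v.month, v.age) for v in visits if v.age is not None]
    if ages:
        last_m, last_age = ages[-1]
        out["age_at_tf"] = last_age + (tf - last_m) / 12.0
    else:
        out["age_at_tf"] = math.nan
    b = history.baseline
    out["sex"] = SEX_CODES.get(b.sex, math.nan)
    out["education_years"] = (math.nan if b.education_years is None
                              else float(b.education_years))
    out["marital"] = MARITAL_CODES.get(b.marital, math.nan)
    out["apoe4_count"] = math.nan if b.apoe4_count is None else float(b.apoe4_count)
    out["months_since_baseline"] = tf - visits[0].month
    return out


@dataclass(frozen=True)
class TrainingSample:
    """One L2C vector with its forecast-month targets.

    At least one of the three targets (ordinal diagnosis, MMSE,
    ICV-normalized ventricle volume) is observed; ``task_mask`` records
    which, in (diagnosis, mmse, ventricle) order.
    """

    participant_id: str
    features: dict
    target_month: float
    last_input_month: float
    diagnosis: float | None
    mmse: float | None
    ventricle_icv: float | None

    @property
    def task_mask(self) -> tuple:
        return (self.diagnosis is not None, self.mmse is not None,
                self.ventricle_icv is not None)

    @property
    def gap_months(self) -> float:
        return self.target_month - self.last_input_month


def _targets_of(visit):
    dx = None if visit.diagnosis is None else float(DX_SEVERITY[visit.diagnosis])
    mmse = None if visit.mmse is None else float(visit.mmse)
    vent = visit.roi_normalized.get("ventricle")
    return dx, mmse, (None if vent is None else float(vent))


def augment_training_samples(history: ParticipantHistory,
                             max_prefix: int | None = None):
    """Enumerate prefix-to-later-visit training samples for one participant.

    Every prefix of length ``p`` (1..m-1) predicts every later visit ``q``;
    m(m-1)/2 candidate samples, minus those whose target visit carries no
    observed target variable.  ``max_prefix`` optionally caps the prefix
    length (used when truncating input histories).
    """
    m = history.n_visits
    if m < 2:
        raise ValueError("need at least 2 visits to augment")
    p_max = m - 1 if max_prefix is None else min(max_prefix, m - 1)
    samples = []
    for p in range(1, p_max + 1):
        prefix = history.visits[:p]
        for q in range(p, m):
            target = history.visits[q]
            if target.month <= prefix[-1].month:
                continue
            dx, mmse, vent = _targets_of(target)
            if dx is None and mmse is None and vent is None:
                continue
            samples.append(TrainingSample(
                participant_id=history.participant_id,
                features=assemble_features(history, target.month, prefix),
                target_month=target.month,
                last_input_month=prefix[-1].month,
                diagnosis=dx, mmse=mmse, ventricle_icv=vent,
            ))
    return samples


def features_to_frame(feature_dicts) -> pd.DataFrame:
    """Stack feature dicts into a design matrix with canonical column order."""
    df = pd.DataFrame(list(feature_dicts), columns=list(FEATURE_NAMES))
    return df.astype(float)


def samples_to_frame(samples) -> tuple:
    """Design matrix plus a target frame for a list of training samples."""
    X = features_to_frame(s.features for s in samples)
    y = pd.DataFrame({
        "participant_id": [s.participant_id for s in samples],
        "target_month": [s.target_month for s in samples],
        "gap_months": [s.gap_months for s in samples],
        "diagnosis": [np.nan if s.diagnosis is None else s.diagnosis for s in samples],
        "mmse": [np.nan if s.mmse is None else s.mmse for s in samples],
        "ventricle_icv": [np.nan if s.ventricle_icv is None else s.ventricle_icv
                          for s in samples],
    })
    return X, y
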