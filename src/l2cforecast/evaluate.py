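"""Metrics, statistical tests and the fold-level experiment harness.

Diagnosis accuracy is the pooled multiclass AUC (mAUC): predictions are
pooled over all test participants and forecast time points, and the mAUC is
the mean of the three one-vs-rest two-class AUCs (CN vs not, MCI vs not,
DEM vs not).  MMSE and ventricle accuracy are mean absolute errors averaged
within each participant first, giving one value per test participant.

Cross-validated performance differences between models are assessed with the
corrected resampled t-test (variance inflated by 1/k + rho to account for
overlapping training sets); pooled mAUC differences with a permutation test
that swaps the two models' probability rows per time point; per-participant
MAE vectors with a paired t-test.  Multiple comparisons use Benjamini-
Hochberg FDR.

The harness trains a model variant per cyclic fold, forecasts each test
participant's second-half visits from their first half, and emits tidy
per-fold reports, optionally stratified by forecast-horizon year, by the
last input diagnosis, by the number of input time points, and by modality
ablation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .cohort import (
    MODALITIES,
    ParticipantHistory,
    blank_modality,
    filter_eligible,
    kfold_partition,
    split_half,
)
from .features import augment_training_samples
from .models import (
    FNNConfig,
    ForecastGrid,
    ModelBundle,
    default_window_spec,
    forecast_monthly,
    make_carry_forward,
    train_fnn,
    train_xgb,
)

logger = logging.getLogger(__name__)

DX_NAMES = ("CN", "MCI", "DEM")


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MetricReport:
    """Pooled mAUC plus per-participant-averaged regression errors."""

    mauc: float
    mmse_mae: float
    ventricle_mae: float
    mmse_rmse: float
    ventricle_rmse: float
    n_participants: int
    n_timepoints: int
    labels: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    k: int | None = None
    n_perm: int | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Forecast-truth matching
# ---------------------------------------------------------------------------

def match_forecasts(grid: ForecastGrid, target_visits):
    """Pair each target visit with the nearest grid month (ties -> earlier).

    Visits beyond the grid horizon are excluded and counted.  Returns
    ``(pairs, n_excluded)`` where each pair is ``(prediction, visit)``.
    """
    if len(grid.months) == 0:
        raise ValueError("empty forecast grid")
    pairs = []
    n_excluded = 0
    horizon_end = grid.months[-1] + 0.5
    for visit in target_visits:
        if visit.month >= horizon_end:
            n_excluded += 1
            continue
        idx = int(np.argmin(np.abs(grid.months - visit.month)))
        pairs.append((grid.predictions[idx], visit))
    if n_excluded:
        logger.warning("%d target visits beyond forecast horizon", n_excluded)
    return pairs, n_excluded


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mauc(diag_probs, true_dx) -> float:
    """Pooled multiclass AUC: mean of the one-vs-rest two-class AUCs.

    ``diag_probs`` is (n, 3) over (CN, MCI, DEM); ``true_dx`` holds ordinal
    codes 0/1/2 (NaN rows are excluded).  Classes without both a positive
    and a negative example are skipped with a log message; if no class is
    computable an :class:`EvaluationError` is raised.
    """
    probs = np.asarray(diag_probs, dtype=float)
    truth = np.asarray(true_dx, dtype=float)
    rows = np.isfinite(truth) & np.all(np.isfinite(probs), axis=1)
    probs, truth = probs[rows], truth[rows]
    aucs = []
    for c in (0, 1, 2):
        positives = truth == c
        if positives.any() and (~positives).any():
            aucs.append(roc_auc_score(positives, probs[:, c]))
        else:
            logger.info("class %s absent from pooled truth; skipped", DX_NAMES[c])
    if not aucs:
        raise EvaluationError("no class with both positive and negative examples")
    return float(np.mean(aucs))


def mae_by_participant(frame: pd.DataFrame, truth_col: str, pred_col: str):
    """Per-participant MAE/RMSE, then averaged across participants.

    ``frame`` has one row per matched (prediction, truth) pair with a
    ``participant_id`` column.  Participants without any observed truth (or
    available prediction) for the variable are excluded and counted.
    Returns a dict with the per-participant vectors and their summaries.
    """
    ok = frame[truth_col].notna() & frame[pred_col].notna()
    sub = frame[ok]
    per_mae = sub.groupby("participant_id").apply(
        lambda g: float(np.mean(np.abs(g[pred_col] - g[truth_col]))),
        include_groups=False)
    per_rmse = sub.groupby("participant_id").apply(
        lambda g: float(np.sqrt(np.mean((g[pred_col] - g[truth_col]) ** 2))),
        include_groups=False)
    n_excluded = frame["participant_id"].nunique() - per_mae.size
    return {
        "per_participant_mae": per_mae,
        "per_participant_rmse": per_rmse,
        "mae": float(per_mae.mean()) if per_mae.size else math.nan,
        "mae_sd": float(per_mae.std(ddof=1)) if per_mae.size > 1 else math.nan,
        "rmse": float(per_rmse.mean()) if per_rmse.size else math.nan,
        "n_participants": int(per_mae.size),
        "n_excluded": int(n_excluded),
    }


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def corrected_resampled_ttest(per_fold_diffs, rho: float = 1.0 / 19.0) -> TestResult:
    """Corrected resampled t-test for k-fold performance differences.

    ``t = mean(d) / sqrt((1/k + rho) * var(d))`` with the unbiased sample
    variance, referred to Student's t with k-1 degrees of freedom.  ``rho``
    defaults to test/train fraction 1/19 of the cyclic 20-partition design;
    ``rho=0`` recovers the classical one-sample t-test.
    """
    d = np.asarray(per_fold_diffs, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 folds")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0:
        if mean == 0:
            return TestResult(0.0, 1.0, "corrected_resampled_t", k=k, rho=rho)
        logger.warning("zero variance with nonzero mean; reporting p=0")
        return TestResult(math.copysign(math.inf, mean), 0.0,
                          "corrected_resampled_t", k=k, rho=rho)
    t = mean / math.sqrt((1.0 / k + rho) * var)
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return TestResult(float(t), float(p), "corrected_resampled_t", k=k, rho=rho)


def paired_ttest(values_a, values_b) -> TestResult:
    """Paired t-test over per-participant metrics of two models."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p), "paired_t", k=a.size)


def permutation_test_mauc(probs_a, probs_b, true_dx, n_perm: int = 1000,
                          seed: int = 0) -> TestResult:
    """Permutation test for a pooled-mAUC difference between two models.

    The null swaps the two models' probability rows independently per time
    point with probability 1/2 and recomputes |mAUC_A - mAUC_B|;
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    truth = np.asarray(true_dx, dtype=float)
    if pa.shape != pb.shape or pa.shape[0] != truth.size:
        raise ValueError("the two models' prediction sets must match")
    observed = abs(mauc(pa, truth) - mauc(pb, truth))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        swap = rng.random(pa.shape[0]) < 0.5
        qa = np.where(swap[:, None], pb, pa)
        qb = np.where(swap[:, None], pa, pb)
        if abs(mauc(qa, truth) - mauc(qb, truth)) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return TestResult(float(observed), float(p), "permutation", n_perm=n_perm)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# Stratifications
# ---------------------------------------------------------------------------

def bin_by_horizon(last_input_month: float, target_month: float) -> int:
    """Yearly horizon bin of one forecast: bin ``ceil(gap/12)`` capped at 6.

    A 10-month gap is "1 year into the future"; exact 12-month multiples
    belong to the lower bin.
    """
    gap = target_month - last_input_month
    if gap <= 0:
        raise ValueError("target must lie after the last input time point")
    return min(math.ceil(gap / 12.0), 6)


def subgroup_by_last_dx(input_visits_by_pid: dict):
    """Group participants by the last observed diagnosis among input visits.

    Participants with no observed input diagnosis are excluded and counted.
    Returns ``(groups, n_excluded)`` with groups mapping pid -> CN/MCI/DEM.
    """
    groups = {}
    n_excluded = 0
    for pid, visits in input_visits_by_pid.items():
        dxs = [v.diagnosis for v in visits if v.diagnosis is not None]
        if dxs:
            groups[pid] = dxs[-1]
        else:
            n_excluded += 1
    return groups, n_excluded


def has_full_feature_set(input_visits) -> bool:
    """True if every recurring feature is observed at least once in the input."""
    has_mmse = any(v.mmse is not None for v in input_visits)
    has_cdr = any(v.cdr_global is not None for v in input_visits)
    has_dx = any(v.diagnosis is not None for v in input_visits)
    vols = ("hippocampus", "fusiform", "midtemp", "ventricle", "wholebrain", "icv")
    has_rois = all(
        any(v.roi_volumes.get(r) is not None for v in input_visits) for r in vols
    )
    return has_mmse and has_cdr and has_dx and has_rois


def ablate_modality(history: ParticipantHistory, modality: str, n_input: int,
                    ) -> ParticipantHistory:
    """Blank one modality at every input visit; target visits untouched."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality: {modality}")
    new_visits = tuple(
        blank_modality(v, modality) if i < n_input else v
        for i, v in enumerate(history.visits)
    )
    return replace(history, visits=new_visits)


def feature_importance_by_ablation(reports: dict) -> pd.DataFrame:
    """Performance deltas of each ablation scenario against the full set.

    ``reports`` maps scenario name ("full", "mri", "cognitive", "diagnosis")
    to a :class:`MetricReport` on the same participant set.  Deltas are
    oriented so positive means degradation.
    """
    if "full" not in reports:
        raise ValueError("reports must include the 'full' scenario")
    full = reports["full"]
    n_ref = full.n_participants
    rows = []
    for scenario, rep in reports.items():
        if scenario == "full":
            continue
        if rep.n_participants != n_ref:
            raise ValueError("ablation scenarios must share the participant set")
        rows.append({"modality": scenario, "target": "diagnosis",
                     "delta": full.mauc - rep.mauc})
        rows.append({"modality": scenario, "target": "mmse",
                     "delta": rep.mmse_mae - full.mmse_mae})
        rows.append({"modality": scenario, "target": "ventricle",
                     "delta": rep.ventricle_mae - full.ventricle_mae})
    return pd.DataFrame(rows, columns=["modality", "target", "delta"])


# ---------------------------------------------------------------------------
# Fold-level harness
# ---------------------------------------------------------------------------

def _pool_predictions(bundle: ModelBundle, items, horizon: int) -> pd.DataFrame:
    """Forecast and match each participant's target visits; tidy pooled rows."""
    rows = []
    for history, input_visits, target_visits in items:
        if not target_visits:
            continue
        last = input_visits[-1].month
        needed = max(v.month for v in target_visits) - last
        h = max(1, min(horizon, int(math.ceil(needed))))
        grid = forecast_monthly(bundle, history, h, input_visits)
        pairs, _ = match_forecasts(grid, target_visits)
        for pred, visit in pairs:
            probs = pred.diag_probs or (np.nan, np.nan, np.nan)
            rows.append({
                "participant_id": history.participant_id,
                "month": visit.month,
                "gap": visit.month - last,
                "horizon_bin": bin_by_horizon(last, visit.month),
                "p_cn": probs[0], "p_mci": probs[1], "p_dem": probs[2],
                "pred_mmse": pred.mmse,
                "pred_ventricle": pred.ventricle_icv,
                "true_dx": (np.nan if visit.diagnosis is None
                            else float(DX_NAMES.index(visit.diagnosis))),
                "true_mmse": np.nan if visit.mmse is None else float(visit.mmse),
                "true_ventricle": visit.roi_normalized.get("ventricle", np.nan),
            })
    return pd.DataFrame(rows)


def compute_report(pooled: pd.DataFrame, **labels) -> MetricReport:
    """Metric report from pooled matched pairs (one row per pair)."""
    if pooled.empty:
        raise EvaluationError("no matched forecast-truth pairs")
    probs = pooled[["p_cn", "p_mci", "p_dem"]].to_numpy(dtype=float)
    truth = pooled["true_dx"].to_numpy(dtype=float)
    try:
        pooled_mauc = mauc(probs, truth)
    except EvaluationError:
        pooled_mauc = math.nan
    mmse = mae_by_participant(pooled, "true_mmse", "pred_mmse")
    vent = mae_by_participant(pooled, "true_ventricle", "pred_ventricle")
    dx_avail = np.isfinite(truth) & np.all(np.isfinite(probs), axis=1)
    coverage = {
        "diagnosis": float(dx_avail.sum()) / max(np.isfinite(truth).sum(), 1),
        "mmse_excluded": mmse["n_excluded"],
        "ventricle_excluded": vent["n_excluded"],
    }
    return MetricReport(
        mauc=pooled_mauc,
        mmse_mae=mmse["mae"], ventricle_mae=vent["mae"],
        mmse_rmse=mmse["rmse"], ventricle_rmse=vent["rmse"],
        n_participants=int(pooled["participant_id"].nunique()),
        n_timepoints=int(len(pooled)),
        labels=dict(labels), coverage=coverage,
    )


def _train_variant(variant: str, train_samples, seed: int,
                   fnn_config: FNNConfig | None, xgb_hp: dict | None) -> ModelBundle:
    if variant == "fnn":
        cfg = fnn_config or FNNConfig(seed=seed)
        return train_fnn(train_samples, cfg)
    if variant == "xgb_nw":
        return train_xgb(train_samples, xgb_hp, windows=None, seed=seed)
    if variant == "xgb_w":
        return train_xgb(train_samples, xgb_hp, windows=default_window_spec(),
                         seed=seed)
    if variant == "carry_forward":
        return make_carry_forward(train_samples)
    raise ValueError(f"unknown variant: {variant}")


def _report_row(report: MetricReport, fold: int, analysis: str, stratum) -> dict:
    return {
        "fold": fold, "analysis": analysis, "stratum": str(stratum),
        "mauc": report.mauc, "mmse_mae": report.mmse_mae,
        "ventricle_mae": report.ventricle_mae,
        "mmse_rmse": report.mmse_rmse, "ventricle_rmse": report.ventricle_rmse,
        "n_participants": report.n_participants,
        "n_timepoints": report.n_timepoints,
    }


VALID_ANALYSES = ("main", "horizon", "n_input_timepoints", "subgroup",
                  "ablation", "importance")


def run_experiment(cohort, variant: str, k: int = 20, seed: int = 0,
                   analyses=("main",), horizon: int = 120,
                   fnn_config: FNNConfig | None = None,
                   xgb_hp: dict | None = None) -> pd.DataFrame:
    """Cyclic k-fold experiment: train per fold, forecast second halves.

    Returns a tidy frame with one row per fold x analysis x stratum.  The
    ``n_input_timepoints`` analysis truncates test inputs to 1..4 visits,
    keeping only participants whose observed input half has at least 4
    visits so the same participants appear in all four conditions; the
    ``ablation``/``importance`` analyses restrict to participants whose
    input half observes every recurring feature at least once.
    """
    unknown = set(analyses) - set(VALID_ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    eligible = filter_eligible(cohort)
    by_id = {h.participant_id: h for h in eligible}
    folds = kfold_partition(sorted(by_id), k=k, seed=seed)
    rows = []
    for fold in folds:
        if not fold.test_ids:
            raise EvaluationError(f"fold {fold.fold_index} has an empty test set")
        train_samples = []
        for pid in sorted(fold.train_ids):
            train_samples.extend(augment_training_samples(by_id[pid]))
        bundle = _train_variant(variant, train_samples,
                                seed=seed * 1000 + fold.fold_index,
                                fnn_config=fnn_config, xgb_hp=xgb_hp)

        items = []
        for pid in sorted(fold.test_ids):
            history = by_id[pid]
            input_visits, target_visits = split_half(history)
            items.append((history, input_visits, target_visits))
        pooled = _pool_predictions(bundle, items, horizon)

        if "main" in analyses:
            rows.append(_report_row(compute_report(pooled), fold.fold_index,
                                    "main", "all"))
        if "horizon" in analyses:
            for year, grp in pooled.groupby("horizon_bin"):
                rows.append(_report_row(compute_report(grp), fold.fold_index,
                                        "horizon", int(year)))
        if "subgroup" in analyses:
            inputs = {h.participant_id: iv for h, iv, _ in items}
            groups, _ = subgroup_by_last_dx(inputs)
            for dx in DX_NAMES:
                pids = [p for p, g in groups.items() if g == dx]
                grp = pooled[pooled["participant_id"].isin(pids)]
                if not grp.empty:
                    rows.append(_report_row(compute_report(grp),
                                            fold.fold_index, "subgroup", dx))
        if "n_input_timepoints" in analyses:
            kept = [(h, iv, tv) for h, iv, tv in items if len(iv) >= 4]
            for n_in in (1, 2, 3, 4):
                truncated = [(h, iv[:n_in], tv) for h, iv, tv in kept]
                sub = _pool_predictions(bundle, truncated, horizon)
                if not sub.empty:
                    rows.append(_report_row(
                        compute_report(sub), fold.fold_index,
                        "n_input_timepoints", n_in))
        if "ablation" in analyses or "importance" in analyses:
            full_items = [(h, iv, tv) for h, iv, tv in items
                          if has_full_feature_set(iv)]
            scenario_reports = {}
            if full_items:
                scenario_reports["full"] = compute_report(
                    _pool_predictions(bundle, full_items, horizon))
                for modality in MODALITIES:
                    ab_items = []
                    for h, iv, tv in full_items:
                        ab_history = ablate_modality(h, modality, len(iv))
                        ab_items.append((ab_history,
                                         ab_history.visits[:len(iv)], tv))
                    scenario_reports[modality] = compute_report(
                        _pool_predictions(bundle, ab_items, horizon))
            if "ablation" in analyses:
                for scenario, rep in scenario_reports.items():
                    rows.append(_report_row(rep, fold.fold_index, "ablation",
                                            scenario))
            if "importance" in analyses and scenario_reports:
                deltas = feature_importance_by_ablation(scenario_reports)
                for _, d in deltas.iterrows():
                    row = _report_row(scenario_reports[d["modality"]],
                                      fold.fold_index, "importance",
                                      f"{d['target']}-{d['modality']}")
                    row["delta"] = d["delta"]
                    rows.append(row)
    return pd.DataFrame(rows)


def compare_fold_metrics(reports_a: pd.DataFrame, reports_b: pd.DataFrame,
                         metric: str, rho: float = 1.0 / 19.0) -> TestResult:
    """Corrected resampled t-test on per-fold metric differences (A - B)."""
    a = reports_a.query("analysis == 'main'").sort_values("fold")[metric]
    b = reports_b.query("analysis == 'main'").sort_values("fold")[metric]
    return corrected_resampled_ttest(a.to_numpy() - b.to_numpy(), rho=rho)
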