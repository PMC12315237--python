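"""Forecasters over L2C features and the open-horizon prediction loop.

Four model variants share one prediction interface:

``fnn``
    A multi-task feedforward network: one body, a five-unit head whose first
    three outputs are softmax diagnosis probabilities (CN, MCI, DEM) and
    whose last two are MMSE and ICV-normalized ventricle volume on the
    Gauss-Rank scale.  Per-sample loss is cross-entropy plus two MAE terms,
    each masked by target availability and summed with equal weights;
    optimization is SGD with momentum and an exponentially decaying learning
    rate.  Implemented directly in numpy so training is bit-reproducible
    from a seed.
``xgb_nw``
    One XGBoost estimator per target variable (3-class classifier for
    diagnosis, regressors for MMSE and ventricle volume), trained on all
    forecast gaps jointly.  No imputation or normalization: the tree learner
    consumes NaN natively.
``xgb_w``
    The window-stratified variant: a separate XGBoost estimator per
    (target, forecast-gap window), 15 in total.  The gap is the time since
    the most recent observed measurement of the target variable, and the
    same gap selects the window at training and prediction time.
``carry_forward``
    Last-observation-carried-forward baseline: probability one on the most
    recent diagnosis, last observed MMSE/ventricle value, training medians
    when never observed.

A separate utility converts a predicted CDR global score into diagnosis
probabilities by piecewise-linear interpolation between the anchors
CDR 0 = CN, CDR 0.5 = MCI, CDR >= 1 = DEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .cohort import ParticipantHistory
from .features import FEATURE_NAMES, features_to_frame, samples_to_frame
from .preprocess import PreprocessState, fit_preprocess

TARGETS = ("diagnosis", "mmse", "ventricle")

#: Feature carrying the forecast gap for each target variable.
GAP_FEATURE = {
    "diagnosis": "time_since_mr_dx",
    "mmse": "time_since_mr_mmse",
    "ventricle": "time_since_mr_ventricle",
}


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Forecast windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Per-target ordered forecast-gap intervals in months, [lo, hi)."""

    intervals: dict

    def __post_init__(self) -> None:
        for target, spans in self.intervals.items():
            for (lo, hi), (lo2, _) in zip(spans, spans[1:]):
                if hi > lo2:
                    raise ValueError(f"overlapping windows for {target}")
            if any(lo >= hi for lo, hi in spans):
                raise ValueError(f"empty window for {target}")

    @property
    def n_models(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def default_window_spec() -> WindowSpec:
    """Gap windows of the original windowed submission (months).

    MMSE leaves (39, 54) uncovered; gaps in the hole route to the adjacent
    27-39 model (nearest lower boundary).
    """
    inf = math.inf
    return WindowSpec(intervals={
        "mmse": ((0, 9), (9, 15), (15, 27), (27, 39), (54, inf)),
        "diagnosis": ((0, 8), (8, 15), (15, 27), (27, 39), (39, 60), (60, inf)),
        "ventricle": ((0, 9), (9, 15), (15, 30), (30, inf)),
    })


def select_window(gap_months: float, target: str, windows: WindowSpec):
    """Index of the window containing ``gap_months`` (closed-left, open-right).

    Gaps falling in an uncovered hole route to the interval with the nearest
    lower boundary.  Returns None when the gap is undefined (NaN: the target
    was never observed), in which case no model is selectable.
    """
    if gap_months is None or (isinstance(gap_months, float) and math.isnan(gap_months)):
        return None
    if gap_months < 0:
        raise ValueError("forecast gap must be non-negative")
    spans = windows.intervals[target]
    for i, (lo, hi) in enumerate(spans):
        if lo <= gap_months < hi:
            return i
    below = [i for i, (_, hi) in enumerate(spans) if hi <= gap_months]
    return max(below)


# ---------------------------------------------------------------------------
# CDR-to-diagnosis conversion
# ---------------------------------------------------------------------------

def cdr_to_diag_probs(cdr: float) -> np.ndarray:
    """Convert a (possibly fractional) CDR global score into (CN, MCI, DEM).

    Piecewise-linear between the anchors CDR 0 -> CN, 0.5 -> MCI and
    CDR >= 1 -> DEM; e.g. CDR 0.1 gives (0.8, 0.2, 0.0) and CDR 0.6 gives
    (0.0, 0.8, 0.2).  Negative scores clip to 0.
    """
    if not math.isfinite(cdr):
        raise ValueError("CDR score must be finite")
    c = max(float(cdr), 0.0)
    if c <= 0.5:
        w = c / 0.5
        return np.array([1.0 - w, w, 0.0])
    if c <= 1.0:
        w = (c - 0.5) / 0.5
        return np.array([0.0, 1.0 - w, w])
    return np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Model bundle and predictions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    """One forecast at month ``month`` (months since participant baseline).

    ``diag_probs`` is a (CN, MCI, DEM) simplex vector; any field may be None
    when the variant cannot produce it (windowed models with a
    never-observed target modality).
    """

    month: float
    diag_probs: tuple | None
    mmse: float | None
    ventricle_icv: float | None

    def __post_init__(self) -> None:
        if self.diag_probs is not None:
            p = np.asarray(self.diag_probs)
            if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("diag_probs must be a probability 3-vector")


EXPECTED_COUNTS = {"fnn": 1, "xgb_nw": 3, "xgb_w": 15, "carry_forward": 0}


@dataclass
class ModelBundle:
    """A trained forecaster plus its frozen preprocessing state."""

    variant: str
    estimators: dict
    preprocess: PreprocessState | None = None
    windows: WindowSpec | None = None
    config: object = None
    seed: int = 0
    medians: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in EXPECTED_COUNTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        expected = EXPECTED_COUNTS[self.variant]
        if self.variant == "xgb_w" and self.windows is not None:
            expected = self.windows.n_models
        if len(self.estimators) != expected:
            raise ValueError(
                f"{self.variant} bundle must hold {expected} estimators, "
                f"got {len(self.estimators)}")

    @property
    def n_estimators(self) -> int:
        return len(self.estimators)


# ---------------------------------------------------------------------------
# Numpy feedforward network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FNNConfig:
    """Multi-task network hyperparameters (search ranges in parentheses)."""

    n_hidden_layers: int = 3        # 2-5
    hidden_size: int = 128          # 128-512
    dropout: float = 0.1            # 0-0.5
    leaky_slope: float = 0.05       # 0.01-0.1
    l2_weight: float = 1e-6         # 1e-7-1e-4
    momentum: float = 0.9           # 0-0.9
    learning_rate: float = 0.05     # 1e-5-1e-1
    lr_gamma: float = 0.9           # 0.1-0.9
    epochs: int = 100
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (2 <= self.n_hidden_layers <= 5, "n_hidden_layers in 2-5"),
            (128 <= self.hidden_size <= 512, "hidden_size in 128-512"),
            (0 <= self.dropout <= 0.5, "dropout in 0-0.5"),
            (0.01 <= self.leaky_slope <= 0.1, "leaky_slope in 0.01-0.1"),
            (1e-7 <= self.l2_weight <= 1e-4, "l2_weight in 1e-7-1e-4"),
            (0 <= self.momentum <= 0.9, "momentum in 0-0.9"),
            (1e-5 <= self.learning_rate <= 1e-1, "learning_rate in 1e-5-1e-1"),
            (0.1 <= self.lr_gamma <= 0.9, "lr_gamma in 0.1-0.9"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"hyperparameter outside search range: {msg}")


def _leaky(z, slope):
    return np.where(z > 0, z, slope * z)


def _leaky_grad(z, slope):
    return np.where(z > 0, 1.0, slope)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FeedforwardNet:
    """Plain numpy MLP with a 5-unit multi-task head."""

    N_OUT = 5

    def __init__(self, n_inputs: int, config: FNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = ([n_inputs] + [config.hidden_size] * config.n_hidden_layers
                 + [self.N_OUT])
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes, sizes[1:])
        ]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self.n_inputs = n_inputs
        self.loss_history: list = []

    def forward(self, X: np.ndarray, rng=None):
        """Return (output, caches); dropout is active only when rng is given."""
        cfg = self.config
        a = X
        caches = []
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if i < len(self.weights) - 1:
                h = _leaky(z, cfg.leaky_slope)
                if rng is not None and cfg.dropout > 0:
                    keep = 1.0 - cfg.dropout
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                else:
                    mask = None
                caches.append((a, z, mask))
                a = h
            else:
                caches.append((a, z, None))
                a = z
        return a, caches

    def loss_and_grads(self, X, dx, mmse_z, vent_z, rng):
        """Masked multi-task loss and parameter gradients on one batch.

        ``dx`` holds class indices with -1 for missing; the regression
        targets are NaN where missing.  Each sample contributes its
        cross-entropy term plus the two MAE terms (Gauss-Rank scale), masked
        by availability and equally weighted; the batch loss is the mean.
        """
        n = X.shape[0]
        out, caches = self.forward(X, rng=rng)
        dout = np.zeros_like(out)
        loss = 0.0

        mask_d = dx >= 0
        if mask_d.any():
            probs = _softmax(out[mask_d, :3])
            rows = np.arange(mask_d.sum())
            loss += -np.log(probs[rows, dx[mask_d]] + 1e-12).sum()
            grad = probs.copy()
            grad[rows, dx[mask_d]] -= 1.0
            dout[mask_d, :3] = grad
        for col, target in ((3, mmse_z), (4, vent_z)):
            mask = np.isfinite(target)
            if mask.any():
                diff = out[mask, col] - target[mask]
                loss += np.abs(diff).sum()
                dout[mask, col] = np.sign(diff)
        loss /= n
        dout /= n

        grads_W, grads_b = [], []
        delta = dout
        cfg = self.config
        for i in range(len(self.weights) - 1, -1, -1):
            a_in, z, mask = caches[i]
            gW = a_in.T @ delta + cfg.l2_weight * self.weights[i]
            gb = delta.sum(axis=0)
            grads_W.insert(0, gW)
            grads_b.insert(0, gb)
            if i > 0:
                delta = delta @ self.weights[i].T
                _, z_prev, mask_prev = caches[i - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * _leaky_grad(z_prev, cfg.leaky_slope)
        return loss, grads_W, grads_b

    def fit(self, X, dx, mmse_z, vent_z):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        vel_W = [np.zeros_like(W) for W in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            lr = cfg.learning_rate * cfg.lr_gamma ** epoch
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, gW, gb = self.loss_and_grads(
                    X[idx], dx[idx], mmse_z[idx], vent_z[idx], rng)
                for i in range(len(self.weights)):
                    vel_W[i] = cfg.momentum * vel_W[i] - lr * gW[i]
                    vel_b[i] = cfg.momentum * vel_b[i] - lr * gb[i]
                    self.weights[i] += vel_W[i]
                    self.biases[i] += vel_b[i]
                epoch_loss += loss
                n_batches += 1
            self.loss_history.append(epoch_loss / max(n_batches, 1))
        return self

    def predict(self, X: np.ndarray):
        out, _ = self.forward(X, rng=None)
        probs = _softmax(out[:, :3])
        return probs, out[:, 3], out[:, 4]


# ---------------------------------------------------------------------------
# Training entry points
# ---------------------------------------------------------------------------

def train_fnn(samples, config: FNNConfig | None = None,
              state: PreprocessState | None = None) -> ModelBundle:
    """Train the multi-task network on augmented training samples."""
    config = config or FNNConfig()
    X, y = samples_to_frame(samples)
    if not ((y["diagnosis"].notna() | y["mmse"].notna()
             | y["ventricle_icv"].notna()).any()):
        raise TrainingError("no sample with any observed target")
    if state is None:
        state = fit_preprocess(
            X, targets=y[["mmse", "ventricle_icv"]].rename(
                columns={"ventricle_icv": "ventricle"}))
    Xt = state.transform(X)
    dx = y["diagnosis"].fillna(-1).to_numpy(dtype=int)
    mmse_z = np.where(y["mmse"].notna(),
                      state.encode_target("mmse", y["mmse"].fillna(0.0)), np.nan)
    vent_z = np.where(y["ventricle_icv"].notna(),
                      state.encode_target("ventricle", y["ventricle_icv"].fillna(0.0)),
                      np.nan)
    net = FeedforwardNet(Xt.shape[1], config).fit(Xt, dx, mmse_z, vent_z)
    medians = _target_medians(y)
    return ModelBundle(variant="fnn", estimators={"fnn": net}, preprocess=state,
                       config=config, seed=config.seed, medians=medians,
                       info={"final_loss": net.loss_history[-1]})


DEFAULT_XGB_HP = {"max_depth": 4, "subsample": 0.8, "learning_rate": 0.1,
                  "n_estimators": 100}


def _check_xgb_hp(hp: dict) -> dict:
    hp = {**DEFAULT_XGB_HP, **(hp or {})}
    if not 3 <= hp["max_depth"] <= 8:
        raise ValueError("max_depth outside 3-8")
    if not 0.4 <= hp["subsample"] <= 1.0:
        raise ValueError("subsample outside 0.4-1")
    if not 0.01 <= hp["learning_rate"] <= 0.2:
        raise ValueError("learning_rate outside 0.01-0.2")
    return hp


def _make_estimator(target: str, hp: dict, seed: int):
    common = dict(max_depth=hp["max_depth"], subsample=hp["subsample"],
                  learning_rate=hp["learning_rate"],
                  n_estimators=hp["n_estimators"], tree_method="hist",
                  random_state=seed, n_jobs=1)
    if target == "diagnosis":
        return xgb.XGBClassifier(**common)
    return xgb.XGBRegressor(objective="reg:squarederror", **common)


def _fit_classifier(est, X, labels):
    """Fit with labels re-encoded to 0..k-1 (window cells may miss a class)."""
    classes, encoded = np.unique(labels.astype(int), return_inverse=True)
    if classes.size < 2:
        # Degenerate single-class cell: remember the constant outcome.
        est._dx_classes = classes
        est._dx_constant = True
        return est
    est.fit(X, encoded)
    est._dx_classes = classes
    est._dx_constant = False
    return est


def train_xgb(samples, hp: dict | None = None, windows: WindowSpec | None = None,
              seed: int = 0) -> ModelBundle:
    """Train gradient-boosted forecasters, optionally window-stratified.

    With ``windows=None`` one estimator per target is fit on all gaps
    (``xgb_nw``); with a :class:`WindowSpec`, one estimator per
    (target, window) cell is fit only on samples whose forecast gap falls in
    the window (``xgb_w``).  Missing feature values pass through to the tree
    learner untouched.
    """
    hp = _check_xgb_hp(hp)
    X, y = samples_to_frame(samples)
    Xv = X.to_numpy(dtype=float)
    estimators = {}
    for target in TARGETS:
        label_col = "diagnosis" if target == "diagnosis" else (
            "mmse" if target == "mmse" else "ventricle_icv")
        labels = y[label_col].to_numpy(dtype=float)
        observed = np.isfinite(labels)
        if windows is None:
            est = _make_estimator(target, hp, seed)
            if target == "diagnosis":
                _fit_classifier(est, Xv[observed], labels[observed])
            else:
                est.fit(Xv[observed], labels[observed])
            estimators[target] = est
        else:
            gaps = X[GAP_FEATURE[target]].to_numpy(dtype=float)
            assigned = np.array([
                select_window(g, target, windows) if np.isfinite(g) else -1
                for g in gaps
            ])
            for w in range(len(windows.intervals[target])):
                rows = observed & (assigned == w)
                if not rows.any():
                    lo, hi = windows.intervals[target][w]
                    raise TrainingError(
                        f"no training samples for {target} window [{lo}, {hi})")
                est = _make_estimator(target, hp, seed + w)
                if target == "diagnosis":
                    _fit_classifier(est, Xv[rows], labels[rows])
                else:
                    est.fit(Xv[rows], labels[rows])
                estimators[(target, w)] = est
    variant = "xgb_nw" if windows is None else "xgb_w"
    return ModelBundle(variant=variant, estimators=estimators, windows=windows,
                       config=hp, seed=seed, medians=_target_medians(y))


def _target_medians(y: pd.DataFrame) -> dict:
    return {
        "mmse": float(np.nanmedian(y["mmse"])) if y["mmse"].notna().any() else 15.0,
        "ventricle": (float(np.nanmedian(y["ventricle_icv"]))
                      if y["ventricle_icv"].notna().any() else 0.02),
    }


def make_carry_forward(samples=None) -> ModelBundle:
    """Last-observation-carried-forward baseline bundle."""
    medians = {"mmse": 15.0, "ventricle": 0.02}
    if samples:
        _, y = samples_to_frame(samples)
        medians = _target_medians(y)
    return ModelBundle(variant="carry_forward", estimators={}, medians=medians)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _scatter_probs(est, X: np.ndarray) -> np.ndarray:
    """Class probabilities expanded onto the fixed (CN, MCI, DEM) axes."""
    classes = np.asarray(est._dx_classes, dtype=int)
    out = np.zeros((X.shape[0], 3))
    if getattr(est, "_dx_constant", False):
        out[:, classes[0]] = 1.0
        return out
    out[:, classes] = est.predict_proba(X)
    return out


def predict_bundle(bundle: ModelBundle, X: pd.DataFrame, months) -> list:
    """Predict all three targets for each row of an L2C feature frame."""
    months = np.asarray(months, dtype=float)
    n = len(X)
    if n != months.size:
        raise ValueError("months must align with feature rows")
    probs = np.full((n, 3), np.nan)
    mmse = np.full(n, np.nan)
    vent = np.full(n, np.nan)

    if bundle.variant == "fnn":
        state = bundle.preprocess
        Xt = state.transform(X)
        if Xt.shape[1] != bundle.estimators["fnn"].n_inputs:
            raise ValueError("feature arity mismatch with preprocessing state")
        probs, mmse_z, vent_z = bundle.estimators["fnn"].predict(Xt)
        mmse = state.decode_target("mmse", mmse_z)
        vent = state.decode_target("ventricle", vent_z)
    elif bundle.variant == "xgb_nw":
        Xv = X.to_numpy(dtype=float)
        probs = _scatter_probs(bundle.estimators["diagnosis"], Xv)
        mmse = bundle.estimators["mmse"].predict(Xv)
        vent = bundle.estimators["ventricle"].predict(Xv)
    elif bundle.variant == "xgb_w":
        Xv = X.to_numpy(dtype=float)
        for target in TARGETS:
            gaps = X[GAP_FEATURE[target]].to_numpy(dtype=float)
            assigned = np.array([
                select_window(g, target, bundle.windows) if np.isfinite(g) else -1
                for g in gaps
            ])
            for w in np.unique(assigned):
                if w < 0:
                    continue  # target never observed: prediction unavailable
                rows = assigned == w
                est = bundle.estimators[(target, int(w))]
                if target == "diagnosis":
                    probs[rows] = _scatter_probs(est, Xv[rows])
                elif target == "mmse":
                    mmse[rows] = est.predict(Xv[rows])
                else:
                    vent[rows] = est.predict(Xv[rows])
    elif bundle.variant == "carry_forward":
        mr_dx = X["mr_dx"].to_numpy(dtype=float)
        probs = np.full((n, 3), 1.0 / 3.0)
        for c in (0, 1, 2):
            rows = mr_dx == c
            probs[rows] = 0.0
            probs[rows, c] = 1.0
        mmse = np.where(np.isfinite(X["mr_mmse"]), X["mr_mmse"],
                        bundle.medians["mmse"])
        vent = np.where(np.isfinite(X["mr_ventricle"]), X["mr_ventricle"],
                        bundle.medians["ventricle"])

    mmse = np.clip(mmse, 0.0, 30.0)
    vent = np.clip(vent, 0.0, None)
    preds = []
    for i in range(n):
        p = probs[i]
        diag = None if not np.all(np.isfinite(p)) else tuple(p / p.sum())
        preds.append(Prediction(
            month=float(months[i]),
            diag_probs=diag,
            mmse=float(mmse[i]) if np.isfinite(mmse[i]) else None,
            ventricle_icv=float(vent[i]) if np.isfinite(vent[i]) else None,
        ))
    return preds


@dataclass(frozen=True)
class ForecastGrid:
    """Monthly open-horizon forecasts for one participant."""

    participant_id: str
    months: np.ndarray
    predictions: tuple

    def __post_init__(self) -> None:
        if len(self.months) != len(self.predictions):
            raise ValueError("months and predictions must align")
        if np.any(np.diff(self.months) <= 0):
            raise ValueError("grid months must be strictly increasing")


def forecast_at(bundle: ModelBundle, history: ParticipantHistory, tf_months,
                input_visits=None) -> list:
    """Predict at arbitrary forecast times (months since baseline)."""
    from .features import assemble_features
    visits = history.visits if input_visits is None else tuple(input_visits)
    rows = [assemble_features(history, tf, visits) for tf in tf_months]
    X = features_to_frame(rows)
    return predict_bundle(bundle, X, tf_months)


def forecast_monthly(bundle: ModelBundle, history: ParticipantHistory,
                     horizon_months: int = 120, input_visits=None) -> ForecastGrid:
    """Monthly forecasts for months 1..H after the last input visit."""
    if horizon_months < 1:
        raise ValueError("horizon must be at least 1 month")
    visits = history.visits if input_visits is None else tuple(input_visits)
    last = visits[-1].month
    months = last + np.arange(1, horizon_months + 1, dtype=float)
    preds = forecast_at(bundle, history, months, visits)
    return ForecastGrid(history.participant_id, months, tuple(preds))


def grid_to_frame(grid: ForecastGrid) -> pd.DataFrame:
    """Tidy monthly forecast rows (one row per month)."""
    rows = []
    for m, p in zip(grid.months, grid.predictions):
        probs = p.diag_probs or (np.nan, np.nan, np.nan)
        rows.append({
            "participant_id": grid.participant_id, "month": m,
            "p_cn": probs[0], "p_mci": probs[1], "p_dem": probs[2],
            "mmse": p.mmse, "ventricle_icv": p.ventricle_icv,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hyperparameter search (plain random search over the documented ranges)
# ---------------------------------------------------------------------------

def random_search_xgb(train_samples, val_samples, n_trials: int = 20,
                      windows: WindowSpec | None = None, seed: int = 0):
    """Random search over the gradient-boosting ranges, scored on validation.

    The score is validation diagnosis accuracy-style mAUC plus negative
    normalized MAEs, equally weighted.
    """
    rng = np.random.default_rng(seed)
    best_hp, best_score = None, -np.inf
    for trial in range(n_trials):
        hp = {
            "max_depth": int(rng.integers(3, 9)),
            "subsample": float(rng.uniform(0.4, 1.0)),
            "learning_rate": float(np.exp(rng.uniform(np.log(0.01), np.log(0.2)))),
            "n_estimators": 100,
        }
        bundle = train_xgb(train_samples, hp, windows=windows,
                           seed=int(rng.integers(0, 2**31)))
        score = _validation_score(bundle, val_samples)
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, best_score


def _validation_score(bundle: ModelBundle, val_samples) -> float:
    from sklearn.metrics import roc_auc_score
    X, y = samples_to_frame(val_samples)
    preds = predict_bundle(bundle, X, y["target_month"].to_numpy())
    dx_true = y["diagnosis"].to_numpy(dtype=float)
    probs = np.array([p.diag_probs if p.diag_probs is not None
                      else (np.nan,) * 3 for p in preds])
    score = 0.0
    rows = np.isfinite(dx_true) & np.all(np.isfinite(probs), axis=1)
    aucs = []
    for c in (0, 1, 2):
        yc = dx_true[rows] == c
        if yc.any() and (~yc).any():
            aucs.append(roc_auc_score(yc, probs[rows, c]))
    if aucs:
        score += float(np.mean(aucs))
    for attr, name, scale in (("mmse", "mmse", 30.0),
                              ("ventricle_icv", "ventricle_icv", 0.05)):
        truth = y[name].to_numpy(dtype=float)
        pred = np.array([getattr(p, attr) if getattr(p, attr) is not None
                         else np.nan for p in preds])
        rows = np.isfinite(truth) & np.isfinite(pred)
        if rows.any():
            score -= float(np.mean(np.abs(pred[rows] - truth[rows]))) / scale
    return score
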