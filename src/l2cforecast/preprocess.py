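"""Fit-on-train / apply-on-test preprocessing for the neural forecaster.

Tree ensembles consume the raw 70-field L2C frame (XGBoost handles NaN
natively), but the feedforward network is sensitive to input scale and
missingness, so its path applies, in order:

1. drop features configured as too-missing (by default the 999-sentinel
   ``time_since_milder`` recency feature);
2. median imputation of numeric features, medians computed on training rows
   only;
3. Gauss-Rank normalization: the empirical distribution of each numeric
   feature is mapped onto a standard Gaussian via averaged ranks,
   ``rank r of n -> Phi^-1((r - 0.5)/n)``, with linear interpolation between
   knots and clipping outside the training range;
4. one-hot encoding of discrete features over the training vocabulary plus
   an explicit "unknown" class that absorbs missing and unseen values.

Regression targets get their own Gauss-Rank maps (losses are computed on the
Gaussian scale; predictions are inverse-mapped before metrics).  Every
statistic is computed from training rows only and frozen in a
:class:`PreprocessState` that serializes to JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import ConfigurationError
from .features import CATEGORICAL_FEATURES, FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_DROP = ("time_since_milder",)
UNKNOWN = "__unknown__"


@dataclass(frozen=True)
class QuantileMap:
    """Invertible rank-to-Gaussian map of one feature.

    Knots are the deduplicated sorted training values paired with the
    Gaussian scores of their averaged ranks; between knots the map is linear,
    outside the training range it clips to the extreme scores.
    """

    values: np.ndarray
    scores: np.ndarray

    @classmethod
    def fit(cls, train_values, name: str = "") -> "QuantileMap":
        x = np.asarray(train_values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need at least 2 finite values to fit a quantile map")
        ranks = rankdata(x, method="average")
        scores = norm.ppf((ranks - 0.5) / x.size)
        order = np.argsort(x, kind="stable")
        xs, ss = x[order], scores[order]
        # Deduplicate: tied values share an averaged rank, hence one knot.
        uniq, idx = np.unique(xs, return_index=True)
        knots_y = ss[idx]
        if uniq.size == 1:
            warnings.warn(f"constant column {name!r}: Gauss-Rank map degenerates to 0")
            return cls(values=uniq, scores=np.zeros(1))
        return cls(values=uniq, scores=knots_y)

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.values.size == 1:
            out = np.zeros_like(v)
            out[~np.isfinite(v)] = np.nan
            return out
        return np.interp(v, self.values, self.scores)

    def inverse(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if self.values.size == 1:
            return np.full_like(s, self.values[0])
        return np.interp(s, self.scores, self.values)


def fit_gauss_rank(train_values, name: str = "") -> QuantileMap:
    return QuantileMap.fit(train_values, name)


def apply_gauss_rank(qmap: QuantileMap, values) -> np.ndarray:
    return qmap.apply(values)


def inverse_gauss_rank(qmap: QuantileMap, scores) -> np.ndarray:
    return qmap.inverse(scores)


def impute_median(values, train_median: float) -> np.ndarray:
    """Replace missing entries with the training median (observed untouched)."""
    v = np.asarray(values, dtype=float).copy()
    v[~np.isfinite(v)] = train_median
    return v


def encode_discrete(value, vocabulary) -> np.ndarray:
    """One-hot indicator over ``vocabulary + [unknown]``.

    Missing (NaN/None) and unseen values map to the unknown class; exactly
    one indicator is set.
    """
    vec = np.zeros(len(vocabulary) + 1)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        vec[-1] = 1.0
        return vec
    try:
        vec[list(vocabulary).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


@dataclass
class PreprocessState:
    """Frozen preprocessing statistics of one training fold."""

    numeric_features: list
    categorical_features: list
    dropped: list
    medians: dict = field(default_factory=dict)
    quantile_maps: dict = field(default_factory=dict)
    vocabularies: dict = field(default_factory=dict)
    target_maps: dict = field(default_factory=dict)

    # -- fitting -----------------------------------------------------------
    @classmethod
    def fit(cls, X: pd.DataFrame, targets: pd.DataFrame | None = None,
            drop: tuple = DEFAULT_DROP) -> "PreprocessState":
        dropped = [c for c in drop if c in X.columns]
        categorical = [c for c in CATEGORICAL_FEATURES
                       if c in X.columns and c not in dropped]
        numeric = [c for c in X.columns
                   if c not in categorical and c not in dropped]
        state = cls(numeric_features=numeric, categorical_features=categorical,
                    dropped=dropped)
        for col in numeric:
            vals = X[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                raise ConfigurationError(f"column {col!r} is entirely missing in training data")
            med = float(np.median(finite))
            state.medians[col] = med
            state.quantile_maps[col] = QuantileMap.fit(impute_median(vals, med), col)
        for col in categorical:
            vals = X[col].to_numpy(dtype=float)
            vocab = sorted(float(v) for v in np.unique(vals[np.isfinite(vals)]))
            state.vocabularies[col] = vocab
        if targets is not None:
            for col in targets.columns:
                vals = targets[col].to_numpy(dtype=float)
                if np.isfinite(vals).sum() >= 2:
                    state.target_maps[col] = QuantileMap.fit(vals, f"target:{col}")
        return state

    # -- applying ----------------------------------------------------------
    @property
    def output_names(self) -> list:
        names = list(self.numeric_features)
        for col in self.categorical_features:
            names.extend(f"{col}={v:g}" for v in self.vocabularies[col])
            names.append(f"{col}={UNKNOWN}")
        return names

    @property
    def width(self) -> int:
        return len(self.output_names)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Encode a feature frame into the fixed-width numeric design matrix."""
        blocks = []
        for col in self.numeric_features:
            vals = impute_median(X[col].to_numpy(dtype=float), self.medians[col])
            blocks.append(self.quantile_maps[col].apply(vals)[:, None])
        for col in self.categorical_features:
            vocab = self.vocabularies[col]
            raw = X[col].to_numpy(dtype=float)
            onehot = np.zeros((len(raw), len(vocab) + 1))
            for j, v in enumerate(vocab):
                onehot[:, j] = raw == v
            onehot[:, -1] = onehot[:, :-1].sum(axis=1) == 0
            blocks.append(onehot)
        return np.hstack(blocks) if blocks else np.empty((len(X), 0))

    def encode_target(self, name: str, values) -> np.ndarray:
        return self.target_maps[name].apply(values)

    def decode_target(self, name: str, scores) -> np.ndarray:
        return self.target_maps[name].inverse(scores)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "version": 1,
            "numeric_features": self.numeric_features,
            "categorical_features": self.categorical_features,
            "dropped": self.dropped,
            "medians": self.medians,
            "vocabularies": self.vocabularies,
            "quantile_maps": {
                k: {"values": m.values.tolist(), "scores": m.scores.tolist()}
                for k, m in self.quantile_maps.items()
            },
            "target_maps": {
                k: {"values": m.values.tolist(), "scores": m.scores.tolist()}
                for k, m in self.target_maps.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        payload = json.loads(text)
        state = cls(
            numeric_features=payload["numeric_features"],
            categorical_features=payload["categorical_features"],
            dropped=payload["dropped"],
            medians={k: float(v) for k, v in payload["medians"].items()},
            vocabularies={k: [float(x) for x in v]
                          for k, v in payload["vocabularies"].items()},
        )
        for attr in ("quantile_maps", "target_maps"):
            for k, m in payload[attr].items():
                getattr(state, attr)[k] = QuantileMap(
                    values=np.asarray(m["values"]), scores=np.asarray(m["scores"]))
        return state


def drop_high_missing(X: pd.DataFrame, drop_list=DEFAULT_DROP) -> pd.DataFrame:
    """Remove configured high-missingness columns (neural path only)."""
    return X.drop(columns=[c for c in drop_list if c in X.columns])


def fit_preprocess(X: pd.DataFrame, targets: pd.DataFrame | None = None,
                   drop: tuple = DEFAULT_DROP) -> PreprocessState:
    """Convenience wrapper used by the FNN training path."""
    missing = [c for c in FEATURE_NAMES if c not in X.columns]
    if missing:
        raise ValueError(f"feature frame missing columns: {missing[:5]}...")
    return PreprocessState.fit(X, targets=targets, drop=drop)
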