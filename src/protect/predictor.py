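"""Random-forest classifier with backward elimination and GDF-guided merging.

Feature selection has two stages.  Backward elimination recursively drops the
least-important module-level feature and keeps the smallest feature set whose
cross-validated AUC stays within a tolerance of the best.  Directional merging
asks, for each (module_a -> module_b, module_b -> module_a) feature pair,
whether collapsing the two directions into one un-directional feature lowers a
relaxed AIC whose complexity term is the generalized degrees of freedom (GDF)
of the forest -- the aggregate sensitivity of fitted values to label flips.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_matrix import BASE_COLUMNS
from .ppi_modules import ModuleFeatureCatalog

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500


@dataclass
class GDFEstimate:
    gdf: float
    n_perturb_draws: int
    perturb_fraction: float
    seed: int


@dataclass
class MergeDecision:
    feature_a: str
    feature_b: str
    merged: bool
    aic_directional: float
    aic_merged: float


@dataclass
class ModelBundle:
    """A fitted forest plus the metadata needed to reapply it elsewhere."""

    model: RandomForestClassifier
    feature_names: list[str]
    n_trees: int
    seed: int
    merge_decisions: list[MergeDecision] = field(default_factory=list)
    elimination_trace: list[tuple[str, float]] = field(default_factory=list)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"format_version": 1, "bundle": self}, fh)

    @staticmethod
    def load(path: str) -> "ModelBundle":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unrecognized model bundle format")
        return payload["bundle"]


def fit(
    features: pd.DataFrame,
    labels: Sequence[int],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ModelBundle:
    """Fit a random forest on the feature matrix; deterministic under seed."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(features.to_numpy(), y)
    return ModelBundle(model=model, feature_names=list(features.columns),
                       n_trees=n_trees, seed=seed)


def predict_scores(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Positive-class probabilities, name-aligned to the training columns."""
    missing = set(bundle.feature_names) - set(features.columns)
    extra = set(features.columns) - set(bundle.feature_names)
    if missing or extra:
        raise ValueError(
            f"feature columns mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    X = features[bundle.feature_names].to_numpy()
    pos = list(bundle.model.classes_).index(1)
    return bundle.model.predict_proba(X)[:, pos]


def feature_importances(bundle: ModelBundle) -> pd.Series:
    return pd.Series(bundle.model.feature_importances_, index=bundle.feature_names)


def estimate_gdf(
    fit_fn: Callable[[pd.DataFrame, np.ndarray], np.ndarray],
    features: pd.DataFrame,
    labels: Sequence[int],
    perturb_fraction: float = 0.2,
    n_draws: int = 10,
    seed: int = 0,
) -> GDFEstimate:
    """Generalized degrees of freedom by simultaneous label perturbation.

    Per draw, a random ``perturb_fraction`` of rows have their binary labels
    inverted; ``fit_fn`` refits on the perturbed labels and returns fitted
    values for all rows.  The draw's GDF is
    ``sum_i (yhat'_i - yhat_i) / (y'_i - y_i)`` over the perturbed rows, and
    the estimate is the mean over draws.  A label-independent predictor gives
    0; a label-memorizing one gives the number of perturbed rows.
    """
    if not 0.0 < perturb_fraction < 1.0:
        raise ValueError("perturb_fraction must be in (0, 1)")
    y = np.asarray(labels, dtype=float)
    n = len(y)
    n_perturb = max(1, int(round(perturb_fraction * n)))
    rng = np.random.default_rng(seed)
    yhat = np.asarray(fit_fn(features, y.astype(int)), dtype=float)
    draws = []
    for _ in range(n_draws):
        idx = rng.choice(n, size=n_perturb, replace=False)
        y_pert = y.copy()
        y_pert[idx] = 1.0 - y_pert[idx]
        yhat_pert = np.asarray(fit_fn(features, y_pert.astype(int)), dtype=float)
        delta_y = y_pert[idx] - y[idx]  # +-1, never 0
        draws.append(float(np.sum((yhat_pert[idx] - yhat[idx]) / delta_y)))
    return GDFEstimate(gdf=float(np.mean(draws)), n_perturb_draws=n_draws,
                       perturb_fraction=perturb_fraction, seed=seed)


def relaxed_aic(l_m: float, gdf: float, n: int) -> float:
    """``AIC = -2 l_m + 2 GDF + GDF (GDF + 1) / (N - GDF - 1)``."""
    if n <= gdf + 1:
        raise ValueError(f"N={n} must exceed gdf+1={gdf + 1}")
    return -2.0 * l_m + 2.0 * gdf + gdf * (gdf + 1.0) / (n - gdf - 1.0)


def _forest_fit_fn(n_trees: int, seed: int) -> Callable:
    def fn(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
        if len(np.unique(y)) < 2:
            return np.full(len(y), float(y[0]))
        bundle = fit(X, y, n_trees=n_trees, seed=seed)
        return predict_scores(bundle, X)
    return fn


def cv_log_likelihood(
    features: pd.DataFrame,
    labels: Sequence[int],
    cv_splitter,
    n_trees: int = 100,
    seed: int = 0,
) -> float:
    """Out-of-fold Bernoulli log-likelihood summed over the held-out rows.

    This is the goodness-of-fit term used in the relaxed AIC: its natural
    scale (O(N)) matches the GDF complexity penalty, so fit differences and
    complexity differences are commensurable.  Forest probabilities are
    Laplace-smoothed (``(p*T + 0.5)/(T + 1)`` for T trees) to keep single
    held-out rows from dominating through log(0).
    """
    y = np.asarray(labels)
    ll = 0.0
    for train_idx, test_idx in cv_splitter.split(features, y):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            continue
        bundle = fit(features.iloc[train_idx], y_tr, n_trees=n_trees, seed=seed)
        p = predict_scores(bundle, features.iloc[test_idx])
        p = (p * n_trees + 0.5) / (n_trees + 1)
        y_te = y[test_idx]
        ll += float(np.sum(y_te * np.log(p) + (1 - y_te) * np.log(1 - p)))
    return ll


def cv_r_squared(
    features: pd.DataFrame,
    labels: Sequence[int],
    cv_splitter,
    n_trees: int = 100,
    seed: int = 0,
) -> float:
    """Goodness-of-fit l_m: mean squared Pearson correlation between held-out
    predicted probabilities and 0/1 labels across the splitter's folds."""
    y = np.asarray(labels)
    r2s = []
    for train_idx, test_idx in cv_splitter.split(features, y):
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            continue
        bundle = fit(features.iloc[train_idx], y_tr, n_trees=n_trees, seed=seed)
        scores = predict_scores(bundle, features.iloc[test_idx])
        if np.std(scores) == 0:
            r2s.append(0.0)
        else:
            r = np.corrcoef(scores, y_te)[0, 1]
            r2s.append(float(r**2) if np.isfinite(r) else 0.0)
    return float(np.mean(r2s)) if r2s else 0.0


def model_relaxed_aic(
    features: pd.DataFrame,
    labels: Sequence[int],
    cv_splitter,
    n_trees: int = 100,
    seed: int = 0,
    gdf_draws: int = 10,
    goodness: str = "loglik",
) -> float:
    """Relaxed AIC of one forest model.

    ``goodness`` selects the l_m flavor: "loglik" (default, out-of-fold
    Bernoulli log-likelihood, commensurable with the GDF penalty) or "r2"
    (mean squared Pearson correlation between held-out probability and
    label).
    """
    if goodness == "loglik":
        l_m = cv_log_likelihood(features, labels, cv_splitter, n_trees=n_trees, seed=seed)
    elif goodness == "r2":
        l_m = cv_r_squared(features, labels, cv_splitter, n_trees=n_trees, seed=seed)
    else:
        raise ValueError(f"unknown goodness flavor {goodness!r}")
    gdf = estimate_gdf(_forest_fit_fn(n_trees, seed), features, labels,
                       n_draws=gdf_draws, seed=seed).gdf
    n = len(features)
    gdf = min(max(gdf, 0.0), n - 2)  # keep the AIC penalty finite
    return relaxed_aic(l_m, gdf, n)


def merge_directional(
    features: pd.DataFrame,
    labels: Sequence[int],
    catalog: ModuleFeatureCatalog,
    cv_splitter,
    n_trees: int = 100,
    seed: int = 0,
    gdf_draws: int = 10,
) -> tuple[pd.DataFrame, list[MergeDecision]]:
    """Merge directional feature pairs whose un-directional variant has
    smaller relaxed AIC.

    Each pair is evaluated independently against the otherwise-full model;
    accepted merges are applied simultaneously at the end.  The merged column
    is the elementwise maximum of its two parents and is named ``a~b``.
    """
    decisions: list[MergeDecision] = []
    pairs = [
        (a, b) for a, b in catalog.directional_pairs()
        if a in features.columns and b in features.columns
    ]
    for a, b in pairs:
        merged_col = features[[a, b]].max(axis=1)
        feats_merged = features.drop(columns=[a, b])
        feats_merged[f"{a}~{b}"] = merged_col
        aic_dir = model_relaxed_aic(features, labels, cv_splitter,
                                    n_trees=n_trees, seed=seed, gdf_draws=gdf_draws)
        aic_mrg = model_relaxed_aic(feats_merged, labels, cv_splitter,
                                    n_trees=n_trees, seed=seed, gdf_draws=gdf_draws)
        decisions.append(MergeDecision(
            feature_a=a, feature_b=b, merged=bool(aic_mrg < aic_dir),
            aic_directional=aic_dir, aic_merged=aic_mrg,
        ))
    out = features.copy()
    for d in decisions:
        if d.merged:
            merged_col = out[[d.feature_a, d.feature_b]].max(axis=1)
            out = out.drop(columns=[d.feature_a, d.feature_b])
            out[f"{d.feature_a}~{d.feature_b}"] = merged_col
    return out, decisions


def backward_eliminate(
    features: pd.DataFrame,
    labels: Sequence[int],
    cv_splitter,
    cv_score_fn: Callable[[pd.DataFrame], float],
    tolerance: float = 0.005,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Recursively drop the least-important module-level feature.

    Activity and distance columns are exempt.  Returns the smallest feature
    set whose CV AUC (per ``cv_score_fn``) is within ``tolerance`` of the best
    AUC seen along the elimination path, plus the (dropped_feature, auc) trace.
    """
    y = np.asarray(labels)
    protected = [c for c in features.columns if c in BASE_COLUMNS]
    current = list(features.columns)
    history: list[tuple[list[str], float]] = []
    trace: list[tuple[str, float]] = []
    while True:
        X = features[current]
        auc = cv_score_fn(X)
        history.append((list(current), auc))
        eliminable = [c for c in current if c not in protected]
        if len(eliminable) <= 1:
            break
        bundle = fit(X, y, n_trees=n_trees, seed=seed)
        imp = feature_importances(bundle)
        worst = imp.loc[eliminable].idxmin()
        trace.append((worst, auc))
        current.remove(worst)
    best_auc = max(a for _, a in history)
    selected = history[-1][0]
    for feats, auc in reversed(history):
        if auc >= best_auc - tolerance:
            selected = feats
            break
    return selected, trace
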