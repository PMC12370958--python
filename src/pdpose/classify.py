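"""Clip-level PD classifier, per-animal PD score (APS), gait classifier.

Modelled after the statsmodels fit workflow: a model object is built from a
feature table plus binary labels, ``fit()`` trains the tree ensemble on a
class-balanced, stratified split and returns a results object carrying the
selected features, held-out validation metrics, per-animal scores and exact
additive (TreeSHAP) attributions.

The clip classifier is a gradient-boosted tree ensemble (XGBoost) on the 30
selected kinematic features at a 7:3 split; the gait classifier is a
randomised-tree ensemble (Extra Trees) on 20 selected per-stride features
at a 6:4 split. The per-animal PD score is the percentage of that animal's
clips (or steps) classified as PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             matthews_corrcoef, precision_score, recall_score)
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

__all__ = [
    "ApsResult",
    "AttributionTable",
    "balance_classes",
    "balance_and_split",
    "select_features",
    "ClipClassifierModel",
    "GaitClassifierModel",
    "ClassifierResults",
    "health_status",
]

STATUS_BINS = ((0.0, 25.0, "NP"), (25.0, 75.0, "mild"), (75.0, 100.0, "severe"))


def health_status(aps: float) -> str:
    """Health-status bin of an APS value: [0,25) NP, [25,75) mild, [75,100] severe."""
    if not 0.0 <= aps <= 100.0:
        raise ValueError("APS must be in [0, 100]")
    if aps < 25.0:
        return "NP"
    if aps < 75.0:
        return "mild"
    return "severe"


@dataclass(frozen=True)
class ApsResult:
    mouse_id: str
    aps: float          # percent of clips classified PD, [0, 100]
    status: str         # NP / mild / severe
    n_clips: int


@dataclass
class AttributionTable:
    """Per-clip signed additive attributions in log-odds."""

    values: pd.DataFrame       # clips x features
    base_value: float
    margins: np.ndarray        # model raw margin per clip

    @property
    def additivity_residual(self) -> float:
        """max |base + sum(attributions) - margin| over clips."""
        total = self.base_value + self.values.sum(axis=1).to_numpy()
        return float(np.max(np.abs(total - self.margins)))

    def ranking(self) -> pd.Series:
        """Features ranked by global mean |attribution|, descending."""
        return self.values.abs().mean().sort_values(ascending=False)


def balance_classes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices downsampling the majority class to the minority count."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def balance_and_split(X: pd.DataFrame, y: np.ndarray, ratio=(7, 3), seed=0,
                      groups: np.ndarray | None = None):
    """Balance classes by downsampling, then stratified-split at ``ratio``.

    With ``groups`` (animal ids) the split is by whole animal instead
    (unseen-animal evaluation mode). Returns (X_tr, X_va, y_tr, y_va).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    keep = balance_classes(y, rng)
    Xb, yb = X.iloc[keep], y[keep]
    test_frac = ratio[1] / sum(ratio)
    if groups is not None:
        gb = np.asarray(groups)[keep]
        uniq = np.unique(gb)
        n_va = max(1, int(round(test_frac * len(uniq))))
        va_mice = rng.choice(uniq, n_va, replace=False)
        mask = np.isin(gb, va_mice)
        return Xb[~mask], Xb[mask], yb[~mask], yb[mask]
    return train_test_split(Xb, yb, test_size=test_frac, stratify=yb,
                            random_state=int(seed) % (2 ** 31))


def select_features(X: pd.DataFrame, y: np.ndarray, k: int, seed=0,
                    var_tol: float = 1e-12, corr_max: float = 0.95) -> list[str]:
    """Pick the k most impactful features.

    Near-zero-variance columns are dropped, then highly collinear pairs
    (|r| > 0.95, first kept), then the survivors are ranked by mean
    |TreeSHAP attribution| of a preliminary gradient-boosted fit.
    """
    variances = X.var()
    cols = [c for c in X.columns if variances[c] > var_tol]
    corr = np.nan_to_num(X[cols].corr().abs().to_numpy())
    keep, keep_idx = [], []
    for i, c in enumerate(cols):
        if all(corr[i, j] <= corr_max for j in keep_idx):
            keep.append(c)
            keep_idx.append(i)
    if len(keep) < k:
        raise ValueError(f"only {len(keep)} eligible features for k={k}")
    model = XGBClassifier(random_state=int(seed) % (2 ** 31), n_jobs=1,
                          tree_method="hist")
    model.fit(X[keep], y)
    contribs = model.get_booster().predict(
        _dmatrix(X[keep]), pred_contribs=True)[:, :-1]
    impact = pd.Series(np.abs(contribs).mean(axis=0), index=keep)
    return impact.sort_values(ascending=False).index[:k].tolist()


def _dmatrix(X: pd.DataFrame):
    import xgboost as xgb
    return xgb.DMatrix(X, feature_names=list(X.columns))


def _metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "kappa": float(cohen_kappa_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
    }


class _BaseClassifierModel:
    """Shared model surface: build from a feature table, fit, get Results."""

    k: int
    ratio: tuple[int, int]

    def __init__(self, table: pd.DataFrame, labels: np.ndarray,
                 feature_columns: list[str] | None = None,
                 mouse_ids: np.ndarray | None = None):
        meta = {"mouse_id", "group", "week", "clip_index", "foot",
                "start_frame", "end_frame"}
        if feature_columns is None:
            feature_columns = [c for c in table.columns if c not in meta
                               and pd.api.types.is_numeric_dtype(table[c])]
        self.table = table.reset_index(drop=True)
        self.X = self.table[feature_columns].astype(float)
        self.y = np.asarray(labels).astype(int)
        if len(self.X) != len(self.y):
            raise ValueError("labels length mismatch")
        self.mouse_ids = (np.asarray(mouse_ids) if mouse_ids is not None
                          else table.get("mouse_id", pd.Series(["?"] * len(table))).to_numpy())

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame, pd_groups, **kw):
        """Label rows by membership of their ``group`` in ``pd_groups``."""
        labels = table["group"].isin(set(pd_groups)).to_numpy().astype(int)
        return cls(table, labels, **kw)

    def _make_estimator(self, seed):
        raise NotImplementedError

    def fit(self, seed: int = 0, by_mouse: bool = False) -> "ClassifierResults":
        X = self.X.fillna(self.X.median(numeric_only=True))
        groups = self.mouse_ids if by_mouse else None
        X_tr, X_va, y_tr, y_va = balance_and_split(
            X, self.y, ratio=self.ratio, seed=seed, groups=groups)
        selected = select_features(X_tr, y_tr, self.k, seed=seed)
        est = self._make_estimator(seed)
        est.fit(X_tr[selected], y_tr)
        y_hat = est.predict(X_va[selected])
        return ClassifierResults(
            model=est, selected_features=selected, seed=int(seed),
            ratio=self.ratio, metrics=_metrics(y_va, y_hat),
            class_counts={"train": int(len(y_tr)), "validation": int(len(y_va))},
            score_name=self.score_name)


class ClipClassifierModel(_BaseClassifierModel):
    """Clip-level PD/non-PD classifier (gradient-boosted trees, k=30, 7:3)."""

    k = 30
    ratio = (7, 3)
    score_name = "APS"

    def _make_estimator(self, seed):
        return XGBClassifier(random_state=int(seed) % (2 ** 31), n_jobs=1,
                             tree_method="hist")


class GaitClassifierModel(_BaseClassifierModel):
    """Per-stride PD-gait classifier (randomised trees, k=20, 6:4)."""

    k = 20
    ratio = (6, 4)
    score_name = "PD gait score"

    def _make_estimator(self, seed):
        return ExtraTreesClassifier(n_estimators=100, n_jobs=1,
                                    random_state=int(seed) % (2 ** 31))


@dataclass
class ClassifierResults:
    """Fitted classifier bundle: model + selected features + metrics."""

    model: object
    selected_features: list[str]
    seed: int
    ratio: tuple[int, int]
    metrics: dict[str, float]
    class_counts: dict[str, int]
    score_name: str = "APS"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.selected_features].astype(float)
        X = X.fillna(X.median(numeric_only=True))
        return np.asarray(self.model.predict(X)).astype(int)

    def score_aps(self, table: pd.DataFrame) -> list[ApsResult]:
        """Per-animal PD score: 100 x PD-classified clips / total clips."""
        if len(table) == 0:
            raise ValueError("no clips to score")
        preds = self.predict(table)
        out = []
        for mouse, idx in table.groupby("mouse_id", sort=True).indices.items():
            p = preds[idx]
            aps = 100.0 * float(p.sum()) / len(p)
            out.append(ApsResult(mouse_id=str(mouse), aps=aps,
                                 status=health_status(aps), n_clips=len(p)))
        return out

    # gait scores share the clip-proportion definition
    score_gait = score_aps

    def attribute(self, table: pd.DataFrame) -> AttributionTable:
        """Exact per-tree additive attributions (log-odds) per clip.

        Path-dependent TreeSHAP evaluated in float64 over the parsed
        booster (see :mod:`pdpose.attribution`), so the additivity identity
        holds to well below 1e-6.
        """
        if not isinstance(self.model, XGBClassifier):
            raise TypeError("additive attribution requires the tree-boosting model")
        from . import attribution
        X = table[self.selected_features].astype(float).to_numpy()
        booster = self.model.get_booster()
        phi, base = attribution.shap_values(booster, X, X.shape[1])
        marg = attribution.margins(booster, X)
        values = pd.DataFrame(phi, columns=self.selected_features)
        return AttributionTable(values=values, base_value=base, margins=marg)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} clip classifier "
            f"(seed={self.seed}, split {self.ratio[0]}:{self.ratio[1]})",
            f"  train/validation clips: {self.class_counts['train']}"
            f"/{self.class_counts['validation']}",
            f"  selected features ({len(self.selected_features)}): "
            + ", ".join(self.selected_features[:5]) + ", ...",
            "  validation metrics:",
        ]
        for name, v in self.metrics.items():
            lines.append(f"    {name:<10} {v:6.3f}")
        return "\n".join(lines)
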