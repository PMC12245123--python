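"""Two-step intraoperative genotyping: tumor detection, then IDH1 call.

Stage 1 separates tumor from normal tissue on the GSH channel (r1 =
I542/I928, elevated in glioma); stage 2 separates IDH1-MUT from IDH1-WT
among tumor points on the H2O2 channel (r2 = I628/I928, depressed by the
higher H2O2 of mutant tumors) or on the quantified H2O2/GSH ratio.  Both
stages are maximum-likelihood logistic regressions; performance is
summarized by ROC/AUC and a three-class confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

CLASSES = ("normal", "WT", "MUT")
RECIPES = ("ratios", "h2o2_gsh")


@dataclass(frozen=True)
class GenotypeCall:
    label: str
    p_tumor: float
    p_mut_given_tumor: Optional[float]
    features: dict

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        if not (0 <= self.p_tumor <= 1):
            raise ValueError("p_tumor must be in [0, 1]")
        if self.p_mut_given_tumor is not None and not (0 <= self.p_mut_given_tumor <= 1):
            raise ValueError("p_mut_given_tumor must be in [0, 1]")


@dataclass
class _LogitModel:
    coef: np.ndarray       # (intercept, slope...)
    separation: bool = False

    def prob(self, x: np.ndarray) -> np.ndarray:
        z = self.coef[0] + np.atleast_2d(x) @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class ClassifierBundle:
    """Fitted two-stage classifier with thresholds and feature recipe."""

    stage1: _LogitModel
    stage2: _LogitModel
    recipe: str = "ratios"
    threshold1: float = 0.5
    threshold2: float = 0.5
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"recipe must be one of {RECIPES}")
        if not (0 < self.threshold1 < 1) or not (0 < self.threshold2 < 1):
            raise ValueError("thresholds must lie in (0, 1)")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "recipe": self.recipe,
                    "threshold1": self.threshold1,
                    "threshold2": self.threshold2,
                    "stage1_coef": self.stage1.coef.tolist(),
                    "stage2_coef": self.stage2.coef.tolist(),
                    "separation_flag": self.separation_flag,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "ClassifierBundle":
        d = json.loads(Path(path).read_text())
        return cls(
            stage1=_LogitModel(np.asarray(d["stage1_coef"])),
            stage2=_LogitModel(np.asarray(d["stage2_coef"])),
            recipe=d["recipe"],
            threshold1=d["threshold1"],
            threshold2=d["threshold2"],
            separation_flag=d["separation_flag"],
        )


def _fit_logit(x: np.ndarray, y: np.ndarray) -> _LogitModel:
    """ML logistic fit; ridge-stabilized fallback under perfect separation."""
    X = sm.add_constant(np.atleast_2d(x.T).T, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = np.asarray(res.params)
        if np.all(np.isfinite(coef)) and np.abs(coef).max() < 1e4:
            return _LogitModel(coef=coef, separation=False)
    except Exception:
        pass
    # (quasi-)separated data: documented L2-regularized fallback, flagged
    clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=1000)
    clf.fit(np.atleast_2d(x.T).T, y)
    coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return _LogitModel(coef=coef, separation=True)


def _stage_features(df: pd.DataFrame, recipe: str, stage: int) -> np.ndarray:
    if stage == 1:
        return df["r1"].to_numpy(dtype=float)[:, None]
    if recipe == "ratios":
        return df["r2"].to_numpy(dtype=float)[:, None]
    if "h2o2_gsh" in df.columns:
        return df["h2o2_gsh"].to_numpy(dtype=float)[:, None]
    if {"c_gsh", "c_h2o2"} <= set(df.columns):
        return (df["c_h2o2"] / df["c_gsh"]).to_numpy(dtype=float)[:, None]
    raise KeyError("h2o2_gsh recipe needs an 'h2o2_gsh' column or quantified concentrations")


def fit_classifier(points: pd.DataFrame, recipe: str = "ratios") -> ClassifierBundle:
    """Fit the hierarchical classifier from labeled measurements.

    ``points`` needs columns ``tissue_class`` (normal/WT/MUT), ``r1``, and —
    depending on the recipe — ``r2`` or ``h2o2_gsh`` (or quantified
    ``c_gsh``/``c_h2o2``).  Stage 1 is fitted on all points (tumor indicator
    vs r1); stage 2 on tumor points only (MUT indicator).
    """
    if recipe not in RECIPES:
        raise ValueError(f"recipe must be one of {RECIPES}")
    present = set(points["tissue_class"])
    missing = set(CLASSES) - present
    if missing:
        raise ValueError(f"classes absent from training points: {sorted(missing)}")
    is_tumor = points["tissue_class"].isin(["WT", "MUT"]).to_numpy()
    stage1 = _fit_logit(_stage_features(points, recipe, 1), is_tumor.astype(int))
    tumor = points[is_tumor]
    stage2 = _fit_logit(
        _stage_features(tumor, recipe, 2),
        (tumor["tissue_class"] == "MUT").to_numpy(dtype=int),
    )
    return ClassifierBundle(
        stage1=stage1,
        stage2=stage2,
        recipe=recipe,
        separation_flag=stage1.separation or stage2.separation,
    )


def classify(m, bundle: ClassifierBundle) -> GenotypeCall:
    """Hierarchical call for one measurement (RatioMeasurement, dict, or row).

    ``p_tumor >= threshold1`` calls tumor (ties resolve toward tumor,
    sensitivity first); tumor points are then labeled MUT when
    ``p_mut >= threshold2``, else WT.
    """
    if hasattr(m, "r1"):
        feats = {"r1": m.r1, "r2": m.r2}
    else:
        feats = dict(m)
    if "r1" not in feats:
        raise KeyError("measurement lacks the r1 feature")
    df = pd.DataFrame([feats])
    p_tumor = float(bundle.stage1.prob(_stage_features(df, bundle.recipe, 1))[0])
    if p_tumor < bundle.threshold1:
        return GenotypeCall(label="normal", p_tumor=p_tumor, p_mut_given_tumor=None, features=feats)
    p_mut = float(bundle.stage2.prob(_stage_features(df, bundle.recipe, 2))[0])
    label = "MUT" if p_mut >= bundle.threshold2 else "WT"
    return GenotypeCall(label=label, p_tumor=p_tumor, p_mut_given_tumor=p_mut, features=feats)


def fit_multinomial(points: pd.DataFrame) -> LogisticRegression:
    """One-step multinomial alternative (comparison mode, not the default)."""
    X = points[["r1", "r2"]].to_numpy(dtype=float)
    y = points["tissue_class"].to_numpy()
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X, y)
    return clf


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Full threshold-sweep ROC curve and its area.

    The AUC equals the Mann-Whitney probability that a random positive scores
    above a random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if np.unique(labels).size < 2:
        raise ValueError("ROC undefined: need both classes present")
    fpr, tpr, _ = _sk_roc(labels, scores)
    curve = np.column_stack([fpr, tpr])
    return curve, float(np.trapezoid(tpr, fpr))


def confusion_matrix(
    calls: Sequence, truth: Sequence[str], classes: Sequence[str] = CLASSES
) -> tuple[pd.DataFrame, pd.Series]:
    """K x K counts (rows = truth, columns = call) and per-class predictive
    values (column diagonal over column sum)."""
    pred = [c.label if isinstance(c, GenotypeCall) else str(c) for c in calls]
    truth = [str(t) for t in truth]
    if len(pred) != len(truth) or len(pred) == 0:
        raise ValueError("need equal-length, non-empty calls and truth")
    unknown = set(pred) | set(truth) - set(classes)
    if not set(pred) <= set(classes) or not set(truth) <= set(classes):
        raise ValueError(f"unknown label(s): {sorted(unknown - set(classes))}")
    counts = _sk_confusion(truth, pred, labels=list(classes))
    df = pd.DataFrame(counts, index=list(classes), columns=list(classes))
    colsum = df.sum(axis=0)
    ppv = pd.Series(
        [df.iloc[i, i] / colsum.iloc[i] if colsum.iloc[i] > 0 else np.nan
         for i in range(len(classes))],
        index=list(classes),
        name="predictive_value",
    )
    return df, ppv


def youden_threshold(scores, labels) -> float:
    """Probability threshold maximizing TPR - FPR (offered alternative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    fpr, tpr, thr = _sk_roc(labels, scores)
    best = np.argmax(tpr - fpr)
    t = float(thr[best])
    return min(max(t, 1e-6), 1 - 1e-6)
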