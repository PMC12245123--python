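"""Regression metric suite and model-comparison reporting.

Per metabolite the suite reports MAE, the sample standard deviation of the
absolute errors (SD), RMSE, and the coefficient of determination R^2.
Improvement tables express each model's metrics as percentage reductions
relative to a reference model, averaged across comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

METRICS = ("mae", "sd_abs_err", "rmse")


@dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    sd_abs_err: float
    rmse: float
    r2: float

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "sd_abs_err": self.sd_abs_err,
            "rmse": self.rmse,
            "r2": self.r2,
        }


@dataclass(frozen=True)
class EvalReport:
    model_id: str
    n: int
    per_metabolite: dict  # {"gsh": RegressionMetrics, "h2o2": RegressionMetrics}


def regression_metrics(pred, truth) -> RegressionMetrics:
    """MAE, sample SD of |error|, RMSE, and R^2 for one prediction vector.

    R^2 = 1 - SSE/SST requires a non-constant truth vector.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1D vectors")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    err = pred - truth
    abs_err = np.abs(err)
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant truth")
    return RegressionMetrics(
        mae=float(abs_err.mean()),
        sd_abs_err=float(abs_err.std(ddof=1)),
        rmse=float(np.sqrt(np.mean(err**2))),
        r2=float(1.0 - np.sum(err**2) / sst),
    )


def evaluate_predictions(pred: np.ndarray, truth: np.ndarray, model_id: str) -> EvalReport:
    """EvalReport from (N, 2) prediction/truth arrays ordered (GSH, H2O2)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError("expected matching (N, 2) arrays")
    return EvalReport(
        model_id=model_id,
        n=pred.shape[0],
        per_metabolite={
            "gsh": regression_metrics(pred[:, 0], truth[:, 0]),
            "h2o2": regression_metrics(pred[:, 1], truth[:, 1]),
        },
    )


def improvement_table(reports: Sequence[EvalReport], reference: str) -> pd.DataFrame:
    """Percentage improvement of the reference model over each comparator.

    improvement = (comparator_metric - reference_metric) / comparator_metric * 100,
    so positive numbers mean the reference model is better.  The returned frame
    has one row per (comparator, metabolite) plus ``mean over comparators``
    rows averaging each metric across comparators.
    """
    if len(reports) < 2:
        raise ValueError("need the reference and at least one comparator")
    by_id = {r.model_id: r for r in reports}
    if reference not in by_id:
        raise ValueError(f"reference model {reference!r} not among reports")
    ref = by_id[reference]
    rows = []
    for r in reports:
        if r.model_id == reference:
            continue
        for met in ("gsh", "h2o2"):
            comp = r.per_metabolite[met].as_dict()
            refm = ref.per_metabolite[met].as_dict()
            row = {"comparator": r.model_id, "metabolite": met}
            for m in METRICS:
                if comp[m] == 0:
                    raise ZeroDivisionError(
                        f"improvement undefined: comparator {r.model_id} has zero {m}"
                    )
                row[m] = (comp[m] - refm[m]) / comp[m] * 100.0
            rows.append(row)
    df = pd.DataFrame(rows)
    means = (
        df.groupby("metabolite")[list(METRICS)]
        .mean()
        .reset_index()
        .assign(comparator="mean over comparators")
    )
    return pd.concat([df, means], ignore_index=True)[
        ["comparator", "metabolite", *METRICS]
    ]
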