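"""Accuracy and agreement metrics, and method-comparison reports.

Error metrics against a manual reference y with predictions ŷ:

    MAE  = mean|y − ŷ|
    RMSE = sqrt(mean (y − ŷ)²)
    MAPE = mean |y − ŷ| / y × 100   (reference in the denominator;
                                     zero references are rejected)
    R²   = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²  (may be negative)

Agreement between repeated measurements/raters uses the intraclass
correlation coefficient in its two-way, absolute-agreement,
single-measure form ICC(A,1), computed from the ANOVA mean squares of
the n-subjects × m-raters table:

    ICC(A,1) = (MSR − MSE) / (MSR + (m−1)·MSE + m·(MSC − MSE)/n)

with MSR the between-subjects, MSC the between-raters and MSE the
residual mean square.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import morphometry, weight_models
from .weight_models import PigRecord


class EvaluationError(ValueError):
    """Raised on malformed metric inputs."""


def error_metrics(y, yhat, mape: bool = True) -> dict:
    """MAE, RMSE, MAPE (%) and R² of predictions against a reference."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise EvaluationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise EvaluationError("need at least 2 observations")
    err = y - yhat
    out = {
        "MAE": float(np.mean(np.abs(err))),
        "RMSE": float(np.sqrt(np.mean(err**2))),
        "n": int(y.size),
    }
    if mape:
        if np.any(y == 0):
            raise EvaluationError("MAPE undefined: reference contains zeros")
        out["MAPE_pct"] = float(np.mean(np.abs(err) / np.abs(y)) * 100.0)
    sst = float(np.sum((y - y.mean()) ** 2))
    out["R2"] = float("nan") if sst == 0 else 1.0 - float(np.sum(err**2)) / sst
    return out


def icc_agreement(ratings) -> float:
    """ICC(A,1): two-way, absolute agreement, single measure.

    ``ratings`` is an n-subjects × m-raters matrix with no missing cells.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise EvaluationError("ratings must be a 2-D subjects × raters table")
    n, m = x.shape
    if n < 2 or m < 2:
        raise EvaluationError(f"need >= 2 subjects and >= 2 raters, got {n}×{m}")
    if np.isnan(x).any():
        raise EvaluationError("ratings contain missing cells (no imputation)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = m * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (m - 1)
    mse = sse / ((n - 1) * (m - 1))
    denom = msr + (m - 1) * mse + m * (msc - mse) / n
    if denom == 0:
        return 1.0  # all cells identical
    return float((msr - mse) / denom)


def compare_methods(
    records: Sequence[PigRecord],
    girth_methods: Sequence[str] = morphometry.GIRTH_METHODS,
    weight_formulas: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-method error table against the records' references.

    Girth models are evaluated on each record's (W, D) against its
    reference girth ``girth_C``; weight formulas on the record dimensions
    against ``ref_weight``. One row per method/formula, deterministic
    order, columns: kind, method, MAE, RMSE, MAPE_pct, R2, n.
    """
    records = list(records)
    if not records:
        raise EvaluationError("no records to compare")
    rows = []
    ref_c = np.array([r.girth_C for r in records])
    for method in girth_methods:
        pred = np.array([morphometry.girth(r.W, r.D, method).C for r in records])
        rows.append({"kind": "girth", "method": method, **error_metrics(ref_c, pred)})
    if weight_formulas:
        ref_w = np.array([r.ref_weight for r in records])
        for tag in weight_formulas:
            pred = np.array(
                [
                    weight_models.empirical_weights(
                        C=r.girth_C, L=r.L, W=r.W, D=r.D, H=r.H
                    ).base_value(tag)
                    for r in records
                ]
            )
            rows.append({"kind": "weight", "method": tag, **error_metrics(ref_w, pred)})
    cols = ["kind", "method", "MAE", "RMSE", "MAPE_pct", "R2", "n"]
    return pd.DataFrame(rows)[cols]


def report_to_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)


def report_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
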