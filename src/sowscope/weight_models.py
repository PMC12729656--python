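"""Empirical pig weight formulas, linear fusion calibration, and k-fold CV.

Four classical girth/dimension weight formulas (inputs in cm, outputs kg):

.. math::

    BW_1 &= 0.634\\, C^2 L / 12500 + 14.6  \\quad\\text{(standard formula)}\\\\
    BW_2 &= 1.247\\, C L D / 7500 + 7.4\\\\
    BW_3 &= 2.142\\, W D L / 7200 + 6.9\\\\
    BW_4 &= (1.245\\, C L D \\cdot 0.8 + 50 H)/1000 + 7.4

where C is chest girth, L body length, W body width, D chest depth and
H body height. The published source of BW4 is typographically garbled;
the parse above is this package's fixed interpretation, isolated behind
its formula tag so a corrected parse is a one-line change.

The final prediction is a single-predictor affine calibration
``BW = slope * BW_base + intercept`` fitted by ordinary least squares on
reference weighings (the reference fit on the original herd was
BW = 0.8294·BW1 + 11.16). Generalization is assessed by seeded k-fold
cross-validation with an explicit train-vs-validation R² gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

#: Reference fusion coefficients from the original 30-animal herd fit.
REFERENCE_SLOPE = 0.8294
REFERENCE_INTERCEPT = 11.16

FORMULA_TAGS = ("bw1", "bw2", "bw3", "bw4")


class WeightModelError(ValueError):
    """Raised on missing or non-positive formula inputs."""


def bw1(C: float, L: float) -> float:
    """Standard formula: 0.634·C²·L/12500 + 14.6 (C, L in cm → kg)."""
    _require_positive(bw1=dict(C=C, L=L))
    return 0.634 * C**2 * L / 12500.0 + 14.6


def bw2(C: float, L: float, D: float) -> float:
    """Girth–length–depth formula: 1.247·C·L·D/7500 + 7.4."""
    _require_positive(bw2=dict(C=C, L=L, D=D))
    return 1.247 * C * L * D / 7500.0 + 7.4


def bw3(W: float, D: float, L: float) -> float:
    """Width–depth–length formula: 2.142·W·D·L/7200 + 6.9."""
    _require_positive(bw3=dict(W=W, D=D, L=L))
    return 2.142 * W * D * L / 7200.0 + 6.9


def bw4(C: float, L: float, D: float, H: float) -> float:
    """Four-parameter formula, fixed parse: (1.245·C·L·D·0.8 + 50·H)/1000 + 7.4."""
    _require_positive(bw4=dict(C=C, L=L, D=D, H=H))
    return (1.245 * C * L * D * 0.8 + H * 50.0) / 1000.0 + 7.4


def _require_positive(**formulas: dict) -> None:
    for formula, args in formulas.items():
        for name, v in args.items():
            if v is None or not v > 0:
                raise WeightModelError(
                    f"{formula}: argument {name} must be > 0, got {v}"
                )


@dataclass(frozen=True)
class WeightEstimate:
    """Per-formula weight estimates in kg; formulas lacking inputs are None."""

    bw1: float | None = None
    bw2: float | None = None
    bw3: float | None = None
    bw4: float | None = None
    fused: float | None = None
    formula_used: str | None = None

    def base_value(self, tag: str) -> float:
        v = getattr(self, tag)
        if v is None:
            raise WeightModelError(f"formula {tag} has no value (missing inputs)")
        return v


@dataclass(frozen=True)
class CalibrationModel:
    """Affine fusion calibration BW = slope·BW_base + intercept."""

    slope: float
    intercept: float
    base_formula: str = "bw1"
    r2_in_sample: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise WeightModelError("calibration coefficients must be finite")
        if self.slope == 0:
            raise WeightModelError("calibration slope must be nonzero (invertibility)")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {"slope": self.slope, "intercept": self.intercept, "base": self.base_formula}
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(slope=d["slope"], intercept=d["intercept"], base_formula=d.get("base", "bw1"))


#: The herd fit published for the original 30 animals.
REFERENCE_CALIBRATION = CalibrationModel(REFERENCE_SLOPE, REFERENCE_INTERCEPT, "bw1")


@dataclass(frozen=True)
class PigRecord:
    """One animal: dimensions (cm), fitted girth (cm), reference weight (kg)."""

    pig_id: str
    L: float
    W: float
    H: float
    D: float
    girth_C: float
    ref_weight: float

    def __post_init__(self) -> None:
        if not self.ref_weight > 0:
            raise WeightModelError(f"{self.pig_id}: ref_weight must be > 0")


def empirical_weights(
    C: float | None = None,
    L: float | None = None,
    W: float | None = None,
    D: float | None = None,
    H: float | None = None,
) -> WeightEstimate:
    """Evaluate every empirical formula whose inputs are all present.

    Formulas with missing inputs are reported as ``None`` rather than
    guessed; a present-but-nonpositive input raises, naming formula and
    argument.
    """

    def maybe(fn, *args):
        if any(a is None for a in args):
            return None
        return fn(*args)

    est = WeightEstimate(
        bw1=maybe(bw1, C, L),
        bw2=maybe(bw2, C, L, D),
        bw3=maybe(bw3, W, D, L),
        bw4=maybe(bw4, C, L, D, H),
    )
    if all(getattr(est, t) is None for t in FORMULA_TAGS):
        raise WeightModelError("no formula has a complete set of inputs")
    return est


def _base_values(records: Sequence[PigRecord], base_formula: str) -> np.ndarray:
    if base_formula not in FORMULA_TAGS:
        raise WeightModelError(f"unknown base formula '{base_formula}'")
    vals = []
    for r in records:
        est = empirical_weights(C=r.girth_C, L=r.L, W=r.W, D=r.D, H=r.H)
        vals.append(est.base_value(base_formula))
    return np.asarray(vals, dtype=np.float64)


def fit_calibration(
    records: Sequence[PigRecord], base_formula: str = "bw1"
) -> CalibrationModel:
    """OLS fit of reference weight on a base formula's output (QR solve).

    Requires at least 3 records and a non-constant predictor.
    """
    if len(records) < 3:
        raise WeightModelError(f"need >= 3 records to calibrate, got {len(records)}")
    x = _base_values(records, base_formula)
    y = np.array([r.ref_weight for r in records], dtype=np.float64)
    if np.ptp(x) == 0:
        raise WeightModelError(
            f"base formula {base_formula} is constant across records (rank deficient)"
        )
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = linalg.lstsq(X, y, lapack_driver="gelsy")
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return CalibrationModel(slope, intercept, base_formula, r2_in_sample=r2)


def predict_weight(est: WeightEstimate, model: CalibrationModel) -> float:
    """Calibrated prediction: slope · BW_base + intercept (kg)."""
    return model.slope * est.base_value(model.base_formula) + model.intercept


def predict_records(
    records: Sequence[PigRecord], model: CalibrationModel
) -> np.ndarray:
    x = _base_values(records, model.base_formula)
    return model.slope * x + model.intercept


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def kfold_cv(
    records: Sequence[PigRecord],
    k: int = 5,
    seed: int = 0,
    base_formula: str = "bw1",
) -> dict:
    """Seeded k-fold cross-validation of the affine calibration.

    The records are randomly partitioned into k mutually exclusive folds
    of size ⌊n/k⌋ or ⌈n/k⌉; each fold is scored with a model fitted on
    the other k−1 folds. R² on the held-out fold is computed against the
    fold's own mean (standard out-of-sample definition).

    Returns a dict with per-fold and mean validation R² and MAE, the mean
    training R², and the train-vs-validation R² gap (overfitting check).
    """
    n = len(records)
    if k < 2:
        raise WeightModelError(f"k must be >= 2, got {k}")
    if k > n:
        raise WeightModelError(f"k={k} folds exceed n={n} records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    val_r2, val_mae, train_r2 = [], [], []
    records = list(records)
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        train = [records[i] for i in range(n) if i not in test_idx]
        test = [records[i] for i in sorted(test_idx)]
        model = fit_calibration(train, base_formula)
        y_tr = np.array([r.ref_weight for r in train])
        y_te = np.array([r.ref_weight for r in test])
        train_r2.append(_r2(y_tr, predict_records(train, model)))
        pred = predict_records(test, model)
        val_r2.append(_r2(y_te, pred))
        val_mae.append(float(np.mean(np.abs(y_te - pred))))
    return {
        "k": k,
        "seed": seed,
        "base_formula": base_formula,
        "folds": [sorted(int(i) for i in f) for f in folds],
        "val_r2": val_r2,
        "val_mae": val_mae,
        "train_r2": train_r2,
        "mean_val_r2": float(np.mean(val_r2)),
        "sd_val_r2": float(np.std(val_r2)),
        "mean_val_mae": float(np.mean(val_mae)),
        "mean_train_r2": float(np.mean(train_r2)),
        "r2_gap": float(np.mean(train_r2) - np.mean(val_r2)),
    }


# ---------------------------------------------------------------------------
# Record table I/O

RECORD_COLUMNS = ["pig_id", "L", "W", "H", "D", "C", "ref_weight"]


def records_to_csv(records: Sequence[PigRecord], path: str | Path) -> Path:
    rows = [
        {"pig_id": r.pig_id, "L": r.L, "W": r.W, "H": r.H, "D": r.D, "C": r.girth_C, "ref_weight": r.ref_weight}
        for r in records
    ]
    path = Path(path)
    # %.17g guarantees float64 round-trip through the CSV.
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False, float_format="%.17g")
    return path


def records_from_csv(path: str | Path) -> list[PigRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PigRecord(
            pig_id=str(row.pig_id), L=row.L, W=row.W, H=row.H, D=row.D,
            girth_C=row.C, ref_weight=row.ref_weight,
        )
        for row in df.itertuples(index=False)
    ]
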