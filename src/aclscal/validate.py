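"""Evaluation protocol: Venetian-blinds split, error metrics, ANOVA, model table.

The protocol mirrors standard chemometric practice for batch-process
calibration data: an interleaved (Venetian blinds) 2-fold split in
acquisition order, so calibration and validation halves share concentration
ranges and correlations; RMSEP / RMSECV / R² as accuracy metrics; and a
one-way ANOVA on absolute prediction errors to judge whether two models'
predictive power differs significantly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import augment, baselines, core
from .types import ComponentMatrix, DegenerateInputError, SpectraMatrix

__all__ = [
    "SplitAssignment",
    "AnovaResult",
    "venetian_blinds_split",
    "rmse",
    "r_squared",
    "anova_abs_errors",
    "compare_models",
    "METHODS",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Fold id per sample; folds partition the samples, sizes differ by <= 1."""

    fold_of_sample: np.ndarray
    n_folds: int

    def fold_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)


def venetian_blinds_split(n_samples: int, n_folds: int = 2) -> SplitAssignment:
    """Interleaved fold assignment in acquisition order: fold(i) = i mod n_folds.

    For smoothly varying batch processes this keeps concentration ranges and
    correlations similar across folds.
    """
    if n_samples < n_folds:
        raise DegenerateInputError("need at least one sample per fold")
    return SplitAssignment(np.arange(n_samples) % n_folds, n_folds)


def rmse(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square error, in concentration units."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predicted and reference must be equal-length, non-empty")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def r_squared(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and reference values."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size < 3:
        raise ValueError("r_squared needs equal-length inputs with at least 3 values")
    if np.ptp(r) == 0:
        raise DegenerateInputError("reference values are constant")
    if np.ptp(p) == 0:
        return 0.0
    return float(np.corrcoef(p, r)[0, 1] ** 2)


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA summary."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_abs_errors(*groups: np.ndarray) -> AnovaResult:
    """One-way ANOVA across groups of absolute prediction errors.

    For two groups, F equals the square of the pooled two-sample t
    statistic and the p values agree.  Groups with zero variance that are
    all identical yield F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise DegenerateInputError("every group needs at least 2 observations")
    n_total = sum(a.size for a in arrs)
    dfb, dfw = len(arrs) - 1, n_total - len(arrs)
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:  # all observations identical
        return AnovaResult(0.0, dfb, dfw, 1.0)
    f, p = scipy.stats.f_oneway(*arrs)
    return AnovaResult(float(f), dfb, dfw, float(p))


#: method name -> fitter; all return a CalibrationModel with uniform predict.
METHODS = ("cls1", "cls2", "cracls", "pcr", "pls", "acls")


def _fit_method(
    name: str,
    A_cal: SpectraMatrix,
    C_cal: ComponentMatrix,
    *,
    n_components: int | None = None,
    k_max: int = 10,
    r2_threshold: float = augment.DEFAULT_R2_THRESHOLD,
    min_spacing: float = augment.DEFAULT_MIN_SPACING,
    m_max: int = augment.DEFAULT_M_MAX,
    m_override: int | None = None,
) -> core.CalibrationModel:
    """Fit one method by name; RMSECV (leave-one-out on the calibration set)
    lands in model.extras['rmsecv'] whenever the fit computes it anyway."""
    if name == "cls1":
        return baselines.fit_cls1(A_cal, C_cal)
    if name == "cls2":
        return baselines.fit_cls2(A_cal, C_cal)
    if name == "cracls":
        return baselines.fit_cracls(A_cal, C_cal)
    if name in ("pcr", "pls"):
        if n_components is None:
            k, curve = baselines.select_num_components(A_cal, C_cal, name, k_max=k_max)
        else:
            k = n_components
            curve = baselines.loo_rmsecv_latent(A_cal, C_cal, name, k)
        fitter = baselines.fit_pcr if name == "pcr" else baselines.fit_pls
        model = fitter(A_cal, C_cal, k)
        model.extras["rmsecv"] = float(curve[min(k, len(curve)) - 1])
        model.extras["rmsecv_curve"] = curve
        return model
    if name == "acls":
        return augment.fit_acls(
            A_cal,
            C_cal,
            r2_threshold=r2_threshold,
            min_spacing=min_spacing,
            m_max=m_max,
            m_override=m_override,
        )
    raise ValueError(f"unknown method {name!r}; known: {', '.join(METHODS)}")


def _loo_rmsecv_refit(name: str, A: SpectraMatrix, C: ComponentMatrix, **opts) -> float:
    """Exhaustive leave-one-out RMSECV by refitting the method per left-out sample."""
    L = A.n_samples
    preds = np.empty(L)
    for i in range(L):
        rows = np.concatenate([np.arange(i), np.arange(i + 1, L)])
        model = _fit_method(name, A.take(rows), C.take(rows), **opts)
        preds[i] = model.predict(A.take(np.array([i])))[0]
    return rmse(preds, C.target_values)


def compare_models(
    A: SpectraMatrix,
    C: ComponentMatrix,
    methods=METHODS,
    split: SplitAssignment | None = None,
    **options,
) -> pd.DataFrame:
    """Fit each method on the calibration fold, score on the validation fold.

    Fold 0 of the (Venetian blinds, by default) split is the calibration
    set, fold 1 the validation set.  Rows are sorted worst-first by RMSEP;
    ``p_vs_previous`` is the two-group ANOVA p value on absolute validation
    errors against the previous (worse) row, so each p answers "is this
    model a significant improvement on the one above it?".

    Returns a DataFrame with columns method, R2, RMSEP, p_vs_previous,
    RMSECV, n_components.
    """
    methods = list(methods)
    if len(methods) < 2:
        raise ValueError("model comparison needs at least 2 methods")
    if split is None:
        split = venetian_blinds_split(A.n_samples, 2)
    cal, val = split.fold_rows(0), split.fold_rows(1)
    A_cal, C_cal = A.take(cal), C.take(cal)
    A_val, C_val = A.take(val), C.take(val)
    y_val = C_val.target_values

    rows = []
    abs_errors = {}
    for name in methods:
        model = _fit_method(name, A_cal, C_cal, **options)
        pred = model.predict(A_val)
        abs_errors[name] = np.abs(pred - y_val)
        rmsecv = model.extras.get("rmsecv")
        if rmsecv is None:
            rmsecv = _loo_rmsecv_refit(name, A_cal, C_cal, **options)
        size = None
        if model.n_components is not None:
            size = model.n_components
        elif model.selection is not None:
            size = model.selection.chosen_m
        rows.append(
            {
                "method": name,
                "R2": r_squared(pred, y_val),
                "RMSEP": rmse(pred, y_val),
                "RMSECV": float(rmsecv),
                "n_components": size,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "RMSEP", ascending=False, kind="stable"
    ).reset_index(drop=True)
    p_vals = [np.nan]
    for i in range(1, len(table)):
        prev, cur = table.loc[i - 1, "method"], table.loc[i, "method"]
        res = anova_abs_errors(abs_errors[prev], abs_errors[cur])
        p_vals.append(res.p_value)
    table.insert(3, "p_vs_previous", p_vals)
    return table
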