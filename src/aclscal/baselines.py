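"""Comparison calibrations: CLS1, CLS2, CRACLS, PCR and PLS.

All fitters honour the same contract as the augmented model: fit on a
calibration set, then ``model.predict(spectra)`` returns target-analyte
concentrations in original units.

CLS1 uses only the target analyte's concentration column; CLS2 uses all
known analyte concentrations.  CRACLS (concentration-residual augmented
CLS) iteratively appends the target calibration residual as a pseudo
column.  PCR regresses the target on leading principal-component scores of
the centered spectra; PLS is the classical univariate-target NIPALS
algorithm with deflation (via scikit-learn).
"""

from __future__ import annotations

import warnings

import numpy as np

from . import core
from .types import (
    ComponentMatrix,
    DegenerateInputError,
    SpectraMatrix,
)

__all__ = [
    "fit_cls1",
    "fit_cls2",
    "fit_cracls",
    "fit_pcr",
    "fit_pls",
    "select_num_components",
    "loo_rmsecv_latent",
]


def _fit_cls_family(
    A: SpectraMatrix, C: ComponentMatrix, method: str, center: bool = True
) -> core.CalibrationModel:
    if center:
        A_c, C_c, state = core.mean_center(A, C)
    else:
        A_c, C_c, state = A, C, None
    K = core.fit_cls(C_c, A_c)
    return core.CalibrationModel(
        method=method,
        kind="cls",
        target_label=C.target_label,
        centering=state,
        pure_spectra=K,
        components=C,
    )


def fit_cls1(A: SpectraMatrix, C: ComponentMatrix, center: bool = True) -> core.CalibrationModel:
    """CLS using only the target analyte's concentration column."""
    return _fit_cls_family(A, C.select_columns([C.target_column]), "cls1", center)


def fit_cls2(A: SpectraMatrix, C: ComponentMatrix, center: bool = True) -> core.CalibrationModel:
    """CLS using all known analyte concentration columns (pseudo columns dropped)."""
    return _fit_cls_family(A, C.select_columns(list(C.analyte_columns)), "cls2", center)


def fit_cracls(
    A: SpectraMatrix,
    C: ComponentMatrix,
    max_iter: int = 10,
    tol: float = 1e-8,
    center: bool = True,
) -> core.CalibrationModel:
    """Concentration-residual augmented CLS.

    Starting from all analyte columns, repeatedly: fit CLS, predict the
    calibration target, and append the residual (predicted - reference) as a
    new pseudo column, refitting until the residual norm stops improving by
    a relative ``tol``, a residual is numerically zero, the matrix would go
    rank deficient, or ``max_iter`` is reached.
    """
    C_work = C.select_columns(list(C.analyte_columns))
    if A.n_samples <= C_work.n_components + max_iter:
        max_iter = max(0, A.n_samples - C_work.n_components - 2)
    model = _fit_cls_family(A, C_work, "cracls", center)
    y = C.target_values
    resid_norm = np.inf
    n_iter = 0
    norms = []
    scale = float(np.linalg.norm(y - y.mean())) or 1.0
    for it in range(max_iter):
        pred = model.predict(A)
        resid = pred - y
        norm = float(np.linalg.norm(resid))
        norms.append(norm)
        if norm <= tol * scale:  # converged: never append a ~0 column
            break
        if resid_norm - norm <= tol * scale:
            break
        resid_norm = norm
        trial = C_work.append_pseudo_columns(resid[:, None], [f"resid{it + 1}"])
        if core._numerical_rank(trial.values) <= core._numerical_rank(C_work.values):
            warnings.warn("CRACLS residual column is collinear; stopping", stacklevel=2)
            break
        C_work = trial
        model = _fit_cls_family(A, C_work, "cracls", center)
        n_iter = it + 1
    model.n_iterations = n_iter
    model.extras["residual_norms"] = norms
    return model


def _pcr_affine(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[np.ndarray, float]:
    """Affine map (coef, intercept) of PCR: regress y on leading PC scores of X."""
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    b, *_ = np.linalg.lstsq(scores, y - y_mean, rcond=None)
    coef = Vt[:n_components].T @ b
    return coef, y_mean - float(x_mean @ coef)


def fit_pcr(
    A: SpectraMatrix, C: ComponentMatrix, n_components: int
) -> core.CalibrationModel:
    """Principal component regression of the target analyte on the spectra."""
    L, P = A.n_samples, A.n_channels
    if not (1 <= n_components <= min(L - 1, P)):
        raise ValueError(
            f"n_components must be in [1, {min(L - 1, P)}], got {n_components}"
        )
    y = C.target_values
    coef, intercept = _pcr_affine(A.intensities, y, n_components)
    Xc = A.intensities - A.intensities.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    return core.CalibrationModel(
        method="pcr",
        kind="latent",
        target_label=C.target_label,
        coef=coef,
        intercept=intercept,
        n_components=n_components,
        extras={"scores": scores},
    )


def fit_pls(
    A: SpectraMatrix, C: ComponentMatrix, n_components: int
) -> core.CalibrationModel:
    """Partial least squares regression (univariate target, NIPALS with deflation)."""
    from sklearn.cross_decomposition import PLSRegression

    L, P = A.n_samples, A.n_channels
    if not (1 <= n_components <= min(L - 1, P)):
        raise ValueError(
            f"n_components must be in [1, {min(L - 1, P)}], got {n_components}"
        )
    y = C.target_values
    k = n_components
    pls = None
    while k >= 1:
        candidate = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate.fit(A.intensities, y)
        if np.all(np.isfinite(candidate.coef_)):
            pls = candidate
            break
        k -= 1
    if pls is None:
        raise DegenerateInputError("PLS found no usable covariance direction")
    if k < n_components:
        warnings.warn(
            f"PLS stopped early at {k} components (zero residual covariance)",
            stacklevel=2,
        )
    coef = np.asarray(pls.coef_).reshape(-1)
    # affine map on raw spectra: predict(0) folds sklearn's internal
    # centering into the intercept
    intercept = float(np.asarray(pls.predict(np.zeros((1, P)))).reshape(-1)[0])
    return core.CalibrationModel(
        method="pls",
        kind="latent",
        target_label=C.target_label,
        coef=coef,
        intercept=intercept,
        n_components=k,
        extras={"scores": np.asarray(pls.x_scores_)},
    )


def loo_rmsecv_latent(
    A: SpectraMatrix, C: ComponentMatrix, method: str, k_max: int
) -> np.ndarray:
    """Leave-one-out RMSECV of PCR or PLS for k = 1..k_max components.

    Returns an array of length k_max (index 0 is k=1), on the original
    concentration scale.
    """
    fitter = {"pcr": fit_pcr, "pls": fit_pls}[method]
    L = A.n_samples
    k_max = min(k_max, L - 2, A.n_channels)
    if k_max < 1:
        raise DegenerateInputError("too few samples for component selection")
    y = C.target_values
    preds = np.empty((k_max, L))
    for i in range(L):
        rows = np.concatenate([np.arange(i), np.arange(i + 1, L)])
        A_tr, C_tr = A.take(rows), C.take(rows)
        A_i = A.take(np.array([i]))
        if method == "pcr":
            # one SVD per fold serves every k
            X = A_tr.intensities
            x_mean = X.mean(axis=0)
            y_mean = float(C_tr.target_values.mean())
            U, s, Vt = np.linalg.svd(X - x_mean, full_matrices=False)
            yc = C_tr.target_values - y_mean
            x_new = A_i.intensities[0] - x_mean
            proj = Vt @ x_new
            b_full = (U.T @ yc) / np.where(s > 0, s, 1.0)
            for k in range(1, k_max + 1):
                preds[k - 1, i] = y_mean + proj[:k] @ b_full[:k]
        else:
            for k in range(1, k_max + 1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fitter(A_tr, C_tr, k)
                preds[k - 1, i] = model.predict(A_i)[0]
    return np.sqrt(np.mean((preds - y) ** 2, axis=1))


def select_num_components(
    A: SpectraMatrix,
    C: ComponentMatrix,
    method: str,
    k_max: int = 10,
    rel_tol: float = 0.02,
) -> tuple[int, np.ndarray]:
    """Pick the latent dimension by parsimonious leave-one-out RMSECV.

    Returns ``(k, curve)`` where k is the smallest component count whose
    RMSECV lies within ``rel_tol`` (relative) of the curve minimum —
    preferring the simplest model among statistically indistinguishable
    ones.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    curve = loo_rmsecv_latent(A, C, method, k_max)
    return parsimonious_k(curve, rel_tol), curve


def parsimonious_k(curve: np.ndarray, rel_tol: float = 0.02) -> int:
    """Smallest k (1-based) whose RMSECV is within ``rel_tol`` of the minimum."""
    curve = np.asarray(curve, dtype=float)
    best = float(np.min(curve))
    return int(np.argmax(curve <= best * (1.0 + rel_tol))) + 1
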