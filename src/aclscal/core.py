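"""Classical least squares calibration and prediction.

The forward model is Beer-Lambert mixing, A = C K + E: each observed
spectrum (row of A) is a linear combination of per-component spectra (rows
of K) weighted by the component quantities (row of C).  Calibration fits K
from known C by least squares; prediction inverts the fitted K to recover
component quantities from new spectra.  Both solves use rank-revealing
minimum-norm least squares rather than explicit normal-equation inverses,
which is numerically equivalent for well-conditioned problems and far more
robust when augmentation introduces near-dependent columns.

Spectra and component quantities are mean-centered around the calibration
set by default; the stored :class:`~aclscal.types.CenteringState` re-applies
the identical transform at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .types import (
    CenteringState,
    CollinearityError,
    ComponentMatrix,
    DegenerateInputError,
    PureSpectraEstimate,
    SingularityError,
    SpectraMatrix,
)

__all__ = [
    "mean_center",
    "fit_cls",
    "predict_cls",
    "CalibrationModel",
    "rank_tolerance",
]


def rank_tolerance(matrix: np.ndarray) -> float:
    """Singular-value cutoff for rank decisions: max(dim) * eps * s_max."""
    if matrix.size == 0:
        return 0.0
    smax = float(np.linalg.norm(matrix, 2))
    return max(matrix.shape) * np.finfo(float).eps * smax


def _numerical_rank(matrix: np.ndarray) -> int:
    if matrix.size == 0:
        return 0
    s = np.linalg.svd(matrix, compute_uv=False)
    return int(np.sum(s > rank_tolerance(matrix)))


def _dependent_columns(matrix: np.ndarray) -> list[int]:
    """Columns not selected by a rank-revealing pivoted QR (the redundant ones)."""
    import scipy.linalg

    _, _, piv = scipy.linalg.qr(matrix, mode="economic", pivoting=True)
    rank = _numerical_rank(matrix)
    return sorted(int(j) for j in piv[rank:])


def mean_center(
    A: SpectraMatrix, C: ComponentMatrix
) -> tuple[SpectraMatrix, ComponentMatrix, CenteringState]:
    """Center spectra and component quantities around the calibration-set mean.

    Returns centered copies of both matrices plus the state needed to undo /
    re-apply the transform exactly.
    """
    if A.n_samples < 2:
        raise DegenerateInputError("mean centering needs at least 2 calibration samples")
    if A.n_samples != C.n_samples:
        raise ValueError("spectra and component matrices must have matching rows")
    a_mean = A.intensities.mean(axis=0)
    c_mean = C.values.mean(axis=0)
    A_c = SpectraMatrix(A.intensities - a_mean, A.axis, A.sample_ids)
    from dataclasses import replace

    C_c = replace(C, values=C.values - c_mean)
    return A_c, C_c, CenteringState(a_mean, c_mean)


def fit_cls(C: ComponentMatrix, A: SpectraMatrix) -> PureSpectraEstimate:
    """Estimate per-component spectra K from known component quantities.

    Solves min ||A - C K||_F, the least-squares form of K = (C'C)^-1 C'A.
    Raises :class:`CollinearityError` naming the redundant columns when C is
    rank deficient beyond the numerical tolerance.
    """
    if C.n_samples != A.n_samples:
        raise ValueError("spectra and component matrices must have matching rows")
    Cv = C.values
    if _numerical_rank(Cv) < C.n_components:
        bad = _dependent_columns(Cv)
        names = ", ".join(C.column_labels[j] for j in bad)
        raise CollinearityError(
            f"component matrix is rank deficient; dependent column(s): {names}"
        )
    K, *_ = np.linalg.lstsq(Cv, A.intensities, rcond=None)
    return PureSpectraEstimate(K, A.axis)


def predict_cls(
    A_new: SpectraMatrix,
    K: PureSpectraEstimate,
    state: CenteringState | None,
    target_column: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert fitted spectra to predict component quantities for new spectra.

    Implements C = A K'(K K')^-1 as a minimum-norm least-squares solve of
    K' c = a per sample.  Returns ``(target, full)``: the target-analyte
    concentrations (centering undone) and the full predicted component
    matrix, whose pseudo-component columns are regression bookkeeping, not
    chemistry.
    """
    if A_new.axis != K.axis:
        raise ValueError("prediction spectra must share the calibration wavenumber axis")
    M = K.n_components
    if not (0 <= target_column < M):
        raise ValueError("target_column out of range for the fitted spectra")
    rank = _numerical_rank(K.rows)
    if rank == 0:
        raise SingularityError("fitted pure spectra are numerically zero")
    if rank < M:
        warnings.warn(
            f"fitted pure spectra have numerical rank {rank} < {M}; "
            "using the minimum-norm solution",
            stacklevel=2,
        )
    X = A_new.intensities
    if state is not None:
        X = X - state.spectra_mean
    C_tilde, *_ = np.linalg.lstsq(K.rows.T, X.T, rcond=None)
    C_tilde = C_tilde.T
    if state is not None:
        C_tilde = C_tilde + state.component_mean
    return C_tilde[:, target_column].copy(), C_tilde


@dataclass
class CalibrationModel:
    """A fitted calibration with a uniform predict contract.

    Two families share the contract: the CLS family stores fitted pure
    spectra and the calibration component-matrix layout; the latent family
    (PCR/PLS) stores an affine map from a spectrum to the target
    concentration.  ``predict`` always returns target concentrations in
    original (un-centered) units.
    """

    method: str
    kind: str  # "cls" | "latent"
    target_label: str
    centering: CenteringState | None = None
    pure_spectra: PureSpectraEstimate | None = None
    components: ComponentMatrix | None = None
    coef: np.ndarray | None = None
    intercept: float | None = None
    n_components: int | None = None
    selection: Any = None  # AugmentationSelection for ACLS
    n_iterations: int | None = None  # CRACLS
    extras: dict = field(default_factory=dict)

    def predict(self, A: SpectraMatrix) -> np.ndarray:
        """Predict the target-analyte concentration for each spectrum."""
        if self.kind == "cls":
            target, _ = predict_cls(
                A, self.pure_spectra, self.centering, self.components.target_column
            )
            return target
        return A.intensities @ self.coef + self.intercept

    def predict_components(self, A: SpectraMatrix) -> np.ndarray:
        """Full predicted component matrix (CLS family only), pseudo columns included."""
        if self.kind != "cls":
            raise ValueError("full component prediction is defined for CLS-family models only")
        _, full = predict_cls(
            A, self.pure_spectra, self.centering, self.components.target_column
        )
        return full
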