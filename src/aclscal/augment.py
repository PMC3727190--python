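"""Concentration-matrix augmentation with low-correlation spectral channels.

When components contributing spectral variance are missing from C (unknown
species, nonlinearity, wavelength drift), the CLS fit of the target
analyte's pure spectrum is corrupted.  The remedy implemented here appends
selected spectral channels — those whose intensity across calibration
samples correlates poorly with the target concentration, hence plausibly
carries the unmodeled variance — to C as pseudo-component columns before
the CLS fit.

Pipeline: squared-correlation ranking of channels -> greedy
region-separated candidate ordering -> leave-one-out RMSECV as a function
of the number of appended channels -> elbow choice of the augmentation
size -> final augmented CLS fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import core
from .types import (
    ComponentMatrix,
    DegenerateInputError,
    PureSpectraEstimate,
    SpectraMatrix,
    WavenumberAxis,
)

__all__ = [
    "ChannelCorrelation",
    "AugmentationSelection",
    "channel_r2",
    "rank_candidates",
    "augment_concentration_matrix",
    "loo_rmsecv_curve",
    "choose_augmentation_size",
    "fit_acls",
]

DEFAULT_R2_THRESHOLD = 0.2
DEFAULT_MIN_SPACING = 100.0  # cm^-1
DEFAULT_M_MAX = 30


@dataclass(frozen=True)
class ChannelCorrelation:
    """Squared Pearson correlation of each spectral channel with the target."""

    r2: np.ndarray

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        if np.any((r2 < 0) | (r2 > 1 + 1e-12)):
            raise ValueError("r2 values must lie in [0, 1]")
        object.__setattr__(self, "r2", np.clip(r2, 0.0, 1.0))


@dataclass(frozen=True)
class AugmentationSelection:
    """Record of one augmentation-size selection run."""

    candidate_order: tuple[int, ...]
    r2: np.ndarray
    r2_threshold: float
    min_spacing: float
    rmsecv_curve: np.ndarray
    chosen_m: int
    chosen_channels: tuple[int, ...]


def channel_r2(A: SpectraMatrix, target: np.ndarray) -> ChannelCorrelation:
    """Squared Pearson correlation of every channel with the target concentration.

    Constant channels get r2 = 0 by convention; a constant target is an error.
    """
    y = np.asarray(target, dtype=float)
    if A.n_samples < 3:
        raise DegenerateInputError("channel correlation needs at least 3 samples")
    if y.shape != (A.n_samples,):
        raise ValueError("target must be one value per sample")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise DegenerateInputError("target concentration vector is constant")
    Xc = A.intensities - A.intensities.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r2 = np.where(sx > 0, r**2, 0.0)
    return ChannelCorrelation(np.clip(r2, 0.0, 1.0))


def rank_candidates(
    corr: ChannelCorrelation,
    axis: WavenumberAxis,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> list[int]:
    """Order low-correlation channels for augmentation, separated in wavenumber.

    Channels with r2 below ``r2_threshold`` are sorted by ascending r2 and
    greedily filtered so every retained channel sits at least ``min_spacing``
    cm^-1 away from all previously retained ones — the reproducible form of
    picking signals from different wavenumber regions, which suppresses the
    mutual redundancy of neighbouring channels in smooth spectra.
    """
    r2 = corr.r2
    if r2.size != axis.n_channels:
        raise ValueError("correlation vector length must equal the axis length")
    below = np.flatnonzero(r2 < r2_threshold)
    if below.size == 0:
        raise DegenerateInputError(
            f"no channel has r2 below the threshold {r2_threshold}"
        )
    order = below[np.lexsort((below, r2[below]))]  # ascending r2, ties by index
    kept: list[int] = []
    kept_wn: list[float] = []
    wn = axis.values
    for j in order:
        if all(abs(wn[j] - w) >= min_spacing for w in kept_wn):
            kept.append(int(j))
            kept_wn.append(float(wn[j]))
    return kept


def augment_concentration_matrix(
    C: ComponentMatrix, A: SpectraMatrix, channels: list[int]
) -> ComponentMatrix:
    """Append the selected spectral channels to C as pseudo-component columns.

    Channels whose intensity vector is (numerically) a linear combination of
    the columns already present are dropped with a warning rather than
    erroring — near-duplicate channels are expected in smooth spectra.
    """
    if C.n_samples != A.n_samples:
        raise ValueError("spectra and component matrices must have matching rows")
    if not channels:
        return C
    channels = [int(j) for j in channels]
    P = A.n_channels
    if any(j < 0 or j >= P for j in channels):
        raise ValueError("channel index out of range")
    if C.n_components + len(channels) >= C.n_samples:
        raise DegenerateInputError(
            "augmentation would leave fewer samples than components "
            f"({C.n_components + len(channels)} columns, {C.n_samples} samples)"
        )
    out = C
    current = C.values
    rank = core._numerical_rank(current)
    wn = A.axis.values
    for j in channels:
        col = A.intensities[:, j]
        trial = np.hstack([current, col[:, None]])
        trial_rank = core._numerical_rank(trial)
        if trial_rank <= rank:
            warnings.warn(
                f"channel {j} ({wn[j]:g} cm^-1) is collinear with existing "
                "columns; dropped from the augmentation",
                stacklevel=2,
            )
            continue
        out = out.append_pseudo_columns(
            col[:, None], [f"ch{j}@{wn[j]:g}cm-1"], [j]
        )
        current = trial
        rank = trial_rank
    return out


def loo_rmsecv_curve(
    A: SpectraMatrix,
    C: ComponentMatrix,
    candidate_order: list[int],
    m_max: int,
    center: bool = True,
    m_values=None,
) -> np.ndarray:
    """Leave-one-out RMSECV of the target analyte versus augmentation size.

    Entry m is the RMSECV of CLS fitted on C augmented with the first m
    candidate channels.  The channel choice is fixed across folds; only the
    CLS fit is redone per left-out sample.  Folds where the component matrix
    goes rank deficient are recorded as NaN with a warning.  RMSECV is on
    the original (un-centered) concentration scale.  ``m_values`` restricts
    evaluation to a subset of m (the rest stay NaN).
    """
    if m_max > len(candidate_order):
        raise ValueError("m_max exceeds the number of candidate channels")
    L = A.n_samples
    curve = np.full(m_max + 1, np.nan)
    if m_values is None:
        m_values = range(m_max + 1)
    for m in m_values:
        C_m = augment_concentration_matrix(C, A, list(candidate_order[:m]))
        if L < C_m.n_components + 2:
            warnings.warn(
                f"m={m}: too few samples for leave-one-out ({L} samples, "
                f"{C_m.n_components} components); recorded as missing",
                stacklevel=2,
            )
            continue
        preds = np.empty(L)
        ok = True
        for i in range(L):
            rows = np.concatenate([np.arange(i), np.arange(i + 1, L)])
            A_tr, C_tr = A.take(rows), C_m.take(rows)
            try:
                if center:
                    A_c, C_c, state = core.mean_center(A_tr, C_tr)
                else:
                    A_c, C_c, state = A_tr, C_tr, None
                K = core.fit_cls(C_c, A_c)
                target, _ = core.predict_cls(
                    A.take(np.array([i])), K, state, C_m.target_column
                )
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(
                    f"m={m}: fold {i} failed ({err}); curve entry recorded as missing",
                    stacklevel=2,
                )
                ok = False
                break
            preds[i] = target[0]
        if ok:
            curve[m] = float(np.sqrt(np.mean((preds - C.target_values) ** 2)))
    return curve


def choose_augmentation_size(
    curve: np.ndarray, override: int | None = None
) -> int:
    """Elbow of the RMSECV-versus-m curve by maximum chord distance.

    The elbow is the m maximizing the perpendicular distance *below* the
    chord joining the first and last finite curve points (Kneedle-style);
    ties break toward smaller m, and a strictly linear curve returns m = 0.
    ``override`` short-circuits the choice so a visually picked size can be
    replicated.  If the elbow's RMSECV exceeds the unaugmented RMSECV the
    choice falls back to m = 0 with a warning — a guard against the
    unstable low-m region.
    """
    curve = np.asarray(curve, dtype=float)
    if override is not None:
        if not (0 <= override < curve.size):
            raise ValueError("override m out of range for the curve")
        return int(override)
    if curve.size < 3:
        raise ValueError("curve must have at least 3 entries")
    finite = np.flatnonzero(np.isfinite(curve))
    if finite.size == 0:
        raise DegenerateInputError("RMSECV curve contains no finite values")
    m0, m1 = finite[0], finite[-1]
    if m0 == m1:
        return int(m0)
    # signed perpendicular distance below the chord (improvement side)
    dx, dy = float(m1 - m0), float(curve[m1] - curve[m0])
    norm = float(np.hypot(dx, dy))
    dist = np.full(curve.size, -np.inf)
    for m in finite:
        dist[m] = ((curve[m0] + dy * (m - m0) / dx) - curve[m]) / norm * dx / abs(dx)
    chosen = int(np.argmax(dist > np.max(dist) - 1e-15))
    if dist[chosen] <= 0:
        chosen = int(m0)
    if np.isfinite(curve[0]) and curve[chosen] > curve[0]:
        warnings.warn(
            f"elbow at m={chosen} has RMSECV {curve[chosen]:.4g} above the "
            f"unaugmented {curve[0]:.4g}; falling back to m=0",
            stacklevel=2,
        )
        return 0
    return chosen


def fit_acls(
    A: SpectraMatrix,
    C: ComponentMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    min_spacing: float = DEFAULT_MIN_SPACING,
    m_max: int = DEFAULT_M_MAX,
    m_override: int | None = None,
    center: bool = True,
) -> core.CalibrationModel:
    """Fit the augmented-CLS model end to end.

    Runs the full pipeline — channel correlation, region-separated candidate
    ranking, leave-one-out RMSECV curve, elbow choice (or explicit
    ``m_override``), augmentation, final CLS fit — and returns a model whose
    ``predict`` reports the target analyte only.
    """
    corr = channel_r2(A, C.target_values)
    candidates = rank_candidates(corr, A.axis, r2_threshold, min_spacing)
    m_cap = min(m_max, len(candidates), max(0, A.n_samples - C.n_components - 2))
    if m_override is not None:
        # manual size: skip the full sweep, evaluate RMSECV at that m only
        if not (0 <= m_override <= m_cap):
            raise ValueError(f"override m must be in [0, {m_cap}]")
        curve = loo_rmsecv_curve(
            A, C, candidates, m_cap, center=center, m_values=[m_override]
        )
        chosen_m = int(m_override)
    else:
        curve = loo_rmsecv_curve(A, C, candidates, m_cap, center=center)
        chosen_m = choose_augmentation_size(curve)
    C_aug = augment_concentration_matrix(C, A, candidates[:chosen_m])
    if center:
        A_c, C_c, state = core.mean_center(A, C_aug)
    else:
        A_c, C_c, state = A, C_aug, None
    K = core.fit_cls(C_c, A_c)
    selection = AugmentationSelection(
        candidate_order=tuple(candidates),
        r2=corr.r2,
        r2_threshold=r2_threshold,
        min_spacing=min_spacing,
        rmsecv_curve=curve,
        chosen_m=chosen_m,
        chosen_channels=tuple(j for j in C_aug.source_channels if j is not None),
    )
    return core.CalibrationModel(
        method="acls",
        kind="cls",
        target_label=C.target_label,
        centering=state,
        pure_spectra=K,
        components=C_aug,
        selection=selection,
        extras={"rmsecv": float(curve[chosen_m]) if np.isfinite(curve[chosen_m]) else None},
    )
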