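"""Data containers shared across the calibration pipeline.

The central objects mirror the Beer-Lambert mixture model A = C K + E:
``SpectraMatrix`` holds the observed intensities A on a wavenumber axis,
``ComponentMatrix`` holds the quantitative matrix C (true analyte
concentrations plus, after augmentation, pseudo-component columns), and
``PureSpectraEstimate`` holds the fitted per-component spectra K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

ANALYTE = "analyte"
PSEUDO = "pseudo"


class DegenerateInputError(ValueError):
    """Input too small, constant, or otherwise degenerate for the operation."""


class CollinearityError(ValueError):
    """Quantitative-matrix columns are linearly dependent beyond tolerance."""


class SingularityError(ValueError):
    """Fitted pure-spectra matrix carries no usable signal."""


def _finite_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1 (uniform spacing not required)."""

    values: np.ndarray

    def __post_init__(self):
        vals = _finite_array(self.values, "axis values", 1)
        if vals.size < 2:
            raise ValueError("axis needs at least 2 wavenumbers")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def n_channels(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class SpectraMatrix:
    """L x P observed intensities on a shared wavenumber axis."""

    intensities: np.ndarray
    axis: WavenumberAxis
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        mat = _finite_array(self.intensities, "intensities", 2)
        if mat.shape[1] != self.axis.n_channels:
            raise ValueError(
                f"intensities have {mat.shape[1]} columns but axis has "
                f"{self.axis.n_channels} wavenumbers"
            )
        ids = tuple(self.sample_ids) or tuple(f"s{i}" for i in range(mat.shape[0]))
        if len(ids) != mat.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        object.__setattr__(self, "intensities", mat)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def take(self, rows: np.ndarray) -> "SpectraMatrix":
        rows = np.asarray(rows)
        return SpectraMatrix(
            self.intensities[rows],
            self.axis,
            tuple(np.asarray(self.sample_ids, dtype=object)[rows]),
        )


@dataclass(frozen=True)
class ComponentMatrix:
    """L x M quantitative matrix: analyte concentrations plus pseudo columns.

    Exactly one column — an analyte column — is the target of calibration.
    Pseudo columns (appended spectral channels or concentration residuals)
    record the spectral channel they came from, or ``None`` when they are not
    channel-derived.
    """

    values: np.ndarray
    column_labels: tuple[str, ...]
    target_column: int = 0
    column_kinds: tuple[str, ...] = ()
    source_channels: tuple = ()

    def __post_init__(self):
        vals = _finite_array(self.values, "component values", 2)
        labels = tuple(self.column_labels)
        m = vals.shape[1]
        if m < 1:
            raise ValueError("component matrix needs at least one column")
        if len(labels) != m:
            raise ValueError("column_labels length must match the number of columns")
        kinds = tuple(self.column_kinds) or (ANALYTE,) * m
        if len(kinds) != m or any(k not in (ANALYTE, PSEUDO) for k in kinds):
            raise ValueError(f"column_kinds must be {ANALYTE!r}/{PSEUDO!r} per column")
        sources = tuple(self.source_channels) or (None,) * m
        if len(sources) != m:
            raise ValueError("source_channels length must match the number of columns")
        if not (0 <= self.target_column < m):
            raise ValueError("target_column out of range")
        if kinds[self.target_column] != ANALYTE:
            raise ValueError("target_column must point at an analyte column")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "column_labels", labels)
        object.__setattr__(self, "column_kinds", kinds)
        object.__setattr__(self, "source_channels", sources)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_columns(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.column_kinds) if k == ANALYTE)

    @property
    def pseudo_columns(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.column_kinds) if k == PSEUDO)

    @property
    def target_label(self) -> str:
        return self.column_labels[self.target_column]

    @property
    def target_values(self) -> np.ndarray:
        return self.values[:, self.target_column]

    def take(self, rows: np.ndarray) -> "ComponentMatrix":
        return replace(self, values=self.values[np.asarray(rows)])

    def select_columns(self, cols: Sequence[int]) -> "ComponentMatrix":
        """Column subset; the target must be among the kept columns."""
        cols = list(cols)
        if self.target_column not in cols:
            raise ValueError("target column must be retained")
        return ComponentMatrix(
            self.values[:, cols],
            tuple(self.column_labels[c] for c in cols),
            cols.index(self.target_column),
            tuple(self.column_kinds[c] for c in cols),
            tuple(self.source_channels[c] for c in cols),
        )

    def append_pseudo_columns(
        self,
        columns: np.ndarray,
        labels: Sequence[str],
        source_channels: Sequence | None = None,
    ) -> "ComponentMatrix":
        """Append columns flagged pseudo; analyte columns and target are untouched."""
        cols = np.atleast_2d(np.asarray(columns, dtype=float))
        if cols.shape[0] != self.n_samples:
            cols = cols.T
        if cols.shape[0] != self.n_samples:
            raise ValueError("appended columns must have one row per sample")
        k = cols.shape[1]
        if len(labels) != k:
            raise ValueError("one label per appended column required")
        sources = tuple(source_channels) if source_channels is not None else (None,) * k
        return ComponentMatrix(
            np.hstack([self.values, cols]),
            self.column_labels + tuple(labels),
            self.target_column,
            self.column_kinds + (PSEUDO,) * k,
            self.source_channels + sources,
        )


@dataclass(frozen=True)
class PureSpectraEstimate:
    """M x P fitted per-component spectra, rows aligned to ComponentMatrix columns."""

    rows: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self):
        mat = _finite_array(self.rows, "pure spectra", 2)
        if mat.shape[1] != self.axis.n_channels:
            raise ValueError("pure spectra column count must equal axis length")
        object.__setattr__(self, "rows", mat)

    @property
    def n_components(self) -> int:
        return self.rows.shape[0]


@dataclass(frozen=True)
class CenteringState:
    """Calibration-set means; re-applied identically at prediction time."""

    spectra_mean: np.ndarray
    component_mean: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "spectra_mean", _finite_array(self.spectra_mean, "spectra_mean", 1))
        object.__setattr__(self, "component_mean", _finite_array(self.component_mean, "component_mean", 1))
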