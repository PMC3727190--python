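"""Delimited-text readers and writers for spectra, concentrations and tables.

A dataset is a pair of CSV files sharing a sample-id first column: the
spectra table's header row holds the wavenumber axis (numeric, strictly
increasing) and the concentration table's header holds component labels.
Readers validate and realign rather than silently coerce.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import InterferentSpec, KineticProfile, PeakSpec, SyntheticScenario
from .types import ComponentMatrix, SpectraMatrix, WavenumberAxis

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_comparison_table",
    "read_comparison_table",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

COMPARISON_COLUMNS = ["method", "R2", "RMSEP", "p_vs_previous", "RMSECV"]


def _read_indexed_csv(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {what} table: {dupes}")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad or df.isna().any().any():
        raise ValueError(f"non-numeric cell(s) in {what} table (columns {bad or 'n/a'})")
    return df


def read_dataset(
    spectra_path, concentrations_path, target: str | None = None
) -> tuple[SpectraMatrix, ComponentMatrix]:
    """Read and align a spectra/concentration CSV pair by sample id.

    ``target`` names the analyte of interest (defaults to the first
    concentration column).
    """
    spec_df = _read_indexed_csv(spectra_path, "spectra")
    conc_df = _read_indexed_csv(concentrations_path, "concentration")
    try:
        wavenumbers = np.array([float(c) for c in spec_df.columns])
    except ValueError as err:
        raise ValueError(f"spectra header must be numeric wavenumbers: {err}") from None
    if np.any(np.diff(wavenumbers) <= 0):
        raise ValueError("spectra header wavenumbers must be strictly increasing")
    if set(spec_df.index) != set(conc_df.index):
        missing = set(spec_df.index) ^ set(conc_df.index)
        raise ValueError(f"sample ids do not match between files: {sorted(missing)[:5]}")
    conc_df = conc_df.loc[spec_df.index]
    A = SpectraMatrix(
        spec_df.to_numpy(float),
        WavenumberAxis(wavenumbers),
        tuple(str(i) for i in spec_df.index),
    )
    labels = tuple(str(c) for c in conc_df.columns)
    tgt = 0 if target is None else labels.index(target)
    C = ComponentMatrix(conc_df.to_numpy(float), labels, target_column=tgt)
    return A, C


def write_dataset(
    A: SpectraMatrix, C: ComponentMatrix, spectra_path, concentrations_path
) -> None:
    """Write the CSV pair at full float precision."""
    spec_df = pd.DataFrame(
        A.intensities,
        index=pd.Index(A.sample_ids, name="sample_id"),
        columns=[f"{w:g}" for w in A.axis.values],
    )
    spec_df.to_csv(spectra_path, float_format="%.17g")
    conc_df = pd.DataFrame(
        C.values,
        index=pd.Index(A.sample_ids, name="sample_id"),
        columns=list(C.column_labels),
    )
    conc_df.to_csv(concentrations_path, float_format="%.17g")


def write_comparison_table(table: pd.DataFrame, path) -> None:
    """Write a model-comparison table to CSV at 5 significant digits."""
    if len(table) == 0:
        raise ValueError("comparison table has no rows")
    cols = [c for c in COMPARISON_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.5g")


def read_comparison_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- scenario serialization ---------------------------------------------


def _peaks_to_list(peaks):
    return [
        {"center": p.center, "width": p.width, "amplitude": p.amplitude, "shape": p.shape}
        for p in peaks
    ]


def _peaks_from_list(items):
    return tuple(PeakSpec(**d) for d in items)


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    """Serialize a scenario as a nested key-value text config."""
    doc = {
        "name": scenario.name,
        "axis": {
            "start": scenario.axis_start,
            "stop": scenario.axis_stop,
            "step": scenario.axis_step,
        },
        "samples_per_batch": list(scenario.samples_per_batch),
        "analytes": {
            label: _peaks_to_list(peaks)
            for label, peaks in zip(scenario.analyte_labels, scenario.analyte_peaks)
        },
        "kinetics": {
            "c0": scenario.kinetics.c0,
            "k1": scenario.kinetics.k1,
            "k2": scenario.kinetics.k2,
            "t_max": scenario.kinetics.t_max,
            "grid_ratio": scenario.kinetics.grid_ratio,
        },
        "interferents": [
            {
                "kind": s.kind,
                "magnitude": s.magnitude,
                "peaks": _peaks_to_list(s.peaks),
                "drift_order": s.drift_order,
            }
            for s in scenario.interferents
        ],
        "noise_sd": scenario.noise_sd,
        "batch_kinetics_jitter": scenario.batch_kinetics_jitter,
        "seed": scenario.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def scenario_from_yaml(path) -> SyntheticScenario:
    doc = yaml.safe_load(Path(path).read_text())
    analytes = doc.get("analytes", {})
    return SyntheticScenario(
        name=doc.get("name", "custom"),
        axis_start=doc["axis"]["start"],
        axis_stop=doc["axis"]["stop"],
        axis_step=doc["axis"]["step"],
        samples_per_batch=tuple(doc["samples_per_batch"]),
        analyte_labels=tuple(analytes.keys()),
        analyte_peaks=tuple(_peaks_from_list(v) for v in analytes.values()),
        kinetics=KineticProfile(**doc["kinetics"]),
        interferents=tuple(
            InterferentSpec(
                kind=d["kind"],
                magnitude=d["magnitude"],
                peaks=_peaks_from_list(d.get("peaks", [])),
                drift_order=d.get("drift_order", 2),
            )
            for d in doc.get("interferents", [])
        ),
        noise_sd=doc.get("noise_sd", 0.0),
        batch_kinetics_jitter=doc.get("batch_kinetics_jitter", 0.0),
        seed=doc.get("seed", 0),
    )
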