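"""Shared fixtures: small algebraic problems and the benchmark scenarios."""

from dataclasses import replace

import numpy as np
import pytest

from aclscal import synth, validate
from aclscal.types import ComponentMatrix, SpectraMatrix, WavenumberAxis


def make_problem(rng, L=12, M=3, P=20, noise=0.0):
    """Random well-conditioned Beer-Lambert problem A = C K (+ noise)."""
    C = rng.uniform(0.1, 1.0, (L, M))
    K = rng.normal(size=(M, P))
    A = C @ K
    if noise:
        A = A + rng.normal(0.0, noise, A.shape)
    axis = WavenumberAxis(400.0 + 2.0 * np.arange(P))
    labels = tuple(f"c{i}" for i in range(M))
    return (
        SpectraMatrix(A, axis),
        ComponentMatrix(C, labels),
        K,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paperlike_data():
    sc = synth.make_benchmark_scenario("paperlike")
    A, C, truth = synth.generate_dataset(sc)
    return A, C, truth


@pytest.fixture(scope="session")
def paperlike_table(paperlike_data):
    """Six-method comparison on the benchmark scenario (shared: it is the
    expensive fixture)."""
    A, C, _ = paperlike_data
    return validate.compare_models(A, C)


@pytest.fixture(scope="session")
def clean_data():
    sc = synth.make_benchmark_scenario("clean")
    A, C, truth = synth.generate_dataset(sc)
    return A, C, truth


@pytest.fixture(scope="session")
def tiny_scenario():
    """Down-scaled scenario for I/O and CLI tests: short axis, 24 samples."""
    base = synth.make_benchmark_scenario("clean")
    peaks = tuple(
        tuple(p for p in plist if p.center <= 1400.0) for plist in base.analyte_peaks
    )
    return replace(
        base,
        name="tiny",
        axis_stop=1430.0,
        axis_step=4.0,
        samples_per_batch=(8, 8, 8),
        analyte_peaks=peaks,
        noise_sd=1e-4,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_scenario):
    A, C, truth = synth.generate_dataset(tiny_scenario)
    return A, C, truth
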