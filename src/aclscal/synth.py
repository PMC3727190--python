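"""Seeded generator of reaction-monitoring Raman datasets.

Emulates in-line Raman monitoring of a sequential catalytic hydrogenation
(phenylacetylene -> styrene -> ethylbenzene): several independent batches,
first-order consecutive kinetics sampled on an uneven time grid, pure
component spectra built from Gaussian/Lorentzian bands on a 230-3500 cm^-1
grid, and controllable unmodeled perturbations — extra spectral components,
baseline drift, per-sample wavelength shift, intensity nonlinearity — plus
i.i.d. Gaussian noise.  Concentrations are never noised: the reference
values stand for chromatographic ground truth.

Perturbation order is fixed: spectral components -> baseline drift ->
wavelength shift -> nonlinearity -> noise.  The full dataset is a pure
function of the scenario (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import ANALYTE, ComponentMatrix, PureSpectraEstimate, SpectraMatrix, WavenumberAxis

__all__ = [
    "PeakSpec",
    "KineticProfile",
    "InterferentSpec",
    "SyntheticScenario",
    "generate_pure_spectra",
    "generate_concentration_profiles",
    "generate_dataset",
    "make_benchmark_scenario",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center/width in cm^-1, unit-free amplitude."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        return self.amplitude * self.width**2 / (d**2 + self.width**2)


@dataclass(frozen=True)
class KineticProfile:
    """First-order consecutive kinetics A -> B -> C.

    c_A(t) = c0 e^{-k1 t};  c_B(t) = c0 k1/(k2-k1) (e^{-k1 t} - e^{-k2 t});
    c_C = c0 - c_A - c_B.  ``t_max`` is the batch duration and
    ``grid_ratio`` > 1 makes the sampling grid geometric (dense early, when
    the reaction is fast), mirroring the uneven concentration spread of a
    decelerating process.  Rate constants are per unit time; time units are
    arbitrary but shared.
    """

    c0: float = 0.4598
    k1: float = 1.0
    k2: float = 0.07
    t_max: float = 35.0
    grid_ratio: float = 1.35

    def __post_init__(self):
        if self.c0 <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("c0, k1, k2 must be positive")
        if self.k1 == self.k2:
            raise ValueError("k1 must differ from k2 (equal-rate limit not supported)")
        if self.t_max <= 0 or self.grid_ratio <= 1:
            raise ValueError("t_max must be positive and grid_ratio > 1")

    def time_grid(self, n_samples: int) -> np.ndarray:
        i = np.arange(n_samples, dtype=float)
        g = self.grid_ratio
        return self.t_max * (g**i - 1.0) / (g ** (n_samples - 1) - 1.0)

    def concentrations(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cA = self.c0 * np.exp(-self.k1 * t)
        cB = (
            self.c0
            * self.k1
            / (self.k2 - self.k1)
            * (np.exp(-self.k1 * t) - np.exp(-self.k2 * t))
        )
        cC = self.c0 - cA - cB
        return np.column_stack([cA, cB, cC])


@dataclass(frozen=True)
class InterferentSpec:
    """One unmodeled perturbation; ``magnitude`` 0 means absent.

    kinds:
      - ``spectral-component``: an extra chemical-like component with its own
        band list and a per-sample amplitude independent of the analytes:
        ``time_profile="random"`` draws it uniform on [0, magnitude];
        ``time_profile="sinusoid"`` makes it a smooth oscillation over each
        batch (``cycles`` periods, random phase per batch, slight wobble),
        emulating slow instrumental drift whose sample correlation with the
        analyte profiles stays low without being exactly zero;
      - ``baseline-drift``: per-sample random polynomial baseline of
        ``drift_order`` with maximum amplitude ``magnitude``;
      - ``wavelength-shift``: per-sample axis shift uniform on
        [-magnitude, magnitude] channels, applied by linear interpolation;
      - ``intensity-nonlinearity``: element-wise saturation x -> x - m x^2
        with m = magnitude.
    """

    kind: str
    magnitude: float = 0.0
    peaks: tuple[PeakSpec, ...] = ()
    drift_order: int = 2
    time_profile: str = "random"
    cycles: float = 2.5

    def __post_init__(self):
        kinds = (
            "spectral-component",
            "baseline-drift",
            "wavelength-shift",
            "intensity-nonlinearity",
        )
        if self.kind not in kinds:
            raise ValueError(f"unknown interferent kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("interferent magnitude must be non-negative")
        if self.time_profile not in ("random", "sinusoid"):
            raise ValueError(f"unknown time_profile {self.time_profile!r}")


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete recipe for one dataset; with the seed it fixes every byte."""

    name: str = "custom"
    axis_start: float = 230.0
    axis_stop: float = 3500.0
    axis_step: float = 2.0
    samples_per_batch: tuple[int, ...] = (16, 16, 16, 16, 16, 15, 15)
    analyte_labels: tuple[str, ...] = ("PA", "ST", "EB")
    analyte_peaks: tuple[tuple[PeakSpec, ...], ...] = ()
    kinetics: KineticProfile = field(default_factory=KineticProfile)
    interferents: tuple[InterferentSpec, ...] = ()
    noise_sd: float = 0.0
    batch_kinetics_jitter: float = 0.05
    seed: int = 0

    @property
    def n_batches(self) -> int:
        return len(self.samples_per_batch)

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_batch))

    def axis(self) -> WavenumberAxis:
        values = np.arange(self.axis_start, self.axis_stop + 0.5 * self.axis_step, self.axis_step)
        return WavenumberAxis(values)


def generate_pure_spectra(
    peaks_per_component: tuple[tuple[PeakSpec, ...], ...],
    axis: WavenumberAxis,
) -> PureSpectraEstimate:
    """True pure-component spectra: each row sums its band profiles on the axis."""
    lo, hi = axis.values[0], axis.values[-1]
    rows = np.zeros((len(peaks_per_component), axis.n_channels))
    for i, peaks in enumerate(peaks_per_component):
        for p in peaks:
            if not (lo <= p.center <= hi):
                raise ValueError(
                    f"peak center {p.center} cm^-1 lies outside the axis [{lo}, {hi}]"
                )
            rows[i] += p.profile(axis.values)
    return PureSpectraEstimate(rows, axis)


def generate_concentration_profiles(
    profile: KineticProfile,
    n_samples: int,
    labels: tuple[str, ...] = ("PA", "ST", "EB"),
    target: int = 0,
) -> ComponentMatrix:
    """Concentrations of the three species along one batch's time grid."""
    if n_samples < 2:
        raise ValueError("a batch needs at least 2 samples")
    conc = profile.concentrations(profile.time_grid(n_samples))
    return ComponentMatrix(conc, labels, target_column=target)


def _apply_wavelength_shift(row: np.ndarray, shift_channels: float) -> np.ndarray:
    idx = np.arange(row.size, dtype=float)
    return np.interp(idx, idx - shift_channels, row)


def generate_dataset(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[SpectraMatrix, ComponentMatrix, ComponentMatrix]:
    """Generate (spectra, known-analyte concentrations, full ground truth).

    The full ground-truth component matrix also carries the spectral
    interferents' per-sample amplitudes.  All randomness flows from one
    ``numpy`` generator seeded by ``seed`` (defaults to the scenario seed).
    """
    if scenario.noise_sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    axis = scenario.axis()
    if not scenario.analyte_peaks:
        raise ValueError("scenario defines no analyte peak lists")
    K_analyte = generate_pure_spectra(scenario.analyte_peaks, axis)

    # concentrations batch by batch, with jittered rate constants
    blocks = []
    t_norm_blocks = []
    for n in scenario.samples_per_batch:
        jit = scenario.batch_kinetics_jitter
        # initial charge varies batch to batch as well: without it the three
        # concentrations close to the same constant sum in every batch and
        # the centered component matrix is structurally rank deficient
        kin = replace(
            scenario.kinetics,
            c0=scenario.kinetics.c0 * float(np.exp(jit * rng.standard_normal())),
            k1=scenario.kinetics.k1 * float(np.exp(jit * rng.standard_normal())),
            k2=scenario.kinetics.k2 * float(np.exp(jit * rng.standard_normal())),
        )
        t = kin.time_grid(n)
        blocks.append(kin.concentrations(t))
        t_norm_blocks.append(t / kin.t_max)
    C_analyte = np.vstack(blocks)
    L = C_analyte.shape[0]

    A = C_analyte @ K_analyte.rows

    # 1. extra spectral components
    full_cols = [C_analyte]
    full_labels = list(scenario.analyte_labels)
    spectral = [s for s in scenario.interferents if s.kind == "spectral-component"]
    for idx, spec in enumerate(spectral):
        profile = generate_pure_spectra((spec.peaks,), axis).rows[0]
        if spec.time_profile == "sinusoid":
            parts = []
            for tn in t_norm_blocks:
                phase = rng.uniform()
                wobble = rng.normal(0.0, 0.05, size=tn.size)
                parts.append(
                    0.5 * (1.0 + np.sin(2.0 * np.pi * (spec.cycles * tn + phase)))
                    + wobble
                )
            amps = spec.magnitude * np.clip(np.concatenate(parts), 0.0, None)
        else:
            amps = rng.uniform(0.0, spec.magnitude, size=L)
        A = A + np.outer(amps, profile)
        full_cols.append(amps[:, None])
        full_labels.append(f"interferent{idx + 1}")

    # 2. baseline drift: random polynomial per sample on a [-1, 1] axis
    for spec in scenario.interferents:
        if spec.kind != "baseline-drift" or spec.magnitude == 0:
            continue
        x = np.linspace(-1.0, 1.0, axis.n_channels)
        basis = np.vstack([x**d for d in range(spec.drift_order + 1)])
        coeffs = rng.uniform(-1.0, 1.0, size=(L, spec.drift_order + 1))
        drift = coeffs @ basis
        peak = np.abs(drift).max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        A = A + spec.magnitude * drift / peak

    # 3. per-sample wavelength shift
    for spec in scenario.interferents:
        if spec.kind != "wavelength-shift" or spec.magnitude == 0:
            continue
        shifts = rng.uniform(-spec.magnitude, spec.magnitude, size=L)
        A = np.vstack([_apply_wavelength_shift(A[i], shifts[i]) for i in range(L)])

    # 4. intensity nonlinearity (quadratic saturation)
    for spec in scenario.interferents:
        if spec.kind != "intensity-nonlinearity" or spec.magnitude == 0:
            continue
        A = A - spec.magnitude * A**2

    # 5. measurement noise
    if scenario.noise_sd > 0:
        A = A + rng.normal(0.0, scenario.noise_sd, size=A.shape)

    ids = tuple(
        f"b{b}s{i}"
        for b, n in enumerate(scenario.samples_per_batch)
        for i in range(n)
    )
    spectra = SpectraMatrix(A, axis, ids)
    known = ComponentMatrix(C_analyte, scenario.analyte_labels, target_column=0)
    truth = ComponentMatrix(
        np.hstack(full_cols),
        tuple(full_labels),
        target_column=0,
        column_kinds=(ANALYTE,) * len(full_labels),
    )
    return spectra, known, truth


# --- registered benchmark scenarios -------------------------------------

_PA_PEAKS = (
    PeakSpec(2110.0, 12.0, 1.00),            # C#C stretch, the marker band
    PeakSpec(1000.0, 8.0, 0.80),             # ring breathing (shared region)
    PeakSpec(1598.0, 10.0, 0.50),
    PeakSpec(3062.0, 18.0, 0.30),            # aromatic C-H
    PeakSpec(650.0, 14.0, 0.25),
)
_ST_PEAKS = (
    PeakSpec(1631.0, 10.0, 1.00),            # vinyl C=C
    PeakSpec(1002.0, 8.0, 0.90),             # ring breathing overlaps PA's
    PeakSpec(1602.0, 9.0, 0.55),
    PeakSpec(3060.0, 18.0, 0.35),
    PeakSpec(1204.0, 10.0, 0.40),
)
_EB_PEAKS = (
    PeakSpec(1003.0, 8.0, 0.90),
    PeakSpec(2930.0, 24.0, 1.00, "lorentzian"),   # aliphatic C-H envelope
    PeakSpec(2872.0, 20.0, 0.60),
    PeakSpec(770.0, 12.0, 0.40),
    PeakSpec(1450.0, 15.0, 0.35),
)
# broad bands sitting mostly in analyte-quiet regions, with one band
# overlapping the fingerprint region so the interferent is not orthogonal
# to the analyte spectra
_INTERFERENT1 = (
    PeakSpec(450.0, 80.0, 0.60),
    PeakSpec(3360.0, 80.0, 1.00),
    PeakSpec(1080.0, 40.0, 0.30),
)
_INTERFERENT2 = (
    PeakSpec(850.0, 60.0, 0.80),
    PeakSpec(2500.0, 90.0, 1.00),
    PeakSpec(1720.0, 50.0, 0.40),
)

SCENARIO_NAMES = ("paperlike", "clean", "two_interferents")


def make_benchmark_scenario(name: str, seed: int = 0) -> SyntheticScenario:
    """Registered study scenarios.

    - ``paperlike``: 7 batches / 110 samples, consecutive-reaction kinetics
      with analyte ranges near 0-0.46 / 0-0.41 / 0-0.38 and correlated
      analytes, one unmodeled spectral interferent, mild quadratic
      nonlinearity, and Gaussian noise.
    - ``clean``: same chemistry with no interferents and no noise.
    - ``two_interferents``: two independent unmodeled spectral components
      (low noise), the information-loss stress case.
    """
    base = SyntheticScenario(
        name=name,
        analyte_peaks=(_PA_PEAKS, _ST_PEAKS, _EB_PEAKS),
        kinetics=KineticProfile(),
        seed=seed,
    )
    if name == "clean":
        return base
    if name == "paperlike":
        return replace(
            base,
            interferents=(
                InterferentSpec("spectral-component", 0.05, _INTERFERENT1),
                InterferentSpec("intensity-nonlinearity", 0.02),
            ),
            noise_sd=1e-3,
        )
    if name == "two_interferents":
        return replace(
            base,
            interferents=(
                InterferentSpec("spectral-component", 0.30, _INTERFERENT1),
                InterferentSpec("spectral-component", 0.25, _INTERFERENT2),
            ),
            noise_sd=2e-4,
        )
    raise ValueError(f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}")
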