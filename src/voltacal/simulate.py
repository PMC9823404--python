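"""Synthetic differential-pulse voltammograms for NSAID mixtures.

Stands in for electrode measurements: each analyte contributes one or two
Gaussian oxidation peaks whose height is proportional to its concentration,
on top of a linear capacitive baseline, with additive white noise.  The
default peak table places paracetamol at 0.446 V, diclofenac at 0.629 V
(with a secondary oxidation at 1.02 V), and naproxen/aspirin at 0.888 and
0.880 V — close enough that their traces are nearly collinear, which is the
property that makes the multivariate calibration problem hard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ANALYTES = ("paracetamol", "diclofenac", "naproxen", "aspirin")
INTERFERENTS = ("ascorbic_acid", "glucose", "sds")

#: fixed interferent levels, µmol/L (ascorbic acid, glucose, SDS)
DEFAULT_INTERFERENT_CONC = (80.0, 18.5, 22.0)

#: calibration domain per analyte, µmol/L
CONC_MIN, CONC_MAX = 0.5, 80.0

# Relative peak sensitivities anchored to the pH-10 peak-current ratios
# 7.26 : 8.81 : 18.10 (paracetamol : diclofenac : naproxen+aspirin combined),
# with paracetamol fixed at 0.1 µA per µmol/L.  Naproxen and aspirin split
# their combined sensitivity equally; diclofenac's second peak carries 40 %
# of its primary sensitivity.
_S_PARA = 0.1
_S_DICLO = _S_PARA * 8.81 / 7.26
_S_NAPASP = _S_PARA * 18.10 / 7.26


@dataclass(frozen=True)
class PotentialGrid:
    """Uniform anodic potential sweep (V vs. reference)."""

    start: float = 0.0
    step: float = 0.00585
    n_points: int = 177

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")

    @property
    def potentials(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian oxidation peak owned by an analyte or interferent.

    ``sensitivity`` is the peak-top current per unit concentration
    (µA per µmol/L); ``width`` is the Gaussian sigma in volts.
    """

    center: float
    width: float
    sensitivity: float
    owner: str

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be non-negative")
        if not (0.0 <= self.center <= 1.2):
            raise ValueError("peak center must lie in [0, 1.2] V")


def default_peak_table() -> list[PeakSpec]:
    """Peak table matching the reported oxidation potentials and pH-10
    peak-current proportions."""
    return [
        PeakSpec(0.446, 0.05, _S_PARA, "paracetamol"),
        PeakSpec(0.629, 0.05, _S_DICLO, "diclofenac"),
        PeakSpec(1.02, 0.05, 0.4 * _S_DICLO, "diclofenac"),
        PeakSpec(0.888, 0.05, 0.5 * _S_NAPASP, "naproxen"),
        PeakSpec(0.880, 0.05, 0.5 * _S_NAPASP, "aspirin"),
        PeakSpec(0.30, 0.05, 0.02, "ascorbic_acid"),
    ]


@dataclass(frozen=True)
class MixtureSample:
    """Concentrations (µmol/L) of the four analytes plus three interferents."""

    analyte_conc: tuple[float, float, float, float]
    interferent_conc: tuple[float, float, float] = DEFAULT_INTERFERENT_CONC

    def __post_init__(self) -> None:
        if len(self.analyte_conc) != len(ANALYTES):
            raise ValueError(f"expected {len(ANALYTES)} analyte concentrations")
        if len(self.interferent_conc) != len(INTERFERENTS):
            raise ValueError(f"expected {len(INTERFERENTS)} interferent concentrations")
        if any(c < 0 for c in self.analyte_conc):
            raise ValueError("concentrations must be non-negative")

    def concentration_of(self, owner: str) -> float:
        if owner in ANALYTES:
            return float(self.analyte_conc[ANALYTES.index(owner)])
        if owner in INTERFERENTS:
            return float(self.interferent_conc[INTERFERENTS.index(owner)])
        raise ValueError(f"unknown species label: {owner!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Baseline and additive-noise parameters.

    ``noise_sd=None`` means "auto": the set generators resolve it to 1 % of
    the maximum clean current of the generated training set.  A single-trace
    simulation requires a numeric value.
    """

    baseline_intercept: float = 0.5  # µA
    baseline_slope: float = 2.0  # µA per V
    noise_sd: float | None = None  # µA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class Voltammogram:
    """Current trace (µA) on a potential grid for one mixture sample."""

    grid: PotentialGrid
    current: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cur = np.asarray(self.current, dtype=float)
        if cur.shape != (self.grid.n_points,):
            raise ValueError("current length must equal grid.n_points")
        if not np.all(np.isfinite(cur)):
            raise ValueError("currents must be finite")
        object.__setattr__(self, "current", cur)


def _baseline(sample: MixtureSample, grid: PotentialGrid, noise: NoiseModel) -> np.ndarray:
    # glucose and SDS are not redox-active here; they only thicken the
    # capacitive baseline slope
    slope = noise.baseline_slope
    for name in ("glucose", "sds"):
        slope *= 1.0 + 0.001 * sample.concentration_of(name)
    return noise.baseline_intercept + slope * grid.potentials


def clean_current(
    sample: MixtureSample, peaks: list[PeakSpec], grid: PotentialGrid, noise: NoiseModel
) -> np.ndarray:
    """Noise-free trace: baseline plus concentration-weighted Gaussian peaks."""
    e = grid.potentials
    current = _baseline(sample, grid, noise)
    for pk in peaks:
        c = sample.concentration_of(pk.owner)
        if c == 0.0 or pk.sensitivity == 0.0:
            continue
        current = current + pk.sensitivity * c * np.exp(
            -((e - pk.center) ** 2) / (2.0 * pk.width**2)
        )
    return current


def simulate_voltammogram(
    sample: MixtureSample,
    peaks: list[PeakSpec],
    grid: PotentialGrid,
    noise: NoiseModel,
) -> Voltammogram:
    """Simulate one DPV trace.  Deterministic given ``noise.seed``."""
    if not set(ANALYTES) <= {p.owner for p in peaks}:
        missing = set(ANALYTES) - {p.owner for p in peaks}
        raise ValueError(f"peak table misses analytes: {sorted(missing)}")
    if noise.noise_sd is None:
        raise ValueError(
            "noise_sd is unresolved ('auto'); pass a numeric value or use the "
            "set generators, which resolve it from the clean training set"
        )
    current = clean_current(sample, peaks, grid, noise)
    if noise.noise_sd > 0:
        rng = np.random.default_rng(noise.seed)
        current = current + rng.normal(0.0, noise.noise_sd, size=grid.n_points)
    return Voltammogram(grid=grid, current=current)


def _as_conc_matrix(design) -> np.ndarray:
    """Accept a DesignTable (actual block) or a plain (runs × 4) array of µM."""
    actual = getattr(design, "actual", design)
    conc = np.asarray(actual, dtype=float)
    if conc.ndim != 2:
        raise ValueError("design must be a 2-D runs × factors table")
    return conc


def _clean_matrix(
    conc: np.ndarray, peaks: list[PeakSpec], grid: PotentialGrid, noise: NoiseModel
) -> np.ndarray:
    cols = []
    for row in conc:
        sample = MixtureSample(analyte_conc=tuple(row))
        cols.append(clean_current(sample, peaks, grid, noise))
    return np.column_stack(cols)


def resolve_noise(
    design, peaks: list[PeakSpec], grid: PotentialGrid, noise: NoiseModel
) -> NoiseModel:
    """Resolve an 'auto' noise level to 1 % of the maximum clean current of
    the given design's voltammogram set."""
    if noise.noise_sd is not None:
        return noise
    conc = _as_conc_matrix(design)
    clean = _clean_matrix(conc, peaks, grid, noise)
    return replace(noise, noise_sd=0.01 * float(np.max(clean)))


def generate_training_set(
    design,
    peaks: list[PeakSpec] | None = None,
    grid: PotentialGrid | None = None,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltammogram matrix (n_points × runs) and concentration matrix
    (4 × runs) for a designed calibration set.

    Columns follow the design row order.  Concentrations must lie inside
    the calibration domain [0.5, 80] µmol/L.
    """
    peaks = default_peak_table() if peaks is None else peaks
    grid = PotentialGrid() if grid is None else grid
    noise = NoiseModel() if noise is None else noise
    conc = _as_conc_matrix(design)
    if conc.shape[1] != len(ANALYTES):
        raise ValueError("training design needs one factor per analyte")
    if np.any(conc < CONC_MIN) or np.any(conc > CONC_MAX):
        raise ValueError(
            f"designed concentrations must lie in [{CONC_MIN}, {CONC_MAX}] µmol/L"
        )
    clean = _clean_matrix(conc, peaks, grid, noise)
    if noise.noise_sd is None:
        noise = replace(noise, noise_sd=0.01 * float(np.max(clean)))
    rng = np.random.default_rng(noise.seed)
    v = clean + rng.normal(0.0, noise.noise_sd, size=clean.shape)
    return v, conc.T.copy()


def generate_random_test_set(
    n: int,
    seed: int,
    peaks: list[PeakSpec] | None = None,
    grid: PotentialGrid | None = None,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """External validation set: per-analyte concentrations i.i.d. uniform on
    [0.5, 80] µmol/L.  Returns (n_points × n, 4 × n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    peaks = default_peak_table() if peaks is None else peaks
    grid = PotentialGrid() if grid is None else grid
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(seed)
    conc = rng.uniform(CONC_MIN, CONC_MAX, size=(n, len(ANALYTES)))
    if noise.noise_sd is None:
        # resolve against the default factorial calibration set, the same
        # reference the training generator uses
        from .design import full_factorial, to_actual, FactorRange

        ff = to_actual(
            full_factorial(3, 4),
            [FactorRange(a, CONC_MIN, CONC_MAX, "umol/L") for a in ANALYTES],
        )
        noise = resolve_noise(ff, peaks, grid, noise)
    clean = _clean_matrix(conc, peaks, grid, noise)
    noise_rng = np.random.default_rng(noise.seed)
    v = clean + noise_rng.normal(0.0, noise.noise_sd, size=clean.shape)
    return v, conc.T.copy()
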