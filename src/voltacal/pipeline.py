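"""End-to-end workflow: design -> simulate -> compress -> calibrate -> report.

A :class:`PipelineConfig` (JSON-serializable, round-trip identical) fixes
every stage; a single global seed deterministically derives per-stage seeds
by stage-name hashing, so each artifact is regenerable from config + seed
alone.  On-disk orientation follows the field convention: voltammogram and
coefficient matrices are features × samples, concentration tables are one
row per sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .calibration import (
    CalibrationDataset,
    MLPCalibrator,
    PLSCalibrator,
)
from .compression import WaveletCompressor
from .design import FactorRange, full_factorial, to_actual
from .metrics import EvaluationReport, evaluate_model
from .simulate import ANALYTES, INTERFERENTS, NoiseModel, PotentialGrid


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 1
    # design
    levels: int = 3
    factors: int = 4
    conc_low: float = sim.CONC_MIN
    conc_high: float = sim.CONC_MAX
    n_test: int = 10
    # simulator
    baseline_intercept: float = 0.5
    baseline_slope: float = 2.0
    noise_sd: float | None = None  # None = 1 % of max clean training current
    # compression
    wavelet: str = "db4"
    level: int = 3
    # calibration
    n_components: int = 12
    mlp_hidden: tuple[int, ...] = (16, 8)
    mlp_solver: str = "lm_bayes"
    mlp_target_error: float = 0.015
    mlp_max_epochs: int = 2000
    mlp_noise_augmentation: bool = True  # jitter inputs with the known noise_sd
    mlp_n_augment: int = 10
    # metrics
    confidence: float = 0.95
    intercept_unit: str = "mol_per_L"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mlp_hidden" in d:
            d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: PipelineConfig
    grid: PotentialGrid
    train_voltammograms: np.ndarray  # n_points × n_train
    train_concentrations: np.ndarray  # 4 × n_train
    test_voltammograms: np.ndarray
    test_concentrations: np.ndarray
    compressor: WaveletCompressor
    mean_comparison_factor: float
    train: CalibrationDataset
    test: CalibrationDataset
    pls: PLSCalibrator
    mlp: MLPCalibrator
    pls_report: EvaluationReport
    mlp_report: EvaluationReport


def run_full_pipeline(
    config: PipelineConfig | None = None, outdir=None
) -> PipelineResult:
    """Run every stage in order and optionally persist all artifacts.

    Re-running with the same config is bit-identical (the MLP is seeded from
    the global seed like every other stage).
    """
    cfg = PipelineConfig() if config is None else config
    grid = PotentialGrid()
    peaks = sim.default_peak_table()

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        ranges = [
            FactorRange(a, cfg.conc_low, cfg.conc_high, "umol/L") for a in ANALYTES
        ]
        design = to_actual(full_factorial(cfg.levels, cfg.factors), ranges)
    except Exception as exc:  # pragma: no cover - defensive
        _fail("design", exc)

    try:
        noise = NoiseModel(
            baseline_intercept=cfg.baseline_intercept,
            baseline_slope=cfg.baseline_slope,
            noise_sd=cfg.noise_sd,
            seed=stage_seed(cfg.seed, "train_noise"),
        )
        noise = sim.resolve_noise(design, peaks, grid, noise)
        v_train, c_train = sim.generate_training_set(design, peaks, grid, noise)
        test_noise = dataclasses.replace(
            noise, seed=stage_seed(cfg.seed, "test_noise")
        )
        v_test, c_test = sim.generate_random_test_set(
            cfg.n_test,
            stage_seed(cfg.seed, "test_concentrations"),
            peaks,
            grid,
            test_noise,
        )
    except Exception as exc:
        _fail("simulate", exc)

    try:
        compressor = WaveletCompressor(wavelet=cfg.wavelet, level=cfg.level)
        X_train = compressor.fit_transform(v_train.T)
        X_test = compressor.transform(v_test.T)
        mean_cf = compressor.mean_comparison_factor(v_train.T)
    except Exception as exc:
        _fail("compress", exc)

    train = CalibrationDataset(X=X_train, Y=c_train.T, role="training")
    test = CalibrationDataset(X=X_test, Y=c_test.T, role="testing")

    try:
        pls = PLSCalibrator(n_components=cfg.n_components).fit(train.X, train.Y)
        mlp = MLPCalibrator(
            hidden_layer_sizes=cfg.mlp_hidden,
            solver=cfg.mlp_solver,
            target_error=cfg.mlp_target_error,
            input_noise_sd=noise.noise_sd if cfg.mlp_noise_augmentation else None,
            n_augment=cfg.mlp_n_augment,
            max_epochs=cfg.mlp_max_epochs,
            random_state=stage_seed(cfg.seed, "mlp_init"),
        ).fit(train.X, train.Y)
    except Exception as exc:
        _fail("calibrate", exc)

    try:
        pls_report = evaluate_model(
            pls, train, test, cfg.confidence, cfg.intercept_unit
        )
        mlp_report = evaluate_model(
            mlp, train, test, cfg.confidence, cfg.intercept_unit
        )
    except Exception as exc:
        _fail("evaluate", exc)

    result = PipelineResult(
        config=cfg,
        grid=grid,
        train_voltammograms=v_train,
        train_concentrations=c_train,
        test_voltammograms=v_test,
        test_concentrations=c_test,
        compressor=compressor,
        mean_comparison_factor=mean_cf,
        train=train,
        test=test,
        pls=pls,
        mlp=mlp,
        pls_report=pls_report,
        mlp_report=mlp_report,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def voltammogram_frame(v: np.ndarray, grid: PotentialGrid) -> pd.DataFrame:
    cols = {"potential_V": grid.potentials}
    for j in range(v.shape[1]):
        cols[f"s{j + 1:03d}"] = v[:, j]
    return pd.DataFrame(cols)


def concentration_frame(c: np.ndarray) -> pd.DataFrame:
    """Samples as rows; analytes plus the fixed interferent levels."""
    n = c.shape[1]
    data = {f"{name}_uM": c[i] for i, name in enumerate(ANALYTES)}
    defaults = dict(zip(INTERFERENTS, sim.DEFAULT_INTERFERENT_CONC))
    rename = {"ascorbic_acid": "ascorbic", "glucose": "glucose", "sds": "sds"}
    for name in INTERFERENTS:
        data[f"{rename[name]}_uM"] = np.full(n, defaults[name])
    return pd.DataFrame(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: PipelineResult, outdir: Path) -> dict:
    """Write every stage artifact plus a manifest with content hashes.

    Files already present with a manifest-matching hash are left untouched,
    so re-runs skip up-to-date artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    old_hashes = {}
    if manifest_path.exists():
        old_hashes = json.loads(manifest_path.read_text()).get("artifacts", {})

    def _write(name: str, text: str):
        path = outdir / name
        digest = hashlib.sha256(text.encode()).hexdigest()
        if old_hashes.get(name) == digest and path.exists():
            return name, digest
        path.write_text(text)
        return name, digest

    cfg = result.config
    entries = dict(
        [
            _write("config.json", json.dumps(cfg.to_dict(), indent=2) + "\n"),
            _write(
                "train_voltammograms.csv",
                voltammogram_frame(result.train_voltammograms, result.grid).to_csv(
                    index=False
                ),
            ),
            _write(
                "test_voltammograms.csv",
                voltammogram_frame(result.test_voltammograms, result.grid).to_csv(
                    index=False
                ),
            ),
            _write(
                "train_concentrations.csv",
                concentration_frame(result.train_concentrations).to_csv(index=False),
            ),
            _write(
                "test_concentrations.csv",
                concentration_frame(result.test_concentrations).to_csv(index=False),
            ),
            _write(
                "train_compressed.csv",
                pd.DataFrame(
                    result.train.X.T,
                    columns=[f"s{j + 1:03d}" for j in range(result.train.n_samples)],
                ).to_csv(index=False),
            ),
            _write(
                "compression.json",
                json.dumps(
                    {
                        "wavelet": cfg.wavelet,
                        "level": cfg.level,
                        "original_length": result.compressor.original_length_,
                        "mean_comparison_factor": result.mean_comparison_factor,
                    },
                    indent=2,
                )
                + "\n",
            ),
            _write(
                "pls_regression.csv",
                result.pls_report.regression_frame().to_csv(index=False),
            ),
            _write(
                "mlp_regression.csv",
                result.mlp_report.regression_frame().to_csv(index=False),
            ),
            _write(
                "recovery.csv",
                pd.merge(
                    result.pls_report.recovery_frame(),
                    result.mlp_report.recovery_frame(),
                    on="analyte",
                    suffixes=("_pls", "_mlp"),
                ).to_csv(index=False),
            ),
            _write(
                "mlp_lod_loq.csv",
                result.mlp_report.sensitivity_frame().to_csv(index=False),
            ),
        ]
    )
    manifest = {"seed": cfg.seed, "artifacts": entries}
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
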