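"""Analytical figures of merit.

Obtained-vs-expected linear regression (R, slope, intercept with 95 %
t-based half-widths, residual SD), recovery yield
Ry = (100/N) * sum(obtained_i / expected_i), and detection limits
LOD = 3 sigma / m, LOQ = 10 sigma / m with sigma the residual standard
deviation of the obtained-vs-expected regression and m its slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationDataset
from .simulate import ANALYTES


@dataclass(frozen=True)
class RegressionComparison:
    R: float
    m: float
    delta_m: float
    b: float
    delta_b: float
    n: int
    sigma_res: float
    confidence: float = 0.95


@dataclass(frozen=True)
class RecoveryReport:
    per_sample_recovery: np.ndarray  # %
    Ry: float  # mean recovery, %
    N: int


@dataclass(frozen=True)
class SensitivityReport:
    LOD: float  # µmol/L
    LOQ: float  # µmol/L
    sigma: float
    m: float


def regression_comparison(
    obtained, expected, confidence: float = 0.95
) -> RegressionComparison:
    """OLS of obtained on expected; the ideal model gives the identity line."""
    obtained = np.asarray(obtained, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if obtained.shape != expected.shape:
        raise ValueError("vectors must have equal length")
    n = len(obtained)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(expected) == 0:
        raise ValueError("expected values have zero variance")
    fit = stats.linregress(expected, obtained)
    resid = obtained - (fit.intercept + fit.slope * expected)
    sigma_res = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    t = stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, n - 2)
    return RegressionComparison(
        R=float(fit.rvalue),
        m=float(fit.slope),
        delta_m=float(t * fit.stderr),
        b=float(fit.intercept),
        delta_b=float(t * fit.intercept_stderr),
        n=n,
        sigma_res=sigma_res,
        confidence=confidence,
    )


def recovery_yield(obtained, expected) -> RecoveryReport:
    """Mean percent recovery over an external set; 100 % is ideal."""
    obtained = np.asarray(obtained, dtype=float).ravel()
    expected = np.asarray(expected, dtype=float).ravel()
    if obtained.shape != expected.shape:
        raise ValueError("vectors must have equal length")
    if np.any(expected == 0):
        raise ValueError("recovery undefined for zero expected concentration")
    per_sample = 100.0 * obtained / expected
    return RecoveryReport(
        per_sample_recovery=per_sample,
        Ry=float(np.mean(per_sample)),
        N=len(obtained),
    )


def lod_loq(comparison: RegressionComparison) -> SensitivityReport:
    """Detection and quantification limits from a calibration regression."""
    if comparison.m <= 0:
        raise ValueError("calibration slope must be positive")
    sigma = comparison.sigma_res
    return SensitivityReport(
        LOD=3.0 * sigma / comparison.m,
        LOQ=10.0 * sigma / comparison.m,
        sigma=sigma,
        m=comparison.m,
    )


@dataclass(frozen=True)
class AnalyteReport:
    analyte: str
    training: RegressionComparison
    testing: RegressionComparison
    recovery_training: RecoveryReport
    recovery_testing: RecoveryReport
    sensitivity: SensitivityReport


@dataclass(frozen=True)
class EvaluationReport:
    per_analyte: dict[str, AnalyteReport]
    intercept_unit: str

    def regression_frame(self) -> pd.DataFrame:
        """Regression table (one row per analyte, training and testing
        columns) mirroring the conventional obtained-vs-expected layout.
        Intercepts are reported in ``intercept_unit``."""
        scale = 1e-6 if self.intercept_unit == "mol_per_L" else 1.0
        rows = []
        for name, rep in self.per_analyte.items():
            row = {"analyte": name}
            for stage, reg in (("training", rep.training), ("testing", rep.testing)):
                row[f"{stage}_R"] = reg.R
                row[f"{stage}_m"] = reg.m
                row[f"{stage}_dm"] = reg.delta_m
                row[f"{stage}_b"] = reg.b * scale
                row[f"{stage}_db"] = reg.delta_b * scale
            rows.append(row)
        return pd.DataFrame(rows)

    def recovery_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analyte": name,
                    "Ry_training_pct": rep.recovery_training.Ry,
                    "Ry_testing_pct": rep.recovery_testing.Ry,
                }
                for name, rep in self.per_analyte.items()
            ]
        )

    def sensitivity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analyte": name,
                    "LOD_uM": rep.sensitivity.LOD,
                    "LOQ_uM": rep.sensitivity.LOQ,
                }
                for name, rep in self.per_analyte.items()
            ]
        )


def evaluate_model(
    model,
    train: CalibrationDataset,
    test: CalibrationDataset,
    confidence: float = 0.95,
    intercept_unit: str = "mol_per_L",
    analyte_names: tuple[str, ...] = ANALYTES,
) -> EvaluationReport:
    """Full per-analyte report: obtained-vs-expected regressions (training
    and testing), recovery yields, and LOD/LOQ from the testing regression.

    Concentrations are handled in µmol/L; regression intercepts are converted
    to mol/L in the tabular output when ``intercept_unit='mol_per_L'``.
    """
    if intercept_unit not in ("mol_per_L", "umol_per_L"):
        raise ValueError("intercept_unit must be 'mol_per_L' or 'umol_per_L'")
    pred_train = model.predict(train.X)
    pred_test = model.predict(test.X)
    reports = {}
    for j, name in enumerate(analyte_names):
        reg_tr = regression_comparison(pred_train[:, j], train.Y[:, j], confidence)
        reg_te = regression_comparison(pred_test[:, j], test.Y[:, j], confidence)
        reports[name] = AnalyteReport(
            analyte=name,
            training=reg_tr,
            testing=reg_te,
            recovery_training=recovery_yield(pred_train[:, j], train.Y[:, j]),
            recovery_testing=recovery_yield(pred_test[:, j], test.Y[:, j]),
            sensitivity=lod_loq(reg_te),
        )
    return EvaluationReport(per_analyte=reports, intercept_unit=intercept_unit)
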