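"""Experimental-design tables: 3^k full factorials and Box–Behnken designs.

Designs are stored in coded units (levels in {-1, 0, +1}) with an optional
actual-unit block obtained by an affine map per factor.  Run order is
deterministic (lexicographic for factorials, pair-ordered for Box–Behnken);
no randomization is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FactorRange:
    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low must be < high")


@dataclass(frozen=True)
class DesignTable:
    factor_names: tuple[str, ...]
    coded: np.ndarray
    kind: str  # "full_factorial" | "box_behnken"
    actual: np.ndarray | None = None

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float)
        object.__setattr__(self, "coded", coded)
        if coded.ndim != 2 or coded.shape[1] != len(self.factor_names):
            raise ValueError("coded block must be runs × factors")
        if self.actual is not None:
            actual = np.asarray(self.actual, dtype=float)
            if actual.shape != coded.shape:
                raise ValueError("actual block must match coded block shape")
            object.__setattr__(self, "actual", actual)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {"run": np.arange(1, self.n_runs + 1)}
        for j, name in enumerate(self.factor_names):
            data[f"{name}_coded"] = self.coded[:, j]
        if self.actual is not None:
            for j, name in enumerate(self.factor_names):
                data[f"{name}_actual"] = self.actual[:, j]
        return pd.DataFrame(data)


def full_factorial(levels: int, factors: int, factor_names=None) -> DesignTable:
    """Full factorial in coded units, lexicographic run order.

    For ``levels=3`` the coded levels are {-1, 0, +1}; in general they are
    equally spaced on [-1, 1].
    """
    if levels < 2:
        raise ValueError("levels must be at least 2")
    if factors < 1:
        raise ValueError("factors must be at least 1")
    coded_levels = np.linspace(-1.0, 1.0, levels)
    rows = list(itertools.product(coded_levels, repeat=factors))
    names = tuple(factor_names) if factor_names else tuple(
        f"X{i + 1}" for i in range(factors)
    )
    return DesignTable(factor_names=names, coded=np.array(rows), kind="full_factorial")


def box_behnken(factors: int, center_points: int = 3, factor_names=None) -> DesignTable:
    """Box–Behnken design: for every factor pair the four (±1, ±1) edge
    midpoints with remaining factors at 0, plus all-zero center runs."""
    if factors not in (3, 4, 5):
        raise ValueError("Box–Behnken construction supported for 3–5 factors")
    if center_points < 1:
        raise ValueError("at least one center point is required")
    rows = []
    for i, j in itertools.combinations(range(factors), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = np.zeros(factors)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(factors) for _ in range(center_points))
    names = tuple(factor_names) if factor_names else tuple(
        f"X{i + 1}" for i in range(factors)
    )
    return DesignTable(factor_names=names, coded=np.array(rows), kind="box_behnken")


def to_actual(design: DesignTable, ranges: list[FactorRange]) -> DesignTable:
    """Attach physical units: coded -1/0/+1 map to low/midpoint/high."""
    if len(ranges) != len(design.factor_names):
        raise ValueError(
            f"need {len(design.factor_names)} factor ranges, got {len(ranges)}"
        )
    low = np.array([r.low for r in ranges])
    high = np.array([r.high for r in ranges])
    actual = low + (design.coded + 1.0) / 2.0 * (high - low)
    return DesignTable(
        factor_names=tuple(r.name for r in ranges),
        coded=design.coded,
        kind=design.kind,
        actual=actual,
    )


def to_coded(actual: np.ndarray, ranges: list[FactorRange]) -> np.ndarray:
    """Inverse of the affine map used by :func:`to_actual`."""
    actual = np.asarray(actual, dtype=float)
    low = np.array([r.low for r in ranges])
    high = np.array([r.high for r in ranges])
    return 2.0 * (actual - low) / (high - low) - 1.0


#: default physical windows for the four DPV instrument factors; chosen to
#: bracket the optimized settings (0.00585 V, 0.75 s, 0.05 s, 0.05 V)
DEFAULT_DPV_RANGES = [
    FactorRange("step_potential", 0.002, 0.01, "V"),
    FactorRange("interval_time", 0.25, 1.25, "s"),
    FactorRange("modulation_time", 0.05, 0.25, "s"),
    FactorRange("modulation_amplitude", 0.025, 0.125, "V"),
]
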