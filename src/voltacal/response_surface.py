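"""Second-order response-surface models for DPV parameter optimization.

A :class:`QuadraticResponseSurface` is a full quadratic polynomial in k coded
factors (intercept, k linear, k pure-quadratic and C(k,2) two-way interaction
terms; 14 coefficients for the four DPV factors).  The package ships the
three published coefficient sets mapping coded (step potential, interval
time, modulation time, modulation amplitude) to the anodic peak currents of
paracetamol, diclofenac and the combined naproxen/aspirin response, and a
multi-response optimizer over the coded cube.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .design import DesignTable, FactorRange, to_actual


def _interaction_pairs(k: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(k), 2))


def quadratic_expansion(x: np.ndarray) -> np.ndarray:
    """Design-matrix columns [1, x_i, x_i^2, x_i x_j (i<j)] for coded points."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    cols = [np.ones(len(x))]
    cols.extend(x[:, i] for i in range(x.shape[1]))
    cols.extend(x[:, i] ** 2 for i in range(x.shape[1]))
    cols.extend(x[:, i] * x[:, j] for i, j in _interaction_pairs(x.shape[1]))
    return np.column_stack(cols)


class QuadraticResponseSurface(RegressorMixin, BaseEstimator):
    """Full second-order polynomial fitted by least squares on coded factors.

    Parameters
    ----------
    response_name : str
        Label for the modeled response (e.g. an analyte peak current).

    Attributes
    ----------
    intercept_ : float
    linear_ : ndarray of shape (k,)
    quadratic_ : ndarray of shape (k,)
        Pure-quadratic coefficients, one per factor.
    interaction_ : ndarray of shape (k*(k-1)/2,)
        Two-way interactions in lexicographic pair order
        (1,2), (1,3), ..., (k-1,k).
    """

    def __init__(self, response_name: str = "response"):
        self.response_name = response_name

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        k = X.shape[1]
        n_terms = 1 + 2 * k + k * (k - 1) // 2
        if X.shape[0] < n_terms + 1:
            raise ValueError(
                f"need at least {n_terms + 1} runs to fit {n_terms} coefficients"
            )
        Z = quadratic_expansion(X)
        if np.linalg.matrix_rank(Z) < n_terms:
            raise ValueError("rank-deficient expanded design")
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        self._unpack(k, beta)
        self.n_features_in_ = k
        return self

    def _unpack(self, k: int, beta: np.ndarray) -> None:
        self.intercept_ = float(beta[0])
        self.linear_ = beta[1 : 1 + k].copy()
        self.quadratic_ = beta[1 + k : 1 + 2 * k].copy()
        self.interaction_ = beta[1 + 2 * k :].copy()
        self.n_factors_ = k

    @property
    def coefficients_(self) -> np.ndarray:
        check_is_fitted(self, "intercept_")
        return np.concatenate(
            [[self.intercept_], self.linear_, self.quadratic_, self.interaction_]
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "intercept_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_factors_:
            raise ValueError(f"expected {self.n_factors_} coded factors")
        return quadratic_expansion(X) @ self.coefficients_

    def evaluate(self, x) -> float:
        """Predicted response (µA) at a single coded point."""
        return float(self.predict(np.atleast_2d(x))[0])

    @classmethod
    def from_coefficients(
        cls, intercept, linear, quadratic, interaction, response_name="response"
    ) -> "QuadraticResponseSurface":
        model = cls(response_name=response_name)
        linear = np.asarray(linear, dtype=float)
        k = len(linear)
        if len(quadratic) != k or len(interaction) != k * (k - 1) // 2:
            raise ValueError("inconsistent coefficient block lengths")
        beta = np.concatenate([[intercept], linear, quadratic, interaction])
        if not np.all(np.isfinite(beta)):
            raise ValueError("coefficients must be finite")
        model._unpack(k, beta)
        model.n_features_in_ = k
        return model

    def to_dict(self) -> dict:
        check_is_fitted(self, "intercept_")
        return {
            "response": self.response_name,
            "intercept": self.intercept_,
            "linear": self.linear_.tolist(),
            "quadratic": self.quadratic_.tolist(),
            "interaction": self.interaction_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticResponseSurface":
        return cls.from_coefficients(
            d["intercept"],
            d["linear"],
            d["quadratic"],
            d["interaction"],
            response_name=d.get("response", "response"),
        )


def fit_quadratic(design: DesignTable | np.ndarray, response, response_name="response"):
    """Least-squares fit of the 14-term quadratic on a coded design."""
    coded = design.coded if isinstance(design, DesignTable) else design
    return QuadraticResponseSurface(response_name=response_name).fit(coded, response)


def evaluate(model: QuadraticResponseSurface, x) -> float:
    return model.evaluate(x)


def load_reported_models() -> list[QuadraticResponseSurface]:
    """The three published peak-current models (paracetamol, diclofenac,
    naproxen/aspirin combined) in coded factors, from packaged fixtures."""
    models = []
    data_dir = resources.files("voltacal") / "data"
    for name in ("paracetamol", "diclofenac", "naproxen_aspirin"):
        text = (data_dir / f"rsm_{name}.json").read_text()
        models.append(QuadraticResponseSurface.from_dict(json.loads(text)))
    return models


@dataclass(frozen=True)
class OptimizationResult:
    coded_optimum: np.ndarray
    predicted_responses: dict[str, float]
    composite_score: float
    grid_score: float  # best composite value among evaluated grid points
    actual_optimum: np.ndarray | None = None


def optimize(
    models: list[QuadraticResponseSurface],
    weights=None,
    grid_points: int = 41,
    ranges: list[FactorRange] | None = None,
) -> OptimizationResult:
    """Maximize a weighted sum of min-max-normalized responses over the coded
    cube [-1, 1]^k.

    Dense grid search (``grid_points`` per axis) locates the basin; a bounded
    local polish refines it.  Normalization constants (per-response min/max)
    are frozen from the grid so the composite is well defined off-grid.  Ties
    on the grid break toward the lexicographically smallest coded point.
    """
    if not models:
        raise ValueError("need at least one model")
    k = models[0].n_factors_
    if any(m.n_factors_ != k for m in models):
        raise ValueError("all models must share the factor space")
    weights = np.ones(len(models)) if weights is None else np.asarray(weights, float)
    if len(weights) != len(models) or np.any(weights < 0):
        raise ValueError("weights must be non-negative, one per model")

    axes = [np.linspace(-1.0, 1.0, grid_points)] * k
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)  # lexicographic order

    lo, hi = np.empty(len(models)), np.empty(len(models))
    norm_sum = np.zeros(len(pts))
    for idx, (model, w) in enumerate(zip(models, weights)):
        vals = model.predict(pts)
        lo[idx], hi[idx] = vals.min(), vals.max()
        span = hi[idx] - lo[idx] if hi[idx] > lo[idx] else 1.0
        norm_sum += w * (vals - lo[idx]) / span

    best = int(np.argmax(norm_sum))  # first max = lowest lexicographic point
    x0, score0 = pts[best], float(norm_sum[best])

    def neg_composite(x):
        total = 0.0
        for idx, (model, w) in enumerate(zip(models, weights)):
            span = hi[idx] - lo[idx] if hi[idx] > lo[idx] else 1.0
            total += w * (model.evaluate(x) - lo[idx]) / span
        return -total

    res = minimize(neg_composite, x0, method="L-BFGS-B", bounds=[(-1, 1)] * k)
    if res.success and -res.fun > score0:
        x_opt, score = np.clip(res.x, -1, 1), float(-res.fun)
    else:
        x_opt, score = x0, score0

    predicted = {m.response_name: m.evaluate(x_opt) for m in models}
    actual = None
    if ranges is not None:
        table = to_actual(
            DesignTable(
                factor_names=tuple(r.name for r in ranges),
                coded=np.atleast_2d(x_opt),
                kind="box_behnken",
            ),
            ranges,
        )
        actual = table.actual[0]
    return OptimizationResult(
        coded_optimum=x_opt,
        predicted_responses=predicted,
        composite_score=score,
        grid_score=score0,
        actual_optimum=actual,
    )
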