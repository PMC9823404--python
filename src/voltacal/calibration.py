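"""Concentration-prediction models on wavelet-compressed voltammograms.

Two calibrators map 28 approximation coefficients to the four NSAID
concentrations:

* :class:`PLSCalibrator` — NIPALS partial least squares (default 12 latent
  variables) with cross-validated component selection;
* :class:`MLPCalibrator` — a 28 × 16 × 8 × 4 multilayer perceptron (identity
  input stage, tanh hidden layers, linear output) trained by
  Levenberg–Marquardt steps under Bayesian regularization: the objective
  F = beta * sum(residuals^2) + alpha * sum(weights^2) with (alpha, beta)
  re-estimated each epoch by MacKay's evidence approximation.  Inputs and
  targets are min-max scaled to [-1, 1]; predictions are returned in
  original units.  A plain gradient-descent-with-momentum solver is also
  provided for the configuration (learning rate 0.05, momentum 0.5) that
  only makes sense in that mode.

In-memory convention throughout: samples are rows (sklearn orientation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass(frozen=True)
class CalibrationDataset:
    """Coefficient matrix X (n_samples × n_features) and concentration
    matrix Y (n_samples × 4, µmol/L)."""

    X: np.ndarray
    Y: np.ndarray
    role: str = "training"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of samples")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


class PLSCalibrator(RegressorMixin, BaseEstimator):
    """Partial least squares regression (NIPALS) for multi-analyte calibration.

    Parameters
    ----------
    n_components : int, default 12
        Number of latent variables.

    Attributes
    ----------
    x_mean_, y_mean_ : centering vectors.
    x_weights_, x_loadings_, y_loadings_ : per-component vectors.
    regression_coefficients_ : ndarray (n_features, n_targets)
        Prediction is ``(X - x_mean_) @ regression_coefficients_ + y_mean_``.
    """

    def __init__(self, n_components: int = 12):
        self.n_components = n_components

    def fit(self, X, Y):
        X = check_array(X)
        Y = check_array(Y, ensure_2d=False)
        if Y.ndim == 1:
            Y = Y[:, None]
        bound = min(X.shape[1], X.shape[0] - 1)
        if not 1 <= self.n_components <= bound:
            raise ValueError(
                f"n_components must be in [1, {bound}] for this dataset"
            )
        zero_var = np.ptp(X, axis=0) == 0
        if np.any(zero_var):
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance predictor column(s)",
                stacklevel=2,
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, Y)
        self.x_mean_ = self._pls._x_mean
        self.y_mean_ = self._pls._y_mean
        self.x_weights_ = self._pls.x_weights_
        self.x_loadings_ = self._pls.x_loadings_
        self.y_loadings_ = self._pls.y_loadings_
        self.regression_coefficients_ = self._pls.coef_.T
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "regression_coefficients_")
        X = check_array(X)
        return (X - self.x_mean_) @ self.regression_coefficients_ + self.y_mean_


def pls_fit(train: CalibrationDataset, n_components: int = 12) -> PLSCalibrator:
    return PLSCalibrator(n_components=n_components).fit(train.X, train.Y)


def select_components(
    train: CalibrationDataset, k_folds: int = 10, max_components: int | None = None
) -> int:
    """Component count minimizing mean k-fold cross-validated RMSE over the
    analytes; ties break toward fewer components.  Folds are contiguous and
    deterministic."""
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    n = train.n_samples
    hard_bound = min(train.X.shape[1], n - max(2, n // k_folds) - 1)
    if max_components is None:
        max_components = hard_bound
    if not 1 <= max_components <= hard_bound:
        raise ValueError(f"max_components must be in [1, {hard_bound}]")
    kf = KFold(n_splits=k_folds, shuffle=False)
    rmse = np.empty(max_components)
    for k in range(1, max_components + 1):
        sq = []
        for tr_idx, va_idx in kf.split(train.X):
            model = PLSCalibrator(n_components=k).fit(
                train.X[tr_idx], train.Y[tr_idx]
            )
            resid = model.predict(train.X[va_idx]) - train.Y[va_idx]
            sq.append(np.mean(resid**2))
        rmse[k - 1] = np.sqrt(np.mean(sq))
    return int(np.argmin(rmse)) + 1  # argmin takes the first (fewest) on ties


# ---------------------------------------------------------------------------
# multilayer perceptron with Bayesian regularization
# ---------------------------------------------------------------------------


def _minmax_params(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column affine map onto [-1, 1]; constant columns map to 0."""
    lo, hi = M.min(axis=0), M.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    return lo, span


def _scale(M, lo, span):
    return 2.0 * (M - lo) / span - 1.0


def _unscale(M, lo, span):
    return (M + 1.0) / 2.0 * span + lo


class MLPCalibrator(RegressorMixin, BaseEstimator):
    """Feed-forward network for concentration prediction.

    Architecture: identity input stage, tanh hidden layers (default 16 and
    8 units), linear output — the classic 28 × 16 × 8 × 4 layout when fed
    28 wavelet coefficients and 4 analytes.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int, default (16, 8)
    solver : {"lm_bayes", "sgd"}, default "lm_bayes"
        ``lm_bayes``: Levenberg–Marquardt steps on the Bayesian-regularized
        objective with MacKay evidence re-estimation of (alpha, beta).
        ``sgd``: full-batch gradient descent with momentum on the scaled MSE.
    target_error : float, default 0.015
        Stop when the mean squared error of the (un-augmented) training set
        on [-1, 1]-scaled targets drops to this level.
    input_noise_sd : float, ndarray or None, default None
        Known measurement-noise standard deviation of the input
        coefficients (original units).  When set, each epoch trains on the
        original samples plus ``n_augment`` copies perturbed with fresh
        Gaussian noise of this magnitude — Tikhonov-type robustification
        matched to the instrument noise, which keeps the network from
        amplifying poorly determined directions (the nearly collinear
        naproxen/aspirin responses) when it interpolates the training set.
    n_augment : int, default 10
        Number of noise-perturbed copies per epoch when ``input_noise_sd``
        is set.
    learning_rate, momentum : float
        Used by the ``sgd`` solver only.
    max_epochs : int, default 2000
    warmup_epochs : int, default 200
        LM epochs run with fixed (alpha = 0, beta = 1) before evidence
        re-estimation starts.  MacKay's update assumes the weights sit near
        a minimum of the current objective; re-estimating (alpha, beta) from
        a random initialization inflates alpha and traps the network in an
        over-regularized basin, so the hyperparameters are frozen until the
        data misfit has been driven down (or the error goal has stopped
        training, whichever comes first).
    random_state : int, default 0
        Seeds the uniform [-0.5, 0.5] weight initialization and the
        augmentation noise.

    Attributes
    ----------
    coefs_, intercepts_ : per-layer weight matrices and bias vectors.
    objective_curve_ : objective value after each accepted step.
    objective_improvements_ : per-step decrease of the objective (>= 0 by
        construction: steps are only accepted if they lower it).
    n_epochs_ : epochs actually run.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (16, 8),
        solver: str = "lm_bayes",
        target_error: float = 0.015,
        input_noise_sd=None,
        n_augment: int = 10,
        learning_rate: float = 0.05,
        momentum: float = 0.5,
        max_epochs: int = 2000,
        warmup_epochs: int = 200,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.solver = solver
        self.target_error = target_error
        self.input_noise_sd = input_noise_sd
        self.n_augment = n_augment
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.warmup_epochs = warmup_epochs
        self.random_state = random_state

    # -- parameter vector packing ------------------------------------------

    def _shapes(self, d_in: int, d_out: int):
        sizes = (d_in, *self.hidden_layer_sizes, d_out)
        return [(sizes[i + 1], sizes[i]) for i in range(len(sizes) - 1)]

    def _unpack(self, w: np.ndarray, shapes):
        Ws, bs, pos = [], [], 0
        for out_d, in_d in shapes:
            Ws.append(w[pos : pos + out_d * in_d].reshape(out_d, in_d))
            pos += out_d * in_d
            bs.append(w[pos : pos + out_d])
            pos += out_d
        return Ws, bs

    @staticmethod
    def _forward(Z0, Ws, bs):
        """Activations per layer; hidden layers tanh, output linear."""
        acts = [Z0]
        a = Z0
        for W, b in zip(Ws[:-1], bs[:-1]):
            a = np.tanh(a @ W.T + b)
            acts.append(a)
        acts.append(a @ Ws[-1].T + bs[-1])
        return acts

    def _jacobian(self, acts, Ws):
        """Jacobian of flattened residuals (sample-major, then output) with
        respect to the packed parameter vector."""
        n = acts[0].shape[0]
        d_out = acts[-1].shape[1]
        P = sum(W.size + W.shape[0] for W in Ws)
        J = np.zeros((n, d_out, P))
        # parameter offsets per layer
        offsets = []
        pos = 0
        for W in Ws:
            offsets.append(pos)
            pos += W.size + W.shape[0]
        for o in range(d_out):
            # output layer: d y_o / d W_last[o, :] = a_prev; bias = 1
            W_last = Ws[-1]
            off = offsets[-1]
            row0 = off + o * W_last.shape[1]
            J[:, o, row0 : row0 + W_last.shape[1]] = acts[-2]
            J[:, o, off + W_last.size + o] = 1.0
            # hidden layers, backwards
            delta = (1.0 - acts[-2] ** 2) * W_last[o]  # (n, h_last)
            for layer in range(len(Ws) - 2, -1, -1):
                W = Ws[layer]
                off = offsets[layer]
                a_prev = acts[layer]
                J[:, o, off : off + W.size] = np.einsum(
                    "nh,nk->nhk", delta, a_prev
                ).reshape(n, -1)
                J[:, o, off + W.size : off + W.size + W.shape[0]] = delta
                if layer > 0:
                    delta = (delta @ W) * (1.0 - acts[layer] ** 2)
        return J.reshape(n * d_out, P)

    # -- training ----------------------------------------------------------

    def fit(self, X, Y):
        X = check_array(X)
        Y = check_array(Y, ensure_2d=False)
        if Y.ndim == 1:
            Y = Y[:, None]
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise ValueError("training data must be finite")
        if self.solver not in ("lm_bayes", "sgd"):
            raise ValueError(f"unknown solver {self.solver!r}")

        self.x_min_, self.x_span_ = _minmax_params(X)
        self.y_min_, self.y_span_ = _minmax_params(Y)
        Z0 = _scale(X, self.x_min_, self.x_span_)
        T = _scale(Y, self.y_min_, self.y_span_)

        shapes = self._shapes(X.shape[1], Y.shape[1])
        P = sum(o * i + o for o, i in shapes)
        rng = np.random.default_rng(self.random_state)
        w = rng.uniform(-0.5, 0.5, size=P)

        if self.input_noise_sd is None:
            draw_batch = None
        else:
            sd = np.broadcast_to(
                np.asarray(self.input_noise_sd, dtype=float), (X.shape[1],)
            )

            def draw_batch():
                X_aug = np.vstack(
                    [X]
                    + [
                        X + rng.normal(0.0, 1.0, X.shape) * sd
                        for _ in range(self.n_augment)
                    ]
                )
                Y_aug = np.vstack([Y] * (self.n_augment + 1))
                return (
                    _scale(X_aug, self.x_min_, self.x_span_),
                    _scale(Y_aug, self.y_min_, self.y_span_),
                )

        if self.solver == "lm_bayes":
            w = self._fit_lm_bayes(w, Z0, T, shapes, P, draw_batch)
        else:
            w = self._fit_sgd(w, Z0, T, shapes)

        self.coefs_, self.intercepts_ = self._unpack(w, shapes)
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_lm_bayes(self, w, Z0, T, shapes, P, draw_batch=None):
        clean_N = T.size
        alpha, beta = 0.0, 1.0
        mu = 1e-3
        eye = np.eye(P)
        curve, improvements = [], []
        warming_up = self.warmup_epochs > 0
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            Ws, bs = self._unpack(w, shapes)
            # the stopping criterion is evaluated on the un-augmented set
            e_clean = (self._forward(Z0, Ws, bs)[-1] - T).ravel()
            if float(e_clean @ e_clean) / clean_N <= self.target_error:
                break

            if draw_batch is None:
                Zb, Tb = Z0, T
            else:
                Zb, Tb = draw_batch()  # fresh noise-perturbed copies
            N = Tb.size
            acts = self._forward(Zb, Ws, bs)
            e = (acts[-1] - Tb).ravel()
            Ed, Ew = float(e @ e), float(w @ w)
            J = self._jacobian(acts, Ws)
            JtJ = J.T @ J

            if warming_up and epoch > self.warmup_epochs:
                warming_up = False
                mu = 1e-3
            if not warming_up:
                # MacKay evidence update; the effective parameter count
                # gamma is kept strictly below N so beta stays positive
                if alpha == 0.0:
                    gamma = float(P)  # limit of P - 2a*tr(H^-1) as a -> 0+
                else:
                    H = 2.0 * beta * JtJ + 2.0 * alpha * eye
                    gamma = P - 2.0 * alpha * np.trace(np.linalg.inv(H))
                gamma = float(np.clip(gamma, 0.0, min(P, 0.99 * N)))
                alpha = gamma / max(2.0 * Ew, 1e-12)
                beta = min((N - gamma) / max(2.0 * Ed, 1e-12), 1e10)

            F = beta * Ed + alpha * Ew
            g = beta * (J.T @ e) + alpha * w
            accepted = False
            while mu <= 1e10:
                A = beta * JtJ + (alpha + mu) * eye
                try:
                    step = -np.linalg.solve(A, g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                w_try = w + step
                Ws_t, bs_t = self._unpack(w_try, shapes)
                e_t = (self._forward(Zb, Ws_t, bs_t)[-1] - Tb).ravel()
                F_try = beta * float(e_t @ e_t) + alpha * float(w_try @ w_try)
                if np.isfinite(F_try) and F_try < F:
                    improvements.append(F - F_try)
                    curve.append(F_try)
                    w = w_try
                    mu = max(mu * 0.1, 1e-20)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                if warming_up:
                    # warm-up converged: hand over to the evidence phase
                    warming_up = False
                    mu = 1e-3
                    continue
                if draw_batch is not None:
                    mu = 1e-3  # next epoch sees a fresh draw
                    continue
                break  # trust region collapsed: local optimum
        self.objective_curve_ = np.array(curve)
        self.objective_improvements_ = np.array(improvements)
        self.alpha_, self.beta_ = alpha, beta
        self.n_epochs_ = epoch
        return w

    def _fit_sgd(self, w, Z0, T, shapes):
        N = T.size
        velocity = np.zeros_like(w)
        curve = []
        epoch = 0
        for epoch in range(1, self.max_epochs + 1):
            Ws, bs = self._unpack(w, shapes)
            acts = self._forward(Z0, Ws, bs)
            e = (acts[-1] - T).ravel()
            mse = float(e @ e) / N
            curve.append(mse)
            if mse <= self.target_error:
                break
            J = self._jacobian(acts, Ws)
            grad = (2.0 / N) * (J.T @ e)
            velocity = self.momentum * velocity - self.learning_rate * grad
            w = w + velocity
        self.objective_curve_ = np.array(curve)
        self.objective_improvements_ = -np.diff(np.array(curve))
        self.n_epochs_ = epoch
        return w

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} input features")
        Z0 = _scale(X, self.x_min_, self.x_span_)
        out = self._forward(Z0, self.coefs_, self.intercepts_)[-1]
        return _unscale(out, self.y_min_, self.y_span_)


def mlp_fit(train: CalibrationDataset, **config) -> MLPCalibrator:
    return MLPCalibrator(**config).fit(train.X, train.Y)


def predict(model, X) -> np.ndarray:
    """Concentrations (µmol/L) for coefficient rows X (n_samples × 28)."""
    return model.predict(X)
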