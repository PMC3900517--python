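"""The six decoders behind one train/predict contract.

Every decoder maps a population response vector to a scalar whose sign is
the predicted state of the binary variable (the tie sign(0) = +1 is fixed
globally).  The decoders are:

``r_ole``
    Regularized optimal linear estimator: ridge regression of the +/-1
    label on the population vector, W = argmin ||W R - C||^2 + lambda
    ||W||^2, solved in closed form on a centred design with a free bias;
    lambda is selected per fit on an inner validation split.
``ann_ole`` / ``ann_nle``
    Feed-forward network estimators with a hyperbolic-tangent transfer,
    zero (OLE) or n/2 (NLE) hidden units, trained by a quasi-Newton
    (limited-memory BFGS) batch optimizer on the regularized cost
    msereg = r * mse + (1 - r) * msw (equal weighting r = 0.5 by default,
    msw the mean square of all weights and biases).
``bayes``
    Gaussian naive Bayes / maximum-likelihood decoder: per-cell
    class-conditional Gaussians with class-specific variances, equal
    priors, decision by the log-posterior computed in log space.
``reservoir`` / ``reservoir_memory``
    Echo-state readout: a fixed random input projection (uniform [0, 1)
    weights times a scale factor), leaky-integrator nodes
    x(t) = (1 - 1/tau) x(t-1) + (1/tau) f(W_in u(t)) with no recurrent
    interconnections, and a Tikhonov-regularized linear readout trained on
    all time steps of a training window.  The static variant (identity
    transfer, tau = 1, scale 10^-1.2, 75 ms window) is algebraically a
    ridge regression on the projected inputs; the memory variant (tanh,
    tau = 55, scale 10^-3.8, wide window) integrates past inputs.
``svm``
    Soft-margin SVM with Gaussian RBF kernel K(x, y) = exp(-gamma
    ||x - y||^2); (cost, gamma) selected by 5-fold cross-validated
    accuracy on the training set.

Inputs are z-scored per cell with training-partition statistics before the
network, reservoir and SVM fits (switchable); ``r_ole`` and ``bayes``
operate on raw rates with an explicit bias / mean term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

log = logging.getLogger(__name__)

KINDS = ("r_ole", "ann_ole", "ann_nle", "bayes", "reservoir", "reservoir_memory", "svm")

#: default hyperparameter grids / constants
R_OLE_LAMBDA_GRID = tuple(10.0 ** np.arange(-6, 4))  # 10^-6 .. 10^3
SVM_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
SVM_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))
RESERVOIR_NODES = 500
STATIC_INPUT_SCALE = 10.0 ** -1.2
MEMORY_INPUT_SCALE = 10.0 ** -3.8
MEMORY_TAU = 55.0
STATIC_TRAIN_HALFWIDTH = 37  # 75 ms window around the training reference


def sign_pm(values: np.ndarray) -> np.ndarray:
    """Binary label from a scalar output; the tie sign(0) = +1."""
    return np.where(np.asarray(values) >= 0, 1, -1)


@dataclass(frozen=True)
class DecoderSpec:
    """Declarative choice of decoder kind plus hyperparameter overrides."""

    kind: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown decoder kind {self.kind!r}")
        allowed = {
            "r_ole": {"lambda_grid", "zscore"},
            "ann_ole": {"reg_ratio", "max_epochs", "gtol", "restarts", "zscore"},
            "ann_nle": {"reg_ratio", "max_epochs", "gtol", "restarts", "zscore"},
            "bayes": {"var_floor_ratio"},
            "reservoir": {"n_nodes", "input_scale", "ridge_lambda", "zscore",
                          "train_halfwidth"},
            "reservoir_memory": {"n_nodes", "input_scale", "ridge_lambda", "tau",
                                 "train_window", "zscore"},
            "svm": {"c_grid", "gamma_grid", "zscore"},
        }[self.kind]
        unknown = set(self.params) - allowed
        if unknown:
            raise ValueError(f"invalid parameters for {self.kind}: {sorted(unknown)}")

    @property
    def is_time_resolved(self) -> bool:
        return self.kind in ("reservoir", "reservoir_memory")


class _Scaler:
    """Per-cell z-scoring with training-partition statistics."""

    def __init__(self, X: np.ndarray, enabled: bool = True):
        # X: (n_cells, n_samples) or (n_cells, trials, time)
        flat = X.reshape(X.shape[0], -1)
        if enabled:
            self.mu = flat.mean(axis=1)
            sd = flat.std(axis=1)
            self.sd = np.where(sd > 0, sd, 1.0)
        else:
            self.mu = np.zeros(X.shape[0])
            self.sd = np.ones(X.shape[0])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        shape = (-1,) + (1,) * (X.ndim - 1)
        return (X - self.mu.reshape(shape)) / self.sd.reshape(shape)


# ---------------------------------------------------------------------------
# Regularized optimal linear estimator


@dataclass
class LinearDecoder:
    kind: str
    weights: np.ndarray  # (n_cells,)
    bias: float
    lam: float | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.weights @ X + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sign_pm(self.decision_values(X))


def _ridge_closed_form(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Ridge normal equations on the centred design; bias unpenalized.

    X is (n_cells, n_trials); returns (W, bias).
    """
    xm = X.mean(axis=1)
    ym = y.mean()
    Xc = X - xm[:, None]
    yc = y - ym
    A = Xc @ Xc.T + lam * np.eye(X.shape[0])
    w = np.linalg.solve(A, Xc @ yc) if lam > 0 else np.linalg.lstsq(Xc.T, yc, rcond=None)[0]
    return w, float(ym - w @ xm)


def fit_r_ole(
    X_train: np.ndarray,
    y_train: np.ndarray,
    lambda_grid: tuple[float, ...] = R_OLE_LAMBDA_GRID,
    rng: np.random.Generator | None = None,
    n_inner_folds: int = 5,
) -> LinearDecoder:
    """Closed-form Tikhonov-regularized linear readout.

    The regularization weight is selected per fit by stratified inner
    cross-validated accuracy on the training partition (ties resolve to
    the strongest regularization, which guards against the instability of
    weakly regularized solutions near the interpolation threshold), then
    the decoder is refit on the full training set.
    """
    y_train = np.asarray(y_train, dtype=float)
    lambda_grid = tuple(lambda_grid)
    rng = rng or np.random.default_rng(0)
    best_lam = lambda_grid[0]
    folds = _stratified_folds(y_train, n_inner_folds, rng)
    if len(lambda_grid) > 1 and len(folds) >= 2:
        best_acc = -1.0
        for lam in lambda_grid:  # ascending; >= keeps the largest winner
            correct = 0
            total = 0
            for val in folds:
                tr = np.setdiff1d(np.arange(y_train.size), val)
                w, b = _ridge_closed_form(X_train[:, tr], y_train[tr], lam)
                correct += np.sum(sign_pm(w @ X_train[:, val] + b) == y_train[val])
                total += val.size
            if correct / total >= best_acc:
                best_lam, best_acc = lam, correct / total
    w, b = _ridge_closed_form(X_train, y_train, best_lam)
    return LinearDecoder("r_ole", w, b, lam=best_lam)


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Stratified validation folds; degenerate classes yield no folds."""
    neg = rng.permutation(np.flatnonzero(y == -1))
    pos = rng.permutation(np.flatnonzero(y == 1))
    k = min(n_folds, neg.size, pos.size)
    if k < 2:
        return []
    return [
        np.concatenate([chunk_n, chunk_p])
        for chunk_n, chunk_p in zip(np.array_split(neg, k), np.array_split(pos, k))
    ]


# ---------------------------------------------------------------------------
# Feed-forward network estimators (tanh transfer, quasi-Newton batch fit)


@dataclass
class NetworkDecoder:
    kind: str
    scaler: _Scaler
    weights: list[np.ndarray]  # [W1, b1, w2, b2] or [w, b]
    converged: bool = True

    def _forward(self, Z: np.ndarray) -> np.ndarray:
        if len(self.weights) == 2:
            w, b = self.weights
            return np.tanh(w @ Z + b)
        W1, b1, w2, b2 = self.weights
        return np.tanh(w2 @ np.tanh(W1 @ Z + b1[:, None]) + b2)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self._forward(self.scaler(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sign_pm(self.decision_values(X))


def _ann_cost_grad(
    theta: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    hidden: int,
    reg_ratio: float,
) -> tuple[float, np.ndarray]:
    """msereg = r*mse + (1-r)*msw and its gradient, by backpropagation."""
    n, m = Z.shape
    P = theta.size
    if hidden == 0:
        w, b = theta[:n], theta[n]
        out = np.tanh(w @ Z + b)
        err = out - y
        dpre = (2.0 / m) * err * (1.0 - out**2)
        gw = Z @ dpre
        gb = dpre.sum()
        grad_mse = np.concatenate([gw, [gb]])
    else:
        W1 = theta[: hidden * n].reshape(hidden, n)
        b1 = theta[hidden * n : hidden * n + hidden]
        w2 = theta[hidden * n + hidden : hidden * n + 2 * hidden]
        b2 = theta[-1]
        H = np.tanh(W1 @ Z + b1[:, None])
        out = np.tanh(w2 @ H + b2)
        err = out - y
        d2 = (2.0 / m) * err * (1.0 - out**2)
        gw2 = H @ d2
        gb2 = d2.sum()
        d1 = (w2[:, None] * d2[None, :]) * (1.0 - H**2)
        gW1 = d1 @ Z.T
        gb1 = d1.sum(axis=1)
        grad_mse = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    mse = float(np.mean((out - y) ** 2))
    msw = float(np.mean(theta**2))
    cost = reg_ratio * mse + (1.0 - reg_ratio) * msw
    grad = reg_ratio * grad_mse + (1.0 - reg_ratio) * (2.0 / P) * theta
    return cost, grad


def ann_cost(
    theta: np.ndarray, Z: np.ndarray, y: np.ndarray, hidden: int, reg_ratio: float
) -> float:
    """The regularized network cost alone (exposed for unit checks)."""
    return _ann_cost_grad(theta, Z, y, hidden, reg_ratio)[0]


def fit_ann(
    X_train: np.ndarray,
    y_train: np.ndarray,
    hidden_units: int,
    rng: np.random.Generator,
    reg_ratio: float = 0.5,
    max_epochs: int = 200,
    gtol: float = 1e-6,
    restarts: int = 1,
    zscore: bool = True,
) -> NetworkDecoder:
    """Train the linear (hidden_units = 0) or non-linear network estimator.

    ``hidden_units`` must be 0 or round(n_cells / 2).  Optimized with
    L-BFGS (quasi-Newton batch back-propagation); on non-convergence the
    best parameters so far are returned with a logged warning.  One random
    restart; the lower-cost solution wins.
    """
    n = X_train.shape[0]
    if hidden_units not in (0, round(n / 2)):
        raise ValueError("hidden_units must be 0 or round(n_cells / 2)")
    scaler = _Scaler(X_train, enabled=zscore)
    Z = scaler(X_train)
    y = np.asarray(y_train, dtype=float)

    n_params = n + 1 if hidden_units == 0 else hidden_units * (n + 2) + 1
    best = None
    converged = False
    for _ in range(1 + restarts):
        theta0 = rng.standard_normal(n_params) / np.sqrt(max(n, 1))
        res = minimize(
            _ann_cost_grad,
            theta0,
            args=(Z, y, hidden_units, reg_ratio),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_epochs, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or res.success
    if not converged:
        log.warning("network fit did not converge; returning best-so-far")
    theta = best.x
    if hidden_units == 0:
        weights = [theta[:n], theta[n]]
    else:
        h = hidden_units
        weights = [
            theta[: h * n].reshape(h, n),
            theta[h * n : h * n + h],
            theta[h * n + h : h * n + 2 * h],
            theta[-1],
        ]
    kind = "ann_ole" if hidden_units == 0 else "ann_nle"
    return NetworkDecoder(kind, scaler, weights, converged=converged)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes / maximum-likelihood decoder


@dataclass
class BayesDecoder:
    kind: str
    mu: np.ndarray  # (2, n_cells): class -1 row 0, class +1 row 1
    sd: np.ndarray  # (2, n_cells)

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        """(2, m) summed log densities, classes ordered [-1, +1]."""
        X = np.atleast_2d(X)
        ll = np.empty((2, X.shape[1]))
        for k in range(2):
            mu = self.mu[k][:, None]
            sd = self.sd[k][:, None]
            ll[k] = np.sum(
                -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((X - mu) / sd) ** 2,
                axis=0,
            )
        return ll

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        ll = self.log_likelihoods(X)
        return ll[1] - ll[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sign_pm(self.decision_values(X))


def fit_bayes(
    X_train: np.ndarray,
    y_train: np.ndarray,
    var_floor_ratio: float = 1e-3,
) -> BayesDecoder:
    """Per-cell class-conditional Gaussians with class-specific variances.

    Class priors are equal by design (balanced conditions).  Zero or
    near-zero standard deviations (e.g. from duplicated trials) are floored
    at ``var_floor_ratio`` times the pooled standard deviation across cells
    and classes.
    """
    y_train = np.asarray(y_train)
    for cond in (-1, 1):
        if np.sum(y_train == cond) < 2:
            raise ValueError("need at least 2 trials per class per cell")
    mu = np.stack([X_train[:, y_train == c].mean(axis=1) for c in (-1, 1)])
    sd = np.stack([X_train[:, y_train == c].std(axis=1, ddof=1) for c in (-1, 1)])
    pooled = sd.mean()
    floor = var_floor_ratio * pooled if pooled > 0 else 1e-6
    n_floored = int(np.sum(sd < floor))
    if n_floored:
        log.info("floored %d degenerate cell variances", n_floored)
    sd = np.maximum(sd, floor)
    return BayesDecoder("bayes", mu, sd)


# ---------------------------------------------------------------------------
# Reservoir readouts


@dataclass
class ReservoirDecoder:
    kind: str
    scaler: _Scaler
    W_in: np.ndarray  # (n_nodes, n_cells)
    readout: np.ndarray  # (n_nodes,)
    bias: float
    tau: float
    transfer: Callable[[np.ndarray], np.ndarray]

    def states_over_time(
        self, traces: np.ndarray, times: np.ndarray | None = None
    ) -> np.ndarray:
        """Leaky-integrated node states (n_nodes, m, len(times)); x(-1) = 0.

        With tau = 1 the state is the instantaneous drive f(W_in u(t));
        otherwise integration runs from the trace start (t = 0) and only
        the requested time points are materialized.
        """
        Z = self.scaler(traces)
        T = Z.shape[2]
        times = np.arange(T) if times is None else np.asarray(times)
        if self.tau == 1.0:
            return self.transfer(
                np.tensordot(self.W_in, Z[:, :, times], axes=(1, 0))
            )
        n_nodes = self.W_in.shape[0]
        m = Z.shape[1]
        states = np.empty((n_nodes, m, times.size))
        keep = {int(t): k for k, t in enumerate(times)}
        x = np.zeros((n_nodes, m))
        a = 1.0 - 1.0 / self.tau
        for t in range(int(times.max()) + 1):
            x = a * x + (1.0 - a) * self.transfer(self.W_in @ Z[:, :, t])
            if t in keep:
                states[:, :, keep[t]] = x
        return states

    def decision_over_time(
        self, traces: np.ndarray, times: np.ndarray | None = None
    ) -> np.ndarray:
        """(m, len(times)) readout values for traces aligned at t = 0."""
        states = self.states_over_time(traces, times)
        return np.tensordot(self.readout, states, axes=(0, 0)) + self.bias

    def predict_over_time(
        self, traces: np.ndarray, times: np.ndarray | None = None
    ) -> np.ndarray:
        return sign_pm(self.decision_over_time(traces, times))


def fit_reservoir(
    traces_train: np.ndarray,
    y_train: np.ndarray,
    train_window: tuple[int, int],
    rng: np.random.Generator,
    n_nodes: int = RESERVOIR_NODES,
    transfer: str = "identity",
    input_scale: float = STATIC_INPUT_SCALE,
    tau: float = 1.0,
    ridge_lambda: float = 1e-6,
    zscore: bool = True,
) -> ReservoirDecoder:
    """Fix a random input projection and train the ridge readout.

    ``traces_train`` is (n_cells, m, T) of event-aligned rate traces; node
    states are integrated from t = 0 and the readout is fit, by Tikhonov-
    regularized regression, to map the states at every time step of
    ``train_window`` (half-open) onto the constant trial label.  tau = 1
    disables the leak (static reservoir); tau < 1 is a configuration error.
    """
    if tau < 1:
        raise ValueError("time constant tau must be >= 1")
    if transfer == "identity":
        f = lambda v: v
    elif transfer == "tanh":
        f = np.tanh
    else:
        raise ValueError(f"unknown transfer {transfer!r}")
    n_cells, m, T = traces_train.shape
    t0, t1 = train_window
    if not (0 <= t0 < t1 <= T):
        raise ValueError("training window exceeds trial bounds")
    scaler = _Scaler(traces_train[:, :, t0:t1], enabled=zscore)
    W_in = rng.random((n_nodes, n_cells)) * input_scale
    dec = ReservoirDecoder("reservoir", scaler, W_in, np.zeros(n_nodes), 0.0, tau, f)
    states = dec.states_over_time(traces_train, np.arange(t0, t1))  # (nodes, m, L)
    S = states.reshape(n_nodes, -1)  # columns: trial-major? see targets below
    targets = np.repeat(np.asarray(y_train, dtype=float)[:, None], t1 - t0, axis=1).reshape(-1)
    # S columns are (trial, time) pairs in the same order as targets
    sm = S.mean(axis=1)
    ym = targets.mean()
    Sc = S - sm[:, None]
    A = Sc @ Sc.T + ridge_lambda * np.eye(n_nodes)
    w = np.linalg.solve(A, Sc @ (targets - ym))
    dec.readout = w
    dec.bias = float(ym - w @ sm)
    return dec


def static_reservoir_spec_params() -> dict:
    return dict(input_scale=STATIC_INPUT_SCALE, ridge_lambda=1e-6)


# ---------------------------------------------------------------------------
# Support vector machine


@dataclass
class SvmDecoder:
    kind: str
    scaler: _Scaler
    model: SVC
    cost: float
    gamma: float

    @property
    def support_vectors(self) -> np.ndarray:
        return self.model.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """alpha_j * C_j for each support vector."""
        return self.model.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(self.scaler(X).T)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sign_pm(self.decision_values(X))


def fit_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    rng: np.random.Generator,
    c_grid: tuple[float, ...] = SVM_C_GRID,
    gamma_grid: tuple[float, ...] = SVM_GAMMA_GRID,
    zscore: bool = True,
) -> SvmDecoder:
    """RBF-kernel SVM with (cost, gamma) chosen by 5-fold CV accuracy.

    Each training set is split into 5 stratified folds; every fold is used
    exactly once for validation.  Ties resolve to the first (smallest)
    grid entry.  The winning pair is refit on the full training set.
    """
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("SVM training requires both classes present")
    for cond in (-1, 1):
        if np.sum(y_train == cond) < 5:
            raise ValueError("need at least 5 trials per class for 5-fold CV")
    scaler = _Scaler(X_train, enabled=zscore)
    Z = scaler(X_train).T  # samples x features
    folds = StratifiedKFold(
        n_splits=5, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    splits = list(folds.split(Z, y_train))
    best = (c_grid[0], gamma_grid[0])
    best_acc = -1.0
    for C in c_grid:
        for gamma in gamma_grid:
            correct = 0
            total = 0
            for tr, va in splits:
                model = SVC(C=C, gamma=gamma, kernel="rbf")
                model.fit(Z[tr], y_train[tr])
                correct += np.sum(model.predict(Z[va]) == y_train[va])
                total += va.size
            acc = correct / total
            if acc > best_acc:
                best, best_acc = (C, gamma), acc
    model = SVC(C=best[0], gamma=best[1], kernel="rbf")
    model.fit(Z, y_train)
    return SvmDecoder("svm", scaler, model, cost=best[0], gamma=best[1])


def svm_kernel_expansion(decoder: SvmDecoder, X: np.ndarray) -> np.ndarray:
    """Decision values recomputed from the stored support-vector expansion,
    sum_j alpha_j C_j exp(-gamma ||x_j - x||^2) + b."""
    Z = decoder.scaler(X).T
    sv = decoder.support_vectors
    d2 = ((Z[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    return (decoder.dual_coef[None, :] * np.exp(-decoder.gamma * d2)).sum(axis=1) + decoder.intercept


# ---------------------------------------------------------------------------
# Dispatch


def predict(decoder, X: np.ndarray) -> np.ndarray:
    """Vectorized label prediction under the global tie rule."""
    return sign_pm(decoder.decision_values(X))


def train_decoder(
    spec: DecoderSpec,
    seed,
    t_train: int,
    rng: np.random.Generator | None = None,
):
    """Fit the decoder described by ``spec`` on a seed's training partition.

    Static decoders train on the population matrix at ``t_train``; the
    reservoir variants train on their time window (75 ms around
    ``t_train`` for the static reservoir, an explicit ``train_window`` —
    default (70, 500) — for the memory variant).
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    p = dict(spec.params)
    y_train = seed.y[seed.train_idx]
    if spec.kind in ("reservoir", "reservoir_memory"):
        traces = seed.X_window(0, seed.duration, seed.train_idx)
        if spec.kind == "reservoir":
            hw = p.pop("train_halfwidth", STATIC_TRAIN_HALFWIDTH)
            window = (t_train - hw, t_train + hw + 1)
            return fit_reservoir(
                traces, y_train, window, rng, transfer="identity", tau=1.0, **p
            )
        window = p.pop("train_window", (70, 500))
        return fit_reservoir(
            traces, y_train, window, rng, transfer="tanh",
            tau=p.pop("tau", MEMORY_TAU),
            input_scale=p.pop("input_scale", MEMORY_INPUT_SCALE), **p,
        )
    X_train = seed.X_at(t_train, seed.train_idx)
    if spec.kind == "r_ole":
        return fit_r_ole(X_train, y_train, rng=rng, **p)
    if spec.kind == "ann_ole":
        return fit_ann(X_train, y_train, hidden_units=0, rng=rng, **p)
    if spec.kind == "ann_nle":
        return fit_ann(
            X_train, y_train, hidden_units=round(X_train.shape[0] / 2), rng=rng, **p
        )
    if spec.kind == "bayes":
        return fit_bayes(X_train, y_train, **p)
    if spec.kind == "svm":
        return fit_svm(X_train, y_train, rng=rng, **p)
    raise AssertionError("unreachable")
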