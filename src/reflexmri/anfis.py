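"""Adaptive noise cancellation with a first-order Takagi-Sugeno ANFIS.

The artifact on the measurement channel is a nonlinear function of the
interference observable on the reference channel.  A grid-partition fuzzy
inference system (generalized-bell membership functions, product T-norm,
first-order Sugeno consequents) maps the interference inputs
``(r, r_dot, theta)`` to the artifact estimate ``w_hat``, and the clean
EMG is recovered as ``x_hat = y - w_hat``.

Training is the classic hybrid scheme: per epoch the linear consequents
are solved exactly by least squares given the current premises, then one
normalized gradient step is taken on the premise parameters.  A
contiguous validation interval is redrawn at a seeded random start every
epoch; the returned model is the per-epoch snapshot with minimum
validation RMSE, which guards against the system overfitting the muscle
signal buried in the training target.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

_EPS = 1e-12


def build_inputs(segment) -> np.ndarray:
    """Interference input matrix ``[r, r_dot, theta]`` from a trial segment.

    The derivative is computed by central differences (one-sided at the
    ends) scaled by the sampling rate; the encoder series is linearly
    resampled onto the segment grid if its length differs.
    """
    r = np.asarray(segment.r, dtype=float)
    theta = np.asarray(segment.theta, dtype=float)
    n = len(r)
    if len(theta) != n:
        theta = np.interp(
            np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, len(theta)), theta
        )
    r_dot = np.gradient(r) * segment.fs
    X = np.column_stack([r, r_dot, theta])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in interference inputs")
    return X


class AnfisRegressor(BaseEstimator, RegressorMixin):
    """First-order Sugeno ANFIS trained by hybrid LSE/backpropagation.

    Parameters
    ----------
    n_mfs : membership functions per input (grid partition; default 2,
        the classic grid-partition default -- with three inputs this gives
        8 rules / 32 consequent coefficients, keeping the consequent solve
        well-determined on a 400-sample trial window).
    mf_type : 'gbell' (generalized bell) or 'gaussian'.
    epochs : training epochs; each performs one exact consequent solve and
        one premise gradient step.
    step_size : initial premise step length (normalized gradient step).
    step_increase, step_decrease : adaptive step-size factors (increase
        after 4 consecutive error drops, decrease on oscillation).
    val_fraction : fraction of samples held out as one contiguous
        validation interval, redrawn each epoch.
    random_state : seed for the validation-interval draws.

    Attributes (after fit)
    ----------------------
    premise_ : (n_inputs, n_mfs, 3) array of (a, b, c) per membership
        function -- width, slope, center.
    consequents_ : (n_rules, n_inputs + 1) linear coefficients (bias last).
    trace_ : dict with per-epoch 'train_rmse' and 'val_rmse' arrays.
    selected_epoch_ : 1-based index of the minimum-validation-RMSE epoch
        whose parameter snapshot the fitted model carries.
    """

    def __init__(
        self,
        n_mfs: int = 2,
        mf_type: str = "gbell",
        epochs: int = 10,
        step_size: float = 0.01,
        step_increase: float = 1.1,
        step_decrease: float = 0.9,
        val_fraction: float = 0.2,
        random_state=None,
    ):
        self.n_mfs = n_mfs
        self.mf_type = mf_type
        self.epochs = epochs
        self.step_size = step_size
        self.step_increase = step_increase
        self.step_decrease = step_decrease
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    def _validate(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_inputs)")
        if y is not None:
            y = np.asarray(y, dtype=float).ravel()
            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            return X, y
        return X

    def _init_premise(self, X):
        """Grid partition over each input's observed range.

        Centers equally spaced on [min, max]; widths range/(2*(m-1));
        slope 2 for generalized bell.  Zero-range inputs get unit-width
        membership functions (logged) so no NaN can arise.
        """
        d, m = X.shape[1], self.n_mfs
        premise = np.empty((d, m, 3))
        for i in range(d):
            lo, hi = X[:, i].min(), X[:, i].max()
            rng_i = hi - lo
            if rng_i <= 0:
                logger.warning("input %d has zero range; using unit-width MFs", i)
                centers = np.full(m, lo)
                width = 1.0
            else:
                centers = np.linspace(lo, hi, m)
                width = rng_i / (2.0 * (m - 1))
            premise[i, :, 0] = width
            premise[i, :, 1] = 2.0
            premise[i, :, 2] = centers
        return premise

    def _memberships(self, X, premise):
        a = premise[:, :, 0][None]  # (1, d, m)
        b = premise[:, :, 1][None]
        c = premise[:, :, 2][None]
        z = (X[:, :, None] - c) / a
        u = z**2
        if self.mf_type == "gaussian":
            return np.exp(-0.5 * u), u
        return 1.0 / (1.0 + u**b), u

    def _firing(self, mu):
        n = mu.shape[0]
        f = np.ones((n, len(self._rules_)))
        for i in range(mu.shape[1]):
            f *= mu[:, i, self._rules_[:, i]]
        return f

    def _forward_parts(self, X, premise, consequents):
        mu, _ = self._memberships(X, premise)
        f = self._firing(mu)
        s = f.sum(axis=1)
        bad = s <= 0
        if np.any(bad):
            logger.warning("%d samples with zero total firing; uniform fallback", bad.sum())
            f[bad] = 1.0
            s[bad] = f.shape[1]
        wbar = f / s[:, None]
        Xa = np.column_stack([X, np.ones(len(X))])
        g = Xa @ consequents.T  # (n, R)
        out = (wbar * g).sum(axis=1)
        return out, mu, f, s, wbar, g, Xa

    def forward(self, X, premise=None, consequents=None):
        """Evaluate the fuzzy system (layer-by-layer Sugeno forward pass)."""
        premise = self.premise_ if premise is None else premise
        consequents = self.consequents_ if consequents is None else consequents
        return self._forward_parts(self._validate(X), premise, consequents)[0]

    # ------------------------------------------------------------------ #
    def _solve_consequents(self, X, y, premise, idx):
        mu, _ = self._memberships(X[idx], premise)
        f = self._firing(mu)
        s = f.sum(axis=1)
        s[s <= 0] = 1.0
        wbar = f / s[:, None]
        Xa = np.column_stack([X[idx], np.ones(len(wbar))])
        A = (wbar[:, :, None] * Xa[:, None, :]).reshape(len(Xa), -1)
        sol, *_ = np.linalg.lstsq(A, y[idx], rcond=None)
        if not np.all(np.isfinite(sol)):
            logger.warning("singular consequent system; ridge fallback")
            lam = 1e-8
            sol = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y[idx])
        return sol.reshape(len(self._rules_), X.shape[1] + 1)

    def _premise_gradient(self, X, y, premise, consequents):
        out, mu, f, s, wbar, g, Xa = self._forward_parts(X, premise, consequents)
        e = out - y  # dE/d out, up to the 1/n in RMSE
        # d out / d f_k = (g_k - out) / s
        dout_df = (g - out[:, None]) / s[:, None]
        coef = e[:, None] * dout_df  # (n, R)
        mu_safe = np.maximum(mu, _EPS)
        d, m = premise.shape[:2]
        dE_dmu = np.zeros_like(mu)
        for i in range(d):
            ridx = self._rules_[:, i]
            contrib = coef * (f / mu_safe[:, i, ridx])  # (n, R)
            for j in range(m):
                sel = ridx == j
                if np.any(sel):
                    dE_dmu[:, i, j] = contrib[:, sel].sum(axis=1)
        a = premise[:, :, 0][None]
        b = premise[:, :, 1][None]
        c = premise[:, :, 2][None]
        z = (X[:, :, None] - c) / a
        u = z**2
        if self.mf_type == "gaussian":
            mu_v = np.exp(-0.5 * u)
            dmu_du = -0.5 * mu_v
            dmu_db = np.zeros_like(u)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ub = u**b
                mu_v = 1.0 / (1.0 + ub)
                dmu_du = np.where(u > 0, -b * u ** (b - 1.0) * mu_v**2, 0.0)
                dmu_db = np.where(u > 0, -ub * np.log(np.maximum(u, _EPS)) * mu_v**2, 0.0)
        du_da = -2.0 * u / a
        du_dc = -2.0 * z / a
        grad = np.empty_like(premise)
        grad[:, :, 0] = (dE_dmu * dmu_du * du_da).sum(axis=0)
        grad[:, :, 1] = (dE_dmu * dmu_db).sum(axis=0)
        grad[:, :, 2] = (dE_dmu * dmu_du * du_dc).sum(axis=0)
        return grad

    # ------------------------------------------------------------------ #
    def fit(self, X, y):
        X, y = self._validate(X, y)
        if not (2 <= self.n_mfs):
            raise ValueError("n_mfs must be >= 2")
        if not (0.0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")
        d = X.shape[1]
        self._rules_ = np.array(
            list(itertools.product(range(self.n_mfs), repeat=d)), dtype=int
        )
        n_rules = len(self._rules_)
        n = len(X)
        if n <= 10 * n_rules:
            logger.warning(
                "only %d samples for %d rules; recommend n > %d", n, n_rules, 10 * n_rules
            )
        rng = np.random.default_rng(self.random_state)
        premise = self._init_premise(X)
        n_val = max(int(round(self.val_fraction * n)), 1)

        step = self.step_size
        train_hist, val_hist, snapshots = [], [], []
        err_window = []
        for epoch in range(self.epochs):
            start = rng.integers(0, n - n_val + 1)
            val_mask = np.zeros(n, dtype=bool)
            val_mask[start : start + n_val] = True
            train_mask = ~val_mask

            consequents = self._solve_consequents(X, y, premise, train_mask)
            out = self._forward_parts(X, premise, consequents)[0]
            train_rmse = float(np.sqrt(np.mean((out[train_mask] - y[train_mask]) ** 2)))
            val_rmse = float(np.sqrt(np.mean((out[val_mask] - y[val_mask]) ** 2)))
            train_hist.append(train_rmse)
            val_hist.append(val_rmse)
            snapshots.append((premise.copy(), consequents.copy()))

            if epoch < self.epochs - 1:
                grad = self._premise_gradient(X[train_mask], y[train_mask], premise, consequents)
                norm = np.sqrt((grad**2).sum())
                if norm > _EPS:
                    premise = premise - step * grad / norm
                    premise[:, :, 0] = np.maximum(np.abs(premise[:, :, 0]), _EPS)
                    premise[:, :, 1] = np.maximum(premise[:, :, 1], 0.1)
                # classic ANFIS step-size schedule
                err_window.append(train_rmse)
                if len(err_window) >= 4:
                    w4 = err_window[-4:]
                    if w4[0] > w4[1] > w4[2] > w4[3]:
                        step *= self.step_increase
                        err_window.clear()
                    elif (w4[1] > w4[0] and w4[2] < w4[1] and w4[3] > w4[2]) or (
                        w4[1] < w4[0] and w4[2] > w4[1] and w4[3] < w4[2]
                    ):
                        step *= self.step_decrease
                        err_window.clear()

        best = int(np.argmin(val_hist))
        self.premise_, self.consequents_ = snapshots[best]
        self.selected_epoch_ = best + 1
        self.trace_ = {
            "train_rmse": np.asarray(train_hist),
            "val_rmse": np.asarray(val_hist),
        }
        self.n_features_in_ = d
        return self

    def predict(self, X):
        if not hasattr(self, "premise_"):
            raise ValueError("AnfisRegressor is not fitted")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return self.forward(X)

    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "premise": self.premise_.tolist(),
            "consequents": self.consequents_.tolist(),
            "selected_epoch": int(self.selected_epoch_),
            "trace": {k: v.tolist() for k, v in self.trace_.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AnfisRegressor":
        model = cls(**payload["params"])
        model.premise_ = np.asarray(payload["premise"], dtype=float)
        model.consequents_ = np.asarray(payload["consequents"], dtype=float)
        model.selected_epoch_ = payload["selected_epoch"]
        model.trace_ = {k: np.asarray(v) for k, v in payload["trace"].items()}
        model.n_features_in_ = model.premise_.shape[0]
        model._rules_ = np.array(
            list(itertools.product(range(model.n_mfs), repeat=model.n_features_in_)),
            dtype=int,
        )
        return model


def denoise(y_f, X, model: AnfisRegressor) -> np.ndarray:
    """Clean-signal estimate ``x_hat = y_f - w_hat`` for a fitted model."""
    y_f = np.asarray(y_f, dtype=float)
    if len(y_f) != len(X):
        raise ValueError("y_f and inputs length mismatch")
    return y_f - model.predict(X)
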