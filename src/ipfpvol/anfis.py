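"""First-order Takagi–Sugeno neuro-fuzzy regressor with FCM rule induction.

The model is a small rule base.  Rule r says

    IF x_1 is Gaussian(c_r1, s_r1) AND ... AND x_d is Gaussian(c_rd, s_rd)
    THEN y_r = a_r · x + b_r

and the prediction is the firing-strength-weighted average of the rule
outputs, with firing strength the product of the per-input Gaussian
memberships.  Rules are induced by fuzzy c-means (FCM) clustering — by
default on the joint (inputs, target) space, then projected onto the inputs
— and refined by hybrid learning: linear least squares for the consequents
(premises frozen) alternating with gradient descent on the premise centers
and widths.

Inputs are z-scored with training-split statistics (switchable); the target
stays in its native units (mm³ for IPFP volume).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

_WIDTH_FLOOR = 1e-4


@dataclass
class FCMResult:
    centers: np.ndarray  # (c, d)
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective_trace: list[float]
    m: float  # fuzziness exponent


def fcm_cluster(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMResult:
    """Bezdek fuzzy c-means by alternating optimization.

    Each iteration recomputes centers from the current memberships (the
    exact minimizer given U) and memberships from the new centers (the exact
    minimizer given V), so the objective trace is non-increasing.  Stops
    when the objective improves by less than ``tol`` or at ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= c <= n, got c={c}, n={n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    if m <= 1:
        raise ValueError("fuzziness m must exceed 1")

    rng = np.random.default_rng(seed)
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)

    expo = 1.0 / (m - 1.0)  # membership ∝ (squared distance)^(−1/(m−1))
    trace: list[float] = []
    centers = np.empty((c, d))
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # exact-hit guard: membership 1 at a zero-distance center
        zero = d2 <= 0.0
        if zero.any():
            U = np.where(zero, 1.0, 0.0)
            rows = zero.any(axis=1)
            free = ~rows
        else:
            free = np.ones(n, dtype=bool)
            U = np.empty_like(d2)
        if free.any():
            inv = d2[free] ** (-expo)
            U[free] = inv / inv.sum(axis=1, keepdims=True)
        U = U / U.sum(axis=1, keepdims=True)
        obj = float(((U**m) * d2).sum())
        trace.append(obj)
        if len(trace) > 1 and trace[-2] - trace[-1] < tol:
            break
    return FCMResult(centers=centers, memberships=U, objective_trace=trace, m=m)


@dataclass
class FISModel:
    """A fitted first-order Takagi–Sugeno fuzzy inference system."""

    centers: np.ndarray  # (R, d) premise Gaussian centers, scaled space
    widths: np.ndarray  # (R, d) premise Gaussian widths, > 0
    coefs: np.ndarray  # (R, d) consequent slopes, output units per scaled input
    intercepts: np.ndarray  # (R,) consequent intercepts, output units
    input_names: list[str]
    scaler_mean: np.ndarray  # (d,) per-input affine normalization
    scaler_scale: np.ndarray  # (d,) strictly positive
    provenance: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def rule_weights(self, X: np.ndarray) -> np.ndarray:
        """Normalized firing strengths, (n, R); rows sum to 1.

        Computed in log space so that inputs far from every rule center do
        not underflow — in that limit the weights collapse onto the nearest
        rule, which is the documented fallback.
        """
        Xs = self._scale(np.asarray(X, dtype=float))
        z = (Xs[:, None, :] - self.centers[None, :, :]) / self.widths[None, :, :]
        logw = -0.5 * (z**2).sum(axis=2)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        return w / w.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} inputs, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        W = self.rule_weights(X)
        Xs = self._scale(X)
        rule_out = Xs @ self.coefs.T + self.intercepts[None, :]  # (n, R)
        return (W * rule_out).sum(axis=1)

    # -- serialization ----------------------------------------------------
    # json round-trips Python floats exactly (repr shortest-round-trip), so
    # an exported model reproduces predictions bit-for-bit.
    def to_dict(self) -> dict:
        return {
            "model": "takagi-sugeno-fis",
            "n_rules": self.n_rules,
            "input_names": list(self.input_names),
            "scaler": {
                "mean": self.scaler_mean.tolist(),
                "scale": self.scaler_scale.tolist(),
            },
            "rules": [
                {
                    "premise": {
                        "centers": self.centers[r].tolist(),
                        "widths": self.widths[r].tolist(),
                    },
                    "consequent": {
                        "coefs": self.coefs[r].tolist(),
                        "intercept": float(self.intercepts[r]),
                    },
                }
                for r in range(self.n_rules)
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: dict) -> "FISModel":
        rules = payload["rules"]
        return cls(
            centers=np.array([r["premise"]["centers"] for r in rules], dtype=float),
            widths=np.array([r["premise"]["widths"] for r in rules], dtype=float),
            coefs=np.array([r["consequent"]["coefs"] for r in rules], dtype=float),
            intercepts=np.array(
                [r["consequent"]["intercept"] for r in rules], dtype=float
            ),
            input_names=list(payload["input_names"]),
            scaler_mean=np.asarray(payload["scaler"]["mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler"]["scale"], dtype=float),
            provenance=dict(payload.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, path) -> "FISModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def evaluate_fis(model: FISModel, x: np.ndarray) -> float:
    """Predicted volume (mm³) for one input vector."""
    return float(model.predict(np.asarray(x, dtype=float)[None, :])[0])


@dataclass(frozen=True)
class TrainConfig:
    """Hybrid-learning hyperparameters; every value is a declared default."""

    n_rules: int | None = None  # None: pick from rule_candidates by test error
    rule_candidates: tuple[int, ...] = (2, 3, 4, 5)
    m: float = 2.0
    epochs: int = 50
    lr: float = 0.01
    tol: float = 1e-10
    seed: int = 0
    normalize: bool = True
    joint_space: bool = True  # FCM on [X | y] rather than X alone

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.m <= 1:
            raise ValueError("fuzziness m must exceed 1")


def _fit_scaler(X: np.ndarray, normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    d = X.shape[1]
    if not normalize:
        return np.zeros(d), np.ones(d)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale <= 0] = 1.0
    return mean, scale


def _lse_consequents(
    model: FISModel, Xs_raw: np.ndarray, y: np.ndarray
) -> None:
    """Globally optimal consequents by (min-norm) linear least squares."""
    W = model.rule_weights(Xs_raw)  # (n, R)
    Xs = model._scale(Xs_raw)
    n, d = Xs.shape
    R = model.n_rules
    A = np.empty((n, R * (d + 1)))
    for r in range(R):
        A[:, r * (d + 1) : r * (d + 1) + d] = W[:, r : r + 1] * Xs
        A[:, r * (d + 1) + d] = W[:, r]
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    theta = theta.reshape(R, d + 1)
    model.coefs = theta[:, :d].copy()
    model.intercepts = theta[:, d].copy()


def init_fis_from_fcm(
    X: np.ndarray,
    y: np.ndarray,
    fcm: FCMResult,
    input_names: list[str] | None = None,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> FISModel:
    """One rule per FCM cluster.

    Premise centers are the cluster centers projected onto the input
    dimensions; widths are the membership-weighted within-cluster standard
    deviations (floored to stay positive).  Consequents are set by one
    global least-squares pass.  Clusters with vanishing total membership
    are dropped with a warning.

    ``X`` here is the raw (unscaled) input matrix; if the FCM ran on scaled
    or joint space the caller passes the matching ``scaler`` and the cluster
    centers are interpreted in that scaled space.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    d = X.shape[1]
    mean, scale = scaler if scaler is not None else (np.zeros(d), np.ones(d))
    Xs = (X - mean) / scale

    Um = fcm.memberships**fcm.m
    mass = Um.sum(axis=0)
    keep = mass > 1e-12
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate FCM cluster(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    centers = fcm.centers[keep][:, :d]  # project joint-space centers onto inputs
    Um = Um[:, keep]
    mass = mass[keep]

    var = np.einsum("nr,nrd->rd", Um, (Xs[:, None, :] - centers[None, :, :]) ** 2)
    widths = np.sqrt(var / mass[:, None])
    widths = np.maximum(widths, _WIDTH_FLOOR)

    model = FISModel(
        centers=centers,
        widths=widths,
        coefs=np.zeros_like(centers),
        intercepts=np.zeros(centers.shape[0]),
        input_names=list(input_names) if input_names is not None else [f"x{i}" for i in range(d)],
        scaler_mean=mean,
        scaler_scale=scale,
    )
    _lse_consequents(model, X, y)
    return model


def _rmse(model: FISModel, X: np.ndarray, y: np.ndarray) -> float:
    e = model.predict(X) - y
    return float(np.sqrt(np.mean(e**2)))


def train_hybrid(
    model: FISModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> FISModel:
    """Alternate global LSE on consequents with gradient steps on premises.

    Per epoch: pass 1 re-solves the consequents exactly with premises
    frozen (training RMSE cannot increase across this pass); pass 2 takes
    one gradient-descent step on the premise centers and widths, with the
    step halved and reverted whenever it increases the error.  ``epochs=0``
    returns the model unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if cfg.epochs == 0:
        return model
    lr = cfg.lr
    prev = np.inf
    for _ in range(cfg.epochs):
        _lse_consequents(model, X, y)
        rmse = _rmse(model, X, y)
        if prev - rmse < cfg.tol:
            break
        prev = rmse

        # pass 2: gradient of 0.5 * MSE wrt premise centers and widths
        W = model.rule_weights(X)  # (n, R)
        Xs = model._scale(X)
        rule_out = Xs @ model.coefs.T + model.intercepts[None, :]
        yhat = (W * rule_out).sum(axis=1)
        err = yhat - y  # (n,)
        # d yhat / d log firing_r = W_r * (rule_out_r - yhat)
        g_logw = W * (rule_out - yhat[:, None]) * err[:, None] / len(y)  # (n, R)
        z = Xs[:, None, :] - model.centers[None, :, :]  # (n, R, d)
        inv_w2 = 1.0 / model.widths**2
        grad_c = np.einsum("nr,nrd->rd", g_logw, z) * inv_w2
        grad_s = np.einsum("nr,nrd->rd", g_logw, z**2) / model.widths**3

        old_c, old_s = model.centers.copy(), model.widths.copy()
        model.centers = model.centers - lr * grad_c
        model.widths = np.maximum(model.widths - lr * grad_s, _WIDTH_FLOOR)
        if _rmse(model, X, y) > rmse:
            model.centers, model.widths = old_c, old_s
            lr *= 0.5
    _lse_consequents(model, X, y)
    return model


def fit_anfis(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    input_names: list[str] | None = None,
) -> FISModel:
    """End-to-end fit: scale, FCM rule induction, hybrid training.

    When ``cfg.n_rules`` is None the rule count is chosen from
    ``cfg.rule_candidates`` by held-out error on an internal 70/30 split of
    the training data (the study's train/test proportion).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, d = X.shape

    def _fit(c: int, X_tr: np.ndarray, y_tr: np.ndarray) -> FISModel:
        mean, scale = _fit_scaler(X_tr, cfg.normalize)
        Xs = (X_tr - mean) / scale
        if cfg.joint_space:
            ys = y_tr.std(ddof=0) or 1.0
            space = np.column_stack([Xs, (y_tr - y_tr.mean()) / ys])
        else:
            space = Xs
        c_eff = min(c, len(X_tr))
        fcm = fcm_cluster(space, c=c_eff, m=cfg.m, seed=cfg.seed)
        model = init_fis_from_fcm(
            X_tr, y_tr, fcm, input_names=input_names, scaler=(mean, scale)
        )
        return train_hybrid(model, X_tr, y_tr, cfg)

    if cfg.n_rules is not None:
        return _fit(cfg.n_rules, X, y)

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_tr = max(int(round(0.7 * n)), 1)
    tr, te = perm[:n_tr], perm[n_tr:]
    if len(te) == 0:
        tr, te = perm, perm
    best_c, best_err = None, np.inf
    for c in cfg.rule_candidates:
        if c > len(tr):
            continue
        mdl = _fit(c, X[tr], y[tr])
        err = _rmse(mdl, X[te], y[te])
        if err < best_err:
            best_c, best_err = c, err
    if best_c is None:
        best_c = 1
    return _fit(best_c, X, y)
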