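"""PSO-based variable selection (PSOBVS) over the 48-feature design space.

A swarm of particles carries one continuous score per candidate feature;
a particle decodes to the subset of the M highest-scoring features.  The
wrapper fitness fits a fast surrogate regressor on the decoded subset and
scores it as a weighted combination of training and testing RMSE (0.7 /
0.3, the study's split proportions), averaged over k = 4 cross-validation
folds.  The search is repeated over Monte-Carlo resplits to measure the
stability of the selected subset, and the Akaike Information Criterion
(computed from out-of-fold residuals) picks the winning subset size.

The full 48-variable lattice (2^48 − 1 subsets) is never enumerated; the
swarm explores it, and correctness is certified against exhaustive
enumeration on small candidate sets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

PENALTY_FITNESS = 1e12


# ---------------------------------------------------------------------------
# surrogate regressors (fitness inner loop)
# ---------------------------------------------------------------------------


class RidgeSurrogate:
    """Closed-form ridge on standardized features; the fast default."""

    def __init__(self, lam: float = 1e-3):
        self.lam = lam

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "RidgeSurrogate":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd <= 0] = 1.0
        self.sd_ = sd
        Xs = (X - self.mean_) / sd
        self.ymean_ = y.mean()
        d = X.shape[1]
        A = Xs.T @ Xs + self.lam * len(y) * np.eye(d)
        self.beta_ = np.linalg.solve(A, Xs.T @ (y - self.ymean_))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean_) / self.sd_) @ self.beta_ + self.ymean_


class ANNSurrogate:
    """Single-hidden-layer feed-forward network (tanh hidden, linear out).

    Trained by full-batch Adam on standardized inputs/target with L2 weight
    decay; deliberately small (8 hidden units) — it is a wrapper-fitness
    scorer, not the final predictor.
    """

    def __init__(
        self,
        hidden: int = 8,
        weight_decay: float = 1e-3,
        epochs: int = 300,
        lr: float = 0.01,
    ):
        self.hidden = hidden
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.lr = lr

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "ANNSurrogate":
        rng = np.random.default_rng(seed)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd <= 0] = 1.0
        self.sd_ = sd
        Xs = (X - self.mean_) / sd
        self.ymean_, ysd = y.mean(), y.std(ddof=0) or 1.0
        self.ysd_ = ysd
        ys = (y - self.ymean_) / ysd

        d, h = X.shape[1], self.hidden
        W1 = rng.normal(0, 1.0 / math.sqrt(d), (d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0, 1.0 / math.sqrt(h), h)
        b2 = 0.0
        params = [W1, b1, W2, np.array([b2])]
        mom = [np.zeros_like(p) for p in params]
        vel = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(ys)
        for t in range(1, self.epochs + 1):
            H = np.tanh(Xs @ W1 + b1)
            pred = H @ W2 + params[3][0]
            err = pred - ys
            gW2 = H.T @ err / n + self.weight_decay * W2
            gb2 = np.array([err.mean()])
            dH = (err[:, None] * W2[None, :]) * (1 - H**2)
            gW1 = Xs.T @ dH / n + self.weight_decay * W1
            gb1 = dH.mean(axis=0)
            for p, g, mo, ve in zip(params, [gW1, gb1, gW2, gb2], mom, vel):
                mo *= beta1
                mo += (1 - beta1) * g
                ve *= beta2
                ve += (1 - beta2) * g * g
                p -= self.lr * (mo / (1 - beta1**t)) / (
                    np.sqrt(ve / (1 - beta2**t)) + eps
                )
            W1, b1, W2 = params[0], params[1], params[2]
        self.params_ = params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = self.params_
        Xs = (X - self.mean_) / self.sd_
        return (np.tanh(Xs @ W1 + b1) @ W2 + b2[0]) * self.ysd_ + self.ymean_


def make_surrogate(kind: str, **kwargs):
    if kind == "ridge":
        return RidgeSurrogate(**kwargs)
    if kind == "ann":
        return ANNSurrogate(**kwargs)
    raise ValueError(f"unknown surrogate {kind!r}")


# ---------------------------------------------------------------------------
# configuration and splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwarmConfig:
    swarm_size: int = 30
    iterations: int = 100
    inertia: tuple[float, float] = (0.9, 0.4)  # linear schedule start → end
    c1: float = 2.0  # cognitive
    c2: float = 2.0  # social
    velocity_clamp: float = 4.0  # also the particle initialization range
    subset_size: int = 5
    mc_repeats: int = 10
    train_weight: float = 0.7
    test_weight: float = 0.3
    k_folds: int = 4
    seed: int = 0
    surrogate: str = "ridge"
    ridge_lambda: float = 1e-3
    #: reinitialize a particle after this many non-improving evaluations
    stall_restart: int | None = 5
    #: greedy single-feature swap refinement of the incumbent after the
    #: swarm finishes (memetic finishing step)
    polish: bool = True

    def __post_init__(self):
        if self.train_weight <= 0 or self.test_weight <= 0:
            raise ValueError("stage weights must be positive")
        total = self.train_weight + self.test_weight
        if abs(total - 1.0) > 1e-12:
            object.__setattr__(self, "train_weight", self.train_weight / total)
            object.__setattr__(self, "test_weight", self.test_weight / total)
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.swarm_size <= 0 or self.iterations < 0:
            raise ValueError("swarm_size must be positive, iterations >= 0")


def kfold_split(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint folds covering 0..n−1; sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds, start = [], 0
    for s in sizes:
        folds.append(np.sort(perm[start : start + s]))
        start += s
    return folds


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


class RidgeCVEvaluator:
    """Fast exact ridge-CV fitness via precomputed per-fold Gram matrices.

    For the ridge surrogate the weighted train/test RMSE of any feature
    subset is a function of centered sufficient statistics (XᵀX, Xᵀy, yᵀy
    per fold), so one O(n·d²) precomputation makes each subset evaluation
    O(|S|³) with no further passes over the data.  Agrees with the direct
    :func:`fitness` path to floating-point accuracy.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        folds: list[np.ndarray],
        lam: float = 1e-3,
        train_weight: float = 0.7,
        test_weight: float = 0.3,
    ):
        self.lam, self.wt, self.we = lam, train_weight, test_weight
        self.constant_target = y.std(ddof=0) == 0
        self._folds = []
        for i, te in enumerate(folds):
            tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
            Xtr, ytr, Xte, yte = X[tr], y[tr], X[te], y[te]
            mu, ybar = Xtr.mean(axis=0), ytr.mean()
            Xc, yc = Xtr - mu, ytr - ybar
            G, cross, syy = Xc.T @ Xc, Xc.T @ yc, float(yc @ yc)
            sd = np.sqrt(np.diag(G) / len(tr))
            sd = np.where(sd > 0, sd, 1.0)
            Xct, yct = Xte - mu, yte - ybar
            self._folds.append(
                (len(tr), len(te), G, cross, syy, sd,
                 Xct.T @ Xct, Xct.T @ yct, float(yct @ yct))
            )

    def __call__(self, subset: tuple[int, ...]) -> float:
        if self.constant_target:
            return PENALTY_FITNESS
        cols = np.asarray(subset, dtype=int)
        score = 0.0
        for (ntr, nte, G, cross, syy, sd, Gt, crosst, syyt) in self._folds:
            D = 1.0 / sd[cols]
            Gs = G[np.ix_(cols, cols)]
            A = Gs * np.outer(D, D)
            A[np.diag_indices_from(A)] += self.lam * ntr
            beta = np.linalg.solve(A, D * cross[cols])
            w = D * beta
            sse_tr = syy - 2 * w @ cross[cols] + w @ Gs @ w
            sse_te = syyt - 2 * w @ crosst[cols] + w @ Gt[np.ix_(cols, cols)] @ w
            score += self.wt * math.sqrt(max(sse_tr, 0.0) / ntr)
            score += self.we * math.sqrt(max(sse_te, 0.0) / nte)
        return score / len(self._folds)


def make_evaluator(
    X: np.ndarray, y: np.ndarray, cfg: "SwarmConfig", folds: list[np.ndarray]
):
    """Subset → fitness callable used by the swarm; fast path for ridge."""
    if cfg.surrogate == "ridge":
        return RidgeCVEvaluator(
            X, y, folds, lam=cfg.ridge_lambda,
            train_weight=cfg.train_weight, test_weight=cfg.test_weight,
        )
    return lambda subset: fitness(X, y, subset, cfg, folds=folds)


def fitness(
    X: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    cfg: SwarmConfig,
    folds: list[np.ndarray] | None = None,
) -> float:
    """Weighted train/test RMSE of the surrogate, averaged over CV folds.

    Singular fits or a constant target return a large penalty fitness so the
    swarm routes around them.
    """
    if len(subset) == 0:
        raise ValueError("empty subset")
    if y.std(ddof=0) == 0:
        return PENALTY_FITNESS
    cols = np.asarray(sorted(set(subset)), dtype=int)
    Xsub = X[:, cols]
    if folds is None:
        folds = kfold_split(len(y), cfg.k_folds, seed=cfg.seed)
    scores = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        kwargs = {"lam": cfg.ridge_lambda} if cfg.surrogate == "ridge" else {}
        try:
            model = make_surrogate(cfg.surrogate, **kwargs).fit(
                Xsub[train_idx], y[train_idx], seed=cfg.seed + i
            )
        except np.linalg.LinAlgError:
            return PENALTY_FITNESS
        e_tr = model.predict(Xsub[train_idx]) - y[train_idx]
        e_te = model.predict(Xsub[test_idx]) - y[test_idx]
        rmse_tr = float(np.sqrt(np.mean(e_tr**2)))
        rmse_te = float(np.sqrt(np.mean(e_te**2)))
        scores.append(cfg.train_weight * rmse_tr + cfg.test_weight * rmse_te)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# particle decoding and the swarm
# ---------------------------------------------------------------------------


def decode_particle(position: np.ndarray, m: int) -> tuple[int, ...]:
    """Indices of the M highest scores; ties broken by canonical order."""
    position = np.asarray(position, dtype=float)
    if m > len(position):
        raise ValueError(f"subset size {m} exceeds {len(position)} features")
    if not np.all(np.isfinite(position)):
        raise ValueError("non-finite particle position")
    # stable argsort on −score: equal scores resolve to the earliest feature
    order = np.argsort(-position, kind="stable")
    return tuple(sorted(int(i) for i in order[:m]))


@dataclass
class SearchTrace:
    best_subset: tuple[int, ...]
    best_fitness: float
    gbest_history: list[float] = field(default_factory=list)
    evaluations: int = 0


def _polish_subset(
    score, subset: tuple[int, ...], fit: float, n_feat: int
) -> tuple[tuple[int, ...], float]:
    """Greedy best-improvement single-feature swaps until a local optimum."""
    improved = True
    while improved:
        improved = False
        for j in list(subset):
            best_k, best_f = None, fit
            for k in range(n_feat):
                if k in subset:
                    continue
                cand = tuple(sorted([x for x in subset if x != j] + [k]))
                f = score(cand)
                if f < best_f - 1e-12:
                    best_k, best_f = k, f
            if best_k is not None:
                subset = tuple(sorted([x for x in subset if x != j] + [best_k]))
                fit = best_f
                improved = True
    return subset, fit


def pso_search(
    X: np.ndarray,
    y: np.ndarray,
    m: int,
    cfg: SwarmConfig,
    folds: list[np.ndarray] | None = None,
    cache: dict | None = None,
) -> SearchTrace:
    """Memetic global-best PSO over continuous per-feature scores.

    Velocity update: ``w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)`` with a
    linearly decaying inertia ``w`` and symmetric velocity clamping;
    positions are initialized uniformly on the clamp range.  A particle
    whose personal best stalls for ``cfg.stall_restart`` evaluations is
    reinitialized at random (keeping the global best), and when
    ``cfg.polish`` is set the incumbent subset is refined to a single-swap
    local optimum after the swarm finishes.  Fitness values are memoized by
    decoded subset, so repeated visits to the same subset cost nothing.
    """
    n_feat = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    if folds is None:
        folds = kfold_split(len(y), cfg.k_folds, seed=cfg.seed)
    if cache is None:
        cache = {}
    evaluate = make_evaluator(X, y, cfg, folds)

    def score(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = evaluate(subset)
        return cache[subset]

    span = cfg.velocity_clamp

    pos = rng.uniform(-span, span, (cfg.swarm_size, n_feat))
    vel = rng.uniform(-span, span, (cfg.swarm_size, n_feat))
    pbest_pos = pos.copy()
    pbest_fit = np.array([score(decode_particle(p, m)) for p in pos])
    g = int(np.argmin(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
    gbest_subset = decode_particle(gbest_pos, m)
    history = [gbest_fit]
    stalled = np.zeros(cfg.swarm_size, dtype=int)

    w0, w1 = cfg.inertia
    for it in range(cfg.iterations):
        w = w0 + (w1 - w0) * (it / max(cfg.iterations - 1, 1))
        r1 = rng.random((cfg.swarm_size, n_feat))
        r2 = rng.random((cfg.swarm_size, n_feat))
        vel = (
            w * vel
            + cfg.c1 * r1 * (pbest_pos - pos)
            + cfg.c2 * r2 * (gbest_pos - pos)
        )
        np.clip(vel, -cfg.velocity_clamp, cfg.velocity_clamp, out=vel)
        pos = pos + vel
        for p in range(cfg.swarm_size):
            f = score(decode_particle(pos[p], m))
            if f < pbest_fit[p] - 1e-12:
                pbest_fit[p] = f
                pbest_pos[p] = pos[p]
                stalled[p] = 0
                if f < gbest_fit:
                    gbest_fit = float(f)
                    gbest_pos = pos[p].copy()
                    gbest_subset = decode_particle(pos[p], m)
            else:
                stalled[p] += 1
                if cfg.stall_restart and stalled[p] >= cfg.stall_restart:
                    pos[p] = rng.uniform(-span, span, n_feat)
                    vel[p] = rng.uniform(-span, span, n_feat)
                    pbest_pos[p] = pos[p]
                    pbest_fit[p] = score(decode_particle(pos[p], m))
                    stalled[p] = 0
                    if pbest_fit[p] < gbest_fit:
                        gbest_fit = float(pbest_fit[p])
                        gbest_pos = pos[p].copy()
                        gbest_subset = decode_particle(pos[p], m)
        history.append(gbest_fit)

    if cfg.polish:
        gbest_subset, gbest_fit = _polish_subset(score, gbest_subset, gbest_fit, n_feat)
        history.append(gbest_fit)

    return SearchTrace(
        best_subset=gbest_subset,
        best_fitness=gbest_fit,
        gbest_history=history,
        evaluations=len(cache),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo repetition and AIC
# ---------------------------------------------------------------------------


@dataclass
class SizeSelection:
    """Outcome of Monte-Carlo PSOBVS at one subset size."""

    subset_size: int
    subset: tuple[int, ...]
    fitness: float  # mean fitness of the chosen subset over its wins
    frequencies: np.ndarray  # per-feature selection frequency in [0, 1]
    aic: float | None = None


def monte_carlo_select(
    X: np.ndarray,
    y: np.ndarray,
    m: int,
    cfg: SwarmConfig,
) -> SizeSelection:
    """Repeat the swarm search over independent fold resplits.

    Each repeat derives a fresh seed from the master seed, reshuffles the
    cross-validation folds, and reruns PSO; the final subset is the modal
    subset across repeats (ties broken by best mean fitness), and each
    feature's selection frequency is the fraction of repeats that chose it.
    """
    if cfg.mc_repeats < 1:
        raise ValueError("mc_repeats must be >= 1")
    # first repeat reuses the master seed so mc_repeats=1 reduces exactly to
    # one pso_search; later repeats draw fresh derived seeds
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.mc_repeats)
    rep_seeds = [cfg.seed] + [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in children[1:]
    ]
    n_feat = X.shape[1]
    picks: list[tuple[int, ...]] = []
    fits: dict[tuple[int, ...], list[float]] = {}
    for rep_seed in rep_seeds:
        rep_cfg = replace(cfg, seed=rep_seed)
        trace = pso_search(X, y, m, rep_cfg)
        picks.append(trace.best_subset)
        fits.setdefault(trace.best_subset, []).append(trace.best_fitness)

    counts = Counter(picks)
    top = max(counts.values())
    tied = [s for s, c in counts.items() if c == top]
    winner = min(tied, key=lambda s: float(np.mean(fits[s])))

    freq = np.zeros(n_feat)
    for subset in picks:
        for i in subset:
            freq[i] += 1
    freq /= cfg.mc_repeats
    return SizeSelection(
        subset_size=m,
        subset=winner,
        fitness=float(np.mean(fits[winner])),
        frequencies=freq,
    )


def aic_score(n: int, sse: float, p: int) -> float:
    """AIC = n·ln(SSE/n) + 2p, with p = selected variables + 1 (intercept)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if sse <= 0:
        # perfectly interpolating model: AIC unbounded below
        import warnings

        warnings.warn("sse <= 0: AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(sse / n) + 2 * p


def holdout_sse(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    subset: tuple[int, ...],
) -> float:
    """Held-out sum of squared errors of an OLS fit on the subset.

    This is the SSE fed to :func:`aic_score` when comparing subset sizes:
    the subsets are themselves chosen by search, so only rows the search
    never saw give an honest error — in-sample (or within-search
    cross-validated) SSE rewards whichever spurious feature happened to
    correlate with the noise, and AIC's 2p penalty cannot compensate for
    that best-of-many selection bias.
    """
    cols = np.asarray(sorted(set(subset)), dtype=int)
    A = np.column_stack([X_train[:, cols], np.ones(len(y_train))])
    beta, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    pred = np.column_stack([X_test[:, cols], np.ones(len(y_test))]) @ beta
    return float(((y_test - pred) ** 2).sum())


def aic_size_scan(
    X: np.ndarray,
    y: np.ndarray,
    sizes: tuple[int, ...],
    cfg: SwarmConfig,
    train_fraction: float = 0.7,
) -> dict[int, float]:
    """AIC per subset size: search on the 70% split, score on the holdout.

    One shuffled train/test split is drawn from ``cfg.seed``; for each size
    the swarm searches the training rows only and the winner's OLS error on
    the held-out rows feeds :func:`aic_score` with p = size + 1.
    """
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(y))
    n_tr = int(round(train_fraction * len(y)))
    tr, te = np.sort(perm[:n_tr]), np.sort(perm[n_tr:])
    out: dict[int, float] = {}
    for m in sizes:
        trace = pso_search(X[tr], y[tr], m, replace(cfg, seed=cfg.seed + m))
        sse = holdout_sse(X[tr], y[tr], X[te], y[te], trace.best_subset)
        out[m] = aic_score(len(te), sse, p=m + 1)
    return out


def cv_sse(
    X: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    k: int = 4,
    seed: int = 0,
) -> float:
    """Out-of-fold sum of squared errors of an OLS fit on the subset.

    This is the SSE fed to :func:`aic_score`: scoring generalization error
    rather than in-sample error keeps the size comparison honest when the
    per-size subsets were themselves chosen by search.
    """
    cols = np.asarray(sorted(set(subset)), dtype=int)
    Xsub = X[:, cols]
    folds = kfold_split(len(y), k, seed=seed)
    sse = 0.0
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        A = np.column_stack([Xsub[train_idx], np.ones(len(train_idx))])
        beta, *_ = np.linalg.lstsq(A, y[train_idx], rcond=None)
        pred = np.column_stack([Xsub[test_idx], np.ones(len(test_idx))]) @ beta
        sse += float(((y[test_idx] - pred) ** 2).sum())
    return sse
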