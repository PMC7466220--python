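"""Regression models for bulk density: PLS with cross-validated Q2, and a
small feed-forward neural network trained by Levenberg-Marquardt.

PLS is the NIPALS algorithm for a single response: predictors are
autoscaled and the response mean-centred inside the fit, X is deflated
after each extracted component, and coefficients are folded back to the
raw scale.  Model quality is reported as

    R2 = 1 - RSS / SS          (training fit)
    Q2 = 1 - PRESS / SS        (cross-validated fit)

where SS is the total sum of squares of y about its mean, RSS the
training residual sum of squares, and PRESS accumulates squared held-out
prediction errors over a seeded 5-fold split.  The component count is
chosen either at the Q2 maximum or parsimoniously (the smallest count
within a tolerance of the maximum).

The neural network is a two-layer feed-forward net: a hidden layer of
sigmoid units (default 10) and a linear output.  Training minimizes the
training-subset MSE with damped Gauss-Newton (Levenberg-Marquardt) steps
and stops early when the validation-subset MSE has not improved for a
configured patience; weights are restored to the best validation epoch.
Samples are split 70/15/15 into training/validation/test by a seeded
permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import autoscale


# ---------------------------------------------------------------------------
# goodness-of-fit
# ---------------------------------------------------------------------------

def r_squared(y, y_hat) -> float:
    """R2 = 1 - RSS/SS with SS centred on mean(y).  Constant y is an error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2:
        raise ValueError("r_squared: need at least 2 samples")
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0.0:
        raise ValueError("r_squared: constant response")
    rss = float(np.sum((y - y_hat) ** 2))
    return 1.0 - rss / ss


def q_squared(press: float, ss: float) -> float:
    """Q2 = 1 - PRESS/SS."""
    if ss <= 0:
        raise ValueError("q_squared: SS must be positive")
    if press < 0:
        raise ValueError("q_squared: PRESS must be non-negative")
    return 1.0 - press / ss


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response)
# ---------------------------------------------------------------------------

@dataclass
class PLSFit:
    """Fitted PLS model in raw units.

    ``coef``/``intercept`` give predictions directly from unscaled X;
    weights and loadings refer to the autoscaled predictor space.
    """

    n_components: int
    x_weights: np.ndarray   # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    coef: np.ndarray        # (p,) raw-space
    intercept: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    r2: float
    mse: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept


def pls_fit(X, y, n_components: int, tol: float = 1e-10, max_iter: int = 500) -> PLSFit:
    """Fit single-response PLS by NIPALS with X-deflation.

    Raises ``ValueError`` if ``n_components`` exceeds the effective rank
    of the autoscaled predictor matrix (detected as a vanishing score
    norm during extraction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"pls_fit: n_components={n_components} outside [1, min(n-1, p)]"
        )
    Xs, x_mean, x_sd = autoscale(X)
    y_mean = float(y.mean())
    yc = y - y_mean

    E = Xs.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    scale = float(np.linalg.norm(Xs)) + 1e-300
    for a in range(n_components):
        # with a single response NIPALS needs no inner iteration:
        # w = E'y converges in one pass
        w = E.T @ yc
        wn = np.linalg.norm(w)
        if wn < tol * scale:
            raise ValueError(
                f"pls_fit: rank exhausted after {a} components "
                f"(requested {n_components})"
            )
        w /= wn
        t = E @ w
        tt = float(t @ t)
        if tt < (tol * scale) ** 2:
            raise ValueError(
                f"pls_fit: rank exhausted after {a} components "
                f"(requested {n_components})"
            )
        P[:, a] = E.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        E = E - np.outer(t, P[:, a])

    # B maps autoscaled X to centred y: B = W (P'W)^-1 q
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = B / x_sd
    intercept = y_mean - float(x_mean @ coef)
    y_hat = X @ coef + intercept
    return PLSFit(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        r2=r_squared(y, y_hat),
        mse=float(np.mean((y - y_hat) ** 2)),
    )


# ---------------------------------------------------------------------------
# cross-validation and component selection
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-component-count cross-validation metrics for a PLS model."""

    components: np.ndarray  # candidate counts, 1..max
    r2: np.ndarray
    q2: np.ndarray
    press: np.ndarray
    mse: np.ndarray
    fold_assignment: np.ndarray  # fold index in 0..folds-1 per sample
    rng_seed: int


def fold_indices(n: int, folds: int, rng_seed: int) -> np.ndarray:
    """Seeded random partition into near-equal folds (sizes differ by <= 1)."""
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    return assignment


def crossval(X, y, max_components: int, folds: int = 5, rng_seed: int = 0) -> CVReport:
    """Grouped k-fold cross-validation of PLS over component counts.

    For each candidate count the model is refit on each training 4/5 and
    held-out predictions accumulate PRESS; R2 and MSE come from the
    full-data fit at that count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < folds:
        raise ValueError(f"crossval: {n} samples < {folds} folds")
    assignment = fold_indices(n, folds, rng_seed)
    ss = float(np.sum((y - y.mean()) ** 2))

    counts = np.arange(1, max_components + 1)
    press = np.zeros(max_components)
    r2 = np.zeros(max_components)
    mse = np.zeros(max_components)
    for i, a in enumerate(counts):
        full = pls_fit(X, y, a)
        r2[i] = full.r2
        mse[i] = full.mse
        acc = 0.0
        for f in range(folds):
            train, test = assignment != f, assignment == f
            if not test.any():
                raise ValueError(f"crossval: empty fold {f}")
            fit = pls_fit(X[train], y[train], a)
            acc += float(np.sum((y[test] - fit.predict(X[test])) ** 2))
        press[i] = acc
    return CVReport(
        components=counts,
        r2=r2,
        q2=np.array([q_squared(p_, ss) for p_ in press]),
        press=press,
        mse=mse,
        fold_assignment=assignment,
        rng_seed=rng_seed,
    )


def select_ncomp(report: CVReport, rule: str = "parsimonious", tolerance: float = 0.02) -> int:
    """Choose the PLS component count from a cross-validation report.

    ``max_q2``: the count with the largest Q2 (smallest count on ties).
    ``parsimonious``: the smallest count whose Q2 is within ``tolerance``
    of the maximum.
    """
    if len(report.q2) == 0:
        raise ValueError("select_ncomp: empty report")
    best = float(report.q2.max())
    if rule == "max_q2":
        return int(report.components[int(np.argmax(report.q2))])
    if rule == "parsimonious":
        ok = np.flatnonzero(report.q2 >= best - tolerance)
        return int(report.components[ok[0]])
    raise ValueError(f"select_ncomp: unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# feed-forward ANN with Levenberg-Marquardt training
# ---------------------------------------------------------------------------

@dataclass
class ANNFit:
    """Trained two-layer network and per-subset performance.

    Weights are stored for standardized inputs/outputs; ``predict``
    handles the transforms.  ``mse`` values are in squared raw response
    units (e.g. (kg/m3)^2).
    """

    w_hidden: np.ndarray  # (hidden, p)
    b_hidden: np.ndarray  # (hidden,)
    w_out: np.ndarray     # (hidden,)
    b_out: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    split_sizes: tuple[int, int, int]
    split_assignment: np.ndarray  # 0 train, 1 validation, 2 test
    stopping_epoch: int
    mse: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)
    train_mse_history: list[float] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        h = _sigmoid(Xs @ self.w_hidden.T + self.b_hidden)
        return (h @ self.w_out + self.b_out) * self.y_sd + self.y_mean


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def split_sizes(n: int, split: tuple[float, float, float]) -> tuple[int, int, int]:
    """Round the 70/15/15 split to integers, training taking the remainder."""
    n_val = int(round(split[1] * n))
    n_test = int(round(split[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split {split} degenerate for n={n}")
    return n_train, n_val, n_test


def _net_forward(theta: np.ndarray, Xs: np.ndarray, hidden: int):
    p = Xs.shape[1]
    W1 = theta[: hidden * p].reshape(hidden, p)
    b1 = theta[hidden * p : hidden * p + hidden]
    w2 = theta[hidden * p + hidden : hidden * p + 2 * hidden]
    b2 = theta[-1]
    H = _sigmoid(Xs @ W1.T + b1)
    return H @ w2 + b2, H, W1, w2


def _net_jacobian(Xs: np.ndarray, H: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Jacobian of predictions w.r.t. the flattened parameter vector."""
    n, p = Xs.shape
    hidden = H.shape[1]
    dH = H * (1.0 - H)  # sigmoid derivative
    JW1 = (dH * w2)[:, :, None] * Xs[:, None, :]  # (n, hidden, p)
    Jb1 = dH * w2
    Jw2 = H
    Jb2 = np.ones((n, 1))
    return np.concatenate([JW1.reshape(n, hidden * p), Jb1, Jw2, Jb2], axis=1)


def ann_fit(
    X,
    y,
    hidden: int = 10,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    max_epochs: int = 200,
    rng_seed: int = 0,
    patience: int = 6,
    lam0: float = 1e-3,
    lam_max: float = 1e12,
) -> ANNFit:
    """Train the sigmoid-hidden / linear-output network with LM updates.

    Inputs and the response are standardized internally.  Each epoch
    solves ``(J'J + lam I) d = J'r`` on the training subset; an accepted
    step (training MSE decreases) divides the damping ``lam`` by 10, a
    rejected one multiplies it by 10 and retries.  Validation MSE is
    checked after every accepted step; when it has not improved for
    ``patience`` checks, training stops and the best-validation weights
    are restored.  Damping overflow before any accepted step is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("ann_fit: need at least 10 samples")
    sizes = split_sizes(n, split)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm[: sizes[0]]] = 0
    assignment[perm[sizes[0] : sizes[0] + sizes[1]]] = 1
    assignment[perm[sizes[0] + sizes[1] :]] = 2

    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_mean, y_sd = float(y.mean()), float(y.std()) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    tr, va = assignment == 0, assignment == 1
    Xtr, ytr = Xs[tr], ys[tr]
    Xva, yva = Xs[va], ys[va]

    # fan-in scaled uniform init
    n_par = hidden * p + 2 * hidden + 1
    theta = np.concatenate(
        [
            rng.uniform(-1, 1, hidden * p) / np.sqrt(p),
            rng.uniform(-1, 1, hidden),
            rng.uniform(-1, 1, hidden) / np.sqrt(hidden),
            rng.uniform(-1, 1, 1),
        ]
    )
    assert theta.size == n_par

    def mse_of(th, Xss, yss):
        pred, *_ = _net_forward(th, Xss, hidden)
        return float(np.mean((yss - pred) ** 2))

    lam = lam0
    train_mse = mse_of(theta, Xtr, ytr)
    best_val = mse_of(theta, Xva, yva)
    best_theta = theta.copy()
    best_epoch = 0
    bad_checks = 0
    history = [train_mse]
    epoch = 0
    accepted_any = False
    while epoch < max_epochs:
        pred, H, _, w2 = _net_forward(theta, Xtr, hidden)
        r = ytr - pred
        J = _net_jacobian(Xtr, H, w2)
        JtJ = J.T @ J
        Jtr_ = J.T @ r
        stepped = False
        while lam <= lam_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(n_par), Jtr_)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta + delta
            cand_mse = mse_of(cand, Xtr, ytr)
            if cand_mse < train_mse:
                theta = cand
                train_mse = cand_mse
                lam = max(lam / 10, 1e-20)
                stepped = True
                accepted_any = True
                break
            lam *= 10
        if not stepped:
            if not accepted_any:
                raise RuntimeError(
                    f"ann_fit: Levenberg-Marquardt damping overflow at epoch "
                    f"{epoch} (lam > {lam_max:g}, train MSE {train_mse:.3g})"
                )
            break  # converged: no descent direction improves training MSE
        epoch += 1
        history.append(train_mse)
        val_mse = mse_of(theta, Xva, yva)
        if val_mse < best_val - 1e-15:
            best_val = val_mse
            best_theta = theta.copy()
            best_epoch = epoch
            bad_checks = 0
        else:
            bad_checks += 1
            if bad_checks >= patience:
                break
        if train_mse < 1e-14:
            break

    pred, H, W1, w2 = _net_forward(best_theta, Xs, hidden)
    b1 = best_theta[hidden * p : hidden * p + hidden]
    fit = ANNFit(
        w_hidden=W1,
        b_hidden=b1,
        w_out=w2,
        b_out=float(best_theta[-1]),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        split_sizes=sizes,
        split_assignment=assignment,
        stopping_epoch=max(best_epoch, 1),
        train_mse_history=history,
    )
    y_hat = fit.predict(X)
    subsets = {"train": assignment == 0, "validation": assignment == 1,
               "test": assignment == 2, "all": np.ones(n, bool)}
    for name, m in subsets.items():
        fit.mse[name] = float(np.mean((y[m] - y_hat[m]) ** 2))
        fit.r2[name] = r_squared(y[m], y_hat[m]) if np.ptp(y[m]) > 0 else float("nan")
    return fit
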