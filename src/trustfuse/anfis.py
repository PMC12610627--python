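"""First-order Takagi-Sugeno ANFIS fusing EEG and questionnaire trust scores.

Two inputs, two Gaussian fuzzy sets per input ('Low', 'High'), and the fixed
2x2 rule grid:

    Rule 1: EEG Low  and questionnaire Low  -> p1
    Rule 2: EEG Low  and questionnaire High -> p2
    Rule 3: EEG High and questionnaire Low  -> p3
    Rule 4: EEG High and questionnaire High -> p4

with first-order consequents ``p_r = a_r x_eeg + b_r x_q + d_r``, product
t-norm firing strengths, and normalized weighted-sum defuzzification.
Training is hybrid: per epoch the consequents are solved exactly by linear
least squares on the normalized-weight design matrix (premise frozen),
followed by one full-batch gradient step on the Gaussian centers and widths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

#: (eeg_set, q_set) per rule; 0 = Low, 1 = High. Order matches Rules 1-4.
RULE_TABLE: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))
_MIN_WIDTH = 1e-3
_RIDGE = 1e-8


@dataclass
class AnfisModel:
    """Premise (Gaussian centers/widths per input per set) and 4 linear consequents.

    ``centers``/``widths`` have shape (2 inputs, 2 sets) with input 0 = EEG,
    input 1 = questionnaire, set 0 = Low, set 1 = High. ``consequents`` has
    shape (4 rules, 3): columns a_r, b_r, d_r.
    """

    centers: np.ndarray
    widths: np.ndarray
    consequents: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(2, 2)
        self.widths = np.asarray(self.widths, dtype=float).reshape(2, 2)
        self.consequents = np.asarray(self.consequents, dtype=float).reshape(4, 3)
        if np.any(self.widths <= 0):
            raise InvalidArgumentError("membership widths must be > 0")

    def to_dict(self) -> dict:
        return {
            "premise": {
                "centers": self.centers.tolist(),
                "widths": self.widths.tolist(),
            },
            "consequents": self.consequents.tolist(),
            "rule_table": [list(r) for r in RULE_TABLE],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnfisModel":
        return cls(
            centers=np.array(d["premise"]["centers"]),
            widths=np.array(d["premise"]["widths"]),
            consequents=np.array(d["consequents"]),
        )


@dataclass
class TrainingTrace:
    rmse_per_epoch: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_rmse: float = np.inf
    config: dict = field(default_factory=dict)


def anfis_init(eeg_scores: np.ndarray, q_scores: np.ndarray, targets: np.ndarray | None = None) -> AnfisModel:
    """Grid initialization: Low/High centers at each input's 25th/75th percentiles.

    Width is half the center separation (floored at 1e-3); consequents start
    as constants at the mean target (or 0 if no targets are given).
    """
    x1 = np.asarray(eeg_scores, dtype=float)
    x2 = np.asarray(q_scores, dtype=float)
    if x1.size != x2.size or x1.size < 4:
        raise InvalidArgumentError("need >= 4 paired training scores")
    centers = np.empty((2, 2))
    widths = np.empty((2, 2))
    for i, x in enumerate((x1, x2)):
        if np.ptp(x) == 0.0:
            raise DegenerateInputError(f"input {i} is constant; grid init undefined")
        lo, hi = np.percentile(x, (25.0, 75.0))
        centers[i] = (lo, hi)
        widths[i] = max((hi - lo) / 2.0, _MIN_WIDTH)
    d0 = float(np.mean(targets)) if targets is not None else 0.0
    consequents = np.zeros((4, 3))
    consequents[:, 2] = d0
    return AnfisModel(centers=centers, widths=widths, consequents=consequents)


def _log_weights(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log firing strengths, shape (n, 4)."""
    # log memberships per (sample, input, set)
    lm = -((X[:, :, None] - model.centers[None]) ** 2) / (2.0 * model.widths[None] ** 2)
    return np.stack([lm[:, 0, e] + lm[:, 1, q] for e, q in RULE_TABLE], axis=1)


def normalized_weights(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Normalized firing strengths w̄ (rows sum to 1); log-space for underflow safety."""
    lw = _log_weights(model, np.atleast_2d(np.asarray(X, dtype=float)))
    lw = lw - lw.max(axis=1, keepdims=True)
    w = np.exp(lw)
    return w / w.sum(axis=1, keepdims=True)


def _consequent_values(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """p_r(x) for each sample and rule, shape (n, 4)."""
    a = model.consequents[:, 0]
    b = model.consequents[:, 1]
    d = model.consequents[:, 2]
    return X[:, [0]] * a[None, :] + X[:, [1]] * b[None, :] + d[None, :]


def anfis_forward(model: AnfisModel, x_eeg, x_q):
    """Fused score(s) for EEG/questionnaire input pairs."""
    X = np.column_stack([np.atleast_1d(np.asarray(x_eeg, dtype=float)),
                         np.atleast_1d(np.asarray(x_q, dtype=float))])
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("inputs must be finite")
    wbar = normalized_weights(model, X)
    y = (wbar * _consequent_values(model, X)).sum(axis=1)
    return float(y[0]) if np.isscalar(x_eeg) and np.isscalar(x_q) else y


def design_matrix(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """n x 12 least-squares design: columns (w̄_r x1, w̄_r x2, w̄_r) per rule."""
    wbar = normalized_weights(model, X)
    cols = []
    for r in range(4):
        cols.extend([wbar[:, r] * X[:, 0], wbar[:, r] * X[:, 1], wbar[:, r]])
    return np.column_stack(cols)


def _solve_consequents(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    D = design_matrix(model, X)
    coeffs, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < D.shape[1]:
        warnings.warn("singular consequent system; falling back to ridge (lambda=1e-8)", stacklevel=2)
        gram = D.T @ D + _RIDGE * np.eye(D.shape[1])
        coeffs = np.linalg.solve(gram, D.T @ y)
    return coeffs.reshape(4, 3)


def _premise_gradient(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the MSE w.r.t. centers and widths.

    Uses the softmax identity dŷ/dθ = Σ_r w̄_r (p_r − ŷ) d log w_r/dθ.
    """
    n = X.shape[0]
    wbar = normalized_weights(model, X)
    p = _consequent_values(model, X)
    yhat = (wbar * p).sum(axis=1)
    resid = yhat - y
    grad_c = np.zeros((2, 2))
    grad_s = np.zeros((2, 2))
    for i in range(2):
        for s in range(2):
            dx = X[:, i] - model.centers[i, s]
            dlw_dc = dx / model.widths[i, s] ** 2
            dlw_ds = dx**2 / model.widths[i, s] ** 3
            uses = np.array([1.0 if rule[i] == s else 0.0 for rule in RULE_TABLE])
            core = (wbar * (p - yhat[:, None]) * uses[None, :]).sum(axis=1)
            grad_c[i, s] = (2.0 / n) * np.sum(resid * core * dlw_dc)
            grad_s[i, s] = (2.0 / n) * np.sum(resid * core * dlw_ds)
    return grad_c, grad_s


def _rmse(model: AnfisModel, X: np.ndarray, y: np.ndarray) -> float:
    pred = anfis_forward(model, X[:, 0], X[:, 1])
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def anfis_fit_hybrid(
    x_eeg: np.ndarray,
    x_q: np.ndarray,
    targets: np.ndarray,
    *,
    epochs: int = 100,
    lr: float = 0.01,
    seed: int | None = None,
) -> tuple[AnfisModel, TrainingTrace]:
    """Hybrid training: exact consequent LSE then one premise gradient step per epoch.

    Returns the parameters with the lowest training RMSE seen over epochs.
    Training is deterministic (full-batch); ``seed`` is accepted for
    interface symmetry and echoed in the trace.
    """
    X = np.column_stack([np.asarray(x_eeg, dtype=float), np.asarray(x_q, dtype=float)])
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.size or y.size < 12:
        raise InvalidArgumentError("need >= 12 training triples (one per consequent coefficient)")
    model = anfis_init(X[:, 0], X[:, 1], y)
    trace = TrainingTrace(config={"epochs": epochs, "lr": lr, "seed": seed})
    best = (np.inf, None, None, None)
    for epoch in range(epochs):
        model.consequents = _solve_consequents(model, X, y)
        rmse = _rmse(model, X, y)
        trace.rmse_per_epoch.append(rmse)
        if rmse < best[0]:
            best = (rmse, model.centers.copy(), model.widths.copy(), model.consequents.copy())
            trace.best_epoch = epoch
        grad_c, grad_s = _premise_gradient(model, X, y)
        model.centers = model.centers - lr * grad_c
        model.widths = np.maximum(model.widths - lr * grad_s, _MIN_WIDTH)
    trace.best_rmse = best[0]
    fitted = AnfisModel(centers=best[1], widths=best[2], consequents=best[3])
    return fitted, trace


def anfis_loocv(
    x_eeg: np.ndarray,
    x_q: np.ndarray,
    targets: np.ndarray,
    groups: np.ndarray,
    *,
    epochs: int = 100,
    lr: float = 0.01,
    seed: int | None = None,
) -> dict:
    """Leave-one-participant-out cross-validation.

    Folds are grouped by participant (not per row, which would leak
    within-participant structure). RMSE and R² = 1 − SSE/SST are computed on
    the pooled held-out predictions.
    """
    X = np.column_stack([np.asarray(x_eeg, dtype=float), np.asarray(x_q, dtype=float)])
    y = np.asarray(targets, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 3:
        raise InvalidArgumentError("grouped LOOCV needs >= 3 participants")
    preds = np.full(y.shape, np.nan)
    folds = []
    for g in uniq:
        test = groups == g
        model, _ = anfis_fit_hybrid(
            X[~test, 0], X[~test, 1], y[~test], epochs=epochs, lr=lr, seed=seed
        )
        preds[test] = anfis_forward(model, X[test, 0], X[test, 1])
        folds.append({"group": str(g), "n_test": int(test.sum())})
    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return {
        "rmse": float(np.sqrt(np.mean((y - preds) ** 2))),
        "r_squared": 1.0 - sse / sst,
        "predictions": preds,
        "folds": folds,
    }


def fusion_surface(
    model: AnfisModel, grid: int = 21, lo: float = 1.0, hi: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fused score over a regular [lo, hi]² grid; rows index the EEG axis."""
    axis = np.linspace(lo, hi, grid)
    surface = np.empty((grid, grid))
    for i, xe in enumerate(axis):
        surface[i] = anfis_forward(model, np.full(grid, xe), axis)
    return axis, surface


def surface_lipschitz_bound(model: AnfisModel, lo: float = 1.0, hi: float = 10.0) -> float:
    """Crude upper bound on |∂y/∂x_i| over the grid domain, from the parameters.

    The output is a convex combination of the rule planes, so the gradient is
    bounded by the largest plane slope plus the membership-reshuffling term
    (p-range times the maximal log-membership slope).
    """
    a = np.abs(model.consequents[:, :2]).max()
    corners = np.array([[lo, lo], [lo, hi], [hi, lo], [hi, hi]])
    p = _consequent_values(model, corners)
    p_range = float(p.max() - p.min())
    dmax = max(hi - model.centers.min(), model.centers.max() - lo, 0.0)
    mslope = dmax / (model.widths.min() ** 2)
    return float(a + p_range * 2.0 * mslope)
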