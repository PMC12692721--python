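"""Two-stage descriptor pre-selection and the LDA baseline classifier.

A raw candidate pool (often thousands of descriptor columns) is first
reduced with classical Stepwise Discriminant Analysis driven by Wilks'
lambda partial-F tests, which cheaply discards insignificant and mutually
correlated columns. The survivors then enter a greedy forward selection
that, at each step, refits a multiclass LDA with every remaining candidate
appended and keeps the one giving the largest accuracy improvement,
stopping once the best marginal gain drops below a threshold (default
5e-5, i.e. 0.005 percentage points). The resulting
:class:`SelectionTrace` records the cumulative-accuracy curve and each
descriptor's marginal contribution.

The LDA here is the standard pooled-within-covariance multiclass linear
discriminant with a small ridge on the covariance diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class FeatureMatrix:
    """Residues x descriptors design with per-row class labels and mask.

    ``mask[i]`` False marks a technical (unresolved) row excluded from all
    fitting and scoring. ``column_meta`` carries one fingerprint string per
    column.
    """

    X: np.ndarray
    y: np.ndarray
    mask: Optional[np.ndarray] = None
    column_meta: Optional[list[str]] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.mask is None:
            self.mask = np.ones(len(self.y), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.X) != len(self.y) or len(self.mask) != len(self.y):
            raise ValueError("X, y and mask must have equal row counts")

    def active(self) -> tuple[np.ndarray, np.ndarray]:
        return self.X[self.mask], self.y[self.mask]


def standardize_impute(X: np.ndarray) -> np.ndarray:
    """Column z-standardization followed by zero-imputation of missing values.

    Means and standard deviations are computed over the observed (finite)
    entries, so imputing NaN with 0 afterwards places missing values at the
    column mean. Constant columns are left centered with unit divisor.
    """
    X = np.array(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    Z = (X - mu) / sd
    Z[~np.isfinite(Z)] = 0.0
    return Z


@dataclass
class LdaModel:
    """Multiclass LDA with pooled within-class covariance."""

    classes: np.ndarray
    means: np.ndarray          # (g, d)
    cov: np.ndarray            # (d, d), regularized pooled covariance
    log_priors: np.ndarray     # (g,)
    coef: np.ndarray = field(init=False)       # (g, d)
    intercept: np.ndarray = field(init=False)  # (g,)

    def __post_init__(self):
        cov_inv = np.linalg.inv(self.cov)
        self.coef = self.means @ cov_inv
        self.intercept = (-0.5 * np.einsum("gd,gd->g", self.coef, self.means)
                          + self.log_priors)


def fit_lda(X: np.ndarray, y: np.ndarray, ridge: Optional[float] = None) -> LdaModel:
    """Fit multiclass LDA; ``ridge`` (default 1e-6 * mean diagonal) is added
    to the pooled covariance diagonal to keep it positive-definite."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, d = X.shape
    means = np.vstack([X[y_idx == g].mean(axis=0) for g in range(len(classes))])
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least two rows")
    resid = X - means[y_idx]
    cov = resid.T @ resid / (n - len(classes))
    if ridge is None:
        ridge = 1e-6 * np.trace(cov) / d
    cov = cov + ridge * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; increase the ridge parameter")
    log_priors = np.log(counts / n)
    return LdaModel(classes=classes, means=means, cov=cov, log_priors=log_priors)


def predict_lda(model: LdaModel, X: np.ndarray,
                return_scores: bool = False):
    """Argmax of the linear discriminant scores; ties break to the lowest
    class index (numpy argmax convention)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coef.shape[1]:
        raise ValueError("feature dimension mismatch")
    scores = X @ model.coef.T + model.intercept
    labels = model.classes[np.argmax(scores, axis=1)]
    if return_scores:
        return labels, scores
    return labels


def lda_accuracy(X_train, y_train, X_eval, y_eval, ridge=None) -> float:
    model = fit_lda(X_train, y_train, ridge=ridge)
    return float(np.mean(predict_lda(model, X_eval) == y_eval))


def _wilks_lambda(X: np.ndarray, y_idx: np.ndarray, cols: list[int],
                  W: np.ndarray, T: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) restricted to the column subset."""
    if not cols:
        return 1.0
    idx = np.ix_(cols, cols)
    sign_w, logdet_w = np.linalg.slogdet(W[idx])
    sign_t, logdet_t = np.linalg.slogdet(T[idx])
    if sign_w <= 0 or sign_t <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def sda_select(
    X: np.ndarray,
    y: np.ndarray,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_keep: Optional[int] = None,
) -> list[int]:
    """Stepwise discriminant analysis on Wilks' lambda.

    Iteratively enters the column with the largest partial F above
    ``f_enter``, then re-tests entered columns and removes any whose partial
    F has dropped below ``f_remove``; stops when no entry or removal is
    possible or ``max_keep`` columns are held. Constant columns are skipped
    with a warning. Exactly collinear pairs can never both stay: the second
    column's partial F given the first is zero.
    """
    if not f_enter > f_remove > 0:
        raise ValueError("need f_enter > f_remove > 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, d = X.shape
    g = len(classes)
    if g < 2:
        warnings.warn("single-class response: no between-class variance")
        return []
    if max_keep is None:
        max_keep = d
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn(f"skipping {int(constant.sum())} constant column(s)")
    # Total and within-class SSCP matrices, computed once.
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    means = np.vstack([X[y_idx == c].mean(axis=0) for c in range(g)])
    R = X - means[y_idx]
    W = R.T @ R

    selected: list[int] = []
    lam_current = 1.0
    while True:
        changed = False
        # Entry step.
        if len(selected) < max_keep:
            best_j, best_f, best_lam = -1, -np.inf, None
            p = len(selected)
            df2 = n - g - p
            if df2 > 0:
                for j in range(d):
                    if j in selected or constant[j]:
                        continue
                    # tolerance check: candidates (near-)collinear with the
                    # entered set can never join it
                    if selected:
                        T_ss = T[np.ix_(selected, selected)]
                        t_sj = T[selected, j]
                        try:
                            r2 = float(t_sj @ np.linalg.solve(T_ss, t_sj) / T[j, j])
                        except np.linalg.LinAlgError:
                            continue
                        if r2 > 1.0 - 1e-4:
                            continue
                    lam_new = _wilks_lambda(X, y_idx, selected + [j], W, T)
                    if lam_new <= 0 or lam_new >= lam_current:
                        f_j = 0.0
                    else:
                        f_j = (lam_current / lam_new - 1.0) * df2 / (g - 1)
                    if f_j > best_f:
                        best_j, best_f, best_lam = j, f_j, lam_new
                if best_j >= 0 and best_f > f_enter:
                    selected.append(best_j)
                    lam_current = best_lam if best_lam and best_lam > 0 else lam_current
                    changed = True
        # Removal step.
        if len(selected) > 1:
            p = len(selected)
            df2 = n - g - (p - 1)
            worst_j, worst_f, worst_lam = -1, np.inf, None
            for j in selected:
                rest = [c for c in selected if c != j]
                lam_rest = _wilks_lambda(X, y_idx, rest, W, T)
                if lam_current <= 0 or lam_rest <= 0:
                    continue
                f_j = (lam_rest / lam_current - 1.0) * df2 / (g - 1)
                if f_j < worst_f:
                    worst_j, worst_f, worst_lam = j, f_j, lam_rest
            if worst_j >= 0 and worst_f < f_remove:
                selected.remove(worst_j)
                lam_current = worst_lam
                changed = True
        if not changed:
            break
    return selected


@dataclass
class SelectionTrace:
    """Ordered greedy choices with the accuracy curve they produced."""

    chosen: list[int]
    cumulative_accuracy: list[float]
    marginal_gain: list[float]
    stop_reason: str

    def __post_init__(self):
        cum = self.cumulative_accuracy
        if not cum:
            return
        expected = [cum[0]] + [cum[k] - cum[k - 1] for k in range(1, len(cum))]
        if not np.allclose(self.marginal_gain, expected):
            raise ValueError("marginal gains inconsistent with cumulative accuracies")


def greedy_lda_select(
    X: np.ndarray,
    y: np.ndarray,
    stop_gain: float = 5e-5,
    max_k: Optional[int] = None,
    eval_fraction: float = 0.2,
    seed: int = 0,
    ridge: Optional[float] = None,
    score_fn=None,
) -> SelectionTrace:
    """Greedy forward LDA selection maximizing held-out accuracy.

    The rows are split (seeded) into a fit part and an evaluation part of
    ``eval_fraction``; at each step every remaining candidate column is
    appended in turn, an LDA is refit, and the accuracy-maximizing candidate
    is kept. Only strictly positive gains are accepted; ties break to the
    lowest column index. Selection stops when the best marginal gain falls
    below ``stop_gain`` or ``max_k`` columns are chosen. Set
    ``eval_fraction=0`` to score on the training rows instead.

    ``score_fn(cols)``, when given, replaces the LDA refit as the accuracy
    measure for a candidate column subset (a tuple of column indices).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if max_k is None:
        max_k = d
    rng = np.random.default_rng(seed)
    if eval_fraction > 0:
        perm = rng.permutation(n)
        n_eval = max(int(round(eval_fraction * n)), 1)
        eval_idx, fit_idx = perm[:n_eval], perm[n_eval:]
    else:
        eval_idx = fit_idx = np.arange(n)
    Xf, yf = X[fit_idx], y[fit_idx]
    Xe, ye = X[eval_idx], y[eval_idx]

    chosen: list[int] = []
    cum: list[float] = []
    gains: list[float] = []
    acc_current = 0.0
    stop_reason = "exhausted"
    while len(chosen) < max_k:
        best_j, best_acc = -1, -np.inf
        for j in range(d):
            if j in chosen:
                continue
            cols = chosen + [j]
            try:
                if score_fn is not None:
                    acc = score_fn(tuple(cols))
                else:
                    acc = lda_accuracy(Xf[:, cols], yf, Xe[:, cols], ye, ridge=ridge)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if acc > best_acc:
                best_j, best_acc = j, acc
        if best_j < 0:
            stop_reason = "no_fittable_candidate"
            break
        gain = best_acc - acc_current
        if gain < stop_gain or gain <= 0:
            stop_reason = "gain_below_threshold"
            break
        chosen.append(best_j)
        cum.append(best_acc)
        gains.append(gain)
        acc_current = best_acc
    else:
        stop_reason = "max_k_reached"
    return SelectionTrace(chosen=chosen, cumulative_accuracy=cum,
                          marginal_gain=gains, stop_reason=stop_reason)


def selection_curve(trace: SelectionTrace) -> dict:
    """Curve data from a trace: (k, cumulative accuracy), (k, marginal gain),
    and the smallest k reaching 95% / 99% of the final cumulative accuracy."""
    if not trace.cumulative_accuracy:
        raise ValueError("empty selection trace")
    cum = np.array(trace.cumulative_accuracy)
    final = cum[-1]
    k95 = int(np.argmax(cum >= 0.95 * final)) + 1
    k99 = int(np.argmax(cum >= 0.99 * final)) + 1
    return {
        "k": list(range(1, len(cum) + 1)),
        "cumulative_accuracy": cum.tolist(),
        "marginal_gain": list(trace.marginal_gain),
        "k95": k95,
        "k99": k99,
        "stop_reason": trace.stop_reason,
    }
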