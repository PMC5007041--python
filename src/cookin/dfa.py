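"""Stepwise discriminant analysis over callers and pairwise F distances.

The caller-identity analysis has three parts:

* **Stepwise feature selection** driven by Wilks' lambda: at each step the
  candidate minimizing the partial lambda enters if its F-to-enter is
  significant at ``p_enter``; after every entry, included features whose
  F-to-remove has p >= ``p_remove`` are taken out again.  F statistics use
  the exact partial-lambda formula with (g - 1, N - g - p) degrees of
  freedom, so a given feature matrix always reproduces the same selection
  path.

* **Classification** of calls to callers by minimal Mahalanobis distance to
  the group centroids under the pooled within-group covariance (equal
  priors), reported both as resubstitution and leave-one-call-out accuracy,
  with chance level 100/g %.

* **Pairwise F distances**: for callers i, j the Mahalanobis distance
  between centroids is converted to the classical pairwise-group F of
  discriminant analysis,

      F_ij = n_i n_j (N - g - p + 1) / ((n_i + n_j) p (N - g)) * D2_ij,

  which in the two-group case is exactly the Hotelling T-squared test's F.
  The symmetric F matrix is the acoustic distance fed to the dyadic model.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "StepwiseLDA",
    "stepwise_select",
    "pairwise_f",
    "classification_report",
    "RankDeficiencyError",
    "InsufficientDataError",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


class InsufficientDataError(ValueError):
    pass


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Total and within-group scatter, class means, class sizes."""
    classes, inv = np.unique(y, return_inverse=True)
    g = len(classes)
    n, p = X.shape
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    means = np.zeros((g, p))
    counts = np.bincount(inv, minlength=g).astype(float)
    for k in range(g):
        means[k] = X[inv == k].mean(axis=0)
    Xw = X - means[inv]
    W = Xw.T @ Xw
    return T, W, means, counts


def _logdets(W: np.ndarray, T: np.ndarray, idx: list[int]) -> tuple[float, float]:
    """(log det W_S, log det T_S); raises on a singular block."""
    if not idx:
        return 0.0, 0.0
    sub = np.ix_(idx, idx)
    sW, ldW = np.linalg.slogdet(W[sub])
    sT, ldT = np.linalg.slogdet(T[sub])
    if sW <= 0 or sT <= 0:
        raise RankDeficiencyError("singular scatter matrix on the candidate set")
    return float(ldW), float(ldT)


def _log_wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float:
    """log of det(W_S)/det(T_S)."""
    ldW, ldT = _logdets(W, T, idx)
    return ldW - ldT


class StepwiseLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant classifier with stepwise Wilks'-lambda selection.

    Parameters
    ----------
    p_enter, p_remove
        Entry and removal significance thresholds for the partial-F tests
        (enter when p <= p_enter, remove when p >= p_remove; requires
        p_enter < p_remove).
    max_steps
        Hard cap on selection steps; default allows every feature to enter
        and leave once.
    var_floor
        Features whose pooled within-group variance falls below this are
        excluded before selection (with a warning).
    tol
        Tolerance guard: a candidate whose within-group variance remaining
        after regression on the included set falls below ``tol`` times its
        marginal within-group variance is skipped as collinear.

    Attributes
    ----------
    selected_ : list of column names, in entry order sorted by index
    steps_ : DataFrame log of (step, action, feature, wilks_lambda, F, p)
    classes_, means_, pooled_cov_, wilks_lambda_
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 max_steps: int | None = None, var_floor: float = 1e-12,
                 tol: float = 1e-7):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_steps = max_steps
        self.var_floor = var_floor
        self.tol = tol

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y) -> "StepwiseLDA":
        if not self.p_enter < self.p_remove:
            raise ValueError("need p_enter < p_remove")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.array([f"x{i}" for i in range(Xa.shape[1])], dtype=object)
        ya = np.asarray(y)
        if np.isnan(Xa).any():
            raise ValueError("feature matrix contains missing values")
        classes, counts = np.unique(ya, return_counts=True)
        if len(classes) < 2:
            raise InsufficientDataError("need at least two callers")
        if (counts < 1).any() or len(ya) <= len(classes):
            raise InsufficientDataError("fewer calls than degrees of freedom require")

        N, p_all = Xa.shape
        g = len(classes)
        T, W, means, nk = _scatter_matrices(Xa, ya)

        within_var = np.diag(W) / max(N - g, 1)
        usable = within_var >= self.var_floor
        if not usable.all():
            dropped = list(self.feature_names_in_[~usable])
            warnings.warn(f"excluding near-constant features: {dropped}", RuntimeWarning,
                          stacklevel=2)
        candidates = [j for j in range(p_all) if usable[j]]

        max_steps = self.max_steps or 2 * p_all
        selected: list[int] = []
        log_lambda = 0.0
        ldW_cur = 0.0
        steps: list[dict] = []
        step = 0

        while step < max_steps:
            # --- entry ---
            df2 = N - g - len(selected)
            if df2 <= 0:
                break
            best_j, best_pl = -1, 1.0
            for j in candidates:
                if j in selected:
                    continue
                try:
                    ldW_j, ldT_j = _logdets(W, T, selected + [j])
                except RankDeficiencyError:
                    continue
                # tolerance guard: within-group variance of j left after
                # regression on the included set, relative to its marginal
                if np.exp(ldW_j - ldW_cur) < self.tol * W[j, j]:
                    continue
                pl = float(np.exp(ldW_j - ldT_j - log_lambda))
                if not np.isfinite(pl) or pl <= 0:
                    continue
                if pl < best_pl - 1e-15:  # exact ties keep the lowest index
                    best_j, best_pl = j, pl
            entered = False
            if best_j >= 0:
                F_enter = (df2 / (g - 1)) * (1.0 - best_pl) / best_pl
                p_val = float(stats.f.sf(F_enter, g - 1, df2))
                if p_val <= self.p_enter:
                    selected.append(best_j)
                    log_lambda += np.log(best_pl)
                    ldW_cur = _logdets(W, T, selected)[0]
                    step += 1
                    steps.append(dict(step=step, action="enter",
                                      feature=self.feature_names_in_[best_j],
                                      wilks_lambda=float(np.exp(log_lambda)),
                                      F=float(F_enter), p=p_val))
                    entered = True
            # --- removal sweep ---
            removed_any = True
            while removed_any and len(selected) > 1:
                removed_any = False
                worst_j, worst_p, worst_pl = -1, -1.0, 1.0
                df2r = N - g - len(selected) + 1
                for j in selected:
                    rest = [k for k in selected if k != j]
                    rest_log = _log_wilks(W, T, rest)
                    pl = float(np.exp(log_lambda - rest_log))
                    F_rm = (df2r / (g - 1)) * (1.0 - pl) / pl
                    p_val = float(stats.f.sf(F_rm, g - 1, df2r))
                    if p_val > worst_p:
                        worst_j, worst_p, worst_pl = j, p_val, pl
                if worst_j >= 0 and worst_p >= self.p_remove:
                    rest = [k for k in selected if k != worst_j]
                    ldW_cur, ldT_rest = _logdets(W, T, rest)
                    log_lambda = ldW_cur - ldT_rest
                    selected = rest
                    step += 1
                    F_rm = ((N - g - len(selected)) / (g - 1)) * (1.0 - worst_pl) / worst_pl
                    steps.append(dict(step=step, action="remove",
                                      feature=self.feature_names_in_[worst_j],
                                      wilks_lambda=float(np.exp(log_lambda)),
                                      F=float(F_rm), p=worst_p))
                    removed_any = True
            if not entered:
                break

        if not selected:
            raise InsufficientDataError("no feature met the entry criterion")

        sel_sorted = sorted(selected)
        self.selected_idx_ = sel_sorted
        self.selected_ = [self.feature_names_in_[j] for j in sel_sorted]
        self.steps_ = pd.DataFrame(steps)
        self.wilks_lambda_ = float(np.exp(log_lambda))
        self.classes_ = classes
        self.class_counts_ = nk
        self.n_samples_ = N
        sub = np.ix_(sel_sorted, sel_sorted)
        self.means_ = means[:, sel_sorted]
        self.pooled_cov_ = W[sub] / (N - g)
        self._W_sel = W[sub]
        self._X = Xa[:, sel_sorted]
        self._y_idx = np.searchsorted(classes, ya)
        try:
            self._cov_inv = np.linalg.inv(self.pooled_cov_)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RankDeficiencyError("pooled within-group covariance singular") from exc
        return self

    # -- prediction and reports ------------------------------------------

    def _mahalanobis(self, X: np.ndarray, means: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
        d = X[:, None, :] - means[None, :, :]
        return np.einsum("nkp,pq,nkq->nk", d, cov_inv, d)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        if isinstance(X, pd.DataFrame):
            Xa = X[self.selected_].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)[:, self.selected_idx_]
        d2 = self._mahalanobis(Xa, self.means_, self._cov_inv)
        return self.classes_[np.argmin(d2, axis=1)]  # argmin ties -> lowest class id

    @property
    def chance_level_(self) -> float:
        check_is_fitted(self, "classes_")
        return 100.0 / len(self.classes_)

    def classification_report(self) -> dict:
        """Resubstitution and leave-one-call-out accuracy with confusion."""
        check_is_fitted(self, "selected_")
        X, y_idx = self._X, self._y_idx
        g = len(self.classes_)
        N = self.n_samples_
        d2 = self._mahalanobis(X, self.means_, self._cov_inv)
        pred = np.argmin(d2, axis=1)
        confusion = np.zeros((g, g), dtype=int)
        np.add.at(confusion, (y_idx, pred), 1)
        acc_resub = 100.0 * float((pred == y_idx).mean())

        # leave-one-out via rank-one downdates of W and the class centroid
        W = self._W_sel
        W_inv = np.linalg.inv(W)
        correct = 0
        counted = 0
        for i in range(N):
            c = y_idx[i]
            n_c = self.class_counts_[c]
            if n_c < 2:
                continue
            x = X[i]
            mean_c = self.means_[c]
            d = x - mean_c
            scale = n_c / (n_c - 1.0)
            # W' = W - scale * d d'   (Sherman-Morrison on the inverse)
            Wd = W_inv @ d
            denom = 1.0 - scale * float(d @ Wd)
            if denom <= 1e-12:
                continue
            Wp_inv = W_inv + (scale / denom) * np.outer(Wd, Wd)
            means_loo = self.means_.copy()
            means_loo[c] = (n_c * mean_c - x) / (n_c - 1.0)
            diff = x[None, :] - means_loo
            dist = np.einsum("kp,pq,kq->k", diff, Wp_inv, diff)
            if np.argmin(dist) == c:
                correct += 1
            counted += 1
        acc_loo = 100.0 * correct / counted if counted else float("nan")

        return {
            "confusion": pd.DataFrame(confusion, index=self.classes_, columns=self.classes_),
            "accuracy_resubstitution": acc_resub,
            "accuracy_loo": acc_loo,
            "chance_level": self.chance_level_,
            "n_calls": int(N),
            "n_callers": int(g),
            "n_selected": len(self.selected_),
        }

    def pairwise_f(self) -> pd.DataFrame:
        """Symmetric matrix of pairwise-group F distances between callers."""
        check_is_fitted(self, "selected_")
        g = len(self.classes_)
        p = len(self.selected_)
        N = self.n_samples_
        nk = self.class_counts_
        diff = self.means_[:, None, :] - self.means_[None, :, :]
        D2 = np.einsum("ijp,pq,ijq->ij", diff, self._cov_inv, diff)
        nmat = np.outer(nk, nk) / (nk[:, None] + nk[None, :])
        F = nmat * (N - g - p + 1) / (p * (N - g)) * D2
        np.fill_diagonal(F, 0.0)
        return pd.DataFrame(F, index=self.classes_, columns=self.classes_)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def stepwise_select(features: pd.DataFrame, labels, p_enter: float = 0.05,
                    p_remove: float = 0.10, max_steps: int | None = None) -> StepwiseLDA:
    """Fit a StepwiseLDA on a feature DataFrame; returns the fitted model."""
    return StepwiseLDA(p_enter=p_enter, p_remove=p_remove, max_steps=max_steps).fit(
        features, labels)


def pairwise_f(features: pd.DataFrame, labels, **kw) -> pd.DataFrame:
    return stepwise_select(features, labels, **kw).pairwise_f()


def classification_report(features: pd.DataFrame, labels, **kw) -> dict:
    return stepwise_select(features, labels, **kw).classification_report()
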