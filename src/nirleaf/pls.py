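"""Partial least squares regression with a single response (PLS1).

Components are extracted sequentially in the NIPALS fashion: each weight
vector maximizes covariance between the deflated predictor block and the
response, scores are the projections onto the weights, and the block is
deflated by the rank-one score/loading outer product.  With one response the
per-component update has a closed form (no inner iteration), which keeps the
fit exactly deterministic.

Reflectance predictors share units, so predictors are mean-centered but not
autoscaled by default; a ``scale`` flag enables unit-variance scaling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError, DegenerateInputError
from .sampling import SplitResult

logger = logging.getLogger(__name__)


class PLS1Regression(RegressorMixin, BaseEstimator):
    """NIPALS partial least squares regression for a single response.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract; must satisfy
        ``1 <= n_components <= min(n_samples - 1, n_predictors)``.
    scale : bool
        Autoscale predictors to unit variance (default off: reflectance
        shares units across wavelengths).
    tol : float
        Relative tolerance on residual norms below which component
        extraction is considered collapsed; the model is then truncated to
        the achieved number of components with a logged note.

    Attributes
    ----------
    x_mean_, y_mean_ : centering constants from the training data.
    x_weights_ : (p, a) weight vectors, unit norm.
    x_loadings_ : (p, a) predictor loadings.
    y_loadings_ : (a,) response loadings.
    x_scores_ : (n, a) training scores (mutually orthogonal).
    coef_ : (p,) regression vector on centered (scaled) predictors.
    n_components_ : achieved number of components (<= n_components).
    predictor_columns_ : column labels seen during fit, if any.
    """

    def __init__(self, n_components: int = 2, scale: bool = False, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.tol = tol

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y) -> "PLS1Regression":
        X, columns = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ConfigurationError("X and y are not row-aligned")
        if n < 2:
            raise ConfigurationError("need at least 2 samples")
        max_comp = min(n - 1, p)
        if not (1 <= self.n_components <= max_comp):
            raise ConfigurationError(
                f"n_components={self.n_components} outside [1, {max_comp}]"
            )
        if np.ptp(y) == 0.0:
            raise DegenerateInputError("response has zero variance")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            self.x_std_ = sd
        else:
            self.x_std_ = np.ones(p)
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        x_norm0 = np.linalg.norm(Xc)
        y_norm0 = np.linalg.norm(yc)
        W = np.zeros((p, self.n_components))
        P = np.zeros((p, self.n_components))
        q = np.zeros(self.n_components)
        T = np.zeros((n, self.n_components))
        achieved = 0
        for a in range(self.n_components):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn <= self.tol * max(x_norm0 * y_norm0, 1.0):
                logger.info("component extraction collapsed at %d components", achieved)
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt <= (self.tol * max(x_norm0, 1.0)) ** 2:
                logger.info("score norm collapsed at %d components", achieved)
                break
            pl = Xc.T @ t / tt
            ql = float(yc @ t / tt)
            Xc = Xc - np.outer(t, pl)
            yc = yc - ql * t
            W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t
            achieved += 1
        if achieved == 0:
            raise DegenerateInputError("no PLS component could be extracted")

        self.x_weights_ = W[:, :achieved]
        self.x_loadings_ = P[:, :achieved]
        self.y_loadings_ = q[:achieved]
        self.x_scores_ = T[:, :achieved]
        self.n_components_ = achieved
        self.coef_ = self._coefficients(achieved)
        self.predictor_columns_ = columns
        return self

    def _coefficients(self, k: int) -> np.ndarray:
        """Regression vector using the first ``k`` components."""
        W = self.x_weights_[:, :k]
        P = self.x_loadings_[:, :k]
        q = self.y_loadings_[:k]
        # P'W is unit upper triangular for NIPALS; a general solve is still
        # cheap at these sizes and more robust
        return W @ np.linalg.solve(P.T @ W, q)

    # -- prediction -------------------------------------------------------
    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X, columns = _as_matrix(X)
        if X.shape[1] != self.x_mean_.shape[0]:
            raise ConfigurationError(
                f"X has {X.shape[1]} columns, model expects {self.x_mean_.shape[0]}"
            )
        if (
            columns is not None
            and self.predictor_columns_ is not None
            and not np.array_equal(columns, self.predictor_columns_)
        ):
            raise ConfigurationError("predictor columns do not match the fitted model")
        if n_components is None:
            b = self.coef_
        else:
            if not (1 <= n_components <= self.n_components_):
                raise ConfigurationError("n_components outside fitted range")
            b = self._coefficients(n_components)
        return self.y_mean_ + ((X - self.x_mean_) / self.x_std_) @ b

    # -- (de)serialization helpers ---------------------------------------
    def to_arrays(self) -> dict:
        return {
            "n_components": int(self.n_components_),
            "scale": bool(self.scale),
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "predictor_columns": (
                None
                if self.predictor_columns_ is None
                else np.asarray(self.predictor_columns_, dtype=float).tolist()
            ),
        }

    @classmethod
    def from_arrays(cls, d: dict) -> "PLS1Regression":
        m = cls(n_components=d["n_components"], scale=d.get("scale", False))
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.x_std_ = np.asarray(d["x_std"], dtype=float)
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.asarray(d["x_weights"], dtype=float)
        m.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.x_scores_ = None
        m.n_components_ = int(d["n_components"])
        cols = d.get("predictor_columns")
        m.predictor_columns_ = None if cols is None else np.asarray(cols, dtype=float)
        return m


def _as_matrix(X):
    """Coerce to a 2-D float array; keep numeric column labels if present."""
    columns = None
    if isinstance(X, pd.DataFrame):
        columns = np.asarray(X.columns, dtype=float)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, columns


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_plsr(X, y, n_components: int, scale: bool = False) -> PLS1Regression:
    """Fit a PLS1 model (thin wrapper over :class:`PLS1Regression`)."""
    return PLS1Regression(n_components=n_components, scale=scale).fit(X, y)


def predict_plsr(model: PLS1Regression, X) -> np.ndarray:
    return model.predict(X)


def choose_components(
    X,
    y,
    max_components: int,
    split: SplitResult | tuple,
) -> int:
    """Pick the component count minimizing validation RMSEP.

    ``split`` holds integer row positions (a :class:`SplitResult` from
    positional ids, or a ``(calibration_idx, validation_idx)`` pair).  The
    model is fit once at ``max_components`` on the calibration rows and
    truncated regression vectors score the validation rows; ties go to the
    smaller component count.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(split, SplitResult):
        cal = np.asarray(split.calibration_ids, dtype=int)
        val = np.asarray(split.validation_ids, dtype=int)
    else:
        cal, val = (np.asarray(s, dtype=int) for s in split)
    n_cal = cal.shape[0]
    max_allowed = min(n_cal - 1, X.shape[1])
    k_max = min(max_components, max_allowed)
    if k_max < 1:
        raise ConfigurationError("max_components must allow at least one component")
    model = PLS1Regression(n_components=k_max).fit(X[cal], y[cal])
    rmseps = np.array(
        [
            float(np.sqrt(np.mean((y[val] - model.predict(X[val], n_components=k)) ** 2)))
            for k in range(1, model.n_components_ + 1)
        ]
    )
    return int(np.argmin(rmseps)) + 1  # argmin takes the first (fewest) on ties
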