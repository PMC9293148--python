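"""Maximum-entropy presence/background model (Maxent), implemented from the objective.

The model places a Gibbs density pi(x) proportional to exp(w . f(x)) over the
background records and chooses w to maximise the mean log-density of the
presence records, minus an L1 penalty:

    minimise_w   -mean_presence[ w . f(x) ] + log Z(w) + sum_j beta_j |w_j|

where Z(w) = (1/B) sum_background exp(w . f(b)). The objective is convex;
it is solved by splitting w into nonnegative parts (w = u - v, u, v >= 0),
which turns the L1 term into a linear one, and running box-constrained
L-BFGS-B to a projected-gradient tolerance of 1e-6. At beta = 0 the
optimum satisfies the classical moment constraint: the pi-weighted
background feature mean equals the presence feature mean.

Features are expansions of the raw covariates (linear, quadratic, pairwise
product and hinge classes), rescaled to [0, 1] using the background range,
as is standard for this model family. The suitability output is converted
to a probability of presence by weighing the relative occurrence rate
r(x) = exp(w . f(x)) / Z against a prevalence tau:

    P(presence | x) = tau * r(x) / (tau * r(x) + 1 - tau)

with tau defaulting to the training prevalence (0.5 for balanced
bootstrap samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["FeatureExpansion", "fit_maxent", "MaxentClassifier"]

_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")


@dataclass
class FeatureExpansion:
    """Deterministic covariate -> feature-vector expansion for Maxent.

    Columns are min-max rescaled with constants taken from the data the
    expansion is fitted on (the full training sample), then expanded
    into the requested feature classes. Hinge knots sit at equally spaced
    quantiles of each rescaled column; both forward and reverse hinges are
    generated.
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    n_hinge_knots: int = 5
    mins_: np.ndarray | None = field(default=None, repr=False)
    ranges_: np.ndarray | None = field(default=None, repr=False)
    knots_: np.ndarray | None = field(default=None, repr=False)
    columns_: tuple[str, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(_FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}; choose from {_FEATURE_CLASSES}")

    def fit(self, X: pd.DataFrame | np.ndarray) -> "FeatureExpansion":
        X, cols = _to_matrix(X)
        self.columns_ = cols
        self.mins_ = X.min(axis=0)
        rng = X.max(axis=0) - self.mins_
        self.ranges_ = np.where(rng > 0, rng, 1.0)
        if "hinge" in self.classes and self.n_hinge_knots > 0:
            scaled = self._scale(X)
            qs = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
            self.knots_ = np.quantile(scaled, qs, axis=0)  # (n_knots, p)
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.mins_) / self.ranges_, 0.0, 1.0)

    def transform(self, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
        if self.mins_ is None:
            raise AttributeError("FeatureExpansion is not fitted")
        X, cols = _to_matrix(X)
        if self.columns_ is not None and cols is not None and tuple(cols) != tuple(self.columns_):
            raise ValueError(f"covariate names {cols} do not match fitted names {self.columns_}")
        s = self._scale(X)
        p = s.shape[1]
        names = list(self.columns_ or [f"x{j}" for j in range(p)])
        blocks: list[np.ndarray] = []
        feat_names: list[str] = []
        if "linear" in self.classes:
            blocks.append(s)
            feat_names += names
        if "quadratic" in self.classes:
            blocks.append(s**2)
            feat_names += [f"{n}^2" for n in names]
        if "product" in self.classes:
            for a in range(p):
                for b in range(a + 1, p):
                    blocks.append((s[:, a] * s[:, b])[:, None])
                    feat_names.append(f"{names[a]}*{names[b]}")
        if "hinge" in self.classes and self.knots_ is not None:
            for k in range(self.knots_.shape[0]):
                t = self.knots_[k]
                blocks.append(np.clip(s - t, 0.0, None))
                feat_names += [f"hinge({n}>{t[j]:.3g})" for j, n in enumerate(names)]
                blocks.append(np.clip(t - s, 0.0, None))
                feat_names += [f"hinge({n}<{t[j]:.3g})" for j, n in enumerate(names)]
        F = np.hstack(blocks) if blocks else np.empty((len(s), 0))
        return F, feat_names

    def fit_transform(self, X) -> tuple[np.ndarray, list[str]]:
        return self.fit(X).transform(X)


def _to_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    return np.asarray(X, dtype=float), None


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    regularization: float | np.ndarray = 0.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Solve the penalised maximum-entropy problem for the feature weights.

    Parameters
    ----------
    presence_features, background_features:
        Already-expanded feature matrices (rows = records). Both must be
        finite; the background needs at least two distinct rows.
    regularization:
        Per-feature L1 penalty beta_j (scalar broadcasts). Zero gives the
        unpenalised maximum-entropy fit.
    tol:
        Projected-gradient tolerance passed to L-BFGS-B.

    Returns
    -------
    np.ndarray of shape (n_features,) -- the fitted weights.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if len(P) < 1:
        raise ValueError("need at least one presence record")
    if len(np.unique(B, axis=0)) < 2:
        raise ValueError("need at least two distinct background rows")
    if not (np.isfinite(P).all() and np.isfinite(B).all()):
        raise ValueError("non-finite feature values")
    d = P.shape[1]
    beta = np.broadcast_to(np.asarray(regularization, dtype=float), (d,)).copy()
    if np.any(beta < 0):
        raise ValueError("regularization must be >= 0")

    pbar = P.mean(axis=0)
    logB = np.log(len(B))

    def objective(uv: np.ndarray):
        u, v = uv[:d], uv[d:]
        w = u - v
        scores = B @ w
        lz = logsumexp(scores) - logB
        # softmax over background = pi-weighted feature expectation
        pi = np.exp(scores - (lz + logB))
        ef = pi @ B
        val = -pbar @ w + lz + beta @ (u + v)
        grad = np.concatenate([-pbar + ef + beta, pbar - ef + beta])
        return val, grad

    x0 = np.zeros(2 * d)
    bounds = [(0.0, None)] * (2 * d)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    u, v = res.x[:d], res.x[d:]
    return u - v


class MaxentClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for the presence/background maximum-entropy model.

    ``fit`` treats rows with y == 1 as presences and rows with y == 0 as
    background (here: true absence records). The per-feature L1 penalty is
    ``regularization * sd_j(background features) / sqrt(n_presence)``, so
    ``regularization`` plays the role of the conventional multiplier on a
    sample-size-aware default penalty.

    Parameters
    ----------
    features : tuple of str
        Feature classes from {"linear", "quadratic", "product", "hinge"}.
    n_hinge_knots : int
        Interior knots per covariate for the hinge class.
    regularization : float
        Penalty multiplier (0 disables shrinkage).
    prevalence : float or None
        tau used by the probability transform; None takes the training
        presence fraction.

    Attributes
    ----------
    coef_ : fitted feature weights
    feature_names_ : names of the expanded features
    expansion_ : the fitted :class:`FeatureExpansion`
    log_z_ : log normaliser over the training background
    prevalence_ : tau actually used
    """

    def __init__(
        self,
        features: tuple[str, ...] = ("linear", "quadratic", "hinge"),
        n_hinge_knots: int = 5,
        regularization: float = 1.0,
        prevalence: float | None = None,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ):
        self.features = features
        self.n_hinge_knots = n_hinge_knots
        self.regularization = regularization
        self.prevalence = prevalence
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "MaxentClassifier":
        y = np.asarray(y)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("y must contain both classes 0 (background) and 1 (presence)")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xp = X[y == 1] if isinstance(X, pd.DataFrame) else np.asarray(X)[y == 1]
        # scaling constants from the full training sample: background-only
        # ranges would clip separable presences onto a single feature value
        self.expansion_ = FeatureExpansion(classes=tuple(self.features), n_hinge_knots=self.n_hinge_knots)
        self.expansion_.fit(X)
        Fp, names = self.expansion_.transform(Xp)
        # background = the whole training sample (absences AND presences).
        # With absences alone, presences occupying feature regions the
        # background never reaches make the penalised objective unbounded
        # below (weights diverge); including presences guarantees
        # max_background(f . d) >= mean_presence(f . d) for every direction d.
        Fb, _ = self.expansion_.transform(X)
        sd = Fb.std(axis=0)
        beta = self.regularization * sd / np.sqrt(len(Fp))
        self.coef_ = fit_maxent(Fp, Fb, regularization=beta, tol=self.tol, max_iter=self.max_iter)
        self.feature_names_ = names
        self.log_z_ = float(logsumexp(Fb @ self.coef_) - np.log(len(Fb)))
        self.prevalence_ = float(np.mean(y)) if self.prevalence is None else float(self.prevalence)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = Fp.shape[1] if not hasattr(self, "feature_names_in_") else len(self.feature_names_in_)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Log relative occurrence rate, log r(x) = w . f(x) - log Z."""
        if not hasattr(self, "coef_"):
            raise AttributeError("MaxentClassifier is not fitted yet")
        if hasattr(self, "feature_names_in_") and isinstance(X, pd.DataFrame):
            missing = set(self.feature_names_in_) - set(X.columns)
            if missing:
                raise ValueError(f"missing covariates {sorted(missing)}")
            X = X[list(self.feature_names_in_)]
        F, _ = self.expansion_.transform(X)
        return F @ self.coef_ - self.log_z_

    def predict_proba(self, X) -> np.ndarray:
        log_r = self.decision_function(X)
        tau = self.prevalence_
        # P = tau*r / (tau*r + 1-tau), computed on the log scale for stability
        logit = log_r + np.log(tau) - np.log1p(-tau)
        p1 = expit(logit)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
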