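"""Non-negative matrix factorization by multiplicative updates.

The factorization X ~ W H (all entries >= 0) is the analytical core of the
package: rows of H are basis spectra, rows of W hold the per-spectrum
weighting factors. The solver minimizes

    1/2 ||X - WH||_F^2
    + alpha * [ l1_ratio * (||W||_1 + ||H||_1)
              + (1 - l1_ratio)/2 * (||W||_F^2 + ||H||_F^2) ]

by alternating the classical multiplicative update rules, which keep both
factors non-negative and make the objective non-increasing. It is written
as a scikit-learn-style transformer so it composes with sklearn pipelines;
it deliberately does not delegate to ``sklearn.decomposition.NMF``, which
serves only as an independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["MultiplicativeNMF"]


class MultiplicativeNMF(TransformerMixin, BaseEstimator):
    """NMF with Frobenius loss, L1/L2 penalties, multiplicative updates.

    Parameters
    ----------
    n_components : int
        Number of components k (here: number of isomers).
    alpha : float, default 0.0
        Regularization strength applied to both factor matrices.
    l1_ratio : float, default 0.0
        L1 fraction of the penalty in [0, 1]; 0 gives a pure L2 penalty.
    max_iter : int, default 2000
        Iteration cap; with ``tol=0`` the solver always runs this long.
    tol : float, default 0.0
        Relative objective-change stopping threshold; 0 disables early
        stopping.
    warm_start_max_iter : int, default 0
        With ``init='custom'`` and a supplied basis H (but no W), run up to
        this many coefficient-only updates first, so the anchored basis is
        not perturbed by a random W before the weights have settled.
    random_state : int, default 0
        Seed for the random initialization; fixed seed gives bit-identical
        results (the factorization itself is not unique, so reporting a
        seed is part of the result).
    eps : float, default 1e-12
        Floor applied to update denominators; entries cannot become exactly
        zero mid-run.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_features)
        Basis matrix H.
    objective_trace_ : ndarray
        Objective value after each iteration (non-increasing within
        numerical slack).
    reconstruction_err_ : float
        Final ||X - WH||_F.
    n_iter_ : int
        Iterations actually run.
    converged_ : bool
        Whether the relative objective change dropped below ``tol``.
    """

    def __init__(
        self,
        n_components: int = 2,
        *,
        init: str = "random",
        alpha: float = 0.0,
        l1_ratio: float = 0.0,
        max_iter: int = 2000,
        tol: float = 0.0,
        warm_start_max_iter: int = 0,
        random_state: int = 0,
        eps: float = 1e-12,
    ):
        self.n_components = n_components
        self.init = init
        self.warm_start_max_iter = warm_start_max_iter
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.eps = eps

    # ------------------------------------------------------------------
    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.any(X < 0):
            raise ValueError("X must be non-negative")
        if not np.any(X > 0):
            raise ValueError("X must not be all zero")
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > min(X.shape):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples, n_features)="
                f"{min(X.shape)}"
            )
        if not (1 <= self.max_iter):
            raise ValueError("max_iter must be >= 1")
        if self.alpha < 0 or not (0 <= self.l1_ratio <= 1) or self.tol < 0:
            raise ValueError("invalid regularization or tolerance settings")
        return X

    def _objective(self, X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
        resid = X - W @ H
        value = 0.5 * float(np.sum(resid * resid))
        if self.alpha > 0:
            l1 = float(np.sum(W) + np.sum(H))
            l2 = float(np.sum(W * W) + np.sum(H * H))
            value += self.alpha * (
                self.l1_ratio * l1 + 0.5 * (1.0 - self.l1_ratio) * l2
            )
        return value

    def _init_factors(self, X: np.ndarray, k: int, W0, H0):
        # scale-matched uniform random start: E[(WH)_ij] ~ mean(X);
        # init="custom" takes caller-supplied starting factors (e.g. known
        # basis spectra), filling whichever of W/H is not given randomly
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(X.mean() / k)
        if self.init == "random":
            if W0 is not None or H0 is not None:
                raise ValueError("W/H starting factors require init='custom'")
            W0 = H0 = None
        elif self.init == "custom":
            if W0 is None and H0 is None:
                raise ValueError("init='custom' needs W and/or H")
        else:
            raise ValueError(f"unknown init {self.init!r}")
        if W0 is None:
            W = scale * rng.uniform(size=(X.shape[0], k))
        else:
            W = np.asarray(W0, dtype=float).copy()
            if W.shape != (X.shape[0], k) or np.any(W < 0):
                raise ValueError("invalid custom W")
        if H0 is None:
            H = scale * rng.uniform(size=(k, X.shape[1]))
        else:
            H = np.asarray(H0, dtype=float).copy()
            if H.shape != (k, X.shape[1]) or np.any(H < 0):
                raise ValueError("invalid custom H")
        return np.maximum(W, self.eps), np.maximum(H, self.eps)

    def _update_W(self, X, W, H):
        numer = X @ H.T
        denom = W @ (H @ H.T)
        if self.alpha > 0:
            denom = denom + self.alpha * self.l1_ratio
            denom = denom + self.alpha * (1.0 - self.l1_ratio) * W
        return W * numer / np.maximum(denom, self.eps)

    def _update_H(self, X, W, H):
        numer = W.T @ X
        denom = (W.T @ W) @ H
        if self.alpha > 0:
            denom = denom + self.alpha * self.l1_ratio
            denom = denom + self.alpha * (1.0 - self.l1_ratio) * H
        return H * numer / np.maximum(denom, self.eps)

    # ------------------------------------------------------------------
    def fit_transform(self, X, y=None, *, W=None, H=None) -> np.ndarray:
        """Factorize X; returns the weight matrix W and stores H.

        With ``init='custom'``, `W` and/or `H` seed the iteration (entries
        are floored at ``eps`` so the updates can still move them).
        """
        X = self._validate(X)
        k = int(self.n_components)
        given_H = H is not None and W is None
        W, H = self._init_factors(X, k, W, H)
        if given_H and self.warm_start_max_iter > 0:
            # coefficient warm start: fit W to the supplied basis before
            # alternating, so the anchored basis is not dragged away by a
            # random W (cheap W-only updates, objective-based early stop)
            previous = None
            for i in range(self.warm_start_max_iter):
                W = self._update_W(X, W, H)
                if i % 10 == 9:
                    current = self._objective(X, W, H)
                    if (
                        previous is not None
                        and previous > 0
                        and abs(previous - current) / previous
                        < max(self.tol, 1e-12)
                    ):
                        break
                    previous = current
        trace = []
        converged = False
        previous = self._objective(X, W, H)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            W = self._update_W(X, W, H)
            H = self._update_H(X, W, H)
            current = self._objective(X, W, H)
            trace.append(current)
            if previous > 0:
                rel_change = abs(previous - current) / previous
                if self.tol > 0 and rel_change < self.tol:
                    converged = True
                    previous = current
                    break
            previous = current

        self.components_ = H
        self.objective_trace_ = np.asarray(trace)
        self.reconstruction_err_ = float(np.linalg.norm(X - W @ H))
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return W

    def fit(self, X, y=None) -> "MultiplicativeNMF":
        self.W_ = self.fit_transform(X)
        return self

    def transform(self, X) -> np.ndarray:
        """Solve for W with the fitted basis H held fixed."""
        if not hasattr(self, "components_"):
            raise AttributeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.components_.shape[1]:
            raise ValueError("X has wrong shape for fitted basis")
        if np.any(X < 0):
            raise ValueError("X must be non-negative")
        H = self.components_
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(X.mean(), self.eps) / self.components_.shape[0])
        W = np.maximum(scale * rng.uniform(size=(X.shape[0], H.shape[0])), self.eps)
        previous = None
        for _ in range(self.max_iter):
            W = self._update_W(X, W, H)
            current = self._objective(X, W, H)
            if previous is not None and self.tol > 0 and previous > 0:
                if abs(previous - current) / previous < self.tol:
                    break
            previous = current
        return W
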