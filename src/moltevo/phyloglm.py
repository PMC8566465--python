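"""Phylogenetic logistic regression of a binary tip trait on covariates.

Model (Ives–Garland two-state switching regression): tip i carries a binary
trait with mean p_i = logit^-1(x_i' beta); residual dependence among tips
comes from a two-state Markov switching process running along the tree whose
relaxation rate is the phylogenetic signal parameter alpha (Myr^-1), so the
working correlation between tips i and j decays as exp(-alpha * d_ij) with
d_ij the patristic distance.  Large alpha means fast switching and hence
phylogenetically independent tips; as alpha grows the fit converges to
ordinary logistic regression.

Estimation: for fixed alpha, beta solves the generalized estimating
equations D' V^-1 (y - p) = 0 with D = dp/dbeta and V the working covariance
diag(sqrt(pq)) R diag(sqrt(pq)), R = exp(-alpha D_patristic); alpha is
profiled on a log grid maximizing the Gaussian working quasi-likelihood
-(log|V| + r' V^-1 r)/2 and then refined by bounded scalar optimization.
Standard errors are model-based, (D' V^-1 D)^-1; Wald tests are two-tailed
against the normal reference.

An optional Firth-type (Jeffreys-penalized working score) update is provided
to stabilize near-separated data; by default the estimator is the plain GEE
solution and perfect separation is refused with a flagged error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.special import expit, ndtr

from .treeio import Phylogeny

__all__ = ["PhyloGLMFit", "SeparationError", "fit_phyloglm", "univariate_table"]

_PCLIP = 1e-10
_ETA_MAX = 30.0


class SeparationError(RuntimeError):
    """The binary response is (quasi-)perfectly separated by the covariates;
    unpenalized estimates diverge.  Refit with ``firth=True`` to stabilize."""


@dataclass
class PhyloGLMFit:
    """A fitted phylogenetic logistic regression."""

    alpha: float
    names: List[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n: int
    converged: bool
    alpha_bound_hit: bool = False
    quasi_loglik: float = float("nan")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "alpha": self.alpha,
            "estimate": self.beta,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "n": self.n,
        })

    def to_dict(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "n": int(self.n),
            "converged": bool(self.converged),
            "alpha_bound_hit": bool(self.alpha_bound_hit),
            "coefficients": {
                nm: {"estimate": float(b), "se": float(s), "z": float(z),
                     "p": float(p)}
                for nm, b, s, z, p in zip(self.names, self.beta, self.se,
                                          self.z, self.p)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhyloGLMFit":
        names = list(d["coefficients"])
        get = lambda k: np.array([d["coefficients"][nm][k] for nm in names])
        return cls(alpha=d["alpha"], names=names, beta=get("estimate"),
                   se=get("se"), z=get("z"), p=get("p"), n=d["n"],
                   converged=d["converged"],
                   alpha_bound_hit=d.get("alpha_bound_hit", False))


def _align(tree: Phylogeny, y, X, names):
    labels = tree.tip_labels
    if isinstance(y, pd.Series):
        missing = sorted(set(labels) - set(y.index))
        extra = sorted(set(y.index) - set(labels))
        if missing or extra:
            raise KeyError(
                "species mismatch between tree and response: "
                f"missing from data: {missing[:10]}; not in tree: {extra[:10]}")
        y = y.loc[labels].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(labels):
            raise ValueError(f"y has {y.shape[0]} rows for {len(labels)} tips")
    if isinstance(X, (pd.DataFrame, pd.Series)):
        if isinstance(X, pd.Series):
            X = X.to_frame()
        missing = sorted(set(labels) - set(X.index))
        extra = sorted(set(X.index) - set(labels))
        if missing or extra:
            raise KeyError(
                "species mismatch between tree and covariates: "
                f"missing from data: {missing[:10]}; not in tree: {extra[:10]}")
        if names is None:
            names = list(X.columns)
        X = X.loc[labels].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(labels):
            raise ValueError(f"X has {X.shape[0]} rows for {len(labels)} tips")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return y, X, list(names)


class _NumericalFailure(RuntimeError):
    """A single working-alpha evaluation failed numerically; skip it."""


def _irls_start(X: np.ndarray, y: np.ndarray, max_iter: int = 50
                ) -> Tuple[np.ndarray, bool]:
    """Plain logistic IRLS for starting values plus a separation check.

    Returns ``(beta, separated)``; ``separated`` flags (quasi-)complete
    separation, diagnosed by the MLE linear predictor running away.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-8, None)
        H = X.T @ (X * w[:, None]) + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    # separability certificate: the fitted direction puts every success above
    # every failure, and the margin keeps running away (|eta| large).  A large
    # |eta| alone is legitimate for wide-ranged covariates, so both must hold.
    eta = X @ beta
    separable = float(eta[y == 1].min()) >= float(eta[y == 0].max())
    separated = bool(separable and np.max(np.abs(eta)) > 15.0)
    return beta, separated


def fit_phyloglm(tree: Phylogeny, y, X, names: Optional[Sequence[str]] = None,
                 alpha_bounds: Tuple[float, float] = (1e-6, 1e3),
                 n_grid: int = 13, max_iter: int = 100, tol: float = 1e-6,
                 firth: bool = False) -> PhyloGLMFit:
    """Fit the phylogenetic logistic regression.

    ``y`` (0/1) and ``X`` may be pandas objects indexed by species name (they
    are aligned to the tree, with mismatches reported) or arrays already in
    tree tip order.  An intercept column is always prepended.  Both response
    classes must be present.  Deterministic given the data.
    """
    y, X, xnames = _align(tree, y, X, names)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain non-finite values")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("y is constant: both classes must be present")
    n = y.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    names_full = ["intercept"] + xnames

    _, D = tree.patristic_matrix()
    lo, hi = alpha_bounds

    def gee(alpha: float, beta0: np.ndarray):
        """Solve the estimating equations for beta at fixed alpha."""
        R = np.exp(-alpha * D)
        jitter = 1e-8
        cf = None
        while jitter <= 1e-2:
            try:
                cf = cho_factor(R + jitter * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        if cf is None:
            raise _NumericalFailure(f"correlation matrix singular at alpha={alpha:g}")
        beta = beta0.copy()
        converged = False
        for _ in range(max_iter):
            eta = Xd @ beta
            if not np.all(np.isfinite(beta)) or np.max(np.abs(eta)) > 1e4:
                raise _NumericalFailure(
                    f"diverging working fit at alpha={alpha:g}")
            p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
            s = np.sqrt(p * (1 - p))
            A = Xd * s[:, None]
            RinvA = cho_solve(cf, A)
            J = A.T @ RinvA
            resid = (y - p) / s
            U = A.T @ cho_solve(cf, resid)
            if firth:
                Jinv = np.linalg.inv(J)
                h = np.einsum("ij,jk,ik->i", RinvA, Jinv, A)
                adj = h * (0.5 - p) / s
                U = U + A.T @ cho_solve(cf, adj)
            step = np.linalg.solve(J + 1e-10 * np.eye(J.shape[0]), U)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        eta = np.clip(Xd @ beta, -_ETA_MAX, _ETA_MAX)
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        s = np.sqrt(p * (1 - p))
        A = Xd * s[:, None]
        J = A.T @ cho_solve(cf, A)
        # Gaussian working quasi-log-likelihood for profiling alpha
        logdetR = 2.0 * np.sum(np.log(np.diag(cf[0])))
        r = (y - p) / s
        quad = float(r @ cho_solve(cf, r))
        ql = -0.5 * (logdetR + 2.0 * np.sum(np.log(s)) + quad)
        return beta, J, ql, converged

    beta0, separated = _irls_start(Xd, y)
    if separated and not firth:
        raise SeparationError(
            "response is (quasi-)perfectly separated by the covariates; "
            "boundary estimates refused (refit with firth=True to stabilize)")
    if separated:
        beta0 = np.zeros(Xd.shape[1])
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    warm = beta0
    best_a, best = None, None
    for a in grid:
        try:
            out = gee(a, warm)
        except (_NumericalFailure, np.linalg.LinAlgError):
            continue
        warm = out[0]
        if best is None or out[2] > best[2]:
            best_a, best = a, out
    if best is None:
        raise SeparationError("no alpha produced a stable fit")

    # refine alpha around the best grid point
    gi = int(np.argmin(np.abs(grid - best_a)))
    la = math.log(grid[max(gi - 1, 0)])
    lb = math.log(grid[min(gi + 1, len(grid) - 1)])
    if lb > la:
        cache = {}

        def neg_ql(loga: float) -> float:
            a = math.exp(loga)
            try:
                out = gee(a, best[0])
            except (_NumericalFailure, np.linalg.LinAlgError):
                return 1e12
            cache[a] = out
            return -out[2]

        res = minimize_scalar(neg_ql, bounds=(la, lb), method="bounded",
                              options={"xatol": 1e-3})
        a_hat = math.exp(float(res.x))
        if a_hat in cache and cache[a_hat][2] >= best[2]:
            beta, J, ql, converged = cache[a_hat]
        else:
            a_hat, (beta, J, ql, converged) = best_a, best
    else:
        a_hat, (beta, J, ql, converged) = best_a, best

    cov = np.linalg.inv(J)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p_values = 2.0 * (1.0 - ndtr(np.abs(z)))
    bound_hit = a_hat <= lo * 1.05 or a_hat >= hi * 0.95
    return PhyloGLMFit(alpha=float(a_hat), names=names_full, beta=beta, se=se,
                       z=z, p=p_values, n=n, converged=bool(converged),
                       alpha_bound_hit=bool(bound_hit), quasi_loglik=float(ql))


def univariate_table(tree: Phylogeny, y, X: pd.DataFrame,
                     **kwargs) -> List[PhyloGLMFit]:
    """One univariate fit (intercept + single covariate) per column of X."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    return [fit_phyloglm(tree, y, X[[col]], **kwargs) for col in X.columns]


def table_frame(fits: Sequence[PhyloGLMFit]) -> pd.DataFrame:
    """Stack univariate fits into a regression-table-shaped frame
    (one row per covariate: alpha, estimate, SE, Z, p, n)."""
    rows = []
    for fit in fits:
        for nm, b, s, z, p in zip(fit.names, fit.beta, fit.se, fit.z, fit.p):
            if nm == "intercept":
                continue
            rows.append({"parameter": nm, "alpha": fit.alpha, "estimate": b,
                         "se": s, "z": z, "p": p, "n": fit.n})
    return pd.DataFrame(rows)
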