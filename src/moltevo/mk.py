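"""Mk models of discrete character evolution on a phylogeny.

A k-state character evolves under a continuous-time Markov chain with
generator Q (rows sum to zero, off-diagonals are transition rates in
Myr^-1).  Three standard parameterizations are supported:

* ``ER``  — equal rates: a single rate for every transition;
* ``SYM`` — symmetric rates: q_ij = q_ji, k(k-1)/2 free rates;
* ``ARD`` — all rates different: k(k-1) free rates.

The tree likelihood is computed by the pruning algorithm (a post-order
dynamic program over per-node conditional likelihood vectors) and maximized
over positive rates on the log scale with multiple restarts.  Model choice
uses AICc with a decisiveness threshold on the AICc difference.

For the molt-strategy character the state order is fixed everywhere as
``absent=0, partial=1, complete=2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import Phylogeny

__all__ = [
    "STATE_ORDER",
    "RateMatrix",
    "MkFit",
    "ModelSelection",
    "build_q",
    "rate_names",
    "transition_probs",
    "mk_loglik",
    "fit_mk",
    "aicc",
    "select_model",
]

STATE_ORDER: Tuple[str, ...] = ("absent", "partial", "complete")

_MODEL_CLASSES = ("ER", "SYM", "ARD")

RootPrior = Union[str, Sequence[float], np.ndarray]


def n_free_params(model_class: str, k: int = 3) -> int:
    if model_class == "ER":
        return 1
    if model_class == "SYM":
        return k * (k - 1) // 2
    if model_class == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model class {model_class!r}; expected one of {_MODEL_CLASSES}")


def rate_names(model_class: str, k: int = 3) -> List[str]:
    """Names of the free rates, in the fixed parameter order.

    SYM uses the upper triangle row-major (q01, q02, q12, ...); ARD uses all
    off-diagonal cells row-major (q01, q02, q10, q12, q20, q21, ...).
    """
    if model_class == "ER":
        return ["q"]
    names = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if model_class == "SYM" and j < i:
                continue
            names.append(f"q{i}{j}")
    return names


@dataclass(frozen=True)
class RateMatrix:
    """A CTMC generator assembled from the free rates of a model class."""

    k: int
    model_class: str
    params: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "params", np.asarray(self.params, dtype=float))
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))


def build_q(model_class: str, params: Sequence[float], k: int = 3) -> RateMatrix:
    """Assemble the k x k generator for a model class from its free rates."""
    params = np.asarray(params, dtype=float)
    expected = n_free_params(model_class, k)
    if params.shape != (expected,):
        raise ValueError(
            f"{model_class} with k={k} needs {expected} rates, got shape {params.shape}")
    if not np.all(np.isfinite(params)) or np.any(params <= 0):
        raise ValueError("all rates must be positive and finite")
    Q = np.zeros((k, k))
    if model_class == "ER":
        Q[:] = params[0]
    elif model_class == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = params[idx]
                idx += 1
    else:  # ARD
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = params[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(k=k, model_class=model_class, params=params, Q=Q)


def transition_probs(Q: Union[RateMatrix, np.ndarray], t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length t >= 0."""
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    if t < 0:
        raise ValueError("branch length must be >= 0")
    P = _edge_propagators(Qm, np.array([t]))[0]
    return P


def _edge_propagators(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q * t) for every t in ``lengths``, shape (m, k, k).

    Uses one eigendecomposition of Q (complex-safe for ARD) with a
    ``scipy.linalg.expm`` fallback when Q is defective or the reconstruction
    is inaccurate.  Rows are clipped to [0, 1] and renormalized to absorb
    roundoff at the 1e-12 level.
    """
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    P = None
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
        if np.isfinite(cond) and cond < 1e8:
            E = np.exp(np.multiply.outer(lengths, w))  # (m, k)
            P = np.einsum("ij,mj,jl->mil", V, E, Vinv).real
    except np.linalg.LinAlgError:
        P = None
    if P is None:
        P = np.stack([expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, 1.0)
    rows = P.sum(axis=2, keepdims=True)
    rows[rows == 0] = 1.0
    P /= rows
    return P


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _check_tip_states(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
                      k: int) -> None:
    for tip in tree.tip_labels:
        if tip not in tip_states:
            raise KeyError(f"tip {tip!r} has no entry in tip_states")
        s = tip_states[tip]
        if s is not None and not (0 <= int(s) < k):
            raise ValueError(f"state {s!r} of tip {tip!r} out of range 0..{k - 1}")


def _resolve_root_prior(root_prior: RootPrior, Q: np.ndarray,
                        L_root: Optional[np.ndarray], k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.full(k, 1.0 / k)
        if root_prior == "stationary":
            # left null vector of Q
            w, V = np.linalg.eig(Q.T)
            i = int(np.argmin(np.abs(w)))
            pi = np.abs(V[:, i].real)
            return pi / pi.sum()
        if root_prior == "fitzjohn":
            if L_root is None:
                raise ValueError("fitzjohn prior needs root conditional likelihoods")
            tot = L_root.sum()
            if tot == 0:
                return np.full(k, 1.0 / k)
            return L_root / tot
        raise ValueError(f"unknown root prior policy {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior must be a length-k probability vector")
    return pi


def _postorder_tables(tree: Phylogeny):
    """Flatten the tree into arrays for fast repeated pruning passes."""
    post = tree.postorder()
    index = {id(n): i for i, n in enumerate(post)}
    lengths = np.array([n.length if n.length is not None else 0.0 for n in post])
    children = [[index[id(c)] for c in n.children] for n in post]
    is_leaf = np.array([n.is_leaf for n in post])
    return post, index, lengths, children, is_leaf


def _conditional_likelihoods(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
                             Q: np.ndarray, tables=None):
    """Post-order conditional likelihood vectors with per-node scaling.

    Returns ``(L, logscale, P, tables)`` where ``L[i]`` is the (rescaled)
    conditional likelihood vector of postorder node i, ``logscale[i]`` the
    accumulated log scaling factor of the subtree rooted at i, and ``P[i]``
    the transition matrix over the branch above node i.
    """
    k = Q.shape[0]
    if tables is None:
        tables = _postorder_tables(tree)
    post, index, lengths, children, is_leaf = tables
    P = _edge_propagators(Q, lengths)
    n = len(post)
    L = np.empty((n, k))
    logscale = np.zeros(n)
    for i, node in enumerate(post):
        if is_leaf[i]:
            s = tip_states[node.label]
            if s is None:
                L[i] = 1.0
            else:
                L[i] = 0.0
                L[i, int(s)] = 1.0
            continue
        v = np.ones(k)
        ls = 0.0
        for ci in children[i]:
            v = v * (P[ci] @ L[ci])
            ls += logscale[ci]
        m = v.max()
        if m <= 0:
            L[i] = 0.0
            logscale[i] = -np.inf
            continue
        L[i] = v / m
        logscale[i] = ls + np.log(m)
    return L, logscale, P, tables


def mk_loglik(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
              Q: Union[RateMatrix, np.ndarray], root_prior: RootPrior = "flat",
              _tables=None) -> float:
    """Log-likelihood of the tip states under the CTMC with generator Q.

    ``tip_states`` maps every tip label to a state index (or ``None`` for a
    missing observation, which contributes an all-ones conditional vector).
    The root state is integrated against ``root_prior`` (a probability vector
    or one of the policies ``"flat"``, ``"stationary"``, ``"fitzjohn"``).
    Polytomies are handled as products over all children.
    """
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = Qm.shape[0]
    _check_tip_states(tree, tip_states, k)
    L, logscale, _, _ = _conditional_likelihoods(tree, tip_states, Qm, _tables)
    L_root, ls_root = L[-1], logscale[-1]
    pi = _resolve_root_prior(root_prior, Qm, L_root, k)
    like = float(pi @ L_root)
    if like <= 0 or not np.isfinite(ls_root):
        return -np.inf
    return float(np.log(like) + ls_root)


# ---------------------------------------------------------------------------
# Fitting and model selection
# ---------------------------------------------------------------------------

def aicc(logL: float, k_free: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1), n = number of tips."""
    if n <= k_free + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k_free + 1}")
    return -2.0 * logL + 2.0 * k_free + 2.0 * k_free * (k_free + 1) / (n - k_free - 1)


@dataclass
class MkFit:
    """A maximum-likelihood Mk fit."""

    model_class: str
    params: np.ndarray
    rate_names: List[str]
    logL: float
    n_params: int
    n_tips: int
    aicc: float
    root_prior_policy: RootPrior
    root_prior: np.ndarray
    n_restarts: int
    best_restart_objective: float
    converged: bool
    non_identifiable: bool = False
    k: int = 3

    @property
    def rate_matrix(self) -> RateMatrix:
        return build_q(self.model_class, self.params, self.k)

    def to_dict(self) -> dict:
        return {
            "model": self.model_class,
            "rates": {nm: float(v) for nm, v in zip(self.rate_names, self.params)},
            "logL": float(self.logL),
            "n_params": int(self.n_params),
            "n_tips": int(self.n_tips),
            "aicc": float(self.aicc),
            "root_prior": [float(p) for p in self.root_prior],
            "converged": bool(self.converged),
            "non_identifiable": bool(self.non_identifiable),
        }


class FitError(RuntimeError):
    pass


def fit_mk(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
           model_class: str = "ER", root_prior: RootPrior = "flat",
           n_restarts: int = 5, seed: int = 0, k: int = 3,
           rate_bounds: Tuple[float, float] = (1e-8, 1e3)) -> MkFit:
    """Maximum-likelihood Mk fit by box-constrained quasi-Newton on log-rates.

    Multi-start: the first start is a heuristic rate 1/tree-height for all
    free rates; the remaining ``n_restarts - 1`` starts perturb it with
    seeded lognormal noise.  Deterministic given ``seed``.
    """
    nfree = n_free_params(model_class, k)
    _check_tip_states(tree, tip_states, k)
    observed = {int(s) for s in tip_states.values() if s is not None}
    n = tree.n_tips
    tables = _postorder_tables(tree)
    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])

    if len(observed) < 2:
        warnings.warn(
            "fewer than two distinct observed states: rates are not identifiable; "
            "returning a boundary fit", RuntimeWarning)
        params = np.full(nfree, rate_bounds[0])
        Q = build_q(model_class, params, k)
        logL = mk_loglik(tree, tip_states, Q, root_prior, _tables=tables)
        L, _, _, _ = _conditional_likelihoods(tree, tip_states, Q.Q, tables)
        pi = _resolve_root_prior(root_prior, Q.Q, L[-1], k)
        return MkFit(model_class, params, rate_names(model_class, k), logL, nfree,
                     n, aicc(logL, nfree, n), root_prior, pi,
                     0, -logL, converged=True, non_identifiable=True, k=k)

    def objective(logp: np.ndarray) -> float:
        Q = build_q(model_class, np.exp(logp), k)
        ll = mk_loglik(tree, tip_states, Q, root_prior, _tables=tables)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    height = tree.height
    base = np.log(np.clip(1.0 / max(height, 1e-12), rate_bounds[0] * 1.01,
                          rate_bounds[1] * 0.99))
    starts = [np.full(nfree, base)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.clip(base + rng.normal(0.0, 1.5, size=nfree), lo, hi))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * nfree,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e9:
        raise FitError(f"Mk fit failed for {model_class}: no restart produced a "
                       f"finite likelihood ({n_restarts} restarts)")
    if not any_success:
        raise FitError(f"Mk fit for {model_class} did not converge in any of "
                       f"{n_restarts} restarts (best objective {best.fun:.6g})")
    params = np.exp(best.x)
    Q = build_q(model_class, params, k)
    logL = -float(best.fun)
    L, logscale, _, _ = _conditional_likelihoods(tree, tip_states, Q.Q, tables)
    pi = _resolve_root_prior(root_prior, Q.Q, L[-1], k)
    return MkFit(model_class, params, rate_names(model_class, k), logL, nfree, n,
                 aicc(logL, nfree, n), root_prior, pi, len(starts), float(best.fun),
                 converged=True, k=k)


@dataclass
class ModelSelection:
    """AICc-based choice among Mk fits of the same data."""

    selected: MkFit
    table: pd.DataFrame = field(repr=False)
    decisive: bool = True
    threshold: float = 2.0

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.model_class,
            "decisive": bool(self.decisive),
            "threshold": float(self.threshold),
            "table": self.table.to_dict(orient="records"),
        }


def select_model(fits: Sequence[MkFit], threshold: float = 2.0) -> ModelSelection:
    """Pick the minimum-AICc model; decisive only if it leads by > threshold.

    When not decisive, fall back to the fewest-parameter model among those
    within ``threshold`` of the best AICc (parsimony fallback, flagged via
    ``decisive=False``).
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    ns = {f.n_tips for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are not on identical data: tip counts {sorted(ns)}")
    aiccs = np.array([f.aicc for f in fits])
    order = np.argsort(aiccs, kind="stable")
    best = fits[int(order[0])]
    second = aiccs[int(order[1])]
    decisive = bool(second - best.aicc > threshold)
    if decisive:
        selected = best
    else:
        within = [f for f in fits if f.aicc - best.aicc <= threshold]
        within.sort(key=lambda f: (f.n_params, f.aicc))
        selected = within[0]
    table = pd.DataFrame({
        "model": [f.model_class for f in fits],
        "logL": [f.logL for f in fits],
        "n_params": [f.n_params for f in fits],
        "aicc": [f.aicc for f in fits],
        "delta_aicc": [f.aicc - best.aicc for f in fits],
        "selected": [f is selected for f in fits],
    })
    return ModelSelection(selected=selected, table=table, decisive=decisive,
                          threshold=threshold)
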