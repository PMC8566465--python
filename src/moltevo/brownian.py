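"""Brownian-motion fitting and ancestral estimation for a continuous trait.

Under Brownian motion a trait accrues independent Gaussian increments with
variance sigma^2 * t along each branch, so the tips are jointly Gaussian with
covariance sigma^2 * C, where C_ij is the root-to-MRCA(i, j) path length.
Everything here is computed in linear time by Gaussian belief propagation on
the tree (messages are (mean, variance) pairs in unit-rate time); the results
are identical to the dense GLS formulas

    root  = (1' C^-1 1)^-1 1' C^-1 x
    sigma2 = (x - root 1)' C^-1 (x - root 1) / n        (ML, 1/n denominator)

and each internal node's estimate equals the GLS root estimate of the tree
re-rooted at that node (the conditional ML reconstruction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .treeio import Phylogeny

__all__ = ["BMFit", "fit_bm", "bm_asr"]

_TRANSFORMS = {None: lambda x: x, "log10": np.log10}


@dataclass
class BMFit:
    """A maximum-likelihood Brownian-motion fit."""

    sigma2: float
    root_value: float
    logL: float
    node_estimates: pd.DataFrame = field(repr=False)  # node_id, estimate, variance
    trait_transform: Optional[str] = None
    n_tips: int = 0


def _combine(msgs):
    """Precision-weighted combination of Gaussian messages (mean, var).

    ``var == inf`` is a flat message; ``var == 0`` is a point mass (wins).
    Returns (mean, var, contrasts) where contrasts lists the (delta, w) terms
    produced by sequential pairwise combination (the independent-contrast
    decomposition of the likelihood).
    """
    mean, var = None, None
    contrasts = []
    for m, v in msgs:
        if mean is None:
            mean, var = m, v
            continue
        if math.isinf(var):
            mean, var = m, v
            continue
        if math.isinf(v):
            continue
        w = var + v
        if w > 0:
            contrasts.append((mean - m, w))
            newvar = (var * v) / w
            mean = (mean * v + m * var) / w
            var = newvar
        else:  # two point masses: only consistent if equal
            contrasts.append((mean - m, 0.0))
            var = 0.0
    return mean, var, contrasts


def fit_bm(tree: Phylogeny, tip_values: Mapping[str, float],
           transform: Optional[str] = None) -> BMFit:
    """ML Brownian-motion fit with ancestral estimates at every node.

    ``transform="log10"`` fits on log10-transformed values (recorded on the
    returned fit); the default fits the raw scale.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    tf = _TRANSFORMS[transform]
    tips = tree.tips()
    if len(tips) < 3:
        raise ValueError("BM fitting needs at least 3 tips")
    if tree.height <= 0:
        raise ValueError("zero-depth tree: no time over which variance accrues")
    x: Dict[str, float] = {}
    for t in tips:
        if t.label not in tip_values:
            raise KeyError(f"tip {t.label!r} has no trait value")
        v = float(tf(tip_values[t.label]))
        if not math.isfinite(v):
            raise ValueError(f"non-finite trait value for tip {t.label!r}")
        x[t.label] = v
    n = len(tips)

    post = tree.postorder()
    up: Dict[int, Tuple[float, float]] = {}
    ssq = 0.0          # sum over contrasts of delta^2 / w   (unit-rate)
    logdet = 0.0       # log |C| accumulated from contrast weights
    for node in post:
        if node.is_leaf:
            up[id(node)] = (x[node.label], 0.0)
            continue
        msgs = []
        for c in node.children:
            m, v = up.pop(id(c))
            msgs.append((m, v + c.length))
        mean, var, contrasts = _combine(msgs)
        for delta, w in contrasts:
            if w > 0:
                ssq += delta * delta / w
                logdet += math.log(w)
            elif delta != 0.0:
                raise ValueError(
                    "conflicting values joined by zero-length branches")
        up[id(node)] = (mean, var)
    root_mean, root_var = up[id(tree.root)]
    logdet += math.log(root_var) if root_var > 0 else -math.inf

    sigma2 = ssq / n
    if sigma2 > 0 and math.isfinite(logdet):
        logL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    else:
        logL = math.inf  # degenerate: constant tips (or zero-variance root)

    estimates = _node_estimates(tree, x, sigma2)
    return BMFit(sigma2=float(sigma2), root_value=float(root_mean), logL=float(logL),
                 node_estimates=estimates, trait_transform=transform, n_tips=n)


def _node_estimates(tree: Phylogeny, x: Mapping[str, float],
                    sigma2: float) -> pd.DataFrame:
    """Two-pass GLS/ML estimates (and variances) for every node."""
    post = tree.postorder()
    up: Dict[int, Tuple[float, float]] = {}
    up_conv: Dict[int, Tuple[float, float]] = {}  # child message seen from parent
    for node in post:
        if node.is_leaf:
            up[id(node)] = (x[node.label], 0.0)
        else:
            msgs = [(up_conv[id(c)]) for c in node.children]
            mean, var, _ = _combine(msgs)
            up[id(node)] = (mean, var)
        if node.parent is not None:
            m, v = up[id(node)]
            up_conv[id(node)] = (m, v + node.length)

    down: Dict[int, Tuple[float, float]] = {id(tree.root): (0.0, math.inf)}
    for node in tree.preorder():
        for child in node.children:
            msgs = [down[id(node)]]
            msgs += [up_conv[id(s)] for s in node.children if s is not child]
            mean, var, _ = _combine(msgs)
            if mean is None:  # root with a single child and flat prior
                mean, var = 0.0, math.inf
            down[id(child)] = (mean, (var + child.length)
                               if not math.isinf(var) else math.inf)

    ids = tree.node_ids()
    rows = []
    for node in tree.preorder():
        mean, var, _ = _combine([down[id(node)], up[id(node)]])
        rows.append((ids[id(node)], float(mean), float(var * sigma2)))
    return pd.DataFrame(rows, columns=["node_id", "estimate", "variance"])


def bm_asr(tree: Phylogeny, tip_values: Mapping[str, float],
           fit: Optional[BMFit] = None,
           transform: Optional[str] = None) -> pd.DataFrame:
    """Ancestral estimates for every node; refits if no BMFit is supplied.

    With a supplied ``fit`` the estimates are recomputed from the same tips
    under that fit's transform and rate (they must come from the same data).
    """
    if fit is None:
        fit = fit_bm(tree, tip_values, transform=transform)
        return fit.node_estimates
    tf = _TRANSFORMS[fit.trait_transform]
    x = {label: float(tf(v)) for label, v in tip_values.items()}
    return _node_estimates(tree, x, fit.sigma2)
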