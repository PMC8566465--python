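"""Marginal (empirical-Bayes) ancestral state reconstruction for Mk models.

Posterior state probabilities at every node are computed exactly with the
model parameters fixed at their maximum-likelihood estimates: one post-order
pass collects the conditional likelihood of the subtree below each node, one
pre-order pass propagates the partial likelihood of the rest of the tree, and
the two are multiplied and normalized per node.  This is mathematically
identical to re-rooting the tree at each node but costs a single O(n) sweep,
and it handles non-symmetric (ARD) generators because the downward messages
follow the root-to-tip direction of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import mk
from .mk import (MkFit, ModelSelection, RateMatrix, RootPrior,
                 _conditional_likelihoods, _resolve_root_prior, fit_mk,
                 select_model)
from .treeio import Phylogeny

__all__ = ["AncestralStates", "marginal_asr", "asr_pipeline", "annotate_tree"]


@dataclass
class AncestralStates:
    """Per-node posterior probability vectors over the character states.

    ``frame`` has one row per node (preorder), columns ``node_id`` plus one
    posterior column per state name; tips with observed states carry the unit
    vector on the observation.
    """

    frame: pd.DataFrame = field(repr=False)
    state_names: Tuple[str, ...]
    fit: Optional[MkFit] = None

    def posterior(self, node_id: str) -> np.ndarray:
        row = self.frame.loc[self.frame["node_id"] == node_id]
        if row.empty:
            raise KeyError(f"unknown node id {node_id!r}")
        return row[[f"p_{s}" for s in self.state_names]].to_numpy()[0]

    @property
    def root_posterior(self) -> np.ndarray:
        # the root is the first preorder node
        return self.frame.iloc[0][[f"p_{s}" for s in self.state_names]].to_numpy(float)


def marginal_asr(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
                 Q: Union[RateMatrix, np.ndarray], root_prior: RootPrior = "flat",
                 state_names: Sequence[str] = mk.STATE_ORDER,
                 fit: Optional[MkFit] = None) -> AncestralStates:
    """Exact marginal posteriors P(state at node | all tip data) for every node.

    The posterior at node v is proportional to ``U_v * L_v`` where ``L_v`` is
    the conditional likelihood of the subtree below v (post-order pass) and
    ``U_v`` the partial likelihood of everything else (pre-order pass seeded
    with the root prior).  At the root this reduces to the likelihood-weighted
    prior decomposition pi_s L_root(s) / sum_s' pi_s' L_root(s').
    """
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = Qm.shape[0]
    if len(state_names) != k:
        raise ValueError("state_names length must match the state count")
    L, logscale, P, tables = _conditional_likelihoods(tree, tip_states, Qm)
    post, index, lengths, children, is_leaf = tables
    pi = _resolve_root_prior(root_prior, Qm, L[-1], k)

    n = len(post)
    U = np.empty((n, k))
    root_i = n - 1
    U[root_i] = pi
    # pre-order: parents before children (reverse postorder)
    for i in range(n - 1, -1, -1):
        kids = children[i]
        if not kids:
            continue
        # messages child -> parent, as functions of the parent state
        msgs = [P[ci] @ L[ci] for ci in kids]
        for j, ci in enumerate(kids):
            S = U[i].copy()
            for jj, m in enumerate(msgs):
                if jj != j:
                    S *= m
            u = S @ P[ci]  # sum over parent state: S[s] P_t(s -> s')
            tot = u.sum()
            U[ci] = u / tot if tot > 0 else np.full(k, 1.0 / k)

    posteriors = U * L
    sums = posteriors.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    posteriors /= sums

    ids = tree.node_ids()
    pre = tree.preorder()
    rows = np.array([posteriors[index[id(node)]] for node in pre])
    frame = pd.DataFrame({"node_id": [ids[id(node)] for node in pre]})
    for s, name in enumerate(state_names):
        frame[f"p_{name}"] = rows[:, s]
    return AncestralStates(frame=frame, state_names=tuple(state_names), fit=fit)


def asr_pipeline(tree: Phylogeny, tip_states: Mapping[str, Optional[int]],
                 root_prior: RootPrior = "flat", seed: int = 0,
                 models: Sequence[str] = ("ER", "SYM", "ARD"),
                 threshold: float = 2.0, n_restarts: int = 5,
                 state_names: Sequence[str] = mk.STATE_ORDER,
                 ) -> Tuple[ModelSelection, AncestralStates]:
    """Fit ER/SYM/ARD, select by AICc, reconstruct under the selected model."""
    fits = [fit_mk(tree, tip_states, m, root_prior=root_prior,
                   n_restarts=n_restarts, seed=seed + j, k=len(state_names))
            for j, m in enumerate(models)]
    selection = select_model(fits, threshold=threshold)
    best = selection.selected
    states = marginal_asr(tree, tip_states, best.rate_matrix,
                          root_prior=root_prior, state_names=state_names, fit=best)
    return selection, states


def annotate_tree(tree: Phylogeny, asr: AncestralStates) -> Phylogeny:
    """Copy of ``tree`` with per-node posteriors written as Newick comments
    (``key=value`` lists inside square brackets)."""
    out = tree.copy()
    ids = out.node_ids()
    lookup = {row.node_id: row for row in asr.frame.itertuples(index=False)}
    for node in out.preorder():
        row = lookup.get(ids[id(node)])
        if row is None:
            continue
        parts = [f"p_{s}={getattr(row, f'p_{s}'):.6f}" for s in asr.state_names]
        node.comment = ",".join(parts)
    return out
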