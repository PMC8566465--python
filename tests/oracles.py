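"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: likelihoods by exhaustive enumeration
of internal-state assignments, posteriors by constrained enumeration, and
Brownian-motion estimates by dense GLS linear algebra with an explicitly
constructed phylogenetic covariance matrix.  These never share code with the
pruning/message-passing implementations they check.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def _edge_probs(tree, Q):
    return {id(n): expm(Q * n.length) for n in tree.postorder()
            if n.length is not None}


def enum_mk_likelihood(tree, tip_states, Q, prior):
    """Total likelihood by summing over all internal-state assignments."""
    post = tree.postorder()
    internal = [n for n in post if not n.is_leaf]
    k = Q.shape[0]
    P = _edge_probs(tree, Q)
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = {id(n): s for n, s in zip(internal, assign)}
        like = prior[st[id(tree.root)]]
        valid = True
        for n in post:
            if n.is_leaf:
                obs = tip_states[n.label]
                if obs is None:
                    # marginalize the tip as well
                    like *= sum(P[id(n)][st[id(n.parent)], s] for s in range(k))
                else:
                    like *= P[id(n)][st[id(n.parent)], int(obs)]
            elif n.length is not None:
                like *= P[id(n)][st[id(n.parent)], st[id(n)]]
        total += like
    return total


def enum_mk_posteriors(tree, tip_states, Q, prior):
    """Marginal posteriors at every node by constrained enumeration."""
    post = tree.postorder()
    internal = [n for n in post if not n.is_leaf]
    k = Q.shape[0]
    P = _edge_probs(tree, Q)
    ids = tree.node_ids()
    joint = {ids[id(n)]: np.zeros(k) for n in tree.preorder()}
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = {id(n): s for n, s in zip(internal, assign)}
        base = prior[st[id(tree.root)]]
        for n in post:
            if not n.is_leaf and n.length is not None:
                base *= P[id(n)][st[id(n.parent)], st[id(n)]]
        # tips: sum over their states (observed tips have one term)
        tip_nodes = [n for n in post if n.is_leaf]
        tip_choices = []
        for n in tip_nodes:
            obs = tip_states[n.label]
            tip_choices.append([int(obs)] if obs is not None else list(range(k)))
        for tips_assign in itertools.product(*tip_choices):
            like = base
            for n, s in zip(tip_nodes, tips_assign):
                like *= P[id(n)][st[id(n.parent)], s]
            for n in internal:
                joint[ids[id(n)]][st[id(n)]] += like
            for n, s in zip(tip_nodes, tips_assign):
                joint[ids[id(n)]][s] += like
    total = joint[ids[id(tree.root)]].sum()
    return {nid: v / total for nid, v in joint.items()}, total


def dense_bm_covariance(tree):
    """Explicit V: V_ij = root-to-MRCA(i, j) path length."""
    labels, D = tree.patristic_matrix()
    depths = tree.node_depths()
    tipd = np.array([depths[id(t)] for t in tree.tips()])
    V = (tipd[:, None] + tipd[None, :] - D) / 2.0
    return labels, V


def dense_bm_fit(tree, tip_values):
    """GLS root value and ML sigma^2 via dense matrix inversion."""
    labels, V = dense_bm_covariance(tree)
    x = np.array([tip_values[lbl] for lbl in labels])
    one = np.ones(len(x))
    Vi = np.linalg.inv(V)
    mu = (one @ Vi @ x) / (one @ Vi @ one)
    s2 = (x - mu) @ Vi @ (x - mu) / len(x)
    return mu, s2


def _dist_from_node(tree, node):
    """Undirected path lengths from ``node`` to every node (graph walk)."""
    adj = {}
    for n in tree.preorder():
        for c in n.children:
            adj.setdefault(id(n), []).append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(n), c.length))
    dist = {id(node): 0.0}
    stack = [id(node)]
    while stack:
        u = stack.pop()
        for v, w in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def dense_node_estimate(tree, tip_values, node):
    """GLS ancestral estimate at ``node``: the root estimate of the tree
    re-rooted there, computed densely from re-rooted covariances."""
    dist = _dist_from_node(tree, node)
    tips = tree.tips()
    labels = [t.label for t in tips]
    _, D = tree.patristic_matrix()
    d_v = np.array([dist[id(t)] for t in tips])
    V = (d_v[:, None] + d_v[None, :] - D) / 2.0
    x = np.array([tip_values[lbl] for lbl in labels])
    one = np.ones(len(x))
    Vi = np.linalg.inv(V)
    return (one @ Vi @ x) / (one @ Vi @ one)
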