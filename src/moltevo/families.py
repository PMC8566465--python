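"""Family-level robustness analysis.

Each family is assigned the ancestral molt strategy with the highest
posterior probability at the most recent common ancestor of its species in
the species-level reconstruction (singleton families use the tip's observed
state).  A one-tip-per-family tree is then built from the species tree by
pruning to one representative per family, and the reconstruction is re-run
on two alternative family-level topologies to check that the root inference
is robust to higher-order topological uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .asr import AncestralStates, asr_pipeline
from .mk import STATE_ORDER, ModelSelection
from .treeio import Phylogeny

__all__ = [
    "FamilyStateAssignment",
    "assign_family_states",
    "build_family_tree",
    "compare_topologies",
    "TopologyComparison",
]


@dataclass
class FamilyStateAssignment:
    """Per-family ancestral state calls.

    ``frame`` columns: family, state, one posterior column per state, and a
    ``tie`` flag.  Ties at the argmax are broken toward the lowest state
    index (absent < partial < complete) and flagged.
    """

    frame: pd.DataFrame = field(repr=False)
    state_names: Tuple[str, ...] = STATE_ORDER

    def states(self) -> Dict[str, str]:
        return dict(zip(self.frame["family"], self.frame["state"]))

    def counts(self) -> Dict[str, int]:
        c = self.frame["state"].value_counts().to_dict()
        return {s: int(c.get(s, 0)) for s in self.state_names}


def assign_family_states(tree: Phylogeny, asr: AncestralStates,
                         family_map: Mapping[str, str]) -> FamilyStateAssignment:
    """State call at each family's MRCA from the species-level posteriors."""
    tips = set(tree.tip_labels)
    missing = sorted(set(family_map) - tips)
    if missing:
        raise KeyError(f"species absent from the tree: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    families: Dict[str, list] = {}
    for sp, fam in family_map.items():
        families.setdefault(fam, []).append(sp)
    ids = tree.node_ids()
    state_names = asr.state_names
    rows = []
    for fam in sorted(families):
        members = families[fam]
        node = tree.mrca(members)
        post = asr.posterior(ids[id(node)]).astype(float)
        best = float(post.max())
        winners = np.flatnonzero(np.isclose(post, best, rtol=0, atol=1e-12))
        state_idx = int(winners[0])
        row = {"family": fam, "state": state_names[state_idx],
               "tie": bool(len(winners) > 1), "n_species": len(members)}
        for s, name in enumerate(state_names):
            row[f"p_{name}"] = float(post[s])
        rows.append(row)
    return FamilyStateAssignment(pd.DataFrame(rows), state_names=state_names)


def build_family_tree(species_tree: Phylogeny, family_map: Mapping[str, str],
                      representative_rule: str = "alphabetical") -> Phylogeny:
    """One-tip-per-family tree: prune to one representative species per
    family, then relabel the tips with the family names.

    ``representative_rule="alphabetical"`` (the only rule provided) picks the
    alphabetically first species of each family, which makes the construction
    deterministic and independent of input row order.
    """
    if representative_rule != "alphabetical":
        raise ValueError(f"unknown representative rule {representative_rule!r}")
    tips = set(species_tree.tip_labels)
    missing = sorted(set(family_map) - tips)
    if missing:
        raise KeyError(f"species absent from the tree: {missing[:10]}")
    reps: Dict[str, str] = {}
    for sp in sorted(family_map):
        fam = family_map[sp]
        reps.setdefault(fam, sp)
    pruned = species_tree.prune_to_taxa(reps.values())
    rep_to_family = {sp: fam for fam, sp in reps.items()}
    for tip in pruned.tips():
        tip.label = rep_to_family[tip.label]
    pruned._validate()
    return pruned


@dataclass
class TopologyComparison:
    """Paired reconstructions of the same family states on two topologies."""

    root_posterior_a: np.ndarray
    root_posterior_b: np.ndarray
    selection_a: ModelSelection
    selection_b: ModelSelection
    asr_a: AncestralStates = field(repr=False)
    asr_b: AncestralStates = field(repr=False)
    pairing: pd.DataFrame = field(repr=False)
    state_names: Tuple[str, ...] = STATE_ORDER


def compare_topologies(tree_a: Phylogeny, tree_b: Phylogeny,
                       family_states: Mapping[str, int], seed: int = 0,
                       **pipeline_kwargs) -> TopologyComparison:
    """Run the full reconstruction pipeline on both family trees.

    ``family_states`` maps family name -> state index; both trees must carry
    exactly the families as tips.  The pairing table (family, position on
    each tree) is the data behind a tanglegram.
    """
    tips_a, tips_b = set(tree_a.tip_labels), set(tree_b.tip_labels)
    if tips_a != tips_b:
        only_a = sorted(tips_a - tips_b)
        only_b = sorted(tips_b - tips_a)
        raise ValueError(f"family sets differ: only in tree_a: {only_a[:10]}; "
                         f"only in tree_b: {only_b[:10]}")
    missing = sorted(tips_a - set(family_states))
    if missing:
        raise KeyError(f"families without a state: {missing[:10]}")
    states = {fam: family_states[fam] for fam in tips_a}
    sel_a, asr_a = asr_pipeline(tree_a, states, seed=seed, **pipeline_kwargs)
    sel_b, asr_b = asr_pipeline(tree_b, states, seed=seed, **pipeline_kwargs)
    order_a = [t for t in tree_a.tip_labels]
    pos_b = {lbl: i for i, lbl in enumerate(tree_b.tip_labels)}
    pairing = pd.DataFrame({
        "family": order_a,
        "position_a": np.arange(len(order_a)),
        "position_b": [pos_b[f] for f in order_a],
        "state": [STATE_ORDER[states[f]] for f in order_a],
    })
    return TopologyComparison(
        root_posterior_a=asr_a.root_posterior,
        root_posterior_b=asr_b.root_posterior,
        selection_a=sel_a, selection_b=sel_b,
        asr_a=asr_a, asr_b=asr_b, pairing=pairing)
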