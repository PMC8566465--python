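"""End-to-end orchestration of the molt-strategy comparative analysis.

``run_full_analysis`` takes a tree, a species trait table and a configuration
and produces the complete report bundle: descriptive statistics, the Mk
model-selection table, node posteriors (CSV + annotated Newick), the
Brownian-motion body-mass reconstruction, the regression table for mass and
latitude, order-level regressions for eligible orders, and a reproducibility
manifest.  All outputs are deterministic given the inputs and seed, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .asr import annotate_tree, asr_pipeline
from .brownian import fit_bm
from .families import assign_family_states, build_family_tree, compare_topologies
from .mk import STATE_ORDER
from .phyloglm import SeparationError, table_frame, univariate_table
from .traits import (TraitTable, code_binary, load_species_table, match_tree,
                     order_subsets, summarize_by_strategy)
from .treeio import Phylogeny, parse_newick

__all__ = ["AnalysisConfig", "run_full_analysis", "run_family_analysis"]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run."""

    tree_path: Optional[str] = None
    traits_path: Optional[str] = None
    output_dir: str = "results/run"
    root_prior: str = "flat"
    models: Tuple[str, ...] = ("ER", "SYM", "ARD")
    aicc_threshold: float = 2.0
    exclude_bdpr: bool = False
    order_min_count: int = 21
    mass_transform: Optional[str] = None
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.aicc_threshold <= 0:
            raise ValueError("aicc_threshold must be > 0")

    def analysis_params(self) -> dict:
        """The fields that define the analysis (output location excluded, so
        the manifest is byte-identical wherever the bundle is written)."""
        d = asdict(self)
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # re-raise with stage context
                raise StageError(f"stage {name!r} failed: {e}") from e
        return inner
    return wrap


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_full_analysis(config: AnalysisConfig,
                      tree: Optional[Phylogeny] = None,
                      table: Optional[TraitTable] = None) -> Dict[str, object]:
    """Run every stage and write the report bundle into ``config.output_dir``.

    ``tree`` and ``table`` may be passed in memory (e.g. from the synthetic
    generator); otherwise they are loaded from the configured paths.
    Returns a dict with the in-memory results and the paths written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if tree is None:
        if config.tree_path is None:
            raise StageError("stage 'load' failed: no tree given (path or object)")
        tree = parse_newick(Path(config.tree_path).read_text())
    if table is None:
        if config.traits_path is None:
            raise StageError("stage 'load' failed: no trait table given")
        table = load_species_table(config.traits_path)

    mapping = _stage("name-matching")(match_tree)(table, tree)
    n_total = table.n_species
    if config.exclude_bdpr:
        table = table.exclude_bdpr()
    used_species = [mapping[sp] for sp in table.species]
    analysis_tree = (tree if len(used_species) == tree.n_tips
                     else tree.prune_to_taxa(used_species))

    results: Dict[str, object] = {"tree": analysis_tree, "table": table}
    paths: Dict[str, str] = {}

    # (e) descriptive summaries
    desc = _stage("descriptives")(summarize_by_strategy)(table)
    _write_csv(desc, out / "descriptive_stats.csv")
    paths["descriptives"] = str(out / "descriptive_stats.csv")
    results["descriptives"] = desc

    # (a, b) Mk model selection + marginal ancestral states
    tip_states = {mapping[sp]: s for sp, s in table.tip_states().items()}
    selection, states = _stage("ancestral-reconstruction")(asr_pipeline)(
        analysis_tree, tip_states, root_prior=config.root_prior,
        seed=config.seed, models=config.models,
        threshold=config.aicc_threshold, n_restarts=config.n_restarts)
    _write_csv(selection.table, out / "mk_model_selection.csv")
    _write_csv(states.frame, out / "node_posteriors.csv")
    annotated = annotate_tree(analysis_tree, states)
    (out / "annotated_tree.nwk").write_text(annotated.write() + "\n")
    paths["model_selection"] = str(out / "mk_model_selection.csv")
    paths["node_posteriors"] = str(out / "node_posteriors.csv")
    paths["annotated_tree"] = str(out / "annotated_tree.nwk")
    results["selection"] = selection
    results["asr"] = states

    # (c) Brownian-motion body-mass reconstruction
    masses = dict(zip((mapping[sp] for sp in table.species),
                      table.data["body_mass_g"]))
    bm = _stage("body-mass-bm")(fit_bm)(analysis_tree, masses,
                                        transform=config.mass_transform)
    bm_frame = bm.node_estimates.copy()
    _write_csv(bm_frame, out / "bm_mass_reconstruction.csv")
    paths["bm_reconstruction"] = str(out / "bm_mass_reconstruction.csv")
    results["bm"] = bm

    # (d) phylogenetic logistic regression, mass and latitude univariate
    y, X, retained = _stage("binary-coding")(code_binary)(table)
    y.index = pd.Index([mapping[sp] for sp in y.index])
    X.index = pd.Index([mapping[sp] for sp in X.index])
    reg_tree = analysis_tree.prune_to_taxa(list(y.index))
    fits = _stage("phylogenetic-regression")(univariate_table)(reg_tree, y, X)
    reg = table_frame(fits)
    _write_csv(reg, out / "phyloglm_table.csv")
    paths["phyloglm"] = str(out / "phyloglm_table.csv")
    results["phyloglm"] = fits

    # (f) order-level regressions where both categories are big enough
    eligible = order_subsets(table, min_per_category=config.order_min_count)
    order_rows: List[pd.DataFrame] = []
    for order in eligible:
        sub = TraitTable(table.data[table.data["order"] == order],
                         source=table.source)
        yo, Xo, _ = code_binary(sub)
        yo.index = pd.Index([mapping[sp] for sp in yo.index])
        Xo.index = pd.Index([mapping[sp] for sp in Xo.index])
        sub_tree = analysis_tree.prune_to_taxa(list(yo.index))
        try:
            ofits = univariate_table(sub_tree, yo, Xo)
            oframe = table_frame(ofits)
        except SeparationError:
            oframe = pd.DataFrame([{"parameter": p, "alpha": np.nan,
                                    "estimate": np.nan, "se": np.nan,
                                    "z": np.nan, "p": np.nan, "n": len(yo)}
                                   for p in Xo.columns])
        oframe.insert(0, "order", order)
        order_rows.append(oframe)
    order_table = (pd.concat(order_rows, ignore_index=True) if order_rows
                   else pd.DataFrame(columns=["order", "parameter", "alpha",
                                              "estimate", "se", "z", "p", "n"]))
    _write_csv(order_table, out / "order_level_phyloglm.csv")
    paths["order_level"] = str(out / "order_level_phyloglm.csv")
    results["order_level"] = order_table
    results["eligible_orders"] = eligible

    # (g) manifest
    manifest = {
        "package": {"moltevo": __version__, "numpy": np.__version__,
                    "pandas": pd.__version__},
        "seed": config.seed,
        "config": config.analysis_params(),
        "config_hash": config.config_hash(),
        "n_species_input": int(n_total),
        "n_species_analyzed": int(table.n_species),
        "n_species_regression": int(len(retained)),
        "eligible_orders": eligible,
        "selected_model": selection.selected.model_class,
        "outputs": sorted(paths),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    paths["manifest"] = str(out / "manifest.json")
    results["manifest"] = manifest
    results["paths"] = paths
    return results


def run_family_analysis(species_tree: Phylogeny, table: TraitTable,
                        asr_states, alt_family_tree: Phylogeny,
                        output_dir: Optional[str] = None,
                        seed: int = 0, **pipeline_kwargs) -> Dict[str, object]:
    """Family-level dual-topology robustness report.

    Assigns family states from the species-level reconstruction, builds the
    one-tip-per-family tree from ``species_tree``, reruns the reconstruction
    on it and on ``alt_family_tree`` (an alternative higher-order topology
    with the same family tips), and pairs the results.
    """
    family_map = table.family_map()
    assignment = assign_family_states(species_tree, asr_states, family_map)
    fam_tree = build_family_tree(species_tree, family_map)
    state_idx = {s: i for i, s in enumerate(STATE_ORDER)}
    fam_states = {fam: state_idx[s] for fam, s in assignment.states().items()}
    comparison = compare_topologies(fam_tree, alt_family_tree, fam_states,
                                    seed=seed, **pipeline_kwargs)
    results: Dict[str, object] = {
        "assignment": assignment,
        "family_tree": fam_tree,
        "comparison": comparison,
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(assignment.frame, out / "family_assignments.csv")
        _write_csv(comparison.pairing, out / "family_pairing.csv")
        (out / "family_tree_a.nwk").write_text(
            annotate_tree(fam_tree, comparison.asr_a).write() + "\n")
        (out / "family_tree_b.nwk").write_text(
            annotate_tree(alt_family_tree, comparison.asr_b).write() + "\n")
        roots = pd.DataFrame({
            "state": list(STATE_ORDER),
            "root_posterior_a": comparison.root_posterior_a,
            "root_posterior_b": comparison.root_posterior_b,
        })
        _write_csv(roots, out / "family_root_posteriors.csv")
        results["paths"] = {p.name: str(p) for p in out.iterdir()}
    return results
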