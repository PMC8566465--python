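"""Generator contracts: tree shape, character laws, study-like dataset."""

import numpy as np
import pandas as pd
import pytest

from moltevo.mk import build_q, transition_probs
from moltevo.simulate import (make_study_like_dataset, perturb_topology,
                              simulate_binary_ig10, simulate_bm, simulate_mk,
                              simulate_tree)
from moltevo.treeio import parse_newick


class TestTreeSimulator:
    def test_two_tips_is_an_ultrametric_cherry(self):
        t = simulate_tree(2, birth_rate=1.0, seed=0)
        assert t.n_tips == 2
        assert t.is_ultrametric(1e-12)

    def test_same_seed_identical_newick(self):
        a = simulate_tree(50, birth_rate=0.5, seed=123)
        b = simulate_tree(50, birth_rate=0.5, seed=123)
        assert a.write() == b.write()

    def test_yule_pendant_edge_expectation(self):
        # pure birth, rate lambda: mean pendant edge ~ 1/(2 lambda)
        lam = 1.0
        lengths = []
        for seed in range(3):
            t = simulate_tree(5000, birth_rate=lam, seed=seed)
            lengths.extend(tip.length for tip in t.tips())
        assert np.mean(lengths) == pytest.approx(1.0 / (2 * lam), rel=0.10)

    def test_birth_death_prunes_extinct_lineages(self):
        t = simulate_tree(100, birth_rate=1.0, death_rate=0.5, seed=7)
        assert t.n_tips == 100
        assert t.is_ultrametric(1e-9)

    def test_nni_perturbation_keeps_tips_and_heights(self):
        t = simulate_tree(20, birth_rate=0.5, seed=9)
        p = perturb_topology(t, n_moves=3, seed=10)
        assert sorted(p.tip_labels) == sorted(t.tip_labels)
        assert p.is_ultrametric(1e-9)
        assert p.write() != t.write()


class TestMkSimulator:
    def test_zero_rate_inherits_root_state(self):
        t = simulate_tree(30, birth_rate=0.5, seed=1)
        Q = np.zeros((3, 3))
        tips, nodes = simulate_mk(t, Q, root_state=2, seed=2)
        assert set(tips.values()) == {2}
        assert set(nodes.values()) == {2}

    def test_stationary_frequencies_at_saturation(self):
        # long branches + high rate: tip states approach the uniform
        # stationary distribution of the ER chain
        star_text = "(" + ",".join(f"s{i}:40" for i in range(10000)) + ");"
        star = parse_newick(star_text)
        tips, _ = simulate_mk(star, build_q("ER", [0.2]).Q, root_state=0, seed=3)
        freqs = np.bincount(list(tips.values()), minlength=3) / 10000
        np.testing.assert_allclose(freqs, np.full(3, 1 / 3), atol=0.02)

    def test_edge_transition_frequencies_match_p_matrix(self):
        # many independent short edges: empirical transition fractions from
        # the root state match the analytic P(t) row within Monte-Carlo error
        t_len = 0.5
        Q = build_q("ARD", [0.3, 0.1, 0.2, 0.4, 0.15, 0.25])
        star = parse_newick("(" + ",".join(f"s{i}:{t_len}" for i in range(20000)) + ");")
        tips, _ = simulate_mk(star, Q.Q, root_state=1, seed=4)
        counts = np.bincount(list(tips.values()), minlength=3) / 20000
        expected = transition_probs(Q, t_len)[1]
        se = np.sqrt(expected * (1 - expected) / 20000)
        assert np.all(np.abs(counts - expected) < 5 * se + 1e-3)


class TestBMSimulator:
    def test_zero_variance_is_constant(self):
        t = simulate_tree(10, birth_rate=0.5, seed=5)
        tips = simulate_bm(t, 0.0, root_value=4.2, seed=6)
        assert set(tips.values()) == {4.2}

    def test_tip_variance_law(self):
        t = parse_newick("(A:3,B:3,C:3);")
        rng = np.random.default_rng(7)
        draws = [simulate_bm(t, 2.0, 0.0, seed=rng)["A"] for _ in range(4000)]
        assert np.var(draws) == pytest.approx(2.0 * 3.0, rel=0.10)

    def test_sister_covariance_law(self):
        t = parse_newick("((A:1,B:1):2,C:3);")
        rng = np.random.default_rng(8)
        a, b = [], []
        for _ in range(4000):
            tips = simulate_bm(t, 1.5, 0.0, seed=rng)
            a.append(tips["A"])
            b.append(tips["B"])
        shared = 2.0  # root-to-MRCA path length
        assert np.cov(a, b)[0, 1] == pytest.approx(1.5 * shared, rel=0.12)


class TestBinarySimulator:
    def test_independence_limit_matches_logistic_means(self):
        t = simulate_tree(4000, birth_rate=1.0, seed=9)
        rng = np.random.default_rng(10)
        x = pd.Series(rng.normal(0, 1, 4000), index=t.tip_labels)
        y = simulate_binary_ig10(t, x, beta=[-0.5, 1.0], alpha=50.0, seed=11)
        from scipy.special import expit
        p = expit(-0.5 + 1.0 * x)
        # aggregate in probability bins: empirical frequency tracks p_i
        bins = pd.qcut(p, 5)
        grouped = pd.DataFrame({"y": y, "p": p, "bin": bins}).groupby(
            "bin", observed=True).mean()
        np.testing.assert_allclose(grouped["y"], grouped["p"], atol=0.05)

    def test_symmetric_null_gives_half_frequency(self):
        rng = np.random.default_rng(12)
        freqs = []
        for _ in range(60):
            t = simulate_tree(200, birth_rate=0.01, seed=rng)
            x = pd.Series(rng.normal(0, 1, 200), index=t.tip_labels)
            y = simulate_binary_ig10(t, x, beta=[0.0, 0.0], alpha=0.05, seed=rng)
            freqs.append(y.mean())
        assert np.mean(freqs) == pytest.approx(0.5, abs=0.05)

    def test_sister_correlation_decreases_with_alpha(self):
        t = parse_newick("((A:5,B:5):20,(C:5,D:5):20);")
        rng = np.random.default_rng(13)
        x = pd.Series(np.zeros(4), index=t.tip_labels)
        corr = {}
        for alpha in (0.01, 0.1, 1.0):
            ys = np.array([simulate_binary_ig10(t, x, [0.0, 0.0], alpha,
                                                seed=rng).to_numpy()
                           for _ in range(4000)], dtype=float)
            corr[alpha] = np.corrcoef(ys[:, 0], ys[:, 1])[0, 1]
        assert corr[0.01] > corr[0.1] > corr[1.0]


class TestStudyLikeDataset:
    def test_study_counts_and_structure(self):
        tree, table = make_study_like_dataset(seed=2)
        assert table.n_species == 1808
        counts = table.data["molt_strategy"].value_counts().to_dict()
        assert counts == {"absent": 1059, "complete": 532, "partial": 217}
        assert table.data["order"].nunique() == 27
        assert table.data["family"].nunique() == 146
        assert int(table.data["bdpr_flag"].sum()) == 179
        assert tree.is_ultrametric(1e-9)
        assert set(table.species) == set(tree.tip_labels)

    def test_orders_and_families_are_monophyletic_and_nested(self):
        tree, table = make_study_like_dataset(seed=4, n_species=300)
        df = table.data
        # families nest inside orders
        assert (df.groupby("family")["order"].nunique() == 1).all()
        # each family is monophyletic: its MRCA contains no other species
        for fam, group in list(df.groupby("family"))[:10]:
            node = tree.mrca(group["species"])
            clade = {n.label for n in tree.preorder()
                     if n.is_leaf and _is_descendant(n, node)}
            assert clade == set(group["species"])

    def test_trait_marginals_match_reported_group_moments(self):
        _, table = make_study_like_dataset(seed=5)
        df = table.data
        comp = df[df.molt_strategy == "complete"]
        other = df[df.molt_strategy != "complete"]
        assert comp["body_mass_g"].between(2.5, 1250).all()
        assert other["body_mass_g"].between(4.5, 11000).all()
        assert comp["mid_latitude_deg"].max() <= 50.0
        # sampling error of the mean: allow ~3 standard errors
        assert comp["body_mass_g"].mean() == pytest.approx(50.0, abs=14.0)
        assert other["body_mass_g"].mean() == pytest.approx(387.5, abs=86.0)
        assert comp["mid_latitude_deg"].mean() == pytest.approx(17.4, abs=1.6)
        assert other["mid_latitude_deg"].mean() == pytest.approx(26.8, abs=1.4)

    def test_same_seed_identical_csv_bytes(self, tmp_path):
        for run in ("a", "b"):
            tree, table = make_study_like_dataset(seed=11, n_species=250)
            table.to_csv(tmp_path / f"{run}.csv")
            (tmp_path / f"{run}.nwk").write_text(tree.write())
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.nwk").read_bytes() == (tmp_path / "b.nwk").read_bytes()


def _is_descendant(node, ancestor):
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False
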