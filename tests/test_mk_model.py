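"""Mk generators, pruning likelihood, ML fitting, AICc and model choice."""

import subprocess
import textwrap

import numpy as np
import pytest

from moltevo.mk import (aicc, build_q, fit_mk, mk_loglik, rate_names,
                        select_model, transition_probs)
from moltevo.simulate import simulate_mk, simulate_tree
from moltevo.treeio import parse_newick
from oracles import enum_mk_likelihood


class TestBuildQ:
    def test_er_structure(self):
        Q = build_q("ER", [0.1]).Q
        assert np.allclose(Q[~np.eye(3, dtype=bool)], 0.1)
        assert np.allclose(np.diag(Q), -0.2)

    def test_sym_structure(self):
        Q = build_q("SYM", [0.1, 0.2, 0.3]).Q
        assert Q[0, 1] == Q[1, 0] == 0.1
        assert Q[0, 2] == Q[2, 0] == 0.2
        assert Q[1, 2] == Q[2, 1] == 0.3
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_ard_structure_and_parameter_order(self):
        params = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        Q = build_q("ARD", params).Q
        assert [Q[0, 1], Q[0, 2], Q[1, 0], Q[1, 2], Q[2, 0], Q[2, 1]] == params
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert rate_names("ARD") == ["q01", "q02", "q10", "q12", "q20", "q21"]

    @pytest.mark.parametrize("model,params", [
        ("ER", [0.1, 0.2]), ("SYM", [0.1]), ("ARD", [0.1] * 5),
        ("ER", [-0.1]), ("SYM", [0.1, 0.0, 0.2]),
    ])
    def test_bad_params_rejected(self, model, params):
        with pytest.raises(ValueError):
            build_q(model, params)


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        Q = build_q("ARD", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        np.testing.assert_allclose(transition_probs(Q, 0.0), np.eye(3), atol=1e-14)

    def test_er_stationary_limit(self):
        Q = build_q("ER", [0.5])
        np.testing.assert_allclose(transition_probs(Q, 1e4),
                                   np.full((3, 3), 1 / 3), atol=1e-10)

    def test_eigendecomposition_matches_series_expm(self):
        from scipy.linalg import expm
        Q = build_q("ER", [0.1])
        np.testing.assert_allclose(transition_probs(Q, 1.0), expm(Q.Q * 1.0),
                                   atol=1e-10)
        Qa = build_q("ARD", [0.11, 0.25, 0.3, 0.07, 0.51, 0.62])
        np.testing.assert_allclose(transition_probs(Qa, 2.5), expm(Qa.Q * 2.5),
                                   atol=1e-10)

    def test_rows_are_distributions(self):
        Q = build_q("ARD", [1.1, 0.2, 3.0, 0.4, 0.05, 0.6])
        for t in (0.0, 0.1, 1.0, 50.0):
            P = transition_probs(Q, t)
            assert np.all(P >= 0) and np.all(P <= 1)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestLoglik:
    def test_zero_rate_limit_two_tips(self):
        t = parse_newick("(A:1,B:1);")
        Q = build_q("ER", [1e-12])
        ll = mk_loglik(t, {"A": 0, "B": 0}, Q, np.full(3, 1 / 3))
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_all_missing_gives_zero_loglik(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        Q = build_q("ER", [0.3])
        assert mk_loglik(t, {"A": None, "B": None, "C": None}, Q) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_with_polytomy_and_missing(self):
        t = parse_newick("((A:1,B:0.5,C:0.8):0.7,(D:2,E:1.2):0.3);")
        Q = build_q("ARD", [0.1, 0.2, 0.3, 0.05, 0.15, 0.25])
        states = {"A": 0, "B": 2, "C": 1, "D": None, "E": 0}
        prior = np.array([0.5, 0.25, 0.25])
        expected = np.log(enum_mk_likelihood(t, states, Q.Q, prior))
        assert mk_loglik(t, states, Q, prior) == pytest.approx(expected, abs=1e-9)

    def test_missing_tip_entry_raises(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            mk_loglik(t, {"A": 0}, build_q("ER", [0.1]))
        with pytest.raises(ValueError):
            mk_loglik(t, {"A": 0, "B": 7}, build_q("ER", [0.1]))


class TestFit:
    def test_relabeling_symmetry_of_ard(self):
        tree = simulate_tree(60, birth_rate=0.5, seed=4)
        states, _ = simulate_mk(tree, build_q("ARD", [0.3, 0.1, 0.2, 0.4, 0.15, 0.25]).Q,
                                root_state=0, seed=5)
        fit = fit_mk(tree, states, "ARD", n_restarts=3, seed=0)
        # swap states 0 <-> 2 in the data; the optimum logL must be unchanged
        perm = {0: 2, 1: 1, 2: 0}
        swapped = {k: perm[v] for k, v in states.items()}
        fit2 = fit_mk(tree, swapped, "ARD", n_restarts=3, seed=0)
        assert fit2.logL == pytest.approx(fit.logL, abs=1e-4)

    def test_monomorphic_data_flagged_non_identifiable(self):
        tree = simulate_tree(10, birth_rate=0.5, seed=1)
        states = {lbl: 1 for lbl in tree.tip_labels}
        with pytest.warns(RuntimeWarning, match="identifiable"):
            fit = fit_mk(tree, states, "ER", seed=0)
        assert fit.non_identifiable

    def test_deterministic_given_seed(self):
        tree = simulate_tree(40, birth_rate=0.5, seed=8)
        states, _ = simulate_mk(tree, build_q("ER", [0.2]).Q, root_state=1, seed=9)
        f1 = fit_mk(tree, states, "SYM", n_restarts=3, seed=7)
        f2 = fit_mk(tree, states, "SYM", n_restarts=3, seed=7)
        np.testing.assert_array_equal(f1.params, f2.params)
        assert f1.logL == f2.logL


class TestAicc:
    def test_direct_evaluations(self):
        assert aicc(-100.0, 6, 1808) == pytest.approx(212 + 84 / 1801, abs=1e-9)
        assert aicc(-100.0, 1, 4) == pytest.approx(204.0, abs=1e-12)
        assert aicc(-57.25, 0, 10) == pytest.approx(114.5, abs=1e-12)

    def test_undefined_below_minimum_sample(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestSelectModel:
    def _fit(self, model, logL, n=100):
        from moltevo.mk import MkFit, n_free_params, rate_names
        kf = n_free_params(model)
        return MkFit(model, np.full(kf, 0.1), rate_names(model), logL, kf, n,
                     aicc(logL, kf, n), "flat", np.full(3, 1 / 3), 1, -logL, True)

    def test_decisive_selection(self):
        # AICc approx {ER: 300, SYM: 250, ARD: 206}
        fits = [self._fit("ER", -148.98), self._fit("SYM", -121.94),
                self._fit("ARD", -96.77)]
        sel = select_model(fits)
        assert sel.selected.model_class == "ARD"
        assert sel.decisive
        assert sel.table.loc[sel.table.model == "ER", "delta_aicc"].iloc[0] > 40

    def test_indecisive_falls_back_to_simplest(self):
        fits = [self._fit("ER", -102.23), self._fit("SYM", -99.94),
                self._fit("ARD", -96.05)]
        aiccs = {f.model_class: f.aicc for f in fits}
        assert max(aiccs.values()) - min(aiccs.values()) < 2.0
        sel = select_model(fits)
        assert sel.selected.model_class == "ER"
        assert not sel.decisive

    def test_boundary_delta_exactly_two_not_decisive(self):
        f1 = self._fit("ER", -100.0)
        # choose SYM logL so aicc difference is exactly 2.0
        target = f1.aicc + 2.0
        logL_sym = -(target - 2 * 3 - 2 * 3 * 4 / (100 - 3 - 1)) / 2
        f2 = self._fit("SYM", logL_sym)
        assert f2.aicc - f1.aicc == pytest.approx(2.0, abs=1e-12)
        sel = select_model([f1, f2])
        assert not sel.decisive

    def test_different_data_sizes_rejected(self):
        with pytest.raises(ValueError, match="identical data"):
            select_model([self._fit("ER", -10, n=50), self._fit("SYM", -9, n=60)])


class TestAgainstPhytools:
    """Independent cross-check against the reference R implementation."""

    def test_likelihood_and_optimum_match_fitMk(self, tmp_path):
        tree = simulate_tree(12, birth_rate=1.0, seed=11)
        states, _ = simulate_mk(tree, build_q("ER", [0.3]).Q, root_state=0, seed=2)
        (tmp_path / "tree.nwk").write_text(tree.write() + "\n")
        lines = ["species,state"] + [f"{k},{v}" for k, v in states.items()]
        (tmp_path / "states.csv").write_text("\n".join(lines) + "\n")
        rscript = textwrap.dedent("""
            suppressMessages(library(phytools))
            tree <- read.tree('tree.nwk')
            d <- read.csv('states.csv')
            x <- setNames(as.character(d$state), d$species)
            fit <- fitMk(tree, x, model='ER', pi='equal')
            cat(fit$rates, logLik(fit), sep='\\n')
        """)
        out = subprocess.run(["Rscript", "-e", rscript], cwd=tmp_path,
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_rate, r_loglik = map(float, out.stdout.strip().split("\n")[-2:])
        # our likelihood evaluated at R's optimum equals R's likelihood
        ll_at_r = mk_loglik(tree, states, build_q("ER", [r_rate]), "flat")
        assert ll_at_r == pytest.approx(r_loglik, abs=1e-4)
        # and our optimizer does at least as well
        fit = fit_mk(tree, states, "ER", seed=0)
        assert fit.logL >= r_loglik - 1e-4
        assert fit.params[0] == pytest.approx(r_rate, rel=1e-3)
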