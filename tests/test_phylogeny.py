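"""GTR+F+I+G4 likelihood against enumeration/closed-form oracles, NJ/NNI
search behavior, bootstrap and monophyly classification."""

import itertools
import warnings

import dendropy
import numpy as np
import pytest

import mitochar as mc
from mitochar.phylogeny import (PhyloModel, PhyloTree, _TransitionCache,
                                jc_distance_matrix, log_likelihood,
                                neighbor_joining, robinson_foulds)


def enumeration_log_likelihood(tree, aln, model, root):
    """Sum over all internal-node state assignments — an exact oracle for
    the pruning recursion (exponential in internal nodes)."""
    cache = _TransitionCache(model)
    pi = cache.pi
    nodes = sorted(tree.adj)
    internal = [n for n in nodes if len(tree.adj[n]) > 1]
    idx = {b: i for i, b in enumerate("ACGT")}
    order = tree.postorder(root)
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for w, r in model.mixture():
            P = {}
            for u, v, l in tree.edges():
                # one matrix per edge: exp(Q l r) indexed [parent, child],
                # whichever endpoint is the parent in the traversal
                M = cache.P(l * r) if r > 0 else np.eye(4)
                P[(u, v)] = M
                P[(v, u)] = M
            cat_lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                for n in nodes:
                    if len(tree.adj[n]) == 1:
                        ch = aln.row(tree.labels[n])[site]
                        st[n] = idx.get(ch)  # None for gap/N
                lik = pi[st[root]]
                for node, parent in order:
                    if parent is None:
                        continue
                    b = st[node]
                    if b is None:
                        continue  # missing data marginalizes to 1
                    lik *= P[(parent, node)][st[parent], b]
                cat_lik += lik
            site_lik += w * cat_lik
        total += np.log(site_lik)
    return total


def _dendropy_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestModel:
    def test_rate_matrix_scaled_to_unit_mean_rate(self):
        m = PhyloModel(rates=(1.3, 4.0, 0.7, 1.1, 3.9, 1.0),
                       freqs=(0.34, 0.27, 0.13, 0.26))
        Q = m.rate_matrix()
        pi = np.array(m.freqs)
        assert -(pi @ np.diag(Q)) == pytest.approx(1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance (reversibility)
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 5.0])
    def test_gamma_category_rates_average_one(self, alpha):
        m = PhyloModel(alpha=alpha)
        rates = m.gamma_category_rates()
        assert len(rates) == 4
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(rates) > 0).all()

    def test_mixture_mean_rate_is_one_with_invariant_sites(self):
        m = PhyloModel(alpha=0.5, p_inv=0.3)
        mix = m.mixture()
        weights = np.array([w for w, _ in mix])
        rates = np.array([r for _, r in mix])
        assert weights.sum() == pytest.approx(1.0)
        assert weights @ rates == pytest.approx(1.0)
        assert rates[0] == 0.0

    def test_transition_matrix_rows_are_distributions(self):
        m = PhyloModel(rates=(2, 3, 0.5, 1.5, 4, 1), freqs=(0.4, 0.3, 0.2, 0.1))
        cache = _TransitionCache(m)
        for t in (0.0, 0.01, 0.5, 10.0):
            P = cache.P(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= 0).all()


class TestLogLikelihood:
    def test_zero_branch_single_site_gives_log_frequency(self):
        t = PhyloTree.from_newick("(A:0,B:0,C:0);")
        aln = mc.Alignment(names=["A", "B", "C"], rows=["G", "G", "G"])
        m = PhyloModel(freqs=(0.34, 0.27, 0.13, 0.26))
        assert log_likelihood(t, aln, m) == pytest.approx(np.log(0.13))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = PhyloTree.from_newick(
            "((A:0.2,B:0.31):0.12,C:0.09,(D:0.27,E:0.05):0.33);")
        nsites = int(rng.integers(2, 6))
        rows = ["".join(rng.choice(list("ACGTN-"), size=nsites,
                                   p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04]))
                for _ in range(5)]
        aln = mc.Alignment(names=list("ABCDE"), rows=rows)
        m = PhyloModel(rates=tuple(rng.uniform(0.5, 3, 6)),
                       freqs=(0.3, 0.3, 0.2, 0.2),
                       alpha=float(rng.uniform(0.3, 2)), p_inv=0.15)
        root = next(n for n in sorted(t.adj) if len(t.adj[n]) > 1)
        assert log_likelihood(t, aln, m, root=root) == pytest.approx(
            enumeration_log_likelihood(t, aln, m, root), abs=1e-9)

    @pytest.mark.parametrize("t_dist", [0.05, 0.1, 0.5])
    def test_jukes_cantor_closed_form_two_taxa(self, t_dist):
        tree = PhyloTree.from_newick(f"(A:{t_dist},B:0);")
        m = PhyloModel()  # equal rates, equal frequencies = JC
        same = mc.Alignment(names=["A", "B"], rows=["A", "A"])
        diff = mc.Alignment(names=["A", "B"], rows=["A", "C"])
        p_same = 0.25 + 0.75 * np.exp(-4 * t_dist / 3)
        assert log_likelihood(tree, same, m) == pytest.approx(
            np.log(0.25 * p_same))
        assert log_likelihood(tree, diff, m) == pytest.approx(
            np.log(0.25 * (1 - p_same) / 3))

    def test_invariance_to_rerooting_and_taxon_order(self):
        rng = np.random.default_rng(12)
        t = PhyloTree.from_newick(
            "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,E:0.3);")
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        aln = mc.Alignment(names=list("ABCDE"), rows=rows)
        m = PhyloModel(rates=(1.5, 3, 1, 0.8, 2.5, 1),
                       freqs=(0.3, 0.25, 0.2, 0.25), alpha=0.8, p_inv=0.1)
        internals = [n for n in sorted(t.adj) if len(t.adj[n]) > 1]
        vals = [log_likelihood(t, aln, m, root=r) for r in internals]
        assert max(vals) - min(vals) < 1e-8
        perm = [3, 1, 4, 0, 2]
        aln2 = mc.Alignment(names=[aln.names[i] for i in perm],
                            rows=[aln.rows[i] for i in perm])
        assert log_likelihood(t, aln2, m) == pytest.approx(vals[0], abs=1e-8)


class TestNeighborJoining:
    def test_recovers_topology_from_additive_distances(self):
        # distances generated on a known 5-taxon tree are exactly additive
        truth = PhyloTree.from_newick(
            "((A:0.1,B:0.2):0.05,(C:0.12,D:0.08):0.1,E:0.3);")
        names = truth.tip_names
        # path distances
        def dist(t, a, b):
            ida, idb = t.node_by_name(a), t.node_by_name(b)
            # BFS
            import collections
            prev = {ida: None}
            q = collections.deque([ida])
            while q:
                u = q.popleft()
                for v in t.adj[u]:
                    if v not in prev:
                        prev[v] = u
                        q.append(v)
            d, node = 0.0, idb
            while prev[node] is not None:
                d += t.adj[node][prev[node]]
                node = prev[node]
            return d
        D = np.array([[dist(truth, a, b) for b in names] for a in names])
        nj = neighbor_joining(D, names)
        assert robinson_foulds(nj, truth) == 0
        # branch lengths are also recovered on an additive matrix
        for u, v, l in nj.edges():
            assert l >= 0

    def test_jc_distance_matrix_matches_hand_formula(self):
        aln = mc.Alignment(names=["a", "b"], rows=["AAAA" * 5, "AAAC" * 5])
        p = 0.25
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert jc_distance_matrix(aln)[0, 1] == pytest.approx(expected)


class TestFitAndSearch:
    def test_recovers_simulated_topology(self):
        truth = PhyloTree.from_newick(
            "((A:0.1,B:0.12):0.08,(C:0.09,D:0.11):0.07,(E:0.1,F:0.13):0.06);")
        model = PhyloModel(rates=(1.2, 3.0, 0.8, 1.1, 3.5, 1.0),
                           freqs=(0.34, 0.27, 0.13, 0.26), alpha=0.7)
        rng = np.random.default_rng(0)
        root = "".join(rng.choice(list("ACGT"), size=800,
                                  p=[0.34, 0.27, 0.13, 0.26]))
        tips = mc.evolve_sequences(root, truth, model, seed=3)
        aln = mc.Alignment(names=sorted(tips), rows=[tips[k] for k in sorted(tips)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mc.fit_and_search(aln, mc.SearchSettings(
                optimize_pinv=False, max_rounds=6))
        assert robinson_foulds(fit.tree, truth) == 0
        # cross-check RF with dendropy on shared taxon namespace
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=fit.tree.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(
            data=truth.to_newick(), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_identical_sequences_collapse_to_star(self):
        aln = mc.Alignment(names=list("ABCD"), rows=["ACGTACGT"] * 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mc.fit_and_search(aln, mc.SearchSettings(
                optimize_rates=False, optimize_alpha=False,
                optimize_pinv=False, nni=False, max_rounds=2))
        assert all(l < 1e-5 for _u, _v, l in fit.tree.edges())

    def test_too_few_taxa(self):
        aln = mc.Alignment(names=["a", "b", "c"], rows=["A", "A", "A"])
        with pytest.raises(ValueError, match="4 taxa"):
            mc.fit_and_search(aln)


class TestBootstrap:
    def test_strong_signal_high_support(self):
        truth = PhyloTree.from_newick(
            "((A:0.08,B:0.1):0.09,(C:0.09,D:0.08):0.08,(E:0.1,F:0.09):0.07);")
        model = PhyloModel(freqs=(0.3, 0.25, 0.2, 0.25), alpha=1.0)
        rng = np.random.default_rng(5)
        root = "".join(rng.choice(list("ACGT"), size=1500,
                                  p=[0.3, 0.25, 0.2, 0.25]))
        tips = mc.evolve_sequences(root, truth, model, seed=8)
        aln = mc.Alignment(names=sorted(tips), rows=[tips[k] for k in sorted(tips)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mc.fit_and_search(aln, mc.SearchSettings(
                optimize_pinv=False, max_rounds=4))
            boot = mc.bootstrap_support(aln, mc.SearchSettings(
                optimize_pinv=False), replicates=25, seed=11, fit=fit)
        assert robinson_foulds(boot.tree, truth) == 0
        assert boot.tree.supports
        for split, support in boot.tree.supports.items():
            assert 0.0 <= support <= 100.0
            assert support >= 95.0

    def test_no_variable_sites_warns(self):
        aln = mc.Alignment(names=list("ABCD"), rows=["AAAA"] * 4)
        settings = mc.SearchSettings(optimize_rates=False,
                                     optimize_alpha=False,
                                     optimize_pinv=False, nni=False,
                                     max_rounds=1)
        with pytest.warns(UserWarning, match="variable"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                mc.bootstrap_support(aln, settings, replicates=2, seed=1)

    def test_replicates_validated(self):
        aln = mc.Alignment(names=list("ABCD"), rows=["ACGT"] * 4)
        with pytest.raises(ValueError):
            mc.bootstrap_support(aln, None, replicates=0, seed=1)


class TestClassifyGroup:
    def test_monophyletic(self):
        t = PhyloTree.from_newick("((A1:1,A2:1):1,(B:1,C:1):1);")
        assert mc.classify_group(t, {"A1", "A2"}, "C") == "monophyletic"

    def test_paraphyletic(self):
        t = PhyloTree.from_newick("((A1:1,(A2:1,B:1):1):1,C:1);")
        assert mc.classify_group(t, {"A1", "A2"}, "C") == "paraphyletic"

    def test_polyphyletic(self):
        t = PhyloTree.from_newick("(((A1:1,B1:1):1,(A2:1,B2:1):1):1,O:1);")
        assert mc.classify_group(t, {"A1", "A2"}, "O") == "polyphyletic"

    def test_matches_dendropy_mrca_definition_on_random_trees(self):
        # independent route: dendropy MRCA-based reimplementation
        rng = np.random.default_rng(17)
        taxa = [f"t{i}" for i in range(7)]
        for trial in range(20):
            import random
            sim = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0,
                taxon_namespace=dendropy.TaxonNamespace(taxa),
                num_extant_tips=len(taxa),
                rng=random.Random(trial))
            newick = sim.as_string(schema="newick").strip()
            tree = PhyloTree.from_newick(
                newick.split("]")[-1] if "]" in newick else newick)
            group = set(rng.choice([t for t in taxa if t != "t0"],
                                   size=rng.integers(1, 5), replace=False))
            ours = mc.classify_group(tree, group, "t0")

            d = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
            d.reroot_at_edge(
                d.find_node_with_taxon_label("t0").edge,
                update_bipartitions=False)
            clades = []
            for node in d.preorder_node_iter():
                tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
                if "t0" not in tips:
                    clades.append(tips)
            g = frozenset(group)
            if g in clades or g == frozenset(taxa) - {"t0"}:
                expected = "monophyletic"
            else:
                spanning = min((c for c in clades if g <= c),
                               key=len, default=frozenset(taxa) - {"t0"})
                intruders = spanning - g
                expected = ("paraphyletic" if intruders in clades
                            else "polyphyletic")
            assert ours == expected, (trial, sorted(group), newick)

    def test_full_ingroup_and_singletons_are_monophyletic(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,O:1);")
        assert mc.classify_group(t, {"A", "B", "C", "D"}, "O") == "monophyletic"
        for tip in "ABCD":
            assert mc.classify_group(t, {tip}, "O") == "monophyletic"

    def test_outgroup_inside_group_rejected(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="outgroup"):
            mc.classify_group(t, {"A", "B"}, "A")


class TestNewick:
    def test_round_trip_preserves_splits_and_lengths(self):
        t = PhyloTree.from_newick(
            "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,E:0.3);")
        t2 = PhyloTree.from_newick(t.to_newick())
        assert t.splits() == t2.splits()
        assert sorted(l for _u, _v, l in t.edges()) == pytest.approx(
            sorted(l for _u, _v, l in t2.edges()))

    def test_supports_written_as_internal_labels(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        split = frozenset({"C", "D"})
        t.supports = {split: 97.0}
        assert ")97" in t.to_newick()
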