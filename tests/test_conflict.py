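"""Quartet support, greedy consensus, window profiles."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import stats

from phyloconflict import conflict, datasets, simdata
from phyloconflict._util import InputError
from phyloconflict.genetrees import GeneTreeSet


def _trees_from_newicks(newicks):
    tn = dendropy.TaxonNamespace()
    trees = [
        dendropy.Tree.get(data=nw, schema="newick", taxon_namespace=tn,
                          preserve_underscores=True)
        for nw in newicks
    ]
    return GeneTreeSet(trees, tn)


def brute_force_quartet(tree: dendropy.Tree, quartet) -> int:
    """Independent quartet read-off: restrict the tree, inspect clades."""
    sub = tree.extract_tree_with_taxa_labels(quartet)
    a, b, c, d = quartet
    for node in sub.preorder_node_iter():
        labels = {lf.taxon.label for lf in node.leaf_iter()}
        pair = labels & set(quartet)
        if len(pair) == 2:
            if pair in ({a, b}, {c, d}):
                return 0
            if pair in ({a, c}, {b, d}):
                return 1
            if pair in ({a, d}, {b, c}):
                return 2
    return -1


def brute_force_support(species_tree, trees):
    out = {}
    for bid, groups in conflict.branch_groups(species_tree):
        counts = [0, 0, 0]
        for a, b, c, d in itertools.product(*groups):
            for tree in trees:
                topo = brute_force_quartet(tree, (a, b, c, d))
                if topo >= 0:
                    counts[topo] += 1
        out[bid] = counts
    return out


class TestQuartetSupport:
    def test_identical_trees_full_support(self):
        nw = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
        trees = _trees_from_newicks([nw] * 20)
        sp = dendropy.Tree.get(data=nw, schema="newick")
        for sup in conflict.quartet_support(sp, trees):
            assert sup.q1 == pytest.approx(1.0)
            assert sup.q2 == sup.q3 == 0.0

    def test_polytomy_branch_near_equal_support(self):
        # T = 0 contested branch: the three resolutions are equally
        # supported ("nearly identical support for all three topologies")
        model = datasets.rorqual_like_model(contested_branch=0.0, gamma=0.0, seed=31)
        trees = simdata.simulate_gene_trees(model, 4000)
        sup = conflict.quartet_support(model.tree, trees, seed=31)
        contested = min(sup, key=lambda s: max(abs(q - 1 / 3) for q in s.q))
        assert {"gray"} in [set(g) for g in contested.groups]
        for q in contested.q:
            assert abs(q - 1 / 3) < 0.05

    def test_matches_brute_force_exactly(self, rng):
        # random 6-taxon species trees scored against simulated tree sets
        for rep in range(3):
            model = simdata.SpeciesTreeModel(
                "(((A:0.3,B:0.3):0.2,(C:0.2,D:0.2):0.3):0.5,(E:0.4,F:0.4):0.6);",
                seed=100 + rep,
            )
            trees = simdata.simulate_gene_trees(model, 50)
            sup = conflict.quartet_support(model.tree, trees, seed=rep)
            expected = brute_force_support(model.tree, trees)
            for s in sup:
                counts = expected[s.branch_id]
                n = sum(counts)
                assert s.n_quartets_evaluated == n
                assert (s.q1, s.q2, s.q3) == pytest.approx(
                    tuple(c / n for c in counts)
                )

    def test_normalization(self, three_taxon_trees):
        model = datasets.rorqual_like_model(seed=3)
        trees = simdata.simulate_gene_trees(model, 200)
        for s in conflict.quartet_support(model.tree, trees, seed=1):
            if s.n_quartets_evaluated:
                assert s.q1 + s.q2 + s.q3 == pytest.approx(1.0)

    def test_label_permutation_equivariance(self):
        nw_sp = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
        gene = ["((A:1,C:1):1,((B:1,D:1):1,(E:1,F:1):1):1);"] * 10
        sp = dendropy.Tree.get(data=nw_sp, schema="newick")
        sup = conflict.quartet_support(sp, _trees_from_newicks(gene))
        # swap B and C everywhere: q2 (AC|BD-type) and q1 exchange roles
        swap = str.maketrans({"B": "C", "C": "B"})
        sp2 = dendropy.Tree.get(data=nw_sp.translate(swap), schema="newick")
        sup2 = conflict.quartet_support(
            sp2, _trees_from_newicks([g.translate(swap) for g in gene])
        )
        qs1 = sorted(tuple(sorted(s.q)) for s in sup)
        qs2 = sorted(tuple(sorted(s.q)) for s in sup2)
        assert qs1 == pytest.approx(qs2)

    def test_sampled_agrees_with_exhaustive(self):
        model = datasets.rorqual_like_model(seed=17)
        trees = simdata.simulate_gene_trees(model, 400)
        exact = conflict.quartet_support(model.tree, trees, sampling_limit=10_000)
        sampled = conflict.quartet_support(model.tree, trees, sampling_limit=4, seed=9)
        for e, s in zip(exact, sampled):
            n = s.n_quartets_evaluated
            for qe, qs in zip(e.q, s.q):
                se = np.sqrt(max(qe * (1 - qe), 0.05) / max(n, 1))
                assert abs(qe - qs) < 4 * se

    def test_small_species_tree_rejected(self):
        sp = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        trees = _trees_from_newicks(["((A:1,B:1):1,C:1);"])
        with pytest.raises(InputError):
            conflict.quartet_support(sp, trees)


class TestExpectedDiscordance:
    @pytest.mark.parametrize(
        "T, expected",
        [(0.0, 2 / 3), (np.log(2.0), 1 / 3), (50.0, 0.0)],
    )
    def test_closed_form(self, T, expected):
        assert conflict.expected_discordance(T) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            conflict.expected_discordance(-0.1)


def independent_greedy_splits(trees):
    """Oracle: greedy split selection via dendropy bipartitions."""
    labels = sorted({lf.taxon.label for lf in trees[0].leaf_node_iter()})
    counts = {}
    for t in trees:
        t2 = t.clone(depth=1)
        t2.is_rooted = False
        t2.update_bipartitions()
        seen = set()
        for bp in t2.bipartition_encoding:
            side = frozenset(
                x.label for x in t2.taxon_namespace.bitmask_taxa_list(bp.leafset_bitmask)
            )
            if labels[0] in side:
                side = frozenset(labels) - side
            if len(side) < 2 or len(labels) - len(side) < 2:
                continue
            seen.add(side)
        for s in seen:
            counts[s] = counts.get(s, 0) + 1
    ranked = sorted(counts, key=lambda s: (-counts[s], tuple(sorted(s))))
    accepted = []
    full = set(labels)
    for s in ranked:
        ok = True
        for o in accepted:
            inter = [s & o, s - o, o - s, full - (s | o)]
            if all(inter):
                ok = False
                break
        if ok:
            accepted.append(s)
    return set(accepted)


class TestGreedyConsensus:
    def test_identical_trees(self):
        nw = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"
        trees = _trees_from_newicks([nw] * 7)
        cons = conflict.greedy_consensus(trees)
        from phyloconflict import splits as sp

        assert sp.tree_splits(cons) == sp.tree_splits(trees[0])

    def test_majority_wins_60_40(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1);"
        trees = _trees_from_newicks([t1] * 6 + [t2] * 4)
        cons = conflict.greedy_consensus(trees)
        from phyloconflict import splits as sp

        assert sp.tree_splits(cons) == sp.tree_splits(trees[0])

    def test_matches_independent_oracle(self):
        from phyloconflict import splits as sp

        for rep in range(5):
            model = simdata.SpeciesTreeModel(
                "((((A:0.2,B:0.2):0.3,(C:0.3,D:0.3):0.2):0.3,"
                "(E:0.4,F:0.4):0.4):0.4,(G:0.6,H:0.6):0.6);",
                seed=rep,
            )
            trees = simdata.simulate_gene_trees(model, 60)
            cons = conflict.greedy_consensus(trees)
            ours = {s.side for s in sp.tree_splits(cons)}
            assert ours == independent_greedy_splits(list(trees))

    def test_inconsistent_leaf_sets_rejected(self):
        trees = _trees_from_newicks(
            ["((A:1,B:1):1,(C:1,D:1):1);", "((A:1,B:1):1,(C:1,E:1):1);"]
        )
        with pytest.raises(InputError):
            conflict.greedy_consensus(trees)


class TestWindowProfile:
    def _species(self):
        return dendropy.Tree.get(
            data="((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);", schema="newick"
        )

    def test_concordant_windows_flat_profile(self):
        nw = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
        sp = self._species()
        branch = conflict.branch_groups(sp)[0][0]
        windows = {i: _trees_from_newicks([nw] * 3) for i in range(4)}
        prof = conflict.window_profile(sp, branch, windows)
        assert all(not e.missing and e.q1 == pytest.approx(1.0) for e in prof.entries)

    def test_empty_fragment_flagged_missing(self):
        sp = self._species()
        branch = conflict.branch_groups(sp)[0][0]
        nw = "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);"
        windows = {0: _trees_from_newicks([nw]), 1: None}
        prof = conflict.window_profile(sp, branch, windows)
        assert [e.missing for e in prof.entries] == [False, True]

    def test_no_runs_under_polytomy(self):
        # windows simulated independently on a T~0 branch: the sequence of
        # per-window majority topologies shows no long runs (independence)
        model = datasets.rorqual_like_model(contested_branch=0.0, gamma=0.0, seed=41)
        sp = model.tree
        branches = conflict.branch_groups(sp)
        focal = next(
            bid for bid, groups in branches if ("gray",) in groups
        )
        n_windows = 120
        labels = []
        for w in range(n_windows):
            wtrees = simdata.simulate_gene_trees(model, 10, seed=1000 + w)
            s = conflict.quartet_support(sp, wtrees, branches=[focal])[0]
            labels.append(int(np.argmax(s.q)))
        # chi-square on first-order transitions vs independence
        k = 3
        trans = np.zeros((k, k))
        for a, b in zip(labels, labels[1:]):
            trans[a, b] += 1
        row = trans.sum(axis=1, keepdims=True)
        col = trans.sum(axis=0, keepdims=True)
        expected = row * col / trans.sum()
        mask = expected > 0
        chi2 = ((trans - expected) ** 2 / np.where(mask, expected, 1))[mask].sum()
        p = stats.chi2.sf(chi2, df=(k - 1) ** 2)
        assert p > 0.01

    def test_unknown_branch_rejected(self):
        sp = self._species()
        with pytest.raises(InputError):
            conflict.window_profile(sp, "B99", {0: None})
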