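"""NG86 Ka/Ks, alignment filters, targeting, screen, enrichment."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phyloconflict import datasets, kaks, simdata
from phyloconflict._util import InputError
from phyloconflict.kaks import CodonAlignment, KaKsEstimate

# --------------------------------------------------------------------------
# independent NG86 oracle (test-side implementation)

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}
_CODE = None


def _aa(codon):
    global _CODE
    if _CODE is None:
        from Bio.Seq import Seq

        _CODE = {}
        for c in ("".join(x) for x in itertools.product("TCAG", repeat=3)):
            aa = str(Seq(c).translate())
            _CODE[c] = None if aa == "*" else aa
    return _CODE[codon]


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1:]
            if _aa(new) is not None and _aa(new) == _aa(codon):
                syn += 1 / 3
    return syn, 3 - syn


def oracle_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    blocked_paths = []
    for order in itertools.permutations(diff):
        cur, steps, ok = c1, [], True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(
            1.0 for a, b in steps
            if _aa(a) is not None and _aa(b) is not None and _aa(a) == _aa(b)
        )
        nsyn = len(steps) - syn
        (paths if ok else blocked_paths).append((syn, nsyn))
    use = paths or blocked_paths
    return (
        float(np.mean([p[0] for p in use])),
        float(np.mean([p[1] for p in use])),
    )


SENSE = [c for c in ("".join(x) for x in itertools.product("TCAG", repeat=3))
         if c not in _STOPS]


class TestNG86:
    def test_identical_sequences(self):
        est = kaks.ng86(CodonAlignment("g", ("ATGAAA", "ATGAAA")))
        assert est.ka == est.ks == 0.0
        assert est.ratio is None

    def test_single_synonymous_difference(self):
        # AAA <-> AAG, Lys <-> Lys: purely synonymous
        est = kaks.ng86(CodonAlignment("g", ("ATGAAA", "ATGAAG")))
        assert est.ka == 0.0
        assert est.ks > 0.0
        sd, nd = oracle_differences("AAA", "AAG")
        assert (sd, nd) == (1.0, 0.0)

    def test_site_counts_match_oracle_exhaustively(self):
        from phyloconflict.kaks import _codon_sites

        for codon in SENSE:
            assert _codon_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_difference_counts_match_oracle_exhaustively(self):
        from phyloconflict.kaks import _codon_differences

        for c1, c2 in itertools.product(SENSE, SENSE):
            assert _codon_differences(c1, c2) == pytest.approx(
                oracle_differences(c1, c2)
            ), (c1, c2)

    def test_symmetry(self, rng):
        for _ in range(10):
            cods_a = [SENSE[int(i)] for i in rng.integers(0, 61, 30)]
            cods_b = [SENSE[int(i)] for i in rng.integers(0, 61, 30)]
            a = "".join(cods_a)
            b = "".join(cods_b)
            e1 = kaks.ng86(CodonAlignment("g", (a, b)))
            e2 = kaks.ng86(CodonAlignment("g", (b, a)))
            assert e1.ka == pytest.approx(e2.ka)
            assert e1.ks == pytest.approx(e2.ks)
            assert e1.p_value == pytest.approx(e2.p_value)

    def test_saturation_flagged(self):
        # divergence so extreme the synonymous proportion saturates
        aln = simdata.simulate_codon_pair(
            simdata.SimCodonParams(300, 30.0, 1.0, seed=2)
        )
        est = kaks.ng86(aln)
        assert est.saturated

    def test_zero_codons_rejected(self):
        with pytest.raises(InputError):
            kaks.ng86(CodonAlignment("g", ("", "")))

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError, match="stop"):
            CodonAlignment("g", ("ATGTAAAAA", "ATGAAAAAA"))


class TestAlignmentFilters:
    def _aln(self, n_var, n_codons=100, ortholog="g"):
        # ATG repeats; vary third positions first (ATG->ATA, Ile), then
        # first positions (ATG->CTG, Leu): up to 2 variable sites/codon,
        # never a stop codon.  n_var = number of variable columns.
        assert n_var <= 2 * n_codons
        base = "ATG" * n_codons
        s2 = list(base)
        for k in range(n_var):
            codon, pos = k % n_codons, (2 if k < n_codons else 0)
            s2[3 * codon + pos] = {2: "A", 0: "C"}[pos]
        return CodonAlignment(ortholog, (base, "".join(s2)))

    def test_low_variability_dropped(self):
        # 4% variable sites: below the "more than 5%" requirement
        res = kaks.filter_alignments([self._aln(12), self._aln(30)])
        assert res.n_dropped_low_variability == 1
        assert len(res.kept) == 1

    def test_boundary_is_strict(self):
        # exactly 5% variable -> dropped; just above -> kept
        at = self._aln(15)   # 15/300 = 5%
        above = self._aln(16)
        res = kaks.filter_alignments([at, above])
        assert res.n_dropped_low_variability == 1
        assert res.kept == [above]

    def test_high_variability_dropped(self):
        res = kaks.filter_alignments([self._aln(130), self._aln(30)])
        assert res.n_dropped_high_variability == 1

    def test_distance_trim_arithmetic(self):
        alns = [self._aln(20 + k, ortholog=f"g{k}") for k in range(100)]
        res = kaks.filter_alignments(alns)
        assert res.n_dropped_distance == 5
        assert len(res.kept) == 95

    def test_filter_order_variability_then_distance(self):
        # the most divergent alignment is already gone after the
        # variability window, so the distance trim removes the runner-up
        alns = [self._aln(125, ortholog="too_var")] + [
            self._aln(20 + k, ortholog=f"g{k}") for k in range(20)
        ]
        res = kaks.filter_alignments(alns)
        kept_ids = {a.ortholog_id for a in res.kept}
        assert "too_var" not in kept_ids
        assert res.n_dropped_distance == 1
        assert "g19" not in kept_ids  # highest distance among survivors


# --------------------------------------------------------------------------
# phylogenetic targeting


def oracle_targeting(tree, values, outgroup):
    """Brute force over all sets of branch-disjoint pairs (networkx)."""
    nx = pytest.importorskip("networkx")
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            g.add_edge(id(node), id(ch))
    leaf_of = {
        lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()
    }
    candidates = sorted(values)
    sd = float(np.std(list(values.values()), ddof=1))
    pairs = []
    for a, b in itertools.combinations(candidates, 2):
        path = nx.shortest_path(g, leaf_of[a], leaf_of[b])
        edges = frozenset(frozenset(e) for e in zip(path, path[1:]))
        pairs.append((a, b, abs(values[a] - values[b]) / sd, edges))
    best = (-1.0, None)
    for r in range(1, len(candidates) // 2 + 1):
        for combo in itertools.combinations(pairs, r):
            taxa = [t for p in combo for t in p[:2]]
            if len(set(taxa)) < len(taxa):
                continue
            eds = [p[3] for p in combo]
            if any(e1 & e2 for e1, e2 in itertools.combinations(eds, 2)):
                continue
            score = sum(p[2] for p in combo)
            if score > best[0] + 1e-12:
                best = (score, combo)
    return best[0], {frozenset(p[:2]) for p in best[1]}


def _random_ultrametric(rng, labels):
    nodes = {lab: (dendropy.Node(), 0.0) for lab in labels}
    tn = dendropy.TaxonNamespace(sorted(labels))
    for lab in labels:
        nodes[lab][0].taxon = tn.get_taxon(lab)
    active = dict(nodes)
    t = 0.0
    while len(active) > 1:
        t += float(rng.exponential(1.0)) + 0.05
        keys = sorted(active)
        i, j = rng.choice(len(keys), size=2, replace=False)
        a, b = keys[int(i)], keys[int(j)]
        (na, ta), (nb, tb) = active.pop(a), active.pop(b)
        parent = dendropy.Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = t - ta
        nb.edge.length = t - tb
        active[min(a, b)] = (parent, t)
    root = next(iter(active.values()))[0]
    tree = dendropy.Tree(taxon_namespace=tn, seed_node=root)
    tree.is_rooted = True
    return tree


class TestPhylogeneticTargeting:
    def test_two_taxa_single_pair(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):1,O:2);", schema="newick", preserve_underscores=True
        )
        traits = pd.DataFrame(
            {"taxon": ["A", "B"], "body_mass_t": [10.0, 1.0]}
        ).set_index("taxon", drop=False)
        res = kaks.phylogenetic_targeting(tree, traits, outgroup="O")
        assert res.labels == ["A-B"]

    def test_matches_exhaustive_oracle(self, rng):
        for rep in range(8):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)] + ["OUT"]
            tree = _random_ultrametric(rng, labels)
            values = {f"t{i}": float(rng.random() * 100) for i in range(n)}
            traits = pd.DataFrame(
                {"taxon": list(values), "body_mass_t": list(values.values())}
            ).set_index("taxon", drop=False)
            res = kaks.phylogenetic_targeting(tree, traits, outgroup="OUT")
            score, pairs = oracle_targeting(tree, values, "OUT")
            assert res.summed_score == pytest.approx(score)
            assert {frozenset(p.taxa) for p in res.pairs} == pairs

    def test_mysticete_demo_pairs(self):
        # body-size ranking on the baleen-whale topology singles out the
        # bowhead/pygmy right, fin/minke and blue/rice whale pairs
        res = kaks.phylogenetic_targeting(
            datasets.mysticete_tree(), datasets.whale_traits(), outgroup="dolphin"
        )
        assert {frozenset(p.taxa) for p in res.pairs} == {
            frozenset({"bowhead", "pygmy_right"}),
            frozenset({"fin", "minke_common"}),
            frozenset({"blue", "rice"}),
        }
        for p in res.pairs:  # large member listed first
            assert p.large in {"bowhead", "fin", "blue"}

    def test_missing_trait_rejected(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,O:2);", schema="newick")
        traits = pd.DataFrame(
            {"taxon": ["A", "B"], "body_mass_t": [10.0, np.nan]}
        ).set_index("taxon", drop=False)
        with pytest.raises(InputError, match="missing trait"):
            kaks.phylogenetic_targeting(tree, traits, outgroup="O")


class TestScreen:
    def _est(self, gene, pair, ratio):
        return KaKsEstimate(
            ortholog_id=gene, pair_label=pair, ka=ratio or 0.0, ks=1.0,
            ratio=ratio, p_value=0.05, n_codons=100, n_sites=200.0,
            s_sites=100.0, n_subs=10.0, s_subs=10.0,
        )

    def test_exactly_one_not_selected(self):
        res = kaks.screen_positive(
            [self._est("g1", "p1", 1.0), self._est("g2", "p1", 1.0001)]
        )
        assert res.per_pair["p1"] == {"g2"}

    def test_set_algebra(self):
        ests = (
            [self._est(g, "p1", 2.0) for g in "abc"]
            + [self._est(g, "p2", 2.0) for g in "ac"]
            + [self._est(g, "p3", 2.0) for g in "ad"]
        )
        res = kaks.screen_positive(ests)
        assert len(res.union) == 4
        assert res.intersection == {"a"}
        assert res.union["a"] == {"p1", "p2", "p3"}

    def test_power_on_simulated_omegas(self):
        # omega = 2 vs 0.2 at 500 codons: the Ka/Ks > 1 rule separates them
        tp = fp = 0
        reps = 25
        for rep in range(reps):
            sel = simdata.simulate_codon_pair(
                simdata.SimCodonParams(500, 1.0, 2.0, seed=rep)
            )
            neu = simdata.simulate_codon_pair(
                simdata.SimCodonParams(500, 1.0, 0.2, seed=1000 + rep)
            )
            tp += kaks.ng86(sel).positive
            fp += kaks.ng86(neu).positive
        assert tp / reps >= 0.9
        assert fp / reps <= 0.1


class TestEnrichment:
    def test_query_equals_reference_fold_one(self):
        genes = [f"g{i}" for i in range(30)]
        ann = {g: {"T1"} if i % 2 else {"T1", "T2"} for i, g in enumerate(genes)}
        df = kaks.enrichment(genes, ann, genes)
        assert np.allclose(df["fold_enrichment"], 1.0)

    def test_worked_example_and_hypergeometric_oracle(self):
        reference = [f"g{i}" for i in range(100)]
        ann = {g: set() for g in reference}
        for g in reference[:10]:
            ann[g].add("T")
        query = reference[:8] + reference[50:62]  # |Q| = 20, q = 8
        df = kaks.enrichment(query, ann, reference)
        row = df[df["term"] == "T"].iloc[0]
        assert row["fold_enrichment"] == pytest.approx(4.0)
        assert row["p_value"] == pytest.approx(
            float(sps.hypergeom.sf(7, 100, 10, 20))
        )

    def test_single_occurrence_removed(self):
        reference = [f"g{i}" for i in range(50)]
        ann = {g: {"common"} for g in reference}
        ann["g0"] = {"common", "rare"}
        df = kaks.enrichment(reference[:10], ann, reference)
        assert "rare" not in set(df["term"])

    def test_bh_is_monotone(self, rng):
        reference = [f"g{i}" for i in range(200)]
        ann = {g: set() for g in reference}
        for t in range(15):
            members = rng.choice(200, size=int(rng.integers(5, 60)), replace=False)
            for m in members:
                ann[f"g{m}"].add(f"T{t}")
        query = [f"g{i}" for i in sorted(rng.choice(200, 40, replace=False))]
        df = kaks.enrichment(query, ann, reference)
        ordered = df.sort_values("p_value")
        assert ordered["p_adjusted"].is_monotonic_increasing

    def test_empty_query_rejected(self):
        with pytest.raises(InputError):
            kaks.enrichment([], {}, ["g1"])
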