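"""Pairwise Ka/Ks selection screen between large- and small-bodied taxa.

The screen: (1) choose phylogenetically independent (branch-disjoint)
large/small species pairs maximizing the standardized body-size
contrast; (2) estimate Ka, Ks per ortholog per pair with the
Nei-Gojobori (NG86) method; (3) collect orthologs with Ka/Ks > 1 per
pair, their union and their intersection; (4) test functional
enrichment of the candidate set with a hypergeometric test and
Benjamini-Hochberg correction.

NG86 counts fractional synonymous/nonsynonymous sites per codon
(averaged over the two sequences), averages substitution differences
over all minimal pathways with equal weights (pathways through stop
codons excluded), and Jukes-Cantor-corrects the proportions:
d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._util import InputError
from .genetrees import MAX_JC_DISTANCE, jc_distance

_BASES = "TCAG"
_STOPS = frozenset({"TAA", "TAG", "TGA"})


@lru_cache(maxsize=1)
def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    return dict(unambiguous_dna_by_id[1].forward_table)


def _aa(codon: str) -> str | None:
    """Amino acid, or None for a stop codon."""
    return _codon_table().get(codon)


@dataclass
class CodonAlignment:
    """In-frame, gap-free codon alignment (pairwise or more)."""

    ortholog_id: str
    seqs: tuple[str, ...]

    def __post_init__(self):
        self.seqs = tuple(s.upper().replace("U", "T") for s in self.seqs)
        if len(self.seqs) < 2:
            raise InputError("need at least two sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise InputError("sequences differ in length")
        (L,) = lengths
        if L % 3 != 0:
            raise InputError("alignment length not divisible by 3")
        for s in self.seqs:
            if any(ch not in "ACGT" for ch in s):
                raise InputError("only unambiguous nucleotides allowed")
            for i in range(0, L, 3):
                if s[i : i + 3] in _STOPS:
                    raise InputError("internal stop codon present")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codons(self, idx: int) -> list[str]:
        s = self.seqs[idx]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def variable_fraction(self) -> float:
        arr = np.array([list(s) for s in self.seqs])
        return float((~(arr == arr[0]).all(axis=0)).mean())

    def mean_pairwise_distance(self) -> float:
        ds = [
            jc_distance(a, b) for a, b in itertools.combinations(self.seqs, 2)
        ]
        return float(np.mean(ds))


def read_codon_fasta(path, ortholog_id=None) -> CodonAlignment:
    from Bio import SeqIO

    recs = list(SeqIO.parse(path, "fasta"))
    return CodonAlignment(
        ortholog_id=ortholog_id or str(path), seqs=tuple(str(r.seq) for r in recs)
    )


# ---------------------------------------------------------------------------
# alignment filters


@dataclass
class AlignmentFilterResult:
    kept: list[CodonAlignment]
    n_input: int
    n_dropped_low_variability: int
    n_dropped_high_variability: int
    n_dropped_distance: int


def filter_alignments(
    alignments,
    min_var: float = 0.05,
    max_var: float = 0.40,
    top_dist: float = 0.05,
) -> AlignmentFilterResult:
    """Variability window, then top-distance trim (in that order).

    Alignments with variable-site fraction <= ``min_var`` or >
    ``max_var`` are dropped first; of the survivors, the
    floor(``top_dist`` * n) with the largest mean pairwise distances
    are then removed.  The order matters and is fixed: variability,
    then distance.
    """
    alns = list(alignments)
    if not alns:
        raise InputError("no alignments to filter")
    n_low = n_high = 0
    surviving = []
    for a in alns:
        v = a.variable_fraction()
        if v <= min_var:
            n_low += 1
        elif v > max_var:
            n_high += 1
        else:
            surviving.append(a)
    n_drop = int(np.floor(top_dist * len(surviving)))
    if n_drop:
        order = sorted(
            range(len(surviving)),
            key=lambda i: (surviving[i].mean_pairwise_distance(), i),
        )
        drop = set(order[len(surviving) - n_drop :])
        kept = [a for i, a in enumerate(surviving) if i not in drop]
    else:
        kept = surviving
    return AlignmentFilterResult(
        kept=kept,
        n_input=len(alns),
        n_dropped_low_variability=n_low,
        n_dropped_high_variability=n_high,
        n_dropped_distance=len(surviving) - len(kept),
    )


# ---------------------------------------------------------------------------
# NG86


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes (# synonymous one-step changes)/3 to the
    synonymous count; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = _aa(codon)
    if aa is None:
        raise InputError(f"stop codon {codon}")
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            new = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(new) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All orderings of the differing positions are weighted equally;
    pathways passing through a stop codon are excluded.  If every
    pathway is blocked (possible only for 2-3 differences), all
    pathways are used with stop-involving steps counted nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def _walk(order, allow_stops):
        cur = c1
        syn = nsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                return None
            a1, a2 = _aa(cur), _aa(nxt)
            if a1 is not None and a1 == a2:
                syn += 1.0
            else:
                nsyn += 1.0
            cur = nxt
        return syn, nsyn

    results = [r for o in itertools.permutations(diff) if (r := _walk(o, False))]
    if not results:
        results = [_walk(o, True) for o in itertools.permutations(diff)]
    syn = float(np.mean([r[0] for r in results]))
    nsyn = float(np.mean([r[1] for r in results]))
    return syn, nsyn


@dataclass
class KaKsEstimate:
    """Per-ortholog pairwise substitution-rate estimate."""

    ortholog_id: str
    pair_label: str
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 (undefined)
    p_value: float
    n_codons: int
    n_sites: float
    s_sites: float
    n_subs: float
    s_subs: float
    saturated: bool = False

    @property
    def positive(self) -> bool:
        return self.ratio is not None and self.ratio > 1.0


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return MAX_JC_DISTANCE, True
    return float(-0.75 * np.log1p(-4.0 * p / 3.0)), False


def ng86(alignment: CodonAlignment, pair_label: str = "") -> KaKsEstimate:
    """NG86 Ka/Ks for the first two sequences of a codon alignment.

    The p-value comes from a two-sided Fisher exact test on the rounded
    substitution and remaining-site counts; Ks = 0 leaves the ratio
    undefined (flagged), pS or pN >= 0.75 flags saturation.
    """
    if alignment.n_codons == 0:
        raise InputError("zero aligned codons")
    cods1, cods2 = alignment.codons(0), alignment.codons(1)
    S = N = Sd = Nd = 0.0
    for a, b in zip(cods1, cods2):
        s1, n1 = _codon_sites(a)
        s2, n2 = _codon_sites(b)
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = _codon_differences(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks, sat_s = _jc_correct(pS)
    ka, sat_n = _jc_correct(pN)
    ratio = ka / ks if ks > 0 and not sat_s else None
    table = [
        [round(Nd), max(0, round(N - Nd))],
        [round(Sd), max(0, round(S - Sd))],
    ]
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return KaKsEstimate(
        ortholog_id=alignment.ortholog_id,
        pair_label=pair_label,
        ka=ka,
        ks=ks,
        ratio=ratio,
        p_value=float(p_value),
        n_codons=alignment.n_codons,
        n_sites=N,
        s_sites=S,
        n_subs=Nd,
        s_subs=Sd,
        saturated=sat_s or sat_n,
    )


# ---------------------------------------------------------------------------
# trait table and phylogenetic targeting


def read_trait_table(path) -> pd.DataFrame:
    """TSV with columns taxon, body_length_m, body_mass_t."""
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "body_length_m", "body_mass_t"}
    if not required <= set(df.columns):
        raise InputError(f"trait table needs columns {sorted(required)}")
    return df.set_index("taxon", drop=False)


@dataclass
class Pair:
    large: str
    small: str
    contrast: float  # |trait difference| / SD(trait over candidates)

    @property
    def taxa(self) -> tuple[str, str]:
        return (self.large, self.small)


@dataclass
class PairSet:
    """Phylogenetically independent pairs with the summed score."""

    pairs: list[Pair]
    trait: str
    summed_score: float
    method: str = "exhaustive"

    @property
    def labels(self) -> list[str]:
        return [f"{p.large}-{p.small}" for p in self.pairs]


def _path_edges(tree: dendropy.Tree):
    """Per-leaf chains of unrooted edge ids, for path computation."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    edge_id = {}
    for i, node in enumerate(t.preorder_node_iter()):
        if node.parent_node is not None:
            edge_id[node] = i
    chains = {}
    for leaf in t.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append(edge_id[node])
            node = node.parent_node
        chains[leaf.taxon.label] = chain
    return chains


def pair_path(chains, a: str, b: str) -> frozenset:
    """Edges on the unrooted path between two leaves."""
    ca, cb = chains[a], chains[b]
    return frozenset(set(ca) ^ set(cb))


def phylogenetic_targeting(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    outgroup: str,
    trait: str = "body_mass_t",
    max_exhaustive: int = 14,
) -> PairSet:
    """Branch-disjoint pairs maximizing the summed standardized contrast.

    Candidates are the taxa present in both the trait table and the
    tree, excluding the outgroup.  Two pairs are phylogenetically
    independent iff the tree paths connecting them share no branch (and
    no taxon).  Per-pair score = |trait difference| / SD of the trait
    over all candidates.  The pair set maximizing the summed score is
    found exhaustively for up to ``max_exhaustive`` candidates, by a
    greedy best-first fallback above that.  The default trait is body
    mass, falling back to body length when mass is absent.
    """
    if trait not in traits.columns:
        if trait == "body_mass_t" and "body_length_m" in traits.columns:
            trait = "body_length_m"
        else:
            raise InputError(f"trait column {trait!r} missing")
    tree_taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
    candidates = sorted(
        set(traits["taxon"] if "taxon" in traits.columns else traits.index)
        & tree_taxa - {outgroup}
    )
    if len(candidates) < 2:
        raise InputError("need at least two candidate taxa with traits")
    values = {}
    for tax in candidates:
        v = traits.loc[tax, trait]
        if pd.isna(v):
            raise InputError(f"taxon {tax} missing trait {trait!r}")
        values[tax] = float(v)
    sd = float(np.std(list(values.values()), ddof=1))
    if sd == 0:
        raise InputError("trait has zero variance over candidates")
    chains = _path_edges(tree)
    missing = [t for t in candidates if t not in chains]
    if missing:
        raise InputError(f"taxa absent from tree: {missing}")
    all_pairs = []
    for a, b in itertools.combinations(candidates, 2):
        large, small = (a, b) if values[a] >= values[b] else (b, a)
        score = abs(values[a] - values[b]) / sd
        all_pairs.append((Pair(large, small, score), pair_path(chains, a, b)))

    if len(candidates) <= max_exhaustive:
        best_score = -1.0
        best_set: list[Pair] = []
        order = sorted(range(len(all_pairs)), key=lambda i: tuple(sorted(all_pairs[i][0].taxa)))

        def _search(start, chosen, used_taxa, used_edges, score):
            nonlocal best_score, best_set
            if score > best_score + 1e-12:
                best_score = score
                best_set = list(chosen)
            for k in range(start, len(order)):
                pair, path = all_pairs[order[k]]
                if used_taxa & set(pair.taxa) or used_edges & path:
                    continue
                chosen.append(pair)
                _search(k + 1, chosen, used_taxa | set(pair.taxa), used_edges | path,
                        score + pair.contrast)
                chosen.pop()

        _search(0, [], set(), frozenset(), 0.0)
        method = "exhaustive"
        pairs = best_set
    else:
        warnings.warn("more than %d candidates: greedy targeting" % max_exhaustive)
        remaining = sorted(all_pairs, key=lambda x: (-x[0].contrast, x[0].taxa))
        pairs, used_taxa, used_edges = [], set(), set()
        for pair, path in remaining:
            if used_taxa & set(pair.taxa) or used_edges & path:
                continue
            pairs.append(pair)
            used_taxa |= set(pair.taxa)
            used_edges |= path
        method = "greedy"
    pairs = sorted(pairs, key=lambda p: (-p.contrast, p.taxa))
    return PairSet(
        pairs=pairs, trait=trait,
        summed_score=float(sum(p.contrast for p in pairs)), method=method,
    )


# ---------------------------------------------------------------------------
# screening and enrichment


@dataclass
class ScreenResult:
    """Ka/Ks > 1 candidate sets: per pair, union, intersection."""

    per_pair: dict[str, set]
    union: dict[str, set] = field(init=False)  # gene -> pairs where positive
    intersection: set = field(init=False)

    def __post_init__(self):
        union: dict[str, set] = {}
        for pair, genes in self.per_pair.items():
            for g in genes:
                union.setdefault(g, set()).add(pair)
        self.union = union
        sets = list(self.per_pair.values())
        self.intersection = set.intersection(*sets) if sets else set()


def screen_positive(estimates, pair_labels=None) -> ScreenResult:
    """Collect genes with Ka/Ks strictly greater than 1 per pair.

    ``estimates`` is a flat list of :class:`KaKsEstimate`; the pair
    panel defaults to the labels present.  A gene at Ka/Ks exactly 1.0
    is NOT selected.
    """
    labels = list(pair_labels) if pair_labels is not None else sorted(
        {e.pair_label for e in estimates}
    )
    per_pair: dict[str, set] = {lab: set() for lab in labels}
    for e in estimates:
        if e.pair_label in per_pair and e.positive:
            per_pair[e.pair_label].add(e.ortholog_id)
    return ScreenResult(per_pair=per_pair)


def enrichment(query_genes, term_annotation: dict, reference_genes) -> pd.DataFrame:
    """Hypergeometric term enrichment of a query set against a reference.

    Per term with query count q and reference count r: fold enrichment
    (q/|Q|)/(r/|R|), hypergeometric upper-tail p, BH-adjusted p.
    Terms with query count <= 1 are removed (before correction); rows
    sorted by adjusted p then term.
    """
    query = set(query_genes)
    reference = set(reference_genes)
    if not query:
        raise InputError("empty query gene set")
    if not query <= reference:
        raise InputError("query genes must be a subset of the reference")
    term_ref: dict[str, int] = {}
    term_query: dict[str, int] = {}
    for gene in reference:
        for term in term_annotation.get(gene, ()):
            term_ref[term] = term_ref.get(term, 0) + 1
            if gene in query:
                term_query[term] = term_query.get(term, 0) + 1
    rows = []
    M, Nq = len(reference), len(query)
    for term in sorted(term_ref):
        q = term_query.get(term, 0)
        if q <= 1:
            continue  # single-occurrence terms are likely artifacts
        r = term_ref[term]
        fold = (q / Nq) / (r / M)
        p = float(stats.hypergeom.sf(q - 1, M, r, Nq))
        rows.append(
            {"term": term, "n_reference": r, "n_query": q,
             "fold_enrichment": fold, "p_value": p}
        )
    df = pd.DataFrame(rows, columns=["term", "n_reference", "n_query",
                                     "fold_enrichment", "p_value"])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_adjusted", "term"]).reset_index(drop=True)
    else:
        df["p_adjusted"] = []
    return df
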