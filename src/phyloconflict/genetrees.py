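"""Per-fragment gene trees: JC distances, neighbor joining, newick I/O.

Distance + NJ stands in for per-fragment maximum-likelihood tree search:
the downstream conflict analyses consume only topologies and branch
lengths, and externally estimated newick tree sets can be ingested with
:func:`read_tree_file` whenever higher-accuracy trees are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._util import InputError, substream

#: Distance reported for saturated pairs (p >= 0.75, where the JC
#: correction diverges).  Flagged, not raised: a saturated fragment is
#: still rankable by the variability filter.
MAX_JC_DISTANCE = 5.0


class ParseError(InputError):
    """Malformed newick input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _as_uint8(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8) if seq.dtype != np.uint8 else seq
    return np.frombuffer(str(seq).upper().encode("ascii"), dtype=np.uint8)


def p_distance(seq_a, seq_b) -> float:
    """Proportion of differing sites between two equal-length sequences."""
    a, b = _as_uint8(seq_a), _as_uint8(seq_b)
    if a.shape != b.shape:
        raise InputError("sequences differ in length")
    if a.size == 0:
        raise InputError("empty sequences")
    return float(np.count_nonzero(a != b) / a.size)


def jc_distance(seq_a, seq_b) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3).

    Returns :data:`MAX_JC_DISTANCE` when p >= 0.75 (saturation).
    """
    p = p_distance(seq_a, seq_b)
    if p >= 0.75:
        return MAX_JC_DISTANCE
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


@dataclass
class DistanceMatrix:
    """Symmetric JC distance matrix over a fixed taxon order."""

    taxa: tuple[str, ...]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean mask, same shape

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise InputError("matrix shape does not match taxon count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise InputError("distance matrix has non-zero diagonal")
        if np.any(self.matrix < 0):
            raise InputError("negative distances")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    @classmethod
    def from_sequences(cls, taxa, seqs) -> "DistanceMatrix":
        taxa = tuple(taxa)
        n = len(taxa)
        mat = np.zeros((n, n))
        sat = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = jc_distance(seqs[i], seqs[j])
                mat[i, j] = mat[j, i] = d
                sat[i, j] = sat[j, i] = d == MAX_JC_DISTANCE
        return cls(taxa, mat, sat)


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard Q-criterion agglomeration.  Ties in Q are broken by the
    lexicographic order of the joined clusters' names, where a cluster
    is named after its lexicographically smallest leaf label.  Negative
    estimated branch lengths are clamped to zero.  The returned tree is
    an unrooted topology represented with a trifurcating seed node.
    """
    n = len(dist.taxa)
    if n < 3:
        raise InputError("neighbor joining requires at least 3 taxa")
    tn = dendropy.TaxonNamespace(sorted(dist.taxa))
    nodes = []
    names = list(dist.taxa)
    for lab in dist.taxa:
        nd = dendropy.Node(taxon=tn.get_taxon(lab))
        nodes.append(nd)
    D = dist.matrix.copy()
    active = list(range(n))

    def _clamp(x):
        return max(0.0, float(x))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((names[i], names[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)
        # reuse slot i for the merged cluster
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        names[i] = min(names[i], names[j])
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    root.add_child(nodes[k])
    nodes[i].edge.length = _clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].edge.length = _clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].edge.length = _clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    tree = dendropy.Tree(taxon_namespace=tn, seed_node=root)
    tree.is_rooted = False
    return tree


class GeneTreeSet:
    """Ordered collection of gene trees over a shared taxon namespace.

    The universal container consumed by the conflict, triplet and split
    analyses.  Trees are dendropy :class:`~dendropy.Tree` objects; the
    optional provenance list tags each tree with its source (fragment id
    or file/line).
    """

    def __init__(self, trees, taxon_namespace=None, provenance=None):
        self.trees = list(trees)
        if taxon_namespace is None:
            taxon_namespace = (
                self.trees[0].taxon_namespace if self.trees else dendropy.TaxonNamespace()
            )
        self.taxon_namespace = taxon_namespace
        for t in self.trees:
            if t.taxon_namespace is not self.taxon_namespace:
                raise InputError("all trees must share one taxon namespace")
        if provenance is not None and len(provenance) != len(self.trees):
            raise InputError("provenance length does not match tree count")
        self.provenance = list(provenance) if provenance is not None else None

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def taxon_universe(self) -> tuple[str, ...]:
        labels = set()
        for t in self.trees:
            labels.update(lf.taxon.label for lf in t.leaf_node_iter())
        return tuple(sorted(labels))

    def sample(self, n: int, seed: int | None = None) -> "GeneTreeSet":
        """Uniform sample of n trees without replacement (seeded).

        Asking for more trees than available returns everything, with a
        warning (matching the behaviour of the triplet sampler).
        """
        if n >= len(self.trees):
            if n > len(self.trees):
                warnings.warn(
                    f"requested {n} trees but only {len(self.trees)} available; using all"
                )
            return self
        rng = substream(seed, 0)
        idx = np.sort(rng.choice(len(self.trees), size=n, replace=False))
        prov = [self.provenance[i] for i in idx] if self.provenance else None
        return GeneTreeSet([self.trees[i] for i in idx], self.taxon_namespace, prov)

    def write(self, path) -> None:
        write_tree_file(self, path)


def read_tree_file(path, taxon_namespace=None) -> GeneTreeSet:
    """Read newick trees, one per line; empty lines are skipped.

    Malformed lines raise :class:`ParseError` carrying the line number.
    An empty file yields an empty set with a warning.
    """
    tn = taxon_namespace or dendropy.TaxonNamespace()
    trees, prov = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line, schema="newick", taxon_namespace=tn,
                    suppress_internal_node_taxa=True, preserve_underscores=True,
                )
            except Exception as exc:  # dendropy raises several parse types
                raise ParseError(str(exc), lineno) from exc
            trees.append(tree)
            prov.append(f"{path}:{lineno}")
    if not trees:
        warnings.warn(f"no trees found in {path}")
    return GeneTreeSet(trees, tn, prov or None)


def write_tree_file(tree_set: GeneTreeSet, path) -> None:
    """Write newick, one tree per line, preserving support labels."""
    with open(path, "w") as fh:
        for t in tree_set:
            fh.write(
                t.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
            )
            fh.write("\n")


def tree_from_fragment(fragment, bootstrap: int = 0, seed: int | None = None):
    """Distance+NJ tree for one alignment fragment.

    With ``bootstrap`` > 0, alignment columns are resampled with a
    seeded generator and internal-edge support (fraction of replicates
    containing the edge's split) is attached as node labels.
    """
    dm = DistanceMatrix.from_sequences(fragment.taxa, fragment.sequences)
    tree = neighbor_joining(dm)
    if bootstrap > 0:
        from . import splits as _splits  # local import avoids a cycle

        universe = tuple(sorted(fragment.taxa))
        counts: dict = {}
        L = fragment.sequences.shape[1]
        for b in range(bootstrap):
            rng = substream(seed, 1, b)
            cols = rng.integers(0, L, size=L)
            res = fragment.sequences[:, cols]
            bt = neighbor_joining(DistanceMatrix.from_sequences(fragment.taxa, res))
            for sp in _splits.tree_splits(bt, universe):
                counts[sp] = counts.get(sp, 0) + 1
        ref = {sp: cnt for sp, cnt in counts.items()}
        for sp, node in _splits.tree_split_nodes(tree, universe):
            node.label = str(round(ref.get(sp, 0) / bootstrap, 3))
    return tree


def build_fragment_trees(fragments, bootstrap: int = 0, seed: int | None = None) -> GeneTreeSet:
    """NJ trees for a list of fragments, skipping any with < 3 taxa."""
    trees, prov = [], []
    tn = dendropy.TaxonNamespace()
    for frag in fragments:
        if len(frag.taxa) < 3:
            warnings.warn(f"fragment {frag.index}: fewer than 3 taxa, skipped")
            continue
        tree = tree_from_fragment(frag, bootstrap=bootstrap, seed=seed)
        tree.migrate_taxon_namespace(tn)
        trees.append(tree)
        prov.append(str(frag.index))
    return GeneTreeSet(trees, tn, prov or None)
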