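"""Gene-tree conflict around species-tree branches.

For every internal branch of a given species tree, the three possible
resolutions of the four taxon groups (A,B),(C,D) around the branch are
tallied across a gene-tree set as normalized quartet frequencies q1
(the species-tree resolution AB|CD), q2 (AC|BD) and q3 (AD|BC).  Under
the neutral MSC with internal branch length T coalescent units, the
expected discordance q2 + q3 is (2/3) e^(-T); a branch with q1 = q2 =
q3 = 1/3 behaves as a hard polytomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from ._util import InputError, clade_masks, leaf_bit_index, substream
from .genetrees import GeneTreeSet


def expected_discordance(T: float) -> float:
    """MSC expectation (2/3) e^(-T) for a branch of T coalescent units."""
    if T < 0:
        raise InputError("branch length must be >= 0")
    return (2.0 / 3.0) * float(np.exp(-T))


@dataclass
class QuartetSupport:
    """Normalized quartet frequencies around one internal branch."""

    branch_id: str
    groups: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    q1: float
    q2: float
    q3: float
    n_quartets_evaluated: int
    n_unresolved_skipped: int

    @property
    def q(self) -> tuple[float, float, float]:
        return (self.q1, self.q2, self.q3)


def _derooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    return t


def branch_groups(species_tree: dendropy.Tree):
    """Enumerate internal branches of the unrooted species tree.

    Yields (branch_id, (A, B, C, D)) where A,B are the leaf sets of the
    two subtrees on the child side of the branch and C,D the two on the
    parent side.  Branches whose endpoints are not binary in the
    unrooted sense are skipped with a warning (their three-resolution
    quartet decomposition is not defined).
    """
    t = _derooted_copy(species_tree)
    leaves = sorted(lf.taxon.label for lf in t.leaf_node_iter())
    if len(leaves) < 4:
        raise InputError("species tree must have at least 4 leaves")
    bit = leaf_bit_index(leaves)
    masks, full = clade_masks(t, bit)
    inv = {i: lab for lab, i in bit.items()}

    def _labels(mask):
        return tuple(inv[i] for i in range(len(bit)) if mask >> i & 1)

    out = []
    idx = 0
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None or node.is_leaf():
            continue
        kids = node.child_nodes()
        # parent-side groups
        sibs = [c for c in parent.child_nodes() if c is not node]
        if parent.parent_node is None:
            side = [masks[s] for s in sibs]
        else:
            side = [masks[s] for s in sibs] + [full & ~masks[parent]]
        if len(kids) != 2 or len(side) != 2:
            warnings.warn("skipping branch at a multifurcation")
            continue
        idx += 1
        groups = (
            _labels(masks[kids[0]]),
            _labels(masks[kids[1]]),
            _labels(side[0]),
            _labels(side[1]),
        )
        out.append((f"B{idx}", groups))
    return out


def _tree_bit_matrix(tree: dendropy.Tree, bit: dict[str, int]):
    """Per-tree data for quartet queries: (bit rows, present mask).

    Rows: boolean matrix (n_taxa x n_clades) where entry [t, c] says
    whether taxon t is inside clade c.  Only clades (rooted-tree node
    leaf sets) are needed: an unrooted split is a clade or its
    complement, and complement membership is derivable from the bits.
    """
    if len(bit) > 64:
        raise InputError("quartet scoring supports at most 64 taxa")
    masks, _ = clade_masks(tree, bit)
    clades = [m for node, m in masks.items()]
    present = 0
    for lf in tree.leaf_node_iter():
        lab = lf.taxon.label if lf.taxon else lf.label
        if lab in bit:
            present |= 1 << bit[lab]
    arr = np.array(clades, dtype=np.uint64)
    n = len(bit)
    rows = ((arr[None, :] >> np.arange(n, dtype=np.uint64)[:, None]) & 1).astype(bool)
    return rows, present


def _quartet_topology(rows, a, b, c, d) -> int:
    """0/1/2 for ab|cd / ac|bd / ad|bc, -1 if unresolved."""
    pat = (
        rows[a].astype(np.int8)
        + 2 * rows[b].astype(np.int8)
        + 4 * rows[c].astype(np.int8)
        + 8 * rows[d].astype(np.int8)
    )
    if np.any((pat == 3) | (pat == 12)):
        return 0
    if np.any((pat == 5) | (pat == 10)):
        return 1
    if np.any((pat == 6) | (pat == 9)):
        return 2
    return -1


def quartet_support(
    species_tree: dendropy.Tree,
    trees: GeneTreeSet,
    sampling_limit: int = 10_000,
    seed: int | None = None,
    branches=None,
) -> list[QuartetSupport]:
    """Score gene-tree support for each internal species-tree branch.

    Quartets (one leaf from each group) are enumerated exhaustively when
    their number is at most ``sampling_limit``, otherwise that many are
    drawn uniformly (with replacement) from the product space with the
    seeded generator.  Gene trees lacking a quartet's taxa are skipped
    for that quartet; unresolved (multifurcating) quartets are skipped
    and counted separately.  q1+q2+q3 = 1 whenever anything resolved.
    """
    enumerated = branch_groups(species_tree)
    if branches is not None:
        wanted = set(branches)
        enumerated = [bg for bg in enumerated if bg[0] in wanted]
        if not enumerated:
            raise InputError(f"focal branch not found among {branches}")
    leaves = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    bit = leaf_bit_index(leaves)
    per_tree = [_tree_bit_matrix(t, bit) for t in trees]
    results = []
    for bidx, (bid, groups) in enumerate(enumerated):
        ga, gb, gc, gd = ([bit[x] for x in g] for g in groups)
        total = len(ga) * len(gb) * len(gc) * len(gd)
        if total <= sampling_limit:
            quartets = [(a, b, c, d) for a in ga for b in gb for c in gc for d in gd]
        else:
            rng = substream(seed, 50, bidx)
            quartets = [
                (
                    ga[int(rng.integers(len(ga)))],
                    gb[int(rng.integers(len(gb)))],
                    gc[int(rng.integers(len(gc)))],
                    gd[int(rng.integers(len(gd)))],
                )
                for _ in range(sampling_limit)
            ]
        counts = [0, 0, 0]
        unresolved = 0
        for rows, present in per_tree:
            for a, b, c, d in quartets:
                need = (1 << a) | (1 << b) | (1 << c) | (1 << d)
                if present & need != need:
                    continue
                topo = _quartet_topology(rows, a, b, c, d)
                if topo < 0:
                    unresolved += 1
                else:
                    counts[topo] += 1
        n_eval = sum(counts)
        q = [ci / n_eval if n_eval else 0.0 for ci in counts]
        results.append(
            QuartetSupport(
                branch_id=bid,
                groups=groups,
                q1=q[0],
                q2=q[1],
                q3=q[2],
                n_quartets_evaluated=n_eval,
                n_unresolved_skipped=unresolved,
            )
        )
    return results


# ---------------------------------------------------------------------------
# greedy consensus


def _canonical_split(mask: int, full: int) -> int:
    """Canonical unrooted split encoding: the side without bit 0."""
    return mask ^ full if mask & 1 else mask


def greedy_consensus(trees: GeneTreeSet) -> dendropy.Tree:
    """Greedy (extended majority-rule) consensus of a gene-tree set.

    Splits are ranked by frequency and added while compatible with the
    growing set; all majority splits are necessarily included.  Ties in
    frequency are broken by the lexicographic encoding of the split
    (the sorted label tuple of its canonical side).  The result may be
    multifurcating when compatible splits run out.
    """
    if len(trees) == 0:
        raise InputError("empty tree set")
    universes = {tuple(sorted(lf.taxon.label for lf in t.leaf_node_iter())) for t in trees}
    if len(universes) != 1:
        raise InputError("greedy consensus requires a common leaf set")
    labels = universes.pop()
    bit = leaf_bit_index(labels)
    inv = {i: lab for lab, i in bit.items()}
    full = (1 << len(labels)) - 1
    counts: dict[int, int] = {}
    for t in trees:
        masks, _ = clade_masks(_derooted_copy(t), bit)
        seen = set()
        for node, m in masks.items():
            if m == 0 or m == full:
                continue
            cs = _canonical_split(m, full)
            if bin(cs).count("1") < 2 or bin(cs ^ full).count("1") < 2:
                continue  # trivial split
            seen.add(cs)
        for cs in seen:
            counts[cs] = counts.get(cs, 0) + 1

    def _encoding(cs):
        return tuple(inv[i] for i in range(len(labels)) if cs >> i & 1)

    ranked = sorted(counts, key=lambda cs: (-counts[cs], _encoding(cs)))
    accepted: list[int] = []
    for cs in ranked:
        comp = True
        for other in accepted:
            a, b = cs, other
            if not (a & b == 0 or a & ~b & full == 0 or ~a & b & full == 0
                    or ~a & ~b & full == 0):
                comp = False
                break
        if comp:
            accepted.append(cs)
    # build the tree: canonical sides exclude taxon bit 0, so they nest
    # as clades of the tree rooted on taxon 0's pendant edge.
    tn = dendropy.TaxonNamespace(list(labels))
    root = dendropy.Node()
    node_of = {full ^ 1: root}  # clade of everything except taxon 0
    for cs in sorted(accepted, key=lambda c: -bin(c).count("1")):
        parent = root
        best = None
        for clade, nd in node_of.items():
            if cs & clade == cs and clade != cs:
                if best is None or bin(clade).count("1") < bin(best).count("1"):
                    best, parent = clade, nd
        nd = dendropy.Node()
        parent.add_child(nd)
        node_of[cs] = nd
    top = dendropy.Node()
    leaf0 = dendropy.Node(taxon=tn.get_taxon(inv[0]))
    top.add_child(leaf0)
    top.add_child(root)
    for i in range(1, len(labels)):
        m = 1 << i
        parent = root
        best = None
        for clade, nd in node_of.items():
            if clade & m:
                if best is None or bin(clade).count("1") < bin(best).count("1"):
                    best, parent = clade, nd
        parent.add_child(dendropy.Node(taxon=tn.get_taxon(inv[i])))
    tree = dendropy.Tree(taxon_namespace=tn, seed_node=top)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# window profiles


@dataclass
class WindowEntry:
    chrom: str
    start: int
    end: int
    q1: float | None
    q2: float | None
    q3: float | None
    missing: bool


@dataclass
class WindowConflictProfile:
    """Per-fragment quartet scores for one focal branch along a chromosome."""

    branch_id: str
    entries: list[WindowEntry]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tq1\tq2\tq3\tmissing\n")
            for e in self.entries:
                row = [e.chrom, str(e.start), str(e.end)]
                if e.missing:
                    row += ["NA", "NA", "NA", "1"]
                else:
                    row += [f"{e.q1:.6g}", f"{e.q2:.6g}", f"{e.q3:.6g}", "0"]
                fh.write("\t".join(row) + "\n")


def window_profile(
    species_tree: dendropy.Tree,
    focal_branch: str,
    window_trees_by_fragment: dict,
    coordinates: dict | None = None,
    sampling_limit: int = 10_000,
    seed: int | None = None,
) -> WindowConflictProfile:
    """Quartet scores of one branch per fragment, from its window trees.

    ``window_trees_by_fragment`` maps a fragment id to the GeneTreeSet of
    its retained windows; ``coordinates`` maps fragment id to (chrom,
    start, end) (defaults to the fragment id as an index).  Fragments
    with no retained windows are flagged missing.  Entries are ordered
    by (chrom, start) and must not overlap.
    """
    known = {bid for bid, _ in branch_groups(species_tree)}
    if focal_branch not in known:
        raise InputError(f"focal branch {focal_branch!r} not in species tree")
    entries = []
    for fid in sorted(window_trees_by_fragment):
        tset = window_trees_by_fragment[fid]
        if coordinates and fid in coordinates:
            chrom, start, end = coordinates[fid]
        else:
            chrom, start, end = "chr", int(fid), int(fid) + 1
        if tset is None or len(tset) == 0:
            entries.append(WindowEntry(chrom, start, end, None, None, None, True))
            continue
        sup = quartet_support(
            species_tree, tset, sampling_limit=sampling_limit, seed=seed,
            branches=[focal_branch],
        )[0]
        if sup.n_quartets_evaluated == 0:
            entries.append(WindowEntry(chrom, start, end, None, None, None, True))
        else:
            entries.append(
                WindowEntry(chrom, start, end, sup.q1, sup.q2, sup.q3, False)
            )
    entries.sort(key=lambda e: (e.chrom, e.start))
    for prev, nxt in zip(entries, entries[1:]):
        if prev.chrom == nxt.chrom and nxt.start < prev.end:
            raise InputError("window entries overlap")
    return WindowConflictProfile(branch_id=focal_branch, entries=entries)


def support_table(supports: list[QuartetSupport], path) -> None:
    """Write the per-branch q-table as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "branch\tgroup_a\tgroup_b\tgroup_c\tgroup_d\tq1\tq2\tq3\t"
            "n_evaluated\tn_unresolved\n"
        )
        for s in supports:
            fh.write(
                "\t".join(
                    [
                        s.branch_id,
                        *[",".join(g) for g in s.groups],
                        f"{s.q1:.6g}",
                        f"{s.q2:.6g}",
                        f"{s.q3:.6g}",
                        str(s.n_quartets_evaluated),
                        str(s.n_unresolved_skipped),
                    ]
                )
                + "\n"
            )
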