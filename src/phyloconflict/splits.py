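"""Consensus-network split systems.

A split is the bipartition of the taxon set induced by removing a tree
edge.  The consensus network keeps every non-trivial split whose
frequency across a tree set reaches a threshold (default 12%), which —
unlike a consensus tree — may include mutually incompatible splits;
those pairs are flagged.  Two splits are compatible iff at least one of
the four side-intersections is empty.  The split system (not its planar
drawing) is the analysis product; export to a SplitsTree-compatible
NEXUS file is provided for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from ._util import InputError, clade_masks, leaf_bit_index
from .genetrees import GeneTreeSet


@dataclass(frozen=True)
class Split:
    """Canonical bipartition: the sorted side NOT containing the first
    taxon of the (sorted) universe."""

    side: frozenset
    universe: tuple[str, ...]

    def __post_init__(self):
        uni = tuple(sorted(self.universe))
        object.__setattr__(self, "universe", uni)
        side = frozenset(self.side)
        if not side or side == set(uni):
            raise InputError("both split sides must be non-empty")
        if not side <= set(uni):
            raise InputError("split side not within the taxon universe")
        if uni[0] in side:
            side = frozenset(uni) - side
        object.__setattr__(self, "side", side)

    @property
    def other_side(self) -> frozenset:
        return frozenset(self.universe) - self.side

    @property
    def is_trivial(self) -> bool:
        return len(self.side) == 1 or len(self.other_side) == 1

    def compatible_with(self, other: "Split") -> bool:
        if self.universe != other.universe:
            raise InputError("splits over different universes")
        a1, a2 = self.side, self.other_side
        b1, b2 = other.side, other.other_side
        return any(not (x & y) for x in (a1, a2) for y in (b1, b2))

    def encoding(self) -> tuple[str, ...]:
        return tuple(sorted(self.side))


def _unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    return t


def tree_splits(tree: dendropy.Tree, universe=None) -> set[Split]:
    """Non-trivial splits induced by the internal edges of a tree.

    The tree is read unrooted; a binary n-taxon tree yields n - 3
    splits.  Trees with fewer than 4 leaves yield the empty set.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    uni = tuple(sorted(universe)) if universe is not None else tuple(labels)
    if len(labels) < 4:
        return set()
    bit = leaf_bit_index(labels)
    masks, full = clade_masks(_unrooted_copy(tree), bit)
    inv = {i: lab for lab, i in bit.items()}
    out = set()
    for node, m in masks.items():
        if m in (0, full):
            continue
        side = frozenset(inv[i] for i in range(len(bit)) if m >> i & 1)
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue
        out.add(Split(side, uni))
    return out


def tree_split_nodes(tree: dendropy.Tree, universe):
    """(split, node) pairs for a tree's internal edges, for support
    annotation.  Operates on the tree as rooted; splits are canonical."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if len(labels) < 4:
        return []
    bit = leaf_bit_index(labels)
    masks, full = clade_masks(tree, bit)
    inv = {i: lab for lab, i in bit.items()}
    out = []
    for node, m in masks.items():
        if m in (0, full) or node.parent_node is None:
            continue
        side = frozenset(inv[i] for i in range(len(bit)) if m >> i & 1)
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue
        out.append((Split(side, tuple(sorted(universe))), node))
    return out


@dataclass
class SplitSystem:
    """Splits with frequencies over a taxon universe, at a threshold.

    Trivial (single-taxon) splits are always present with frequency 1.
    ``denominators`` records, per split, how many trees contained all of
    its taxa (the frequency denominator); ``incompatible_pairs`` flags
    retained pairs that conflict.
    """

    universe: tuple[str, ...]
    frequencies: dict
    threshold: float
    denominators: dict = field(default_factory=dict)
    incompatible_pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.universe = tuple(sorted(self.universe))
        for sp, f in self.frequencies.items():
            if not 0.0 < f <= 1.0:
                raise InputError("split frequencies must be in (0, 1]")
            if sp.universe != self.universe:
                raise InputError("split universe mismatch")
        for lab in self.universe:
            triv = Split(frozenset({lab}), self.universe)
            self.frequencies.setdefault(triv, 1.0)

    @property
    def nontrivial(self) -> dict:
        return {s: f for s, f in self.frequencies.items() if not s.is_trivial}

    def is_compatible_system(self) -> bool:
        return not self.incompatible_pairs


def consensus_network(trees: GeneTreeSet, threshold: float = 0.12) -> SplitSystem:
    """Split system of all splits at frequency >= threshold.

    The frequency denominator for a split counts only the trees that
    contain all taxa of the universe it partitions (trees missing taxa
    are skipped for that split).  Raising the threshold never adds
    splits; above 0.5 the retained system is pairwise compatible.
    """
    if len(trees) == 0:
        raise InputError("empty tree set")
    if not 0.0 < threshold <= 1.0:
        raise InputError("threshold must be in (0, 1]")
    universe = trees.taxon_universe
    counts: dict[Split, int] = {}
    denom: dict[Split, int] = {}
    full_set = set(universe)
    n_full = 0
    for t in trees:
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        complete = leaves == full_set
        if complete:
            n_full += 1
        for sp_local in tree_splits(t):
            if not complete:
                # lift to the full universe only when all taxa present
                continue
            sp = Split(sp_local.side, universe)
            counts[sp] = counts.get(sp, 0) + 1
    retained = {}
    for sp, c in counts.items():
        if n_full == 0:
            continue
        f = c / n_full
        if f >= threshold:
            retained[sp] = f
            denom[sp] = n_full
    incompat = []
    items = sorted(retained, key=lambda s: s.encoding())
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if not a.compatible_with(b):
                incompat.append((a, b))
    return SplitSystem(
        universe=universe,
        frequencies=retained,
        threshold=threshold,
        denominators=denom,
        incompatible_pairs=incompat,
    )


# ---------------------------------------------------------------------------
# NEXUS export (SplitsTree TAXA + ST_SPLITS blocks)


def export_splits_nexus(system: SplitSystem, path) -> None:
    """Write the split system as a SplitsTree-compatible NEXUS file.

    Weights are the split frequencies; each matrix row lists the taxon
    indices (1-based, in declared universe order) of the split side not
    containing the first taxon.  Round-trips through
    :func:`read_splits_nexus`.
    """
    taxa = system.universe
    index = {lab: i + 1 for i, lab in enumerate(taxa)}
    rows = sorted(system.nontrivial.items(), key=lambda kv: kv[0].encoding())
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)};\nTAXLABELS\n")
        for lab in taxa:
            fh.write(f"  '{lab}'\n")
        fh.write(";\nEND;\n\nBEGIN ST_SPLITS;\n")
        fh.write(f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(rows)};\n")
        fh.write("FORMAT LABELS=NO WEIGHTS=YES;\n")
        fh.write(f"THRESHOLD={system.threshold:.6g};\n")
        fh.write("MATRIX\n")
        for sp, f in rows:
            ids = " ".join(str(index[lab]) for lab in sorted(sp.side, key=index.get))
            fh.write(f"  {f:.6g} {ids},\n")
        fh.write(";\nEND;\n")


def read_splits_nexus(path) -> SplitSystem:
    """Read a split system written by :func:`export_splits_nexus`."""
    taxa: list[str] = []
    freqs: dict = {}
    threshold = 1.0
    mode = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("TAXLABELS"):
                mode = "taxa"
                continue
            if upper.startswith("MATRIX"):
                mode = "matrix"
                continue
            if upper.startswith("THRESHOLD"):
                threshold = float(line.rstrip(";").split("=")[1])
                continue
            if line.startswith(";") or upper.startswith("END"):
                mode = None
                continue
            if mode == "taxa":
                taxa.append(line.strip("'\""))
            elif mode == "matrix":
                parts = line.rstrip(",").split()
                weight = float(parts[0])
                side = frozenset(taxa[int(i) - 1] for i in parts[1:])
                freqs[Split(side, tuple(taxa))] = weight
    if not taxa:
        raise InputError("no TAXA block found")
    universe = tuple(sorted(taxa))
    fixed = {Split(sp.side, universe): w for sp, w in freqs.items()}
    items = sorted(fixed, key=lambda s: s.encoding())
    incompat = [
        (a, b)
        for i, a in enumerate(items)
        for b in items[i + 1 :]
        if not a.compatible_with(b)
    ]
    return SplitSystem(
        universe=universe, frequencies=fixed, threshold=threshold,
        incompatible_pairs=incompat,
    )


def splits_table(system: SplitSystem, path) -> None:
    """TSV: split encoding, frequency, compatibility flag."""
    conflicted = set()
    for a, b in system.incompatible_pairs:
        conflicted.add(a)
        conflicted.add(b)
    with open(path, "w") as fh:
        fh.write("split\tfrequency\tn_trees\tconflicts\n")
        for sp in sorted(system.nontrivial, key=lambda s: s.encoding()):
            fh.write(
                "{}\t{:.6g}\t{}\t{}\n".format(
                    ",".join(sp.encoding()),
                    system.frequencies[sp],
                    system.denominators.get(sp, ""),
                    int(sp in conflicted),
                )
            )
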