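"""Synthetic data under the multispecies coalescent (MSC).

Generates the four kinds of input the analysis assumes:

* gene trees drawn under the MSC on a rooted species tree in coalescent
  units, with optional instantaneous introgression pulses (each
  recipient-side lineage alive at the pulse time moves to the donor
  branch independently with probability gamma);
* nucleotide fragments evolved along those trees under JC69;
* pairwise codon alignments with a controlled dN/dS ratio (omega);
* single-sample genotype tables with controlled heterozygosity and
  Poisson depth noise.

For a species-tree internal branch of length T coalescent units above a
three-taxon clade, the expected fraction of discordant gene trees is
(2/3) e^(-T); the simulator is checked against that closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._util import ConfigurationError, InputError, substream
from .fragments import AlignmentFragment
from .genetrees import GeneTreeSet

# ---------------------------------------------------------------------------
# species-tree model


@dataclass
class IntrogressionEvent:
    """Instantaneous pulse of gene flow from donor into recipient.

    Donor and recipient branches are identified by the leaf-label sets
    of the clades they subtend (a single label names a pendant branch).
    ``time`` is measured in coalescent units before the present and must
    fall strictly within the lifespan of both branches.
    """

    donor: tuple[str, ...]
    recipient: tuple[str, ...]
    time: float
    gamma: float

    def __post_init__(self):
        self.donor = tuple(sorted(self.donor if not isinstance(self.donor, str) else [self.donor]))
        self.recipient = tuple(
            sorted(self.recipient if not isinstance(self.recipient, str) else [self.recipient])
        )
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError("gamma must be in [0, 1]")
        if self.time < 0:
            raise ConfigurationError("event time must be >= 0")


class SpeciesTreeModel:
    """Rooted binary species tree in coalescent units, plus pulses.

    The newick branch lengths are coalescent units (time scaled by 2N);
    the tree must be ultrametric so that node ages are well defined.
    """

    def __init__(self, tree, introgression_events=(), seed: int | None = None):
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
        self.tree = tree
        self.seed = seed
        self.events = [
            ev if isinstance(ev, IntrogressionEvent) else IntrogressionEvent(*ev)
            for ev in introgression_events
        ]
        self._prepare()

    def _prepare(self):
        tree = self.tree
        self.leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        # node ages from branch lengths; require consistency (ultrametric)
        age: dict = {}
        self.clade: dict = {}
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if not kids:
                age[node] = 0.0
                self.clade[node] = (node.taxon.label,)
                continue
            if len(kids) != 2:
                raise ConfigurationError("species tree must be binary")
            ages = []
            for ch in kids:
                if ch.edge.length is None or ch.edge.length < 0:
                    raise ConfigurationError("species tree needs non-negative branch lengths")
                ages.append(age[ch] + ch.edge.length)
            if abs(ages[0] - ages[1]) > 1e-8:
                raise ConfigurationError("species tree is not ultrametric")
            age[node] = ages[0]
            self.clade[node] = tuple(sorted(sum((self.clade[c] for c in kids), ())))
        self.age = age
        self.root = tree.seed_node
        self._by_clade = {cl: nd for nd, cl in self.clade.items()}
        # stable branch indices (preorder) for deterministic iteration
        self.branch_index = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
        # merge schedule: internal nodes by age; on exact age ties a child
        # must merge before its parent (higher preorder index first)
        self.merges = sorted(
            (nd for nd in age if nd.child_nodes()),
            key=lambda nd: (age[nd], -self.branch_index[nd]),
        )
        for ev in self.events:
            self._validate_event(ev)

    def _branch_interval(self, clade) -> tuple[float, float]:
        node = self._by_clade.get(tuple(sorted(clade)))
        if node is None:
            raise ConfigurationError(f"no species-tree branch subtends clade {clade}")
        top = self.age[node.parent_node] if node.parent_node else float("inf")
        return self.age[node], top

    def _validate_event(self, ev: IntrogressionEvent):
        for clade in (ev.donor, ev.recipient):
            lo, hi = self._branch_interval(clade)
            if not (lo < ev.time < hi):
                raise ConfigurationError(
                    f"event time {ev.time} outside branch lifespan ({lo}, {hi}) of {clade}"
                )
        if ev.donor == ev.recipient:
            raise ConfigurationError("donor and recipient branches must differ")

    def node_for(self, clade):
        return self._by_clade[tuple(sorted(clade))]

    def to_config(self) -> str:
        lines = [
            "newick = "
            + self.tree.as_string(schema="newick", suppress_rooting=True).strip(),
            f"seed = {self.seed if self.seed is not None else ''}",
        ]
        for ev in self.events:
            lines.append(
                "pulse = {} -> {} @ {} gamma {}".format(
                    ",".join(ev.donor), ",".join(ev.recipient), ev.time, ev.gamma
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SpeciesTreeModel":
        newick, seed, events = None, None, []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "newick":
                newick = value
            elif key == "seed":
                seed = int(value) if value else None
            elif key == "pulse":
                left, _, rest = value.partition("->")
                mid, _, tail = rest.partition("@")
                t_str, _, g_str = tail.partition("gamma")
                events.append(
                    IntrogressionEvent(
                        tuple(left.strip().split(",")),
                        tuple(mid.strip().split(",")),
                        float(t_str),
                        float(g_str),
                    )
                )
        if newick is None:
            raise ConfigurationError("config lacks a newick line")
        return cls(newick, events, seed=seed)


# ---------------------------------------------------------------------------
# gene-tree simulation


def _coalesce(pop, rng, t0, t1, tn):
    """Coalesce lineages in one population between times t0 and t1.

    ``pop`` is a list of (dendropy node, node age); pairs merge at rate
    k(k-1)/2 per coalescent unit.  Mutates and returns the list.
    """
    t = t0
    while len(pop) >= 2:
        k = len(pop)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t >= t1:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        node_j, age_j = pop.pop(j)
        node_i, age_i = pop.pop(i)
        parent = dendropy.Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.edge.length = t - age_i
        node_j.edge.length = t - age_j
        pop.append((parent, t))
    return pop


def _simulate_one_tree(model: SpeciesTreeModel, rng, tn) -> dendropy.Tree:
    pops: dict = {}
    for lf in model.tree.leaf_node_iter():
        taxon = tn.get_taxon(lf.taxon.label) or tn.new_taxon(lf.taxon.label)
        pops[lf] = [(dendropy.Node(taxon=taxon), 0.0)]
    # schedule: species-node merges and pulses, time-ordered (merges first
    # on exact ties so a branch has ceased before a pulse at its top).
    schedule = [(model.age[nd], 0, ("merge", nd)) for nd in model.merges]
    schedule += [(ev.time, 1, ("pulse", ev)) for ev in model.events]
    schedule.sort(key=lambda x: (x[0], x[1]))
    t_now = 0.0
    for t_ev, _, (kind, payload) in schedule:
        for branch in sorted(pops, key=model.branch_index.get):
            _coalesce(pops[branch], rng, t_now, t_ev, tn)
        if kind == "merge":
            merged = []
            for ch in payload.child_nodes():
                merged.extend(pops.pop(ch, []))
            pops[payload] = merged
        else:
            ev = payload
            rec = model.node_for(ev.recipient)
            don = model.node_for(ev.donor)
            stay, move = [], []
            for lin in pops.get(rec, []):
                (move if rng.random() < ev.gamma else stay).append(lin)
            pops[rec] = stay
            pops.setdefault(don, []).extend(move)
        t_now = t_ev
    root_pop = pops[model.root]
    _coalesce(root_pop, rng, t_now, float("inf"), tn)
    root_node, _ = root_pop[0]
    tree = dendropy.Tree(taxon_namespace=tn, seed_node=root_node)
    tree.is_rooted = True
    return tree


def simulate_gene_trees(
    model: SpeciesTreeModel, n_loci: int, seed: int | None = None
) -> GeneTreeSet:
    """Draw independent MSC gene trees, branch lengths in coalescent units.

    Each locus gets its own deterministic RNG sub-stream derived from the
    seed (``model.seed`` when no explicit seed is given), so any single
    locus is reproducible in isolation.
    """
    if n_loci < 1:
        raise InputError("n_loci must be >= 1")
    seed = model.seed if seed is None else seed
    tn = dendropy.TaxonNamespace(model.leaves)
    trees = []
    for locus in range(n_loci):
        rng = substream(seed, 10, locus)
        trees.append(_simulate_one_tree(model, rng, tn))
    return GeneTreeSet(trees, tn, [f"locus{idx}" for idx in range(n_loci)])


# ---------------------------------------------------------------------------
# sequence simulation


@dataclass
class SimSequenceParams:
    """JC69 sequence evolution: ``scale`` converts one unit of gene-tree
    branch length into expected substitutions per site."""

    locus_length: int = 20_000
    scale: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if self.locus_length < 1:
            raise InputError("locus_length must be >= 1")
        if self.scale < 0:
            raise InputError("scale must be >= 0")


def simulate_sequences(
    tree: dendropy.Tree,
    params: SimSequenceParams,
    chrom: str = "sim",
    index: int = 0,
) -> AlignmentFragment:
    """Evolve a gap-free alignment along a gene tree under JC69.

    Under JC69 an expected ``d`` substitutions/site gives an observed
    proportion of differing sites p = (3/4)(1 - e^(-4d/3)).
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InputError("tree must have at least 2 leaves")
    L = params.locus_length
    rng = substream(params.seed, 20, index)
    seqs: dict = {}
    root = tree.seed_node
    seqs[root] = rng.integers(0, 4, size=L, dtype=np.uint8)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length or 0.0
        d = params.scale * bl
        parent_seq = seqs[node.parent_node]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        child = parent_seq.copy()
        hit = rng.random(L) < p_change
        n_hit = int(hit.sum())
        if n_hit:
            shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
            child[hit] = (child[hit] + shift) % 4
        seqs[node] = child
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    taxa = sorted(lf.taxon.label for lf in leaves)
    by_label = {lf.taxon.label: seqs[lf] for lf in leaves}
    data = np.vstack([alphabet[by_label[t]] for t in taxa])
    return AlignmentFragment(
        taxa=tuple(taxa), sequences=data, chrom=chrom, index=index, start=0, end=L
    )


# ---------------------------------------------------------------------------
# codon-pair simulation


@dataclass
class SimCodonParams:
    """Pairwise codon divergence with a controlled dN/dS ratio.

    ``divergence`` is the expected number of proposed single-nucleotide
    mutations per codon site (split evenly between the two lineages)
    before selection; nonsynonymous proposals are accepted with relative
    probability ``omega`` (synonymous with relative probability 1).
    Mutations creating stop codons are always rejected.
    """

    n_codons: int = 500
    divergence: float = 1.0
    omega: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_codons < 1:
            raise InputError("n_codons must be >= 1")
        if self.omega < 0:
            raise InputError("omega must be >= 0")
        if self.divergence < 0:
            raise InputError("divergence must be >= 0")


_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in _CODONS if c not in _STOPS]

_AA = {}


def _translate(codon: str) -> str:
    if not _AA:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        table = unambiguous_dna_by_id[1]
        for c in _SENSE:
            _AA[c] = table.forward_table[c]
    return _AA[codon]


def simulate_codon_pair(params: SimCodonParams, ortholog_id: str = "sim"):
    """Two homologous codon sequences diverged under proposal/selection.

    Returns a :class:`~phyloconflict.kaks.CodonAlignment`.
    """
    from .kaks import CodonAlignment

    rng = substream(params.seed, 30)
    anc = [_SENSE[int(i)] for i in rng.integers(0, len(_SENSE), size=params.n_codons)]
    p_acc_nonsyn = params.omega / max(1.0, params.omega)
    p_acc_syn = 1.0 / max(1.0, params.omega)

    def _evolve(codons):
        codons = list(codons)
        n_events = rng.poisson(0.5 * params.divergence * params.n_codons)
        for _ in range(int(n_events)):
            site = int(rng.integers(params.n_codons))
            pos = int(rng.integers(3))
            old = codons[site]
            alt = _BASES[int(rng.integers(4))]
            if alt == old[pos]:
                continue
            new = old[:pos] + alt + old[pos + 1 :]
            if new in _STOPS:
                continue  # purifying rejection of nonsense changes
            syn = _translate(new) == _translate(old)
            p_acc = p_acc_syn if syn else p_acc_nonsyn
            if rng.random() < p_acc:
                codons[site] = new
        return "".join(codons)

    seq_a = _evolve(anc)
    seq_b = _evolve(anc)
    return CodonAlignment(ortholog_id=ortholog_id, seqs=(seq_a, seq_b))


# ---------------------------------------------------------------------------
# genotype simulation


def simulate_genotypes(
    n_sites: int,
    het_rate: float,
    mean_depth: float,
    seed: int | None = None,
    missing_rate: float = 0.0,
    hom_alt_rate: float = 0.0,
    depth_outlier_rate: float = 0.0,
    chrom: str = "sim1",
):
    """Single-sample genotype table with controlled heterozygosity.

    Genotype classes are drawn i.i.d. per site (het with probability
    ``het_rate``); read depth is Poisson(``mean_depth``) except for an
    optional fraction of outlier sites whose depth is drawn at 8x or
    0.1x the mean (half each), which the depth filter should remove.
    Returns a :class:`~phyloconflict.diversity.GenotypeTable`.
    """
    from .diversity import GenotypeTable

    if not 0.0 <= het_rate <= 1.0:
        raise InputError("het_rate must be in [0, 1]")
    if n_sites < 1:
        raise InputError("n_sites must be >= 1 (empty table)")
    rng = substream(seed, 40)
    u = rng.random(n_sites)
    gt = np.zeros(n_sites, dtype=np.int8)  # 0 hom-ref
    gt[u < het_rate + hom_alt_rate + missing_rate] = 2
    gt[u < het_rate + missing_rate] = -1
    gt[u < het_rate] = 1
    depth = rng.poisson(mean_depth, size=n_sites)
    if depth_outlier_rate > 0:
        out = rng.random(n_sites) < depth_outlier_rate
        hi = rng.random(n_sites) < 0.5
        depth = np.where(out & hi, rng.poisson(8.0 * mean_depth, size=n_sites), depth)
        depth = np.where(out & ~hi, rng.poisson(0.1 * mean_depth, size=n_sites), depth)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1),  # VCF convention, 1-based
            "gt": gt,
            "depth": depth.astype(int),
        }
    )
    return GenotypeTable(df)
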