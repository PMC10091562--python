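import dendropy
import numpy as np
import pytest

from phyloconflict import datasets, simdata
from phyloconflict.fragments import AlignmentFragment, WgaBlock


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def balanced_tree():
    return dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick", preserve_underscores=True
    )


@pytest.fixture(scope="session")
def three_taxon_trees():
    """Gene trees from the T = ln 2 reference model (1/3 discordance)."""
    model = datasets.three_taxon_model(np.log(2.0), seed=99)
    return simdata.simulate_gene_trees(model, 5000)


def random_block(rng, n_taxa=6, length=1200, p_var=0.1, chrom="chr1"):
    """Random gap-free alignment block with ~p_var variable columns."""
    base = rng.integers(0, 4, size=length)
    data = np.tile(base, (n_taxa, 1))
    var = rng.random(length) < p_var
    for j in np.flatnonzero(var):
        k = int(rng.integers(1, n_taxa))
        rows = rng.choice(n_taxa, size=k, replace=False)
        data[rows, j] = (data[rows, j] + int(rng.integers(1, 4))) % 4
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return WgaBlock(
        taxa=tuple(f"t{i}" for i in range(n_taxa)),
        data=alphabet[data],
        chrom=chrom,
    )


def fragment_from_strings(seqs, taxa=None, index=0):
    taxa = taxa or tuple(f"t{i}" for i in range(len(seqs)))
    arr = np.vstack(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    )
    return AlignmentFragment(
        taxa=tuple(taxa), sequences=arr, chrom="chr1", index=index,
        start=0, end=arr.shape[1],
    )
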