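"""Bundled demonstration inputs: a baleen-whale species tree, a body-size
trait table, and the "rapid radiation" simulation scenario.

The mysticete topology follows the consensus arrangement of the three
baleen whale families — Balaenidae (right whales and bowhead),
Cetotheriidae (the pygmy right whale, sole survivor of the family) and
Balaenopteridae (rorquals) — with the gray whale grouped with the
fin + humpback pair and a blue + rice whale sister clade, and the
bottlenose dolphin as outgroup.  The contested placement of the gray
whale at the base of that arrangement is the motivating example for
the conflict analyses.

The trait values are a SYNTHETIC compilation of typical adult body
sizes from the general literature (not measurements shipped with any
particular study); only their ranking matters for the demonstrations.
"""

from __future__ import annotations

import io

import dendropy
import pandas as pd

from .simdata import IntrogressionEvent, SpeciesTreeModel

#: Rooted mysticete topology (branch lengths omitted; outgroup dolphin).
MYSTICETE_NEWICK = (
    "(dolphin,((bowhead,(right_NA,right_NP)),(pygmy_right,"
    "((minke_antarctic,minke_common),(sei,((gray,(fin,humpback)),(blue,rice)))))));"
)


def mysticete_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=MYSTICETE_NEWICK, schema="newick", preserve_underscores=True)


_TRAITS_TSV = """taxon\tbody_length_m\tbody_mass_t
bowhead\t18.0\t90.0
pygmy_right\t6.5\t3.4
fin\t24.0\t70.0
minke_common\t8.5\t9.0
blue\t27.0\t150.0
rice\t12.5\t27.0
"""


def whale_traits() -> pd.DataFrame:
    """Synthetic body-size table for the six screen candidates."""
    df = pd.read_csv(io.StringIO(_TRAITS_TSV), sep="\t")
    return df.set_index("taxon", drop=False)


def rorqual_like_model(
    contested_branch: float = 0.02,
    gamma: float = 0.3,
    seed: int | None = None,
) -> SpeciesTreeModel:
    """Simulation scenario for a rapid radiation with gene flow.

    Six taxa mirror the contested part of the rorqual radiation: the
    branch joining the gray whale + (fin, humpback) clade to the
    (blue, rice) clade is near zero (``contested_branch`` coalescent
    units), so its quartets show nearly equal support for all three
    resolutions, while two introgression pulses between the common
    minke whale and the pygmy right whale (probability ``gamma`` per
    lineage, one in each direction) add a strongly shifted class of
    triplet internal branch lengths for the mixture test to find.

    The pulses deliberately connect two lineages on the same side of
    the contested branch: gene flow ACROSS that branch at an
    appreciable rate would by itself skew the quartet balance away
    from the near-1/3 pattern the scenario is meant to exhibit.

    Divergence times (coalescent units): (fin, humpback) 1.0, gray
    joins at 2.0, (blue, rice) 1.5, the two clades join at
    2.0 + ``contested_branch``, minke_common at 4.0, pygmy_right at
    6.0.  Pulses: minke_common <- pygmy_right at 1.0 and
    pygmy_right <- minke_common at 2.0 (recipient lineages move to the
    donor branch, backwards in time).
    """
    t_join = 2.0 + contested_branch
    newick = (
        "((((gray:2.0,(fin:1.0,humpback:1.0):1.0):{cb},"
        "(blue:1.5,rice:1.5):{br}):{mk},minke_common:4.0):2.0,"
        "pygmy_right:6.0);".format(
            cb=contested_branch, br=t_join - 1.5, mk=4.0 - t_join
        )
    )
    events = [
        IntrogressionEvent(("pygmy_right",), ("minke_common",), 1.0, gamma),
        IntrogressionEvent(("minke_common",), ("pygmy_right",), 2.0, gamma),
    ]
    return SpeciesTreeModel(newick, events, seed=seed)


def three_taxon_model(T: float, seed: int | None = None) -> SpeciesTreeModel:
    """((A,B),C) with internal branch T coalescent units.

    The reference case for the MSC discordance law: the probability
    that a gene tree is discordant is (2/3) e^(-T).
    """
    newick = f"((A:1.0,B:1.0):{T},C:{1.0 + T});"
    return SpeciesTreeModel(newick, seed=seed)


def write_trait_table(path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRAITS_TSV)
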