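# phyloconflict

Phylogenomic conflict analysis for rapid radiations, and a paired Ka/Ks
selection screen for body-size evolution.

When a clade radiates quickly — the textbook case being the rorquals, where
the gray whale's position is contested — individual gene trees disagree with
any single species tree.  Two processes produce that discordance: incomplete
lineage sorting (ILS), which under the multispecies coalescent (MSC) makes a
gene tree discordant with probability (2/3)·e^(−T) across an internal branch
of T coalescent units, and introgression, which both skews discordant-topology
frequencies and shifts the distribution of triplet internal branch lengths.
`phyloconflict` quantifies and disentangles the two:

* **Quartet support** — for every internal branch of a species tree, the
  normalized frequencies q1, q2, q3 of the three possible resolutions among a
  gene-tree set; a branch with q1 ≈ q2 ≈ q3 ≈ 1/3 behaves as a hard polytomy.
* **Branch-length mixture test** — per triplet, discordant internal branch
  lengths t are fitted under H0 (ILS only): t ~ λe^(−λt), and H1 (ILS +
  introgression): (1−π₂)λ₁e^(−λ₁t) + π₂λ₂e^(−λ₂(t−C))·1[t≥C], by EM;
  introgression is called when ΔBIC = BIC_H1 − BIC_H0 < −10.
* **Consensus networks** — all splits above a frequency threshold (default
  12%), with incompatible pairs flagged, exported as SplitsTree-compatible
  NEXUS.
* **Selection screen** — phylogenetically independent large/small species
  pairs maximizing the standardized body-size contrast, NG86 Ka/Ks per
  ortholog and pair, Ka/Ks > 1 candidate sets (per pair, union,
  intersection), and hypergeometric term enrichment with BH correction.
* **Supporting stages** — whole-genome-alignment fragment extraction (gap
  purging, 20-kbp fragments, 1-kbp windows, variability trim), JC + neighbor
  joining gene trees, genome-wide heterozygosity with depth/missingness
  filters, and an MSC simulator (gene trees with introgression pulses, JC69
  sequences, codon pairs with controlled dN/dS, genotype tables) so every
  stage runs without genome-scale data.

The intended users are phylogenomicists studying radiations with gene-tree
conflict and comparative genomicists running pairwise selection screens.

## Worked example

Run the conflict pipeline on the bundled rapid-radiation scenario — seven
whale-like taxa, a 0.02-coalescent-unit contested branch, two γ = 0.3
introgression pulses — with 2,000 simulated loci:

```bash
phyloconflict run-conflict --seed 7 --n-loci 2000 --out-dir demo_out
```

prints

```
contested branch B2: q = [0.351062, 0.312875, 0.336062] (max deviation 0.020458)
5/35 triplets with introgression; 3 incompatible split pairs
```

Reading this: the contested branch receives nearly identical support for all
three resolutions (each q within 0.02 of 1/3) — the quartet signature of a
hard polytomy, indistinguishable from a star divergence.  Yet the
branch-length mixture test still resolves *why* trees disagree: exactly the 5
triplets touching the simulated introgression pulses are called introgression
(ΔBIC < −10), while triplets affected only by ILS are not.  At the 12%
threshold the split system retains 3 mutually incompatible split pairs — the
conflict structure a consensus network displays.  `demo_out/` contains the
per-branch quartet table, the per-triplet test table, the split system
(`splits.nex`, loadable in SplitsTree) and a JSON summary; re-running with the
same seed reproduces every file byte for byte.

The selection-screen side, on the bundled whale topology and body-size table:

```python
from phyloconflict import datasets, kaks

pairs = kaks.phylogenetic_targeting(
    datasets.mysticete_tree(), datasets.whale_traits(), outgroup="dolphin"
)
for p in pairs.pairs:
    print(f"{p.large:<12} {p.small:<14} contrast {p.contrast:.2f}")
```

```
blue         rice           contrast 2.18
bowhead      pygmy_right    contrast 1.53
fin          minke_common   contrast 1.08
```

These are the three branch-disjoint pairs maximizing the summed standardized
mass contrast (4.79): each pairs a giant with a small relative, and no two
pairs share a tree branch, so their Ka/Ks comparisons are phylogenetically
independent.  `phyloconflict run-selection` continues from here through
simulated codon alignments to the Ka/Ks > 1 candidate sets and an enrichment
table.

## Layout

```
src/phyloconflict/
  simdata.py     MSC gene trees, JC69 sequences, codon pairs, genotypes
  fragments.py   WGA blocks -> gap-free fragments and windows
  genetrees.py   JC distances, neighbor joining, newick I/O
  conflict.py    quartet support, greedy consensus, window profiles
  quibl.py       triplet extraction, exponential/mixture fits, calls
  splits.py      split systems, consensus networks, NEXUS export
  kaks.py        NG86, targeting, screen, enrichment
  diversity.py   heterozygosity with depth/missingness filters
  pipeline.py    end-to-end pipelines + plain-text config
  cli.py         `phyloconflict` command-line interface
docs/methods.md  models, parameters, numerical choices, limitations
```
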