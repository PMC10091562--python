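# Methods

## Scope

`phyloconflict` implements a phylogenomic conflict analysis for clades that
radiated rapidly, where gene trees disagree with any single species tree, and a
paired Ka/Ks selection screen contrasting large- and small-bodied species.  The
motivating system is the baleen-whale radiation: the position of the gray whale
among the rorquals behaves as a hard polytomy, and body size (hence, under
Peto's paradox, cancer resistance) evolved repeatedly.  All stages run on
synthetic data produced by the package's own multispecies-coalescent (MSC)
generator, so every result below is reproducible without genome-scale inputs.

## The multispecies coalescent generator

Gene trees are simulated backwards in time within a rooted, ultrametric,
binary species tree whose branch lengths are **coalescent units** (1 unit =
2N generations for diploids).  Within a species-tree branch carrying k
lineages, pairs coalesce at rate k(k−1)/2 per unit; at each species-tree node
the child populations merge.  Introgression is a **pulse**: at a fixed time,
each lineage present in the recipient branch moves to the donor branch
independently with probability γ.  This is the simplest mechanism that
produces the second, shifted class of triplet internal branch lengths that the
mixture test looks for.

For a triplet with internal species-tree branch T, the probability that a gene
tree is discordant is (2/3)·e^(−T).  The simulator is validated against this
closed form at T ∈ {0, ln 2, 2} with 30,000 loci (3-SE binomial bands) and
against msprime as an independent coalescent implementation.

Nucleotide fragments evolve along gene trees under JC69; a scale parameter d
converts coalescent-unit branch lengths to expected substitutions/site, so the
MSC arithmetic stays exact and sequence noise is a separate, controllable
layer.  Codon pairs diverge by proposing uniform single-nucleotide changes
(`divergence` proposals per codon site, split between the two lineages);
nonsynonymous proposals are accepted with relative probability ω, proposals
creating stop codons are always rejected.  Under this proposal distribution
NG86's site counting is exactly calibrated, so ω = 1 yields Ka/Ks ≈ 1.
Genotype tables draw per-site genotype classes i.i.d. with a controlled
heterozygosity and Poisson read depth, with optional depth-outlier and
missingness contamination for exercising the filters.

Randomness: one integer seed; every locus, replicate and stage derives a
deterministic sub-stream (`numpy` `SeedSequence` keyed by small integers), so
identical (inputs, seed) runs are byte-identical and any single locus can be
re-simulated in isolation.

### The rapid-radiation ("rorqual-like") scenario

`datasets.rorqual_like_model()` is the package's standing demonstration: seven
taxa (gray, fin, humpback, blue, rice, common minke, pygmy right) with the
branch joining {gray, fin, humpback} to {blue, rice} set to 0.02 coalescent
units — effectively a hard polytomy — plus two γ = 0.3 pulses between the
common minke and pygmy right lineages (times 1.0 and 2.0, one in each
direction).

The pulse placement is a deliberate design choice.  A pulse *straddling* the
contested branch at γ = 0.3 would shift that branch's quartet support by
roughly γ × P(moved lineage coalesces on the donor side) ≈ 0.2, destroying the
near-equal q1 ≈ q2 ≈ q3 pattern the scenario is meant to exhibit.  Placing
both pulses between two taxa on the same side of the contested branch (and in
the same quartet group around it) makes them invisible to that branch's
quartets while still producing a strongly shifted branch-length class: the
moved lineage coalesces with its new neighbour long before the ordinary
speciation time, so affected triplets carry internal branches shifted by
several coalescent units — easily separable from the ILS exponential.

## Quartet support

For each internal branch of an unrooted species tree with surrounding taxon
groups A, B (child side) and C, D (parent side), quartets take one leaf from
each group and each gene tree votes for one of the three resolutions:
q1 = AB|CD (the species-tree resolution), q2 = AC|BD, q3 = AD|BC.  Votes are
found by scanning the gene tree's bipartition bitmasks restricted to the four
leaves — exact, and fast enough for thousands of trees.  Quartet spaces larger
than `sampling_limit` (default 10,000) are sampled uniformly with replacement
with the seeded generator.  Unresolved (multifurcating) quartets are excluded
from the denominator so q1+q2+q3 = 1.  Support is computed for a *given*
species tree (scoring, not search); the default species tree is the greedy
consensus of the gene trees.  Implementation is verified by exact agreement
with per-quartet brute force (tree restriction) on 6-taxon/50-tree instances.

The greedy consensus ranks unrooted splits by frequency (ties broken by the
lexicographic label encoding of the canonical split side) and adds each split
compatible with all previously accepted ones; all majority splits are
necessarily included and the result may be multifurcating.

## The branch-length mixture test

For a triplet, discordant gene trees under ILS alone have internal branch
lengths t ~ Exp(λ); introgression adds a class shifted away from zero.  H1 is

    f(t) = (1−π₂)·λ₁e^(−λ₁t) + π₂·λ₂e^(−λ₂(t−C))·1[t ≥ C]

fitted by EM: responsibilities and rate updates are closed-form; the shift C
moves by a line search whose step halves (shrink factor 0.5) on
non-improvement.  Iteration stops when the log-likelihood gain falls below
0.01 or after 50 steps (both configurable; the defaults are the analysis
constants used throughout).  Four documented starts — (π₂, C) ∈ {(0.1, 0),
(0.5, median), (0.3, q75), (0.05, 0)} — guard against local optima; the best
final likelihood is kept.

Two numerical guards exclude the classic mixture degeneracy (a component
collapsing onto one observation with λ₂ → ∞): C may not exceed the
5th-largest observation, and rates are capped at 10⁶.  Topologies with fewer
than 20 observations are reported "insufficient-data" (EM is unstable below
that).

Model comparison: BIC = k·ln n − 2·logL with k(H0) = 1 and k(H1) = 4, n the
number of branch-length observations for the tested topology; introgression is
called iff ΔBIC = BIC_H1 − BIC_H0 < −10 (a strict cutoff).  By default only
the two discordant topologies are tested (the concordant one can be included
with a flag).  The triplet's introgressed fraction of the total tree set is
Σ frequency(topology)·π̂₂ over topologies called introgression; the ILS-only
fraction is the remaining discordance.  Error rates under the defaults:
false-positive rate 0–2% on pure exponential panels (n = 1000), ≥ 90%
detection with |π̂₂ − π₂| ≤ 0.1 when the second class is well separated.

Branch-length units cancel in the test (it is scale-free); mixing units within
one panel is nevertheless rejected at the interface level by requiring a
single tree set per panel.

## Consensus networks

The split system of a tree set keeps every non-trivial unrooted split whose
frequency reaches the threshold (default 12%).  Frequencies are computed over
trees containing the full taxon set (recorded per split); retained pairs are
flagged incompatible when all four side-intersections are non-empty.  Raising
the threshold never adds splits, and above 50% the system is necessarily
compatible.  The package computes the split system and conflict flags, not the
planar splits-graph drawing; a SplitsTree-compatible NEXUS export (TAXA +
ST_SPLITS blocks, weights = frequencies) is provided and round-trips through
the package's own reader.

## Fragments, windows, distance trees

Whole-genome-alignment blocks are purged column-wise: any column with a gap or
ambiguity (anything outside A/C/G/T, case-insensitive) in *any* taxon is
removed for all taxa, with a column catalog mapping back to original
coordinates.  Gap-free blocks are cut into fixed 20-kbp fragments (trailing
remainder discarded; coordinates 0-based half-open everywhere).  The
variability trim ranks fragments by mean pairwise JC69 distance and removes
the ⌊5%·n⌋ least and most variable (ties broken by fragment index); JC is used
as the monotone desk-scale proxy for ML distances since the filter consumes
only ranks, and the trim is applied over the full fragment set (whether the
original analysis trimmed per chromosome is not determinable; the report
records the choice).  Fragments split into 1-kbp windows; windows with fewer
than 50 parsimony-informative sites (≥ 2 states each in ≥ 2 taxa) are
excluded, and a window with exactly 50 is retained.

Per-fragment trees are JC-distance neighbor-joining trees (Q-criterion, ties
broken by the lexicographic pair of cluster names, negative branch estimates
clamped to zero).  NJ replaces per-fragment ML search: downstream analyses
consume topologies and branch lengths only, external newick tree sets can be
ingested in place of NJ trees, and on 20-kbp JC fragments from well-separated
trees NJ recovers the true topology in ≥ 95% of replicates (a calibration
property of the desk-scale setup, not a claim about real alignments).
Fragments missing taxa are skipped with a log entry; bootstrap support
(seeded column resampling) is available but off by default.

## The selection screen

**Phylogenetic targeting.**  Candidate taxa are those with trait values
(default body mass in tonnes, body length as fallback — the scored trait is
not uniquely determined by convention, so it is explicit and configurable).
Two pairs are phylogenetically independent iff the unrooted tree paths
connecting them share no branch; each pair scores
|trait difference| / SD(trait over candidates); the returned pair set
maximizes the summed score, by exhaustive branch-and-bound for ≤ 14 candidates
and a documented greedy fallback above.  On the bundled whale topology and
body sizes the optimum is {bowhead–pygmy right, fin–common minke, blue–rice}.
The bundled trait table is a synthetic literature-style compilation; only its
ranking matters.

**NG86.**  Fractional synonymous site counts per codon (each position
contributes n_syn/3; changes to stop codons count as nonsynonymous), averaged
over the two sequences; substitution differences averaged over all minimal
pathways with equal weights, pathways through stop codons excluded (if every
pathway is blocked, all pathways are used).  Proportions are Jukes-Cantor
corrected, d = −(3/4)·ln(1 − 4p/3); pS ≥ 0.75 flags saturation, Ks = 0 leaves
the ratio undefined.  The per-gene p-value is a two-sided Fisher exact test on
the rounded substitution/site table.  NG86 was chosen because it is fully
specifiable and exactly checkable against a brute-force pathway-enumeration
oracle over all 61×61 sense-codon pairs; the estimator slot is pluggable.
A subtlety: under purely synonymous evolution (ω = 0) NG86 can report a small
positive Ka, because a codon hit twice synonymously may admit only pathways
whose individual steps are nonsynonymous; the generator-level invariant
(identical proteins) still holds exactly.

**Screen and enrichment.**  Per pair, orthologs first pass the alignment
filters — variable-site fraction must exceed 5% and not exceed 40%, then the
top ⌊5%⌋ by mean pairwise distance are dropped (variability before distance;
the order changes survivors and is fixed) — and genes with Ka/Ks strictly
greater than 1 are collected; the screen reports per-pair sets, the union with
membership, and the intersection across pairs.  Note the distance trim
preferentially removes the fastest-evolving (often genuinely selected)
orthologs, so the intersection is a conservative set — visible in the
simulated panels, where a truly selected gene occasionally drops out of one
pair.  Enrichment is a plain hypergeometric upper-tail test per term with
Benjamini–Hochberg correction (terms with query count ≤ 1 removed before
correction, mirroring the single-occurrence rule); graph-aware GO algorithms
are out of scope and the interface accepts any gene→term map.

## Heterozygosity

Single-sample genotype tables (VCF, GT + DP) are filtered by depth — strict
inequalities, remove depth > 3× or < 0.3× the expected mean — then by
missingness (> 5% missing removes the site; for one sample that is any
missing call, the one defensible per-site reading of a missingness threshold
on a single-genome call set, and it is documented).  Heterozygosity is
n_het / n_retained with monomorphic sites in the denominator, reported both as
a float and an exact rational.  Multi-sample input is rejected.

## Pipelines and problem sizes

`run_conflict_pipeline` chains simulation (or file input) → optional
fragment/window tree building → greedy consensus → per-branch quartet table →
window conflict profile (sequence mode) → triplet panel → split system, and
writes TSV/JSON reports with fixed float formatting so identical (config,
seed) runs are byte-identical.  `run_selection_pipeline` chains targeting →
simulated ortholog panel → alignment filters → NG86 per pair → positive sets →
enrichment.

Default problem sizes are chosen for desk-scale runs: 5,000 loci for the
conflict demonstration (quartet standard errors ≈ 0.01 on the contested
branch), 1,000 sampled trees per triplet test, 30,000 loci for the discordance
law (3-SE bands ≈ 0.008), 20,000 codons for the neutrality calibration, 10⁶
sites for the heterozygosity recovery.  The full acceptance recomputation
(`scripts/acceptance.py`) takes well under a minute of CPU.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analyses assume —
MSC discordance frequencies, pulse-shifted branch-length classes, controlled
ω and heterozygosity — under idealized conditions: no recombination within
loci, no demographic size change, no alignment error, no rate heterogeneity
(JC69 everywhere), i.i.d. genotype sites, and an ortholog panel with exactly
two ω classes.  Passing tests therefore demonstrate correctness of the
implementations and their statistical calibration, not robustness to the
violations real whole-genome alignments exhibit (alignment error, reference
bias, selection on silent sites, GC-biased gene conversion).  Empirical
headline numbers from genome-scale studies are not reproduction targets at
desk scale.

## Known limitations

* Quartet scoring requires ≤ 64 taxa (bitmask representation) and skips
  branches adjacent to multifurcations in the scored species tree.
* The EM mixture's k(H1) = 4 parameter count is a documented convention (the
  shift C is counted); it is configurable where a different convention is
  preferred.
* Triplet extraction requires rooted gene trees; unrooted external tree sets
  must be rooted (e.g. on an outgroup) before the mixture test.
* The NEXUS reader parses the package's own ST_SPLITS dialect, not arbitrary
  SplitsTree files.
* The greedy targeting fallback (> 14 candidates) is not guaranteed optimal;
  the method is reported in the result object.
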