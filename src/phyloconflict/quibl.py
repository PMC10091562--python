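"""ILS-vs-introgression classification from triplet branch lengths.

For a triplet of taxa, gene trees showing a discordant rooted topology
arise either from incomplete lineage sorting alone (H0), in which case
the internal branch length t of the triplet is exponentially
distributed, or from ILS together with introgression (H1), which adds
a second branch-length class shifted away from zero.  H1 is modelled
as a two-component mixture

    f(t) = (1 - pi2) * lam1 * exp(-lam1 * t)
         + pi2 * lam2 * exp(-lam2 * (t - C)) * 1[t >= C],

fitted by EM with a shrinking line search on the shift C.  Models are
compared by BIC; a topology is called introgression when
Delta BIC = BIC_H1 - BIC_H0 falls below a strict cutoff (-10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import (
    DegenerateDataError,
    InputError,
    InsufficientDataError,
    clade_masks,
    leaf_bit_index,
    substream,
)
from .genetrees import GeneTreeSet

DELTA_BIC_CUTOFF = -10.0
#: Rate cap guarding against the degenerate spike (a component collapsing
#: onto a single observation with lam2 -> infinity).
LAMBDA_MAX = 1e6
#: The shift C may not exceed the 5th-largest observation, so the second
#: component always has support on at least 5 points.
MIN_TAIL = 5


@dataclass
class TripletObservation:
    """One gene tree restricted to a triplet: which taxon branches first
    (the outlier) and the internal branch length t."""

    triplet: tuple[str, str, str]
    outlier: str
    t: float

    def __post_init__(self):
        self.triplet = tuple(sorted(self.triplet))
        if self.outlier not in self.triplet:
            raise InputError("outlier must be one of the triplet taxa")
        if self.t < 0:
            raise InputError("internal branch length must be >= 0")


@dataclass
class TripletSample:
    """Observations for one triplet plus extraction bookkeeping."""

    triplet: tuple[str, str, str]
    observations: list[TripletObservation]
    n_trees_sampled: int
    n_polytomies_dropped: int
    n_missing_taxa: int

    def counts(self) -> dict[str, int]:
        out = {tax: 0 for tax in self.triplet}
        for obs in self.observations:
            out[obs.outlier] += 1
        return out


def extract_triplets(
    trees: GeneTreeSet,
    triplet,
    n_sample: int = 1000,
    seed: int | None = None,
) -> TripletSample:
    """Restrict sampled gene trees to three taxa.

    ``n_sample`` trees are drawn without replacement (all trees, with a
    warning, when fewer are available).  Rooted input trees are
    required: the triplet topology is read off as the taxon whose
    lineage branches first.  Restrictions that are polytomous (the
    three taxa join at one node) are dropped and counted.
    """
    triplet = tuple(sorted(triplet))
    if len(set(triplet)) != 3:
        raise InputError("a triplet needs three distinct taxa")
    sampled = trees.sample(n_sample, seed=seed)
    bit = leaf_bit_index(triplet)
    target = {1 << i for i in range(3)}
    observations = []
    n_poly = 0
    n_missing = 0
    for tree in sampled:
        masks, _ = clade_masks(tree, bit)
        root_mask = masks[tree.seed_node]
        if root_mask != 7:
            n_missing += 1
            continue
        # distance from root along the tree, for branch-length read-off
        depth = {tree.seed_node: 0.0}
        cherry_node, cherry_mask, cherry_depth = None, 0, -np.inf
        mrca_node, mrca_depth = None, -np.inf
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
            m = masks[node]
            bits = bin(m & 7).count("1")
            if m & 7 == 7 and depth[node] > mrca_depth:
                mrca_node, mrca_depth = node, depth[node]
            if bits == 2 and depth[node] > cherry_depth:
                cherry_node, cherry_mask, cherry_depth = node, m & 7, depth[node]
        if cherry_node is None:
            n_poly += 1
            continue
        outlier = triplet[(7 ^ cherry_mask).bit_length() - 1]
        t = cherry_depth - mrca_depth
        observations.append(TripletObservation(triplet, outlier, max(0.0, t)))
    return TripletSample(
        triplet=triplet,
        observations=observations,
        n_trees_sampled=len(sampled),
        n_polytomies_dropped=n_poly,
        n_missing_taxa=n_missing,
    )


# ---------------------------------------------------------------------------
# model fits


def fit_exponential(lengths) -> tuple[float, float]:
    """MLE of an exponential rate: lam = 1/mean, logL = n (ln lam - 1)."""
    t = np.asarray(lengths, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 branch lengths")
    if np.any(t < 0):
        raise InputError("branch lengths must be >= 0")
    mean = float(t.mean())
    if mean <= 0:
        raise DegenerateDataError("all branch lengths are zero")
    lam = 1.0 / mean
    return lam, t.size * (np.log(lam) - 1.0)


@dataclass
class MixtureFit:
    """Fitted shifted-exponential mixture (the H1 model)."""

    pi2: float
    lam1: float
    lam2: float
    C: float
    loglik: float
    n_iterations: int
    converged: bool
    degenerate: bool = False
    n_obs: int = 0
    starts: tuple = field(default=(), repr=False)


def _mixture_loglik(t, pi2, lam1, lam2, C) -> float:
    f1 = lam1 * np.exp(-lam1 * t)
    f2 = np.where(t >= C, lam2 * np.exp(-lam2 * np.maximum(t - C, 0.0)), 0.0)
    dens = (1.0 - pi2) * f1 + pi2 * f2
    if np.any(dens <= 0):
        return -np.inf
    return float(np.log(dens).sum())


def _em_run(t, pi2, lam1, lam2, C, max_steps, lik_threshold, shrink, c_max):
    step = max(float(np.median(t)) / 4.0, 1e-6)
    ll = _mixture_loglik(t, pi2, lam1, lam2, C)
    it = 0
    converged = False
    for it in range(1, max_steps + 1):
        f1 = lam1 * np.exp(-lam1 * t)
        f2 = np.where(t >= C, lam2 * np.exp(-lam2 * np.maximum(t - C, 0.0)), 0.0)
        denom = (1.0 - pi2) * f1 + pi2 * f2
        denom = np.where(denom <= 0, 1e-300, denom)
        r = pi2 * f2 / denom
        pi2 = float(np.clip(r.mean(), 1e-6, 1.0 - 1e-6))
        w1 = 1.0 - r
        s1 = float((w1 * t).sum())
        lam1 = min(float(w1.sum()) / s1, LAMBDA_MAX) if s1 > 0 else LAMBDA_MAX
        s2 = float((r * np.maximum(t - C, 0.0)).sum())
        lam2 = min(float(r.sum()) / s2, LAMBDA_MAX) if s2 > 0 else LAMBDA_MAX
        # line search on the shift C: step shrinks on non-improvement
        base = _mixture_loglik(t, pi2, lam1, lam2, C)
        improved = False
        for cand in (min(C + step, c_max), max(C - step, 0.0)):
            cand_ll = _mixture_loglik(t, pi2, lam1, lam2, cand)
            if cand_ll > base + 1e-12:
                C, base, improved = cand, cand_ll, True
                break
        if not improved:
            step *= shrink
        new_ll = base
        if new_ll - ll < lik_threshold and new_ll >= ll:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return pi2, lam1, lam2, C, ll, it, converged


def fit_mixture_em(
    lengths,
    max_steps: int = 50,
    lik_threshold: float = 0.01,
    shrink: float = 0.5,
    seed: int | None = None,
    min_obs: int = 20,
) -> MixtureFit:
    """Fit the two-component shifted-exponential mixture by EM.

    Responsibilities and rate updates are closed-form; the shift C is
    updated by a line search whose step halves (factor ``shrink``) on
    non-improvement, and is capped below the 5th-largest observation to
    exclude the single-point spike degeneracy.  Several documented
    starts are run and the best final log-likelihood kept.
    """
    t = np.asarray(lengths, dtype=float)
    if t.size < min_obs:
        raise InsufficientDataError(f"need at least {min_obs} branch lengths")
    if np.any(t < 0):
        raise InputError("branch lengths must be >= 0")
    if float(t.max()) - float(t.min()) <= 0:
        return MixtureFit(
            pi2=0.0, lam1=LAMBDA_MAX, lam2=LAMBDA_MAX, C=float(t[0]),
            loglik=float("nan"), n_iterations=0, converged=False,
            degenerate=True, n_obs=t.size,
        )
    mean = float(t.mean())
    c_max = float(np.sort(t)[-MIN_TAIL])
    q50, q75 = (float(np.quantile(t, q)) for q in (0.5, 0.75))
    starts = (
        (0.1, 0.0),
        (0.5, min(q50, c_max)),
        (0.3, min(q75, c_max)),
        (0.05, 0.0),
    )
    best = None
    for pi0, c0 in starts:
        lam1 = 1.0 / mean
        tail = t[t >= c0]
        lam2 = 1.0 / max(float(np.mean(tail - c0)), 1e-6) if tail.size else 1.0 / mean
        lam2 = min(lam2, LAMBDA_MAX)
        res = _em_run(t, pi0, lam1, lam2, c0, max_steps, lik_threshold, shrink, c_max)
        if best is None or res[4] > best[4]:
            best = res
    pi2, lam1, lam2, C, ll, it, converged = best
    if not converged:
        warnings.warn("mixture EM did not converge; best iterate returned")
    return MixtureFit(
        pi2=pi2, lam1=lam1, lam2=lam2, C=C, loglik=ll,
        n_iterations=it, converged=converged, n_obs=t.size, starts=starts,
    )


# ---------------------------------------------------------------------------
# classification


@dataclass
class TopologyTest:
    """H0-vs-H1 comparison for one tested triplet topology."""

    outlier: str
    n: int
    call: str  # "introgression" | "ILS" | "insufficient-data"
    bic_h0: float | None = None
    bic_h1: float | None = None
    delta_bic: float | None = None
    lam_h0: float | None = None
    mixture: MixtureFit | None = None


@dataclass
class TripletTest:
    """Per-triplet mixture-test result with summary fractions."""

    triplet: tuple[str, str, str]
    counts: dict[str, int]
    frequencies: dict[str, float]
    concordant_outlier: str
    tests: dict[str, TopologyTest]
    fraction_discordant: float
    fraction_introgression: float  # of the total tree set
    fraction_ils_only: float

    @property
    def any_introgression(self) -> bool:
        return any(t.call == "introgression" for t in self.tests.values())


def classify_triplet(
    sample: TripletSample,
    delta_bic_cutoff: float = DELTA_BIC_CUTOFF,
    min_obs: int = 20,
    k_h0: int = 1,
    k_h1: int = 4,
    test_concordant: bool = False,
    concordant_outlier: str | None = None,
    max_steps: int = 50,
    lik_threshold: float = 0.01,
    shrink: float = 0.5,
    seed: int | None = None,
) -> TripletTest:
    """Fit H0 and H1 per discordant topology and call by Delta BIC.

    BIC = k ln n - 2 logL with k(H0) = 1 and k(H1) = 4 (pi2, lam1,
    lam2, C); n is the number of branch-length observations for the
    tested topology.  Introgression is called iff
    Delta BIC < ``delta_bic_cutoff`` (default -10, a strict cutoff).
    The concordant topology defaults to the most frequent one (tie
    broken lexicographically) and is not tested unless requested.
    """
    obs = sample.observations
    counts = sample.counts()
    n_total = len(obs)
    if concordant_outlier is None:
        concordant_outlier = max(sorted(counts), key=lambda k: counts[k])
    elif concordant_outlier not in sample.triplet:
        raise InputError("concordant outlier must belong to the triplet")
    freqs = {k: (counts[k] / n_total if n_total else 0.0) for k in counts}
    by_outlier = {k: [o.t for o in obs if o.outlier == k] for k in counts}
    tests: dict[str, TopologyTest] = {}
    for outlier in sorted(counts):
        if outlier == concordant_outlier and not test_concordant:
            continue
        lengths = by_outlier[outlier]
        n = len(lengths)
        if n < min_obs:
            tests[outlier] = TopologyTest(outlier=outlier, n=n, call="insufficient-data")
            continue
        try:
            lam, ll0 = fit_exponential(lengths)
        except DegenerateDataError:
            tests[outlier] = TopologyTest(outlier=outlier, n=n, call="insufficient-data")
            continue
        mix = fit_mixture_em(
            lengths, max_steps=max_steps, lik_threshold=lik_threshold,
            shrink=shrink, seed=seed, min_obs=min_obs,
        )
        if mix.degenerate or not np.isfinite(mix.loglik):
            tests[outlier] = TopologyTest(
                outlier=outlier, n=n, call="ILS", lam_h0=lam, mixture=mix
            )
            continue
        bic0 = k_h0 * np.log(n) - 2.0 * ll0
        bic1 = k_h1 * np.log(n) - 2.0 * mix.loglik
        delta = bic1 - bic0
        call = "introgression" if delta < delta_bic_cutoff else "ILS"
        tests[outlier] = TopologyTest(
            outlier=outlier, n=n, call=call, bic_h0=float(bic0), bic_h1=float(bic1),
            delta_bic=float(delta), lam_h0=lam, mixture=mix,
        )
    frac_disc = 1.0 - freqs.get(concordant_outlier, 0.0) if n_total else 0.0
    frac_intro = sum(
        freqs[o] * t.mixture.pi2
        for o, t in tests.items()
        if t.call == "introgression" and o != concordant_outlier
    )
    if test_concordant and concordant_outlier in tests:
        t = tests[concordant_outlier]
        if t.call == "introgression":
            frac_intro += freqs[concordant_outlier] * t.mixture.pi2
    return TripletTest(
        triplet=sample.triplet,
        counts=counts,
        frequencies=freqs,
        concordant_outlier=concordant_outlier,
        tests=tests,
        fraction_discordant=frac_disc,
        fraction_introgression=frac_intro,
        fraction_ils_only=max(frac_disc - frac_intro, 0.0),
    )


def summarize_triplet_panel(tests: list[TripletTest]):
    """Panel summary: per-triplet and mean fractions, as a DataFrame.

    Columns mirror the per-triplet report layout: percent discordant,
    percent of discordant attributed to introgression, percent of the
    total attributed to introgression, and percent ILS-only.
    """
    import pandas as pd

    if not tests:
        raise InputError("no triplet tests to summarize")
    rows = []
    for t in tests:
        disc = t.fraction_discordant
        rows.append(
            {
                "triplet": "|".join(t.triplet),
                "concordant_outlier": t.concordant_outlier,
                "n_trees": sum(t.counts.values()),
                "pct_discordant": 100.0 * disc,
                "pct_discordant_introgressed": (
                    100.0 * t.fraction_introgression / disc if disc > 0 else 0.0
                ),
                "pct_total_introgression": 100.0 * t.fraction_introgression,
                "pct_total_ils_only": 100.0 * t.fraction_ils_only,
                "n_topologies_called": sum(
                    1 for x in t.tests.values() if x.call == "introgression"
                ),
            }
        )
    df = pd.DataFrame(rows)
    mean = df.drop(columns=["triplet", "concordant_outlier"]).mean(numeric_only=True)
    mean_row = {"triplet": "MEAN", "concordant_outlier": ""}
    mean_row.update({k: mean[k] for k in mean.index})
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def panel_to_tsv(tests: list[TripletTest], path) -> None:
    """Write the per-topology detail table (counts, fits, BICs, calls)."""
    with open(path, "w") as fh:
        fh.write(
            "triplet\toutlier\tn\tfrequency\tlam_h0\tpi2\tlam1\tlam2\tC\t"
            "bic_h0\tbic_h1\tdelta_bic\tcall\n"
        )
        for t in tests:
            for outlier in sorted(t.counts):
                tt = t.tests.get(outlier)
                base = [
                    "|".join(t.triplet), outlier, str(t.counts[outlier]),
                    f"{t.frequencies[outlier]:.6g}",
                ]
                if tt is None:
                    fh.write("\t".join(base + ["NA"] * 8 + ["concordant"]) + "\n")
                    continue
                m = tt.mixture
                vals = [
                    f"{tt.lam_h0:.6g}" if tt.lam_h0 is not None else "NA",
                    f"{m.pi2:.6g}" if m else "NA",
                    f"{m.lam1:.6g}" if m else "NA",
                    f"{m.lam2:.6g}" if m else "NA",
                    f"{m.C:.6g}" if m else "NA",
                    f"{tt.bic_h0:.6g}" if tt.bic_h0 is not None else "NA",
                    f"{tt.bic_h1:.6g}" if tt.bic_h1 is not None else "NA",
                    f"{tt.delta_bic:.6g}" if tt.delta_bic is not None else "NA",
                    tt.call,
                ]
                fh.write("\t".join(base + vals) + "\n")
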