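"""Runnable pipelines: conflict analysis and selection screen.

Ties the stages together behind a single plain-text configuration whose
defaults are the analysis constants used throughout the package
(20-kbp fragments, 1-kbp windows with a 50-informative-site floor,
5%/5% variability trim, 1000 sampled trees for the triplet test with
likelihood threshold 0.01 / 50 EM steps / shrink 0.5 / Delta BIC < -10,
12% network threshold).  All randomness flows from one integer seed and
reports are written with fixed formatting, so identical (config, seed)
runs produce byte-identical output.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import conflict, datasets, diversity, fragments, genetrees, kaks, quibl, simdata, splits
from ._util import ConfigurationError, InputError

log = logging.getLogger("phyloconflict")


def _stage(name):
    log.info("[%s] %s", time.strftime("%H:%M:%S"), name)


@dataclass
class PipelineConfig:
    """Configuration for both pipelines; defaults are the analysis
    constants documented in the module docstring."""

    # input source: "sim-trees" | "sim-sequences" | "files"
    source: str = "sim-trees"
    gene_trees: str | None = None       # newick path (files mode)
    alignment: str | None = None        # aligned FASTA path (files mode)
    species_tree: str | None = None     # newick path; default greedy consensus
    # simulation
    n_loci: int = 5000
    contested_branch: float = 0.02
    gamma: float = 0.3
    sequence_scale: float = 0.01
    # fragments / windows
    fragment_size: int = 20_000
    window_size: int = 1_000
    min_informative: int = 50
    filter_lower: float = 0.05
    filter_upper: float = 0.05
    # triplet test
    quibl_n_trees: int = 1000
    quibl_lik_threshold: float = 0.01
    quibl_max_steps: int = 50
    quibl_shrink: float = 0.5
    delta_bic_cutoff: float = -10.0
    min_triplet_obs: int = 20
    # conflict / network
    sampling_limit: int = 10_000
    network_threshold: float = 0.12
    # selection screen
    n_orthologs: int = 60
    n_selected: int = 6
    omega_selected: float = 2.0
    omega_background: float = 0.2
    codons_per_ortholog: int = 500
    # proposal density per codon site; chosen so that simulated orthologs
    # span the 5-40% variable-site window the alignment filter expects
    codon_divergence: float = 1.0
    # shared
    seed: int = 0
    out_dir: str = "phyloconflict_out"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# phyloconflict pipeline config v1\n")
            for key, value in asdict(self).items():
                if key == "out_dir":  # output location is not an analysis parameter
                    continue
                fh.write(f"{key} = {'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        defaults = cls()
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ConfigurationError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if value == "":
                    kwargs[key] = None
                elif isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int) and not isinstance(current, bool):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        if self.source not in ("sim-trees", "sim-sequences", "files"):
            raise ConfigurationError(f"unknown source {self.source!r}")
        if self.source == "files" and not (self.gene_trees or self.alignment):
            raise ConfigurationError("files mode needs gene_trees or alignment path")
        for path in (self.gene_trees, self.alignment, self.species_tree):
            if path and not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")
        if not 0 < self.network_threshold <= 1:
            raise ConfigurationError("network threshold must be in (0, 1]")
        if self.fragment_size < self.window_size:
            raise ConfigurationError("fragment size smaller than window size")


def _json_dump(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


# ---------------------------------------------------------------------------
# conflict pipeline


def _acquire_trees(config: PipelineConfig, out: Path):
    """Stage 1-2: obtain fragment trees (and window trees when possible)."""
    window_trees_by_fragment = None
    coordinates = None
    if config.source == "files":
        if config.gene_trees:
            _stage("reading gene trees")
            trees = genetrees.read_tree_file(config.gene_trees)
            return trees, None, None
        _stage("reading alignment")
        block = fragments.read_fasta_block(config.alignment)
        return _trees_from_block(config, block, out)
    model = datasets.rorqual_like_model(
        contested_branch=config.contested_branch, gamma=config.gamma, seed=config.seed
    )
    (out / "model.cfg").write_text(model.to_config())
    _stage(f"simulating {config.n_loci} gene trees under the MSC")
    trees = simdata.simulate_gene_trees(model, config.n_loci, seed=config.seed)
    if config.source == "sim-trees":
        return trees, None, None
    _stage("simulating sequences and rebuilding trees")
    frags = []
    params = simdata.SimSequenceParams(
        locus_length=config.fragment_size, scale=config.sequence_scale, seed=config.seed
    )
    for i, gtree in enumerate(trees):
        frag = simdata.simulate_sequences(gtree, params, chrom="sim", index=i)
        frags.append(frag)
    report = fragments.filter_by_variability(
        frags, lower=config.filter_lower, upper=config.filter_upper
    )
    kept = [f for f in frags if f.index in set(report.kept_indices)]
    fragments.write_manifest(frags, report, out / "fragments.tsv")
    nj_trees = genetrees.build_fragment_trees(kept)
    window_trees_by_fragment = {}
    coordinates = {}
    for frag in kept:
        wins = fragments.window_split(
            frag, window=config.window_size, min_informative=config.min_informative
        )
        wtrees = genetrees.build_fragment_trees(
            [
                fragments.AlignmentFragment(
                    taxa=w.taxa, sequences=w.sequences, chrom=w.chrom,
                    index=w.fragment_index, start=w.start, end=w.end,
                )
                for w in wins
            ]
        ) if wins else None
        window_trees_by_fragment[frag.index] = wtrees
        coordinates[frag.index] = (frag.chrom, frag.index * config.fragment_size,
                                   (frag.index + 1) * config.fragment_size)
    return nj_trees, window_trees_by_fragment, coordinates


def _trees_from_block(config: PipelineConfig, block, out: Path):
    _stage("purging gapped/ambiguous columns")
    clean = fragments.remove_gap_ambiguous_columns(block)
    _stage("slicing fragments")
    frags = fragments.slice_fragments(clean, size=config.fragment_size)
    if not frags:
        raise InputError("alignment yielded no full-size fragments")
    report = fragments.filter_by_variability(
        frags, lower=config.filter_lower, upper=config.filter_upper
    )
    kept = [f for f in frags if f.index in set(report.kept_indices)]
    fragments.write_manifest(frags, report, out / "fragments.tsv")
    _stage(f"building {len(kept)} fragment trees")
    trees = genetrees.build_fragment_trees(kept)
    window_trees = {}
    coords = {}
    for frag in kept:
        wins = fragments.window_split(
            frag, window=config.window_size, min_informative=config.min_informative
        )
        wts = genetrees.build_fragment_trees(
            [
                fragments.AlignmentFragment(
                    taxa=w.taxa, sequences=w.sequences, chrom=w.chrom,
                    index=w.fragment_index, start=w.start, end=w.end,
                )
                for w in wins
            ]
        ) if wins else None
        window_trees[frag.index] = wts
        coords[frag.index] = (frag.chrom, frag.start, frag.end)
    return trees, window_trees, coords


def run_conflict_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Fragments -> trees -> consensus -> quartet table -> window profile
    -> triplet panel -> split system.  Returns the JSON-able summary."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.cfg")
    trees, window_trees, coords = _acquire_trees(config, out)
    if len(trees) == 0:
        raise InputError("no gene trees available")
    genetrees.write_tree_file(trees, out / "gene_trees.nwk")

    if config.species_tree:
        import dendropy

        species_tree = dendropy.Tree.get(path=config.species_tree, schema="newick", preserve_underscores=True)
        consensus_src = "file"
    else:
        _stage("greedy consensus")
        species_tree = conflict.greedy_consensus(trees)
        consensus_src = "greedy-consensus"
    (out / "species_tree.nwk").write_text(
        species_tree.as_string(schema="newick", suppress_rooting=True)
    )

    _stage("quartet support")
    supports = conflict.quartet_support(
        species_tree, trees, sampling_limit=config.sampling_limit, seed=config.seed
    )
    conflict.support_table(supports, out / "quartet_support.tsv")
    contested = min(supports, key=lambda s: max(abs(q - 1 / 3) for q in s.q))

    profile_summary = None
    if window_trees:
        _stage("window conflict profile")
        profile = conflict.window_profile(
            species_tree, contested.branch_id, window_trees, coords,
            sampling_limit=config.sampling_limit, seed=config.seed,
        )
        profile.to_tsv(out / "window_profile.tsv")
        n_missing = sum(e.missing for e in profile.entries)
        profile_summary = {"n_windows": len(profile.entries), "n_missing": n_missing}

    _stage("triplet panel")
    universe = trees.taxon_universe
    tests = []
    for triplet in itertools.combinations(universe, 3):
        sample = quibl.extract_triplets(
            trees, triplet, n_sample=config.quibl_n_trees, seed=config.seed
        )
        if len(sample.observations) < config.min_triplet_obs:
            continue
        tests.append(
            quibl.classify_triplet(
                sample,
                delta_bic_cutoff=config.delta_bic_cutoff,
                min_obs=config.min_triplet_obs,
                max_steps=config.quibl_max_steps,
                lik_threshold=config.quibl_lik_threshold,
                shrink=config.quibl_shrink,
                seed=config.seed,
            )
        )
    quibl.panel_to_tsv(tests, out / "triplet_tests.tsv")
    if tests:
        panel = quibl.summarize_triplet_panel(tests)
        panel.to_csv(out / "triplet_panel.tsv", sep="\t", index=False,
                     float_format="%.6g")

    _stage("consensus network")
    system = splits.consensus_network(trees, threshold=config.network_threshold)
    splits.export_splits_nexus(system, out / "splits.nex")
    splits.splits_table(system, out / "splits.tsv")

    summary = {
        "n_trees": len(trees),
        "species_tree_source": consensus_src,
        "contested_branch": {
            "branch_id": contested.branch_id,
            "groups": [list(g) for g in contested.groups],
            "q": [_round(q) for q in contested.q],
            "max_q_deviation": _round(max(abs(q - 1 / 3) for q in contested.q)),
        },
        "branches": {
            s.branch_id: [_round(q) for q in s.q] for s in supports
        },
        "window_profile": profile_summary,
        "n_triplets_tested": len(tests),
        "n_triplets_introgression": int(sum(t.any_introgression for t in tests)),
        "mean_pct_discordant": _round(
            float(np.mean([100 * t.fraction_discordant for t in tests]))
        ) if tests else None,
        "mean_pct_total_introgression": _round(
            float(np.mean([100 * t.fraction_introgression for t in tests]))
        ) if tests else None,
        "n_splits_retained": len(system.nontrivial),
        "n_incompatible_split_pairs": len(system.incompatible_pairs),
        "network_threshold": config.network_threshold,
        "seed": config.seed,
    }
    _json_dump(summary, out / "conflict_summary.json")
    return summary


# ---------------------------------------------------------------------------
# selection pipeline


def run_selection_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Targeting pairs -> alignment filters -> Ka/Ks per pair ->
    positive sets -> enrichment.  Simulated orthologs unless codon
    alignments are supplied via files (not implemented here: the
    library functions accept them directly)."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.cfg")

    _stage("phylogenetic targeting")
    tree = datasets.mysticete_tree()
    traits = datasets.whale_traits()
    pairs = kaks.phylogenetic_targeting(tree, traits, outgroup="dolphin")
    with open(out / "pairs.tsv", "w") as fh:
        fh.write("large\tsmall\tcontrast\n")
        for p in pairs.pairs:
            fh.write(f"{p.large}\t{p.small}\t{p.contrast:.6g}\n")

    _stage(f"simulating {config.n_orthologs} orthologs for {len(pairs.pairs)} pairs")
    selected_ids = {f"OG{i:04d}" for i in range(config.n_selected)}
    estimates = []
    n_filtered = 0
    for pi, pair in enumerate(pairs.pairs):
        alns = []
        for gi in range(config.n_orthologs):
            og = f"OG{gi:04d}"
            omega = config.omega_selected if og in selected_ids else config.omega_background
            alns.append(
                simdata.simulate_codon_pair(
                    simdata.SimCodonParams(
                        n_codons=config.codons_per_ortholog,
                        divergence=config.codon_divergence,
                        omega=omega,
                        seed=config.seed + 1000 * pi + gi,
                    ),
                    ortholog_id=og,
                )
            )
        result = kaks.filter_alignments(alns)
        n_filtered += result.n_input - len(result.kept)
        label = f"{pair.large}-{pair.small}"
        for aln in result.kept:
            estimates.append(kaks.ng86(aln, pair_label=label))

    with open(out / "kaks.tsv", "w") as fh:
        fh.write("ortholog\tpair\tka\tks\tka_ks\tp_value\n")
        for e in sorted(estimates, key=lambda e: (e.ortholog_id, e.pair_label)):
            ratio = f"{e.ratio:.6g}" if e.ratio is not None else "NA"
            fh.write(
                f"{e.ortholog_id}\t{e.pair_label}\t{e.ka:.6g}\t{e.ks:.6g}\t"
                f"{ratio}\t{e.p_value:.6g}\n"
            )

    _stage("positive-selection screen")
    screen = kaks.screen_positive(estimates, pair_labels=pairs.labels)

    _stage("enrichment")
    reference = [f"OG{gi:04d}" for gi in range(config.n_orthologs)]
    rng = np.random.default_rng([config.seed, 77])
    terms = [f"T{k:02d}" for k in range(12)]
    annotation = {
        g: {terms[int(t)] for t in rng.choice(len(terms), size=3, replace=False)}
        for g in reference
    }
    for g in sorted(selected_ids):
        annotation[g].add("T00")  # enriched term among the selected set
    query = sorted(screen.union)
    if query:
        table = kaks.enrichment(query, annotation, reference)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        top_term = table.iloc[0]["term"] if len(table) else None
    else:
        top_term = None

    summary = {
        "pairs": pairs.labels,
        "summed_score": _round(pairs.summed_score),
        "trait": pairs.trait,
        "n_orthologs": config.n_orthologs,
        "n_alignments_filtered_out": n_filtered,
        "per_pair_positive": {k: sorted(v) for k, v in screen.per_pair.items()},
        "n_union": len(screen.union),
        "intersection": sorted(screen.intersection),
        "true_selected": sorted(selected_ids),
        "top_enriched_term": top_term,
        "seed": config.seed,
    }
    _json_dump(summary, out / "selection_summary.json")
    return summary


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(message)s"))
    log.handlers = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
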