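"""Whole-genome-alignment fragments: gap purging, slicing, filtering.

Turns an aligned block of genomes into gap-free, fixed-size analysis
fragments (default 20 kbp) and 1-kbp sub-windows, with the variability
trim applied on mean pairwise JC distance.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import AlignIO

from ._util import InputError
from .genetrees import MAX_JC_DISTANCE, jc_distance

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode_rows(seqs) -> np.ndarray:
    rows = []
    for s in seqs:
        if isinstance(s, np.ndarray):
            rows.append(s.astype(np.uint8))
        else:
            rows.append(np.frombuffer(str(s).upper().encode("ascii"), dtype=np.uint8))
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise InputError("ragged alignment block: unequal sequence lengths")
    return np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)


@dataclass
class WgaBlock:
    """One aligned block: taxa x columns, anchored on a reference taxon.

    ``column_map`` maps current columns back to the original alignment
    coordinates (the catalog kept while removing gapped columns).
    """

    taxa: tuple[str, ...]
    data: np.ndarray  # (n_taxa, n_columns) uint8, upper-case ASCII
    reference_taxon: str | None = None
    chrom: str = "chr"
    ref_start: int = 0
    column_map: np.ndarray = field(default=None)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise InputError("block data shape does not match taxon count")
        if self.column_map is None:
            self.column_map = np.arange(self.data.shape[1])
        if len(self.column_map) != self.data.shape[1]:
            raise InputError("column map length does not match column count")

    @classmethod
    def from_sequences(cls, taxa, seqs, **kw) -> "WgaBlock":
        return cls(tuple(taxa), _encode_rows(seqs), **kw)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]


@dataclass
class AlignmentFragment:
    """A gap-free aligned window: the fixed-size unit of analysis."""

    taxa: tuple[str, ...]
    sequences: np.ndarray  # (n_taxa, size) uint8
    chrom: str
    index: int
    start: int  # 0-based, half-open, in gap-free block coordinates
    end: int
    n_informative: int = -1
    mean_pairwise_distance: float = float("nan")

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        if self.n_informative < 0:
            self.n_informative = count_informative_sites(self.sequences)
        if np.isnan(self.mean_pairwise_distance):
            self.mean_pairwise_distance = mean_pairwise_jc(self.sequences)

    def sequence_of(self, taxon: str) -> np.ndarray:
        return self.sequences[self.taxa.index(taxon)]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, row in zip(self.taxa, self.sequences):
                fh.write(f">{lab}\n{row.tobytes().decode('ascii')}\n")


@dataclass
class FragmentFilterReport:
    """Bookkeeping for the variability trim (applied to the full set)."""

    n_input: int
    n_removed_low: int
    n_removed_high: int
    kept_indices: tuple[int, ...]
    low_cutoff: float
    high_cutoff: float

    def __post_init__(self):
        if self.n_input != len(self.kept_indices) + self.n_removed_low + self.n_removed_high:
            raise InputError("filter report counts are inconsistent")


def remove_gap_ambiguous_columns(block: WgaBlock) -> WgaBlock:
    """Drop every column where ANY taxon has a gap or ambiguity.

    Ambiguity means any character outside {A, C, G, T} (case-insensitive;
    the block stores upper-case).  Column removal applies to all taxa,
    preserving relative order; the returned block's ``column_map``
    points back at the input block's coordinates.
    """
    if block.n_columns == 0:
        raise InputError("empty block")
    ok = np.isin(block.data, _VALID).all(axis=0)
    if not ok.any():
        warnings.warn("all columns contain a gap or ambiguity; block is empty")
    return WgaBlock(
        block.taxa,
        np.ascontiguousarray(block.data[:, ok]),
        reference_taxon=block.reference_taxon,
        chrom=block.chrom,
        ref_start=block.ref_start,
        column_map=block.column_map[ok],
    )


def slice_fragments(block: WgaBlock, size: int = 20_000) -> list[AlignmentFragment]:
    """Cut consecutive non-overlapping windows of exactly ``size`` columns.

    The trailing remainder shorter than ``size`` is discarded: the
    analysis unit is the fixed-size fragment.  Fragment i spans columns
    [i*size, (i+1)*size) of the (gap-free) block.
    """
    if size < 1:
        raise InputError("fragment size must be >= 1")
    if not np.isin(block.data, _VALID).all():
        raise InputError("block contains gaps/ambiguities; purge columns first")
    n_frag = block.n_columns // size
    if n_frag == 0:
        warnings.warn(
            f"block has {block.n_columns} columns, shorter than one {size}-column fragment"
        )
    out = []
    for i in range(n_frag):
        s, e = i * size, (i + 1) * size
        out.append(
            AlignmentFragment(
                taxa=block.taxa,
                sequences=np.ascontiguousarray(block.data[:, s:e]),
                chrom=block.chrom,
                index=i,
                start=s,
                end=e,
            )
        )
    return out


def count_informative_sites(sequences) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct states each occur
    in at least two taxa.  Input must be gap-free (A/C/G/T only).
    """
    arr = sequences.sequences if isinstance(sequences, AlignmentFragment) else sequences
    arr = _encode_rows(arr) if not isinstance(arr, np.ndarray) else arr
    counts = np.stack([(arr == b).sum(axis=0) for b in _VALID])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def mean_pairwise_jc(sequences) -> float:
    """Mean pairwise JC distance over all taxon pairs (saturation-capped)."""
    arr = sequences
    n = arr.shape[0]
    if n < 2:
        return 0.0
    ds = [jc_distance(arr[i], arr[j]) for i, j in combinations(range(n), 2)]
    return float(np.mean(ds))


def filter_by_variability(
    fragments, lower: float = 0.05, upper: float = 0.05
) -> FragmentFilterReport:
    """Trim the most and least variable fragments by mean JC distance.

    Fragments are ranked by ``mean_pairwise_distance``; floor(lower*n)
    lowest and floor(upper*n) highest are removed.  Ties are broken by
    fragment index with the lower index kept first (i.e. among equal
    distances the higher index is removed first on the high side, the
    lower index removed first on the low side is avoided by ranking on
    (distance, index)).
    """
    frags = list(fragments)
    n = len(frags)
    if n == 0:
        raise InputError("no fragments to filter")
    order = sorted(range(n), key=lambda i: (frags[i].mean_pairwise_distance, frags[i].index))
    n_low = int(np.floor(lower * n))
    n_high = int(np.floor(upper * n))
    removed_low = order[:n_low]
    removed_high = order[n - n_high :] if n_high else []
    kept = order[n_low : n - n_high] if n_high else order[n_low:]
    kept_indices = tuple(sorted(frags[i].index for i in kept))
    low_cut = max((frags[i].mean_pairwise_distance for i in removed_low), default=float("nan"))
    high_cut = min(
        (frags[i].mean_pairwise_distance for i in removed_high), default=float("nan")
    )
    return FragmentFilterReport(
        n_input=n,
        n_removed_low=len(removed_low),
        n_removed_high=len(removed_high),
        kept_indices=kept_indices,
        low_cutoff=low_cut,
        high_cutoff=high_cut,
    )


@dataclass
class Window:
    """A retained 1-kbp sub-window of a parent fragment."""

    fragment_index: int
    chrom: str
    start: int  # block coordinates, 0-based half-open
    end: int
    taxa: tuple[str, ...]
    sequences: np.ndarray
    n_informative: int


def window_split(
    fragment: AlignmentFragment, window: int = 1_000, min_informative: int = 50
) -> list[Window]:
    """Split a fragment into consecutive windows, keeping informative ones.

    Windows with fewer than ``min_informative`` parsimony-informative
    sites are excluded (a window with exactly the minimum is retained).
    """
    size = fragment.end - fragment.start
    if window > size:
        raise InputError("window larger than fragment")
    out = []
    for w in range(size // window):
        s, e = w * window, (w + 1) * window
        seqs = np.ascontiguousarray(fragment.sequences[:, s:e])
        ninf = count_informative_sites(seqs)
        if ninf < min_informative:
            continue
        out.append(
            Window(
                fragment_index=fragment.index,
                chrom=fragment.chrom,
                start=fragment.start + s,
                end=fragment.start + e,
                taxa=fragment.taxa,
                sequences=seqs,
                n_informative=ninf,
            )
        )
    return out


def read_fasta_block(path, reference_taxon=None, chrom="chr", ref_start=0) -> WgaBlock:
    """Read an aligned multi-FASTA file as one block."""
    aln = AlignIO.read(path, "fasta")
    taxa = tuple(rec.id for rec in aln)
    return WgaBlock.from_sequences(
        taxa,
        [str(rec.seq) for rec in aln],
        reference_taxon=reference_taxon,
        chrom=chrom,
        ref_start=ref_start,
    )


def read_maf_blocks(path, reference_taxon: str) -> list[WgaBlock]:
    """Read reference-anchored MAF blocks.

    Sequence names may be ``species.chrom``; the species part is used as
    the taxon label and the reference row supplies chrom/start.
    """
    blocks = []
    for aln in AlignIO.parse(path, "maf"):
        taxa, seqs = [], []
        chrom, start = "chr", 0
        for rec in aln:
            species = rec.id.split(".")[0]
            taxa.append(species)
            seqs.append(str(rec.seq))
            if species == reference_taxon:
                parts = rec.id.split(".", 1)
                chrom = parts[1] if len(parts) > 1 else "chr"
                start = int(rec.annotations.get("start", 0))
        blocks.append(
            WgaBlock.from_sequences(
                taxa, seqs, reference_taxon=reference_taxon, chrom=chrom, ref_start=start
            )
        )
    return blocks


def write_manifest(fragments, report: FragmentFilterReport | None, path) -> None:
    """TSV manifest: fragment id, chrom, start, end, informative sites,
    mean JC distance, kept/removed status."""
    kept = set(report.kept_indices) if report is not None else None
    with open(path, "w") as fh:
        fh.write("fragment\tchrom\tstart\tend\tn_informative\tmean_jc_distance\tstatus\n")
        for f in fragments:
            status = "kept" if kept is None or f.index in kept else "removed"
            fh.write(
                f"{f.index}\t{f.chrom}\t{f.start}\t{f.end}\t{f.n_informative}\t"
                f"{f.mean_pairwise_distance:.6g}\t{status}\n"
            )
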