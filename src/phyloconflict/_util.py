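"""Shared helpers: errors, RNG sub-streams, leaf-set bitmask utilities."""

from __future__ import annotations

import numpy as np


class PhyloconflictError(Exception):
    """Base class for package errors."""


class InputError(PhyloconflictError):
    """Invalid argument or malformed input data."""


class ConfigurationError(PhyloconflictError):
    """Inconsistent model or pipeline configuration."""


class InsufficientDataError(PhyloconflictError):
    """Too few observations for the requested estimate."""


class DegenerateDataError(PhyloconflictError):
    """Data admit no meaningful estimate (e.g. all-zero branch lengths)."""


def substream(seed: int | None, *key: int) -> np.random.Generator:
    """Derive a deterministic child generator from a global seed.

    Every source of randomness in the package flows through a single
    integer seed; sub-streams are keyed by small integers (e.g. locus
    index) so any unit of work is reproducible in isolation.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def leaf_bit_index(labels) -> dict[str, int]:
    """Map sorted taxon labels to bit positions for leaf-set masks."""
    ordered = sorted(set(labels))
    return {lab: i for i, lab in enumerate(ordered)}


def clade_masks(tree, bit_index: dict[str, int]):
    """Return (per-node leafset masks dict, full mask) for a dendropy tree.

    Leaves whose label is not in ``bit_index`` contribute no bits (they
    are invisible to mask-based queries).
    """
    masks: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            masks[node] = 1 << bit_index[label] if label in bit_index else 0
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    full = (1 << len(bit_index)) - 1
    return masks, full
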