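"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately work per base on dense boolean vectors so they
stay independent of the interval arithmetic used by the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from episegsom.format_io import GenomeLayout, RegionSet


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def tiny_layout():
    return GenomeLayout({"chr1": 1_000})


def oracle_call_regions(kept_positions, max_gap, min_len):
    """Per-base merge/filter oracle for region calling.

    Label every base lying between consecutive kept positions whose distance
    is strictly below ``max_gap``, extract maximal runs, filter by length.
    """
    kept = sorted(set(int(p) for p in kept_positions))
    if not kept:
        return []
    top = kept[-1] + 1
    marked = np.zeros(top, dtype=bool)
    for p in kept:
        marked[p] = True
    for a, b in zip(kept, kept[1:]):
        if b - a < max_gap:
            marked[a : b + 1] = True
    padded = np.concatenate(([0], marked.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def oracle_segment_chromosome(ref_masks, min_len):
    """Per-base labeling oracle for boundary segmentation of one chromosome.

    Stack the reference masks into a per-base label, extract maximal
    constant-label runs, filter by length. Returns (start, end, bits) tuples.
    """
    stacked = np.stack([m.astype(np.int8) for m in ref_masks], axis=1)
    length = stacked.shape[0]
    change = np.any(stacked[1:] != stacked[:-1], axis=1)
    cuts = np.concatenate(([0], np.flatnonzero(change) + 1, [length]))
    out = []
    for s, e in zip(cuts, cuts[1:]):
        if e - s >= min_len:
            out.append((int(s), int(e), tuple(int(b) for b in stacked[s])))
    return out


def oracle_coverage(mask, start, end):
    """Base-counting coverage oracle."""
    return float(mask[start:end].sum()) / (end - start)


def random_region_set(rng, layout, chrom="chr1", n_max=8, len_min=100, len_max=3000,
                      label="state"):
    """A random merged RegionSet on one chromosome."""
    length = layout[chrom]
    k = int(rng.integers(0, n_max + 1))
    ivs = []
    for _ in range(k):
        size = int(rng.integers(len_min, len_max + 1))
        start = int(rng.integers(0, max(1, length - size)))
        ivs.append((start, start + size))
    return RegionSet(label, layout, {chrom: ivs} if ivs else {})
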