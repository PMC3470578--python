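"""Binary discretization of per-position read counts into modification states.

The pipeline is: optional H3 validation of the modification counts, positional
enrichment against the whole-cell-extract (WCE) control, then region calling
by joining nearby enriched positions and discarding short regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .format_io import CountTrack, GenomeLayout, RegionSet

__all__ = [
    "DiscretizationConfig",
    "EnrichmentTrack",
    "validate_against_h3",
    "compute_enrichment",
    "call_modified_regions",
    "discretize_track",
]


@dataclass
class DiscretizationConfig:
    """Thresholds for enrichment-based region calling.

    A position is kept when its enrichment ratio is >= ``enrichment_threshold``
    (inclusive). Consecutive kept positions are joined when their coordinate
    difference is strictly smaller than ``max_join_gap``. Candidate regions
    shorter than ``min_region_length`` are treated as unmodified and dropped.
    ``wce_zero_policy`` decides what happens at positions with modification
    reads but zero control reads: ``exclude`` leaves the ratio undefined,
    ``pseudocount`` divides by ``pseudocount`` instead.
    """

    enrichment_threshold: float = 3.0
    max_join_gap: int = 100
    min_region_length: int = 100
    wce_zero_policy: str = "exclude"
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.enrichment_threshold <= 0:
            raise ValidationError("enrichment_threshold must be > 0")
        if self.max_join_gap <= 0:
            raise ValidationError("max_join_gap must be > 0")
        if self.min_region_length <= 0:
            raise ValidationError("min_region_length must be > 0")
        if self.wce_zero_policy not in ("exclude", "pseudocount"):
            raise ValidationError(f"unknown wce_zero_policy {self.wce_zero_policy!r}")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")


@dataclass
class EnrichmentTrack:
    """Sparse per-position enrichment ratios; undefined positions are absent."""

    layout: GenomeLayout
    data: dict[str, dict[int, float]] = field(default_factory=dict)

    def ratios(self, chrom: str) -> dict[int, float]:
        return self.data.get(chrom, {})


def validate_against_h3(mod: CountTrack, h3: CountTrack) -> CountTrack:
    """Zero modification counts wherever the H3 control has no reads.

    Positions with h3 > 0 pass through untouched; positions with h3 == 0 are
    dropped from the sparse mapping.
    """
    if mod.layout != h3.layout:
        raise ValidationError("modification and H3 tracks are on different layouts")
    data: dict[str, dict[int, int]] = {}
    for chrom, counts in mod.data.items():
        h3_counts = h3.counts(chrom)
        kept = {p: v for p, v in counts.items() if h3_counts.get(p, 0) > 0}
        if kept:
            data[chrom] = kept
    return CountTrack(mod.layout, data)


def compute_enrichment(
    mod: CountTrack, wce: CountTrack, cfg: DiscretizationConfig | None = None
) -> EnrichmentTrack:
    """Positional enrichment = modification count / WCE count.

    Only positions with a modification count > 0 carry a ratio; 0/0 is
    undefined by construction. WCE zeros follow ``cfg.wce_zero_policy``.
    """
    cfg = cfg or DiscretizationConfig()
    if mod.layout != wce.layout:
        raise ValidationError("modification and WCE tracks are on different layouts")
    data: dict[str, dict[int, float]] = {}
    for chrom, counts in mod.data.items():
        wce_counts = wce.counts(chrom)
        ratios: dict[int, float] = {}
        for pos, count in counts.items():
            if count <= 0:
                continue
            denom = wce_counts.get(pos, 0)
            if denom > 0:
                ratios[pos] = count / denom
            elif cfg.wce_zero_policy == "pseudocount":
                ratios[pos] = count / cfg.pseudocount
            # exclude: undefined, position skipped
        if ratios:
            data[chrom] = ratios
    return EnrichmentTrack(mod.layout, data)


def call_modified_regions(
    enr: EnrichmentTrack, cfg: DiscretizationConfig | None = None, label: str = "MS"
) -> RegionSet:
    """Join enriched positions into modified regions.

    Kept positions (ratio >= threshold) are scanned per chromosome in
    coordinate order; a region extends while the gap to the next kept
    position is strictly below ``max_join_gap``. The region interval is
    [first_kept, last_kept + 1). Regions shorter than
    ``min_region_length`` are dropped.
    """
    cfg = cfg or DiscretizationConfig()
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, ratios in enr.data.items():
        kept = np.array(
            sorted(p for p, r in ratios.items() if r >= cfg.enrichment_threshold),
            dtype=np.int64,
        )
        if kept.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(kept) >= cfg.max_join_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [kept.size - 1]))
        out = []
        for i, j in zip(starts, ends):
            region = (int(kept[i]), int(kept[j]) + 1)
            if region[1] - region[0] >= cfg.min_region_length:
                out.append(region)
        if out:
            intervals[chrom] = out
    return RegionSet(label, enr.layout, intervals)


def discretize_track(
    mod: CountTrack,
    wce: CountTrack,
    h3: CountTrack | None = None,
    cfg: DiscretizationConfig | None = None,
    label: str = "MS",
) -> RegionSet:
    """Full discretization: optional H3 validation, enrichment, region calling."""
    cfg = cfg or DiscretizationConfig()
    if h3 is not None:
        mod = validate_against_h3(mod, h3)
    return call_modified_regions(compute_enrichment(mod, wce, cfg), cfg, label=label)
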