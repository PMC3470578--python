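"""Readers and writers for every external file format the pipeline touches.

All genomic intervals are 0-based half-open (BED convention) internally.
GTF input is converted on read. Chromosome names are matched by exact
string equality; no ``chr`` aliasing is attempted.
"""

from __future__ import annotations

import csv
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BoundsError, ParseError, ValidationError

__all__ = [
    "GenomeLayout",
    "CountTrack",
    "RegionSet",
    "GeneModel",
    "ExpressionTable",
    "read_chrom_sizes",
    "read_count_track",
    "write_count_track",
    "read_regions",
    "read_gene_models",
    "read_expression",
    "read_fasta",
    "write_fasta",
    "write_node_matrix",
    "read_node_matrix",
]


class GenomeLayout(Mapping):
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int] | list[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        seen: dict[str, int] = {}
        for name, length in items:
            if name in seen:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
            seen[name] = length
        self._sizes = seen

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self):
        return len(self._sizes)

    def __repr__(self):
        return f"GenomeLayout({self._sizes!r})"

    def __eq__(self, other):
        return isinstance(other, GenomeLayout) and self._sizes == other._sizes

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._sizes:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self._sizes[chrom]:
            raise BoundsError(
                f"interval [{start}, {end}) outside chromosome {chrom!r} "
                f"of length {self._sizes[chrom]}"
            )
        if end <= start:
            raise ValidationError(f"empty or inverted interval [{start}, {end}) on {chrom!r}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column chromosome-sizes TSV."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 tab-separated columns", path, i)
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ParseError(f"bad length field {fields[1]!r}", path, i) from exc
    return GenomeLayout(pairs)


@dataclass
class CountTrack:
    """Sparse per-position read counts; positions absent from the mapping are 0."""

    layout: GenomeLayout
    data: dict[str, dict[int, int]] = field(default_factory=dict)

    def counts(self, chrom: str) -> dict[int, int]:
        return self.data.get(chrom, {})

    def get(self, chrom: str, pos: int) -> int:
        return self.data.get(chrom, {}).get(pos, 0)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(self.data.get(chrom, {})), dtype=np.int64)

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.data.values())

    def validate(self) -> None:
        for chrom, d in self.data.items():
            if chrom not in self.layout:
                raise BoundsError(f"unknown chromosome {chrom!r}")
            length = self.layout[chrom]
            for pos, count in d.items():
                if not 0 <= pos < length:
                    raise BoundsError(f"position {pos} outside {chrom!r} (length {length})")
                if count < 0:
                    raise ValidationError(f"negative count {count} at {chrom}:{pos}")


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Union of possibly overlapping/adjacent half-open intervals, sorted by start."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


class RegionSet:
    """Merged, sorted, non-adjacent intervals per chromosome; one modification state."""

    def __init__(
        self,
        label: str,
        layout: GenomeLayout,
        intervals: Mapping[str, "np.ndarray | list"] | None = None,
    ):
        self.label = label
        self.layout = layout
        self._intervals: dict[str, np.ndarray] = {}
        for chrom, ivs in (intervals or {}).items():
            arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                continue
            if np.any(arr[:, 0] >= arr[:, 1]):
                bad = arr[arr[:, 0] >= arr[:, 1]][0]
                raise ValidationError(f"invalid interval [{bad[0]}, {bad[1]}) on {chrom!r}")
            if chrom not in layout:
                raise BoundsError(f"unknown chromosome {chrom!r}")
            if arr[:, 0].min() < 0 or arr[:, 1].max() > layout[chrom]:
                raise BoundsError(f"interval outside chromosome {chrom!r}")
            merged = _merge_intervals(arr)
            if len(merged):
                self._intervals[chrom] = merged

    def chromosomes(self) -> list[str]:
        return [c for c in self.layout if c in self._intervals]

    def intervals(self, chrom: str) -> np.ndarray:
        return self._intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def n_regions(self) -> int:
        return sum(len(a) for a in self._intervals.values())

    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._intervals.values()))

    def to_mask(self, chrom: str) -> np.ndarray:
        """Boolean per-base vector over the full chromosome."""
        mask = np.zeros(self.layout[chrom], dtype=bool)
        for start, end in self.intervals(chrom):
            mask[start:end] = True
        return mask

    @classmethod
    def from_mask(cls, label: str, layout: GenomeLayout, chrom: str, mask: np.ndarray):
        diff = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        return cls(label, layout, {chrom: np.column_stack([starts, ends])})

    def __eq__(self, other):
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._intervals) != set(other._intervals):
            return False
        return all(np.array_equal(self._intervals[c], other._intervals[c]) for c in self._intervals)

    def __repr__(self):
        return f"RegionSet({self.label!r}, {self.n_regions()} regions, {self.total_bases()} bp)"

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes():
                for start, end in self.intervals(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class GeneModel:
    """One gene with its transcript intervals (0-based half-open) and strands."""

    gene_id: str
    chrom: str
    transcripts: list[tuple[int, int, str]] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        starts, ends, _ = zip(*self.transcripts)
        return min(starts), max(ends)


@dataclass
class ExpressionTable:
    """Per-gene binary present/absent flags, one column per cell type."""

    cell_types: list[str]
    flags: dict[str, dict[str, int]] = field(default_factory=dict)

    def present_in_all(self, gene_id: str) -> int:
        row = self.flags[gene_id]
        return int(all(row[c] == 1 for c in self.cell_types))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.flags


def read_count_track(path, layout: GenomeLayout) -> CountTrack:
    """Parse a 4-column bedGraph into a sparse count track.

    Every covered base receives the record's value. Values must be integral
    and non-negative; overlapping count records are an error (ambiguity
    fails loudly rather than being summed).
    """
    covered: dict[str, list[tuple[int, int]]] = {}
    data: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError("expected 4 bedGraph columns", path, i)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates {fields[1:3]}", path, i) from exc
            try:
                raw = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"non-numeric value {fields[3]!r}", path, i) from exc
            if raw != int(raw):
                raise ParseError(f"non-integer count value {fields[3]!r}", path, i)
            value = int(raw)
            if value < 0:
                raise ParseError(f"negative count {value}", path, i)
            layout.check_interval(chrom, start, end)
            covered.setdefault(chrom, []).append((start, end))
            if value > 0:
                d = data.setdefault(chrom, {})
                for pos in range(start, end):
                    d[pos] = value
    for chrom, ivs in covered.items():
        ivs.sort()
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"overlapping count records on {chrom!r} near position {s2}", path
                )
    return CountTrack(layout, data)


def write_count_track(track: CountTrack, path) -> None:
    """Write a sparse count track as bedGraph, run-length compressing equal counts."""
    with open(path, "w") as fh:
        for chrom in track.layout:
            d = track.counts(chrom)
            if not d:
                continue
            positions = sorted(p for p, v in d.items() if v > 0)
            if not positions:
                continue
            run_start = positions[0]
            run_value = d[run_start]
            prev = run_start
            for pos in positions[1:]:
                if pos == prev + 1 and d[pos] == run_value:
                    prev = pos
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value}\n")
                run_start = prev = pos
                run_value = d[pos]
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_value}\n")


def read_regions(path, layout: GenomeLayout, label: str | None = None) -> RegionSet:
    """Read a BED3+ file; overlapping/adjacent input intervals are unioned."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError("expected >= 3 BED columns", path, i)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates {fields[1:3]}", path, i) from exc
            if start >= end:
                raise ValidationError(f"start >= end at {path}:{i}: [{start}, {end})")
            layout.check_interval(chrom, start, end)
            intervals.setdefault(chrom, []).append((start, end))
    return RegionSet(label or str(path), layout, intervals)


_STRANDS = {"+", "-"}


def _parse_gtf_attrs(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path, layout: GenomeLayout, fmt: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GTF (dialect chosen by ``fmt``, no sniffing).

    Transcript intervals are clipped to chromosome bounds. One GeneModel per
    gene id, transcripts grouped under it.
    """
    if fmt not in ("bed12", "gtf"):
        raise ValidationError(f"unknown gene-model format {fmt!r}")
    genes: dict[str, GeneModel] = {}
    if fmt == "bed12":
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError("expected >= 6 BED columns for gene models", path, i)
                chrom, start, end, name, _score, strand = fields[:6]
                if strand not in _STRANDS:
                    raise ValidationError(f"unknown strand {strand!r} at {path}:{i}")
                if chrom not in layout:
                    raise BoundsError(f"unknown chromosome {chrom!r} at {path}:{i}")
                start = max(0, int(start))
                end = min(layout[chrom], int(end))
                if end <= start:
                    raise ValidationError(f"empty transcript at {path}:{i}")
                model = genes.setdefault(name, GeneModel(name, chrom))
                model.transcripts.append((start, end, strand))
    else:
        # group transcript spans by transcript_id under gene_id; GTF is 1-based inclusive
        spans: dict[tuple[str, str], list] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ParseError("expected 9 GTF columns", path, i)
                chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                if feature not in ("transcript", "exon", "mRNA"):
                    continue
                if strand not in _STRANDS:
                    raise ValidationError(f"unknown strand {strand!r} at {path}:{i}")
                if chrom not in layout:
                    raise BoundsError(f"unknown chromosome {chrom!r} at {path}:{i}")
                parsed = _parse_gtf_attrs(attrs)
                gene_id = parsed.get("gene_id")
                tx_id = parsed.get("transcript_id", gene_id)
                if gene_id is None:
                    raise ParseError("GTF record without gene_id", path, i)
                s0 = max(0, int(start) - 1)
                e0 = min(layout[chrom], int(end))
                key = (gene_id, tx_id)
                if key not in spans:
                    spans[key] = [chrom, s0, e0, strand]
                else:
                    spans[key][1] = min(spans[key][1], s0)
                    spans[key][2] = max(spans[key][2], e0)
        for (gene_id, _tx), (chrom, s0, e0, strand) in spans.items():
            model = genes.setdefault(gene_id, GeneModel(gene_id, chrom))
            model.transcripts.append((s0, e0, strand))
    return list(genes.values())


def read_expression(path) -> ExpressionTable:
    """Read a TSV of gene id plus one 0/1 present-call column per cell type."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = df.columns[0]
    cells = list(df.columns[1:])
    if not cells:
        raise ParseError("expression table needs at least one cell-type column", path)
    flags: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        entry = {}
        for cell in cells:
            value = int(row[cell])
            if value not in (0, 1):
                raise ValidationError(f"present flag must be 0/1, got {value} for {row[gene_col]}")
            entry[cell] = value
        flags[str(row[gene_col])] = entry
    return ExpressionTable(cells, flags)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-cased sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_node_matrix(node_map, path) -> None:
    """Write a NodeMap as a TSV grid (header of column indices, NA for masked)."""
    height, width = node_map.shape
    values = np.asarray(node_map.values, dtype=float)
    if values.size != height * width:
        raise ValidationError(
            f"value count {values.size} != grid size {height * width}"
        )
    mask = np.asarray(node_map.mask, dtype=bool)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow([str(c) for c in range(width)])
        for r in range(height):
            row = []
            for c in range(width):
                k = r * width + c
                row.append("NA" if mask[k] else repr(float(values[k])))
            writer.writerow(row)


def read_node_matrix(path) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Read a node-matrix TSV back; returns (values, mask, (height, width))."""
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        width = len(header)
        values, mask = [], []
        for row in reader:
            if len(row) != width:
                raise ParseError(f"ragged row with {len(row)} cells (expected {width})", path)
            for cell in row:
                if cell == "NA":
                    values.append(np.nan)
                    mask.append(True)
                else:
                    values.append(float(cell))
                    mask.append(False)
    height = len(values) // width
    return np.array(values), np.array(mask, dtype=bool), (height, width)
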