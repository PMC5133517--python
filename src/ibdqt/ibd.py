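"""Refined-IBD segment handling and the pairs-by-markers sharing matrix.

The marker scan works on a binary matrix with one row per unordered pair of
individuals and one column per marker: cell (pair, marker) is 1 when a
detected IBD segment of that pair covers the marker's physical position.
Segments arrive as Beagle Refined IBD output (tab-separated, 8 columns, no
header); several detection runs with different seeds are merged into a single
pair-level segment set before the matrix is built.

Coordinates are 1-based physical positions (bp); the marker-in-segment test
uses the closed interval [start_bp, end_bp].  Genetic positions (cM) come from
a HapMap-style recombination map by piecewise-linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import GeneticMapError, IbdParseError, IbdqtError


class IbdSegment(NamedTuple):
    """One pairwise IBD segment as reported by Refined IBD."""

    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start_bp: int
    end_bp: int
    lod: float

    def pair(self) -> tuple[str, str]:
        """The unordered pair key (lexicographically sorted ids)."""
        return (self.id1, self.id2) if self.id1 <= self.id2 else (self.id2, self.id1)


def parse_ibd(path) -> list[IbdSegment]:
    """Parse a Refined-IBD ``.ibd`` file (8 tab-separated columns, no header).

    Columns: sample1, haplotype1, sample2, haplotype2, chromosome, start bp,
    end bp, LOD.  Line order is preserved.  Malformed lines raise
    :class:`IbdParseError` carrying the 1-based line number.
    """
    segments: list[IbdSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise IbdParseError(lineno, f"expected 8 tab-separated columns, got {len(fields)}")
            try:
                seg = IbdSegment(
                    id1=fields[0],
                    hap1=int(fields[1]),
                    id2=fields[2],
                    hap2=int(fields[3]),
                    chrom=fields[4],
                    start_bp=int(fields[5]),
                    end_bp=int(fields[6]),
                    lod=float(fields[7]),
                )
            except ValueError as exc:
                raise IbdParseError(lineno, f"non-numeric field: {exc}") from None
            if seg.start_bp >= seg.end_bp:
                raise IbdParseError(lineno, f"start {seg.start_bp} not before end {seg.end_bp}")
            if seg.id1 == seg.id2:
                raise IbdParseError(lineno, f"segment pairs individual {seg.id1!r} with itself")
            segments.append(seg)
    return segments


def write_ibd(segments: Iterable[IbdSegment], path) -> None:
    """Write segments in the Refined-IBD 8-column dialect (no header)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.id1}\t{s.hap1}\t{s.id2}\t{s.hap2}\t{s.chrom}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.lod:.2f}\n"
            )


def merge_runs(runs: Sequence[Sequence[IbdSegment]]) -> list[IbdSegment]:
    """Union the segments of several detection runs at the pair level.

    Haplotype indices are ignored (a pair shares wherever any haplotype pair
    shares); per pair, overlapping or book-ended intervals (gap tolerance
    0 bp, i.e. next start <= current end + 1) are coalesced.  The merged
    segment keeps the maximum LOD of its constituents and haplotype index 0
    to mark pair-level provenance.  Output is sorted by (pair, start).

    All runs must be on a single chromosome; mixing chromosomes raises.
    Merging is idempotent and order-independent across runs.
    """
    all_segments = [seg for run in runs for seg in run]
    if not all_segments:
        return []
    chroms = {s.chrom for s in all_segments}
    if len(chroms) > 1:
        raise IbdqtError(f"segments span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    by_pair: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    for s in all_segments:
        by_pair.setdefault(s.pair(), []).append((s.start_bp, s.end_bp, s.lod))

    merged: list[IbdSegment] = []
    for pair in sorted(by_pair):
        intervals = sorted(by_pair[pair])
        cur_start, cur_end, cur_lod = intervals[0]
        for start, end, lod in intervals[1:]:
            if start <= cur_end + 1:  # overlap or book-ended
                cur_end = max(cur_end, end)
                cur_lod = max(cur_lod, lod)
            else:
                merged.append(IbdSegment(pair[0], 0, pair[1], 0, chrom, cur_start, cur_end, cur_lod))
                cur_start, cur_end, cur_lod = start, end, lod
        merged.append(IbdSegment(pair[0], 0, pair[1], 0, chrom, cur_start, cur_end, cur_lod))
    return merged


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear genetic map: physical anchors (bp) with cM positions."""

    chrom: str
    positions_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if pos.size != cm.size:
            raise GeneticMapError("positions and cM arrays differ in length")
        if pos.size == 0:
            raise GeneticMapError("empty genetic map")
        if pos.size > 1 and not (np.diff(pos) > 0).all():
            raise GeneticMapError("anchor positions must be strictly increasing")
        if pos.size > 1 and not (np.diff(cm) >= 0).all():
            raise GeneticMapError("cM values must be non-decreasing")
        object.__setattr__(self, "positions_bp", pos)
        object.__setattr__(self, "cm", cm)

    @classmethod
    def read(cls, path, chrom: str | None = None) -> "GeneticMap":
        """Read a HapMap-style map: one header line, then position, rate (cM/Mb), cM."""
        table = pd.read_csv(path, sep=r"\s+", header=0)
        if table.shape[1] < 3:
            raise GeneticMapError("expected 3 whitespace-separated columns")
        pos = table.iloc[:, 0].to_numpy(dtype=float)
        cm = table.iloc[:, 2].to_numpy(dtype=float)
        return cls(chrom or "?", pos, cm)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position COMBINED_rate(cM/Mb) Genetic_Map(cM)\n")
            pos, cm = self.positions_bp, self.cm
            for i in range(pos.size):
                if i + 1 < pos.size:
                    rate = (cm[i + 1] - cm[i]) / (pos[i + 1] - pos[i]) * 1e6
                else:
                    rate = 0.0
                fh.write(f"{int(pos[i])} {rate:.6f} {cm[i]:.6f}\n")

    def interpolate(self, position_bp):
        """Genetic position (cM) of physical position(s) by linear interpolation.

        Positions outside the anchor range are extrapolated with the nearest
        terminal inter-anchor recombination rate (constant-rate extension).
        A single-anchor map is treated as rate 0 away from the anchor.
        """
        q = np.asarray(position_bp, dtype=float)
        pos, cm = self.positions_bp, self.cm
        if pos.size == 1:
            out = np.full_like(q, cm[0], dtype=float)
            return float(out) if out.ndim == 0 else out
        out = np.interp(q, pos, cm)
        lo_rate = (cm[1] - cm[0]) / (pos[1] - pos[0])
        hi_rate = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
        out = np.where(q < pos[0], cm[0] + (q - pos[0]) * lo_rate, out)
        out = np.where(q > pos[-1], cm[-1] + (q - pos[-1]) * hi_rate, out)
        return float(out) if out.ndim == 0 else out


def interpolate_cM(genetic_map: GeneticMap, position_bp):
    """Functional alias for :meth:`GeneticMap.interpolate` (needs >= 2 anchors)."""
    if genetic_map.positions_bp.size < 2:
        raise GeneticMapError("interpolation needs at least 2 anchors")
    return genetic_map.interpolate(position_bp)


@dataclass
class IbdMatrix:
    """Binary pairs x markers IBD-sharing indicator matrix.

    Rows run over ALL unordered pairs of the sample set, lexicographically
    ordered, including pairs that never share (all-zero rows); columns follow
    the marker positions in increasing bp order.  Stored sparse (CSC uint8)
    because chromosome-wide sharing rates are of order 1e-3.
    """

    pairs: list[tuple[str, str]]
    marker_positions_bp: np.ndarray
    indicator: sp.csc_matrix
    chrom: str = "?"
    pair_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.marker_positions_bp = np.asarray(self.marker_positions_bp, dtype=np.int64)
        self.pair_index = {p: i for i, p in enumerate(self.pairs)}
        if self.indicator.shape != (len(self.pairs), self.marker_positions_bp.size):
            raise IbdqtError(
                f"indicator shape {self.indicator.shape} does not match "
                f"{len(self.pairs)} pairs x {self.marker_positions_bp.size} markers"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_markers(self) -> int:
        return int(self.marker_positions_bp.size)

    def individuals(self) -> list[str]:
        """Sorted sample ids underlying the pair rows."""
        return sorted({i for p in self.pairs for i in p})

    def mean_sharing_rate(self) -> float:
        """Chromosome-wide mean per-marker sharing rate: 1-cells / (pairs x markers)."""
        return float(self.indicator.nnz) / (self.n_pairs * self.n_markers)


def build_matrix(
    segments: Sequence[IbdSegment],
    marker_positions_bp: Sequence[int],
    samples: Sequence[str],
    chrom: str | None = None,
) -> IbdMatrix:
    """Build the binary pairs x markers matrix from merged segments.

    A cell is 1 iff some segment of that pair satisfies
    ``start_bp <= marker <= end_bp`` (closed interval).  ``samples`` defines
    the full unrelated set: every unordered pair appears as a row even with no
    segments.  If ``chrom`` is given, segments on any other chromosome raise;
    otherwise the (single) segment chromosome is adopted.
    """
    markers = np.asarray(marker_positions_bp, dtype=np.int64)
    if markers.size and not (np.diff(markers) >= 0).all():
        raise IbdqtError("marker positions must be sorted")
    seg_chroms = {s.chrom for s in segments}
    if chrom is not None and seg_chroms - {chrom}:
        raise IbdqtError(
            f"markers are on chromosome {chrom} but segments include {sorted(seg_chroms - {chrom})}"
        )
    if chrom is None and len(seg_chroms) > 1:
        raise IbdqtError(f"segments span multiple chromosomes: {sorted(seg_chroms)}")

    sample_set = set(samples)
    pairs = list(combinations(sorted(sample_set), 2))
    pair_index = {p: i for i, p in enumerate(pairs)}

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for seg in segments:
        key = seg.pair()
        if key not in pair_index:
            continue  # segment involves an individual outside the unrelated set
        lo = int(np.searchsorted(markers, seg.start_bp, side="left"))
        hi = int(np.searchsorted(markers, seg.end_bp, side="right"))
        if hi > lo:
            cols.append(np.arange(lo, hi))
            rows.append(np.full(hi - lo, pair_index[key]))

    if rows:
        row_idx = np.concatenate(rows)
        col_idx = np.concatenate(cols)
        data = np.ones(row_idx.size, dtype=np.uint8)
        mat = sp.coo_matrix((data, (row_idx, col_idx)), shape=(len(pairs), markers.size))
        mat = mat.tocsc()
        mat.data[:] = 1  # collapse duplicate hits to a binary indicator
        mat.sum_duplicates()
        mat.data[:] = 1
    else:
        mat = sp.csc_matrix((len(pairs), markers.size), dtype=np.uint8)
    resolved_chrom = chrom if chrom is not None else (seg_chroms.pop() if seg_chroms else "?")
    return IbdMatrix(pairs=pairs, marker_positions_bp=markers, indicator=mat, chrom=resolved_chrom)


def sharing_rate(matrix: IbdMatrix, markers) -> float:
    """Fraction of pairs sharing at a marker or anywhere in a marker range.

    ``markers`` is a single column index or an inclusive ``(first, last)``
    index range; a pair counts if it shares at ANY marker in the range.
    """
    if matrix.n_pairs == 0 or matrix.n_markers == 0:
        raise IbdqtError("empty IBD matrix")
    if np.isscalar(markers):
        first = last = int(markers)
    else:
        first, last = (int(markers[0]), int(markers[1]))
    if last < first:
        raise IbdqtError(f"empty marker range ({first}, {last})")
    if first < 0 or last >= matrix.n_markers:
        raise IbdqtError(f"marker range ({first}, {last}) outside 0..{matrix.n_markers - 1}")
    sub = matrix.indicator[:, first:last + 1]
    sharing_pairs = int((sub.sum(axis=1) > 0).sum())
    return sharing_pairs / matrix.n_pairs


# ---------------------------------------------------------------------------
# on-disk matrix format: sparse triplets + marker index + pair roster

def write_matrix(matrix: IbdMatrix, out_dir) -> dict[str, str]:
    """Write an IbdMatrix as plain-text files; returns the file manifest.

    ``triplets.tsv`` holds one line per 1-cell (pair_id1, pair_id2,
    marker_index); ``markers.tsv`` the marker positions; ``samples.txt`` the
    sample roster from which the full pair set is reconstructed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = matrix.indicator.tocoo()
    with open(out / "triplets.tsv", "w") as fh:
        fh.write("id1\tid2\tmarker_index\n")
        order = np.lexsort((coo.col, coo.row))
        for r, c in zip(coo.row[order], coo.col[order]):
            p = matrix.pairs[r]
            fh.write(f"{p[0]}\t{p[1]}\t{c}\n")
    with open(out / "markers.tsv", "w") as fh:
        fh.write("marker_index\tposition_bp\n")
        for i, pos in enumerate(matrix.marker_positions_bp):
            fh.write(f"{i}\t{pos}\n")
    with open(out / "samples.txt", "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n")
        for s in matrix.individuals():
            fh.write(f"{s}\n")
    return {name: str(out / name) for name in ("triplets.tsv", "markers.tsv", "samples.txt")}


def read_matrix(in_dir) -> IbdMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    in_dir = Path(in_dir)
    markers = pd.read_csv(in_dir / "markers.tsv", sep="\t")["position_bp"].to_numpy(np.int64)
    chrom = "?"
    samples: list[str] = []
    with open(in_dir / "samples.txt") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#chrom="):
                chrom = line.split("=", 1)[1]
            elif line:
                samples.append(line)
    pairs = list(combinations(sorted(samples), 2))
    pair_index = {p: i for i, p in enumerate(pairs)}
    trip = pd.read_csv(in_dir / "triplets.tsv", sep="\t", dtype={"id1": str, "id2": str})
    rows = [pair_index[(a, b) if a <= b else (b, a)] for a, b in zip(trip["id1"], trip["id2"])]
    cols = trip["marker_index"].to_numpy()
    mat = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.uint8), (rows, cols)),
        shape=(len(pairs), markers.size),
    ).tocsc()
    return IbdMatrix(pairs=pairs, marker_positions_bp=markers, indicator=mat, chrom=chrom)
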