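"""Genome coordinate system, interval algebra, and binned signal tracks.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; conversion to 1-based display coordinates, where needed, happens
only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class LayoutMismatchError(ValueError):
    """Two objects refer to different genome layouts."""


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes with their lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in number")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be strictly positive")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths.keys()), tuple(int(v) for v in lengths.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def items(self):
        return zip(self.chrom_names, self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, optionally labelled genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_COLUMNS = ["chrom", "start", "end", "strand", "label", "score"]


class IntervalSet:
    """A sorted collection of genomic intervals backed by a DataFrame.

    Normalisation sorts by (chrom, start, end). Domain-type sets (LADs,
    TADs, chromatin states) are expected to be non-overlapping within a
    chromosome; ``merge`` produces such a set from any input.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] | pd.DataFrame = (),
                 layout: GenomeLayout | None = None):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
            for col, default in (("strand", "."), ("label", ""), ("score", np.nan)):
                if col not in df.columns:
                    df[col] = default
            df = df[_COLUMNS]
        else:
            rows = [(iv.chrom, iv.start, iv.end, iv.strand, iv.label,
                     np.nan if iv.score is None else iv.score)
                    for iv in intervals]
            df = pd.DataFrame(rows, columns=_COLUMNS)
            if df.empty:
                df = pd.DataFrame(columns=_COLUMNS)
        df["start"] = df["start"].astype(np.int64) if len(df) else df.get("start", pd.Series(dtype=np.int64))
        if len(df):
            df["end"] = df["end"].astype(np.int64)
        self.df = df.reset_index(drop=True)
        self.layout = layout
        if layout is not None:
            self.validate_against(layout)
        self._sort()

    def _sort(self):
        if len(self.df):
            self.df = self.df.sort_values(
                ["chrom", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)

    def validate_against(self, layout: GenomeLayout):
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in layout:
                raise LayoutMismatchError(f"unknown chromosome {chrom!r}")
            if (grp["end"] > layout.length_of(chrom)).any():
                raise ValueError(f"interval beyond end of {chrom}")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand, row.label,
                                  None if pd.isna(row.score) else float(row.score))

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self.df.iloc[i]
        return GenomicInterval(row.chrom, int(row.start), int(row.end),
                               row.strand, row.label,
                               None if pd.isna(row.score) else float(row.score))

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def total_length(self) -> int:
        if not len(self.df):
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def merge(self) -> "IntervalSet":
        """Union of all intervals: sorted, non-overlapping, strand-agnostic."""
        out = []
        for chrom, grp in self.df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return IntervalSet(
            pd.DataFrame(out, columns=["chrom", "start", "end"])
            if out else pd.DataFrame(columns=_COLUMNS),
            layout=self.layout,
        )

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[np.asarray(mask)], layout=self.layout)


def bin_genome(layout: GenomeLayout, bin_size: int) -> IntervalSet:
    """Tile every chromosome with consecutive bins; the last bin may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in layout.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return IntervalSet(pd.concat(rows, ignore_index=True), layout=layout)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-pair overlap segments between two interval sets."""
    if a.layout is not None and b.layout is not None and a.layout != b.layout:
        raise LayoutMismatchError("interval sets are on different layouts")
    out = []
    b_by_chrom = dict(tuple(b.df.groupby("chrom", sort=False)))
    for chrom, grp in a.df.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            continue
        bs = b_by_chrom[chrom]["start"].to_numpy()
        be = b_by_chrom[chrom]["end"].to_numpy()
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            # sorted by start: candidates have bs < e and be > s
            hi = np.searchsorted(bs, e, side="left")
            sel = be[:hi] > s
            for os_, oe in zip(np.maximum(bs[:hi][sel], s),
                               np.minimum(be[:hi][sel], e)):
                out.append((chrom, int(os_), int(oe)))
    return IntervalSet(
        pd.DataFrame(out, columns=["chrom", "start", "end"])
        if out else pd.DataFrame(columns=_COLUMNS),
        layout=a.layout or b.layout,
    )


def overlap_lengths(targets: IntervalSet, query: IntervalSet) -> np.ndarray:
    """Base pairs of each target covered by the *union* of query intervals."""
    merged = query.merge()
    q_by_chrom = dict(tuple(merged.df.groupby("chrom", sort=False)))
    out = np.zeros(len(targets), dtype=np.int64)
    for i, row in enumerate(targets.df.itertuples(index=False)):
        grp = q_by_chrom.get(row.chrom)
        if grp is None:
            continue
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        hi = np.searchsorted(qs, row.end, side="left")
        sel = qe[:hi] > row.start
        if sel.any():
            out[i] = int(np.sum(np.minimum(qe[:hi][sel], row.end)
                                - np.maximum(qs[:hi][sel], row.start)))
    return out


def coverage_fraction(targets: IntervalSet, query: IntervalSet) -> np.ndarray:
    """Fraction of each target's length covered by the union of ``query``."""
    lengths = (targets.df["end"] - targets.df["start"]).to_numpy()
    if len(targets) == 0:
        return np.zeros(0)
    return overlap_lengths(targets, query) / lengths


class BinnedTrack:
    """A per-bin numeric signal over a genome layout with a validity mask.

    Values are stored as one concatenated float array in layout order;
    masked bins are NaN and flagged False in ``mask``.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int,
                 values: np.ndarray | None = None,
                 mask: np.ndarray | None = None):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.layout = layout
        self.bin_size = int(bin_size)
        self._offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for chrom, length in layout.items():
            n = -(-length // bin_size)
            self._offsets[chrom] = (pos, n)
            pos += n
        self.n_bins = pos
        if values is None:
            values = np.full(pos, np.nan)
        values = np.asarray(values, dtype=float)
        if values.shape != (pos,):
            raise ValueError(f"expected {pos} bins, got {values.shape}")
        if mask is None:
            mask = np.isfinite(values)
        mask = np.asarray(mask, dtype=bool)
        values = values.copy()
        values[~mask] = np.nan
        self.values = values
        self.mask = mask

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "BinnedTrack":
        return BinnedTrack(self.layout, self.bin_size, values, mask)

    def chrom_slice(self, chrom: str) -> slice:
        off, n = self._offsets[chrom]
        return slice(off, off + n)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.chrom_slice(chrom)]

    def n_chrom_bins(self, chrom: str) -> int:
        return self._offsets[chrom][1]

    def bin_index(self, chrom: str, pos: int) -> int:
        off, n = self._offsets[chrom]
        if not 0 <= pos < self.layout.length_of(chrom):
            raise IndexError(f"position {pos} outside {chrom}")
        return off + pos // self.bin_size

    def bins(self) -> IntervalSet:
        return bin_genome(self.layout, self.bin_size)

    def same_grid_as(self, other: "BinnedTrack") -> bool:
        return (self.layout == other.layout
                and self.bin_size == other.bin_size)
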