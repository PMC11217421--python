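"""Readers and writers for the plain-text formats the pipeline exchanges.

BED/bedGraph are 0-based half-open. Malformed lines are reported with
their line number; coordinates are validated against the layout when one
is supplied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomeLayout, GenomicInterval, IntervalSet


class FormatError(ValueError):
    pass


def read_chrom_sizes(path) -> GenomeLayout:
    names, lengths = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected two tab-separated columns")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path, layout: GenomeLayout | None = None) -> IntervalSet:
    ivs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
        label = parts[3] if len(parts) > 3 else ""
        score = None
        if len(parts) > 4 and parts[4] not in (".", ""):
            score = float(parts[4])
        strand = parts[5] if len(parts) > 5 else "."
        try:
            ivs.append(GenomicInterval(chrom, start, end, strand, label, score))
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
    return IntervalSet(ivs, layout=layout)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t"
                     f"{score}\t{iv.strand}\n")


def read_bedgraph(path, layout: GenomeLayout, bin_size: int) -> BinnedTrack:
    """Read a bedGraph whose intervals align to the track's bin grid.

    Bins absent from the file stay masked.
    """
    track = BinnedTrack(layout, bin_size)
    values = np.full(track.n_bins, np.nan)
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: fewer than 4 bedGraph columns")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in layout:
            raise FormatError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        if end > layout.length_of(chrom):
            raise FormatError(f"{path}:{ln}: interval beyond chromosome end")
        if start % bin_size:
            raise FormatError(f"{path}:{ln}: start not aligned to {bin_size}-bp grid")
        i0 = track.bin_index(chrom, start)
        nb = -(-(end - start) // bin_size)
        values[i0:i0 + nb] = value
    return track.copy_with(values)


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write one line per unmasked bin (masked bins are omitted)."""
    with open(path, "w") as fh:
        for chrom, length in track.layout.items():
            vals = track.chrom_values(chrom)
            for i, v in enumerate(vals):
                if np.isfinite(v):
                    start = i * track.bin_size
                    end = min(start + track.bin_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_count_table(path, layout: GenomeLayout, bin_size: int,
                     value_col: str = "count") -> BinnedTrack:
    """Read a headered TSV (chrom, start, end, <value_col>) into a track."""
    df = pd.read_csv(path, sep="\t")
    track = BinnedTrack(layout, bin_size)
    values = np.full(track.n_bins, np.nan)
    for row in df.itertuples(index=False):
        chrom = getattr(row, "chrom")
        if chrom not in layout:
            raise FormatError(f"unknown chromosome {chrom!r} in {path}")
        values[track.bin_index(chrom, int(getattr(row, "start")))] = getattr(row, value_col)
    return track.copy_with(values)


def write_count_table(track: BinnedTrack, path, value_col: str = "count") -> None:
    rows = []
    for chrom, length in track.layout.items():
        vals = track.chrom_values(chrom)
        starts = np.arange(len(vals)) * track.bin_size
        ends = np.minimum(starts + track.bin_size, length)
        keep = np.isfinite(vals)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts[keep],
                                  "end": ends[keep], value_col: vals[keep]}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_contacts_coo(path) -> tuple[str, int, np.ndarray]:
    """Read a COO contact list: header lines ``#chrom=..`` ``#bin_size=..``
    ``#n_bins=..`` then tab-separated ``bin_i  bin_j  count`` triplets.

    Returns (chrom, bin_size, dense symmetric matrix).
    """
    chrom = None
    bin_size = None
    n_bins = None
    triplets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key == "chrom":
                chrom = val
            elif key == "bin_size":
                bin_size = int(val)
            elif key == "n_bins":
                n_bins = int(val)
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{ln}: expected 3 columns")
        triplets.append((int(parts[0]), int(parts[1]), float(parts[2])))
    if chrom is None or bin_size is None or n_bins is None:
        raise FormatError(f"{path}: missing #chrom/#bin_size/#n_bins header")
    m = np.zeros((n_bins, n_bins))
    for i, j, c in triplets:
        m[i, j] = c
        m[j, i] = c
    return chrom, bin_size, m


def write_contacts_coo(chrom: str, bin_size: int, matrix: np.ndarray, path) -> None:
    n = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write(f"#chrom={chrom}\n#bin_size={bin_size}\n#n_bins={n}\n")
        iu = np.triu_indices(n)
        for i, j in zip(*iu):
            v = matrix[i, j]
            if v != 0 and np.isfinite(v):
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
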