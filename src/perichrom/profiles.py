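"""Anchor-averaged signal profiles, strand-aware metagene profiles, and
A/T-content analysis around binding sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import BinnedTrack, IntervalSet


@dataclass
class AveragedProfile:
    positions: np.ndarray   # offsets relative to the anchor (bp or scaled)
    mean: np.ndarray
    n: np.ndarray           # anchors contributing at each position


def _resample(track: BinnedTrack, chrom: str, gstart: int, gend: int,
              n_out: int) -> np.ndarray:
    """Area-weighted mean of source bins over ``n_out`` equal display bins
    spanning [gstart, gend); positions outside the chromosome or masked
    are NaN."""
    length = track.layout.length_of(chrom)
    vals = track.chrom_values(chrom)
    bs = track.bin_size
    edges = np.linspace(gstart, gend, n_out + 1)
    out = np.full(n_out, np.nan)
    for k in range(n_out):
        a, b = edges[k], edges[k + 1]
        a_in, b_in = max(a, 0.0), min(b, float(length))
        if b_in <= a_in:
            continue
        i0 = int(a_in // bs)
        i1 = int(np.ceil(b_in / bs))
        acc = w = 0.0
        for i in range(i0, min(i1, len(vals))):
            v = vals[i]
            if not np.isfinite(v):
                continue
            ov = min(b_in, (i + 1) * bs) - max(a_in, i * bs)
            if ov > 0:
                acc += v * ov
                w += ov
        if w > 0:
            out[k] = acc / w
    return out


def average_anchor_profile(track: BinnedTrack, anchors: IntervalSet,
                           flank: int, out_bins: int = 50) -> AveragedProfile:
    """Mean signal around anchor midpoints, resampled to ``out_bins``
    display positions over [-flank, +flank]. Anchors truncated by a
    chromosome end contribute only their defined positions."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    if len(anchors) == 0:
        raise ValueError("no anchors")
    acc = np.zeros(out_bins)
    cnt = np.zeros(out_bins)
    for iv in anchors:
        mid = iv.midpoint
        prof = _resample(track, iv.chrom, mid - flank, mid + flank, out_bins)
        ok = np.isfinite(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
    centers = np.linspace(-flank, flank, out_bins + 1)
    centers = (centers[:-1] + centers[1:]) / 2.0
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return AveragedProfile(centers, mean, cnt)


def metagene_profile(track: BinnedTrack, genes: IntervalSet,
                     body_bins: int = 100, flank: int = 2000) -> AveragedProfile:
    """Gene bodies rescaled to ``body_bins`` positions with fixed-bp
    flanks; minus-strand genes are reversed so the profile runs 5' to 3'.

    Positions are display-bin indices with 0 at the 5' gene end.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    flank_bins = max(1, flank // track.bin_size)
    total = flank_bins + body_bins + flank_bins
    acc = np.zeros(total)
    cnt = np.zeros(total)
    for iv in genes:
        if iv.length <= track.bin_size:
            continue
        up = _resample(track, iv.chrom, iv.start - flank, iv.start, flank_bins)
        body = _resample(track, iv.chrom, iv.start, iv.end, body_bins)
        down = _resample(track, iv.chrom, iv.end, iv.end + flank, flank_bins)
        prof = np.concatenate([up, body, down])
        if iv.strand == "-":
            prof = prof[::-1]
        ok = np.isfinite(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return AveragedProfile(np.arange(total) - flank_bins, mean, cnt)


def _get_seq(fasta, chrom: str, start: int, end: int) -> str:
    """Sequence slice from a pyfaidx.Fasta or a plain dict of strings."""
    if isinstance(fasta, dict):
        return fasta[chrom][start:end]
    return str(fasta[chrom][start:end])


def _at_percent(seq: str) -> float:
    """% A/T excluding N bases from numerator and denominator."""
    seq = seq.upper()
    n_valid = sum(1 for c in seq if c != "N")
    if n_valid == 0:
        return np.nan
    at = sum(1 for c in seq if c in "AT")
    return 100.0 * at / n_valid


def at_content_profile(fasta, anchors: IntervalSet, flank: int,
                       window: int = 20) -> AveragedProfile:
    """Per-window percentage of A/T bases in consecutive ``window``-bp bins
    spanning anchor midpoint +/- flank, averaged over anchors."""
    if len(anchors) == 0:
        raise ValueError("no anchors")
    n_win = (2 * flank) // window
    acc = np.zeros(n_win)
    cnt = np.zeros(n_win)
    for iv in anchors:
        mid = iv.midpoint
        start = mid - flank
        try:
            seq = _get_seq(fasta, iv.chrom, start, start + n_win * window)
        except (KeyError, IndexError, ValueError):
            warnings.warn(f"anchor at {iv.chrom}:{mid} outside sequence; skipped")
            continue
        if len(seq) < n_win * window or start < 0:
            warnings.warn(f"anchor at {iv.chrom}:{mid} outside sequence; skipped")
            continue
        for k in range(n_win):
            pct = _at_percent(seq[k * window:(k + 1) * window])
            if np.isfinite(pct):
                acc[k] += pct
                cnt[k] += 1
    pos = np.arange(n_win) * window - flank + window / 2.0
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return AveragedProfile(pos, mean, cnt)


def has_at_rich_window(seq: str, window: int = 20,
                       min_at_fraction: float = 0.9) -> bool:
    """True if any 20-bp window sliding by 1 bp is at least
    ``min_at_fraction`` A/T."""
    seq = seq.upper()
    if len(seq) < window:
        return False
    is_at = np.frombuffer(seq.encode(), dtype=np.uint8)
    at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(float)
    sums = np.convolve(at, np.ones(window), mode="valid")
    return bool((sums >= min_at_fraction * window).any())


def at_rich_fraction(fasta, sites: IntervalSet, flank: int = 150,
                     window: int = 20, min_at_fraction: float = 0.9) -> float:
    """Percentage of sites with at least one A/T-rich window (by sliding
    ``window``-bp windows) within +/- ``flank`` bp of the site centre."""
    if len(sites) == 0:
        raise ValueError("empty site set")
    hits = 0
    used = 0
    for iv in sites:
        mid = iv.midpoint
        start = max(0, mid - flank)
        try:
            seq = _get_seq(fasta, iv.chrom, start, mid + flank)
        except (KeyError, IndexError, ValueError):
            continue
        if not seq:
            continue
        used += 1
        if has_at_rich_window(seq, window, min_at_fraction):
            hits += 1
    if used == 0:
        raise ValueError("no sites with available sequence")
    return 100.0 * hits / used
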