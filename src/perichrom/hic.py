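"""Hi-C contact-map statistics: balancing, observed/expected, TAD calling
with the Armatus objective, average contact frequency (ACF), Jaccard TAD
grouping, compartment PC1 and saddle analysis, modified insulation score
(IS^m), and anchor pileups.

Matrices are per-chromosome dense symmetric arrays. Analyses are cis-only.
The main diagonal (self-contacts) is excluded from ACF; expected profiles
are computed per separation including s=0 so every O/E diagonal has unit
mean by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .genome import GenomicInterval, IntervalSet


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact matrix.

    ``valid_mask`` flags usable bins; rows/columns of invalid bins are NaN
    once the matrix has been balanced.
    """

    chrom: str
    bin_size: int
    matrix: np.ndarray
    valid_mask: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        finite = np.where(np.isfinite(m), m, 0.0)
        if not np.allclose(finite, finite.T):
            raise ValueError("matrix must be symmetric")
        self.matrix = m
        if self.valid_mask is None:
            self.valid_mask = np.ones(m.shape[0], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def total(self) -> float:
        m = np.where(np.isfinite(self.matrix), self.matrix, 0.0)
        return float(np.triu(m).sum())


@dataclass(frozen=True)
class TAD:
    start_bin: int
    end_bin: int    # inclusive

    def __post_init__(self):
        if self.end_bin < self.start_bin:
            raise ValueError("end_bin < start_bin")

    def interval(self, chrom: str, bin_size: int) -> GenomicInterval:
        return GenomicInterval(chrom, self.start_bin * bin_size,
                               (self.end_bin + 1) * bin_size)

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class TADGroupRecord:
    tad: TAD
    lad_fraction: float      # X
    active_fraction: float   # Y
    jacc: float
    group: str


@dataclass
class SaddleResult:
    grid: np.ndarray
    n_quantiles: int
    trim: float


# --------------------------------------------------------------------------
# Matrix preparation
# --------------------------------------------------------------------------

def remove_short_range(cm: ContactMatrix, min_separation: int = 1000) -> ContactMatrix:
    """Zero contacts between bins whose midpoints are closer than
    ``min_separation`` base pairs (self-contacts always qualify at the
    default 1 kb for >=1-kb bins)."""
    m = cm.matrix.copy()
    n = cm.n_bins
    max_off = int(np.ceil(min_separation / cm.bin_size))
    for off in range(0, max_off):
        if off * cm.bin_size < min_separation:
            idx = np.arange(n - off)
            m[idx, idx + off] = 0.0
            m[idx + off, idx] = 0.0
    return replace(cm, matrix=m)


def downsample(cm: ContactMatrix, target_total: float, seed: int = 0) -> ContactMatrix:
    """Binomial thinning of the upper triangle to an expected total of
    ``target_total`` contacts, mirrored back to a symmetric matrix."""
    total = cm.total()
    if target_total > total:
        raise ValueError("target exceeds current total")
    p = target_total / total if total > 0 else 0.0
    rng = np.random.default_rng(seed)
    n = cm.n_bins
    iu = np.triu_indices(n)
    counts = cm.matrix[iu]
    thinned = rng.binomial(counts.astype(np.int64), p).astype(float)
    m = np.zeros_like(cm.matrix)
    m[iu] = thinned
    m = m + np.triu(m, 1).T
    return replace(cm, matrix=m)


def coverage_mask(cm: ContactMatrix, percentile: float = 5.0) -> np.ndarray:
    """Valid-bin mask: drop all-zero bins and bins whose nonzero-cell count
    falls below the given percentile of per-bin nonzero counts."""
    m = np.where(np.isfinite(cm.matrix), cm.matrix, 0.0)
    nnz = (m > 0).sum(axis=1)
    valid = nnz > 0
    if valid.any():
        floor = np.percentile(nnz[valid], percentile)
        valid &= nnz >= floor
    return valid


def iterative_correction(cm: ContactMatrix, tol: float = 1e-6,
                         max_iter: int = 200,
                         mask_percentile: float = 5.0) -> ContactMatrix:
    """Matrix balancing: multiplicative per-bin biases equalising unmasked
    row sums. Invalid rows/columns become NaN."""
    valid = cm.valid_mask & coverage_mask(cm, mask_percentile)
    m = np.where(np.isfinite(cm.matrix), cm.matrix, 0.0).copy()
    m[~valid, :] = 0.0
    m[:, ~valid] = 0.0
    converged = False
    for _ in range(max_iter):
        s = m[np.ix_(valid, valid)].sum(axis=1)
        if s.size == 0 or (s <= 0).any():
            break
        s = s / s.mean()
        full = np.ones(cm.n_bins)
        full[valid] = s
        m = m / np.outer(full, full)
        if np.abs(s - 1.0).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("iterative correction did not converge; returning last iterate")
    m[~valid, :] = np.nan
    m[:, ~valid] = np.nan
    return ContactMatrix(cm.chrom, cm.bin_size, np.where(np.isnan(m), np.nan, m),
                         valid_mask=valid, balanced=True)


def expected_profile(cm: ContactMatrix) -> np.ndarray:
    """Mean contact per bin separation over unmasked cells; NaN where a
    separation has no unmasked cells."""
    n = cm.n_bins
    out = np.full(n, np.nan)
    valid = cm.valid_mask
    for s in range(n):
        i = np.arange(n - s)
        vals = cm.matrix[i, i + s]
        ok = valid[i] & valid[i + s] & np.isfinite(vals)
        if ok.any():
            out[s] = vals[ok].mean()
    return out


def observed_over_expected(cm: ContactMatrix) -> ContactMatrix:
    """Distance-normalised matrix: each cell divided by the mean contact at
    its separation. Every diagonal's unmasked mean is 1 by construction."""
    exp = expected_profile(cm)
    n = cm.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = cm.matrix / exp[sep]
    oe[~cm.valid_mask, :] = np.nan
    oe[:, ~cm.valid_mask] = np.nan
    return ContactMatrix(cm.chrom, cm.bin_size, oe,
                         valid_mask=cm.valid_mask, balanced=cm.balanced)


# --------------------------------------------------------------------------
# TAD calling (Armatus objective)
# --------------------------------------------------------------------------

def armatus_preprocess(cm: ContactMatrix) -> ContactMatrix:
    """Interpolate missing cells along diagonals, clip to the [P1, P99]
    range of finite cells, and natural-log transform.

    Zeros are replaced by half the smallest positive value before the log
    so ln is defined everywhere.
    """
    m = cm.matrix.copy()
    n = cm.n_bins
    for s in range(n):
        i = np.arange(n - s)
        d = m[i, i + s]
        ok = np.isfinite(d)
        if ok.sum() >= 2 and not ok.all():
            d = d.copy()
            d[~ok] = np.interp(np.flatnonzero(~ok), np.flatnonzero(ok), d[ok])
            m[i, i + s] = d
            m[i + s, i] = d
    finite = m[np.isfinite(m)]
    if finite.size:
        p1, p99 = np.percentile(finite, [1, 99])
        m = np.clip(m, p1, p99)
        pos = finite[finite > 0]
        floor = pos.min() / 2.0 if pos.size else 1.0
        m[np.isfinite(m) & (m <= 0)] = floor
        if p1 <= 0:
            m = np.maximum(m, floor)
        with np.errstate(invalid="ignore"):
            m = np.log(m)
    return ContactMatrix(cm.chrom, cm.bin_size, m,
                         valid_mask=cm.valid_mask, balanced=cm.balanced)


def _window_sums(m: np.ndarray) -> np.ndarray:
    """S[k, l] = sum of cells i, j with k <= i < j <= l (strictly upper
    triangle, diagonal excluded), via 2-D prefix sums."""
    a = np.where(np.isfinite(m), m, 0.0)
    n = a.shape[0]
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = a.cumsum(0).cumsum(1)

    def rect(r0, r1, c0, c1):   # sum over rows [r0,r1), cols [c0,c1)
        return P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]

    S = np.zeros((n, n))
    for k in range(n):
        full = np.array([rect(k, l + 1, k, l + 1) for l in range(k, n)])
        diag = np.array([a[i, i] for i in range(k, n)]).cumsum()
        S[k, k:] = (full - diag) / 2.0
    return S


def armatus_quality(m: np.ndarray, gamma: float):
    """Per-window quality q(k, l) = s/(size)^gamma - mu(size): scaled sum
    of within-window contacts (pairs i < j; self-contacts excluded) minus
    the mean scaled density over all windows of that size. Domains span at
    least 2 bins; single-bin windows have undefined quality."""
    n = m.shape[0]
    S = _window_sums(m)
    sizes = np.abs(np.arange(n)[None, :] - np.arange(n)[:, None]) + 1
    scaled = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    scaled[iu] = S[iu] / (sizes[iu].astype(float) ** gamma)
    mu = np.full(n + 1, np.nan)
    for d in range(2, n + 1):
        i = np.arange(n - d + 1)
        mu[d] = scaled[i, i + d - 1].mean()
    with np.errstate(invalid="ignore"):
        q = scaled - mu[sizes]
    return q


def call_tads(pre: ContactMatrix, gamma: float = 1.0) -> list[TAD]:
    """Optimal non-overlapping domain partition maximising summed Armatus
    quality; only domains with positive quality are scored, gaps allowed.
    Ties are broken toward fewer domains."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    m = pre.matrix
    n = pre.n_bins
    q = armatus_quality(m, gamma)
    opt = np.zeros(n + 1)
    choice = [None] * (n + 1)    # (k, l) of domain ending at l, or None
    for l in range(1, n + 1):
        best = opt[l - 1]
        best_choice = None
        ql = q[:l, l - 1]
        cand = opt[:l] + ql
        ok = np.isfinite(ql) & (ql > 0)
        if ok.any():
            ks = np.flatnonzero(ok)
            vals = cand[ks]
            j = int(np.argmax(vals))
            if vals[j] > best + 1e-12:
                best = vals[j]
                best_choice = (int(ks[j]), l - 1)
        opt[l] = best
        choice[l] = best_choice
    tads = []
    l = n
    while l > 0:
        if choice[l] is None:
            l -= 1
        else:
            k, end = choice[l]
            tads.append(TAD(k, end))
            l = k
    return sorted(tads, key=lambda t: t.start_bin)


def tad_partition_score(pre: ContactMatrix, tads: list[TAD], gamma: float) -> float:
    q = armatus_quality(pre.matrix, gamma)
    return float(sum(q[t.start_bin, t.end_bin] for t in tads))


def match_tads(tads_a: list[TAD], tads_b: list[TAD]) -> list[tuple[TAD, TAD]]:
    """Pairs with exactly identical boundaries in the two sets."""
    bset = {(t.start_bin, t.end_bin): t for t in tads_b}
    return [(t, bset[(t.start_bin, t.end_bin)]) for t in tads_a
            if (t.start_bin, t.end_bin) in bset]


# --------------------------------------------------------------------------
# ACF and TAD grouping
# --------------------------------------------------------------------------

def tad_acf(oe: ContactMatrix, tad: TAD) -> float:
    """Mean distance-normalised contact over off-diagonal pairs (i < j)
    with both bins inside the TAD; compaction proxy."""
    if tad.n_bins < 2:
        warnings.warn("1-bin TAD has no off-diagonal pairs; ACF undefined")
        return np.nan
    sub = oe.matrix[tad.start_bin:tad.end_bin + 1, tad.start_bin:tad.end_bin + 1]
    iu = np.triu_indices(sub.shape[0], k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def acf_log2fc(oe_kd: ContactMatrix, oe_ctrl: ContactMatrix,
               shared: list[TAD]) -> np.ndarray:
    """Per-TAD log2(ACF_kd / ACF_ctrl) over TADs with identical boundaries
    in both conditions."""
    out = np.full(len(shared), np.nan)
    for i, t in enumerate(shared):
        a = tad_acf(oe_kd, t)
        b = tad_acf(oe_ctrl, t)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            out[i] = np.log2(a / b)
    return out


def jaccard_group(tad: TAD, chrom: str, bin_size: int,
                  lads: IntervalSet, active: IntervalSet) -> TADGroupRecord:
    """Group a TAD by Jacc = (X - Y)/(X + Y), X = LAD coverage fraction,
    Y = active-chromatin coverage fraction. Jacc < -0.8 -> A (active),
    Jacc > 0.8 -> C (inactive), otherwise B; X = Y = 0 defines Jacc = 0."""
    from .genome import coverage_fraction
    iv = tad.interval(chrom, bin_size)
    target = IntervalSet([iv])
    x = float(coverage_fraction(target, lads)[0]) if len(lads) else 0.0
    y = float(coverage_fraction(target, active)[0]) if len(active) else 0.0
    jacc = 0.0 if (x + y) == 0 else (x - y) / (x + y)
    group = "A" if jacc < -0.8 else ("C" if jacc > 0.8 else "B")
    return TADGroupRecord(tad, x, y, jacc, group)


# --------------------------------------------------------------------------
# Modified insulation score
# --------------------------------------------------------------------------

ISM_RESOLUTION = 2000
ISM_SPAN = 4    # offsets 1..4 bins on each side: regions 2-8 kb away


def ism_profile(oe: ContactMatrix, expected_bin_size: int = ISM_RESOLUTION) -> np.ndarray:
    """Modified insulation score: per-bin mean O/E over the 4x4 square of
    cells linking the 4 bins upstream to the 4 bins downstream of the
    central bin (the central bin and its first-diagonal contacts are
    excluded). NaN near edges and where all 16 cells are masked."""
    if oe.bin_size != expected_bin_size:
        raise ValueError(
            f"IS^m requires {expected_bin_size}-bp bins, got {oe.bin_size}")
    n = oe.n_bins
    out = np.full(n, np.nan)
    m = oe.matrix
    for i in range(ISM_SPAN, n - ISM_SPAN):
        block = m[i - ISM_SPAN:i, i + 1:i + 1 + ISM_SPAN]
        vals = block[np.isfinite(block)]
        if vals.size:
            out[i] = vals.mean()
    return out


def averaged_ism_around(ism: np.ndarray, anchor_bins: np.ndarray,
                        flank_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor-centred average of the IS^m curve with linear-interpolation
    smoothing: undefined positions are first filled by interpolation
    between the nearest defined neighbours.

    Returns (offsets, mean, n_contributing).
    """
    anchor_bins = np.asarray(anchor_bins, dtype=int)
    if anchor_bins.size == 0:
        raise ValueError("no anchors")
    filled = ism.copy()
    ok = np.isfinite(filled)
    if ok.sum() >= 2:
        filled[~ok] = np.interp(np.flatnonzero(~ok), np.flatnonzero(ok), filled[ok])
    offs = np.arange(-flank_bins, flank_bins + 1)
    acc = np.zeros(offs.size)
    cnt = np.zeros(offs.size)
    for a in anchor_bins:
        lo, hi = a - flank_bins, a + flank_bins
        if lo < 0 or hi >= filled.size:
            continue
        w = filled[lo:hi + 1]
        good = np.isfinite(w)
        acc[good] += w[good]
        cnt[good] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return offs, mean, cnt


# --------------------------------------------------------------------------
# Compartments and saddles
# --------------------------------------------------------------------------

def compartment_pc1(oe: ContactMatrix, orientation: np.ndarray | None = None,
                    min_bins: int = 20) -> np.ndarray:
    """First principal component of the Pearson correlation matrix of O/E
    rows, per chromosome. Sign oriented so positive PC1 correlates
    positively with ``orientation`` (e.g. gene expression / activity).
    """
    valid = oe.valid_mask & np.isfinite(oe.matrix).any(axis=1)
    if valid.sum() < min_bins:
        raise ValueError("too few unmasked bins for PC1")
    sub = oe.matrix[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if np.allclose(sub.std(axis=1), 0):
        raise ValueError("degenerate (constant) matrix; PC1 undefined")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    w, v = np.linalg.eigh(corr)
    pc1_sub = v[:, -1]
    pc1 = np.full(oe.n_bins, np.nan)
    pc1[valid] = pc1_sub
    if orientation is not None:
        o = np.asarray(orientation, dtype=float)
        ok = np.isfinite(pc1) & np.isfinite(o)
        if ok.sum() >= 2 and np.corrcoef(pc1[ok], o[ok])[0, 1] < 0:
            pc1 = -pc1
    return pc1


def saddle(oe: ContactMatrix, pc1: np.ndarray, n_quantiles: int = 50,
           trim: float = 0.01) -> SaddleResult:
    """PC1-quantile by PC1-quantile grid of mean O/E.

    Bins are ranked by PC1, the extreme ``trim`` fraction dropped at each
    end, the rest digitised into equal-count quantile groups (ascending
    PC1: quantile 0 = most negative PC1 = B side).
    """
    ok = np.isfinite(pc1) & oe.valid_mask
    if ok.sum() < n_quantiles:
        raise ValueError("fewer usable bins than quantiles")
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(pc1[idx])]
    n_drop = int(np.floor(trim * order.size))
    if n_drop:
        order = order[n_drop:-n_drop]
    groups = np.array_split(order, n_quantiles)
    grid = np.full((n_quantiles, n_quantiles), np.nan)
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            block = oe.matrix[np.ix_(groups[a], groups[b])]
            vals = block[np.isfinite(block)]
            if vals.size:
                grid[a, b] = grid[b, a] = vals.mean()
    return SaddleResult(grid, n_quantiles, trim)


def saddle_difference_summary(saddle_kd: SaddleResult, saddle_ctrl: SaddleResult,
                              k: int = 10) -> dict:
    """KD-minus-control saddle cells in the three corner blocks.

    With A-positive PC1 orientation and ascending quantiles, the highest-k
    block is AA, the lowest-k block is BB and the off-blocks are AB.
    Wilcoxon signed-rank vs 0 per block.
    """
    if saddle_kd.n_quantiles != saddle_ctrl.n_quantiles:
        raise ValueError("saddles have different quantile counts")
    nq = saddle_kd.n_quantiles
    if nq < 2 * k:
        raise ValueError("n_quantiles must be at least 2k")
    diff = saddle_kd.grid - saddle_ctrl.grid
    low = np.arange(k)
    high = np.arange(nq - k, nq)
    bb = diff[np.ix_(low, low)].ravel()
    aa = diff[np.ix_(high, high)].ravel()
    ab = diff[np.ix_(low, high)].ravel()
    out = {}
    for name, vals in (("AA", aa), ("BB", bb), ("AB", ab)):
        vals = vals[np.isfinite(vals)]
        if vals.size and np.any(vals != 0):
            p = float(stats.wilcoxon(vals)[1])
        else:
            p = 1.0
        out[name] = {"values": vals, "median": float(np.median(vals)) if vals.size else np.nan,
                     "p": p}
    return out


# --------------------------------------------------------------------------
# Pileups
# --------------------------------------------------------------------------

def pileup_oe(oe: ContactMatrix, anchor_bins: np.ndarray, flank_bins: int) -> np.ndarray:
    """Element-wise mean of (2*flank+1)^2 O/E windows centred on anchors;
    anchors whose window leaves the chromosome are skipped."""
    anchor_bins = np.asarray(anchor_bins, dtype=int)
    size = 2 * flank_bins + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    used = 0
    for a in anchor_bins:
        lo, hi = a - flank_bins, a + flank_bins
        if lo < 0 or hi >= oe.n_bins:
            continue
        w = oe.matrix[lo:hi + 1, lo:hi + 1]
        good = np.isfinite(w)
        acc[good] += w[good]
        cnt[good] += 1
        used += 1
    if used == 0:
        raise ValueError("no anchors with a full window inside the chromosome")
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
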