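"""DamID normalisation and HMM domain calling.

The signal of a Dam-fusion experiment is the log2 ratio of fusion to
Dam-only read counts after reads-per-million scaling; lamina-associated
domains (two-state model) or binding sites of the fusion partner
(three-state model) are maximal runs of the high-emission HMM state, with
sub-900-bp gaps between called domains filled in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .genome import BinnedTrack, GenomicInterval, IntervalSet


@dataclass
class DamIDNormalizationResult:
    log2_ratio: BinnedTrack
    fusion_rpm: BinnedTrack
    dam_rpm: BinnedTrack
    pseudocount: float


@dataclass
class HMMSegmentation:
    n_states: int
    means: np.ndarray          # ascending
    variances: np.ndarray
    transmat: np.ndarray
    states: np.ndarray         # per-bin decoded state, -1 on masked bins
    log_likelihood: float
    converged: bool = True


def _merge_replicates(reps: list[BinnedTrack]) -> BinnedTrack:
    if not reps:
        raise ValueError("no replicate tracks")
    proto = reps[0]
    for r in reps[1:]:
        if not proto.same_grid_as(r):
            raise ValueError("replicate tracks on different grids")
    if len(reps) >= 2:
        a, b = reps[0].values, reps[1].values
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3:
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            if r < 0.8:
                warnings.warn(f"replicate Pearson correlation {r:.2f} < 0.8")
    total = np.zeros(proto.n_bins)
    any_ok = np.zeros(proto.n_bins, dtype=bool)
    for r in reps:
        v = np.where(np.isfinite(r.values), r.values, 0.0)
        total += v
        any_ok |= np.isfinite(r.values)
    return proto.copy_with(np.where(any_ok, total, np.nan))


def normalize_damid(fusion_reps: list[BinnedTrack], dam_reps: list[BinnedTrack],
                    pseudocount: float = 1.0) -> DamIDNormalizationResult:
    """Merge replicates by summing counts, scale each sample to reads per
    million, and return log2(fusion_RPM / dam_RPM).

    The pseudocount is added to raw counts before RPM scaling; bins where
    the Dam count plus pseudocount is zero are masked.
    """
    fusion = _merge_replicates(fusion_reps)
    dam = _merge_replicates(dam_reps)
    if not fusion.same_grid_as(dam):
        raise ValueError("fusion and Dam tracks on different grids")
    f = np.where(np.isfinite(fusion.values), fusion.values, np.nan)
    d = np.where(np.isfinite(dam.values), dam.values, np.nan)
    if np.nansum(f) == 0 or np.nansum(d) == 0:
        raise ValueError("all-zero sample")
    f_pc = f + pseudocount
    d_pc = d + pseudocount
    f_total = np.nansum(f_pc)
    d_total = np.nansum(d_pc)
    f_rpm = f_pc / f_total * 1e6
    d_rpm = d_pc / d_total * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(f_rpm / d_rpm)
    mask = np.isfinite(f_pc) & np.isfinite(d_pc) & (d_pc > 0) & (f_pc > 0)
    log2[~mask] = np.nan
    return DamIDNormalizationResult(
        log2_ratio=fusion.copy_with(log2),
        fusion_rpm=fusion.copy_with(np.where(np.isfinite(f_pc), f_rpm, np.nan)),
        dam_rpm=dam.copy_with(np.where(np.isfinite(d_pc), d_rpm, np.nan)),
        pseudocount=pseudocount,
    )


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) index runs where mask is True."""
    runs = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def fit_hmm(track: BinnedTrack, n_states: int = 2, seed: int = 0,
            max_iter: int = 200, var_floor: float = 1e-4) -> HMMSegmentation:
    """Fit a Gaussian-emission HMM to the unmasked log2-ratio values and
    decode the most-probable state path.

    Masked bins split the chain into independent segments. Emission means
    are initialised from empirical quantiles (2-state: 25th/75th; 3-state:
    10th/50th/90th) and the result is canonicalised so states are ordered
    by ascending mean.
    """
    values = track.values
    ok = np.isfinite(values)
    if ok.sum() < 10 * n_states:
        raise ValueError("too few unmasked bins to fit the HMM")
    runs = _contiguous_runs(ok)
    segments = [values[a:b] for a, b in runs]
    X = np.concatenate(segments).reshape(-1, 1)
    lengths = [len(s) for s in segments]
    qs = {2: [25, 75], 3: [10, 50, 90]}.get(n_states)
    if qs is None:
        raise ValueError("n_states must be 2 or 3")
    init_means = np.percentile(X.ravel(), qs).reshape(-1, 1)
    var0 = max(np.var(X.ravel()) / n_states, var_floor)
    model = GaussianHMM(n_components=n_states, covariance_type="diag",
                        n_iter=max_iter, random_state=seed,
                        init_params="", params="stmc",
                        min_covar=var_floor)
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    stay = 0.99
    model.transmat_ = np.full((n_states, n_states),
                              (1 - stay) / (n_states - 1))
    np.fill_diagonal(model.transmat_, stay)
    model.means_ = init_means
    model.covars_ = np.full((n_states, 1), var0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("HMM EM did not converge; returning best model")
    ll, decoded = model.decode(X, lengths, algorithm="viterbi")
    # canonicalise by ascending emission mean
    order = np.argsort(model.means_.ravel())
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    states = np.full(track.n_bins, -1, dtype=int)
    pos = 0
    for (a, b), ln in zip(runs, lengths):
        states[a:b] = relabel[decoded[pos:pos + ln]]
        pos += ln
    variances = np.asarray(model.covars_).reshape(n_states, -1)[:, 0]
    return HMMSegmentation(
        n_states=n_states,
        means=model.means_.ravel()[order],
        variances=np.maximum(variances[order], var_floor),
        transmat=model.transmat_[np.ix_(order, order)],
        states=states,
        log_likelihood=float(ll),
        converged=converged,
    )


def states_to_domains(seg: HMMSegmentation, track: BinnedTrack,
                      bound_states: tuple[int, ...] | None = None) -> IntervalSet:
    """Maximal runs of consecutive bins decoded in a bound state, as
    genomic intervals. By default the bound state is the highest-mean
    state. Runs do not extend across masked gaps."""
    if bound_states is None:
        bound_states = (seg.n_states - 1,)
    if not bound_states:
        raise ValueError("bound_states must be non-empty")
    ivs = []
    for chrom, length in track.layout.items():
        sl = track.chrom_slice(chrom)
        st = seg.states[sl]
        bound = np.isin(st, bound_states)
        for a, b in _contiguous_runs(bound):
            start = a * track.bin_size
            end = min(b * track.bin_size, length)
            ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, layout=track.layout)


def fill_domain_gaps(domains: IntervalSet, max_gap: int = 900) -> IntervalSet:
    """Merge consecutive same-chromosome domains separated by a gap
    strictly smaller than ``max_gap`` base pairs."""
    if len(domains) == 0:
        return domains
    out = []
    for chrom, grp in domains.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < max_gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return IntervalSet(out, layout=domains.layout)


def call_damid_domains(fusion_reps, dam_reps, n_states: int = 2,
                       pseudocount: float = 1.0, max_gap: int = 900,
                       seed: int = 0,
                       bound_states: tuple[int, ...] | None = None):
    """Full caller: normalise, fit HMM, extract bound-state runs, fill
    gaps. Returns (domains, normalisation result, segmentation)."""
    norm = normalize_damid(fusion_reps, dam_reps, pseudocount)
    seg = fit_hmm(norm.log2_ratio, n_states=n_states, seed=seed)
    domains = states_to_domains(seg, norm.log2_ratio, bound_states)
    return fill_domain_gaps(domains, max_gap), norm, seg
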