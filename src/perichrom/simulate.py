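"""Synthetic data generators emulating the study's inputs.

Every generator is deterministic under its seed and plants structure that
the downstream stage is expected to recover: LADs and NPC-linked binding
sites in DamID log-ratio tracks, TADs / compartments / anchor contacts in
Hi-C maps, radial-position shifts in FISH geometry, class-specific
fold-changes in expression counts, and A/T-rich islands in sequence.

Default sizes are desk scale (megabase chromosomes) so the whole pipeline
runs in seconds while preserving the statistical structure of the real
assays: LAD/inter-LAD contrast of roughly +/-1.2 log2 units with 0.4 sd
of bin noise, distance decay P(s) ~ s^-1, and negative-binomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinnedTrack, GenomeLayout, GenomicInterval, IntervalSet
from .hic import ContactMatrix


def _default_layout() -> GenomeLayout:
    return GenomeLayout(("chrS1", "chrS2"), (2_000_000, 2_000_000))


# --------------------------------------------------------------------------
# DamID
# --------------------------------------------------------------------------

@dataclass
class DamIDSimParams:
    """Planted LAD / binding-site structure for Dam and Dam-fusion counts.

    ``lad_log2`` / ``background_log2`` are the per-bin log2(fusion/Dam)
    means inside and outside planted LADs; ``noise_sd`` is per-bin Gaussian
    spread around those means. NPC-like sites planted inside LADs carry a
    local dip (``npc_dip_log2``) in the lamina signal, emulating binding
    sites at nuclear pores piercing the lamina domains; nucleoplasmic-like
    sites sit in active regions with their own enrichment.
    """

    layout: GenomeLayout = field(default_factory=_default_layout)
    bin_size: int = 300
    lads: IntervalSet | None = None
    npc_sites: IntervalSet | None = None
    nucl_sites: IntervalSet | None = None
    lad_log2: float = 1.2
    background_log2: float = -1.2
    noise_sd: float = 0.4
    npc_dip_log2: float = -1.5
    nucl_site_log2: float = 1.2
    depth: int = 1_000_000
    n_replicates: int = 2
    accessibility_sd: float = 0.2
    seed: int = 0


def default_planted_lads(layout: GenomeLayout,
                         lad_fraction: float = 0.5,
                         n_lads_per_chrom: int = 8,
                         seed: int = 0) -> IntervalSet:
    """Evenly spaced LADs covering roughly ``lad_fraction`` of each chromosome."""
    rng = np.random.default_rng(seed)
    ivs = []
    for chrom, length in layout.items():
        period = length // n_lads_per_chrom
        lad_len = int(period * lad_fraction)
        for k in range(n_lads_per_chrom):
            jitter = int(rng.integers(-period // 10, period // 10 + 1))
            start = max(0, k * period + period // 4 + jitter)
            end = min(length, start + lad_len)
            if end > start:
                ivs.append(GenomicInterval(chrom, start, end, label="LAD"))
    return IntervalSet(ivs, layout=layout)


def default_planted_sites(lads: IntervalSet, layout: GenomeLayout,
                          site_len: int = 1800, per_lad: int = 2,
                          seed: int = 1) -> tuple[IntervalSet, IntervalSet]:
    """NPC-like sites inside LADs and nucleoplasmic sites between them."""
    rng = np.random.default_rng(seed)
    npc, nucl = [], []
    lad_list = list(lads)
    for lad in lad_list:
        usable = lad.length - 2 * site_len
        if usable <= per_lad * site_len:
            continue
        starts = np.sort(rng.choice(usable // site_len, size=per_lad, replace=False))
        for s in starts:
            a = lad.start + site_len + int(s) * site_len
            npc.append(GenomicInterval(lad.chrom, a, a + site_len, label="npc"))
    # nucleoplasmic sites in gaps between consecutive LADs
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for lad in lad_list:
        by_chrom.setdefault(lad.chrom, []).append(lad)
    for chrom, chrom_lads in by_chrom.items():
        for a, b in zip(chrom_lads[:-1], chrom_lads[1:]):
            gap = b.start - a.end
            if gap > 3 * site_len:
                mid = a.end + gap // 2
                nucl.append(GenomicInterval(chrom, mid - site_len // 2,
                                            mid + site_len // 2, label="nucl"))
    return IntervalSet(npc, layout=layout), IntervalSet(nucl, layout=layout)


def _paint(track_values: np.ndarray, track: BinnedTrack,
           intervals: IntervalSet, value: float, add: bool = False) -> None:
    for iv in intervals:
        i0 = track.bin_index(iv.chrom, iv.start)
        i1 = track.bin_index(iv.chrom, min(iv.end - 1, track.layout.length_of(iv.chrom) - 1))
        if add:
            track_values[i0:i1 + 1] += value
        else:
            track_values[i0:i1 + 1] = value


def planted_lamina_log2(p: DamIDSimParams) -> tuple[BinnedTrack, IntervalSet, IntervalSet, IntervalSet]:
    """Noise-free planted log2 lamina signal plus the planted truth sets."""
    lads = p.lads if p.lads is not None else default_planted_lads(p.layout, seed=p.seed)
    if p.npc_sites is not None or p.nucl_sites is not None:
        npc = p.npc_sites if p.npc_sites is not None else IntervalSet(layout=p.layout)
        nucl = p.nucl_sites if p.nucl_sites is not None else IntervalSet(layout=p.layout)
    else:
        npc, nucl = default_planted_sites(lads, p.layout, seed=p.seed + 1)
    proto = BinnedTrack(p.layout, p.bin_size)
    mu = np.full(proto.n_bins, p.background_log2)
    _paint(mu, proto, lads, p.lad_log2)
    _paint(mu, proto, npc, p.npc_dip_log2, add=True)
    return proto.copy_with(mu), lads, npc, nucl


def planted_elys_log2(p: DamIDSimParams) -> BinnedTrack:
    """Noise-free planted log2 track for the binding-site factor itself:
    enriched over both NPC-like and nucleoplasmic sites."""
    _, lads, npc, nucl = planted_lamina_log2(p)
    proto = BinnedTrack(p.layout, p.bin_size)
    mu = np.full(proto.n_bins, p.background_log2)
    _paint(mu, proto, npc, p.lad_log2)
    _paint(mu, proto, nucl, p.nucl_site_log2)
    return proto.copy_with(mu)


def simulate_damid_counts(p: DamIDSimParams, signal: str = "lamina"):
    """Draw Dam and Dam-fusion replicate count tracks.

    Counts are multinomial over bins at the requested depth: the Dam
    sample's bin weights model accessibility (log-normal noise around
    uniform); the fusion sample's weights are the Dam weights scaled by
    2**(planted log2 ratio + Gaussian bin noise). Returns
    (fusion_tracks, dam_tracks, truth) where truth is a dict with the
    planted LADs/sites and the noise-free log2 track.
    """
    rng = np.random.default_rng(p.seed)
    mu_track, lads, npc, nucl = planted_lamina_log2(p)
    if signal == "lamina":
        mu = mu_track.values
    elif signal == "elys":
        mu = planted_elys_log2(p).values
    else:
        raise ValueError("signal must be 'lamina' or 'elys'")
    n = len(mu)
    access = np.exp(rng.normal(0.0, p.accessibility_sd, size=n))
    ratio = 2.0 ** (mu + rng.normal(0.0, p.noise_sd, size=n))
    dam_w = access / access.sum()
    fus_w = access * ratio
    fus_w = fus_w / fus_w.sum()
    proto = BinnedTrack(p.layout, p.bin_size)
    fusion, dam = [], []
    for _ in range(p.n_replicates):
        dam.append(proto.copy_with(rng.multinomial(p.depth, dam_w).astype(float)))
        fusion.append(proto.copy_with(rng.multinomial(p.depth, fus_w).astype(float)))
    truth = {"lads": lads, "npc_sites": npc, "nucl_sites": nucl,
             "log2_mu": proto.copy_with(mu)}
    return fusion, dam, truth


# --------------------------------------------------------------------------
# Hi-C
# --------------------------------------------------------------------------

@dataclass
class HiCSimParams:
    """Distance-decay contact map with planted TADs, compartments, anchors."""

    chrom: str = "chrS1"
    chrom_length: int = 2_000_000
    bin_size: int = 2000
    decay_alpha: float = 1.0
    tad_boundaries: tuple[int, ...] = ()          # bin indices, sorted
    tad_multipliers: tuple[float, ...] = ()       # one per TAD between boundaries
    compartment_labels: np.ndarray | None = None  # +1/-1 per bin, checkerboard
    compartment_strength: float = 0.0
    inactive_boost: float = 1.0    # extra multiplier on B-B (label -1) cells
    anchor_bins: tuple[int, ...] = ()
    anchor_boost: float = 1.0                     # multiplier on cross-anchor cells
    anchor_span: int = 4                          # offsets 1..span on each side
    total_contacts: int = 2_000_000
    seed: int = 0

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)


def expected_hic_intensity(p: HiCSimParams) -> np.ndarray:
    """Noise-free expected contact intensity (unnormalised weights)."""
    n = p.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        w = sep ** (-p.decay_alpha)
    w[sep == 0] = 2.0   # self-contacts kept high, removed downstream
    if p.tad_boundaries:
        bounds = (0,) + tuple(p.tad_boundaries) + (n,)
        mults = p.tad_multipliers or (2.0,) * (len(bounds) - 1)
        for (a, b), m in zip(zip(bounds[:-1], bounds[1:]), mults):
            w[a:b, a:b] *= m
    if p.compartment_labels is not None and p.compartment_strength > 0:
        lab = np.asarray(p.compartment_labels)
        same = lab[:, None] == lab[None, :]
        w[same] *= 1.0 + p.compartment_strength
        w[~same] *= max(1.0 - p.compartment_strength, 0.05)
    if p.compartment_labels is not None and p.inactive_boost != 1.0:
        lab = np.asarray(p.compartment_labels)
        bb = (lab[:, None] == -1) & (lab[None, :] == -1)
        w[bb] *= p.inactive_boost
    if p.anchor_bins and p.anchor_boost != 1.0:
        for a in p.anchor_bins:
            for du in range(1, p.anchor_span + 1):
                for dv in range(1, p.anchor_span + 1):
                    i, j = a - du, a + dv
                    if 0 <= i and j < n:
                        w[i, j] *= p.anchor_boost
                        w[j, i] *= p.anchor_boost
    return w


def simulate_hic(p: HiCSimParams) -> ContactMatrix:
    """Poisson counts around the planted expected intensity, symmetrised."""
    if any(b < 0 or b > p.n_bins for b in p.tad_boundaries):
        raise ValueError("TAD boundary outside chromosome")
    if list(p.tad_boundaries) != sorted(p.tad_boundaries):
        raise ValueError("TAD boundaries must be sorted")
    rng = np.random.default_rng(p.seed)
    w = expected_hic_intensity(p)
    n = p.n_bins
    iu = np.triu_indices(n)
    wu = w[iu]
    lam = wu / wu.sum() * p.total_contacts
    counts = rng.poisson(lam).astype(float)
    m = np.zeros((n, n))
    m[iu] = counts
    m = m + np.triu(m, 1).T
    return ContactMatrix(chrom=p.chrom, bin_size=p.bin_size, matrix=m)


# --------------------------------------------------------------------------
# Nuclear geometry
# --------------------------------------------------------------------------

@dataclass
class GeometrySimParams:
    """FISH radial distances and diameter intensity profiles.

    ``model`` selects the radial distribution of the locus-to-envelope
    distance: 'attached' concentrates near the envelope (d/R around
    ``attached_mean``), 'detached' is shifted inward by ``shift``.
    """

    n_nuclei: int = 100
    radius_mean: float = 2.5       # micrometres
    radius_sd: float = 0.3
    model: str = "attached"
    attached_mean: float = 0.08    # in units of R
    shift: float = 0.10
    distance_sd: float = 0.07
    profile_points: int = 64
    ne_peak_width: float = 0.04    # fraction of diameter
    chromatin_mode: str = "peripheral"   # or "displaced"
    noise: float = 0.05
    seed: int = 0


def simulate_geometry(p: GeometrySimParams):
    """Per-nucleus (volume, distance) records and diameter profiles.

    Returns a dict with 'volumes', 'distances' (micrometres), 'radii',
    'profiles' (n_nuclei x points, chromatin channel) and 'ne_profiles'
    (envelope-marker channel with peaks at both ends).
    """
    if p.radius_mean <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(p.seed)
    radii = np.abs(rng.normal(p.radius_mean, p.radius_sd, size=p.n_nuclei))
    radii = np.maximum(radii, 0.1)
    mean_frac = p.attached_mean + (p.shift if p.model == "detached" else 0.0)
    frac = rng.normal(mean_frac, p.distance_sd, size=p.n_nuclei)
    frac = np.clip(np.abs(frac), 0.0, 1.0)
    distances = frac * radii
    x = np.linspace(0.0, 1.0, p.profile_points)
    ne = (np.exp(-0.5 * ((x - 0.0) / p.ne_peak_width) ** 2)
          + np.exp(-0.5 * ((x - 1.0) / p.ne_peak_width) ** 2))
    profiles = np.empty((p.n_nuclei, p.profile_points))
    ne_profiles = np.empty_like(profiles)
    for i in range(p.n_nuclei):
        if p.chromatin_mode == "peripheral":
            chrom = (np.exp(-0.5 * ((x - 0.08) / 0.06) ** 2)
                     + np.exp(-0.5 * ((x - 0.92) / 0.06) ** 2) + 0.3)
        else:
            chrom = np.full_like(x, 0.9) - 0.4 * ((x - 0.5) ** 2) * 4
        scale = np.exp(rng.normal(0, 0.2))   # arbitrary per-nucleus gain
        profiles[i] = scale * (chrom + rng.normal(0, p.noise, size=x.size))
        ne_profiles[i] = scale * (ne + 0.1 + rng.normal(0, p.noise, size=x.size))
    volumes = 4.0 / 3.0 * np.pi * radii ** 3
    return {"volumes": volumes, "radii": radii, "distances": distances,
            "profiles": profiles, "ne_profiles": ne_profiles,
            "positions": x, "model": p.model}


# --------------------------------------------------------------------------
# Expression
# --------------------------------------------------------------------------

@dataclass
class ExpressionSimParams:
    """Negative-binomial counts with a planted class-specific knockdown effect."""

    n_genes: int = 200
    gene_length_mean: float = 2000.0
    base_mean: float = 200.0
    dispersion: float = 0.1        # NB size = 1/dispersion
    class_labels: np.ndarray | None = None   # e.g. 'NPC_only', 'none', ...
    planted_log2fc: dict = field(default_factory=lambda: {"NPC_only": 0.5})
    library_size: float = 1.0
    n_replicates: int = 2
    seed: int = 0


def simulate_expression(p: ExpressionSimParams):
    """Counts for control and knockdown conditions, ``n_replicates`` each.

    Returns dict with 'lengths', 'labels', 'control' and 'kd'
    (n_genes x n_replicates count arrays).
    """
    rng = np.random.default_rng(p.seed)
    lengths = rng.gamma(4.0, p.gene_length_mean / 4.0, size=p.n_genes).astype(int) + 200
    if p.class_labels is None:
        labels = np.array(["NPC_only" if i % 4 == 0 else "none"
                           for i in range(p.n_genes)])
    else:
        labels = np.asarray(p.class_labels)
    base = rng.lognormal(np.log(p.base_mean), 1.0, size=p.n_genes)
    fc = np.array([2.0 ** p.planted_log2fc.get(l, 0.0) for l in labels])
    size = 1.0 / p.dispersion

    def draw(mean):
        out = np.empty((p.n_genes, p.n_replicates))
        for r in range(p.n_replicates):
            lam = rng.gamma(size, mean * p.library_size / size)
            out[:, r] = rng.poisson(lam)
        return out

    return {"lengths": lengths, "labels": labels,
            "control": draw(base), "kd": draw(base * fc)}


# --------------------------------------------------------------------------
# Sequence
# --------------------------------------------------------------------------

def simulate_sequence(layout: GenomeLayout, at_islands: IntervalSet,
                      seed: int = 0, island_at: float = 0.975,
                      background_at: float = 0.5) -> dict[str, str]:
    """Random genome with A/T-rich islands planted at the given intervals.

    Background is ~50% A/T; islands draw A/T with probability
    ``island_at`` so a 20-bp window inside an island is A/T-rich.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ATGC"))
    p_bg = np.array([background_at / 2, background_at / 2,
                     (1 - background_at) / 2, (1 - background_at) / 2])
    p_isl = np.array([island_at / 2, island_at / 2,
                      (1 - island_at) / 2, (1 - island_at) / 2])
    seqs = {}
    for chrom, length in layout.items():
        arr = rng.choice(4, size=length, p=p_bg)
        seqs[chrom] = arr
    for iv in at_islands:
        if iv.end > layout.length_of(iv.chrom):
            raise ValueError("island overlaps chromosome end")
        seqs[iv.chrom][iv.start:iv.end] = rng.choice(4, size=iv.length, p=p_isl)
    return {c: "".join(alphabet[a]) for c, a in seqs.items()}
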