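"""Site classification against NPC / nucleoplasmic reference sets,
interval-shuffle permutation enrichment, gene categorisation by site
content, and expression summaries per category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (GenomeLayout, GenomicInterval, IntervalSet,
                     overlap_lengths)

SITE_LABELS = ("Elys_NPC", "Elys_nucl", "Elys_NPC/nucl", "unassigned")
GENE_CATEGORIES = ("nucl_only", "NPC_only", "combination", "none")


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    n_perm: int
    p_value: float
    seed: int

    def human_p(self) -> str:
        if (self.null_counts >= self.observed).sum() == 0:
            return f"P < {1.0 / self.n_perm:g}"
        return f"P = {self.p_value:.4g}"


def classify_sites(elys: IntervalSet, npc_ref: IntervalSet,
                   nucl_ref: IntervalSet, min_overlap: int = 1) -> pd.DataFrame:
    """Label each site by which reference set(s) it shares at least
    ``min_overlap`` bases with: NPC only, nucleoplasmic only, both
    (ambivalent), or neither (unassigned)."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be at least 1")
    npc_bp = overlap_lengths(elys, npc_ref)
    nucl_bp = overlap_lengths(elys, nucl_ref)
    has_npc = npc_bp >= min_overlap
    has_nucl = nucl_bp >= min_overlap
    labels = np.where(has_npc & has_nucl, "Elys_NPC/nucl",
                      np.where(has_npc, "Elys_NPC",
                               np.where(has_nucl, "Elys_nucl", "unassigned")))
    df = elys.df[["chrom", "start", "end"]].copy()
    df["label"] = labels
    return df


def class_fractions(classes: pd.DataFrame) -> dict[str, float]:
    """Fraction of sites per label; the four fractions sum to 1."""
    n = len(classes)
    return {lab: float((classes["label"] == lab).sum()) / n for lab in SITE_LABELS}


def shuffle_intervals(sites: IntervalSet, layout: GenomeLayout, seed: int = 0,
                      preserve_chrom: bool = True) -> IntervalSet:
    """Random relocation of each interval: length preserved exactly, start
    uniform over valid positions, chromosome preserved when requested.
    Shuffled intervals may overlap each other."""
    rng = np.random.default_rng(seed)
    chroms = list(layout.chrom_names)
    lengths = np.array(layout.chrom_lengths)
    out = []
    for iv in sites:
        size = iv.length
        if preserve_chrom:
            chrom = iv.chrom
            L = layout.length_of(chrom)
            if size > L:
                raise ValueError(f"site longer than chromosome {chrom}")
        else:
            fit = lengths >= size
            if not fit.any():
                raise ValueError("site longer than every chromosome")
            k = rng.integers(fit.sum())
            chrom = [c for c, f in zip(chroms, fit) if f][k]
            L = layout.length_of(chrom)
        start = int(rng.integers(0, L - size + 1))
        out.append(GenomicInterval(chrom, start, start + size,
                                   iv.strand, iv.label, iv.score))
    return IntervalSet(out, layout=layout)


def count_overlapping(query: IntervalSet, reference: IntervalSet) -> int:
    """Number of query intervals sharing at least one base with the
    reference set."""
    return int((overlap_lengths(query, reference) >= 1).sum())


def permutation_overlap_test(query: IntervalSet, reference: IntervalSet,
                             layout: GenomeLayout, n_perm: int = 10000,
                             seed: int = 0,
                             preserve_chrom: bool = True) -> PermutationResult:
    """Enrichment of query/reference colocalisation against random
    placement: the query set is reshuffled ``n_perm`` times and the number
    of overlapping query sites recounted each time.

    p = (#{null >= observed} + 1) / (n_perm + 1), an add-one estimator
    that cannot return zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("empty interval set")
    merged_ref = reference.merge()
    observed = count_overlapping(query, merged_ref)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=int)
    if preserve_chrom:
        # vectorised placement, identical in distribution to
        # shuffle_intervals with preserve_chrom=True
        ref_by_chrom = dict(tuple(merged_ref.df.groupby("chrom", sort=False)))
        for chrom, grp in query.df.groupby("chrom", sort=False):
            L = layout.length_of(chrom)
            sizes = (grp["end"] - grp["start"]).to_numpy()
            if (sizes > L).any():
                raise ValueError(f"site longer than chromosome {chrom}")
            ref = ref_by_chrom.get(chrom)
            if ref is None or not len(ref):
                continue
            rs = ref["start"].to_numpy()
            re_ = ref["end"].to_numpy()
            for k in range(n_perm):
                starts = rng.integers(0, L - sizes + 1)
                ends = starts + sizes
                j = np.searchsorted(rs, ends, side="left") - 1
                hit = (j >= 0) & (re_[np.maximum(j, 0)] > starts)
                null[k] += int(hit.sum())
    else:
        for k in range(n_perm):
            shuf = shuffle_intervals(query, layout,
                                     seed=int(rng.integers(2**31)),
                                     preserve_chrom=False)
            null[k] = count_overlapping(shuf, merged_ref)
    p = (float((null >= observed).sum()) + 1.0) / (n_perm + 1.0)
    return PermutationResult(observed, null, n_perm, p, seed)


def overlap_fraction(a: IntervalSet, b: IntervalSet, mode: str = "length") -> float:
    """Percentage of a covered by b, by base pairs ('length' mode) or by
    the fraction of a's intervals with any overlap ('count' mode)."""
    if len(a) == 0:
        raise ValueError("empty interval set a")
    if mode == "length":
        return 100.0 * float(overlap_lengths(a, b).sum()) / a.total_length()
    if mode == "count":
        return 100.0 * count_overlapping(a, b) / len(a)
    raise ValueError("mode must be 'length' or 'count'")


def filter_interior_sites(sites: IntervalSet, domains: IntervalSet,
                          margin: int = 2000) -> IntervalSet:
    """Keep sites whose midpoint lies inside a domain and at least
    ``margin`` bp away from both of that domain's boundaries."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    dom_by_chrom = dict(tuple(domains.df.groupby("chrom", sort=False)))
    keep = []
    for i, iv in enumerate(sites):
        grp = dom_by_chrom.get(iv.chrom)
        ok = False
        if grp is not None:
            mid = iv.midpoint
            ds = grp["start"].to_numpy()
            de = grp["end"].to_numpy()
            j = np.searchsorted(ds, mid, side="right") - 1
            if j >= 0 and ds[j] + margin <= mid <= de[j] - margin:
                ok = True
        keep.append(ok)
    return sites.subset(np.array(keep, dtype=bool))


def classify_genes_by_sites(genes: IntervalSet, classes: pd.DataFrame) -> pd.DataFrame:
    """Categorise genes by the classes of sites they overlap: only
    nucleoplasmic sites -> nucl_only; only NPC sites -> NPC_only; any
    mixture (including ambivalent sites) -> combination; none -> none."""
    def ref(label):
        sub = classes[classes["label"] == label]
        return IntervalSet(sub, layout=genes.layout)

    npc = overlap_lengths(genes, ref("Elys_NPC")) >= 1
    nucl = overlap_lengths(genes, ref("Elys_nucl")) >= 1
    both = overlap_lengths(genes, ref("Elys_NPC/nucl")) >= 1
    cat = np.where(both | (npc & nucl), "combination",
                   np.where(npc, "NPC_only",
                            np.where(nucl, "nucl_only", "none")))
    df = genes.df[["chrom", "start", "end", "strand", "label"]].copy()
    df = df.rename(columns={"label": "gene"})
    df["category"] = cat
    return df


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million: length-normalised counts rescaled to sum
    to one million."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if counts.sum() == 0:
        raise ValueError("all-zero counts")
    rate = counts / lengths
    return rate / rate.sum() * 1e6


def expression_group_summary(tpm_ctrl: np.ndarray, tpm_kd: np.ndarray,
                             groups: np.ndarray, epsilon: float = 1.0) -> pd.DataFrame:
    """Per-group distribution of log2((TPM_kd + eps)/(TPM_ctrl + eps)) with
    a two-sided Wilcoxon signed-rank test of symmetry around zero."""
    tpm_ctrl = np.asarray(tpm_ctrl, dtype=float)
    tpm_kd = np.asarray(tpm_kd, dtype=float)
    groups = np.asarray(groups)
    log2fc = np.log2((tpm_kd + epsilon) / (tpm_ctrl + epsilon))
    rows = []
    for g in pd.unique(groups):
        vals = log2fc[groups == g]
        if vals.size == 0:
            raise ValueError(f"empty group {g!r}")
        if np.any(vals != 0):
            p = float(stats.wilcoxon(vals)[1])
        else:
            p = 1.0
        rows.append({"group": g, "n": int(vals.size),
                     "median_log2fc": float(np.median(vals)),
                     "q25": float(np.percentile(vals, 25)),
                     "q75": float(np.percentile(vals, 75)),
                     "wilcoxon_p": p})
    return pd.DataFrame(rows)
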