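"""End-to-end orchestration: run every analysis stage on synthetic (or
user-provided) inputs with one config, producing a single report plus
provenance sidecars.

Defaults follow the study conventions throughout: 300-bp DamID bins,
two-state lamina / three-state binding-site HMMs, 900-bp gap filling,
10,000 permutations, Armatus gamma = 1 on autosome-like chromosomes,
1% saddle trim with 10 extreme quantiles, 2-kb IS^m resolution,
Jacc thresholds +/-0.8, and the 0-0.15R peripheral zone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import damid, geometry, hic, profiles, simulate, sites
from .genome import GenomeLayout, IntervalSet, bin_genome, GenomicInterval


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the study defaults."""

    seed: int = 0
    # DamID
    bin_size: int = 300
    lam_states: int = 2
    elys_states: int = 3
    max_gap: int = 900
    pseudocount: float = 1.0
    damid_depth: int = 1_000_000
    # permutation testing
    n_perm: int = 10000
    # Hi-C
    hic_bin_size: int = 2000
    hic_contacts: int = 2_000_000
    gamma: float = 1.0
    saddle_quantiles: int = 50
    saddle_trim: float = 0.01
    saddle_extreme: int = 10
    # geometry
    n_nuclei: int = 100
    zone: float = 0.15
    # expression
    n_genes: int = 200

    def validate(self):
        errs = []
        if self.bin_size <= 0:
            errs.append("bin_size must be positive")
        if self.lam_states not in (2, 3) or self.elys_states not in (2, 3):
            errs.append("HMM states must be 2 or 3")
        if self.n_perm < 1:
            errs.append("n_perm must be at least 1")
        if not 0 < self.zone < 0.5:
            errs.append("zone must be in (0, 0.5)")
        if self.saddle_quantiles < 2 * self.saddle_extreme:
            errs.append("saddle_quantiles must be at least twice saddle_extreme")
        if errs:
            raise ValueError("; ".join(errs))


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def provenance(stage: str, config: PipelineConfig, outputs: dict) -> dict:
    return {"stage": stage, "params": asdict(config),
            "seed": config.seed, "checksum": _checksum(outputs),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}


def _f1(track_mask_true: np.ndarray, track_mask_called: np.ndarray) -> float:
    tp = float((track_mask_true & track_mask_called).sum())
    fp = float((~track_mask_true & track_mask_called).sum())
    fn = float((track_mask_true & ~track_mask_called).sum())
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def interval_base_mask(intervals: IntervalSet, proto) -> np.ndarray:
    """Boolean per-bin mask of bins whose start falls inside an interval."""
    mask = np.zeros(proto.n_bins, dtype=bool)
    for iv in intervals:
        i0 = proto.bin_index(iv.chrom, iv.start)
        i1 = proto.bin_index(iv.chrom, min(iv.end - 1,
                                           proto.layout.length_of(iv.chrom) - 1))
        mask[i0:i1 + 1] = True
    return mask


def run_damid_stage(config: PipelineConfig) -> dict:
    """Simulate lamina DamID, call domains, score recovery of the planted
    LADs at base (bin) level."""
    p = simulate.DamIDSimParams(bin_size=config.bin_size,
                                depth=config.damid_depth, seed=config.seed)
    fusion, dam, truth = simulate.simulate_damid_counts(p, signal="lamina")
    domains, norm, seg = damid.call_damid_domains(
        fusion, dam, n_states=config.lam_states,
        pseudocount=config.pseudocount, max_gap=config.max_gap,
        seed=config.seed)
    proto = norm.log2_ratio
    true_mask = interval_base_mask(truth["lads"], proto)
    called_mask = interval_base_mask(domains, proto)
    lad_coverage = 100.0 * domains.total_length() / p.layout.total_length
    lengths = (domains.df["end"] - domains.df["start"]).to_numpy()
    return {
        "domains": domains, "norm": norm, "truth": truth, "params": p,
        "f1": _f1(true_mask, called_mask),
        "n_domains": len(domains),
        "median_domain_kb": float(np.median(lengths)) / 1000 if len(domains) else np.nan,
        "lad_coverage_pct": lad_coverage,
    }


def run_elys_stage(config: PipelineConfig) -> dict:
    """Simulate binding-factor DamID, call sites with the three-state HMM."""
    p = simulate.DamIDSimParams(bin_size=config.bin_size,
                                depth=config.damid_depth, seed=config.seed + 17)
    fusion, dam, truth = simulate.simulate_damid_counts(p, signal="elys")
    domains, norm, seg = damid.call_damid_domains(
        fusion, dam, n_states=config.elys_states,
        pseudocount=config.pseudocount, max_gap=config.max_gap,
        seed=config.seed)
    return {"sites": domains, "norm": norm, "truth": truth, "params": p,
            "n_sites": len(domains)}


def run_classify_stage(config: PipelineConfig, elys_sites: IntervalSet,
                       truth: dict, layout: GenomeLayout) -> dict:
    """Classify called sites against the planted NPC / nucleoplasmic
    reference sets and run the permutation enrichment test."""
    classes = sites.classify_sites(elys_sites, truth["npc_sites"],
                                   truth["nucl_sites"])
    fractions = sites.class_fractions(classes)
    perm = sites.permutation_overlap_test(
        elys_sites, truth["npc_sites"], layout,
        n_perm=config.n_perm, seed=config.seed)
    return {"classes": classes, "fractions": fractions, "perm": perm}


def default_hic_params(config: PipelineConfig, knockdown: bool = False) -> simulate.HiCSimParams:
    """Study-conditions Hi-C simulation: planted TADs every 50 bins,
    alternating-block compartments, anchor bins at planted-TAD interiors;
    the knockdown condition loses the anchor boost and part of the
    within-TAD compaction of inactive TADs."""
    n = 1000   # 2 Mb at 2 kb
    boundaries = tuple(range(50, n, 50))
    labels = np.repeat(np.resize([1, -1], n // 50), 50)[:n]
    mults = []
    for k in range(len(boundaries) + 1):
        inactive = labels[min(k * 50, n - 1)] == -1
        if knockdown:
            mults.append(1.6 if inactive else 2.0)
        else:
            mults.append(2.0)
    anchors = tuple(25 + 100 * k for k in range(n // 100))
    return simulate.HiCSimParams(
        chrom="chrS1", chrom_length=n * config.hic_bin_size,
        bin_size=config.hic_bin_size,
        tad_boundaries=boundaries, tad_multipliers=tuple(mults),
        compartment_labels=labels, compartment_strength=0.4,
        anchor_bins=anchors, anchor_boost=1.0 if knockdown else 1.8,
        total_contacts=config.hic_contacts,
        seed=config.seed + (101 if knockdown else 100))


def run_hic_stage(config: PipelineConfig) -> dict:
    """Simulate control and knockdown maps, balance, compute O/E, call
    TADs, and produce ACF, IS^m, compartment and saddle summaries."""
    p_ctrl = default_hic_params(config, knockdown=False)
    p_kd = default_hic_params(config, knockdown=True)
    cm_ctrl = simulate.simulate_hic(p_ctrl)
    cm_kd = simulate.simulate_hic(p_kd)
    results = {"params_ctrl": p_ctrl, "params_kd": p_kd}

    prepped = {}
    for name, cm in (("ctrl", cm_ctrl), ("kd", cm_kd)):
        cm = hic.remove_short_range(cm, 1000)
        bal = hic.iterative_correction(cm)
        oe = hic.observed_over_expected(bal)
        prepped[name] = {"bal": bal, "oe": oe}
    target = min(cm_ctrl.total(), cm_kd.total())
    results["prepped"] = prepped

    pre_ctrl = hic.armatus_preprocess(prepped["ctrl"]["bal"])
    pre_kd = hic.armatus_preprocess(prepped["kd"]["bal"])
    tads_ctrl = hic.call_tads(pre_ctrl, config.gamma)
    tads_kd = hic.call_tads(pre_kd, config.gamma)
    shared = [a for a, _ in hic.match_tads(tads_ctrl, tads_kd)]
    log2fc = hic.acf_log2fc(prepped["kd"]["oe"], prepped["ctrl"]["oe"], shared)
    results.update({"tads_ctrl": tads_ctrl, "tads_kd": tads_kd,
                    "shared_tads": shared, "acf_log2fc": log2fc})

    # compartments on the same O/E (single desk-scale resolution)
    labels = np.asarray(p_ctrl.compartment_labels, dtype=float)
    pc1 = hic.compartment_pc1(prepped["ctrl"]["oe"], orientation=labels)
    ok = np.isfinite(pc1)
    agreement = float((np.sign(pc1[ok]) == labels[ok]).mean())
    sad_ctrl = hic.saddle(prepped["ctrl"]["oe"], pc1,
                          config.saddle_quantiles, config.saddle_trim)
    pc1_kd = hic.compartment_pc1(prepped["kd"]["oe"], orientation=labels)
    sad_kd = hic.saddle(prepped["kd"]["oe"], pc1_kd,
                        config.saddle_quantiles, config.saddle_trim)
    sad_diff = hic.saddle_difference_summary(sad_kd, sad_ctrl,
                                             config.saddle_extreme)
    results.update({"pc1": pc1, "pc1_agreement": agreement,
                    "saddle_ctrl": sad_ctrl, "saddle_kd": sad_kd,
                    "saddle_diff": sad_diff})

    ism_ctrl = hic.ism_profile(prepped["ctrl"]["oe"])
    ism_kd = hic.ism_profile(prepped["kd"]["oe"])
    anchors = np.array(p_ctrl.anchor_bins)
    offs, ism_avg_ctrl, _ = hic.averaged_ism_around(ism_ctrl, anchors, 15)
    _, ism_avg_kd, _ = hic.averaged_ism_around(ism_kd, anchors, 15)
    pile_ctrl = hic.pileup_oe(prepped["ctrl"]["oe"], anchors, 10)
    pile_kd = hic.pileup_oe(prepped["kd"]["oe"], anchors, 10)
    results.update({"ism_ctrl": ism_ctrl, "ism_kd": ism_kd,
                    "ism_offsets": offs, "ism_avg_ctrl": ism_avg_ctrl,
                    "ism_avg_kd": ism_avg_kd,
                    "pileup_ctrl": pile_ctrl, "pileup_kd": pile_kd})
    return results


def run_geometry_stage(config: PipelineConfig) -> dict:
    """Simulate attached vs detached FISH geometry and peripheral vs
    displaced chromatin profiles; run the positioning statistics."""
    att = simulate.simulate_geometry(simulate.GeometrySimParams(
        n_nuclei=config.n_nuclei, model="attached", seed=config.seed + 7))
    det = simulate.simulate_geometry(simulate.GeometrySimParams(
        n_nuclei=config.n_nuclei, model="detached", seed=config.seed + 8))
    nd_att = np.concatenate([
        geometry.normalized_radial_distance(d, v)
        for d, v in zip(att["distances"], att["volumes"])])
    nd_det = np.concatenate([
        geometry.normalized_radial_distance(d, v)
        for d, v in zip(det["distances"], det["volumes"])])
    dist_test = geometry.compare_distance_distributions(nd_att, nd_det)

    per = simulate.simulate_geometry(simulate.GeometrySimParams(
        n_nuclei=config.n_nuclei, chromatin_mode="peripheral",
        seed=config.seed + 9))
    dis = simulate.simulate_geometry(simulate.GeometrySimParams(
        n_nuclei=config.n_nuclei, chromatin_mode="displaced",
        seed=config.seed + 10))
    _, _, aligned_per = geometry.align_and_average_profiles(
        per["profiles"], per["ne_profiles"])
    _, _, aligned_dis = geometry.align_and_average_profiles(
        dis["profiles"], dis["ne_profiles"])
    zone_test = geometry.peripheral_zone_test(aligned_per, aligned_dis,
                                              config.zone)
    return {"distance_test": dist_test, "zone_test": zone_test,
            "median_attached": dist_test["median_a"],
            "median_detached": dist_test["median_b"]}


def run_expression_stage(config: PipelineConfig) -> dict:
    """Simulate class-labelled expression counts and summarise knockdown
    fold-changes per gene category."""
    p = simulate.ExpressionSimParams(n_genes=config.n_genes,
                                     seed=config.seed + 23)
    sim = simulate.simulate_expression(p)
    ctrl_counts = sim["control"].sum(axis=1)
    kd_counts = sim["kd"].sum(axis=1)
    tpm_ctrl = sites.compute_tpm(ctrl_counts, sim["lengths"])
    tpm_kd = sites.compute_tpm(kd_counts, sim["lengths"])
    summary = sites.expression_group_summary(tpm_ctrl, tpm_kd, sim["labels"])
    return {"summary": summary, "params": p}


def run_all(config: PipelineConfig | None = None) -> dict:
    """Run every stage on synthetic inputs and collect one report."""
    config = config or PipelineConfig()
    config.validate()
    damid_res = run_damid_stage(config)
    elys_res = run_elys_stage(config)
    classify_res = run_classify_stage(config, elys_res["sites"],
                                      elys_res["truth"],
                                      elys_res["params"].layout)
    hic_res = run_hic_stage(config)
    geom_res = run_geometry_stage(config)
    expr_res = run_expression_stage(config)
    return {"damid": damid_res, "elys": elys_res, "classify": classify_res,
            "hic": hic_res, "geometry": geom_res, "expression": expr_res,
            "config": config}


def summarize_report(report: dict) -> dict:
    """Flat, JSON-serialisable digest of a run_all report."""
    hic_res = report["hic"]
    cls = report["classify"]
    expr = report["expression"]["summary"]
    npc_row = expr[expr["group"] == "NPC_only"]
    fc = hic_res["acf_log2fc"]
    fc = fc[np.isfinite(fc)]
    center = len(hic_res["ism_offsets"]) // 2
    return {
        "damid_f1": report["damid"]["f1"],
        "n_lad_domains": report["damid"]["n_domains"],
        "lad_coverage_pct": report["damid"]["lad_coverage_pct"],
        "median_domain_kb": report["damid"]["median_domain_kb"],
        "n_elys_sites": report["elys"]["n_sites"],
        "class_fractions": cls["fractions"],
        "permutation_p": cls["perm"].p_value,
        "n_tads_ctrl": len(hic_res["tads_ctrl"]),
        "n_tads_kd": len(hic_res["tads_kd"]),
        "n_shared_tads": len(hic_res["shared_tads"]),
        "median_acf_log2fc": float(np.median(fc)) if fc.size else None,
        "pc1_agreement": hic_res["pc1_agreement"],
        "saddle_diff_medians": {k: v["median"]
                                for k, v in hic_res["saddle_diff"].items()},
        "ism_center_over_flank": float(
            hic_res["ism_avg_ctrl"][center]
            / np.nanmean(np.r_[hic_res["ism_avg_ctrl"][:5],
                               hic_res["ism_avg_ctrl"][-5:]])),
        "geometry_mwu_p": report["geometry"]["distance_test"]["p"],
        "zone_test_p": report["geometry"]["zone_test"]["p"],
        "npc_gene_median_log2fc": (float(npc_row["median_log2fc"].iloc[0])
                                   if len(npc_row) else None),
        "seed": report["config"].seed,
    }


def write_report(report: dict, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = summarize_report(report)
    path = out_dir / "report.json"
    path.write_text(json.dumps(digest, indent=2, default=float))
    prov = provenance("run_all", report["config"], digest)
    (out_dir / "report.provenance.json").write_text(
        json.dumps(prov, indent=2))
    return path
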