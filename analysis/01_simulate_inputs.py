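"""Generate the synthetic study inputs: DamID count tracks with planted
LADs and binding sites, a Hi-C contact map with planted TADs /
compartments / anchors, and the planted-truth BED files.

Writes everything under results/inputs/ in the same plain-text formats
the pipeline reads back.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from perichrom import io, pipeline, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    config = pipeline.PipelineConfig(seed=SEED)

    p = simulate.DamIDSimParams(seed=SEED)
    fusion, dam, truth = simulate.simulate_damid_counts(p, signal="lamina")
    for i, (f, d) in enumerate(zip(fusion, dam), 1):
        io.write_count_table(f, OUT / f"lam_fusion_rep{i}.tsv")
        io.write_count_table(d, OUT / f"dam_rep{i}.tsv")
    io.write_bed(truth["lads"], OUT / "planted_lads.bed")
    io.write_bed(truth["npc_sites"], OUT / "planted_npc_sites.bed")
    io.write_bed(truth["nucl_sites"], OUT / "planted_nucl_sites.bed")
    io.write_chrom_sizes(p.layout, OUT / "chrom.sizes")
    print(f"DamID: {p.n_replicates} replicate pairs at depth {p.depth:,}, "
          f"{len(truth['lads'])} planted LADs, "
          f"{len(truth['npc_sites'])} NPC-like and "
          f"{len(truth['nucl_sites'])} nucleoplasmic sites")

    hp = pipeline.default_hic_params(config)
    cm = simulate.simulate_hic(hp)
    io.write_contacts_coo(hp.chrom, hp.bin_size, cm.matrix,
                          OUT / "hic_control.coo.tsv")
    print(f"Hi-C: {cm.n_bins} bins at {hp.bin_size} bp, "
          f"{cm.total():,.0f} contacts, "
          f"{len(hp.tad_boundaries) + 1} planted TADs")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
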