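"""Hi-C compaction analysis on control vs knockdown synthetic maps:
TAD calling, per-TAD average contact frequency (ACF) fold changes by
activity group, compartment saddles, and the modified insulation score
around planted anchor sites.

Writes TAD tables, saddle summaries and IS^m curves under results/hic/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from perichrom import hic, pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main():
    out = ROOT / "hic"
    out.mkdir(parents=True, exist_ok=True)
    config = pipeline.PipelineConfig(seed=SEED)
    res = pipeline.run_hic_stage(config)

    tads = res["tads_ctrl"]
    shared = res["shared_tads"]
    fc = res["acf_log2fc"]
    fc = fc[np.isfinite(fc)]
    print(f"{len(tads)} TADs in control, {len(res['tads_kd'])} in knockdown; "
          f"{len(shared)} with identical boundaries "
          f"({100 * len(shared) / len(tads):.0f}% of control TADs)")
    print(f"median ACF log2FC (knockdown/control) over shared TADs: "
          f"{np.median(fc):+.3f}")
    pd.DataFrame({"start_bin": [t.start_bin for t in tads],
                  "end_bin": [t.end_bin for t in tads]}).to_csv(
        out / "tads_control.tsv", sep="\t", index=False)
    pd.DataFrame({"log2fc": fc}).to_csv(out / "acf_log2fc.tsv", sep="\t",
                                        index=False)

    print(f"compartment PC1 sign agreement with planted labels: "
          f"{100 * res['pc1_agreement']:.1f}%")
    sd = res["saddle_diff"]
    print("saddle difference medians (knockdown - control): "
          + ", ".join(f"{k} {v['median']:+.3f} (p={v['p']:.2g})"
                      for k, v in sd.items()))

    offs = res["ism_offsets"]
    pd.DataFrame({"offset_bins": offs, "ism_ctrl": res["ism_avg_ctrl"],
                  "ism_kd": res["ism_avg_kd"]}).to_csv(
        out / "ism_around_anchors.tsv", sep="\t", index=False)
    c = len(offs) // 2
    flank = np.nanmean(np.r_[res["ism_avg_ctrl"][:5], res["ism_avg_ctrl"][-5:]])
    print(f"IS^m at anchor centre {res['ism_avg_ctrl'][c]:.2f} vs flank "
          f"{flank:.2f} in control; knockdown centre "
          f"{res['ism_avg_kd'][c]:.2f} (anchor-bridging contacts lost)")


if __name__ == "__main__":
    main()
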