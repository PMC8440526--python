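#!/usr/bin/env python
"""Single-cell vacuole analysis on a synthetic yeast field.

Generates a 100-cell population whose baseline donor lifetime rises with
vacuolar ratio and whose post-shock lifetime drop depends on vacuolar
ratio (vacuoles buffering water loss), runs the full image pipeline
(segmentation, vacuole detection, per-cell statistics), and reports the
two Pearson correlations alongside the planted values.

Writes: results/cell_records.csv, results/cell_correlations.csv, and the
        rendered field as scratch/field_pre.tif (+ sidecar JSON)
"""

import argparse
from pathlib import Path

import pandas as pd

from idrfret import cellquant, flim, io, synth


def main(seed: int, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = synth.PopulationTruth.with_target_correlations(
        0.44, -0.47, n_cells=100, seed=seed)
    pre, post, ground_truth = synth.gen_cell_population(truth)
    scratch = Path("scratch")
    scratch.mkdir(exist_ok=True)
    io.write_stack_tiff(pre, scratch / "field_pre.tif")

    labels = cellquant.segment_cells(pre)
    stats_pre = cellquant.vacuolar_ratio_stats(pre, labels)
    stats_post = cellquant.vacuolar_ratio_stats(post, labels)
    records = stats_pre.rename(columns={"mean_lifetime": "lifetime_pre_ns"})
    records["lifetime_post_ns"] = stats_post.mean_lifetime
    records["delta_lifetime"] = [
        flim.delta_lifetime(a, b)
        for a, b in zip(records.lifetime_pre_ns, records.lifetime_post_ns)
    ]
    records.to_csv(out_dir / "cell_records.csv", index=False)

    base = cellquant.pearson_correlate(
        records.vacuolar_ratio, records.lifetime_pre_ns,
        "vacuolar_ratio", "baseline_lifetime")
    buff = cellquant.pearson_correlate(
        records.vacuolar_ratio, records.delta_lifetime,
        "vacuolar_ratio", "delta_lifetime")
    out = pd.DataFrame([
        {"pair": f"{c.variable_x} vs {c.variable_y}", "r": c.r,
         "p_value": c.p_value, "n": c.n, "planted_r": planted}
        for c, planted in ((base, 0.44), (buff, -0.47))
    ])
    out.to_csv(out_dir / "cell_correlations.csv", index=False)
    print(f"segmented {labels.max()} cells "
          f"({len(ground_truth)} planted)")
    print(out.round(4).to_string(index=False))
    print("\ncells with larger vacuoles start at longer donor lifetimes and "
          "lose less lifetime on shock - the buffering signature")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.seed, args.out_dir)
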