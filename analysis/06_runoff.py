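#!/usr/bin/env python
"""Translational-inhibitor run-off: nascent-chain spots vanish, mRNA persists.

A two-channel run-off scene (8 cells, exponential disappearance at
0.05 /s after drug addition at t = 50 s) is reduced to per-cell
normalized spot-count curves with cell-to-cell SEM; a log-linear fit of
the post-drug mean recovers the run-off rate.
"""

import argparse
from pathlib import Path

import numpy as np

from livespot import io, quantify, synth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rate = 0.05
    scene = synth.RunoffScene(
        n_cells=8, spots_per_cell=25, n_frames=20, drug_time_s=50.0, runoff_rate=rate
    )
    optics = synth.Optics(field_px=(128, 128), frame_interval_s=10.0)
    _, truth = synth.make_runoff_scene(scene, optics, seed=args.seed)
    counts = quantify.spot_counts(truth, scene.n_frames, optics.frame_interval_s)
    curve = quantify.runoff_curve(counts, scene.drug_time_s)
    io.write_table(args.outdir / "runoff_curve.csv", curve)

    nascent = curve[(curve.channel == 0) & (curve.time_s > scene.drug_time_s)]
    mask = nascent["mean"] > 0
    slope = np.polyfit(nascent.time_s[mask] - scene.drug_time_s, np.log(nascent["mean"][mask]), 1)[0]
    mrna = curve[curve.channel == 1]["mean"]
    print(f"recovered run-off rate {-slope:.4f} /s (true {rate})")
    print(f"mRNA channel stays at {mrna.mean():.3f} (persistent, as constructed)")


if __name__ == "__main__":
    main()
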