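#!/usr/bin/env python
"""Bound-molecule filtering: target simulation vs free-probe control.

Simulates a chromatin-bound population (30 nm jitter) and a free-probe
control (D = 0.5 µm²/s) at the 43.8 ms sparse-tracking cadence, links
both with the nearest-neighbor tracker, applies the >=16-frame / <220 nm
filter, and writes the filtered-track counts and a mobility map.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from livespot import io, linker, mobility, synth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    n, dt = 250, 0.0438
    bound = synth.make_tracks(
        synth.MotionModel("bound", jitter_sd=0.03), n, 40, dt, bounds=(33.3, 33.3), seed=args.seed
    )
    control = synth.make_tracks(
        synth.MotionModel("brownian", D=0.5), n, 40, dt, bounds=(33.3, 33.3), seed=args.seed + 1
    )
    rng = np.random.default_rng(args.seed + 2)
    for df in (bound, control):
        df["x_um"] += rng.normal(0, 0.02, len(df))
        df["y_um"] += rng.normal(0, 0.02, len(df))

    args.outdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, df in (("target", bound), ("control", control)):
        linked = linker.link_nearest_neighbor(df[["frame", "x_um", "y_um"]], 0.22)
        kept = linker.filter_bound(linked)
        counts[name] = kept.track_id.nunique()
        io.write_table(args.outdir / f"filtered_tracks_{name}.csv", kept)
        if name == "target":
            mobility.mobility_map(kept, figure_path=str(args.outdir / "mobility_map.png"))

    excess = counts["target"] / max(counts["control"], 1)
    print(f"filtered tracks: target {counts['target']}, control {counts['control']}")
    print(f"target/control excess: {excess:.0f}x (bound molecules dominate the filtered set)")


if __name__ == "__main__":
    main()
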