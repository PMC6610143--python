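#!/usr/bin/env python
"""Embryo development: nuclear counts, areas and Nuc/Cyt ratios over divisions.

A synthetic three-channel embryo sequence (4 -> 8 -> 16 nuclei, nuclear
probe enrichment ramping 1 -> 2.5) is segmented in the marker channel,
ring masks are built by 4 px / 1 px dilation, probe-channel ratios are
measured, and nuclei are lineage-tracked through divisions.
"""

import argparse
from pathlib import Path

from livespot import io, quantify, synth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    movie, truth = synth.make_embryo_sequence(
        n_start_nuclei=4, division_period_frames=10, n_frames=21,
        expression_ramp=(1.0, 2.5), seed=args.seed,
    )
    labelings = [quantify.segment_nuclei(movie.frame(t, 0)) for t in range(movie.n_frames)]
    probe = [movie.frame(t, 1) for t in range(movie.n_frames)]
    lineages = quantify.track_nuclei(labelings, probe)
    series = quantify.nucleus_count_series(lineages)
    io.write_table(args.outdir / "embryo_lineages.csv", lineages)
    io.write_table(args.outdir / "embryo_series.csv", series)

    first, mid, last = series.iloc[0], series.iloc[10], series.iloc[-1]
    print(f"counts: {first['count']:.0f} -> {mid['count']:.0f} -> {last['count']:.0f} nuclei")
    print(f"mean nuclear area: {first.mean_area_px2:.0f} -> {last.mean_area_px2:.0f} px^2")
    print(
        f"mean Nuc/Cyt ratio: {first.mean_ratio:.2f} -> {last.mean_ratio:.2f} "
        f"(generated ramp 1.0 -> 2.5)"
    )


if __name__ == "__main__":
    main()
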