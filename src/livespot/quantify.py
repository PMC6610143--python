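"""Region-based intensity quantification.

Covers nuclear segmentation, perinuclear ring masks by morphological
dilation (ring = dilate(nucleus, 4 px) minus dilate(all nuclei, 1 px),
disk-shaped structuring element), nuclear/cytoplasmic and
signal/background ratios, ratio-of-means with first-order SEM
propagation, drug run-off curves, spot colocalization, box-whisker
distribution summaries, and nucleus lineage tracking through divisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

logger = logging.getLogger(__name__)

__all__ = [
    "RatioOfMeans",
    "segment_nuclei",
    "cytoplasm_ring",
    "region_ratio",
    "ratio_of_means",
    "runoff_curve",
    "spot_counts",
    "colocalize_spots",
    "summarize_distribution",
    "track_nuclei",
    "nucleus_count_series",
]


@dataclass
class RatioOfMeans:
    ratio: float
    sem: float


def segment_nuclei(
    frame: np.ndarray,
    threshold: str | float = "otsu",
    min_area: int = 20,
) -> np.ndarray:
    """Segment bright nuclei in a 2-D (max-projected) frame.

    Threshold (Otsu by default, or an explicit intensity), connected
    components, discard components below ``min_area`` px².  Returns an
    integer label image; 0 is background.  A frame where nothing survives
    yields an all-zero labeling.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a 2-D frame")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold strategy {threshold!r}")
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=int)
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    binary = img > thr
    labels, n = ndimage.label(binary)
    if n == 0:
        return labels
    areas = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    kill = np.flatnonzero(areas < min_area) + 1
    if len(kill):
        labels[np.isin(labels, kill)] = 0
        # relabel compactly
        labels, _ = ndimage.label(labels > 0)
    return labels


def cytoplasm_ring(
    nuclear_masks: np.ndarray,
    outer_dilation_px: int = 4,
    inner_dilation_px: int = 1,
) -> np.ndarray:
    """Perinuclear ring masks by dilation.

    Per nucleus, ring = dilate(nucleus, outer) minus dilate(all nuclei,
    inner), with a disk (Euclidean) structuring element; rings are clipped
    at the frame edges.  Where the rings of adjacent nuclei would overlap,
    each pixel is assigned to the nearer nucleus (by Euclidean distance to
    the nuclear mask), which is deterministic.  Returns a label image with
    the same label ids as the input.
    """
    if not outer_dilation_px > inner_dilation_px or inner_dilation_px < 0:
        raise ValueError("need outer_dilation_px > inner_dilation_px >= 0")
    labels = np.asarray(nuclear_masks)
    any_nuc = labels > 0
    if not any_nuc.any():
        return np.zeros_like(labels)
    outer_all = dilation(any_nuc, disk(outer_dilation_px))
    inner_all = dilation(any_nuc, disk(inner_dilation_px)) if inner_dilation_px > 0 else any_nuc
    ring_zone = outer_all & ~inner_all
    # nearest-nucleus label for every pixel, from the EDT of the nuclear mask
    _, (iy, ix) = ndimage.distance_transform_edt(~any_nuc, return_indices=True)
    nearest = labels[iy, ix]
    rings = np.where(ring_zone, nearest, 0)
    return rings


def region_ratio(
    frame: np.ndarray,
    region_masks: np.ndarray,
    ring_masks: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Mean-intensity ratio of each labeled region to its surround.

    For nuclear/cytoplasmic ratios pass the ring label image from
    :func:`cytoplasm_ring`; for signal/background ratios (e.g.
    mitochondria over diffuse cytoplasm) pass an explicit boolean
    ``background_mask`` shared by all labels.  Labels whose surround is
    empty are dropped with a logged reason.  Returns a table
    ``(label, frame, area_px2, mean_in, mean_ring, ratio)``.
    """
    img = np.asarray(frame, dtype=float)
    if img.shape != np.asarray(region_masks).shape:
        raise ValueError("frame and masks must share shape")
    if (ring_masks is None) == (background_mask is None):
        raise ValueError("pass exactly one of ring_masks or background_mask")
    rows = []
    bg_mean = float(img[background_mask].mean()) if background_mask is not None else None
    for lab in np.unique(region_masks):
        if lab == 0:
            continue
        inside = region_masks == lab
        if ring_masks is not None:
            ring = ring_masks == lab
            if not ring.any():
                logger.info("label %s dropped: empty ring", lab)
                continue
            surround = float(img[ring].mean())
        else:
            if background_mask is None or not background_mask.any():
                logger.info("label %s dropped: empty background region", lab)
                continue
            surround = bg_mean
        rows.append(
            (
                int(lab),
                frame_index,
                int(inside.sum()),
                float(img[inside].mean()),
                surround,
                float(img[inside].mean() / surround),
            )
        )
    return pd.DataFrame(rows, columns=["label", "frame", "area_px2", "mean_in", "mean_ring", "ratio"])


def ratio_of_means(m1: float, sem1: float, m2: float, sem2: float) -> RatioOfMeans:
    """Ratio of two means with first-order (delta-method) SEM propagation.

    ratio = m1/m2 and
    sem = |ratio|·sqrt((sem1/m1)² + (sem2/m2)²).
    """
    if m2 == 0:
        raise ValueError("denominator mean must be nonzero")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be >= 0")
    ratio = m1 / m2
    rel1 = sem1 / m1 if m1 != 0 else 0.0
    rel2 = sem2 / m2
    sem = abs(ratio) * float(np.sqrt(rel1**2 + rel2**2))
    return RatioOfMeans(ratio=float(ratio), sem=sem)


def spot_counts(
    spots: pd.DataFrame,
    n_frames: int,
    frame_interval_s: float,
) -> pd.DataFrame:
    """Dense per-cell, per-frame spot counts from a long-format spot table.

    Frames where a cell has no surviving spots get an explicit zero —
    dropping them would bias a run-off curve toward survivors.  Returns
    ``(channel, cell_id, frame, count, time_s)``.
    """
    counts = (
        spots.groupby(["channel", "cell_id", "frame"]).size().rename("count").reset_index()
    )
    full = (
        pd.MultiIndex.from_product(
            [sorted(spots["channel"].unique()), sorted(spots["cell_id"].unique()), range(n_frames)],
            names=["channel", "cell_id", "frame"],
        )
        .to_frame(index=False)
        .merge(counts, how="left")
        .fillna({"count": 0})
    )
    full["count"] = full["count"].astype(int)
    full["time_s"] = full["frame"] * frame_interval_s
    return full


def runoff_curve(
    counts: pd.DataFrame,
    drug_time_s: float,
    time_column: str = "time_s",
) -> pd.DataFrame:
    """Normalized spot-count run-off curve with cell-to-cell SEM.

    ``counts`` has columns ``(cell_id, time_s, count)`` (a ``channel``
    column, if present, is processed per channel).  Each cell's counts are
    divided by that cell's own pre-drug mean; the curve is the mean across
    cells with SEM across cells.  Cells with zero pre-drug spots cannot be
    normalized and are excluded with a log entry.
    """
    df = counts.copy()
    if "channel" not in df:
        df["channel"] = 0
    out = []
    for ch, chg in df.groupby("channel"):
        per_cell = []
        for cell, g in chg.groupby("cell_id"):
            g = g.sort_values(time_column)
            pre = g[g[time_column] < drug_time_s]["count"]
            if len(pre) == 0 or pre.mean() == 0:
                logger.info("cell %s excluded from run-off: no pre-drug spots", cell)
                continue
            per_cell.append(g.assign(norm=g["count"] / pre.mean()))
        if not per_cell:
            continue
        allc = pd.concat(per_cell)
        agg = allc.groupby(time_column)["norm"].agg(["mean", "std", "count"]).reset_index()
        agg["sem"] = np.where(agg["count"] > 1, agg["std"] / np.sqrt(agg["count"]), 0.0)
        agg["channel"] = ch
        out.append(agg[[time_column, "mean", "sem", "count", "channel"]])
    if not out:
        raise ValueError("no cell had pre-drug spots; run-off curve undefined")
    return pd.concat(out, ignore_index=True)


def colocalize_spots(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    radius_um: float,
) -> tuple[pd.DataFrame, float]:
    """Per-frame mutual-nearest-neighbor colocalization of two spot tables.

    Both tables must already sit in one registered coordinate frame.
    Returns the matched-pair table and the colocalized fraction
    matched_A / total_A (NaN when table A is empty, not 0).
    """
    from scipy.spatial import cKDTree

    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if len(table_a) == 0:
        return pd.DataFrame(columns=["frame", "index_a", "index_b", "distance_um"]), float("nan")
    pairs = []
    for frame in sorted(set(table_a["frame"]).intersection(set(table_b["frame"]))):
        a = table_a[table_a["frame"] == frame]
        b = table_b[table_b["frame"] == frame]
        axy = a[["x_um", "y_um"]].to_numpy(float)
        bxy = b[["x_um", "y_um"]].to_numpy(float)
        ta, tb = cKDTree(axy), cKDTree(bxy)
        d_ab, i_ab = tb.query(axy, distance_upper_bound=radius_um)
        d_ba, i_ba = ta.query(bxy, distance_upper_bound=radius_um)
        for i, (d, j) in enumerate(zip(d_ab, i_ab)):
            if np.isfinite(d) and j < len(bxy) and i_ba[j] == i:
                pairs.append((frame, a.index[i], b.index[j], float(d)))
    matched = pd.DataFrame(pairs, columns=["frame", "index_a", "index_b", "distance_um"])
    return matched, len(matched) / len(table_a)


def summarize_distribution(values) -> dict:
    """Box-whisker summary: median, 25–75% box, 5–95% whiskers, mean ± SEM.

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q = np.percentile(v, [5, 25, 50, 75, 95], method="linear")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {
        "median": float(q[2]),
        "p25": float(q[1]),
        "p75": float(q[3]),
        "p5": float(q[0]),
        "p95": float(q[4]),
        "mean": float(v.mean()),
        "sem": sem,
        "n": int(v.size),
    }


def track_nuclei(
    labelings: list[np.ndarray],
    frames: list[np.ndarray] | None = None,
    ring_outer_px: int = 4,
    ring_inner_px: int = 1,
    link_dilation_px: int = 6,
    max_link_dist_px: float = 50.0,
) -> pd.DataFrame:
    """Track segmented nuclei through time, following divisions.

    Nuclei are linked frame-to-frame by mask overlap: a nucleus at t+1 is
    assigned to the lineage whose ``link_dilation_px``-dilated mask at t it
    overlaps most; with zero overlap (daughters thrown clear of the parent
    at division) the fallback is the nearest previous-frame centroid
    within ``max_link_dist_px``.  When one parent gains two or more
    children, each child starts a new lineage branch recorded against the
    parent.  When an intensity ``frames`` sequence is given, each row also
    carries the nucleus/ring intensity ratio.

    Returns one row per nucleus per frame:
    ``(frame, lineage_id, parent_lineage, label, x_px, y_px, area_px2
    [, ratio])``.
    """
    rows = []
    next_lineage = 0
    prev_labels: np.ndarray | None = None
    prev_lineage_of_label: dict[int, int] = {}

    for t, labels in enumerate(labelings):
        props = regionprops(labels)
        if not props:
            logger.info("frame %d has zero nuclei; all lineages terminated", t)
            prev_labels, prev_lineage_of_label = None, {}
            continue
        ratios: dict[int, float] = {}
        if frames is not None:
            rings = cytoplasm_ring(labels, ring_outer_px, ring_inner_px)
            meas = region_ratio(frames[t], labels, rings, frame_index=t)
            ratios = dict(zip(meas["label"], meas["ratio"]))

        lineage_of_label: dict[int, int] = {}
        if prev_labels is None:
            for p in props:
                lineage_of_label[p.label] = next_lineage
                parent = -1
                rows.append(_nucleus_row(t, next_lineage, parent, p, ratios))
                next_lineage += 1
        else:
            # children per parent lineage, assigned by maximal overlap with
            # the dilated previous-frame masks
            se = disk(link_dilation_px)
            dilated_prev = {
                lab: dilation(prev_labels == lab, se) for lab in prev_lineage_of_label
            }
            prev_centroids = {
                p.label: p.centroid
                for p in regionprops(prev_labels)
                if p.label in prev_lineage_of_label
            }
            assignment: dict[int, int | None] = {}
            children_of: dict[int, list[int]] = {}
            for p in props:
                mask = labels == p.label
                best_lab, best_ov = None, 0
                for lab, dmask in dilated_prev.items():
                    ov = int((mask & dmask).sum())
                    if ov > best_ov or (ov == best_ov and ov > 0 and (best_lab is None or lab < best_lab)):
                        best_lab, best_ov = lab, ov
                if best_lab is None and prev_centroids:
                    # daughters displaced beyond the dilated parent:
                    # nearest previous centroid within the gate
                    cy, cx = p.centroid
                    lab_near, d_near = min(
                        (
                            (lab, float(np.hypot(cx - c[1], cy - c[0])))
                            for lab, c in prev_centroids.items()
                        ),
                        key=lambda lc: (lc[1], lc[0]),
                    )
                    if d_near <= max_link_dist_px:
                        best_lab = lab_near
                assignment[p.label] = best_lab
                if best_lab is not None:
                    children_of.setdefault(best_lab, []).append(p.label)
            for p in props:
                parent_lab = assignment[p.label]
                if parent_lab is None:
                    lineage, parent = next_lineage, -1
                    next_lineage += 1
                elif len(children_of[parent_lab]) == 1:
                    lineage = prev_lineage_of_label[parent_lab]
                    parent = -1  # continuation
                else:
                    # division: every daughter starts a new branch
                    lineage, parent = next_lineage, prev_lineage_of_label[parent_lab]
                    next_lineage += 1
                lineage_of_label[p.label] = lineage
                rows.append(_nucleus_row(t, lineage, parent, p, ratios))
        prev_labels = labels
        prev_lineage_of_label = lineage_of_label

    cols = ["frame", "lineage_id", "parent_lineage", "label", "x_px", "y_px", "area_px2", "ratio"]
    return pd.DataFrame(rows, columns=cols)


def nucleus_count_series(lineages: pd.DataFrame) -> pd.DataFrame:
    """Per-frame nucleus count, mean area and mean ratio from a lineage table."""
    g = lineages.groupby("frame")
    return pd.DataFrame(
        {
            "count": g["label"].size(),
            "mean_area_px2": g["area_px2"].mean(),
            "mean_ratio": g["ratio"].mean(),
        }
    ).reset_index()


def _nucleus_row(t, lineage, parent, prop, ratios):
    cy, cx = prop.centroid
    return (
        t,
        lineage,
        parent,
        int(prop.label),
        float(cx),
        float(cy),
        int(prop.area),
        float(ratios.get(prop.label, np.nan)),
    )

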