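"""Image-analysis stage: tissue ROI, label detection, colocalization, and
core-size-normalised quantification.

The pipeline mirrors operator-driven TMA image analysis: an intensity
threshold on a tissue channel defines the region of interest (holes larger
than a configured area are excluded from the tissue area), per-channel
intensity thresholds plus size gates turn connected components into cell
labels, labels may be required to centre on DAPI, and co-labels for 2–4-way
marker combinations are emitted where member labels mutually overlap.
Counts are normalised to the core's tissue area (counts/mm^2) and
log10(x+1)-transformed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from tilquant.errors import ConfigError, EmptyROIError
from tilquant.syndata import DAPI, CoreImage, combination_key


@dataclass
class TissueROI:
    """Tissue-occupying region of one core after hole removal."""

    core_id: str
    mask: np.ndarray
    um_per_px: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.um_per_px**2 / 1e6


@dataclass
class CellLabel:
    """One detected marker(-combination) label."""

    label_id: int
    core_id: str
    centroid: tuple[float, float]  # (row, col), 0-based
    area_px: int
    markers: frozenset[str]


@dataclass
class LabelSet:
    """All labels for one marker (or combination) on one core.

    ``label_image`` holds the filtered labels (0 = background) so that
    downstream colocalization can reason about pixel overlap.
    """

    core_id: str
    markers: frozenset[str]
    labels: list[CellLabel]
    label_image: np.ndarray
    threshold: float | None = None

    @property
    def count(self) -> int:
        return len(self.labels)

    @property
    def key(self) -> str:
        return combination_key(self.markers)


def roi_from_mask(mask: np.ndarray, um_per_px: float, core_id: str = "core") -> TissueROI:
    """Wrap an externally supplied boolean tissue mask as a ROI."""
    return TissueROI(core_id=core_id, mask=np.asarray(mask, dtype=bool), um_per_px=um_per_px)


def compute_tissue_roi(
    image: CoreImage,
    channel_for_tissue: str = DAPI,
    threshold: float = 0.0,
    min_hole_area_um2: float = 100.0,
    closing_radius_px: int = 3,
) -> TissueROI:
    """Segment the tissue-occupying area of a core.

    The mask is the largest connected above-threshold component after
    morphological closing; interior holes larger than ``min_hole_area_um2``
    stay excluded (they are non-tissue), smaller ones are filled.

    Raises :class:`EmptyROIError` when no pixel exceeds the threshold, so the
    caller can flag and exclude the core.
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    arr = image.channel(channel_for_tissue)
    fg = arr > threshold
    if not fg.any():
        raise EmptyROIError(f"core {image.core_id!r}: no pixel above {threshold}")
    if closing_radius_px > 0:
        fg = ndi.binary_closing(fg, structure=disk(closing_radius_px))
    lab = cc_label(fg, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = lab == largest
    filled = ndi.binary_fill_holes(comp)
    holes = filled & ~comp
    min_hole_px = min_hole_area_um2 / image.um_per_px**2
    hole_lab = cc_label(holes, connectivity=2)
    mask = comp.copy()
    for r in regionprops(hole_lab):
        if r.area <= min_hole_px:
            mask[tuple(r.coords.T)] = True
    return TissueROI(core_id=image.core_id, mask=mask, um_per_px=image.um_per_px)


def detect_labels(
    image: CoreImage,
    marker: str,
    threshold: float,
    roi: TissueROI,
    size_gate_um2: tuple[float, float] = (20.0, 400.0),
    dapi_labels: "LabelSet | None" = None,
) -> LabelSet:
    """Detect cells positive for one marker by thresholding + size gating.

    Connected components (8-connectivity) of above-threshold pixels inside the
    ROI are filtered to the size gates (given in um^2). When ``dapi_labels``
    is supplied, a component is retained only if it contains or touches the
    centroid of a DAPI label ("centred on DAPI").
    """
    if marker not in image.channels:
        raise ConfigError(f"marker {marker!r} not in panel {list(image.channels)}")
    lo, hi = size_gate_um2
    if lo <= 0 or hi < lo:
        raise ConfigError("size gates must be positive and ordered")
    arr = image.channel(marker)
    fg = (arr > threshold) & roi.mask
    lab = cc_label(fg, connectivity=2)
    lo_px = lo / image.um_per_px**2
    hi_px = hi / image.um_per_px**2

    anchored: set[int] | None = None
    if dapi_labels is not None:
        anchored = set()
        nrow, ncol = lab.shape
        for dl in dapi_labels.labels:
            r0, c0 = int(round(dl.centroid[0])), int(round(dl.centroid[1]))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r, c = r0 + dr, c0 + dc
                    if 0 <= r < nrow and 0 <= c < ncol and lab[r, c] > 0:
                        anchored.add(int(lab[r, c]))

    labels: list[CellLabel] = []
    out = np.zeros_like(lab)
    next_id = 0
    for reg in regionprops(lab):
        if not (lo_px <= reg.area <= hi_px):
            continue
        if anchored is not None and reg.label not in anchored:
            continue
        next_id += 1
        out[tuple(reg.coords.T)] = next_id
        labels.append(
            CellLabel(
                label_id=next_id,
                core_id=image.core_id,
                centroid=tuple(reg.centroid),
                area_px=int(reg.area),
                markers=frozenset({marker}),
            )
        )
    return LabelSet(
        core_id=image.core_id,
        markers=frozenset({marker}),
        labels=labels,
        label_image=out,
        threshold=threshold,
    )


def colocalize(
    labels_by_marker: Mapping[str, LabelSet],
    combination: Sequence[str],
    min_overlap_frac: float = 0.5,
    method: str = "overlap",
    max_centroid_dist_um: float = 5.0,
) -> LabelSet:
    """Co-labels for a 2–4-marker combination.

    ``overlap`` (default): a co-label is a connected region where the labels
    of all members overlap, retained when its pixel area is at least
    ``min_overlap_frac`` of the smallest contributing member label.
    ``centroid``: greedy matching of member labels whose centroids lie within
    ``max_centroid_dist_um`` of a label of the rarest member.
    """
    combo = tuple(combination)
    if not 2 <= len(combo) <= 4:
        raise ValueError("combination must have 2-4 markers")
    missing = [m for m in combo if m not in labels_by_marker]
    if missing:
        raise ConfigError(f"no detected labels supplied for {missing}")
    sets = [labels_by_marker[m] for m in combo]
    core_id = sets[0].core_id
    markers = frozenset(combo)

    if method == "centroid":
        return _colocalize_centroid(sets, markers, core_id, max_centroid_dist_um)
    if method != "overlap":
        raise ValueError(f"unknown colocalization method {method!r}")

    inter = np.logical_and.reduce([ls.label_image > 0 for ls in sets])
    comp = cc_label(inter, connectivity=2)
    out = np.zeros_like(comp)
    labels: list[CellLabel] = []
    next_id = 0
    for reg in regionprops(comp):
        coords = tuple(reg.coords.T)
        # smallest member label contributing to this overlap region
        min_member_area = math.inf
        for ls in sets:
            ids, cnts = np.unique(ls.label_image[coords], return_counts=True)
            best = ids[np.argmax(cnts)]
            area = next(l.area_px for l in ls.labels if l.label_id == best)
            min_member_area = min(min_member_area, area)
        if reg.area / min_member_area < min_overlap_frac:
            continue
        next_id += 1
        out[coords] = next_id
        labels.append(
            CellLabel(
                label_id=next_id,
                core_id=core_id,
                centroid=tuple(reg.centroid),
                area_px=int(reg.area),
                markers=markers,
            )
        )
    return LabelSet(core_id=core_id, markers=markers, labels=labels, label_image=out)


def _colocalize_centroid(
    sets: list[LabelSet], markers: frozenset[str], core_id: str, max_dist_um: float
) -> LabelSet:
    sets = sorted(sets, key=lambda s: s.count)
    base, rest = sets[0], sets[1:]
    # px scale is unknown here; centroids are in px and the distance is given
    # in um — infer scale from the first label image via attached threshold is
    # not possible, so accept distance in px when no scale is available.
    labels: list[CellLabel] = []
    used = [set() for _ in rest]
    next_id = 0
    for bl in base.labels:
        ok = True
        picks = []
        for k, ls in enumerate(rest):
            best, best_d = None, math.inf
            for ol in ls.labels:
                if ol.label_id in used[k]:
                    continue
                d = math.hypot(bl.centroid[0] - ol.centroid[0], bl.centroid[1] - ol.centroid[1])
                if d < best_d:
                    best, best_d = ol, d
            if best is None or best_d > max_dist_um:
                ok = False
                break
            picks.append((k, best))
        if ok:
            for k, ol in picks:
                used[k].add(ol.label_id)
            next_id += 1
            labels.append(
                CellLabel(
                    label_id=next_id,
                    core_id=core_id,
                    centroid=bl.centroid,
                    area_px=bl.area_px,
                    markers=markers,
                )
            )
    return LabelSet(core_id=core_id, markers=markers, labels=labels,
                    label_image=np.zeros_like(base.label_image))


def summarize_core(
    label_sets: Sequence[LabelSet],
    roi: TissueROI,
    image: CoreImage | None = None,
) -> pd.DataFrame:
    """Tidy per-core quantification records.

    One row per label set: raw count, tissue area, density per mm^2,
    log10(density + 1), and — for single markers when the image is supplied —
    the MFI (mean intensity of the label pixels, which are above threshold by
    construction).
    """
    if roi.area_mm2 <= 0:
        raise EmptyROIError(f"core {roi.core_id!r}: empty ROI")
    rows = []
    for ls in label_sets:
        count = ls.count
        density = count / roi.area_mm2
        mfi = np.nan
        if image is not None and len(ls.markers) == 1 and count > 0:
            arr = image.channel(next(iter(ls.markers)))
            mfi = float(arr[ls.label_image > 0].mean())
        rows.append(
            {
                "core_id": roi.core_id,
                "combination_key": ls.key,
                "raw_count": count,
                "area_mm2": roi.area_mm2,
                "density": density,
                "log_value": math.log10(density + 1.0),
                "mfi": mfi,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PanelConfig:
    """Per-channel thresholds, gates and requested combinations for a panel."""

    thresholds: Mapping[str, float]
    size_gate_um2: tuple[float, float] = (20.0, 400.0)
    combinations: Sequence[Sequence[str]] = field(default_factory=list)
    tissue_channel: str = DAPI
    tissue_threshold: float = 0.0
    min_hole_area_um2: float = 100.0
    dapi_threshold: float | None = None
    min_overlap_frac: float = 0.5


def quantify_core(
    image: CoreImage,
    config: PanelConfig,
    roi: TissueROI | None = None,
) -> pd.DataFrame:
    """Run the full quantification chain on one core.

    Computes the ROI (unless supplied), detects DAPI labels when a DAPI
    threshold is configured (labels are then required to centre on DAPI),
    detects per-marker labels, forms the configured co-labels, and returns the
    per-core records. A core whose ROI is empty raises
    :class:`EmptyROIError`; callers batching many cores should catch it and
    log the exclusion.
    """
    if roi is None:
        roi = compute_tissue_roi(
            image,
            channel_for_tissue=config.tissue_channel,
            threshold=config.tissue_threshold,
            min_hole_area_um2=config.min_hole_area_um2,
        )
    dapi_set = None
    if config.dapi_threshold is not None and DAPI in image.channels:
        dapi_set = detect_labels(
            image, DAPI, config.dapi_threshold, roi, size_gate_um2=config.size_gate_um2
        )
    by_marker: dict[str, LabelSet] = {}
    for marker, thr in config.thresholds.items():
        if marker == DAPI:
            continue
        by_marker[marker] = detect_labels(
            image, marker, thr, roi,
            size_gate_um2=config.size_gate_um2, dapi_labels=dapi_set,
        )
    sets: list[LabelSet] = list(by_marker.values())
    for combo in config.combinations:
        sets.append(colocalize(by_marker, combo, min_overlap_frac=config.min_overlap_frac))
    return summarize_core(sets, roi, image)


def quantify_cores(images: Sequence[CoreImage], config: PanelConfig) -> pd.DataFrame:
    """Quantify many cores, excluding (with a warning) any with an empty ROI."""
    frames = []
    for img in images:
        try:
            frames.append(quantify_core(img, config))
        except EmptyROIError as exc:
            warnings.warn(f"excluding core {img.core_id!r}: {exc}")
    if not frames:
        return pd.DataFrame(
            columns=["core_id", "combination_key", "raw_count", "area_mm2",
                     "density", "log_value", "mfi"]
        )
    return pd.concat(frames, ignore_index=True)
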