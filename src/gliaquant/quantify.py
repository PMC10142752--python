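"""Mask-based image quantification.

Implements the three tissue pipelines: pathology-load measurement
(threshold-clip masks, integrated intensity per ROI area), tissue-wide
microglial marker expression (adaptive per-marker masks combined into a
master mask), and single-cell identification/measurement (each connected
component of the master mask is one cell; per-cell mean marker intensity
approximates protein concentration per cell).

Conventions: pixel coordinates are 0-based (row, col); connected components
use 8-connectivity; objects touching the ROI border are kept; areas are
reported in px and um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .config import MARKERS, QuantConfig


class ImageInputError(ValueError):
    """Shape mismatch, missing channel, or empty ROI."""


@dataclass
class ChannelImage:
    """One aligned channel: 2D non-negative intensities plus pixel size."""

    pixels: np.ndarray
    name: str
    um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImageInputError(f"channel {self.name}: expected a 2D array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ImageInputError(f"channel {self.name}: non-finite or negative pixels")
        if self.um_per_px <= 0:
            raise ImageInputError("um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MultiplexImageSet:
    """Aligned named channels + ROI mask + metadata for one tissue section."""

    channels: dict[str, ChannelImage]
    roi: np.ndarray
    case_id: str
    group: str
    region: str
    um_per_px: float

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, dtype=bool)
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ImageInputError("channels differ in shape")
        if shapes and self.roi.shape not in shapes:
            raise ImageInputError("ROI shape differs from channel shape")

    def __getitem__(self, name: str) -> ChannelImage:
        try:
            return self.channels[name]
        except KeyError:
            raise ImageInputError(f"channel {name!r} not in image set") from None


@dataclass
class BinaryMask:
    """Boolean mask with provenance (source channel + method tag)."""

    mask: np.ndarray
    source: str
    method: str  # "clip" | "adaptive" | "union"
    um_per_px: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.um_per_px**2


@dataclass
class LoadMeasures:
    """Per-section tissue-wide measures.

    ptdp_load: pTDP-43 integrated intensity / ROI area (intensity/um^2);
    gfap_load: GFAP mask area fraction of the ROI; cell_density in
    cells/mm^2; tissue_wide_intensity: per-marker integrated intensity over
    the master mask / ROI area (or / mask area when mask-normalised).
    """

    case_id: str
    group: str
    region: str
    ptdp_load: float
    gfap_load: float
    cell_density: float
    tissue_wide_intensity: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "group": self.group,
            "region": self.region,
            "ptdp_load": self.ptdp_load,
            "gfap_load": self.gfap_load,
            "cell_density": self.cell_density,
        }
        for m, v in self.tissue_wide_intensity.items():
            row[f"tw_{m}"] = v
        return row


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ImageInputError(f"shape mismatch: {sorted(shapes)}")


def clip_threshold_mask(img: ChannelImage, threshold: float) -> BinaryMask:
    """Fixed-threshold ("clip") mask: true where pixel > threshold."""
    if threshold < 0:
        raise ImageInputError("threshold must be >= 0")
    return BinaryMask(img.pixels > threshold, img.name, "clip", img.um_per_px)


def adaptive_threshold_mask(
    img: ChannelImage, window_um: float, offset: float
) -> BinaryMask:
    """Local-mean adaptive mask: true where pixel exceeds the mean over a
    square window of side ``window_um`` by more than ``offset``.

    Mirrors per-marker immunolabelling segmentation where illumination and
    background vary across the field.
    """
    if window_um <= 0:
        raise ImageInputError("window_um must be > 0")
    win = max(int(round(window_um / img.um_per_px)), 1)
    if win > min(img.shape):
        raise ImageInputError(
            f"window of {win}px exceeds image extent {min(img.shape)}px"
        )
    local_mean = ndimage.uniform_filter(img.pixels, size=win, mode="reflect")
    return BinaryMask(img.pixels > local_mean + offset, img.name, "adaptive", img.um_per_px)


def subtract_bleedthrough(
    ptdp_img: ChannelImage, hla_img: ChannelImage, clip_threshold: float
) -> ChannelImage:
    """Remove HLA-DR bleed-through from the pTDP-43 channel.

    Pixels inside the high-HLA-DR clip mask are zeroed (the residual
    cross-reactive signal there cannot be attributed to pTDP-43), rather
    than arithmetically subtracted.
    """
    _check_same_shape(ptdp_img.pixels, hla_img.pixels)
    high = clip_threshold_mask(hla_img, clip_threshold)
    out = ptdp_img.pixels.copy()
    out[high.mask] = 0.0
    return ChannelImage(out, ptdp_img.name, ptdp_img.um_per_px)


def master_mask(masks: list[BinaryMask]) -> BinaryMask:
    """Pixelwise union of per-marker masks.

    In the human arm the inputs are the Iba1, HLA-DR, CD68 and CD74
    adaptive masks; in the mouse arm a single Iba1 mask suffices (all
    microglia are strongly Iba1-immunoreactive there).
    """
    if not masks:
        raise ImageInputError("master_mask requires at least one mask")
    _check_same_shape(*(m.mask for m in masks))
    union = np.zeros_like(masks[0].mask)
    for m in masks:
        union |= m.mask
    source = "+".join(m.source for m in masks)
    return BinaryMask(union, source, "union", masks[0].um_per_px)


def label_objects(
    mask: BinaryMask, roi: np.ndarray, min_area_px: int = 1
) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connected components of mask ∩ ROI, dropping objects below
    ``min_area_px``. Returns (label map, objects table with id/centroid/area).
    """
    if min_area_px < 1:
        raise ImageInputError("min_area_px must be >= 1")
    roi = np.asarray(roi, dtype=bool)
    _check_same_shape(mask.mask, roi)
    lab = _cc_label(mask.mask & roi, connectivity=2)
    rows = []
    keep = np.zeros(lab.max() + 1, dtype=np.int64)
    nxt = 1
    for rp in regionprops(lab):
        if rp.area < min_area_px:
            continue
        keep[rp.label] = nxt
        cy, cx = rp.centroid
        rows.append(
            {
                "object_id": nxt,
                "y": cy,
                "x": cx,
                "area_px": int(rp.area),
                "area_um2": rp.area * mask.um_per_px**2,
            }
        )
        nxt += 1
    relabelled = keep[lab]
    return relabelled, pd.DataFrame(
        rows, columns=["object_id", "y", "x", "area_px", "area_um2"]
    )


def measure_cells(
    labels: np.ndarray,
    objects: pd.DataFrame,
    imgset: MultiplexImageSet,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Per-object mean intensity of each marker (= protein concentration per
    cell). Returns a cell table with metadata copied from the image set."""
    _check_same_shape(labels, imgset.roi)
    if objects.empty:
        cols = ["cell_id", *markers, "case_id", "group", "region", "y", "x", "area_px"]
        return pd.DataFrame(columns=cols)
    idx = objects["object_id"].to_numpy()
    out = objects[["object_id", "y", "x", "area_px"]].copy()
    for marker in markers:
        img = imgset[marker]
        _check_same_shape(labels, img.pixels)
        means = ndimage.mean(img.pixels, labels=labels, index=idx)
        out[marker] = np.asarray(means, dtype=float)
    out.insert(0, "cell_id", [f"{imgset.case_id}:{int(i)}" for i in idx])
    out = out.drop(columns="object_id")
    out["case_id"] = imgset.case_id
    out["group"] = imgset.group
    out["region"] = imgset.region
    return out


def _roi_area_um2(roi: np.ndarray, um_per_px: float) -> float:
    area_px = int(np.asarray(roi, dtype=bool).sum())
    if area_px == 0:
        raise ImageInputError("ROI is empty")
    return area_px * um_per_px**2


def pathology_load(ptdp_img: ChannelImage, ptdp_mask: BinaryMask, roi: np.ndarray) -> float:
    """Integrated masked pTDP-43 intensity normalised to ROI area
    (intensity per um^2)."""
    roi = np.asarray(roi, dtype=bool)
    _check_same_shape(ptdp_img.pixels, ptdp_mask.mask, roi)
    area = _roi_area_um2(roi, ptdp_img.um_per_px)
    return float(ptdp_img.pixels[ptdp_mask.mask & roi].sum() / area)


def area_load(mask: BinaryMask, roi: np.ndarray) -> float:
    """Mask area as a fraction of ROI area, in [0, 1] (GFAP astrogliosis)."""
    roi = np.asarray(roi, dtype=bool)
    _check_same_shape(mask.mask, roi)
    roi_px = int(roi.sum())
    if roi_px == 0:
        raise ImageInputError("ROI is empty")
    return float((mask.mask & roi).sum() / roi_px)


def cell_density(n_cells: int, roi: np.ndarray, um_per_px: float) -> float:
    """Cell count per ROI area in cells/mm^2."""
    area_mm2 = _roi_area_um2(roi, um_per_px) / 1e6
    return n_cells / area_mm2


def tissue_wide_intensity(
    marker_img: ChannelImage,
    master: BinaryMask,
    roi: np.ndarray,
    normalise_to: str = "roi",
) -> float:
    """Integrated marker intensity over (master ∩ ROI) per unit area.

    ``normalise_to='roi'`` divides by ROI area (default); ``'mask'`` divides
    by the master-mask area inside the ROI — both normalisations are in use
    for bulk expression measures, so the choice is explicit.
    """
    roi = np.asarray(roi, dtype=bool)
    _check_same_shape(marker_img.pixels, master.mask, roi)
    sel = master.mask & roi
    total = float(marker_img.pixels[sel].sum())
    if normalise_to == "roi":
        return total / _roi_area_um2(roi, marker_img.um_per_px)
    if normalise_to == "mask":
        area_px = int(sel.sum())
        if area_px == 0:
            return 0.0
        return total / (area_px * marker_img.um_per_px**2)
    raise ImageInputError("normalise_to must be 'roi' or 'mask'")


def quantify_image_set(
    imgset: MultiplexImageSet, qc: QuantConfig
) -> tuple[pd.DataFrame, LoadMeasures]:
    """Run all three pipelines on one section.

    1. Pathology load: HLA-DR bleed correction (when an HLA-DR clip
       threshold is configured), clip masks for pTDP-43 and GFAP, integrated
       intensity / area fraction per ROI area.
    2. Tissue-wide expression: adaptive per-marker masks combined into the
       master mask; integrated intensity of each of the five markers.
    3. Single cell: master-mask connected components measured per marker.
    """
    ptdp = imgset["pTDP-43"]
    if "HLA-DR" in qc.clip_thresholds:
        ptdp = subtract_bleedthrough(ptdp, imgset["HLA-DR"], qc.clip_thresholds["HLA-DR"])
    ptdp_mask = clip_threshold_mask(ptdp, qc.clip_thresholds["pTDP-43"])
    gfap_mask = clip_threshold_mask(imgset["GFAP"], qc.clip_thresholds["GFAP"])

    marker_masks = [
        adaptive_threshold_mask(imgset[m], qc.adaptive_window_um, qc.adaptive_offset)
        for m in qc.master_markers
    ]
    master = master_mask(marker_masks)
    labels, objects = label_objects(master, imgset.roi, qc.min_cell_area_px)
    cells = measure_cells(labels, objects, imgset)

    loads = LoadMeasures(
        case_id=imgset.case_id,
        group=imgset.group,
        region=imgset.region,
        ptdp_load=pathology_load(ptdp, ptdp_mask, imgset.roi),
        gfap_load=area_load(gfap_mask, imgset.roi),
        cell_density=cell_density(len(cells), imgset.roi, imgset.um_per_px),
        tissue_wide_intensity={
            m: tissue_wide_intensity(imgset[m], master, imgset.roi, qc.normalise_to)
            for m in MARKERS
        },
    )
    return cells, loads
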