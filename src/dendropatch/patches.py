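"""Dendritic patch detection and relative-enrichment quantification.

Patches (local acto-myosin accumulations along the dendritic shaft) are
detected as connected regions whose POI/cytosol ratio exceeds a multiple of
the mean ratio in the dendrite. Enrichment of a protein in a patch relative
to the adjacent shaft is the background-corrected double ratio

    [(POI_patch − POI_bg) / (Cyto_patch − Cyto_bg)]
    ----------------------------------------------
    [(POI_dend  − POI_bg) / (Cyto_dend  − Cyto_bg)]

where each term is a region-mean intensity and the background per channel is
the average of four sectors placed outside the cell around the patch. A value
of 1.0 means no enrichment over the adjacent dendrite; the reported
percentage enrichment is (value − 1) × 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage import measure

from .ratio import CellMask, ChannelImage, RatioImage, compute_ratio, max_project

__all__ = [
    "PatchInfo",
    "PatchSet",
    "EnrichmentMeasurement",
    "DrugResponseRecord",
    "TTestResult",
    "detect_patches",
    "place_background_sectors",
    "dendrite_reference_mask",
    "measure_regions",
    "relative_enrichment",
    "drug_response",
    "welch_t_test",
]

log = logging.getLogger(__name__)


@dataclass
class PatchInfo:
    label: int
    centroid: tuple[float, float]  # (row, col)
    area_px: int
    mean_ratio: float


@dataclass
class PatchSet:
    """Labelled patch regions within a dendrite mask."""

    labels: np.ndarray  # 0 = no patch, 1..n = patch ids
    patches: list[PatchInfo]
    threshold: float

    def __len__(self) -> int:
        return len(self.patches)

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label


@dataclass
class EnrichmentMeasurement:
    """The six region-mean intensities entering the enrichment double ratio."""

    poi_patch: float
    poi_dendrite: float
    poi_bg: float
    cyto_patch: float
    cyto_dendrite: float
    cyto_bg: float


@dataclass
class DrugResponseRecord:
    """Per-patch normalized enrichment before and after drug addition."""

    label: int
    before: float
    after: float
    change: float  # after / before
    drug: str = ""
    interval_min: float = float("nan")


@dataclass
class TTestResult:
    t: float
    df: float  # Welch–Satterthwaite degrees of freedom
    p: float  # two-tailed


def detect_patches(
    ratio: RatioImage,
    dendrite_mask: CellMask,
    factor: float = 3.0,
    min_area_px: int = 4,
) -> PatchSet:
    """Detect patches as supra-threshold connected components of the ratio.

    The threshold is ``factor`` × the mean valid ratio within the dendrite
    mask; the default factor 3.0 reads "more than 200% above the average
    ratio" as average + 2×average (pass factor=2.0 for the ">2× average"
    reading). Components use 8-connectivity and must reach ``min_area_px``.
    """
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    if not dendrite_mask.any():
        raise ValueError("dendrite mask is empty")
    if not factor > 1:
        raise ValueError("factor must be > 1")
    valid = ratio.valid_mask & dendrite_mask
    if not valid.any():
        raise ValueError("no valid ratio pixels inside the dendrite mask")
    mean_ratio = float(ratio.values[valid].mean())
    threshold = factor * mean_ratio
    supra = valid & (ratio.values > threshold)
    labels = measure.label(supra, connectivity=2)
    patches: list[PatchInfo] = []
    keep = np.zeros_like(labels)
    next_id = 0
    for region in measure.regionprops(labels, intensity_image=ratio.values):
        if region.area < min_area_px:
            continue
        next_id += 1
        keep[labels == region.label] = next_id
        patches.append(
            PatchInfo(
                label=next_id,
                centroid=tuple(region.centroid),
                area_px=int(region.area),
                mean_ratio=float(region.intensity_mean),
            )
        )
    return PatchSet(labels=keep, patches=patches, threshold=threshold)


def place_background_sectors(
    cell_mask: CellMask,
    centroid: tuple[float, float],
    side_px: int = 10,
) -> list[np.ndarray]:
    """Place four square background sectors around a patch.

    One ``side_px`` square per 90° angular sector (centered on E/N/W/S)
    around the patch centroid, each at the smallest distance at which the
    square lies entirely outside the cell mask and inside the image. Raises
    when any of the four angular sectors cannot host a square.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    h, w = cell_mask.shape
    if h < side_px or w < side_px:
        raise ValueError("image smaller than the sector side")
    cy, cx = centroid
    # window sums over all side_px x side_px windows, indexed by top-left corner
    integral = np.zeros((h + 1, w + 1))
    integral[1:, 1:] = cell_mask.cumsum(0).cumsum(1)
    s = side_px
    win = (
        integral[s:, s:] - integral[:-s, s:] - integral[s:, :-s] + integral[:-s, :-s]
    )  # (h-s+1, w-s+1)
    candidates = win == 0
    y0s, x0s = np.mgrid[0 : h - s + 1, 0 : w - s + 1]
    ctr_y = y0s + (s - 1) / 2.0
    ctr_x = x0s + (s - 1) / 2.0
    angles = np.degrees(np.arctan2(-(ctr_y - cy), ctr_x - cx))  # image y grows down
    quadrant = ((angles + 45.0) % 360.0) // 90.0  # 0=E, 1=N, 2=W, 3=S
    dist2 = (ctr_y - cy) ** 2 + (ctr_x - cx) ** 2
    sectors: list[np.ndarray] = []
    for q, name in enumerate(("east", "north", "west", "south")):
        sel = candidates & (quadrant == q)
        if not sel.any():
            raise ValueError(
                f"cannot place the {name} background sector outside the cell"
            )
        d2 = np.where(sel, dist2, np.inf)
        r, c = np.unravel_index(int(np.argmin(d2)), d2.shape)
        sector = np.zeros((h, w), dtype=bool)
        sector[r : r + s, c : c + s] = True
        sectors.append(sector)
    return sectors


def dendrite_reference_mask(
    dendrite_mask: CellMask,
    patch_mask: np.ndarray,
    all_patches_mask: np.ndarray,
    pixel_size: float,
    min_um: float = 2.0,
    max_um: float = 5.0,
) -> np.ndarray:
    """Adjacent-shaft reference region for one patch.

    Dendrite pixels whose distance from the patch lies within
    [``min_um``, ``max_um``], minus every patch pixel.
    """
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    dist_px = ndimage.distance_transform_edt(~np.asarray(patch_mask, dtype=bool))
    dist_um = dist_px * pixel_size
    ref = dendrite_mask & (dist_um >= min_um) & (dist_um <= max_um)
    ref &= ~np.asarray(all_patches_mask, dtype=bool)
    if not ref.any():
        raise ValueError("dendrite reference region is empty")
    return ref


def _region_mean(values: np.ndarray, region: np.ndarray, name: str) -> float:
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError(f"region {name!r} is empty")
    return float(values[region].mean())


def measure_regions(
    poi: ChannelImage,
    cyto: ChannelImage,
    patch_mask: np.ndarray,
    dendrite_ref_region: np.ndarray,
    bg_sectors: list[np.ndarray],
) -> EnrichmentMeasurement:
    """Region-mean intensities for the enrichment double ratio.

    Background per channel is the mean of the four sector means.
    """
    if len(bg_sectors) < 4:
        raise ValueError(f"need four background sectors, got {len(bg_sectors)}")
    poi_bg = float(np.mean([_region_mean(poi.values, s, f"bg sector {i}") for i, s in enumerate(bg_sectors)]))
    cyto_bg = float(np.mean([_region_mean(cyto.values, s, f"bg sector {i}") for i, s in enumerate(bg_sectors)]))
    return EnrichmentMeasurement(
        poi_patch=_region_mean(poi.values, patch_mask, "patch"),
        poi_dendrite=_region_mean(poi.values, dendrite_ref_region, "dendrite reference"),
        poi_bg=poi_bg,
        cyto_patch=_region_mean(cyto.values, patch_mask, "patch"),
        cyto_dendrite=_region_mean(cyto.values, dendrite_ref_region, "dendrite reference"),
        cyto_bg=cyto_bg,
    )


def relative_enrichment(m: EnrichmentMeasurement) -> float:
    """Background-corrected enrichment of the POI in a patch vs the shaft.

    Returns the double ratio; 1.0 means no enrichment over the adjacent
    dendrite. Invariant to uniform rescaling of all six means and to common
    offsets applied to a channel's triplet (patch, dendrite, background).
    """
    if (
        m.poi_patch == m.poi_dendrite == m.poi_bg
        and m.cyto_patch == m.cyto_dendrite == m.cyto_bg
    ):
        return 1.0  # degenerate-uniform input: no contrast anywhere
    diffs = {
        "POI_patch - POI_bg": m.poi_patch - m.poi_bg,
        "Cytosol_patch - Cytosol_bg": m.cyto_patch - m.cyto_bg,
        "POI_dendrite - POI_bg": m.poi_dendrite - m.poi_bg,
        "Cytosol_dendrite - Cytosol_bg": m.cyto_dendrite - m.cyto_bg,
    }
    for name in ("Cytosol_patch - Cytosol_bg", "POI_dendrite - POI_bg",
                 "Cytosol_dendrite - Cytosol_bg"):
        if diffs[name] <= 0:
            raise ValueError(f"enrichment undefined: {name} = {diffs[name]} <= 0")
    patch_term = diffs["POI_patch - POI_bg"] / diffs["Cytosol_patch - Cytosol_bg"]
    dend_term = diffs["POI_dendrite - POI_bg"] / diffs["Cytosol_dendrite - Cytosol_bg"]
    return patch_term / dend_term


@dataclass
class ImagePair:
    """One acquisition epoch: POI and cytosol z-stacks sharing geometry."""

    poi: list[ChannelImage]
    cyto: list[ChannelImage]


def drug_response(
    before: ImagePair,
    after: ImagePair,
    dendrite_mask: CellMask,
    min_cyto: float,
    factor: float = 3.0,
    min_area_px: int = 4,
    drug: str = "",
    interval_min: float = float("nan"),
) -> tuple[list[DrugResponseRecord], PatchSet]:
    """Quantify per-patch enrichment change across a drug addition.

    Both epochs are max-projected; patches are detected on the *before*
    projection only and the same masks are reused on the after projection.
    Normalized enrichment = mean patch ratio / mean shaft ratio (shaft =
    dendrite minus all patches), which cancels global illumination changes.
    """
    poi_b, cyto_b = max_project(before.poi), max_project(before.cyto)
    poi_a, cyto_a = max_project(after.poi), max_project(after.cyto)
    ratio_b = compute_ratio(poi_b, cyto_b, min_cyto)
    ratio_a = compute_ratio(poi_a, cyto_a, min_cyto)
    patch_set = detect_patches(ratio_b, dendrite_mask, factor=factor, min_area_px=min_area_px)
    if len(patch_set) == 0:
        log.warning("drug_response: no patches detected on the before projection")
        return [], patch_set
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    shaft = dendrite_mask & ~patch_set.mask()
    records: list[DrugResponseRecord] = []
    for info in patch_set.patches:
        pm = patch_set.mask(info.label)
        vals = {}
        for tag, rimg in (("before", ratio_b), ("after", ratio_a)):
            pv = rimg.values[pm & rimg.valid_mask]
            sv = rimg.values[shaft & rimg.valid_mask]
            if pv.size == 0 or sv.size == 0:
                raise ValueError(
                    f"patch {info.label}: no valid ratio pixels in the {tag} epoch"
                )
            vals[tag] = float(pv.mean() / sv.mean())
        records.append(
            DrugResponseRecord(
                label=info.label,
                before=vals["before"],
                after=vals["after"],
                change=vals["after"] / vals["before"],
                drug=drug,
                interval_min=interval_min,
            )
        )
    return records, patch_set


def cumulative_distribution(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support and probabilities, for before/after overlays."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size


def welch_t_test(sample_a, sample_b) -> TTestResult:
    """Two-tailed two-sample t-test with unequal variances (Welch)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
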