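"""Lung masking, cranio-caudal zone partitioning and regional summaries.

The upper/middle/lower zones are thirds of the total lung height measured
along the cranio-caudal axis, which is identified from the NIfTI affine
(never assumed from array order). Left and right lungs are pooled per zone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .data import ParameterMap
from .errors import GeometryError, ParameterError
from .fitting import estimate_noise_sd

__all__ = ["ZonedLungMask", "RegionSummary", "compute_lung_mask", "split_zones",
           "summarize_map", "summaries_to_frame"]

ZONES = ("upper", "middle", "lower")
ZONE_LABELS = {"upper": 1, "middle": 2, "lower": 3}


def compute_lung_mask(b0_volume: np.ndarray, k: float = 5.0, closing_iterations: int = 1,
                      min_component: int = 25) -> np.ndarray:
    """Estimate a lung mask from the b=0 volume.

    Threshold at ``k`` × the corner-estimated background noise SD, keep the
    two largest connected components (the lungs; with a warning if only one
    is found), then apply morphological closing. Deterministic. A noiseless
    volume (zero background) falls back to thresholding at zero.
    """
    vol = np.asarray(b0_volume, float)
    if vol.ndim != 4 and vol.ndim != 3:
        raise ParameterError("expected a 3-D b=0 volume")
    if vol.ndim == 4:
        vol = vol[..., 0]
    sigma = estimate_noise_sd(vol)
    thresh = k * sigma
    cand = vol > thresh
    labels, n = ndimage.label(cand)
    if n == 0:
        raise GeometryError("empty lung mask: no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    big = np.argsort(sizes)[::-1]
    big = [i + 1 for i in big if sizes[i] >= min_component]
    if len(big) == 0:
        raise GeometryError("empty lung mask: all components below the size threshold")
    if len(big) == 1:
        warnings.warn("only one connected component found; expected two lungs", stacklevel=2)
    keep = big[:2]
    mask = np.isin(labels, keep)
    if closing_iterations > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_closing(mask, structure=structure, iterations=closing_iterations)
    if not mask.any():
        raise GeometryError("empty lung mask after morphology")
    return mask


def craniocaudal_axis(affine: np.ndarray) -> tuple[int, int]:
    """(array axis, direction) of the superior–inferior anatomical axis.

    ``direction`` is +1 if increasing array index moves superior, −1
    otherwise.
    """
    ornt = nib.orientations.io_orientation(np.asarray(affine, float))
    for axis in range(3):
        if int(ornt[axis, 0]) == 2:  # S axis of RAS
            return axis, int(ornt[axis, 1])
    raise GeometryError("affine has no superior-inferior component")


@dataclass
class ZonedLungMask:
    """Binary lung mask partitioned into upper/middle/lower zone labels.

    ``labels`` is 0 outside the mask and 1/2/3 for upper/middle/lower.
    ``slice_ranges`` maps zone name → (start, stop) array-slice indices
    along the cranio-caudal axis.
    """

    mask: np.ndarray
    labels: np.ndarray
    axis: int
    direction: int
    slice_ranges: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        self.labels = np.asarray(self.labels)
        if self.mask.shape != self.labels.shape:
            raise GeometryError("mask/labels shape mismatch")
        if np.any((self.labels > 0) != self.mask):
            raise GeometryError("zone labels must cover exactly the lung mask")

    def zone_mask(self, zone: str) -> np.ndarray:
        if zone == "global":
            return self.mask.copy()
        return self.labels == ZONE_LABELS[zone]


def split_zones(mask: np.ndarray, affine: np.ndarray, by: str = "slices") -> ZonedLungMask:
    """Partition a lung mask into cranio-caudal thirds of the lung height.

    Lung height is the span of mask-containing slices along the
    cranio-caudal axis. With ``by="slices"`` the span is cut into three
    contiguous slice blocks of equal slice count; remainder slices are
    assigned superior-first (31 slices → 11/10/10 with the extra slice in
    the upper zone). ``by="mm"`` cuts the physical height into thirds
    instead and assigns each slice by its centre coordinate.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise GeometryError("empty mask")
    axis, direction = craniocaudal_axis(affine)
    proj = mask.any(axis=tuple(i for i in range(3) if i != axis))
    occupied = np.nonzero(proj)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    height = hi - lo + 1
    if height < 3:
        raise GeometryError(f"mask spans only {height} slices; need >= 3 for three zones")

    # slice indices ordered superior -> inferior
    order = np.arange(lo, hi + 1)
    if direction > 0:
        order = order[::-1]
    if by == "slices":
        n, r = divmod(height, 3)
        counts = [n + (1 if r >= 1 else 0), n + (1 if r == 2 else 0), n]
    elif by == "mm":
        thickness = np.sqrt((np.asarray(affine, float)[:3, axis] ** 2).sum())
        centres = (np.arange(height) + 0.5) * thickness
        total = height * thickness
        zone_of = np.minimum((centres / (total / 3.0)).astype(int), 2)
        counts = [int((zone_of == z).sum()) for z in range(3)]
    else:
        raise ParameterError(f"unknown zone scheme {by!r}")

    labels = np.zeros(mask.shape, dtype=np.int8)
    ranges = {}
    start = 0
    for zone, cnt in zip(ZONES, counts):
        sl = order[start:start + cnt]
        ranges[zone] = (int(sl.min()), int(sl.max()) + 1)
        sel = [slice(None)] * 3
        for s in sl:
            sel[axis] = s
            view = labels[tuple(sel)]
            view[mask[tuple(sel)]] = ZONE_LABELS[zone]
        start += cnt
    return ZonedLungMask(mask=mask, labels=labels, axis=axis, direction=direction,
                         slice_ranges=ranges, affine=np.asarray(affine, float))


@dataclass
class RegionSummary:
    """Summary statistics of one parameter map over one region."""

    region: str
    metric: str
    mean: float
    median: float
    sd: float
    n_voxels: int
    hist_edges: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    flagged: bool = False


def summarize_map(pmap: ParameterMap, zones: ZonedLungMask, airway_mask=None,
                  n_bins: int = 32) -> list[RegionSummary]:
    """Global and per-zone summaries of a parameter map over valid voxels.

    Both mean and median are always reported (regional medians and global
    means are the common reporting conventions, and mixing them silently is
    a classic source of irreproducibility). An optional airway mask is
    subtracted before summarising. Empty regions yield NaN statistics with
    ``flagged=True`` rather than raising.
    """
    if pmap.data.shape != zones.mask.shape:
        raise ParameterError("map and zones are not co-registered (shape mismatch)")
    exclude = np.zeros(zones.mask.shape, bool)
    if airway_mask is not None:
        exclude = np.asarray(airway_mask).astype(bool)
        if exclude.shape != zones.mask.shape:
            raise ParameterError("airway mask shape mismatch")
    out = []
    for region in ("global",) + ZONES:
        sel = zones.zone_mask(region) & ~exclude & pmap.valid
        vals = pmap.data[sel]
        if vals.size == 0:
            out.append(RegionSummary(region, pmap.name, np.nan, np.nan, np.nan, 0, flagged=True))
            continue
        span = np.ptp(vals)
        bins = n_bins if span > 1e-9 * max(abs(vals).max(), 1e-30) else 1
        counts, edges = np.histogram(vals, bins=bins)
        out.append(RegionSummary(
            region=region, metric=pmap.name,
            mean=float(vals.mean()), median=float(np.median(vals)),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            n_voxels=int(vals.size), hist_edges=edges, hist_counts=counts,
        ))
    return out


def summaries_to_frame(summaries: list[RegionSummary], subject: str | None = None,
                       visit: str | None = None) -> pd.DataFrame:
    """Flatten RegionSummary objects to the tabular schema used downstream."""
    rows = []
    for s in summaries:
        row = {"metric": s.metric, "region": s.region, "mean": s.mean,
               "median": s.median, "sd": s.sd, "n_voxels": s.n_voxels}
        if subject is not None:
            row = {"subject": subject, "visit": visit, **row}
        rows.append(row)
    return pd.DataFrame(rows)
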