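"""Nuclear segmentation and margin-distance measurement for confocal stacks.

The pipeline mirrors a standard immunofluorescence quantification
workflow for flat-mounted zebrafish embryos: nuclei are segmented from
the DAPI channel of a 3D stack, per-nucleus mean intensities are
compiled for every channel, and each nucleus is assigned a distance from
the manually traced embryonic margin via a Euclidean distance transform
of the trace.

Stages
------
1. ``subtract_out_of_plane`` - per-slice background correction: the
   out-of-focus contribution to slice *i* is approximated by Gaussian
   blurring the mean of its two neighbouring slices and subtracted.
2. ``segment_slice`` - local-mean adaptive threshold, morphological
   opening with a disc, area filter; returns labeled 2D objects.
3. ``link_2d_to_3d`` - 2D objects on neighbouring slices are merged into
   3D nuclei by stamping a disc at each 2D centroid into a sparse volume
   and labeling with 6-connectivity; this merges objects whose centroids
   are < (2 x disc radius) pixels apart.  Nuclei spanning fewer than
   ``min_z_span`` slices are discarded.
4. ``measure_nuclei`` - mean pixel intensity of each channel over the
   union of a nucleus's member 2D masks.
5. ``compute_margin_distance`` - distance transform of the rasterized
   margin polyline on the 2D projection, sampled at nucleus centroids
   and scaled to micrometres.

``segment_stack`` chains stages 1-5 and returns a tidy table in the
per-nucleus schema (GFP, pSmad2Raw, "pSmad2 Normalized", DAPI,
marginDist, GFP_Flag, "Embryo Number").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk, line as draw_line
from skimage.filters import threshold_local
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk, opening

__all__ = [
    "ImageStack",
    "SegmentationParams",
    "MarginTrace",
    "Nucleus3D",
    "RECORD_COLUMNS",
    "subtract_out_of_plane",
    "segment_slice",
    "link_2d_to_3d",
    "measure_nuclei",
    "compute_margin_distance",
    "segment_stack",
]

# Source-data column order used by all per-nucleus tables.
RECORD_COLUMNS = ["GFP", "pSmad2Raw", "pSmad2 Normalized", "DAPI",
                  "marginDist", "GFP_Flag", "Embryo Number"]


@dataclass
class ImageStack:
    """Multi-channel confocal stack: channels are (z, y, x) arrays.

    ``z_bounds`` is the inclusive slice range accepted for segmentation
    (manually chosen in practice to exclude internal yolk-syncytial-layer
    nuclei); ``None`` uses the whole stack.
    """

    dapi: np.ndarray
    gfp: np.ndarray
    psmad2: np.ndarray
    pixel_size_xy: float = 1.0
    z_step: float = 2.0
    z_bounds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.dapi.shape == self.gfp.shape == self.psmad2.shape):
            raise ValueError("all channels must share one (z, y, x) shape")
        if self.dapi.ndim != 3:
            raise ValueError("channels must be 3D (z, y, x)")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.z_bounds is not None:
            lo, hi = self.z_bounds
            if not (0 <= lo <= hi < self.dapi.shape[0]):
                raise ValueError("z_bounds outside stack")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dapi.shape

    def z_range(self) -> tuple[int, int]:
        if self.z_bounds is None:
            return 0, self.dapi.shape[0] - 1
        return self.z_bounds


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation pipeline (pixel units).

    ``bg_sigma``: Gaussian blur width for the out-of-plane background
    estimate; ``adaptive_window``/``adaptive_offset``: local-mean
    threshold window (odd) and subtracted offset; ``min_area``: minimum
    2D object area; ``opening_radius``: disc radius for the opening;
    ``match_disc_diameter``: disc stamped at centroids when linking
    slices (objects merge when centroids are closer than twice this);
    ``min_z_span``: minimum number of slices a 3D nucleus must span.
    """

    bg_sigma: float = 10.0
    adaptive_window: int = 51
    adaptive_offset: float = 2.0
    min_area: int = 50
    opening_radius: int = 2
    match_disc_diameter: int = 5
    min_z_span: int = 2

    def __post_init__(self) -> None:
        if min(self.bg_sigma, self.adaptive_window, self.min_area,
               self.opening_radius, self.match_disc_diameter) <= 0:
            raise ValueError("segmentation parameters must be positive")
        if self.min_z_span < 2:
            raise ValueError("min_z_span must be >= 2")
        if self.adaptive_window % 2 == 0:
            raise ValueError("adaptive_window must be odd")


@dataclass
class MarginTrace:
    """Manually traced embryo-YSL boundary on the 2D projection.

    ``vertices`` are (y, x) pixel coordinates of the polyline drawn on the
    DAPI maximum-intensity projection.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("margin trace needs >= 2 (y, x) vertices")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary contour mask of the polyline on an image of ``shape``."""
        mask = np.zeros(shape, dtype=bool)
        v = np.rint(self.vertices).astype(int)
        if (v[:, 0].min() < 0 or v[:, 1].min() < 0
                or v[:, 0].max() >= shape[0] or v[:, 1].max() >= shape[1]):
            raise ValueError("margin trace extends outside the image")
        for (y0, x0), (y1, x1) in zip(v[:-1], v[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            mask[rr, cc] = True
        return mask

    @classmethod
    def from_csv(cls, path) -> "MarginTrace":
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(pts)


@dataclass
class Nucleus3D:
    """One linked 3D nucleus: member 2D masks keyed by slice index."""

    label: int
    member_masks: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def z_span(self) -> int:
        return len(self.member_masks)

    @property
    def centroid(self) -> tuple[float, float, float]:
        """(z, y, x) intensity-free centroid over the member masks."""
        zs, ys, xs, w = [], [], [], []
        for z, m in self.member_masks.items():
            yy, xx = np.nonzero(m)
            zs.append(z * len(yy))
            ys.append(yy.sum())
            xs.append(xx.sum())
            w.append(len(yy))
        n = sum(w)
        return (sum(zs) / n, sum(ys) / n, sum(xs) / n)


def subtract_out_of_plane(stack: ImageStack, params: SegmentationParams) -> np.ndarray:
    """Background-correct the DAPI channel within the accepted z-bounds.

    The out-of-plane contribution to each slice is approximated by the
    Gaussian-blurred mean of its two adjacent slices (one neighbour at
    the stack edges) and subtracted, clamping at zero.  Returns an array
    over the full stack depth with uncorrected slices outside z_bounds
    left at zero.
    """
    lo, hi = stack.z_range()
    if hi - lo + 1 < 2:
        raise ValueError("need at least 2 z-slices within z_bounds")
    dapi = stack.dapi.astype(float)
    out = np.zeros_like(dapi)
    for i in range(lo, hi + 1):
        neighbours = [j for j in (i - 1, i + 1) if lo <= j <= hi]
        bg = np.mean([dapi[j] for j in neighbours], axis=0)
        bg = ndimage.gaussian_filter(bg, params.bg_sigma)
        out[i] = np.clip(dapi[i] - bg, 0.0, None)
    return out


def segment_slice(corrected: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment one background-corrected slice into labeled 2D objects.

    Local-mean adaptive threshold (window ``adaptive_window``, offset
    ``adaptive_offset``), binary opening with a disc of radius
    ``opening_radius``, then connected components with area >=
    ``min_area``.  Returns an int label image (0 = background); an empty
    label set is a valid result.
    """
    if (corrected < 0).any():
        raise ValueError("corrected slice must be non-negative")
    thresh = threshold_local(corrected, block_size=params.adaptive_window,
                             method="mean", offset=-params.adaptive_offset)
    mask = corrected > thresh
    mask = opening(mask, disk(params.opening_radius))
    labels = sk_label(mask, connectivity=2)
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    keep = np.nonzero(areas >= params.min_area)[0]
    keep = keep[keep != 0]
    relabel = np.zeros(areas.size, dtype=labels.dtype)
    relabel[keep] = np.arange(1, keep.size + 1)
    return relabel[labels]


def link_2d_to_3d(slice_labels: dict[int, np.ndarray], params: SegmentationParams) -> list[Nucleus3D]:
    """Merge per-slice 2D objects into 3D nuclei by centroid matching.

    A disc of radius ``match_disc_diameter`` pixels is stamped at every
    2D centroid into a sparse (z, y, x) volume, which is then labeled
    with a 6-connected neighbourhood; objects on neighbouring slices end
    up in the same 3D component exactly when their centroids are
    separated by less than twice that radius (< 10 px at the default).
    Components spanning fewer than ``min_z_span`` slices are discarded.
    """
    if not slice_labels:
        return []
    zmin, zmax = min(slice_labels), max(slice_labels)
    shape2d = next(iter(slice_labels.values())).shape
    vol = np.zeros((zmax - zmin + 1, *shape2d), dtype=bool)

    # radius 5 px at the default: discs overlap iff centroids < 10 px apart
    radius = params.match_disc_diameter
    object_info: list[tuple[int, int, tuple[float, float]]] = []  # (z, 2d label, centroid)
    for z, lab in sorted(slice_labels.items()):
        for rp in regionprops(lab):
            cy, cx = rp.centroid
            rr, cc = draw_disk((cy, cx), radius, shape=shape2d)
            vol[z - zmin, rr, cc] = True
            object_info.append((z, rp.label, (cy, cx)))

    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    comp, n = ndimage.label(vol, structure=struct)

    nuclei: dict[int, Nucleus3D] = {}
    for z, lab2d, (cy, cx) in object_info:
        c = int(comp[z - zmin, int(round(cy)), int(round(cx))])
        if c == 0:  # rounding fell off the stamped disc; nearest stamped pixel
            zz = comp[z - zmin]
            yy, xx = np.nonzero(zz)
            idx = np.argmin((yy - cy) ** 2 + (xx - cx) ** 2)
            c = int(zz[yy[idx], xx[idx]])
        nuc = nuclei.setdefault(c, Nucleus3D(label=c))
        member = slice_labels[z] == lab2d
        if z in nuc.member_masks:
            nuc.member_masks[z] |= member
        else:
            nuc.member_masks[z] = member
    return [n for n in nuclei.values() if n.z_span >= params.min_z_span]


def measure_nuclei(stack: ImageStack, nuclei: list[Nucleus3D]) -> pd.DataFrame:
    """Mean channel intensities over each nucleus's member-mask union.

    Returns one row per nucleus with columns DAPI, GFP, pSmad2Raw and the
    (z, y, x) centroid in pixel units.
    """
    rows = []
    for nuc in nuclei:
        if nuc.z_span == 0 or all(not m.any() for m in nuc.member_masks.values()):
            raise ValueError(f"nucleus {nuc.label} has an empty mask")
        sums = {"DAPI": 0.0, "GFP": 0.0, "pSmad2Raw": 0.0}
        npix = 0
        for z, m in nuc.member_masks.items():
            npix += int(m.sum())
            sums["DAPI"] += float(stack.dapi[z][m].sum())
            sums["GFP"] += float(stack.gfp[z][m].sum())
            sums["pSmad2Raw"] += float(stack.psmad2[z][m].sum())
        cz, cy, cx = nuc.centroid
        rows.append({k: v / npix for k, v in sums.items()}
                    | {"centroid_z": cz, "centroid_y": cy, "centroid_x": cx,
                       "n_pixels": npix, "z_span": nuc.z_span})
    return pd.DataFrame(rows)


def compute_margin_distance(
    trace: MarginTrace,
    shape: tuple[int, int],
    points: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Euclidean distance (um) from the margin trace.

    The trace is rasterized onto the 2D projection and a distance
    transform applied, so every pixel carries its distance to the nearest
    contour pixel.  With ``points`` (an (n, 2) array of (y, x) pixel
    coordinates, e.g. nucleus centroids) the map is sampled at those
    positions; otherwise the dense map is returned (for pixel-binned
    kymographs).
    """
    contour = trace.rasterize(shape)
    if not contour.any():
        raise ValueError("margin contour mask is empty")
    dist = ndimage.distance_transform_edt(~contour) * pixel_size
    if points is None:
        return dist
    pts = np.asarray(points, dtype=float)
    iy = np.rint(pts[:, 0]).astype(int)
    ix = np.rint(pts[:, 1]).astype(int)
    if (iy < 0).any() or (ix < 0).any() or (iy >= shape[0]).any() or (ix >= shape[1]).any():
        raise ValueError("a centroid lies outside the image")
    return dist[iy, ix]


def segment_stack(
    stack: ImageStack,
    trace: MarginTrace,
    params: SegmentationParams | None = None,
    embryo_number: int = 1,
) -> pd.DataFrame:
    """Full per-embryo pipeline: segment, measure, locate.

    Returns a table in the source-data schema.  ``pSmad2 Normalized`` is
    left as NaN (filled by the gradient-quantification stage, which needs
    the whole-embryo baseline) and ``GFP_Flag`` as -1 (set by the GFP
    classifier).
    """
    params = params or SegmentationParams()
    corrected = subtract_out_of_plane(stack, params)
    lo, hi = stack.z_range()
    slice_labels = {z: segment_slice(corrected[z], params) for z in range(lo, hi + 1)}
    nuclei = link_2d_to_3d(slice_labels, params)
    table = measure_nuclei(stack, nuclei)
    if table.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS + ["centroid_z", "centroid_y", "centroid_x"])
    centroids = table[["centroid_y", "centroid_x"]].to_numpy()
    table["marginDist"] = compute_margin_distance(
        trace, stack.shape[1:], points=centroids, pixel_size=stack.pixel_size_xy)
    table["pSmad2 Normalized"] = np.nan
    table["GFP_Flag"] = -1
    table["Embryo Number"] = embryo_number
    return table[RECORD_COLUMNS + ["centroid_z", "centroid_y", "centroid_x", "n_pixels", "z_span"]]
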