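"""Cell morphometry and cluster quantification from grayscale images.

Measurements follow the conventions of common image-analysis practice:
objects are segmented by a global automatic threshold (Otsu), connected
components (8-connectivity) above a minimum area are measured, the best-fit
ellipse is derived from second-order central moments, and

    circularity = 4 * pi * area / perimeter**2   (capped at 1)
    roundness   = minor axis / major axis.

Cluster sizes (major axis, µm) are binned into occurrence percentages, and
cluster density is the percentage of the cluster region occupied by cell
(foreground) pixels after thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BIN_PRESETS",
    "binarize",
    "measure_shapes",
    "bin_cluster_sizes",
    "cluster_density",
    "identify_clusters",
]

# size bins in µm; left-closed, right-open. The 'paper' preset reproduces a
# published bin list that leaves a 50-100 µm gap (sizes falling there are
# reported in an explicit 'unbinned' bucket); 'default' closes the gap.
_PAPER_BINS = [(0, 10), (10, 30), (30, 50), (100, 150), (150, 200), (200, 250), (250, np.inf)]
_DEFAULT_BINS = [(0, 10), (10, 30), (30, 50), (50, 100), (100, 150), (150, 200), (200, 250), (250, np.inf)]
BIN_PRESETS = {"paper": _PAPER_BINS, "default": _DEFAULT_BINS}


def _bin_label(lo: float, hi: float) -> str:
    if lo <= 0:
        return f"<{hi:g} um"
    if np.isinf(hi):
        return f">{lo:g} um"
    return f"{lo:g}-{hi:g} um"


def binarize(image: np.ndarray, method: str = "otsu", dark_foreground: bool = True):
    """Segment foreground from background with a global automatic threshold.

    ``dark_foreground=True`` treats pixels *below* the threshold as object
    (cells rendered black on a white background); set it False for bright
    objects. Returns ``(mask, threshold)``. A constant image has no
    threshold and raises.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("binarize expects a single-channel image")
    if img.min() == img.max():
        raise ValueError("constant image: no threshold exists")
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(img))
    elif method == "mean":
        thr = float(img.mean())
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    # Otsu places the threshold on the upper edge of the background class for
    # a two-valued image, so the dark-object comparison must be inclusive.
    mask = img <= thr if dark_foreground else img > thr
    # guard against unimodal images (background only): an automatic threshold
    # always splits the histogram, but the two classes it produces are then
    # separated by less than the within-class spread scale
    if mask.any() and not mask.all():
        a, b = img[mask].astype(float), img[~mask].astype(float)
        within_sd = np.sqrt((a.size * a.var() + b.size * b.var()) / img.size)
        if abs(a.mean() - b.mean()) < 4.0 * max(within_sd, 1e-12):
            mask = np.zeros_like(mask)
    return mask, thr


@dataclass
class ShapeMetrics:
    """Morphological descriptors of one connected component (µm units)."""

    object_id: int
    area: float  # µm²
    perimeter: float  # µm
    major_axis: float  # µm
    minor_axis: float  # µm
    circularity: float  # [0, 1]
    roundness: float  # (0, 1]
    centroid_um: tuple[float, float]


def _subpixel_perimeter(region_mask: np.ndarray, sigma: float = 1.5) -> float:
    """Boundary length from a sub-pixel contour of the smoothed mask.

    Marching-squares contours of the lightly smoothed indicator function
    remove the staircase bias that makes pixel boundary walks overestimate
    smooth outlines by ~5%, while keeping straight polygon sides accurate to
    well under 1%.
    """
    from scipy.ndimage import gaussian_filter
    from skimage import measure

    f = gaussian_filter(np.pad(region_mask, 3).astype(float), sigma, mode="constant")
    per = 0.0
    for contour in measure.find_contours(f, 0.5):
        per += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return per


def measure_shapes(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    min_area_px: int = 10,
    perimeter_method: str = "subpixel",
) -> "pd.DataFrame":
    """Per-object morphometry of a binary mask.

    Components are labelled with 8-connectivity and those below
    ``min_area_px`` are ignored. Area is pixel count times pixel_size**2;
    perimeter defaults to the sub-pixel contour length of the smoothed
    component (accurate to <1% for both smooth and polygonal outlines;
    ``perimeter_method='weighted'`` gives the classic boundary walk with
    sqrt(2) diagonals, ``'crofton'`` the Crofton estimate); ellipse axes come
    from the second-order central moments of the filled component.
    Circularity is capped at 1, since discretisation can push the raw ratio
    slightly above the isoperimetric bound.
    """
    import pandas as pd
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    rows = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        if perimeter_method == "subpixel":
            per_px = _subpixel_perimeter(rp.image)
            if per_px == 0.0:  # speck too small for the smoothed contour
                per_px = rp.perimeter
        elif perimeter_method == "weighted":
            per_px = rp.perimeter
        elif perimeter_method == "crofton":
            per_px = rp.perimeter_crofton
        else:
            raise ValueError(f"unknown perimeter method {perimeter_method!r}")
        area = rp.area * pixel_size**2
        perimeter = per_px * pixel_size
        major = rp.axis_major_length * pixel_size
        minor = rp.axis_minor_length * pixel_size
        circ = min(1.0, 4.0 * np.pi * area / perimeter**2) if perimeter > 0 else np.nan
        roundness = minor / major if major > 0 else np.nan
        rows.append(
            {
                "object_id": rp.label,
                "area_um2": area,
                "perimeter_um": perimeter,
                "major_um": major,
                "minor_um": minor,
                "circularity": circ,
                "roundness": roundness,
                "centroid_row_um": rp.centroid[0] * pixel_size,
                "centroid_col_um": rp.centroid[1] * pixel_size,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "object_id", "area_um2", "perimeter_um", "major_um", "minor_um",
            "circularity", "roundness", "centroid_row_um", "centroid_col_um",
        ],
    )


def bin_cluster_sizes(sizes, preset: str = "default", bin_edges=None) -> "pd.DataFrame":
    """Occurrence percentages of cluster sizes over left-closed size bins.

    ``bin_edges`` (list of (lo, hi) tuples, µm) overrides the preset. Sizes
    falling in no bin are counted in an explicit ``unbinned`` bucket rather
    than silently dropped; percentages always sum to 100 over non-empty
    input.
    """
    import pandas as pd

    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("sizes must be non-empty")
    bins = list(bin_edges) if bin_edges is not None else BIN_PRESETS[preset]
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    counts = np.zeros(len(bins), dtype=int)
    unbinned = 0
    for s in sizes:
        for i, (lo, hi) in enumerate(bins):
            if lo <= s < hi:
                counts[i] += 1
                break
        else:
            unbinned += 1
    rows = [{"bin": lab, "count": int(c), "percent": 100.0 * c / sizes.size}
            for lab, c in zip(labels, counts)]
    if unbinned:
        rows.append({"bin": "unbinned", "count": unbinned, "percent": 100.0 * unbinned / sizes.size})
    return pd.DataFrame(rows)


def _roi_mask(shape, roi) -> np.ndarray:
    """ROI as boolean mask, from a mask, a (row, col) polygon, or None (all)."""
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool and roi_arr.shape == tuple(shape):
        return roi_arr
    if roi_arr.ndim == 2 and roi_arr.shape[1] == 2:  # polygon vertices
        from skimage.draw import polygon

        rr, cc = polygon(roi_arr[:, 0], roi_arr[:, 1], shape=shape)
        if rr.size == 0:
            raise ValueError("ROI polygon lies outside the image")
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m
    raise ValueError("roi must be a boolean mask or an (n, 2) polygon in pixel coords")


def cluster_density(image: np.ndarray, roi=None, method: str = "otsu",
                    dark_foreground: bool = True):
    """Percentage of an ROI occupied by cell (foreground) pixels.

    The image is binarized with the automatic threshold and the density is
    100 * foreground / ROI area. Returns ``(density_pct, threshold)`` so the
    applied threshold can be audited. ``roi`` may be a boolean mask, a
    polygon of (row, col) vertices, or None for the whole image; a binary
    ``image`` is used as-is.
    """
    img = np.asarray(image)
    m = _roi_mask(img.shape, roi)
    if m.sum() == 0:
        raise ValueError("ROI has zero area")
    if img.dtype == bool:
        fg, thr = img, None
    else:
        fg, thr = binarize(img, method=method, dark_foreground=dark_foreground)
    dens = 100.0 * float(fg[m].sum()) / float(m.sum())
    return dens, thr


def identify_clusters(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    min_cluster_area_um2: float | None = None,
    min_area_px: int = 10,
) -> "pd.DataFrame":
    """Connected foreground components large enough to be multicellular.

    A cluster is a component whose area exceeds ``min_cluster_area_um2``
    (default: twice the median component area, the heuristic for 'larger
    than a single cell'). Returns per-cluster size (major axis, µm) and area.
    """
    shapes = measure_shapes(mask, pixel_size=pixel_size, min_area_px=min_area_px)
    if shapes.empty:
        return shapes.assign(size_um=[])
    if min_cluster_area_um2 is None:
        min_cluster_area_um2 = 2.0 * float(shapes["area_um2"].median())
    clusters = shapes[shapes["area_um2"] >= min_cluster_area_um2].copy()
    clusters["size_um"] = clusters["major_um"]
    return clusters.reset_index(drop=True)
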