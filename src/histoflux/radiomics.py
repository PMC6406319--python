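"""Nuclear morphology: Laplacian edge extraction, circularity, fractal dimension.

Nuclei are delineated on the DAPI channel by a Laplacian-of-Gaussian edge
finder: the LoG response is negative just inside a bright blob's boundary
(its zero crossing is the edge), so filling the interiors of the negative
response yields the nucleus regions.  Each object carries its smoothed
boundary contour, from which two shape descriptors are computed:

* circularity 4*pi*A / P^2 — 1 for a disk, falling as the boundary
  lengthens relative to area (fragmentation, jagged outlines);
* box-counting fractal dimension of the boundary point set — 1 for smooth
  curves, rising with boundary irregularity.

Apoptotic nuclei fragment into several lobes; components within a merge
radius can be grouped and measured jointly as one nucleus, so that
fragmentation lowers circularity and raises the fractal dimension of the
grouped object.  Analyses can be restricted to nuclei near vessels
(centroid within ~80 um) to mirror the perivascular sampling used when
relating morphology to antibody exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage import measure

from .section import SectionImage

__all__ = ["NucleusObject", "extract_nuclei", "circularity_from_mask",
           "fractal_dimension", "box_counts", "proximal_filter",
           "mask_contours", "contour_perimeter"]

CIRCULARITY_CAP = 1.05  # discretization can push 4*pi*A/P^2 slightly past 1


@dataclass
class NucleusObject:
    """One segmented nucleus (possibly several grouped fragments)."""

    label: int
    contour: np.ndarray            # (n, 2) boundary points, row/col
    area_px: float
    perimeter_px: float
    circularity: float
    fractal_dimension: float
    fd_r2: float
    centroid_rc: tuple[float, float]
    n_components: int = 1
    distance_to_vessel_um: float | None = None
    component_labels: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# contours and circularity
# ---------------------------------------------------------------------------

def mask_contours(mask: np.ndarray, smooth_sigma: float = 1.0) -> list[np.ndarray]:
    """Closed sub-pixel boundary contours of a binary mask.

    Marching-squares contours at the 0.5 level are smoothed along arc
    length with a periodic Gaussian (sigma in contour samples, ~1 px).
    This removes the staircase excess that biases raw digital perimeters
    (up to ~8% on disks) while barely rounding true corners.
    """
    cs = measure.find_contours(np.asarray(mask, float), 0.5)
    out = []
    for c in cs:
        if np.allclose(c[0], c[-1]):
            c = c[:-1]
        if len(c) < 4:
            out.append(c)
            continue
        sm = np.column_stack([
            gaussian_filter1d(c[:, i], smooth_sigma, mode="wrap") for i in (0, 1)
        ])
        out.append(sm)
    return out


def contour_perimeter(contours: list[np.ndarray]) -> float:
    total = 0.0
    for c in contours:
        if len(c) < 2:
            continue
        closed = np.vstack([c, c[:1]])
        total += float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))
    return total


def circularity_from_mask(mask: np.ndarray) -> float:
    """4*pi*A/P^2 of a binary mask with sub-pixel perimeter estimation."""
    mask = np.asarray(mask, bool)
    area = float(mask.sum())
    if area < 2:
        raise ValueError("degenerate (single-pixel) object")
    perim = contour_perimeter(mask_contours(np.pad(mask, 2)))
    if perim == 0:
        raise ValueError("object has no measurable boundary")
    return min(4.0 * np.pi * area / perim**2, CIRCULARITY_CAP)


# ---------------------------------------------------------------------------
# box-counting fractal dimension
# ---------------------------------------------------------------------------

def box_counts(points: np.ndarray, sizes: np.ndarray, n_offsets: int = 4,
               seed: int = 0) -> np.ndarray:
    """Minimal box-cover counts of a 2-D point set at the given box sizes.

    For each size the grid is placed at ``n_offsets`` offsets (the origin
    plus random shifts) and the smallest count is kept, approximating the
    minimal cover that defines the box-counting dimension; averaging over
    offsets instead inflates counts at coarse scales and biases the
    dimension low.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    lo = pts.min(axis=0)
    rng = np.random.default_rng(seed)
    out = np.empty(len(sizes))
    for k, eps in enumerate(sizes):
        best = None
        offsets = [np.zeros(2)] + [rng.uniform(0, eps, 2) for _ in range(n_offsets - 1)]
        for off in offsets:
            idx = np.floor((pts - lo + off) / eps).astype(np.int64)
            count = len(np.unique(idx, axis=0))
            best = count if best is None else min(best, count)
        out[k] = best
    return out


def fractal_dimension(points_or_object: np.ndarray | NucleusObject,
                      box_sizes: np.ndarray | None = None,
                      n_offsets: int = 4, seed: int = 0,
                      min_points: int = 16) -> tuple[float, float]:
    """Box-counting dimension of a boundary point set.

    Counts N(eps) over a dyadic ladder of box sizes (default 2 px up to a
    quarter of the bounding-box diagonal) and returns (-slope, R^2) of the
    least-squares fit of log N vs log eps.  Saturated scales — boxes so
    small that counts approach the number of points, or so large that
    fewer than 8 boxes are hit — are excluded from the fit when at least
    three scales remain, since they flatten the scaling law on both ends.
    """
    pts = points_or_object.contour if isinstance(points_or_object, NucleusObject) \
        else np.asarray(points_or_object, dtype=float)
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} boundary points, got {len(pts)}")
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag <= 0:
        raise ValueError("degenerate point set with zero extent")
    if box_sizes is None:
        sizes = []
        s = 2.0
        while s <= diag * 0.25:
            sizes.append(s)
            s *= 2.0
        if len(sizes) < 2:
            sizes = [max(diag / 8, 1.0), max(diag / 4, 2.0)]
        box_sizes = np.asarray(sizes)
    else:
        box_sizes = np.asarray(box_sizes, dtype=float)
    if len(box_sizes) < 2:
        raise ValueError("need at least two box sizes")

    counts = box_counts(pts, box_sizes, n_offsets=n_offsets, seed=seed)
    keep = (counts <= 0.25 * len(pts)) & (counts >= 8)
    if keep.sum() < 3:
        keep = np.ones(len(box_sizes), dtype=bool)
    logs = np.log(box_sizes[keep])
    logn = np.log(counts[keep])
    A = np.column_stack([logs, np.ones(len(logs))])
    (slope, intercept), *_ = np.linalg.lstsq(A, logn, rcond=None)
    resid = logn - A @ [slope, intercept]
    ss_tot = float(np.sum((logn - logn.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return -float(slope), r2


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _log_interiors(img: np.ndarray, log_sigma: float) -> np.ndarray:
    """Filled interiors of the negative Laplacian-of-Gaussian response.

    Inside a bright blob the LoG is negative in a closed band along the
    boundary (the zero crossing is the edge); filling that band's holes
    recovers the blob interior.
    """
    response = ndimage.gaussian_laplace(img, sigma=log_sigma)
    scale = np.abs(response).max()
    if scale == 0:
        return np.zeros(img.shape, dtype=bool)
    negative = response < -1e-3 * scale
    return ndimage.binary_fill_holes(negative)


def extract_nuclei(section: SectionImage, log_sigma: float = 2.0,
                   min_size_px: int = 12,
                   merge_radius_px: float | None = None,
                   fd_seed: int = 0) -> list[NucleusObject]:
    """Segment nuclei from the DAPI channel and measure their shape.

    Laplacian-of-Gaussian zero-crossing interiors are labelled as objects;
    components smaller than ``min_size_px`` are discarded.  When
    ``merge_radius_px`` is set, components whose masks lie within that
    distance of each other (edge to edge) are grouped into one object —
    fragments of an apoptotic nucleus are then measured jointly, with
    summed area, summed perimeter and the union of boundary points.  A
    value somewhat above the inter-fragment gap and below the spacing
    between neighboring nuclei separates the two scales.

    Returns an empty list (not an error) when no objects survive.
    """
    img = section.nuclei_channel
    if img.max() == img.min():
        return []
    filled = _log_interiors(img, log_sigma)
    labels, n = ndimage.label(filled)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    keep_ids = [i + 1 for i in range(n) if sizes[i] >= min_size_px]
    if not keep_ids:
        return []

    comps = []
    slices = ndimage.find_objects(labels)
    for cid in keep_ids:
        sl = slices[cid - 1]
        # pad so marching squares closes contours at the crop border
        local = np.pad(labels[sl] == cid, 2)
        com = ndimage.center_of_mass(local)
        origin = np.array([sl[0].start - 2, sl[1].start - 2], dtype=float)
        contours = mask_contours(local)
        pts = np.vstack([c + origin for c in contours if len(c) >= 2])
        first = np.argwhere(local)[0]
        comps.append({
            "id": cid,
            "area": float(local.sum()),
            "perimeter": contour_perimeter(contours),
            "centroid": origin + np.asarray(com),
            "pixel": (int(first[0] + origin[0]), int(first[1] + origin[1])),
            "points": pts,
        })

    # group components whose masks lie within merge_radius of each other
    # (edge to edge): dilate every component by half the radius and read
    # connectivity off the dilated image.  Fragments of one nucleus sit a
    # thin gap apart and reconnect; distinct nuclei stay separate.
    groups: list[list[int]]
    if merge_radius_px is None:
        groups = [[i] for i in range(len(comps))]
    else:
        kept_mask = np.isin(labels, keep_ids)
        dilated = ndimage.distance_transform_edt(~kept_mask) <= merge_radius_px / 2.0
        glab, _ = ndimage.label(dilated)
        by_group: dict[int, list[int]] = {}
        for i, comp in enumerate(comps):
            r, c = comp["pixel"]
            by_group.setdefault(int(glab[r, c]), []).append(i)
        groups = list(by_group.values())

    objects: list[NucleusObject] = []
    for out_label, grp in enumerate(sorted(groups, key=lambda g: min(g)), start=1):
        members = [comps[i] for i in grp]
        area = sum(m["area"] for m in members)
        perim = sum(m["perimeter"] for m in members)
        pts = np.vstack([m["points"] for m in members])
        centroid = np.sum([m["centroid"] * m["area"] for m in members], axis=0) / area
        circ = min(4.0 * np.pi * area / perim**2, CIRCULARITY_CAP) if perim > 0 else np.nan
        try:
            fd, r2 = fractal_dimension(pts, seed=fd_seed)
        except ValueError:
            fd, r2 = np.nan, np.nan
        objects.append(NucleusObject(
            label=out_label, contour=pts, area_px=area, perimeter_px=perim,
            circularity=circ, fractal_dimension=fd, fd_r2=r2,
            centroid_rc=(float(centroid[0]), float(centroid[1])),
            n_components=len(members),
            component_labels=[m["id"] for m in members]))
    return objects


def proximal_filter(objects: list[NucleusObject], distance_um: np.ndarray,
                    pixel_size_um: float | None = None,
                    max_dist_um: float = 80.0) -> list[NucleusObject]:
    """Keep nuclei whose centroid lies within ``max_dist_um`` of a vessel.

    ``distance_um`` is a per-pixel distance map in um (see
    :func:`histoflux.penetration.distance_field`); each object's
    ``distance_to_vessel_um`` is filled from its centroid pixel.
    """
    kept = []
    h, w = distance_um.shape
    for obj in objects:
        r = int(round(obj.centroid_rc[0]))
        c = int(round(obj.centroid_rc[1]))
        r = min(max(r, 0), h - 1)
        c = min(max(c, 0), w - 1)
        obj.distance_to_vessel_um = float(distance_um[r, c])
        if obj.distance_to_vessel_um <= max_dist_um:
            kept.append(obj)
    return kept
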