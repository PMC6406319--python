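"""Multi-channel section images, TIFF I/O and the 12-region sampling layout.

A section is a co-registered triple of grayscale channels from one tumor
cryosection: a nuclear stain (DAPI), a perfused-vessel stain
(rhodamine-lectin) and the labelled antibody (FITC / Alexa-488), plus the
physical pixel size.  Regions of interest are sampled in three bands along
the tumor's principal axis — four at 25% of the apex-to-base extent, four
central, four at 75% — mirroring the acquisition protocol the package
quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SectionImage",
    "Region",
    "RegionSet",
    "load_section",
    "save_section",
    "sample_regions",
    "ensure_tumor_mask",
]

BAND_LABELS = ("apex25", "central", "apex75")
BAND_FRACTIONS = {"apex25": 0.25, "central": 0.50, "apex75": 0.75}


@dataclass
class SectionImage:
    """One registered multi-channel field with physical pixel size.

    Channels are float arrays of identical shape with finite, non-negative
    intensities in arbitrary units.  ``tumor_mask`` (optional) marks the
    tissue extent; analyses that need it can derive a default with
    :func:`ensure_tumor_mask`.
    """

    nuclei_channel: np.ndarray
    vessel_channel: np.ndarray
    antibody_channel: np.ndarray
    pixel_size_um: float
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nuclei_channel = np.asarray(self.nuclei_channel, dtype=float)
        self.vessel_channel = np.asarray(self.vessel_channel, dtype=float)
        self.antibody_channel = np.asarray(self.antibody_channel, dtype=float)
        shapes = {
            self.nuclei_channel.shape,
            self.vessel_channel.shape,
            self.antibody_channel.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        if self.nuclei_channel.ndim != 2:
            raise ValueError("channels must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for name in ("nuclei_channel", "vessel_channel", "antibody_channel"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"{name} contains negative intensities")
        if self.tumor_mask is not None:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if self.tumor_mask.shape != self.shape:
                raise ValueError("tumor_mask shape differs from channels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_channel.shape

    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass(frozen=True)
class Region:
    """Rectangular ROI with 0-based, row-major, half-open bounds."""

    label: str
    row0: int
    col0: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"label": r.label, "row0": r.row0, "col0": r.col0,
             "height": r.height, "width": r.width}
            for r in self.regions
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionSet":
        payload = json.loads(Path(path).read_text())
        return cls([Region(**item) for item in payload])


def _read_channel(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return np.asarray(arr, dtype=float)


def load_section(
    nuclei_path: str | Path,
    vessel_path: str | Path,
    antibody_path: str | Path,
    pixel_size_um: float,
    tumor_mask_path: str | Path | None = None,
) -> SectionImage:
    """Load three per-channel grayscale TIFFs into a validated section.

    Integer payloads are converted to float without rescaling, so a
    write/read round trip of 16-bit data preserves intensities exactly.
    """
    nuclei = _read_channel(nuclei_path)
    vessels = _read_channel(vessel_path)
    antibody = _read_channel(antibody_path)
    mask = None
    if tumor_mask_path is not None:
        mask = tifffile.imread(str(tumor_mask_path)) > 0
    return SectionImage(nuclei, vessels, antibody, pixel_size_um, tumor_mask=mask)


def save_section(section: SectionImage, out_dir: str | Path) -> dict[str, Path]:
    """Write per-channel 16-bit grayscale TIFFs plus a metadata sidecar.

    Intensities are rounded to the nearest integer and must fit the uint16
    range; integer-valued channels therefore round-trip bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in (
        ("nuclei", section.nuclei_channel),
        ("vessels", section.vessel_channel),
        ("antibody", section.antibody_channel),
    ):
        if arr.max() > np.iinfo(np.uint16).max:
            raise ValueError(f"{name} channel exceeds the 16-bit range")
        path = out / f"{name}.tif"
        tifffile.imwrite(str(path), np.round(arr).astype(np.uint16))
        paths[name] = path
    if section.tumor_mask is not None:
        path = out / "tumor_mask.tif"
        tifffile.imwrite(str(path), section.tumor_mask.astype(np.uint8))
        paths["tumor_mask"] = path
    meta = out / "section.json"
    meta.write_text(json.dumps({"pixel_size_um": section.pixel_size_um}, indent=2))
    paths["meta"] = meta
    return paths


def load_section_dir(in_dir: str | Path) -> SectionImage:
    """Load a section previously written by :func:`save_section`."""
    d = Path(in_dir)
    meta = json.loads((d / "section.json").read_text())
    mask = d / "tumor_mask.tif"
    return load_section(
        d / "nuclei.tif", d / "vessels.tif", d / "antibody.tif",
        pixel_size_um=meta["pixel_size_um"],
        tumor_mask_path=mask if mask.exists() else None,
    )


def ensure_tumor_mask(section: SectionImage) -> np.ndarray:
    """Return the section's tumor mask, deriving a default when absent.

    The default is the Otsu threshold of a heavily smoothed nuclear
    channel (the blur bridges the gaps between individual nuclei into a
    contiguous tissue signal) followed by hole filling of the largest
    connected component — appropriate for whole-section tumor tissue
    where nuclei fill the tissue extent.
    """
    if section.tumor_mask is not None:
        return section.tumor_mask
    nuc = section.nuclei_channel
    if nuc.max() == nuc.min():
        raise ValueError("cannot derive a tumor mask from a constant nuclear channel")
    smoothed = ndimage.gaussian_filter(nuc, sigma=12.0)
    rough = smoothed > threshold_otsu(smoothed)
    labels, n = ndimage.label(rough)
    if n == 0:
        raise ValueError("tumor mask derivation found no foreground")
    largest = np.argmax(ndimage.sum_labels(rough, labels, index=range(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    section.tumor_mask = mask
    return mask


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit principal axis of a point cloud, oriented apex-up.

    The apex end of the axis is the one reaching smaller row indices (image
    top); for a perfectly horizontal axis the apex is on the left.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def sample_regions(
    section: SectionImage,
    region_size_px: int,
    seed: int = 0,
    n_per_band: int = 4,
    band_halfwidth_px: int | None = None,
) -> RegionSet:
    """Place the 12-region sampling layout inside the tumor mask.

    Four square ROIs are drawn in each of three bands along the tumor's
    principal axis, at 25%, 50% and 75% of the apex-to-base extent.  ROIs
    lie entirely inside the mask, do not overlap, and the placement is
    deterministic for a given seed.  Raises if the mask is missing or too
    small for the requested region size.
    """
    if section.tumor_mask is None:
        raise ValueError("sample_regions requires a tumor mask "
                         "(set one or call ensure_tumor_mask first)")
    if region_size_px < 1:
        raise ValueError("region_size_px must be >= 1")
    mask = section.tumor_mask
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("tumor mask is empty")

    axis = _principal_axis(coords)
    t = (coords - coords.mean(axis=0)) @ axis
    tmin, tmax = t.min(), t.max()
    extent = tmax - tmin
    if band_halfwidth_px is None:
        band_halfwidth_px = max(region_size_px, int(round(0.05 * extent)))

    # True where a full region_size square fits inside the mask (top-left anchor
    # at pixel - region_size//2 is handled by center-based erosion).
    fits = ndimage.minimum_filter(mask.astype(np.uint8), size=region_size_px,
                                  mode="constant", cval=0) > 0

    rng = np.random.default_rng(seed)
    regions: list[Region] = []
    half = region_size_px // 2
    for label in BAND_LABELS:
        target = tmin + BAND_FRACTIONS[label] * extent
        in_band = np.abs(t - target) <= band_halfwidth_px
        cand = coords[in_band]
        cand = cand[fits[cand[:, 0], cand[:, 1]]]
        if len(cand) < n_per_band:
            raise ValueError(
                f"mask too small for region size {region_size_px} in band {label}")
        order = rng.permutation(len(cand))
        chosen: list[np.ndarray] = []
        for idx in order:
            c = cand[idx]
            r0, c0 = int(c[0] - half), int(c[1] - half)
            if r0 < 0 or c0 < 0 or r0 + region_size_px > mask.shape[0] \
                    or c0 + region_size_px > mask.shape[1]:
                continue
            if not mask[r0:r0 + region_size_px, c0:c0 + region_size_px].all():
                continue
            if all(np.max(np.abs(c - p)) >= region_size_px for p in chosen):
                chosen.append(c)
            if len(chosen) == n_per_band:
                break
        if len(chosen) < n_per_band:
            raise ValueError(
                f"could not place {n_per_band} non-overlapping regions in band {label}")
        for c in chosen:
            regions.append(Region(label, int(c[0] - half), int(c[1] - half),
                                  region_size_px, region_size_px))
    return RegionSet(regions)
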