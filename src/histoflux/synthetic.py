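"""Synthetic tumor-section generator with known ground truth.

Emulates the three-channel imaging setup the analysis pipeline consumes:
a vessel channel containing tubular perfused-vessel structures, an
antibody channel whose intensity decays exponentially with distance from
the nearest vessel (configurable amplitude and decay length), and a
nuclear channel of intact (smooth, convex) or fragmented (multi-lobed,
jagged) nuclei.  Every stochastic element is driven by one seed, so a
given spec reproduces bit-identical images, and the generator returns the
ground truth (vessel mask, distance field, per-nucleus class and mask)
needed to benchmark each analysis stage.

What it does not model: optics (no PSF or blur), 3-D structure,
photobleaching, vessel branching, autofluorescence gradients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .section import SectionImage, save_section

__all__ = ["SyntheticSpec", "GroundTruth", "NucleusTruth",
           "generate_section", "render_nucleus"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of one synthetic tumor section.

    Defaults emulate a 10x widefield field of view: 512 x 512 px at
    0.65 um/px (~333 um across), a handful of capillary-scale vessels
    (5 um radius), an antibody decay length of 20 um (the scale on which
    antibody penetration profiles in tumor tissue fall off), and nuclei of
    5 um radius.  ``frac_fragmented`` sets the proportion of apoptotic
    (fragmented) nuclei; ``fragmentation_severity`` scales both the lobe
    separation and the boundary roughness of fragmented nuclei, with 0
    reducing to the intact shape.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    n_vessels: int = 6
    vessel_radius_um: float = 5.0
    decay_length_um: float = 20.0
    surface_margin_um: float = 15.0
    n_nuclei: int = 150
    frac_fragmented: float = 0.0
    nucleus_radius_um: float = 5.0
    fragmentation_severity: float = 2.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    antibody_amplitude: float = 1000.0
    vessel_intensity: float = 3000.0
    nucleus_intensity: float = 2000.0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        for name in ("pixel_size_um", "vessel_radius_um", "decay_length_um",
                     "surface_margin_um", "nucleus_radius_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.frac_fragmented <= 1.0:
            raise ValueError(f"frac_fragmented must lie in [0, 1], got {self.frac_fragmented}")
        if self.fragmentation_severity < 0:
            raise ValueError("fragmentation_severity must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_vessels < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class NucleusTruth:
    label: int
    kind: str                       # "intact" | "fragmented"
    severity: float
    centroid_rc: tuple[float, float]
    bbox: tuple[int, int, int, int]  # row0, col0, height, width
    mask: np.ndarray                 # local boolean mask within bbox


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    vessel_mask: np.ndarray
    tumor_mask: np.ndarray
    distance_to_vessel_um: np.ndarray | None   # None when n_vessels == 0
    nuclei: list[NucleusTruth] = field(default_factory=list)

    @property
    def has_vessels(self) -> bool:
        return self.distance_to_vessel_um is not None

    def vessel_area_fraction(self) -> float:
        """Tube-area fraction inside the tumor mask (density oracle)."""
        inside = self.tumor_mask
        return float((self.vessel_mask & inside).sum() / inside.sum())

    def sidecar(self, path: str | Path) -> None:
        """Write a JSON ground-truth summary next to exported images."""
        payload = {
            "spec": asdict(self.spec),
            "vessel_area_fraction": self.vessel_area_fraction(),
            "nuclei": [
                {"label": n.label, "kind": n.kind, "severity": n.severity,
                 "centroid_rc": list(n.centroid_rc), "bbox": list(n.bbox)}
                for n in self.nuclei
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _smooth_periodic_noise(theta: np.ndarray, rng: np.random.Generator,
                           harmonics: range) -> np.ndarray:
    """Random sum of sinusoids, unit-scale, evaluated at angles theta."""
    out = np.zeros_like(theta)
    for h in harmonics:
        amp = rng.uniform(0.4, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.sin(h * theta + phase)
    norm = max(np.abs(out).max(), 1e-12)
    return out / norm


def render_nucleus(kind: str, severity: float, seed: int | np.random.Generator,
                   radius_px: float = 20.0) -> np.ndarray:
    """Render one nucleus as a binary mask on a local grid.

    ``intact`` gives a discrete disk (single convex smooth component).
    ``fragmented`` splits the disk Voronoi-style around interior seed
    points, opening gaps whose width grows with ``severity``, and roughens
    the outer boundary with high-frequency radial perturbation whose
    amplitude also grows with ``severity``.  At severity 0 the fragmented
    shape reduces exactly to the intact disk.
    """
    if kind not in ("intact", "fragmented"):
        raise ValueError(f"unknown nucleus class {kind!r}")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r = float(radius_px)
    pad = int(math.ceil(r * 1.4)) + 2
    n = 2 * pad + 1
    yy, xx = np.mgrid[:n, :n]
    dy, dx = yy - pad, xx - pad
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # Outer boundary: jagged radial perturbation, amplitude ~ severity.
    roughness = 0.0 if kind == "intact" else min(0.14 * severity, 0.45)
    if roughness > 0:
        perturb = _smooth_periodic_noise(theta, rng, range(10, 32))
        radius_map = r * (1.0 + roughness * perturb)
    else:
        # keep the rng call pattern identical so severity->0 stays comparable
        radius_map = np.full_like(theta, r)
    mask = rho <= radius_map

    if kind == "fragmented":
        # Voronoi-style splitting: erase a band around the boundaries
        # between cells of interior seed points; band width ~ severity.
        n_seeds = 3
        # rejection-sample seeds with a minimum separation so the gap band
        # between lobes cannot swallow the whole disk
        seeds_list: list[np.ndarray] = []
        for _ in range(200):
            cand = pad + rng.uniform(-0.55 * r, 0.55 * r, size=2)
            if all(np.hypot(*(cand - s)) >= 0.7 * r for s in seeds_list):
                seeds_list.append(cand)
            if len(seeds_list) == n_seeds:
                break
        while len(seeds_list) < n_seeds:  # deterministic fallback: triangle
            ang = 2 * np.pi * len(seeds_list) / n_seeds
            seeds_list.append(pad + 0.45 * r * np.array([math.sin(ang), math.cos(ang)]))
        seeds = np.asarray(seeds_list)
        # half-band in px; floored at 2 px so cracks are genuine separations
        # rather than hairlines, capped so lobes survive on small nuclei
        gap = min(max(0.9 * severity, 2.0), 0.25 * r) if severity > 0 else 0.0
        d = np.sqrt((yy[..., None] - seeds[:, 0]) ** 2
                    + (xx[..., None] - seeds[:, 1]) ** 2)
        d.sort(axis=-1)
        if gap > 0:
            mask &= (d[..., 1] - d[..., 0]) >= 2 * gap
    return mask


def _render_vessels(shape: tuple[int, int], n_vessels: int, radius_px: float,
                    tumor_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Constant-radius line-segment tubes with random placement/orientation."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if n_vessels == 0:
        return mask
    yy, xx = np.mgrid[:h, :w]
    inside = np.argwhere(tumor_mask)
    diag = math.hypot(h, w)
    for _ in range(n_vessels):
        p0 = inside[rng.integers(len(inside))].astype(float)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 0.9) * diag
        direction = np.array([math.sin(ang), math.cos(ang)])
        a = p0 - 0.5 * length * direction
        b = p0 + 0.5 * length * direction
        ab = b - a
        denom = float(ab @ ab)
        t = ((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(yy - (a[0] + t * ab[0]), xx - (a[1] + t * ab[1]))
        mask |= dist <= radius_px
    return mask


def _tumor_ellipse(shape: tuple[int, int], margin_px: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = cy - margin_px, cx - margin_px
    if ry <= 0 or rx <= 0:
        raise ValueError("surface margin leaves no tumor interior")
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_section(spec: SyntheticSpec) -> tuple[SectionImage, GroundTruth]:
    """Generate one synthetic section and its ground truth.

    The tumor occupies an ellipse inset from the image border by
    ``surface_margin_um``.  The antibody channel inside the tumor follows
    A * exp(-d / lambda) with d the Euclidean distance (um) to the nearest
    vessel pixel; with no vessels it is pure noise.  Gaussian noise of sd
    ``noise_sd`` is added to every channel (clipped at zero).
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_shape
    px = spec.pixel_size_um

    tumor_mask = _tumor_ellipse((h, w), spec.surface_margin_um / px)
    vessel_mask = _render_vessels((h, w), spec.n_vessels,
                                  spec.vessel_radius_um / px, tumor_mask, rng)

    if spec.n_vessels > 0 and vessel_mask.any():
        dist_um = ndimage.distance_transform_edt(~vessel_mask) * px
        antibody = spec.antibody_amplitude * np.exp(-dist_um / spec.decay_length_um)
        antibody = np.where(tumor_mask, antibody, 0.0)
    else:
        dist_um = None
        antibody = np.zeros((h, w))

    vessels = np.where(vessel_mask, spec.vessel_intensity, 0.0)

    # --- nuclei ---
    nuclei_img = np.zeros((h, w))
    truths: list[NucleusTruth] = []
    r_px = spec.nucleus_radius_um / px
    n_frag = int(round(spec.frac_fragmented * spec.n_nuclei))
    kinds = ["fragmented"] * n_frag + ["intact"] * (spec.n_nuclei - n_frag)
    placed: list[np.ndarray] = []
    min_sep = 3.4 * r_px
    margin = int(math.ceil(1.6 * r_px)) + 2
    interior = np.argwhere(tumor_mask[margin:h - margin, margin:w - margin]) + margin \
        if h > 2 * margin and w > 2 * margin else np.empty((0, 2), int)
    max_tries = 200 * max(spec.n_nuclei, 1)
    tries = 0
    label = 0
    for kind in kinds:
        center = None
        while tries < max_tries:
            tries += 1
            cand = interior[rng.integers(len(interior))] if len(interior) else None
            if cand is None:
                break
            if vessel_mask[cand[0], cand[1]]:
                continue
            if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
                center = cand
                break
        if center is None:
            break  # field is saturated; stop placing
        placed.append(center)
        label += 1
        local = render_nucleus(kind, spec.fragmentation_severity if kind == "fragmented" else 0.0,
                               rng, radius_px=r_px)
        lh, lw = local.shape
        r0 = int(center[0]) - lh // 2
        c0 = int(center[1]) - lw // 2
        nuclei_img[r0:r0 + lh, c0:c0 + lw] = np.maximum(
            nuclei_img[r0:r0 + lh, c0:c0 + lw], local * spec.nucleus_intensity)
        com = ndimage.center_of_mass(local)
        truths.append(NucleusTruth(
            label=label, kind=kind,
            severity=spec.fragmentation_severity if kind == "fragmented" else 0.0,
            centroid_rc=(r0 + com[0], c0 + com[1]),
            bbox=(r0, c0, lh, lw), mask=local))

    if spec.noise_sd > 0:
        nuclei_img = nuclei_img + rng.normal(0, spec.noise_sd, (h, w))
        vessels = vessels + rng.normal(0, spec.noise_sd, (h, w))
        antibody = antibody + rng.normal(0, spec.noise_sd, (h, w))

    section = SectionImage(
        np.clip(nuclei_img, 0, None), np.clip(vessels, 0, None),
        np.clip(antibody, 0, None), pixel_size_um=px, tumor_mask=tumor_mask)
    truth = GroundTruth(spec=spec, vessel_mask=vessel_mask, tumor_mask=tumor_mask,
                        distance_to_vessel_um=dist_um, nuclei=truths)
    return section, truth


def write_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Export a generated section as 16-bit TIFFs plus a ground-truth sidecar."""
    import tifffile

    section, truth = generate_section(spec)
    out = Path(out_dir)
    save_section(section, out)
    tifffile.imwrite(str(out / "vessel_mask_truth.tif"),
                     truth.vessel_mask.astype(np.uint8))
    truth.sidecar(out / "ground_truth.json")
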