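"""Seeded synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis stage
assumes — they are deliberately simple (no point-spread function, no
photorealism):

* :func:`gen_cell_scene` — multichannel scenes (bright-field contour ring,
  DAPI nucleus discs, antigen channels with optional nuclear enrichment or
  edge bands, constant or ramped background, additive Gaussian noise) with
  per-cell ground-truth masks, contrasts, ratios and positivity,
* :func:`gen_afm_curves` — indentation strain-stress curves from the AFM
  forward model (shared implementation, multiplicative Gaussian noise),
* :func:`gen_confocal_stack` — analytic slice areas (and optional rasterised
  stacks) of solids of known volume,
* :func:`gen_fate_counts` — per-repeat multinomial fate counts.

All generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import afm
from .stats import CATEGORIES, FateTable
from .errors import NicheMechError

__all__ = [
    "SceneSpec",
    "AFMSimSpec",
    "FateSimSpec",
    "SceneTruth",
    "gen_cell_scene",
    "gen_afm_curves",
    "gen_confocal_stack",
    "gen_fate_counts",
    "DEFAULT_FATE_PROBS",
]

#: per-condition category probabilities echoing the reported contrasts:
#: cultured/uncompressed cells are mostly differentiation-committed (>60%,
#: with ~70% MyoD+ overall), compressed cells keep a Pax7+ majority with the
#: committed fraction pushed below 10%.
DEFAULT_FATE_PROBS = {
    "uncompressed": {"stem": 0.05, "progenitor": 0.20, "committed": 0.65,
                     "double_negative": 0.10},
    "compressed": {"stem": 0.40, "progenitor": 0.40, "committed": 0.08,
                   "double_negative": 0.12},
}


@dataclass(frozen=True)
class ChannelModel:
    """Intensity model of one antigen channel (arbitrary units)."""

    cell_contrast: float = 100.0      # painted above background inside positives
    negative_contrast: float = 0.0    # painted contrast of antigen-negative cells
    nucleus_multiplier: float = 1.0   # nuclear enrichment factor
    edge_multiplier: float = 1.0      # edge-band enrichment factor
    #: painted band width: this fraction of the boundary-to-nucleus distance
    #: (the 1/5 measurement convention) plus ``edge_band_margin`` pixels to
    #: cover the segmentation's inward bias
    edge_width_frac: float = 0.2
    #: painted band spans Euclidean depths [inset, width + margin] so the
    #: measured band (which sits ~1-2 px inside the true boundary) samples
    #: the plateau of the enriched zone
    edge_band_inset: int = 1
    edge_band_margin: int = 2
    background: float = 20.0          # constant background level
    background_ramp: tuple = (0.0, 0.0)   # linear gradient per px (dy, dx)
    noise_sd: float = 2.0             # additive Gaussian noise


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple = (768, 768)
    pixel_size: float = 0.23
    n_cells: int = 6
    cell_radius: tuple = (40, 52)     # px, semi-major axis range (um-scale cells at 0.23 um/px)
    eccentricity_max: float = 1.5     # max axis ratio of the ellipses
    nucleus_radius_frac: float = 0.4
    channels: dict = field(default_factory=lambda: {"antigen": ChannelModel()})
    positive_fraction: float = 1.0
    cluster_fraction: float = 0.0     # fraction of cells placed as touching pairs
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.positive_fraction <= 1 or not 0 <= self.cluster_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.cell_radius[0] <= 0:
            raise ValueError("cell radii must be positive")


@dataclass(frozen=True)
class AFMSimSpec:
    r0: float = 8.0                   # spreading radius, um
    p_prime: float = 200.0            # true effective pressure, Pa
    n_steps: int = 400                # indentation steps per curve
    strain_max: float = 0.10
    noise_sd: float = 0.02            # multiplicative Gaussian noise
    n_curves: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.strain_max > afm.MAX_STRAIN + 1e-12:
            raise ValueError("strain_max exceeds the small-strain regime")
        if self.n_steps < 10:
            raise ValueError("n_steps must be >= 10")


@dataclass(frozen=True)
class FateSimSpec:
    probabilities: dict = field(default_factory=lambda: DEFAULT_FATE_PROBS)
    repeats: int = 3
    cells_per_repeat: int = 200
    seed: int = 0

    def __post_init__(self):
        for cond, probs in self.probabilities.items():
            total = sum(probs.get(c, 0.0) for c in CATEGORIES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities for '{cond}' sum to {total}, not 1")


@dataclass
class SceneTruth:
    """Ground-truth annotations of one generated scene."""

    labels: np.ndarray                # cell label image (0 = background)
    nucleus_labels: np.ndarray
    cells: pd.DataFrame               # per-cell: center, radii, clustered,
                                      # per-channel true contrast/ratios/positive


def _ellipse_mask(shape, cy, cx, ry, rx, angle):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    ca, sa = math.cos(angle), math.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def gen_cell_scene(spec: SceneSpec):
    """Generate a multichannel scene and its ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps ``"bf"``,
    ``"dapi"`` and every antigen name to float rasters.  Cells are placed
    as isolated ellipses (plus touching pairs for the requested cluster
    fraction); a placement that cannot satisfy the separation constraints
    raises an error rather than silently overlapping.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    labels = np.zeros(spec.shape, dtype=int)
    nuc_labels = np.zeros(spec.shape, dtype=int)

    n_cluster_pairs = int(round(spec.n_cells * spec.cluster_fraction / 2))
    n_single = spec.n_cells - 2 * n_cluster_pairs
    placements = []  # (mask, nucleus_mask, clustered, geometry)

    occupied = np.zeros(spec.shape, bool)

    def try_place(clustered_with=None, tries=300):
        for _ in range(tries):
            ry = rng.uniform(*spec.cell_radius)
            ratio = rng.uniform(1.0, spec.eccentricity_max)
            rx = ry / ratio
            angle = rng.uniform(0, math.pi)
            margin = ry + 30
            if clustered_with is None:
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
            else:
                ocy, ocx, ory = clustered_with
                phi = rng.uniform(0, 2 * math.pi)
                d = (ory + min(rx, ry)) * 0.92  # slightly overlapping -> touching
                cy, cx = ocy + d * math.sin(phi), ocx + d * math.cos(phi)
                if not (margin < cy < h - margin and margin < cx < w - margin):
                    continue
            mask = _ellipse_mask(spec.shape, cy, cx, ry, rx, angle)
            dil = _ellipse_mask(spec.shape, cy, cx, ry + 28, rx + 28, angle)
            clash = occupied & (mask if clustered_with is not None else dil)
            if clash.any():
                continue
            nr = spec.nucleus_radius_frac
            nmask = _ellipse_mask(spec.shape, cy, cx, ry * nr, rx * nr, angle)
            return mask, nmask, (cy, cx, ry, rx, angle)
        raise NicheMechError("could not place cells without overlap; relax the scene parameters")

    for _ in range(n_single):
        mask, nmask, geom = try_place()
        occupied |= mask
        placements.append((mask, nmask, False, geom))
    for _ in range(n_cluster_pairs):
        mask1, nmask1, geom1 = try_place()
        occupied |= mask1
        mask2, nmask2, geom2 = try_place(clustered_with=geom1[:3])
        occupied |= mask2
        placements.append((mask1, nmask1, True, geom1))
        placements.append((mask2, nmask2, True, geom2))

    n = len(placements)
    positive = np.zeros(n, bool)
    n_pos = int(round(spec.positive_fraction * n))
    positive[rng.choice(n, size=n_pos, replace=False)] = True

    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # bright-field: grey background, dark interior, bright contour ring
    bf = np.full(spec.shape, 110.0)
    dapi = np.full(spec.shape, 10.0)
    antigen_clean = {name: np.zeros(spec.shape) for name in spec.channels}

    from scipy import ndimage as ndi

    rows = []
    for idx, (mask, nmask, clustered, geom) in enumerate(placements, start=1):
        labels[mask] = idx
        nuc_labels[nmask] = idx
        boundary = mask & ~ndi.binary_erosion(mask, iterations=2)
        bf[mask] = 95.0
        bf[boundary] = 230.0
        dapi[nmask] = 160.0

        row = {"cell_id": idx, "clustered": clustered,
               "cy": geom[0], "cx": geom[1], "ry": geom[2], "rx": geom[3]}
        dist_to_nuc = ndi.distance_transform_edt(~nmask)
        bdist = dist_to_nuc[mask & ~ndi.binary_erosion(mask)]
        mean_bd = float(bdist.mean()) if bdist.size else 0.0
        for name, cm in spec.channels.items():
            contrast = cm.cell_contrast if positive[idx - 1] else cm.negative_contrast
            paint = np.zeros(spec.shape)
            paint[mask] = contrast
            if cm.edge_multiplier != 1.0 and mean_bd > 0:
                width = max(int(round(cm.edge_width_frac * mean_bd)), 1) + cm.edge_band_margin
                depth = ndi.distance_transform_edt(mask)  # Euclidean depth into the cell
                edge_band = mask & (depth <= width) & (depth >= cm.edge_band_inset)
                paint[edge_band] = contrast * cm.edge_multiplier
            if cm.nucleus_multiplier != 1.0:
                paint[nmask] = contrast * cm.nucleus_multiplier
            antigen_clean[name] += paint
            true_level = float(paint[mask].mean())
            row[f"level_{name}"] = true_level
            row[f"positive_{name}"] = bool(positive[idx - 1])
            row[f"edge_center_{name}"] = cm.edge_multiplier
            row[f"nuc_cyt_{name}"] = cm.nucleus_multiplier
        rows.append(row)

    channels = {}
    for name, cm in spec.channels.items():
        ramp = cm.background_ramp[0] * yy + cm.background_ramp[1] * xx
        img = antigen_clean[name] + cm.background + ramp
        img += rng.normal(0.0, cm.noise_sd, size=spec.shape)
        channels[name] = img
    bf += rng.normal(0.0, 2.0, size=spec.shape)
    dapi += rng.normal(0.0, 2.0, size=spec.shape)
    channels["bf"] = bf
    channels["dapi"] = dapi

    truth = SceneTruth(labels=labels, nucleus_labels=nuc_labels,
                       cells=pd.DataFrame(rows))
    return channels, truth


def gen_afm_curves(spec: AFMSimSpec):
    """Simulated indentation curves: ``stress = P' * f(strain) * (1 + noise)``.

    Returns a list of :class:`nichemech.afm.IndentationCurve`; the forward
    model is the package's theoretical force curve itself (shared single
    implementation), so a zero-noise curve is exactly the theoretical curve
    scaled by the true pressure.
    """
    rng = np.random.default_rng(spec.seed)
    theory = afm.theoretical_force_curve(strain_max=spec.strain_max,
                                         n_points=min(spec.n_steps, 50))
    strains = np.linspace(0.0, spec.strain_max, spec.n_steps + 1)[1:]
    f = np.interp(strains, theory.strain, theory.f_over_p)
    curves = []
    for i in range(spec.n_curves):
        noise = rng.normal(0.0, spec.noise_sd, size=strains.shape) if spec.noise_sd else 0.0
        stress = spec.p_prime * f * (1.0 + noise)
        curves.append(afm.IndentationCurve(strain=strains, stress=stress,
                                           cell_id=f"sim{i:03d}"))
    return curves


def gen_confocal_stack(shape: str, radius: float, dz: float, height: float | None = None,
                       rasterize: bool = False, pixel_size: float = 0.21,
                       noise_sd: float = 0.0, seed: int = 0):
    """Slice areas (and optionally a rasterised stack) of a known solid.

    ``shape`` is ``"hemisphere"`` (``A(z) = pi (R^2 - z^2)``),
    ``"cylinder"`` (constant ``A``) or ``"cap"`` (spherical cap of the given
    ``height``).  Slices are sampled at slice centers ``z = (i + 1/2) dz``.

    Returns ``(areas, analytic_volume)`` or, with ``rasterize=True``,
    ``(areas, analytic_volume, stack)``.
    """
    if radius <= 0 or dz <= 0:
        raise ValueError("radius and dz must be positive")
    if shape == "hemisphere":
        zmax, vol = radius, 2 / 3 * math.pi * radius ** 3
        area_of = lambda z: math.pi * (radius ** 2 - z ** 2)
    elif shape == "cylinder":
        zmax = height if height is not None else radius
        vol = math.pi * radius ** 2 * zmax
        area_of = lambda z: math.pi * radius ** 2
    elif shape == "cap":
        if height is None or not 0 < height <= radius:
            raise ValueError("cap requires 0 < height <= radius")
        zmax = height
        vol = math.pi * height ** 2 * (3 * radius - height) / 3
        shift = radius - height
        area_of = lambda z: math.pi * (radius ** 2 - (z + shift) ** 2)
    else:
        raise ValueError(f"unknown shape '{shape}'")

    centers = np.arange(dz / 2, zmax, dz)
    areas = np.array([max(area_of(z), 0.0) for z in centers])
    if not rasterize:
        return areas, vol

    rng = np.random.default_rng(seed)
    npx = int(2 * (radius / pixel_size)) + 41
    c = npx // 2
    yy, xx = np.mgrid[0:npx, 0:npx]
    stack = []
    for a in areas:
        r_px = math.sqrt(a / math.pi) / pixel_size
        sl = np.where((yy - c) ** 2 + (xx - c) ** 2 <= r_px ** 2, 120.0, 10.0)
        if noise_sd:
            sl = sl + rng.normal(0.0, noise_sd, size=sl.shape)
        stack.append(sl)
    return areas, vol, np.array(stack)


def gen_fate_counts(spec: FateSimSpec) -> FateTable:
    """Per-repeat multinomial fate counts for each condition."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond, probs in spec.probabilities.items():
        p = [probs.get(c, 0.0) for c in CATEGORIES]
        for rep in range(1, spec.repeats + 1):
            draw = rng.multinomial(spec.cells_per_repeat, p)
            for cat, count in zip(CATEGORIES, draw):
                rows.append({"condition": cond, "repeat": rep,
                             "category": cat, "count": int(count)})
    return FateTable(pd.DataFrame(rows))
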