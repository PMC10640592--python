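"""Ground-truth generators: 2D ring-stained capillary scenes, 3D tube networks.

The 2D generator emulates the appearance of membrane (endothelium) stained
capillary cross-sections: each capillary is a bright elliptical annulus
(the stained wall) around a dimmer lumen, on a textured background, with
intensity jitter along the wall to exercise the gap-closing morphology and
Poisson + Gaussian sensor noise.  Every rendered shape carries its analytic
descriptors (area, roundness = minor/major, circularity from the Ramanujan
ellipse perimeter), so pipeline output can be validated against closed-form
truth.

Shape presets parameterise the two study conditions: ``control_like``
capillaries are predominantly elongated (aspect ratio log-uniform 1.5–6)
and ``injury_like`` ones rounder (aspect ratio log-uniform 1–2); the
presets emulate the direction of the real contrast, not any measured
distribution.

The 3D generator grows random binary-tree centerlines with optional
sinusoidal tortuosity and rasterises them as swept spheres, recording exact
polyline lengths, per-segment tortuosity and junction counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ptcmorph.io_config import CalibratedImage2D
from ptcmorph.vessel3d import VesselVolume3D

SHAPE_PRESETS = {
    # aspect-ratio range (log-uniform)
    "control_like": (1.5, 6.0),
    "injury_like": (1.0, 2.0),
}

DEFAULT_AREA_RANGE = (15.0, 2000.0)   # µm², log-uniform, inside the 10–8000 filter
DEFAULT_PIXEL_SIZE = 0.5              # µm/px
DEFAULT_AREA_FRACTION = 0.12
WALL_THICKNESS_UM = 1.5
MIN_SEMI_MINOR_UM = 2.5               # vessel caliber floor: minor diameter >= 5 µm

_BG, _LUMEN, _WALL = 25.0, 50.0, 190.0


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def ellipse_circularity(a: float, b: float) -> float:
    return 4.0 * math.pi * (math.pi * a * b) / ellipse_perimeter(a, b) ** 2


@dataclass
class SyntheticScene2D:
    image: CalibratedImage2D
    truth: pd.DataFrame       # one row per capillary, analytic descriptors
    condition: str
    seed: int


def make_scene_2d(
    n_capillaries: int,
    shape_mix: str | tuple[float, float] = "control_like",
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: float = 0.3,
    seed: int = 0,
    *,
    area_range: tuple[float, float] = DEFAULT_AREA_RANGE,
    area_fraction: float = DEFAULT_AREA_FRACTION,
    wall_jitter: float = 0.25,
    max_tries: int = 200,
) -> SyntheticScene2D:
    """Render a seeded scene of non-overlapping ring-stained capillaries.

    ``shape_mix`` is a preset name or an (ar_min, ar_max) aspect-ratio range
    sampled log-uniformly; areas are log-uniform over ``area_range``.  The
    image side is chosen so the shapes occupy about ``area_fraction`` of it.
    Fully reproducible from ``seed``.
    """
    if isinstance(shape_mix, str):
        try:
            ar_range = SHAPE_PRESETS[shape_mix]
        except KeyError:
            raise ValueError(f"unknown shape preset {shape_mix!r}") from None
        condition = shape_mix
    else:
        ar_range = shape_mix
        condition = f"ar{ar_range[0]:g}-{ar_range[1]:g}"
    rng = np.random.default_rng(seed)

    areas = np.exp(rng.uniform(np.log(area_range[0]), np.log(area_range[1]),
                               n_capillaries))
    ars = np.exp(rng.uniform(np.log(ar_range[0]), np.log(ar_range[1]),
                             n_capillaries))
    # Outer semi-axes from area and aspect ratio; the minor diameter is
    # floored at the anatomical capillary caliber (a vessel narrower than an
    # erythrocyte, with a wall thicker than its lumen, is not a capillary),
    # since elongation in section comes from cut angle, not from a thinner
    # vessel.
    areas = np.maximum(areas, np.pi * ars * MIN_SEMI_MINOR_UM**2)
    bs = np.sqrt(areas / (np.pi * ars))
    as_ = bs * ars
    thetas = rng.uniform(0, np.pi, n_capillaries)

    side_um = math.sqrt(areas.sum() / area_fraction) if n_capillaries else 64 * pixel_size
    n_px = max(int(math.ceil(side_um / pixel_size)), 64)
    margin_um = 2.0

    occupied = np.zeros((n_px, n_px), dtype=bool)
    img = np.full((n_px, n_px), _BG)
    rows = []
    order = np.argsort(-areas)  # place large shapes first
    for i in order:
        a, b, th = as_[i], bs[i], thetas[i]
        placed = False
        for _ in range(max_tries):
            half = (a + margin_um) / pixel_size + 2
            cr = rng.uniform(half, n_px - half)
            cc = rng.uniform(half, n_px - half)
            sl, shape_masks = _ellipse_masks(cr, cc, a, b, th, pixel_size,
                                             margin_um, n_px)
            if shape_masks is None:
                continue
            outer_m, wall_m, grown_m = shape_masks
            if (occupied[sl] & grown_m).any():
                continue
            occupied[sl] |= grown_m
            # paint: lumen then wall with angular jitter
            sub = img[sl]
            sub[outer_m & ~wall_m] = _LUMEN
            yy, xx = np.nonzero(wall_m)
            ang = np.arctan2(yy - (cr - sl[0].start), xx - (cc - sl[1].start))
            k = rng.integers(2, 6)
            phase = rng.uniform(0, 2 * np.pi)
            mod = 1.0 + wall_jitter * np.sin(k * ang + phase)
            sub[yy, xx] = np.clip(_WALL * mod, _LUMEN + 20, 255)
            img[sl] = sub
            rows.append({
                "center_row_um": cr * pixel_size,
                "center_col_um": cc * pixel_size,
                "semi_major_um": a,
                "semi_minor_um": b,
                "orientation_rad": th,
                "area_um2": math.pi * a * b,
                "aspect_ratio": a / b,
                "roundness": b / a,
                "circularity": ellipse_circularity(a, b),
            })
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place {n_capillaries} capillaries at area "
                f"fraction {area_fraction} after {max_tries} tries each"
            )

    if noise > 0:
        texture = ndimage.gaussian_filter(rng.normal(0, 1, img.shape), 12)
        texture *= 8.0 * noise / max(texture.std(), 1e-9)
        img = np.clip(img + texture, 1, 255)
        img = rng.poisson(img).astype(np.float64)
        img += rng.normal(0, 8.0 * noise, img.shape)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=["center_row_um", "center_col_um", "semi_major_um",
                 "semi_minor_um", "orientation_rad", "area_um2",
                 "aspect_ratio", "roundness", "circularity"],
    )
    image = CalibratedImage2D(out, pixel_size, name=f"{condition}_seed{seed}")
    return SyntheticScene2D(image, truth, condition, seed)


def _ellipse_masks(cr, cc, a, b, theta, pixel_size, margin_um, n_px):
    """Outer/wall/safety masks of one rotated ellipse within its bbox slice."""
    half_px = int(math.ceil((a + margin_um) / pixel_size)) + 2
    r0, r1 = int(cr) - half_px, int(cr) + half_px + 1
    c0, c1 = int(cc) - half_px, int(cc) + half_px + 1
    if r0 < 0 or c0 < 0 or r1 > n_px or c1 > n_px:
        return (slice(None), slice(None)), None
    sl = (slice(r0, r1), slice(c0, c1))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = (yy - cr) * pixel_size
    dx = (xx - cc) * pixel_size
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st       # along major axis
    v = -dx * st + dy * ct
    outer = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    wi = max(b - WALL_THICKNESS_UM, 0.5 * pixel_size)
    ai = a - (b - wi)           # inner ellipse, same wall thickness all round
    inner = (u / ai) ** 2 + (v / wi) ** 2 <= 1.0
    grown = (u / (a + margin_um)) ** 2 + (v / (b + margin_um)) ** 2 <= 1.0
    return sl, (outer, outer & ~inner, grown)


# ---------------------------------------------------------------------------
# 3D networks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNetwork3D:
    volume: VesselVolume3D        # intensity volume (tube bright on dark)
    binary: np.ndarray            # exact swept-sphere rasterisation
    truth: pd.DataFrame           # per-segment length_um, tortuosity
    n_junctions: int
    n_endpoints: int
    total_length_um: float
    seed: int


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())


def _perturb(start: np.ndarray, end: np.ndarray, amp: float,
             rng: np.random.Generator, n_pts: int = 200) -> np.ndarray:
    """Densely sampled straight segment with a sinusoidal half-wave bend.

    ``amp`` is the peak offset as a fraction of the segment length, applied
    perpendicular to the segment; the polyline is analytic ground truth.
    """
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = start + t * (end - start)
    if amp > 0:
        d = (end - start) / np.linalg.norm(end - start)
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        perp = np.cross(d, ref)
        perp /= np.linalg.norm(perp)
        L = np.linalg.norm(end - start)
        pts = pts + (amp * L) * np.sin(np.pi * t) * perp
    return pts


def rasterize_tubes(polylines: Sequence[np.ndarray], radius: float,
                    margin: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Swept-sphere rasterisation of polylines (coords in voxels, z,y,x).

    Returns (binary volume, offset) where offset was subtracted from all
    coordinates to fit the volume with the given margin.
    """
    allpts = np.concatenate(polylines)
    lo = np.floor(allpts.min(axis=0) - radius - margin)
    hi = np.ceil(allpts.max(axis=0) + radius + margin)
    shape = (hi - lo + 1).astype(int)
    vol = np.zeros(shape, dtype=bool)
    r = int(math.ceil(radius))
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = np.argwhere(zz**2 + yy**2 + xx**2 <= radius**2) - r
    for pl in polylines:
        # resample densely so consecutive stamps overlap
        seg = pl - lo
        dists = np.sqrt((np.diff(seg, axis=0) ** 2).sum(axis=1))
        n = max(int(dists.sum() / 0.5) + 2, len(seg))
        t = np.linspace(0, 1, len(seg))
        ti = np.linspace(0, 1, n)
        dense = np.stack([np.interp(ti, t, seg[:, k]) for k in range(3)], axis=1)
        centers = np.rint(dense).astype(int)
        vox = (centers[:, None, :] + ball[None, :, :]).reshape(-1, 3)
        np.clip(vox, 0, np.array(shape) - 1, out=vox)
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return vol, lo


def make_network_3d(
    n_segments: int = 13,
    tortuosity_amp: float = 0.0,
    radius: float = 3.0,
    voxel_um: float = 1.0,
    seed: int = 0,
    *,
    segment_length: tuple[float, float] = (30.0, 60.0),
    min_separation_factor: float = 3.0,
    max_tries: int = 200,
) -> SyntheticNetwork3D:
    """Grow a random binary-tree tube network with known metrics.

    ``n_segments`` must be odd (a binary tree with s segments has
    (s - 1) / 2 junctions and (s + 3) / 2 endpoints).  ``tortuosity_amp``
    bends each segment sinusoidally; per-segment tortuosity is computed
    analytically from the generating polyline.  Segments are placed with a
    clearance of ``min_separation_factor * radius`` so the rasterised tubes
    do not merge.
    """
    if radius < 2:
        raise ValueError("radius must be >= 2 voxels")
    if n_segments < 1 or n_segments % 2 == 0:
        raise ValueError("n_segments must be odd (binary tree)")
    rng = np.random.default_rng(seed)
    polylines: list[np.ndarray] = []
    # active tips: (point, direction)
    root = np.zeros(3)
    d0 = _unit(rng.normal(size=3))
    first = _grow_segment(root, d0, segment_length, tortuosity_amp, rng,
                          polylines, min_separation_factor * radius, max_tries)
    tips = [(first[-1], _unit(first[-1] - first[-2]))]
    polylines.append(first)
    while len(polylines) < n_segments:
        if not tips:
            raise RuntimeError("network growth exhausted all tips")
        idx = rng.integers(len(tips))
        tip, d = tips.pop(idx)
        children = []
        ok = True
        for k in range(2):
            sib = (_unit(children[0][-1] - children[0][0])
                   if children else None)
            try:
                child = _grow_segment(tip, d, segment_length, tortuosity_amp,
                                      rng, polylines + children,
                                      min_separation_factor * radius, max_tries,
                                      sibling_dir=sib)
            except RuntimeError:
                ok = False
                break
            children.append(child)
        if not ok:
            continue  # tip abandoned; try another
        for child in children:
            polylines.append(child)
            tips.append((child[-1], _unit(child[-1] - child[-2])))

    binary, _ = rasterize_tubes(polylines, radius)
    vol = np.where(binary, 200.0, 10.0)
    lengths = [_polyline_length(p) * voxel_um for p in polylines]
    torts = [
        _polyline_length(p) / np.linalg.norm(p[-1] - p[0]) for p in polylines
    ]
    truth = pd.DataFrame({"length_um": lengths, "tortuosity": torts})
    return SyntheticNetwork3D(
        volume=VesselVolume3D(vol, (voxel_um, voxel_um, voxel_um)),
        binary=binary,
        truth=truth,
        n_junctions=(n_segments - 1) // 2,
        n_endpoints=(n_segments + 3) // 2,
        total_length_um=float(sum(lengths)),
        seed=seed,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _grow_segment(start, parent_dir, length_range, amp, rng, existing,
                  clearance, max_tries, sibling_dir=None) -> np.ndarray:
    """One child polyline from ``start``, rejected if too close to others.

    Sibling branches must diverge by at least ~50° so the rasterised tubes
    separate immediately at the branch point (one junction per branching).
    """
    from scipy.spatial import cKDTree

    trees = [cKDTree(p) for p in existing] if existing else []
    for _ in range(max_tries):
        L = rng.uniform(*length_range)
        # direction within ~20-60 degrees of the parent
        d = _unit(parent_dir + rng.normal(scale=0.6, size=3))
        if np.dot(d, parent_dir) < 0.3:
            continue
        if sibling_dir is not None and np.dot(d, sibling_dir) > 0.64:
            continue
        end = np.asarray(start) + L * d
        pl = _perturb(np.asarray(start, float), end, amp, rng)
        if trees:
            # ignore the stretch near the shared junction point
            away = np.linalg.norm(pl - pl[0], axis=1) > 1.5 * clearance
            body = pl[away]
            if body.size:
                dmin = min(t.query(body)[0].min() for t in trees)
                if dmin < clearance:
                    continue
        return pl
    raise RuntimeError("could not place a segment with required clearance")
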