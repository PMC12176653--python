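"""Render synthetic brightfield-style branched-organoid images.

An organoid is a union of simple primitives — thick line segments
(capsules) for branches, disks for cores / terminal end buds / cell
clumps, and carved circular holes for micro-lumens — rasterized at a
known pixel size.  Because the geometry is explicit, every structural
descriptor (branch points, endpoints, end buds, lumen count and area,
major axis) is known exactly before any noise is applied, and is returned
alongside the image as ground truth.

Brightfield emulation: dark organoid on a bright background, Gaussian
blur of 1 px, optional additive Gaussian noise, and multiplicative
speckle inside the organoid emulating cytoplasmic granularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

from ..archetypes import PhenotypeArchetype, jitter_archetype

DEFAULT_PIXEL_SIZE_UM = 1.29
_BACKGROUND = 0.90
_FOREGROUND_DROP = 0.55  # organoid intensity = background - drop (pre-speckle)


@dataclass(frozen=True)
class GroundTruth:
    """Exact pre-noise morphometrics of a rendered organoid."""

    phenotype: str
    major_axis_um: float
    core_thickness_um: float
    n_main_branches: int
    n_nodes: int
    n_endpoints: int
    n_terminal_end_buds: int
    n_lumens: int
    n_spiky_branches: int
    total_lumen_area_um2: float
    core_area_um2: float
    n_components: int
    pixel_size_um: float
    seed: int

    def __post_init__(self):
        for f in ("n_main_branches", "n_nodes", "n_endpoints",
                  "n_terminal_end_buds", "n_lumens", "n_spiky_branches",
                  "n_components"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.major_axis_um < self.core_thickness_um:
            raise ValueError("major axis cannot be smaller than core thickness")

    def as_dict(self) -> dict:
        return asdict(self)


class CanvasError(ValueError):
    """Raised when the requested geometry does not fit the canvas."""


class _Geometry:
    """Union of capsules, disks and holes plus its design skeleton-graph counts."""

    def __init__(self):
        self.capsules: list[tuple[np.ndarray, np.ndarray, float]] = []
        self.disks: list[tuple[np.ndarray, float]] = []
        self.holes: list[tuple[np.ndarray, float]] = []
        self.n_nodes = 0
        self.n_endpoints = 0
        self.n_buds = 0
        self.n_spiky = 0
        self.n_main = 0
        self.n_lumens = 0
        self.lumen_area = 0.0
        self.core_radius = 0.0
        self.n_components = 1

    def add_capsule(self, p0, p1, radius):
        self.capsules.append((np.asarray(p0, float), np.asarray(p1, float), float(radius)))

    def add_disk(self, c, radius):
        self.disks.append((np.asarray(c, float), float(radius)))

    def add_hole(self, c, radius):
        self.holes.append((np.asarray(c, float), float(radius)))

    # -- exact descriptors ------------------------------------------------
    def support_points(self):
        pts, rad = [], []
        for p0, p1, r in self.capsules:
            pts += [p0, p1]
            rad += [r, r]
        for c, r in self.disks:
            pts.append(c)
            rad.append(r)
        return np.array(pts), np.array(rad)

    def major_axis_um(self) -> float:
        pts, rad = self.support_points()
        if len(pts) == 0:
            return 0.0
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        feret = d + rad[:, None] + rad[None, :]
        # a single disk supports a diameter of 2r
        np.fill_diagonal(feret, 2 * rad)
        return float(feret.max())

    def bounds(self):
        pts, rad = self.support_points()
        lo = (pts - rad[:, None]).min(axis=0)
        hi = (pts + rad[:, None]).max(axis=0)
        return lo, hi


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _build_trunk_family(a: PhenotypeArchetype, rng: np.random.Generator) -> _Geometry:
    """Trunk-based families: TEBBO, thick_branched, tree_like."""
    g = _Geometry()
    L = a.trunk_length_um
    rt = a.trunk_thickness_um / 2.0
    g.core_radius = rt
    p0, p1 = np.array([-L / 2, 0.0]), np.array([L / 2, 0.0])
    g.add_capsule(p0, p1, rt)

    B = a.n_main_branches
    tips = []
    main_dirs, main_roots = [], []
    if B:
        fr = np.linspace(0.18, 0.82, B) if B > 1 else np.array([0.5])
        for i in range(B):
            root = p0 + fr[i] * (p1 - p0)
            side = 1.0 if i % 2 == 0 else -1.0
            # mostly perpendicular, tilted toward the nearest trunk end
            tilt = math.radians(rng.uniform(15, 30))
            dirsign = 1.0 if fr[i] >= 0.5 else -1.0
            ang = side * (math.pi / 2 - dirsign * tilt)
            d = _unit(ang)
            tip = root + a.main_branch_length_um * d
            g.add_capsule(root, tip, a.main_branch_thickness_um / 2.0)
            tips.append(tip)
            main_dirs.append(d)
            main_roots.append(root)
            g.n_nodes += 1
            g.n_endpoints += 1

    S = a.n_sub_branches
    occ = [0] * max(B, 1)
    sub_attach_frac = (0.62, 0.34, 0.82)
    # keep a tip bud clear of the sub-branch: the gap between the sub
    # junction and the main tip must exceed the bud reach even across the
    # sub's divergence angle (drawn within 48-56 degrees below)
    frac_cap = 1.0
    if a.n_terminal_end_buds and a.main_branch_length_um > 0:
        clearance = (a.bud_radius_um + a.sub_branch_thickness_um / 2 + 12.0) / math.sin(
            math.radians(48))
        frac_cap = max(0.30, 1.0 - clearance / a.main_branch_length_um)
    for j in range(S):
        i = j % max(B, 1)
        k = min(occ[i], len(sub_attach_frac) - 1)
        occ[i] += 1
        d = main_dirs[i]
        attach = main_roots[i] + min(sub_attach_frac[k], frac_cap) * a.main_branch_length_um * d
        rot = math.radians(52 + rng.uniform(-4, 4)) * (1.0 if k % 2 == 0 else -1.0)
        c, s = math.cos(rot), math.sin(rot)
        d2 = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        tip = attach + a.sub_branch_length_um * d2
        g.add_capsule(attach, tip, a.sub_branch_thickness_um / 2.0)
        tips.append(tip)
        g.n_nodes += 1
        g.n_endpoints += 1

    K = a.n_spiky_branches
    if K:
        # spikes sit on the trunk midway between main-branch roots, where
        # they cannot be swallowed by a thicker branch
        if B > 1:
            mids = [(fr[i] + fr[i + 1]) / 2 for i in range(B - 1)]
        else:
            mids = []
        mids += [0.10, 0.90, 0.04, 0.96]
        main_sides = [1.0 if i % 2 == 0 else -1.0 for i in range(B)]

        def safe_side(mid):
            # main branches tilt toward the nearest trunk end; avoid the
            # side of the neighbour that tilts toward this midpoint
            if not B:
                return 1.0
            if mid < 0.5:
                danger = [i for i in range(B) if fr[i] > mid]
                i_d = min(danger, key=lambda i: fr[i] - mid) if danger else None
            else:
                danger = [i for i in range(B) if fr[i] < mid]
                i_d = max(danger, key=lambda i: fr[i]) if danger else None
            return -main_sides[i_d] if i_d is not None else 1.0

        for i in range(K):
            mid = mids[i % len(mids)]
            root = p0 + mid * (p1 - p0)
            side = safe_side(mid)
            ang = side * (math.pi / 2 + math.radians(rng.uniform(-10, 10)))
            tip = root + a.spike_length_um * _unit(ang)
            g.add_capsule(root, tip, a.spike_thickness_um / 2.0)
            g.n_nodes += 1
            g.n_endpoints += 1
            g.n_spiky += 1

    # trunk contributes two endpoints
    g.n_endpoints += 2
    g.n_main = B

    # terminal end buds on branch tips (mains first, then subs, then trunk ends)
    bud_sites = tips + [p1, p0]
    nb = min(a.n_terminal_end_buds, len(bud_sites))
    for site in bud_sites[:nb]:
        g.add_disk(site, a.bud_radius_um)
    g.n_buds = nb
    return g


def _build_core_family(a: PhenotypeArchetype, rng: np.random.Generator) -> _Geometry:
    """Core-based families: cystic_branched, branched_mesenchymal, firework, star_like, clump."""
    g = _Geometry()
    R = a.core_radius_um
    g.core_radius = R
    g.add_disk((0.0, 0.0), R)

    B = a.n_main_branches
    dirs = []
    if B:
        spacing = 2 * math.pi / B
        phase = rng.uniform(0, 2 * math.pi)
        jig = min(math.radians(3.0), 0.12 * spacing)
        for i in range(B):
            ang = phase + i * spacing + rng.uniform(-jig, jig)
            d = _unit(ang)
            tip = (R + a.main_branch_length_um) * d
            g.add_capsule(np.zeros(2), tip, a.main_branch_thickness_um / 2.0)
            dirs.append(d)
            g.n_endpoints += 1
        if B >= 3:
            g.n_nodes += 1
        elif B == 2:
            pass  # centre is a pass-through, not a branch point
        else:
            g.n_endpoints += 1  # stub: centre end of the single branch

    S = a.n_sub_branches
    for j in range(S):
        i = (j * max(B, 1) // max(S, 1)) % max(B, 1)
        d = dirs[i]
        attach = (R + 0.55 * a.main_branch_length_um) * d
        # one rotational sense for all sub-branches: each sub occupies the
        # gap counter-clockwise of its parent, so subs never meet
        rot = math.radians(38 + rng.uniform(-5, 5))
        c, s = math.cos(rot), math.sin(rot)
        d2 = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        tip = attach + a.sub_branch_length_um * d2
        g.add_capsule(attach, tip, a.sub_branch_thickness_um / 2.0)
        g.n_nodes += 1
        g.n_endpoints += 1

    g.n_main = B

    # micro-lumens carved inside the core on a ring at half the core radius
    n_l = a.n_lumens
    if n_l:
        ring = 0.5 * R
        margin = 8.0
        lr = a.lumen_radius_um
        lr = min(lr, R - ring - margin)  # keep holes fully enclosed
        if n_l > 1:
            chord = 2 * ring * math.sin(math.pi / n_l)
            lr = min(lr, (chord - margin) / 2.0)
        if lr <= 2.0:
            raise CanvasError("core too small to host the requested lumens")
        phase = rng.uniform(0, 2 * math.pi)
        for i in range(n_l):
            ang = phase + 2 * math.pi * i / n_l
            g.add_hole(ring * _unit(ang), lr)
        g.n_lumens = n_l
        g.lumen_area = n_l * math.pi * lr ** 2
    return g


def _build_scattered(a: PhenotypeArchetype, rng: np.random.Generator) -> _Geometry:
    g = _Geometry()
    n = a.n_fragments
    rlo, rhi = a.fragment_radius_um
    field = 320.0  # fragments land within this radius of the image centre
    centers, radii = [], []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > 20000:
            raise CanvasError("could not place disconnected fragments")
        c = rng.uniform(-field, field, size=2)
        r = rng.uniform(rlo, rhi)
        ok = all(np.linalg.norm(c - c2) >= r + r2 + 12.0
                 for c2, r2 in zip(centers, radii))
        if ok:
            centers.append(c)
            radii.append(r)
    for c, r in zip(centers, radii):
        g.add_disk(c, r)
    g.n_components = n
    g.core_radius = float(max(radii))
    return g


def build_geometry(archetype: PhenotypeArchetype, rng: np.random.Generator) -> _Geometry:
    name = archetype.name
    if name in ("TEBBO", "thick_branched", "tree_like"):
        return _build_trunk_family(archetype, rng)
    if name in ("cystic_branched", "branched_mesenchymal", "firework",
                "star_like", "clump"):
        return _build_core_family(archetype, rng)
    if name == "scattered":
        return _build_scattered(archetype, rng)
    raise ValueError(f"no builder for phenotype {name!r}")


# ---------------------------------------------------------------------------
# rasterization

def _paint(mask: np.ndarray, center_px: np.ndarray, geom: _Geometry, px: float):
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]

    for p0, p1, r in geom.capsules:
        a = p0 / px + center_px
        b = p1 / px + center_px
        rp = r / px
        lo = np.floor(np.minimum(a, b) - rp - 2).astype(int)
        hi = np.ceil(np.maximum(a, b) + rp + 2).astype(int)
        x0, y0 = np.clip(lo, 0, [w - 1, h - 1])
        x1, y1 = np.clip(hi, 0, [w - 1, h - 1])
        X = xx[y0:y1 + 1, x0:x1 + 1]
        Y = yy[y0:y1 + 1, x0:x1 + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = (X - a[0]) ** 2 + (Y - a[1]) ** 2
        else:
            t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / denom
            t = np.clip(t, 0.0, 1.0)
            d2 = (X - (a[0] + t * ab[0])) ** 2 + (Y - (a[1] + t * ab[1])) ** 2
        mask[y0:y1 + 1, x0:x1 + 1] |= d2 <= rp ** 2

    for c, r in geom.disks:
        cc = c / px + center_px
        rp = r / px
        lo = np.floor(cc - rp - 2).astype(int)
        hi = np.ceil(cc + rp + 2).astype(int)
        x0, y0 = np.clip(lo, 0, [w - 1, h - 1])
        x1, y1 = np.clip(hi, 0, [w - 1, h - 1])
        X = xx[y0:y1 + 1, x0:x1 + 1]
        Y = yy[y0:y1 + 1, x0:x1 + 1]
        mask[y0:y1 + 1, x0:x1 + 1] |= (X - cc[0]) ** 2 + (Y - cc[1]) ** 2 <= rp ** 2

    for c, r in geom.holes:
        cc = c / px + center_px
        rp = r / px
        lo = np.floor(cc - rp - 2).astype(int)
        hi = np.ceil(cc + rp + 2).astype(int)
        x0, y0 = np.clip(lo, 0, [w - 1, h - 1])
        x1, y1 = np.clip(hi, 0, [w - 1, h - 1])
        X = xx[y0:y1 + 1, x0:x1 + 1]
        Y = yy[y0:y1 + 1, x0:x1 + 1]
        mask[y0:y1 + 1, x0:x1 + 1] &= ~((X - cc[0]) ** 2 + (Y - cc[1]) ** 2 <= rp ** 2)


def rasterize(geom: _Geometry, canvas_px: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Rasterize geometry (µm, centre origin) onto a boolean canvas."""
    h, w = canvas_px
    center = np.array([w / 2.0, h / 2.0])
    lo, hi = geom.bounds()
    margin = 3 * pixel_size_um
    if (lo[0] - margin < -w / 2 * pixel_size_um or hi[0] + margin > w / 2 * pixel_size_um
            or lo[1] - margin < -h / 2 * pixel_size_um or hi[1] + margin > h / 2 * pixel_size_um):
        raise CanvasError(
            f"geometry extent [{lo}, {hi}] µm exceeds canvas "
            f"{w * pixel_size_um:.0f}x{h * pixel_size_um:.0f} µm")
    mask = np.zeros((h, w), dtype=bool)
    _paint(mask, center, geom, pixel_size_um)
    return mask


def _ground_truth(geom: _Geometry, a: PhenotypeArchetype,
                  pixel_size_um: float, seed: int) -> GroundTruth:
    core_r = geom.core_radius
    return GroundTruth(
        phenotype=a.name,
        major_axis_um=geom.major_axis_um(),
        core_thickness_um=2 * core_r,
        n_main_branches=geom.n_main,
        n_nodes=geom.n_nodes,
        n_endpoints=geom.n_endpoints,
        n_terminal_end_buds=geom.n_buds,
        n_lumens=geom.n_lumens,
        n_spiky_branches=geom.n_spiky,
        total_lumen_area_um2=geom.lumen_area,
        core_area_um2=math.pi * core_r ** 2,
        n_components=geom.n_components,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )


def generate_organoid_image(
    archetype: PhenotypeArchetype,
    canvas_px: tuple[int, int] = (800, 800),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_level: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one organoid; returns (float image in [0,1], GroundTruth).

    Deterministic for fixed arguments.  Raises :class:`CanvasError` if the
    geometry would not fit the canvas (never silently crops).
    """
    rng = np.random.default_rng(seed)
    geom = build_geometry(archetype, rng)
    mask = rasterize(geom, canvas_px, pixel_size_um)
    truth = _ground_truth(geom, archetype, pixel_size_um, seed)

    img = np.full(mask.shape, _BACKGROUND, dtype=np.float64)
    drop = np.full(mask.shape, _FOREGROUND_DROP)
    if archetype.granularity_sigma > 0:
        speck = 1.0 + archetype.granularity_sigma * rng.standard_normal(mask.shape)
        drop = drop * np.clip(speck, 0.2, 1.8)
    img[mask] -= drop[mask]
    img = ndi.gaussian_filter(img, sigma=1.0)
    if noise_level > 0:
        img = img + noise_level * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0), truth
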