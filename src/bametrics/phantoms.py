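"""Synthetic imaging phantoms with analytically known geometry.

Two families of fixtures:

* **Tube phantoms** — curved tubular vessels (straight / arc / helix / spline
  centerlines, constant or linearly tapering radius) rendered into an
  anisotropic voxel grid at time-of-flight-like resolution. The analytic
  centerline, its arc length between landmarks and the diameter profile are
  returned as ground truth, so centerline extraction and lumen quantification
  can be scored against closed-form values.
* **Brain phantoms** — a nested-ellipsoid head (ventricles, tissue band,
  cortical shell with lobar wedge labels) with spherical FLAIR-hyperintense
  lesions seeded at known positions, volumes and lobe/layer assignments.

Rendering model for tubes: signed distance to the analytic centerline,
mapped through a one-voxel linear partial-volume ramp at the local radius
(an anti-aliased threshold), Gaussian-blurred and corrupted with additive
Gaussian noise; the rendered tube also continues tangentially past both
curve ends, as a real vessel continues past its annotated landmarks. All
randomness flows from the integer seed in the spec; no global state is
touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grids import LANDMARK_NAMES, LandmarkSet, VoxelGrid, axis_aligned_affine

#: In-plane / through-plane voxel size of the emulated ToF MRA acquisition.
TOF_SPACING = (0.357, 0.357, 0.5)

#: Cortical lobe labels used throughout the package.
LOBE_LABELS = {"frontal": 1, "parietal": 2, "occipital": 3, "other": 4}


# ---------------------------------------------------------------------------
# parametric centerlines
# ---------------------------------------------------------------------------

class ParametricCurve:
    """A smooth curve p(t), t in [0, 1], with arc-length reparameterization."""

    def __init__(self, point_fn, deriv_fn, n_dense: int = 8193):
        self._p = point_fn
        self._dp = deriv_fn
        ts = np.linspace(0.0, 1.0, n_dense)
        speed = np.linalg.norm(self._dp(ts), axis=-1)
        self._ts = ts
        # cumulative arc length on the dense grid (trapezoid is ample at n=8193)
        self._s = np.concatenate([[0.0], cumulative_trapezoid(speed, ts)])

    def point(self, t):
        return self._p(np.asarray(t, dtype=float))

    def tangent(self, t):
        d = self._dp(np.asarray(t, dtype=float))
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    @property
    def total_length(self) -> float:
        return float(self._s[-1])

    def t_at_arclength(self, s):
        """Parameter value(s) at the given arc length(s)."""
        return np.interp(s, self._s, self._ts)

    def arclength_at(self, t):
        return np.interp(t, self._ts, self._s)

    def length_by_quadrature(self, t0: float = 0.0, t1: float = 1.0) -> float:
        """Adaptive quadrature of the parametric speed (independent check)."""
        val, _ = quad(lambda t: float(np.linalg.norm(self._dp(t))), t0, t1,
                      limit=400)
        return val

    def min_curvature_radius(self, n: int = 2000) -> float:
        """Smallest radius of curvature along the curve (finite differences)."""
        ts = np.linspace(0.0, 1.0, n)
        p = self.point(ts)
        d1 = np.gradient(p, ts, axis=0)
        d2 = np.gradient(d1, ts, axis=0)
        num = np.linalg.norm(np.cross(d1, d2), axis=1)
        den = np.linalg.norm(d1, axis=1) ** 3
        kappa = num / np.maximum(den, 1e-30)
        kmax = kappa.max()
        return float(1.0 / kmax) if kmax > 0 else np.inf


def _straight_curve(p0, p1) -> ParametricCurve:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0

    def p(t):
        return p0 + np.multiply.outer(np.asarray(t, float), d)

    def dp(t):
        shape = np.shape(np.asarray(t, float)) + (3,)
        return np.broadcast_to(d, shape).copy()

    return ParametricCurve(p, dp)


def _arc_curve(radius: float, angle_rad: float) -> ParametricCurve:
    def p(t):
        a = np.asarray(t, float) * angle_rad
        return np.stack([radius * np.cos(a), radius * np.sin(a),
                         np.zeros_like(a)], axis=-1)

    def dp(t):
        a = np.asarray(t, float) * angle_rad
        return np.stack([-radius * angle_rad * np.sin(a),
                         radius * angle_rad * np.cos(a),
                         np.zeros_like(a)], axis=-1)

    return ParametricCurve(p, dp)


def _helix_curve(radius: float, pitch: float, turns: float) -> ParametricCurve:
    # pitch = axial advance per full turn; c = pitch / 2pi
    w = 2.0 * np.pi * turns
    c = pitch / (2.0 * np.pi)

    def p(t):
        a = np.asarray(t, float) * w
        return np.stack([radius * np.cos(a), radius * np.sin(a), c * a], axis=-1)

    def dp(t):
        a = np.asarray(t, float) * w
        return np.stack([-radius * w * np.sin(a), radius * w * np.cos(a),
                         np.full_like(a, c * w)], axis=-1)

    return ParametricCurve(p, dp)


def _spline_curve(control_points) -> ParametricCurve:
    cp = np.asarray(control_points, float)
    if cp.ndim != 2 or cp.shape[0] < 4 or cp.shape[1] != 3:
        raise ValueError("spline needs >= 4 control points of dimension 3")
    chord = np.linalg.norm(np.diff(cp, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    cs = CubicSpline(u, cp, axis=0, bc_type="natural")
    dcs = cs.derivative()
    return ParametricCurve(lambda t: cs(t), lambda t: dcs(t))


# ---------------------------------------------------------------------------
# tube phantom
# ---------------------------------------------------------------------------

@dataclass
class TubePhantomSpec:
    """Specification of a synthetic tubular-vessel volume.

    ``radius_mm`` is either a single float (constant lumen radius) or a pair
    ``(r_start, r_end)`` describing a linear taper in arc length.
    ``landmark_arclengths`` are four strictly increasing fractions of the total
    centerline length where the named landmarks are placed.
    """

    centerline_kind: str = "helix"  # straight | arc | helix | spline
    length_mm: float = 50.0                      # straight
    arc_radius_mm: float = 30.0                  # arc
    arc_angle_deg: float = 90.0                  # arc
    helix_radius_mm: float = 8.0                 # helix
    helix_pitch_mm: float = 10.0                 # helix: axial advance / turn
    helix_turns: float = 1.0                     # helix
    control_points: np.ndarray | None = None     # spline
    radius_mm: float | tuple[float, float] = 1.5
    landmark_arclengths: tuple[float, float, float, float] = (0.0, 0.35, 0.7, 1.0)
    voxel_spacing: tuple[float, float, float] = TOF_SPACING
    background_intensity: float = 20.0
    foreground_intensity: float = 200.0
    blur_sigma_mm: float = 0.3
    noise_sd: float = 4.0
    margin_mm: float = 3.0
    #: the rendered tube continues tangentially past both curve ends, as a
    #: real vessel continues past its annotated landmarks (avoids artificial
    #: end caps at the branch endpoints)
    extend_mm: float = 3.0
    seed: int = 0

    def curve(self) -> ParametricCurve:
        k = self.centerline_kind
        if k == "straight":
            return _straight_curve((0, 0, 0), (0, 0, self.length_mm))
        if k == "arc":
            return _arc_curve(self.arc_radius_mm, np.deg2rad(self.arc_angle_deg))
        if k == "helix":
            return _helix_curve(self.helix_radius_mm, self.helix_pitch_mm,
                                self.helix_turns)
        if k == "spline":
            if self.control_points is None:
                raise ValueError("spline centerline requires control_points")
            return _spline_curve(self.control_points)
        raise ValueError(f"unknown centerline_kind {k!r}")

    def radius_at(self, s_frac):
        """Lumen radius (mm) at fractional arc length ``s_frac`` in [0, 1]."""
        if np.isscalar(self.radius_mm):
            return np.broadcast_to(float(self.radius_mm), np.shape(s_frac)).copy() \
                if np.ndim(s_frac) else float(self.radius_mm)
        r0, r1 = self.radius_mm
        return r0 + (r1 - r0) * np.asarray(s_frac, float)

    def validate(self) -> None:
        la = np.asarray(self.landmark_arclengths, float)
        if la.shape != (4,) or np.any(np.diff(la) <= 0):
            raise ValueError("landmark_arclengths must be 4 strictly increasing fractions")
        if la.min() < 0 or la.max() > 1:
            raise ValueError("landmark_arclengths must lie in [0, 1]")
        sp = np.asarray(self.voxel_spacing, float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError("voxel_spacing must be three positive numbers")
        rmin = np.min(self.radius_at(np.linspace(0, 1, 32)))
        if rmin <= 0:
            raise ValueError("lumen radius must stay positive")
        rmax = np.max(self.radius_at(np.linspace(0, 1, 32)))
        rc = self.curve().min_curvature_radius()
        if rc < 2.0 * rmax:
            raise ValueError(
                f"centerline radius of curvature {rc:.2f} mm is below twice "
                f"the lumen radius ({rmax:.2f} mm): the tube self-intersects "
                "and is not a valid vessel phantom")


@dataclass
class TubeTruth:
    """Closed-form ground truth accompanying a tube phantom."""

    total_length_mm: float
    #: arc length of each landmark from the start of the curve (mm)
    landmark_arclengths_mm: np.ndarray
    #: arc length between the first and last landmark — the "whole branch"
    branch_length_mm: float
    #: dense (s_mm, diameter_mm) profile over the full centerline
    profile_s_mm: np.ndarray
    profile_diameter_mm: np.ndarray
    resolvability_warning: bool
    curve: ParametricCurve

    def length_between(self, i: int, j: int) -> float:
        """Analytic arc length between landmarks i and j (0-based indices)."""
        a, b = sorted((i, j))
        return float(self.landmark_arclengths_mm[b] - self.landmark_arclengths_mm[a])

    def diameter_at_arclength(self, s_mm):
        return np.interp(s_mm, self.profile_s_mm, self.profile_diameter_mm)


def make_tube_phantom(spec: TubePhantomSpec) -> tuple[VoxelGrid, LandmarkSet, TubeTruth]:
    """Render a tube phantom and return (volume, landmarks, truth).

    The voxel lattice is axis-aligned with positive spacing and sized to the
    curve's bounding box plus a margin. A resolvability warning is set (not an
    error) when the minimum radius is below twice the coarsest voxel dimension.
    """
    spec.validate()
    curve = spec.curve()
    total = curve.total_length

    # dense centerline samples for distance queries, step ~ quarter of the
    # finest voxel dimension
    step = min(spec.voxel_spacing) / 4.0
    n = max(int(np.ceil(total / step)) + 1, 64)
    ts = curve.t_at_arclength(np.linspace(0.0, total, n))
    pts = curve.point(ts)
    s_frac = np.linspace(0.0, 1.0, n)
    radii = np.atleast_1d(spec.radius_at(s_frac)).astype(float)
    radii_core = radii.copy()

    # tangential extensions past both ends (constant end radius)
    if spec.extend_mm > 0:
        n_ext = max(int(np.ceil(spec.extend_mm / step)), 1)
        ext = np.arange(1, n_ext + 1)[:, None] * step
        t0, t1 = curve.tangent(0.0), curve.tangent(1.0)
        head = pts[0] - ext[::-1] * t0
        tail = pts[-1] + ext * t1
        pts = np.concatenate([head, pts, tail])
        radii = np.concatenate([np.full(n_ext, radii[0]), radii,
                                np.full(n_ext, radii[-1])])

    rmax = float(radii.max())
    lo = pts.min(axis=0) - (rmax + spec.margin_mm)
    hi = pts.max(axis=0) + (rmax + spec.margin_mm)
    spacing = np.asarray(spec.voxel_spacing, float)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 4)
    affine = axis_aligned_affine(spacing, origin=lo)

    grid_idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = grid_idx * spacing + lo
    tree = cKDTree(pts)
    dist, nearest = tree.query(world, workers=-1)
    # anti-aliased boundary: linear partial-volume ramp over one (finest)
    # voxel, so the rendered radius is not quantized to the lattice
    aa = float(spacing.min())
    frac = np.clip((radii[nearest] - dist) / aa + 0.5, 0.0, 1.0)
    vol = (spec.background_intensity
           + (spec.foreground_intensity - spec.background_intensity)
           * frac).reshape(shape).astype(np.float64)

    if spec.blur_sigma_mm > 0:
        vol = gaussian_filter(vol, sigma=spec.blur_sigma_mm / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    la = np.asarray(spec.landmark_arclengths, float)
    lm_s = la * total
    lm_pts = curve.point(curve.t_at_arclength(lm_s))
    landmarks = LandmarkSet(dict(zip(LANDMARK_NAMES, lm_pts)))

    warn = bool(np.min(radii) < 2.0 * spacing.max())
    if warn:
        warnings.warn("tube radius below ~2 voxels: diameter estimates may be "
                      "resolution-limited", stacklevel=2)

    prof_s = np.linspace(0.0, total, n)
    truth = TubeTruth(
        total_length_mm=total,
        landmark_arclengths_mm=lm_s,
        branch_length_mm=float(lm_s[-1] - lm_s[0]),
        profile_s_mm=prof_s,
        profile_diameter_mm=2.0 * radii_core,
        resolvability_warning=warn,
        curve=curve,
    )
    return VoxelGrid(vol, affine), landmarks, truth


def random_vessel_spec(seed: int, length_mm: float = 45.0,
                       lateral_sd_mm: float = 2.5,
                       radius_range_mm: tuple[float, float] = (1.2, 1.8),
                       min_curvature_radius_mm: float = 8.0) -> TubePhantomSpec:
    """A random, anatomically plausible curved-vessel spec (spline centerline).

    Control points march along one axis with a lateral random walk; draws are
    rejected until the minimum radius of curvature is at least
    ``min_curvature_radius_mm`` (real basilar arteries curve gently — a bend
    tighter than the lumen would self-intersect). Radius tapers linearly
    between two values drawn from ``radius_range_mm``. Deterministic per seed.
    """
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(64)):
        rng = np.random.default_rng(child)
        z = np.linspace(0.0, length_mm, 5)
        lateral = np.cumsum(rng.normal(0.0, lateral_sd_mm, (5, 2)), axis=0)
        cp = np.column_stack([lateral, z])
        r0, r1 = np.sort(rng.uniform(*radius_range_mm, 2))
        spec = TubePhantomSpec(centerline_kind="spline", control_points=cp,
                               radius_mm=(float(r0), float(r1)), seed=seed)
        if spec.curve().min_curvature_radius() >= min_curvature_radius_mm:
            return spec
    raise RuntimeError("could not draw a plausible vessel in 64 attempts")


# ---------------------------------------------------------------------------
# brain phantom
# ---------------------------------------------------------------------------

@dataclass
class LesionSeed:
    """A spherical lesion: world-mm center, radius, intended lobe and layer."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    lobe: str
    layer: int  # 1..4


@dataclass
class BrainPhantomSpec:
    """Nested-ellipsoid head phantom with lobar wedges and seeded lesions.

    Conventions: array axis 0 = left-right, axis 1 = posterior-anterior,
    axis 2 = inferior-superior. Lobe wedges partition the cortical shell by
    the sagittal-plane angle from the anterior direction: frontal (anterior),
    parietal (superior), occipital (posterior), other (inferior).
    """

    shape: tuple[int, int, int] = (72, 88, 72)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radii_mm: tuple[float, float, float] = (30.0, 38.0, 30.0)
    ventricle_radii_mm: tuple[float, float, float] = (9.0, 14.0, 9.0)
    cortex_shell_rel: float = 0.88  # shell = rho in (cortex_shell_rel, 1]
    lesions: list[LesionSeed] = field(default_factory=list)
    #: channel means: (csf, tissue, cortex, lesion)
    t1_means: tuple[float, float, float, float] = (30.0, 100.0, 70.0, 80.0)
    flair_means: tuple[float, float, float, float] = (20.0, 100.0, 90.0, 170.0)
    noise_sd: float = 8.0
    blur_sigma_mm: float = 0.5
    seed: int = 0


@dataclass
class BrainPhantom:
    t1: VoxelGrid
    flair: VoxelGrid
    lobes: VoxelGrid
    ventricle_mask: VoxelGrid
    cortex_mask: VoxelGrid
    brain_mask: VoxelGrid
    truth: list[dict]


def _ellipsoid_rho(world: np.ndarray, center: np.ndarray, radii) -> np.ndarray:
    return np.sqrt(np.sum(((world - center) / np.asarray(radii, float)) ** 2, axis=-1))


def lobe_of_direction(dy: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Wedge label from the sagittal-plane angle (y anterior, z superior)."""
    theta = np.degrees(np.arctan2(dz, dy))  # 0 = anterior, 90 = superior
    lab = np.full(np.shape(theta), LOBE_LABELS["other"], dtype=np.int16)
    lab[(theta > -45) & (theta <= 60)] = LOBE_LABELS["frontal"]
    lab[(theta > 60) & (theta <= 135)] = LOBE_LABELS["parietal"]
    lab[(theta > 135) | (theta <= -135)] = LOBE_LABELS["occipital"]
    return lab


def lesion_center_for(spec: BrainPhantomSpec, lobe: str, layer: int,
                      depth_jitter: float = 0.0) -> tuple[float, float, float]:
    """Convenience: a world-mm center inside the given lobe wedge at the
    mid-depth of the given layer (depth measured on the ellipsoidal axis)."""
    center = (np.asarray(spec.shape, float) - 1) / 2 * np.asarray(spec.spacing)
    ang = {"frontal": 0.0, "parietal": 90.0, "occipital": 180.0, "other": -90.0}[lobe]
    a = np.deg2rad(ang)
    direction = np.array([0.0, np.cos(a), np.sin(a)])
    d = (layer - 0.5) / 4.0 + depth_jitter
    # ellipsoid surface distances along this ray, then interpolate in depth
    vr = np.asarray(spec.ventricle_radii_mm, float)
    br = np.asarray(spec.brain_radii_mm, float) * spec.cortex_shell_rel
    r_v = 1.0 / np.sqrt(np.sum((direction / vr) ** 2))
    r_c = 1.0 / np.sqrt(np.sum((direction / br) ** 2))
    return tuple(center + direction * (r_v + d * (r_c - r_v)))


def make_brain_phantom(spec: BrainPhantomSpec) -> BrainPhantom:
    """Render the brain phantom; lesions are FLAIR-hyperintense spheres.

    Raises ``ValueError`` naming any lesion that does not lie strictly between
    the ventricular and (inner) cortical surfaces.
    """
    spacing = np.asarray(spec.spacing, float)
    affine = axis_aligned_affine(spacing)
    shape = tuple(spec.shape)
    center = (np.asarray(shape, float) - 1) / 2 * spacing

    idx = np.indices(shape).astype(float)
    world = np.moveaxis(idx, 0, -1) * spacing
    rho_b = _ellipsoid_rho(world, center, spec.brain_radii_mm)
    rho_v = _ellipsoid_rho(world, center, spec.ventricle_radii_mm)

    brain = rho_b <= 1.0
    ventricle = rho_v <= 1.0
    cortex = (rho_b > spec.cortex_shell_rel) & brain
    band = brain & ~ventricle & ~cortex

    dy = world[..., 1] - center[1]
    dz = world[..., 2] - center[2]
    lobes = np.where(cortex, lobe_of_direction(dy, dz), 0).astype(np.int16)

    csf, tissue, ctx, les_t1 = spec.t1_means
    t1 = np.zeros(shape)
    t1[brain] = tissue
    t1[cortex] = ctx
    t1[ventricle] = csf
    csf_f, tissue_f, ctx_f, les_fl = spec.flair_means
    flair = np.zeros(shape)
    flair[brain] = tissue_f
    flair[cortex] = ctx_f
    flair[ventricle] = csf_f

    truth = []
    for i, seed_ in enumerate(spec.lesions):
        c = np.asarray(seed_.center_mm, float)
        r = float(seed_.radius_mm)
        sphere = np.linalg.norm(world - c, axis=-1) <= r
        if not sphere.any():
            raise ValueError(f"lesion {i} ({seed_.lobe}/{seed_.layer}): empty on grid")
        if not np.all(band[sphere]):
            raise ValueError(
                f"lesion {i} ({seed_.lobe}/layer {seed_.layer}) leaves the "
                "band between ventricular and cortical surfaces")
        t1[sphere] = les_t1
        flair[sphere] = les_fl
        truth.append({
            "index": i, "center_mm": tuple(c), "radius_mm": r,
            "volume_mm3": 4.0 / 3.0 * np.pi * r ** 3,
            "volume_ml": 4.0 / 3.0 * np.pi * r ** 3 / 1000.0,
            "lobe": seed_.lobe, "layer": int(seed_.layer),
        })

    if spec.blur_sigma_mm > 0:
        sig = spec.blur_sigma_mm / spacing
        t1 = gaussian_filter(t1, sig)
        flair = gaussian_filter(flair, sig)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        t1 = t1 + rng.normal(0, spec.noise_sd, shape)
        flair = flair + rng.normal(0, spec.noise_sd, shape)

    g = lambda a, dt=np.float64: VoxelGrid(np.asarray(a, dtype=dt), affine)
    return BrainPhantom(
        t1=g(t1), flair=g(flair), lobes=g(lobes, np.int16),
        ventricle_mask=g(ventricle, np.uint8), cortex_mask=g(cortex, np.uint8),
        brain_mask=g(brain, np.uint8), truth=truth,
    )
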