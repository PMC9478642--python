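"""Synthetic decorated-filament scenes for training and benchmarking.

This module fabricates everything the picking/classification stages need:

* a synthetic decorated-protomer atomic model (pseudo-atoms; stand-in for a
  real actin+cross-linker asymmetric unit, labelled as such),
* 3D density volumes of decorated filaments (Gaussian-atom rendering),
* uniformly sampled two-filament bundle configurations and their exact
  filament-pose realisations (the inverse of the geometry measurement),
* orthographic projections with CTF corruption and white Gaussian noise,
* composed micrograph-scale scenes with per-pixel class labels and
  ground-truth picks, and
* on-disk training datasets with a fully reproducing manifest.

All randomness flows through explicit seeds; identical config + seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import BoxSizeError, ConfigError
from .formats import AtomicModel, Micrograph, VolumeMap
from .structmath import (
    FilamentPose,
    HelicalParams,
    RigidTransform,
    _axis_reference,
    rotation_about_axis,
)

import pandas as pd

# Label classes used by every mask in the package.
CLASS_BACKGROUND = 0
CLASS_SINGLE = 1
CLASS_BUNDLE2 = 2
CLASS_HIGHER = 3
N_CLASSES = 4

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------

@dataclass
class BundleConfig:
    """Ground-truth descriptor of one two-filament bridge.

    ``skew`` (out-of-plane tilt) and ``splay`` (in-plane rotation) are signed
    degrees; ``interfilament_distance`` and ``axial_offset`` are Angstrom;
    ``spins`` are the two filaments' azimuths; ``view`` is
    ``(tilt, psi, shift_x, shift_y)`` where tilt 0 is a top view (both
    filaments resolved in projection) and tilt 90 a side view (overlapping).
    """

    polarity: str = PARALLEL
    skew: float = 0.0
    splay: float = 0.0
    interfilament_distance: float = 150.0
    axial_offset: float = 0.0
    spins: tuple[float, float] = (0.0, 0.0)
    view: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.polarity not in (PARALLEL, ANTIPARALLEL):
            raise ConfigError(f"polarity must be parallel/antiparallel, got {self.polarity!r}")
        if not self.interfilament_distance > 0:
            raise ConfigError("interfilament_distance must be > 0")
        for name in ("skew", "splay"):
            v = getattr(self, name)
            if not -90 < v < 90:
                raise ConfigError(f"{name} must be in (-90, 90), got {v}")


@dataclass
class CTFParams:
    """Standard contrast-transfer-function parameters."""

    defocus_um: float = 1.5
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07

    def __post_init__(self) -> None:
        if not self.defocus_um > 0:
            raise ConfigError("defocus must be > 0")
        if not 0 <= self.amplitude_contrast <= 1:
            raise ConfigError("amplitude contrast must be in [0, 1]")


@dataclass
class SampleRanges:
    """Uniform sampling ranges for bundle configurations.

    Defaults bracket the measured bundle geometry: interfilament distance
    120-180 A (the per-particle means sit near 146-149 A), skew and splay
    within +-30 deg, spins and view angles over their full ranges.
    """

    interfilament_distance: tuple[float, float] = (120.0, 180.0)
    skew: tuple[float, float] = (-30.0, 30.0)
    splay: tuple[float, float] = (-30.0, 30.0)
    axial_offset: tuple[float, float] = (-13.75, 13.75)
    spin: tuple[float, float] = (0.0, 360.0)
    view_tilt: tuple[float, float] = (0.0, 90.0)
    view_psi: tuple[float, float] = (0.0, 360.0)
    view_shift: tuple[float, float] = (-10.0, 10.0)
    parallel_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.as_dict().items():
            if lo > hi:
                raise ConfigError(f"range {name}: min {lo} > max {hi}")
        if not 0 <= self.parallel_fraction <= 1:
            raise ConfigError("parallel_fraction must be in [0, 1]")

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("parallel_fraction")
        return d


# ---------------------------------------------------------------------------
# Synthetic protomer model
# ---------------------------------------------------------------------------

def make_protomer_model(seed: int = 0) -> AtomicModel:
    """A synthetic decorated-protomer pseudo-atom model.

    Stand-in for one actin protomer plus its bound cross-linker ABD (no real
    coordinates are shipped): a compact "actin" lobe near the filament axis
    and a smaller "ABD" lobe protruding radially and tilted toward the plus
    end. The axial tilt makes filament projections polar, which is what the
    polarity classifier keys on. Axis along +z, plus end toward +z, protomer
    azimuth 0 along +x.
    """
    rng = np.random.default_rng(seed)
    actin = rng.normal(scale=8.0, size=(70, 3)) + np.array([12.0, 0.0, 0.0])
    # ABD lobe: radially out at ~38 A, displaced toward the plus end, with an
    # arm slanting further plus-ward to break the projection's 2-fold symmetry
    abd = rng.normal(scale=5.0, size=(24, 3)) + np.array([38.0, 6.0, 8.0])
    arm = rng.normal(scale=3.0, size=(10, 3)) + np.array([30.0, 3.0, 20.0])
    xyz = np.vstack([actin, abd, arm])
    n = len(xyz)
    df = pd.DataFrame(
        {
            "chain": ["A"] * 70 + ["P"] * (n - 70),
            "resnum": np.arange(1, n + 1),
            "resname": ["GLY"] * n,
            "atom": ["CA"] * n,
            "element": ["C"] * n,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "b": 30.0,
            "occ": 1.0,
        }
    )
    return AtomicModel(df)


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

def _gaussian_splat(grid: np.ndarray, centers_vox: np.ndarray, weights: np.ndarray,
                    sigma_vox: float) -> None:
    """Accumulate isotropic 3D Gaussians (unit integral x weight) onto a grid."""
    half = max(2, int(np.ceil(4 * sigma_vox)))
    offs = np.arange(-half, half + 1)
    nz, ny, nx = grid.shape
    norm = (2 * np.pi * sigma_vox ** 2) ** -1.5
    for (cx, cy, cz), w in zip(centers_vox, weights):
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))
        if not (-half <= ix < nx + half and -half <= iy < ny + half and -half <= iz < nz + half):
            continue
        gz = np.exp(-((iz + offs - cz) ** 2) / (2 * sigma_vox ** 2))
        gy = np.exp(-((iy + offs - cy) ** 2) / (2 * sigma_vox ** 2))
        gx = np.exp(-((ix + offs - cx) ** 2) / (2 * sigma_vox ** 2))
        z0, z1 = max(iz - half, 0), min(iz + half + 1, nz)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        sz = gz[z0 - (iz - half): z1 - (iz - half)]
        sy = gy[y0 - (iy - half): y1 - (iy - half)]
        sx = gx[x0 - (ix - half): x1 - (ix - half)]
        grid[z0:z1, y0:y1, x0:x1] += (
            w * norm * sz[:, None, None] * sy[None, :, None] * sx[None, None, :]
        )


def filament_atoms(model: AtomicModel, helical: HelicalParams, n_protomers: int) -> np.ndarray:
    """All-atom coordinates of a filament: the protomer repeated under the
    helical symmetry (k'th copy rotated by k*twist about z, shifted k*rise),
    centered axially on the filament midpoint."""
    base = model.coords()
    mid = (n_protomers - 1) / 2.0
    parts = []
    for k in range(n_protomers):
        R = rotation_about_axis([0, 0, 1], k * helical.twist)
        parts.append(base @ R.T + np.array([0, 0, (k - mid) * helical.rise]))
    return np.vstack(parts)


def build_decorated_volume(model: AtomicModel, helical: HelicalParams | None = None,
                           n_protomers: int = 13, voxel_size: float = 4.4,
                           resolution: float = 12.0, box: int | None = None) -> VolumeMap:
    """Render a decorated filament as a sum of per-atom isotropic Gaussians.

    Each atom contributes a Gaussian of unit integral (weight 1 per
    pseudo-atom) with sigma tied to the nominal resolution
    (sigma = resolution / (2*sqrt(2 ln 2)), i.e. FWHM = resolution). The box
    is cubic, auto-sized to contain the filament plus a 4-sigma margin unless
    given; a box too small to contain the filament raises ``BoxSizeError``.
    The filament axis runs along z through the box center.
    """
    if helical is None:
        helical = HelicalParams()
    if n_protomers < 1:
        raise ConfigError("n_protomers must be >= 1")
    atoms = filament_atoms(model, helical, n_protomers)
    sigma = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    margin = 4.0 * sigma
    extent = 2 * (np.abs(atoms).max() + margin)
    need = int(np.ceil(extent / voxel_size))
    if box is None:
        box = need
    elif box < need:
        raise BoxSizeError(
            f"box {box} voxels too small: filament needs {need} at {voxel_size} A/voxel"
        )
    grid = np.zeros((box, box, box), dtype=np.float64)
    center = (box - 1) / 2.0
    centers_vox = atoms / voxel_size + center  # (x, y, z) in voxel units
    sigma_vox = sigma / voxel_size
    # per-atom weight 1: integral sum(data) * voxel^3 == n_atoms
    weights = np.ones(len(atoms)) / voxel_size ** 3
    _gaussian_splat(grid, centers_vox, weights, sigma_vox)
    return VolumeMap(grid.astype(np.float32), voxel_size)


# ---------------------------------------------------------------------------
# Bundle configuration sampling and realisation
# ---------------------------------------------------------------------------

def sample_bundle_config(rng: np.random.Generator | int,
                         ranges: SampleRanges | None = None) -> BundleConfig:
    """Draw one bundle configuration, each parameter i.i.d. uniform over its
    range, polarity Bernoulli(parallel_fraction)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if ranges is None:
        ranges = SampleRanges()
    u = lambda lo_hi: float(rng.uniform(lo_hi[0], lo_hi[1]))
    polarity = PARALLEL if rng.uniform() < ranges.parallel_fraction else ANTIPARALLEL
    return BundleConfig(
        polarity=polarity,
        skew=u(ranges.skew),
        splay=u(ranges.splay),
        interfilament_distance=u(ranges.interfilament_distance),
        axial_offset=u(ranges.axial_offset),
        spins=(u(ranges.spin), u(ranges.spin)),
        view=(u(ranges.view_tilt), u(ranges.view_psi),
              u(ranges.view_shift), u(ranges.view_shift)),
    )


def place_pair(config: BundleConfig, length: int = 13) -> tuple[FilamentPose, FilamentPose]:
    """Realise a bundle configuration as two filament poses in the bundle
    frame: filament A along +z through the origin; filament B's origin
    displaced by the interfilament distance along +x (plus the axial offset
    along z), its direction deviated from the ideal by splay (in the x-z
    plane, toward +x) then skew (out of plane, toward +y), and flipped for
    antiparallel bundles. Exact inverse of
    :func:`filbundle.bundlegeom.pair_geometry`.
    """
    sk = np.deg2rad(config.skew)
    sp = np.deg2rad(config.splay)
    dev = np.array([np.sin(sp) * np.cos(sk), np.sin(sk), np.cos(sp) * np.cos(sk)])
    sign = 1.0 if config.polarity == PARALLEL else -1.0
    pose_a = FilamentPose(np.zeros(3), np.array([0.0, 0.0, 1.0]), config.spins[0], length)
    origin_b = np.array([config.interfilament_distance, 0.0, config.axial_offset])
    pose_b = FilamentPose(origin_b, sign * dev, config.spins[1], length)
    return pose_a, pose_b


def pose_to_transform(pose: FilamentPose) -> RigidTransform:
    """Rigid transform taking reference-filament coordinates (axis along z
    through the origin, protomer-0 azimuth along the axis reference) to the
    posed filament's lab coordinates."""
    u = pose.direction
    e1 = _axis_reference(u)
    e2 = np.cross(u, e1)
    M = np.column_stack([e1, e2, u])  # maps z->u, x->e1
    R = M @ rotation_about_axis([0, 0, 1], pose.spin)
    return RigidTransform(R, pose.origin)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def view_rotation(tilt: float, psi: float) -> np.ndarray:
    """Scene rotation for a bundle view.

    The scene (bundle frame: filament axes near z, separation near x) is
    rotated so the axes lie in the image plane; ``tilt`` rolls the bundle
    about its own axis (0 = top view, separation in-plane; 90 = side view,
    filaments superimposed along the beam), ``psi`` spins the image in-plane.
    """
    return (
        rotation_about_axis([0, 0, 1], psi)
        @ rotation_about_axis([0, 1, 0], 90.0)
        @ rotation_about_axis([0, 0, 1], 90.0 - tilt)
    )


def project(volumes_and_poses, view_matrix: np.ndarray | None = None,
            pixel_size: float = 4.4, box: int = 128,
            shift: tuple[float, float] = (0.0, 0.0), order: int = 1,
            depth: int | None = None) -> Micrograph:
    """Orthographic projection of a scene of posed volumes along lab z.

    ``volumes_and_poses``: list of ``(VolumeMap, RigidTransform | FilamentPose
    | None)`` placing each volume in the scene frame (None = centered
    identity). The scene is rotated by ``view_matrix`` (identity if None) and
    line-integrated along z; the line integral carries units of density * A so
    integrated intensity is conserved:
    sum(pixels) * pixel^2 == sum(voxels) * voxel^3 for fully contained scenes.
    ``shift`` is an in-plane (x, y) shift in pixels, applied with subpixel
    interpolation of the stated ``order``.
    """
    if view_matrix is None:
        view_matrix = np.eye(3)
    if depth is None:
        depth = box
    out = np.zeros((box, box), dtype=np.float64)
    c_out = (np.array([depth, box, box]) - 1) / 2.0
    shift_vec = np.array([0.0, shift[1], shift[0]])  # (z, y, x) pixels
    for vol, pose in volumes_and_poses:
        if pose is None:
            t = RigidTransform.identity()
        elif isinstance(pose, FilamentPose):
            t = pose_to_transform(pose)
        else:
            t = pose
        # scene point for output sample s (z,y,x px): X = Rv^T . ((s - c_out - shift) * px)
        # volume voxel v = (R^T (X - trans)) / voxel + c_in   [xyz order]
        c_in = (np.array(vol.shape[::-1]) - 1) / 2.0  # (x, y, z) voxel center
        A_xyz = t.rotation.T @ view_matrix.T * (pixel_size / vol.voxel_size)
        # output sample in xyz pixel units relative to center
        P = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx<->xyz swap
        A_full = P @ A_xyz @ P  # acts on (z,y,x)
        b = (
            P @ (t.rotation.T @ (-t.translation) / vol.voxel_size)
            + P @ np.array(c_in)
            - A_full @ (c_out + shift_vec)
        )
        res = ndimage.affine_transform(
            vol.data.astype(np.float64), A_full, offset=b,
            output_shape=(depth, box, box), order=order, prefilter=order > 1,
        )
        out += res.sum(axis=0)
    out *= pixel_size  # line-integral step in Angstrom
    return Micrograph(out.astype(np.float32), pixel_size)


def project_bundle(volume: VolumeMap, config: BundleConfig, pixel_size: float = 4.4,
                   box: int = 128, order: int = 1) -> Micrograph:
    """Projection image of a two-filament bundle realised from its config."""
    pose_a, pose_b = place_pair(config)
    R = view_rotation(config.view[0], config.view[1])
    # center the pair: shift scene so the midpoint between axes projects to center
    mid = np.array([config.interfilament_distance / 2.0, 0.0, config.axial_offset / 2.0])
    mid_img = R @ (-mid) * (1.0 / pixel_size)
    shift = (config.view[2] / pixel_size + mid_img[0], config.view[3] / pixel_size + mid_img[1])
    return project([(volume, pose_a), (volume, pose_b)], R, pixel_size, box,
                   shift=shift, order=order)


# ---------------------------------------------------------------------------
# CTF and noise
# ---------------------------------------------------------------------------

def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    h = 6.62607015e-34
    m = 9.1093837015e-31
    e = 1.602176634e-19
    c = 2.99792458e8
    return h / np.sqrt(2 * m * e * v * (1 + e * v / (2 * m * c ** 2))) * 1e10


def ctf_2d(shape: tuple[int, int], pixel_size: float, ctf: CTFParams) -> np.ndarray:
    """CTF(s) = -[sqrt(1-A^2) sin chi(s) + A cos chi(s)] on the FFT grid,
    with chi(s) = pi lambda z s^2 - (pi/2) Cs lambda^3 s^4 (z > 0 underfocus).
    At s = 0 this equals -A (the amplitude-contrast term only)."""
    lam = electron_wavelength(ctf.voltage_kv)
    z = ctf.defocus_um * 1e4  # A
    cs = ctf.cs_mm * 1e7  # A
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    s2 = fy[:, None] ** 2 + fx[None, :] ** 2
    chi = np.pi * lam * z * s2 - 0.5 * np.pi * cs * lam ** 3 * s2 ** 2
    A = ctf.amplitude_contrast
    return -(np.sqrt(1 - A ** 2) * np.sin(chi) + A * np.cos(chi))


def corrupt(clean: Micrograph, ctf: CTFParams | None = None, snr: float = 0.2,
            rng: np.random.Generator | int = 0) -> Micrograph:
    """CTF-filter a clean projection and add white Gaussian noise.

    The noise variance is set so var(filtered signal) / var(noise) = snr over
    the whole frame. ``snr = inf`` returns the CTF-filtered image exactly.
    """
    if not snr > 0:
        raise ConfigError("snr must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    img = clean.data.astype(np.float64)
    if ctf is not None:
        img = np.real(np.fft.ifft2(np.fft.fft2(img) * ctf_2d(img.shape, clean.pixel_size, ctf)))
    if np.isinf(snr):
        return Micrograph(img.astype(np.float32), clean.pixel_size, clean.id)
    sigma = np.sqrt(img.var() / snr)
    noisy = img + rng.normal(scale=sigma, size=img.shape)
    return Micrograph(noisy.astype(np.float32), clean.pixel_size, clean.id)


# ---------------------------------------------------------------------------
# 2D scene composition
# ---------------------------------------------------------------------------

@dataclass
class SceneObject:
    kind: str                       # 'single' | 'bundle2' | 'higher'
    center: tuple[float, float]     # px (x, y)
    angle: float                    # in-plane axis angle, deg
    length: float                   # px
    config: BundleConfig | None = None
    n_filaments: int = 1


@dataclass
class SceneTruth:
    """Ground truth for one composed scene."""

    labels: np.ndarray                       # (ny, nx) uint8 class mask
    objects: list[SceneObject] = field(default_factory=list)
    picks: pd.DataFrame | None = None        # columns x, y, component
    bundle_configs: list[BundleConfig] = field(default_factory=list)
    n_failed_placements: int = 0


# transverse density profile of a projected decorated filament (Angstrom)
_CORE_SIGMA_A = 16.0
_DECOR_RADIUS_A = 38.0
_DECOR_SIGMA_A = 11.0
_DECOR_AMP = 0.45
HALF_WIDTH_A = 50.0      # label half-width around each filament axis
_MOD_PERIOD_A = 55.0     # axial decoration periodicity in projection
_MOD_DEPTH = 0.25


def _profile(r_ang: np.ndarray) -> np.ndarray:
    core = np.exp(-r_ang ** 2 / (2 * _CORE_SIGMA_A ** 2))
    dec = _DECOR_AMP * np.exp(-(np.abs(r_ang) - _DECOR_RADIUS_A) ** 2 / (2 * _DECOR_SIGMA_A ** 2))
    return core + dec


def _segment_fields(shape, p0: np.ndarray, p1: np.ndarray, margin: float):
    """(slices, t, r) of a bounding window around a segment: axial coordinate
    t (px, 0 at p0) and unsigned transverse distance r per pixel."""
    ny, nx = shape
    lo = np.floor(np.minimum(p0, p1)).astype(int) - int(np.ceil(margin))
    hi = np.ceil(np.maximum(p0, p1)).astype(int) + int(np.ceil(margin)) + 1
    x0, y0 = np.clip(lo, 0, [nx, ny])
    x1, y1 = np.clip(hi, 0, [nx, ny])
    if x1 <= x0 or y1 <= y0:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    v = p1 - p0
    L = np.linalg.norm(v)
    vhat = v / L
    wx, wy = xs - p0[0], ys - p0[1]
    t = wx * vhat[0] + wy * vhat[1]
    r = np.abs(wx * vhat[1] - wy * vhat[0])
    return (slice(y0, y1), slice(x0, x1)), t, r, L


def _render_segment(img: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                    pixel_size: float, phase: float = 0.0, amp: float = 1.0) -> None:
    """Draw one filament segment as an analytic projected ridge."""
    margin = HALF_WIDTH_A / pixel_size + 4 * _CORE_SIGMA_A / pixel_size
    fields = _segment_fields(img.shape, p0, p1, margin)
    if fields is None:
        return
    sl, t, r, L = fields
    inside_t = np.clip((t + 2) / 4.0, 0, 1) * np.clip((L - t + 2) / 4.0, 0, 1)  # soft ends
    modulation = 1.0 + _MOD_DEPTH * np.cos(
        2 * np.pi * (t * pixel_size) / _MOD_PERIOD_A + np.deg2rad(phase)
    )
    img[sl] += amp * _profile(r * pixel_size) * inside_t * modulation


def _stamp_band(labels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                half_width_px: float, label: int) -> None:
    """Stamp a class label over the band within half_width of a segment.
    Higher class values win on overlap (bundle2 over single, higher over both)."""
    fields = _segment_fields(labels.shape, p0, p1, half_width_px)
    if fields is None:
        return
    sl, t, r, L = fields
    region = (r <= half_width_px) & (t >= 0) & (t <= L)
    sub = labels[sl]
    sub[region & (sub < label)] = label


def _object_segments(obj: SceneObject, pixel_size: float) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Filament segments (p0, p1, phase) of a scene object, in pixels."""
    c = np.array(obj.center, float)
    a = np.deg2rad(obj.angle)
    axis = np.array([np.cos(a), np.sin(a)])
    perp = np.array([-np.sin(a), np.cos(a)])
    segs = []
    if obj.kind == "single":
        segs.append((c - axis * obj.length / 2, c + axis * obj.length / 2, 0.0))
    elif obj.kind == "bundle2":
        # symmetric in-plane splay about the bundle midline, so the midline
        # (where ground-truth picks go) is the straight center segment
        cfg = obj.config
        sep_px = cfg.interfilament_distance * np.cos(np.deg2rad(cfg.view[0])) / pixel_size
        sp = np.deg2rad(cfg.splay) / 2.0
        ax1 = np.array([np.cos(a - sp), np.sin(a - sp)])
        ax2 = np.array([np.cos(a + sp), np.sin(a + sp)])
        off = cfg.axial_offset / pixel_size
        half = obj.length / 2
        c1 = c - perp * sep_px / 2
        segs.append((c1 - ax1 * half, c1 + ax1 * half, cfg.spins[0]))
        c2 = c + perp * sep_px / 2 + axis * off
        segs.append((c2 - ax2 * half, c2 + ax2 * half, cfg.spins[1]))
    else:  # higher-order assembly, 3+ roughly parallel filaments
        n = obj.n_filaments
        sep_px = 150.0 / pixel_size
        for k in range(n):
            off = (k - (n - 1) / 2.0) * sep_px
            jitter = np.deg2rad((k % 2) * 3.0 - 1.5)
            axk = np.array([np.cos(a + jitter), np.sin(a + jitter)])
            ck = c + perp * off
            segs.append((ck - axk * obj.length / 2, ck + axk * obj.length / 2, 37.0 * k))
    return segs


_KIND_LABEL = {"single": CLASS_SINGLE, "bundle2": CLASS_BUNDLE2, "higher": CLASS_HIGHER}

# Scene-scale bundle sampling: relative tilts between bridged filaments stay
# small over micron lengths (repeated cross-linking constrains divergence to
# the bridge-span scale), so scenes cap skew/splay at +-8 deg. The wide
# +-30 deg defaults of SampleRanges describe per-particle pose variability.
SCENE_RANGES = SampleRanges(skew=(-8.0, 8.0), splay=(-8.0, 8.0))

# Class-average emulation: 2D classification aligns many particles, so the
# residual within-class geometry spread is modest and the usable averages are
# top-view-like (both tracks resolved).
CLASS_AVG_RANGES = SampleRanges(skew=(-12.0, 12.0), splay=(-12.0, 12.0),
                                view_tilt=(0.0, 25.0), view_shift=(-5.0, 5.0))


def make_class_averages(volume: VolumeMap, n: int, snr: float = 1.0,
                        seed: int = 0, ranges: SampleRanges | None = None,
                        pixel_size: float = 4.4, box: int = 128):
    """Synthetic two-filament class averages with known polarity.

    Yields ``(image, BundleConfig)`` pairs: a bundle projection at a sampled
    configuration plus white Gaussian noise at the requested variance-ratio
    snr (no CTF: class averages are aligned averages of many CTF-corrected
    particles). Polarity alternates deterministically 50/50.
    """
    if ranges is None:
        ranges = CLASS_AVG_RANGES
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cfg = sample_bundle_config(rng, ranges)
        cfg.polarity = PARALLEL if i % 2 == 0 else ANTIPARALLEL
        clean = project_bundle(volume, cfg, pixel_size, box)
        noisy = corrupt(clean, None, snr, rng)
        out.append((noisy.data, cfg))
    return out


def compose_scene(objects, shape: tuple[int, int] = (1024, 1024),
                  pixel_size: float = 4.4, min_separation: float = 40.0,
                  rng: np.random.Generator | int = 0,
                  ranges: SampleRanges | None = None,
                  length_px: tuple[float, float] = (300.0, 500.0),
                  pick_step: float = 50.0, max_tries: int = 200):
    """Compose a clean micrograph-scale scene with ground truth.

    ``objects`` is a list of object descriptors: the strings ``'single'``,
    ``'bundle2'``, ``'higher'`` or tuples ``('bundle2', BundleConfig)``.
    Objects are placed by rejection sampling so their label supports, dilated
    by ``min_separation`` pixels, do not overlap; objects that cannot be
    placed within ``max_tries`` attempts are dropped and counted in
    ``SceneTruth.n_failed_placements``. Ground-truth picks are laid every
    ``pick_step`` pixels along each two-filament bundle's centerline.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if ranges is None:
        ranges = SCENE_RANGES
    ny, nx = shape
    img = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)
    placed: list[SceneObject] = []
    configs: list[BundleConfig] = []
    picks_rows = []
    failed = 0
    half_px = HALF_WIDTH_A / pixel_size

    for spec in objects:
        if isinstance(spec, tuple):
            kind, cfg = spec
        else:
            kind, cfg = spec, None
        for _ in range(max_tries):
            length = rng.uniform(*length_px)
            angle = rng.uniform(0, 360)
            center = np.array([rng.uniform(0.1 * nx, 0.9 * nx), rng.uniform(0.1 * ny, 0.9 * ny)])
            obj = SceneObject(kind, tuple(center), angle, length)
            if kind == "bundle2":
                obj.config = cfg if cfg is not None else sample_bundle_config(rng, ranges)
            elif kind == "higher":
                obj.n_filaments = int(rng.integers(3, 5))
            segs = _object_segments(obj, pixel_size)
            # support test on a coarse grid of segment sample points
            ok = True
            clearance = half_px + min_separation
            for p0, p1, _ in segs:
                npts = max(2, int(np.linalg.norm(p1 - p0) / 8) + 1)
                for s in np.linspace(0, 1, npts):
                    p = p0 + s * (p1 - p0)
                    xi, yi = int(round(p[0])), int(round(p[1]))
                    y0, y1 = max(yi - int(clearance), 0), min(yi + int(clearance) + 1, ny)
                    x0, x1 = max(xi - int(clearance), 0), min(xi + int(clearance) + 1, nx)
                    if y1 <= y0 or x1 <= x0:
                        continue
                    if occupied[y0:y1, x0:x1].any():
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            # place it
            label = _KIND_LABEL[kind]
            # density from the individual filament segments; the class label
            # covers the whole object band (filled between the filaments of a
            # bundle, so the bundle midline is bundle2-labeled)
            a_rad = np.deg2rad(obj.angle)
            axis_v = np.array([np.cos(a_rad), np.sin(a_rad)])
            c_v = np.array(obj.center)
            if kind == "single":
                band_half = half_px
            elif kind == "bundle2":
                sep = obj.config.interfilament_distance * np.cos(
                    np.deg2rad(obj.config.view[0])) / pixel_size
                band_half = abs(sep) / 2 + half_px
            else:
                band_half = (obj.n_filaments - 1) / 2 * 150.0 / pixel_size + half_px
            _stamp_band(labels, c_v - axis_v * obj.length / 2,
                        c_v + axis_v * obj.length / 2, band_half, label)
            for p0, p1, phase in segs:
                _render_segment(img, p0, p1, pixel_size, phase)
                _stamp_band(labels, p0, p1, half_px, label)
                npts = max(2, int(np.linalg.norm(p1 - p0) / 4) + 1)
                for s in np.linspace(0, 1, npts):
                    p = p0 + s * (p1 - p0)
                    xi, yi = int(round(p[0])), int(round(p[1]))
                    y0, y1 = max(yi - int(half_px), 0), min(yi + int(half_px) + 1, ny)
                    x0, x1 = max(xi - int(half_px), 0), min(xi + int(half_px) + 1, nx)
                    occupied[y0:y1, x0:x1] = True
            placed.append(obj)
            if kind == "bundle2":
                configs.append(obj.config)
                comp = len(placed) - 1
                # picks along the bundle centerline
                a = np.deg2rad(obj.angle)
                axis = np.array([np.cos(a), np.sin(a)])
                c = np.array(obj.center)
                n_picks = int(np.floor(obj.length / pick_step))
                for k in range(n_picks):
                    t = (k + 0.5) * pick_step - obj.length / 2
                    p = c + axis * t
                    if 0 <= p[0] < nx and 0 <= p[1] < ny:
                        picks_rows.append({"x": p[0], "y": p[1], "component": comp})
            break
        else:
            failed += 1

    picks = pd.DataFrame(picks_rows, columns=["x", "y", "component"])
    truth = SceneTruth(labels=labels, objects=placed, picks=picks,
                       bundle_configs=configs, n_failed_placements=failed)
    return Micrograph(img.astype(np.float32), pixel_size), truth


def default_scene_objects(rng: np.random.Generator,
                          n_single: int = 3, n_bundle2: int = 3, n_higher: int = 1) -> list:
    objs = ["single"] * n_single + ["bundle2"] * n_bundle2 + ["higher"] * n_higher
    perm = rng.permutation(len(objs))
    return [objs[i] for i in perm]


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def make_training_patches(n_patches: int = 200, patch: int = 128, pixel_size: float = 4.4,
                          snr: float = 0.2, seed: int = 0,
                          ranges: SampleRanges | None = None,
                          defocus_range: tuple[float, float] = (0.8, 2.5)):
    """In-memory training triples (noisy, clean, labels) of small scenes.

    Each patch holds one or two randomly chosen objects so all four classes
    (background/single/bundle2/higher) are represented across the set.
    """
    rng = np.random.default_rng(seed)
    out = []
    kinds = ["single", "bundle2", "bundle2", "higher"]  # bundles oversampled
    for i in range(n_patches):
        n_obj = int(rng.integers(1, 3))
        objs = [kinds[rng.integers(len(kinds))] for _ in range(n_obj)]
        clean, truth = compose_scene(
            objs, shape=(patch, patch), pixel_size=pixel_size, min_separation=20.0,
            rng=rng, ranges=ranges, length_px=(patch * 0.8, patch * 1.6), max_tries=60,
        )
        ctf = CTFParams(defocus_um=float(rng.uniform(*defocus_range)))
        noisy = corrupt(clean, ctf, snr, rng)
        out.append((noisy.data, clean.data, truth.labels))
    return out


def emit_dataset(n_scenes: int, out_dir, seed: int = 0, shape=(1024, 1024),
                 pixel_size: float = 4.4, snr: float = 0.2,
                 ranges: SampleRanges | None = None,
                 n_single: int = 3, n_bundle2: int = 3, n_higher: int = 1,
                 defocus_range: tuple[float, float] = (0.8, 2.5)) -> dict:
    """Write a labeled scene dataset: per scene a noisy and a clean MRC
    micrograph, a label-mask MRC, a ground-truth pick table (CSV), and a YAML
    manifest recording every seed and parameter. Re-running
    :func:`emit_dataset` with the manifest's parameters reproduces the images
    bit for bit."""
    from . import formats

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ranges is None:
        ranges = SCENE_RANGES
    master = np.random.default_rng(seed)
    scene_seeds = [int(s) for s in master.integers(0, 2 ** 31 - 1, size=n_scenes)]
    manifest = {
        "seed": seed,
        "n_scenes": n_scenes,
        "shape": list(shape),
        "pixel_size": pixel_size,
        "snr": snr,
        "counts": {"single": n_single, "bundle2": n_bundle2, "higher": n_higher},
        "defocus_range": list(defocus_range),
        "ranges": {k: list(v) for k, v in ranges.as_dict().items()},
        "parallel_fraction": ranges.parallel_fraction,
        "scenes": [],
    }
    for i, sseed in enumerate(scene_seeds):
        rng = np.random.default_rng(sseed)
        objs = default_scene_objects(rng, n_single, n_bundle2, n_higher)
        clean, truth = compose_scene(objs, shape=shape, pixel_size=pixel_size,
                                     rng=rng, ranges=ranges)
        ctf = CTFParams(defocus_um=float(rng.uniform(*defocus_range)))
        noisy = corrupt(clean, ctf, snr, rng)
        stem = f"scene_{i:04d}"
        formats.write_micrograph(noisy, out_dir / f"{stem}_noisy.mrc")
        formats.write_micrograph(clean, out_dir / f"{stem}_clean.mrc")
        formats.write_map(VolumeMap(truth.labels[None].astype(np.float32), pixel_size),
                          out_dir / f"{stem}_labels.mrc")
        truth.picks.to_csv(out_dir / f"{stem}_picks.csv", index=False)
        manifest["scenes"].append({
            "index": i,
            "seed": sseed,
            "defocus_um": ctf.defocus_um,
            "n_objects_placed": len(truth.objects),
            "n_failed_placements": truth.n_failed_placements,
            "bundle_configs": [
                {"polarity": c.polarity, "skew": c.skew, "splay": c.splay,
                 "interfilament_distance": c.interfilament_distance,
                 "axial_offset": c.axial_offset, "spins": list(c.spins),
                 "view": list(c.view)}
                for c in truth.bundle_configs
            ],
        })
    manifest["hash"] = hashlib.sha256(
        yaml.safe_dump(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
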