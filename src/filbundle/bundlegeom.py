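"""Bundle-geometry analysis: the quantitative core of the pipeline.

Given the per-particle rigid poses of two bridged filaments (e.g. from
multibody refinement), this module measures the four descriptors of a
two-filament bridge — polarity, skew, splay, interfilament distance — plus
the bridge span across the cross-linking molecule, and summarizes their
distributions.

Common 3D frame (this package's definition)
-------------------------------------------
With filament A the reference: ẑ = A's plus-end direction; x̂ = the unit
component, perpendicular to ẑ, of the displacement from A's origin (body
center) to B's origin; ŷ = ẑ x x̂. Filament B's direction d̂ is flipped when
the bundle is antiparallel (sign of d̂·ẑ), so both polarities measure
deviation from their ideal. Then

* splay = signed angle between ẑ and the projection of d̂ on the x-z plane
  (positive toward +x̂) — the in-plane rotation;
* skew = signed elevation of d̂ out of the x-z plane (positive toward +ŷ)
  — the out-of-plane tilt;
* interfilament_distance = norm of the perpendicular displacement component
  (origin-referenced axis separation);
* axial_offset = displacement component along ẑ.

This construction is the exact inverse of
:func:`filbundle.synthgen.place_pair`, so simulated configurations round-trip
to machine precision. The minimum distance between the two infinite axis
lines is additionally reported as ``axis_min_distance`` (for exactly
antiparallel ideal bundles the two coincide; for skewed pairs the line-line
minimum is origin-independent but collapses to 0 for coplanar axes, which is
why the origin-referenced definition is the primary one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, SelectionError
from .formats import AtomicModel, PoseTable, VolumeMap
from .structmath import (
    FilamentPose,
    PlastinAnnotation,
    RigidTransform,
    euler_zyz_matrix,
)
from .synthgen import ANTIPARALLEL, PARALLEL

GEOMETRY_COLUMNS = ["particle", "polarity", "skew", "splay",
                    "interfilament_distance", "axial_offset",
                    "axis_min_distance", "degenerate"]


@dataclass
class BundleGeometry:
    """Measured descriptors of one two-filament bridge."""

    polarity: str
    skew: float
    splay: float
    interfilament_distance: float
    axial_offset: float
    bridge_span: float | None = None
    axis_min_distance: float | None = None
    degenerate: bool = False


@dataclass
class GeometrySummary:
    """Per-parameter mean/SD/n, histograms and the correlation matrix."""

    n: int
    mean: dict
    sd: dict
    histograms: dict
    correlation: pd.DataFrame
    constant_columns: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pair geometry
# ---------------------------------------------------------------------------

def pair_geometry(pose_a: FilamentPose, pose_b: FilamentPose,
                  degenerate_tol: float = 1e-9) -> BundleGeometry:
    """Measure the bundle geometry of two filament poses (see module docs).

    Exactly coincident axes are flagged degenerate with distance and angles 0.
    """
    z = pose_a.direction
    delta = pose_b.origin - pose_a.origin
    axial = float(delta @ z)
    perp = delta - axial * z
    dist = float(np.linalg.norm(perp))

    d = pose_b.direction
    dz = float(d @ z)
    polarity = PARALLEL if dz >= 0 else ANTIPARALLEL
    dhat = d if dz >= 0 else -d

    if dist < degenerate_tol:
        # coincident or axially-stacked axes: frame undefined; put any
        # direction deviation into splay via the deviation's own azimuth
        dev = dhat - (dhat @ z) * z
        if np.linalg.norm(dev) < degenerate_tol:
            return BundleGeometry(polarity, 0.0, 0.0, dist, axial,
                                  axis_min_distance=0.0, degenerate=True)
        x = dev / np.linalg.norm(dev)
        degenerate = True
    else:
        x = perp / dist
        degenerate = False
    y = np.cross(z, x)

    splay = float(np.degrees(np.arctan2(dhat @ x, dhat @ z)))
    skew = float(np.degrees(np.arcsin(np.clip(dhat @ y, -1.0, 1.0))))
    return BundleGeometry(polarity, skew, splay, dist, axial,
                          axis_min_distance=_line_min_distance(pose_a, pose_b),
                          degenerate=degenerate)


def _line_min_distance(pose_a: FilamentPose, pose_b: FilamentPose) -> float:
    """Shortest distance between the two infinite axis lines."""
    n = np.cross(pose_a.direction, pose_b.direction)
    delta = pose_b.origin - pose_a.origin
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # parallel axes
        perp = delta - (delta @ pose_a.direction) * pose_a.direction
        return float(np.linalg.norm(perp))
    return float(abs(delta @ (n / nn)))


# ---------------------------------------------------------------------------
# Bridge span
# ---------------------------------------------------------------------------

def bridge_span(model: AtomicModel, annotation: PlastinAnnotation | None = None,
                plastin_chain: str | None = None, cutoff: float = 4.0,
                filament_of: dict[str, int] | None = None) -> float:
    """Distance across a bridging cross-linker molecule.

    Identifies the actin protomer (chain) contacting the CH1-side
    actin-binding surface and the protomer contacting the CH3-side surface
    (heavy-atom distance <= ``cutoff`` A; the most-contacted protomer wins)
    and returns the distance between the two protomers' Cα centroids.

    ``plastin_chain`` defaults to the single chain containing the annotated
    CH3 range. ``filament_of`` optionally maps actin chain ids to filament
    ids; when given, the two anchor protomers must belong to different
    filaments.
    """
    if annotation is None:
        annotation = PlastinAnnotation()
    if plastin_chain is None:
        lo, hi = annotation.domains["CH3"]
        candidates = [
            ch for ch in model.chains
            if ((model.chain_table(ch)["resnum"] >= lo)
                & (model.chain_table(ch)["resnum"] <= hi)).any()
        ]
        if len(candidates) != 1:
            raise SelectionError(
                f"cannot identify a unique cross-linker chain (candidates {candidates}); "
                "pass plastin_chain explicitly"
            )
        plastin_chain = candidates[0]

    actin_chains = [ch for ch in model.chains if ch != plastin_chain]
    if len(actin_chains) < 2:
        raise SelectionError("bridge model must contain >= 2 actin protomer chains")

    def anchor(domain: str) -> str:
        abs_xyz = model.coords(chain=plastin_chain, resnums=annotation.domains[domain])
        if not len(abs_xyz):
            raise SelectionError(f"no atoms in {domain} range on chain {plastin_chain}")
        tree = cKDTree(abs_xyz)
        counts = {}
        for ch in actin_chains:
            xyz = model.coords(chain=ch)
            hits = tree.query_ball_point(xyz, r=cutoff)
            counts[ch] = int(sum(1 for h in hits if h))
        best = max(counts, key=counts.get)
        if counts[best] == 0:
            raise SelectionError(f"{domain} contacts no actin protomer within {cutoff} A")
        return best

    prot1 = anchor("CH1")
    prot2 = anchor("CH3")
    if prot1 == prot2:
        raise SelectionError("CH1 and CH3 contact the same protomer; not a bridge")
    if filament_of is not None and filament_of.get(prot1) == filament_of.get(prot2):
        raise SelectionError("CH1 and CH3 anchor protomers lie on the same filament")
    c1 = model.coords(chain=prot1, atom="CA").mean(axis=0)
    c2 = model.coords(chain=prot2, atom="CA").mean(axis=0)
    return float(np.linalg.norm(c2 - c1))


# ---------------------------------------------------------------------------
# Multibody pose ingestion
# ---------------------------------------------------------------------------

@dataclass
class BodyReference:
    """A body's reference filament pose in the consensus frame, plus the
    rotation center used by the multibody poses (the body center)."""

    pose: FilamentPose
    center: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float).reshape(3)


def body_transform(rot: float, tilt: float, psi: float,
                   translation, center) -> RigidTransform:
    """Lab-frame rigid transform of one body row: rotation (ZYZ intrinsic,
    degrees) about the body center, then translation (A)."""
    R = euler_zyz_matrix(rot, tilt, psi)
    center = np.asarray(center, float)
    t = np.asarray(translation, float) + center - R @ center
    return RigidTransform(R, t)


def poses_from_bodies(particle_rows: pd.DataFrame,
                      body_refs: dict[int, BodyReference]) -> tuple[FilamentPose, FilamentPose]:
    """Compose each body's per-particle pose with its reference filament pose
    to yield lab-frame filament poses. Expects exactly the two bodies of
    ``body_refs`` present in ``particle_rows``."""
    poses = []
    for body_id in sorted(body_refs):
        ref = body_refs[body_id]
        row = particle_rows[particle_rows["body"] == body_id]
        if len(row) != 1:
            raise SelectionError(f"particle lacks a unique row for body {body_id}")
        row = row.iloc[0]
        t = body_transform(row["rot"], row["tilt"], row["psi"],
                           [row["ox"], row["oy"], row.get("oz", 0.0)], ref.center)
        poses.append(ref.pose.transformed(t))
    if len(poses) != 2:
        raise SelectionError(f"need exactly 2 bodies, got {len(poses)}")
    return poses[0], poses[1]


def per_particle_geometry(table: PoseTable,
                          body_refs: dict[int, BodyReference]) -> pd.DataFrame:
    """One geometry row per particle (columns ``GEOMETRY_COLUMNS`` plus
    ``error``); per-particle failures are recorded, not fatal."""
    rows = []
    for pid in table.particle_ids:
        rec = {"particle": pid, "error": ""}
        try:
            pa, pb = poses_from_bodies(table.particle(pid), body_refs)
            g = pair_geometry(pa, pb)
            rec.update(polarity=g.polarity, skew=g.skew, splay=g.splay,
                       interfilament_distance=g.interfilament_distance,
                       axial_offset=g.axial_offset,
                       axis_min_distance=g.axis_min_distance,
                       degenerate=g.degenerate)
        except Exception as exc:  # recorded per particle
            rec["error"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rigid-body docking
# ---------------------------------------------------------------------------

_PZYX = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)


def _resample(template: VolumeMap, target_shape, voxel: float,
              transform: RigidTransform, order: int = 1,
              source: np.ndarray | None = None) -> np.ndarray:
    """Template density resampled on the target grid after a rigid motion of
    the template (rotation about the template/box center, translation in A).
    ``source`` may hold a pre-spline-filtered copy of the template data (used
    with order 3 to avoid re-filtering on every call)."""
    c_t = (np.array(template.shape[::-1]) - 1) / 2.0 * template.voxel_size
    c_o = (np.array(target_shape[::-1]) - 1) / 2.0 * voxel
    A = _PZYX @ transform.rotation.T @ _PZYX * (voxel / template.voxel_size)
    # template voxel = R^T (x_out - c_o - t) / v_t + c_t / v_t
    b_xyz = (transform.rotation.T @ (-c_o - transform.translation) + c_t) / template.voxel_size
    src = template.data.astype(np.float64) if source is None else source
    return ndimage.affine_transform(src, A, offset=_PZYX @ b_xyz,
                                    output_shape=target_shape, order=order,
                                    prefilter=(order > 1 and source is None))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def dock_model_into_map(template: VolumeMap, target: VolumeMap,
                        initial: RigidTransform | None = None,
                        rot_range: float = 10.0, rot_step: float = 5.0,
                        trans_range: float = 10.0,
                        correlation_floor: float = 0.2):
    """Rigid-body docking of a template density into a target map.

    Maximizes the real-space normalized cross-correlation over a local search
    around ``initial`` (identity if None): a coarse grid over rotation offsets
    (three axes, ±``rot_range`` deg in ``rot_step`` steps) with the best
    translation found by FFT cross-correlation (capped at ±``trans_range`` A),
    followed by Powell refinement of all six parameters on a cubic-spline
    resampling of the template, reaching sub-voxel / sub-degree precision.
    Returns ``(RigidTransform, correlation, low_confidence)``.
    """
    from scipy.spatial.transform import Rotation

    if initial is None:
        initial = RigidTransform.identity()
    tgt = target.data.astype(np.float64)
    tgt0 = tgt - tgt.mean()
    tgt_norm = np.sqrt((tgt0 * tgt0).sum())
    voxel = target.voxel_size
    max_shift_vox = trans_range / voxel

    steps = np.arange(-rot_range, rot_range + 1e-9, rot_step)
    F_tgt = np.fft.rfftn(tgt0)
    nz, ny, nx = tgt.shape
    fz = np.fft.fftfreq(nz, 1.0 / nz)
    fy = np.fft.fftfreq(ny, 1.0 / ny)
    fx = np.fft.fftfreq(nx, 1.0 / nx)
    shift_mask = (
        (np.abs(fz)[:, None, None] <= max_shift_vox)
        & (np.abs(fy)[None, :, None] <= max_shift_vox)
        & (np.abs(fx)[None, None, :] <= max_shift_vox)
    )

    def best_shift(density: np.ndarray):
        d0 = density - density.mean()
        cc = np.fft.irfftn(F_tgt * np.conj(np.fft.rfftn(d0)), s=tgt.shape,
                           axes=(0, 1, 2))
        cc_m = np.where(shift_mask, cc, -np.inf)
        idx = np.unravel_index(np.argmax(cc_m), cc.shape)
        shift_vox = np.array([fz[idx[0]], fy[idx[1]], fx[idx[2]]])
        d_norm = np.sqrt((d0 * d0).sum())
        score = cc[idx] / (tgt_norm * d_norm) if d_norm > 0 else 0.0
        return shift_vox[::-1] * voxel, float(score)  # (x, y, z) A

    best = (-np.inf, None, None)
    for ax in steps:
        for ay in steps:
            for az in steps:
                dR = Rotation.from_euler("xyz", [ax, ay, az], degrees=True).as_matrix()
                R = dR @ initial.rotation
                dens = _resample(template, tgt.shape, voxel,
                                 RigidTransform(R, initial.translation))
                shift, score = best_shift(dens)
                if score > best[0]:
                    best = (score, R, initial.translation + shift)

    _, R0, t0 = best
    rv0 = Rotation.from_matrix(R0).as_rotvec(degrees=True)
    spline = ndimage.spline_filter(template.data.astype(np.float64), order=3)

    def neg_ncc(params):
        R = Rotation.from_rotvec(params[:3], degrees=True).as_matrix()
        dens = _resample(template, tgt.shape, voxel,
                         RigidTransform(R, params[3:]), order=3, source=spline)
        return -_ncc(dens, tgt)

    res = minimize(neg_ncc, np.concatenate([rv0, t0]), method="Powell",
                   options={"xtol": 2e-3, "ftol": 1e-9, "maxiter": 6})
    R = Rotation.from_rotvec(res.x[:3], degrees=True).as_matrix()
    t = res.x[3:]
    corr = -res.fun
    return RigidTransform(R, t), float(corr), bool(corr < correlation_floor)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(table: pd.DataFrame, bins: int = 60,
              columns: list[str] | None = None) -> GeometrySummary:
    """Mean, sample SD (n-1 denominator), n, histograms and the Pearson
    correlation matrix over the numeric geometry columns. Constant columns
    get SD 0 and NaN correlations, and are listed in ``constant_columns``."""
    if len(table) < 2:
        raise DegenerateGeometryError(f"summarize needs >= 2 rows, got {len(table)}")
    if columns is None:
        columns = [c for c in ["skew", "splay", "interfilament_distance",
                               "bridge_span", "axial_offset"]
                   if c in table.columns]
        if not columns:
            columns = [c for c in table.columns
                       if pd.api.types.is_numeric_dtype(table[c])]
    data = table[columns].astype(float)
    n = len(data)
    mean = {c: float(data[c].mean()) for c in columns}
    sd = {c: float(data[c].std(ddof=1)) for c in columns}
    constant = [c for c in columns if sd[c] == 0.0]
    hists = {}
    for c in columns:
        counts, edges = np.histogram(data[c].to_numpy(), bins=bins)
        hists[c] = (counts, edges)
    corr = data.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return GeometrySummary(n=n, mean=mean, sd=sd, histograms=hists,
                           correlation=corr, constant_columns=constant)
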