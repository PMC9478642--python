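"""Rigid-body superposition and structural measurements.

This module provides the geometric primitives used everywhere else: Kabsch
superposition, rotation-angle extraction, hinge ("domain swing") measurements
between two conformations, landmark displacements, orientation-vector angles,
end-to-end distances across unresolved linker segments, and least-squares
fitting of a helical filament axis through protomer centroids.

Angle conventions: swings and vector angles are reported as unsigned
magnitudes in degrees; signed conventions live in :mod:`filbundle.bundlegeom`.
All superpositions here use Cα atoms selected by residue range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SelectionError
from .formats import AtomicModel

__all__ = [
    "RigidTransform",
    "PlastinAnnotation",
    "HelicalParams",
    "FilamentPose",
    "superpose",
    "rotation_angle",
    "rotation_about_axis",
    "euler_zyz_matrix",
    "domain_swing",
    "atom_displacement",
    "orientation_vector_angle",
    "linker_gap",
    "fit_filament_axis",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (R proper orthogonal, t in Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise DegenerateGeometryError(
                f"rotation determinant {np.linalg.det(self.rotation):.8f} != +1"
            )
        resid = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if resid > 1e-6:
            raise DegenerateGeometryError(f"rotation orthogonality residual {resid:.2e}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


_DEFAULT_DOMAINS = {
    # Sequence ranges (inclusive). The linker lengths (CH1-2: 28 residues at
    # 240-269, CH2-3: 20 residues, CH3-4: 7 residues) and the modeled ABD2
    # region 388-630 are fixed by the structures; the remaining CHD boundaries
    # are approximate defaults and fully overridable in configuration.
    "CH1": (10, 239),
    "linker12": (240, 269),
    "CH2": (270, 374),
    "linker23": (375, 394),
    "CH3": (395, 510),
    "linker34": (511, 517),
    "CH4": (518, 630),
}

_DEFAULT_LANDMARKS = {
    "I309": 309,   # CH2 orientation vector start
    "P363": 363,   # CH2 orientation vector end
    "D332": 332,   # CH2 displacement marker
    "W390": 390,   # CH2-3 linker docking residue
    "F191": 191,   # ABS1 (CH1 actin-binding site)
    "R594": 594,   # CH4, CH1-CH4 auto-inhibition interface
    "R595": 595,
}


@dataclass
class PlastinAnnotation:
    """Residue landmarks of T-plastin's actin-binding core.

    Domain ranges for the four calponin-homology domains (CH1-CH4) and the
    three inter-domain linkers, plus individual marker residues. Only the
    linker lengths and the modeled ABD2 range (388-630) are pinned by the
    structures; CHD boundaries default to reasonable values and should be
    overridden from configuration when exact boundaries are known.
    """

    domains: dict = field(default_factory=lambda: dict(_DEFAULT_DOMAINS))
    landmarks: dict = field(default_factory=lambda: dict(_DEFAULT_LANDMARKS))
    modeled_postbound: tuple[int, int] = (388, 630)

    def __post_init__(self) -> None:
        order = ["CH1", "linker12", "CH2", "linker23", "CH3", "linker34", "CH4"]
        prev_end = -(10 ** 9)
        for name in order:
            lo, hi = self.domains[name]
            if lo > hi:
                raise DegenerateGeometryError(f"domain {name}: start {lo} > end {hi}")
            if lo <= prev_end:
                raise DegenerateGeometryError(f"domain {name} overlaps or is out of order")
            prev_end = hi

    def linker_length(self, name: str) -> int:
        lo, hi = self.domains[name]
        return hi - lo + 1


@dataclass
class HelicalParams:
    """Helical symmetry of a filament: rise (A) and twist (deg) per subunit.

    Defaults are canonical F-actin values (rise 27.5 A, left-handed twist
    -166.7 deg per protomer); both are configurable.
    """

    rise: float = 27.5
    twist: float = -166.7

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise DegenerateGeometryError(f"rise must be > 0, got {self.rise}")
        if abs(self.twist) > 180:
            raise DegenerateGeometryError(f"|twist| must be <= 180, got {self.twist}")


@dataclass
class FilamentPose:
    """Rigid placement of one helical filament in the lab frame.

    ``origin`` is a point on the axis, ``direction`` the unit vector toward
    the filament plus end, ``spin`` the azimuth (deg) of protomer 0 about the
    axis relative to a fixed reference perpendicular, and ``length`` the
    number of protomers.
    """

    origin: np.ndarray
    direction: np.ndarray
    spin: float = 0.0
    length: int = 13

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise DegenerateGeometryError("filament direction has zero length")
            self.direction = self.direction / n
        if self.length < 3:
            raise DegenerateGeometryError(f"filament length must be >= 3, got {self.length}")

    def spin_vector(self) -> np.ndarray:
        """Unit vector perpendicular to the axis at azimuth ``spin``."""
        e1 = _axis_reference(self.direction)
        e2 = np.cross(self.direction, e1)
        a = np.deg2rad(self.spin)
        return np.cos(a) * e1 + np.sin(a) * e2

    def transformed(self, t: RigidTransform) -> "FilamentPose":
        """The pose after a rigid lab-frame motion (spin re-expressed in the
        new axis reference frame)."""
        origin = t.apply(self.origin)
        direction = t.rotation @ self.direction
        v = t.rotation @ self.spin_vector()
        e1 = _axis_reference(direction)
        e2 = np.cross(direction, e1)
        spin = np.degrees(np.arctan2(v @ e2, v @ e1)) % 360.0
        return FilamentPose(origin, direction, spin, self.length)


def _axis_reference(direction: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``direction`` (azimuth 0).

    Uses lab x̂ projected off the axis; falls back to ŷ for near-x axes.
    """
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - (ref @ direction) * direction
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, reflections disallowed).

    Returns the proper rigid transform minimizing ||R·mobile + t - target||
    and the post-fit RMSD. Requires n >= 3 paired, non-collinear points.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError(
            f"paired (n,3) sets required, got {mobile.shape} vs {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    A, B = mobile - mc, target - tc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    # collinear points leave the rotation about the line undetermined
    if S[1] <= max(1e-9 * max(S[0], 1.0), 1e-12):
        raise DegenerateGeometryError("point set is collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def rotation_angle(t: RigidTransform | np.ndarray) -> float:
    """Axis-angle magnitude of a rotation, in degrees, in [0, 180].

    Quaternion-based (numerically stable near 0 and 180, where the trace
    formula loses precision)."""
    R = t.rotation if isinstance(t, RigidTransform) else np.asarray(t, float)
    return float(np.degrees(Rotation.from_matrix(R).magnitude()))


def rotation_about_axis(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(degrees) * axis).as_matrix()


def euler_zyz_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Intrinsic ZYZ Euler rotation matrix from angles in degrees (the STAR
    dialect used throughout)."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# Model-level measurements
# ---------------------------------------------------------------------------

def _ca_coords(model: AtomicModel, selection) -> np.ndarray:
    """Cα coordinates for a selection: (chain, (lo, hi)) or list of such."""
    if isinstance(selection, tuple) and len(selection) == 2 and isinstance(selection[0], str):
        selection = [selection]
    parts = []
    for chain, resrange in selection:
        xyz = model.coords(chain=chain, resnums=resrange, atom="CA")
        if len(xyz):
            parts.append(xyz)
    if not parts:
        raise SelectionError(f"selection {selection!r} matched no Cα atoms")
    return np.vstack(parts)


def _align(model_a: AtomicModel, model_b: AtomicModel, align_selection) -> RigidTransform:
    ca_a = _ca_coords(model_a, align_selection)
    ca_b = _ca_coords(model_b, align_selection)
    if len(ca_a) != len(ca_b):
        raise SelectionError(
            f"align selection sizes differ: {len(ca_a)} vs {len(ca_b)} Cα atoms"
        )
    t, _ = superpose(ca_b, ca_a)  # move B onto A
    return t


def domain_swing(model_a: AtomicModel, model_b: AtomicModel,
                 align_selection, measure_selection) -> float:
    """Hinge rotation (deg) of ``measure_selection`` between two conformations
    after removing the rigid motion of ``align_selection``.

    Superposes B onto A on the align selection, then reports the rotation
    magnitude of the residual superposition of the measure selection.
    """
    t_align = _align(model_a, model_b, align_selection)
    meas_a = _ca_coords(model_a, measure_selection)
    meas_b = t_align.apply(_ca_coords(model_b, measure_selection))
    if len(meas_a) != len(meas_b):
        raise SelectionError("measure selection sizes differ between models")
    t_meas, _ = superpose(meas_b, meas_a)
    return rotation_angle(t_meas)


def atom_displacement(model_a: AtomicModel, model_b: AtomicModel,
                      align_selection, atom_spec) -> float:
    """Distance (A) between one named atom's positions after alignment.

    ``atom_spec`` is ``(chain, resnum, atom_name)``.
    """
    chain, resnum, name = atom_spec
    pa = model_a.coords(chain=chain, resnums=resnum, atom=name)
    pb = model_b.coords(chain=chain, resnums=resnum, atom=name)
    if len(pa) != 1 or len(pb) != 1:
        raise SelectionError(f"atom {atom_spec!r} not uniquely present in both models")
    t_align = _align(model_a, model_b, align_selection)
    return float(np.linalg.norm(t_align.apply(pb)[0] - pa[0]))


def orientation_vector_angle(model_a: AtomicModel, model_b: AtomicModel,
                             align_selection, from_res, to_res) -> float:
    """Angle (deg, [0,180]) between the Cα(from)→Cα(to) vectors of two models
    after aligning on ``align_selection``.

    ``from_res``/``to_res`` are ``(chain, resnum)`` pairs (e.g. the I309→P363
    CH2 orientation vector).
    """
    def vec(model):
        a = model.coords(chain=from_res[0], resnums=from_res[1], atom="CA")
        b = model.coords(chain=to_res[0], resnums=to_res[1], atom="CA")
        if len(a) != 1 or len(b) != 1:
            raise SelectionError(f"residues {from_res}/{to_res} lack unique Cα")
        return b[0] - a[0]

    va = vec(model_a)
    t_align = _align(model_a, model_b, align_selection)
    vb = t_align.rotation @ vec(model_b)
    cos = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def linker_gap(model: AtomicModel, chain: str, gap: tuple[int, int] | None = None) -> float:
    """End-to-end distance (A) across an unresolved chain segment.

    Measures between the Cα of the last resolved residue before a numbering
    gap and the Cα of the first resolved residue after it. With ``gap=None``
    the chain must contain exactly one gap; otherwise pass the flanking
    residue pair as reported by :meth:`AtomicModel.gaps`.
    """
    gaps = model.gaps(chain)
    if gap is None:
        if len(gaps) != 1:
            raise SelectionError(
                f"chain {chain}: expected exactly one gap, available gaps: {gaps}"
            )
        gap = gaps[0]
    elif tuple(gap) not in [tuple(g) for g in gaps]:
        raise SelectionError(f"chain {chain}: no gap {gap}; available gaps: {gaps}")
    a = model.coords(chain=chain, resnums=gap[0], atom="CA")
    b = model.coords(chain=chain, resnums=gap[1], atom="CA")
    if len(a) != 1 or len(b) != 1:
        raise SelectionError(f"gap-flanking residues {gap} lack unique Cα in chain {chain}")
    return float(np.linalg.norm(b[0] - a[0]))


# ---------------------------------------------------------------------------
# Filament axis fitting
# ---------------------------------------------------------------------------

def fit_filament_axis(points: np.ndarray, helical: HelicalParams | None = None):
    """Fit the central axis of a helical filament through protomer centroids.

    ``points`` are >= 3 protomer centroids ordered minus end → plus end. The
    axis is the line minimizing the variance of point-to-line distances (all
    helix points sit at one radius); its direction is signed so it points
    toward the plus end given the ordering. Returns a
    :class:`FilamentPose` (origin at the projected centroid, spin from the
    first protomer's azimuth) plus a diagnostics dict with the fit residual
    (RMS radius deviation, A), estimated rise (A) and twist (deg) per subunit,
    the mean helix radius, and a ``degenerate`` warning flag set when the fit
    residual stays above threshold.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 centroid points, got shape {pts.shape}")
    if helical is None:
        helical = HelicalParams()

    center = pts.mean(axis=0)
    # initial direction: principal component of the centroids
    _, _, Vt = np.linalg.svd(pts - center)
    u0 = Vt[0]

    def direction(theta, phi):
        return np.array([np.sin(theta) * np.cos(phi),
                         np.sin(theta) * np.sin(phi),
                         np.cos(theta)])

    theta0 = np.arccos(np.clip(u0[2], -1, 1))
    phi0 = np.arctan2(u0[1], u0[0])
    # offset parametrized in the plane perpendicular to the initial axis;
    # shifts along the axis do not change point-to-line distances
    b1 = _axis_reference(u0)
    b2 = np.cross(u0, b1)

    def residuals(params):
        theta, phi, a, b = params
        u = direction(theta, phi)
        p0 = center + a * b1 + b * b2
        rel = pts - p0
        radial = rel - np.outer(rel @ u, u)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    sol = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0], method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    theta, phi, a, b = sol.x
    u = direction(theta, phi)
    p0 = center + a * b1 + b * b2

    rel = pts - p0
    axial = rel @ u
    # orient toward the plus end: axial coordinate must increase with order
    if np.polyfit(np.arange(len(pts)), axial, 1)[0] < 0:
        u = -u
        axial = -axial
    radial = rel - np.outer(axial, u)
    radii = np.linalg.norm(radial, axis=1)
    residual = float(np.sqrt(np.mean((radii - radii.mean()) ** 2)))

    origin = p0 + axial.mean() * u  # point on axis nearest the centroid
    e1 = _axis_reference(u)
    e2 = np.cross(u, e1)
    az = np.degrees(np.arctan2(radial @ e2, radial @ e1))
    spin = float(az[0] % 360.0)

    rise = float(np.mean(np.diff(axial)))
    dtw = np.diff(az)
    dtw = (dtw + 180.0) % 360.0 - 180.0
    twist = float(np.mean(dtw))

    pose = FilamentPose(origin, u, spin, length=len(pts))
    info = {
        "residual": residual,
        "rise": rise,
        "twist": twist,
        "radius": float(radii.mean()),
        "degenerate": bool(residual > 0.25 * max(radii.mean(), 1.0)),
    }
    return pose, info
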