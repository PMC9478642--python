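"""Readers and writers for the standard formats the pipeline touches.

Conventions used throughout the package (defined here, used everywhere):

* Coordinates are in Angstrom, right-handed axes.
* Images are indexed ``(row, col)`` with row 0 at the top; pixel indices are
  0-based and pixel centers sit at integer coordinates.
* STAR tables use RELION-style labels: ``_rlnCoordinateX/Y`` (pixels),
  ``_rlnAngleRot/Tilt/Psi`` (ZYZ intrinsic Euler angles, degrees),
  ``_rlnOriginXAngst/YAngst/ZAngst`` (translations, Angstrom).
* MRC2014 is used for 2D micrographs (nz = 1) and 3D maps alike.

gemmi backs all heavy parsing (MRC/CCP4, PDB/mmCIF, STAR); this module only
adds the package's domain containers and invariant checks on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger("filbundle")

# Canonical STAR labels (RELION dialect). Overridable per call via column_map.
STAR_LABELS = {
    "particle": "_rlnImageName",
    "body": "_rlnBodyNumber",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "ox": "_rlnOriginXAngst",
    "oy": "_rlnOriginYAngst",
    "oz": "_rlnOriginZAngst",
    "class": "_rlnClassNumber",
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "score": "_rlnAutopickFigureOfMerit",
    "angle": "_rlnAnglePsi",
}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Micrograph:
    """A 2D image with physical sampling.

    Parameters
    ----------
    data : (ny, nx) float array, arbitrary intensity units.
    pixel_size : pixel size in Angstrom per pixel (> 0).
    id : free-form identifier (e.g. source filename stem).
    """

    data: np.ndarray
    pixel_size: float
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise FormatError(f"Micrograph data must be 2D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise FormatError("Micrograph contains non-finite values")
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class VolumeMap:
    """A 3D scalar field with isotropic voxel size and an origin offset (A).

    ``data`` is indexed ``(z, y, x)``; voxel centers at integer indices.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise FormatError(f"VolumeMap data must be 3D, got {self.data.ndim}D")
        if not self.voxel_size > 0:
            raise FormatError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


class AtomicModel:
    """Atomic coordinates as a flat table with per-chain gap detection.

    Backed by a pandas DataFrame with columns
    ``chain, resnum, resname, atom, element, x, y, z, b, occ``.
    Residue numbers must be strictly increasing within a chain.
    """

    COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z", "b", "occ"]

    def __init__(self, atoms: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in atoms.columns]
        if missing:
            raise FormatError(f"AtomicModel table missing columns {missing}")
        self.atoms = atoms.reset_index(drop=True)
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.isfinite(xyz).all():
            raise FormatError("AtomicModel contains non-finite coordinates")
        for chain, sub in self.atoms.groupby("chain", sort=False):
            resnums = sub["resnum"].to_numpy()
            # strictly increasing over residue boundaries (equal within a residue)
            boundary = resnums[1:][resnums[1:] != resnums[:-1]]
            prev = resnums[:-1][resnums[1:] != resnums[:-1]]
            if np.any(boundary <= prev):
                raise FormatError(f"chain {chain}: residue numbers not strictly increasing")

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def chain_table(self, chain: str) -> pd.DataFrame:
        sub = self.atoms[self.atoms["chain"] == chain]
        if sub.empty:
            raise FormatError(f"no such chain: {chain!r} (have {self.chains})")
        return sub

    def gaps(self, chain: str) -> list[tuple[int, int]]:
        """Residue-numbering discontinuities in a chain.

        Returns pairs ``(last_before, first_after)`` for every place where
        consecutive residue numbers differ by more than 1.
        """
        resnums = np.array(sorted(set(self.chain_table(chain)["resnum"])))
        jumps = np.nonzero(np.diff(resnums) > 1)[0]
        return [(int(resnums[i]), int(resnums[i + 1])) for i in jumps]

    def coords(self, chain=None, resnums=None, atom=None) -> np.ndarray:
        """(n, 3) coordinates of the selected atoms (all atoms by default)."""
        sub = self.atoms
        if chain is not None:
            sub = sub[sub["chain"] == chain]
        if resnums is not None:
            lo, hi = (resnums, resnums) if np.isscalar(resnums) else resnums
            sub = sub[(sub["resnum"] >= lo) & (sub["resnum"] <= hi)]
        if atom is not None:
            sub = sub[sub["atom"] == atom]
        return sub[["x", "y", "z"]].to_numpy(float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicModel":
        out = self.atoms.copy()
        xyz = out[["x", "y", "z"]].to_numpy(float) @ np.asarray(rotation).T + translation
        out[["x", "y", "z"]] = xyz
        return AtomicModel(out)


@dataclass
class PoseTable:
    """Per-particle multibody poses: one row per (particle, body).

    Columns: ``particle, body, rot, tilt, psi`` (degrees, ZYZ intrinsic) and
    ``ox, oy[, oz]`` (Angstrom), optional ``class``. Every particle must carry
    a complete set of body rows.
    """

    rows: pd.DataFrame
    bodies: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        req = ["particle", "body", "rot", "tilt", "psi", "ox", "oy"]
        missing = [c for c in req if c not in self.rows.columns]
        if missing:
            raise FormatError(f"pose table missing columns {missing}")
        ang = self.rows[["rot", "tilt", "psi"]].to_numpy(float)
        if not np.isfinite(ang).all():
            raise FormatError("pose table contains non-finite angles")
        bodies = tuple(sorted(set(self.rows["body"])))
        counts = self.rows.groupby("particle")["body"].apply(lambda s: tuple(sorted(s)))
        bad = counts[counts != bodies]
        if len(bad):
            raise FormatError(
                f"incomplete body sets for particles {list(bad.index[:5])} "
                f"(expected bodies {bodies})"
            )
        self.bodies = bodies

    def particle(self, particle_id) -> pd.DataFrame:
        return self.rows[self.rows["particle"] == particle_id]

    @property
    def particle_ids(self) -> list:
        return list(dict.fromkeys(self.rows["particle"]))


# ---------------------------------------------------------------------------
# MRC maps and micrographs
# ---------------------------------------------------------------------------

def _grid_to_array(ccp4: gemmi.Ccp4Map) -> np.ndarray:
    return np.array(ccp4.grid, copy=True).astype(np.float32)


def read_map(path) -> VolumeMap:
    """Read an MRC/CCP4 3D map. Voxel size from the unit cell; origin from
    header words 50-52 (MRC2014 ORIGIN)."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    data = _grid_to_array(ccp4)
    nz, ny, nx = data.shape
    vx = ccp4.grid.unit_cell.a / nx
    vy = ccp4.grid.unit_cell.b / ny
    vz = ccp4.grid.unit_cell.c / nz
    if vx <= 0:
        raise FormatError(f"{path}: non-positive voxel size {vx} (unit cell a={ccp4.grid.unit_cell.a})")
    if abs(vy - vx) > 1e-3 or abs(vz - vx) > 1e-3:
        raise FormatError(f"{path}: anisotropic voxel size ({vx:.4f},{vy:.4f},{vz:.4f}) not supported")
    origin = tuple(ccp4.header_float(i) for i in (50, 51, 52))
    return VolumeMap(data, float(vx), origin)


def write_map(vol: VolumeMap, path) -> None:
    ccp4 = gemmi.Ccp4Map()
    nz, ny, nx = vol.data.shape
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    ccp4.grid.set_unit_cell(
        gemmi.UnitCell(nx * vol.voxel_size, ny * vol.voxel_size, nz * vol.voxel_size, 90, 90, 90)
    )
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), vol.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


def read_micrograph(path) -> Micrograph:
    """Read a 2D micrograph stored as an nz=1 MRC."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    data = _grid_to_array(ccp4)
    if data.shape[0] != 1:
        raise FormatError(f"{path}: expected a 2D image (nz=1), got shape {data.shape}")
    nx = data.shape[2]
    px = ccp4.grid.unit_cell.a / nx
    if px <= 0:
        raise FormatError(f"{path}: non-positive pixel size {px}")
    return Micrograph(data[0], float(px), id=Path(path).stem)


def write_micrograph(mic: Micrograph, path) -> None:
    vol = VolumeMap(mic.data[None], mic.pixel_size)
    write_map(vol, path)


# ---------------------------------------------------------------------------
# Atomic models (PDB / mmCIF)
# ---------------------------------------------------------------------------

def read_model(path) -> AtomicModel:
    """Parse ATOM records from a PDB or mmCIF file.

    Altlocs: the highest-occupancy location is kept; ties keep the first
    encountered. Waters are dropped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    st.remove_waters()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    (chain.name, res.seqid.num, res.name, atom.name,
                     atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z,
                     atom.b_iso, atom.occ)
                )
    if not rows:
        raise FormatError(f"{path}: no ATOM records parsed")
    return AtomicModel(pd.DataFrame(rows, columns=AtomicModel.COLUMNS))


def write_model(model: AtomicModel, path) -> None:
    """Write an AtomicModel as PDB (coordinates at PDB's 1e-3 A precision)."""
    st = gemmi.Structure()
    st.name = "filbundle"
    gm = gemmi.Model("1")
    for chain_name, sub in model.atoms.groupby("chain", sort=False):
        ch = gemmi.Chain(str(chain_name))
        for resnum, rsub in sub.groupby("resnum", sort=True):
            res = gemmi.Residue()
            res.name = str(rsub["resname"].iloc[0])
            res.seqid = gemmi.SeqId(int(resnum), " ")
            for _, row in rsub.iterrows():
                at = gemmi.Atom()
                at.name = str(row["atom"])
                at.element = gemmi.Element(str(row["element"]))
                at.pos = gemmi.Position(row["x"], row["y"], row["z"])
                at.b_iso = float(row["b"])
                at.occ = float(row["occ"])
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# STAR tables: poses and picks
# ---------------------------------------------------------------------------

def _star_block(path) -> gemmi.cif.Block:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(doc) == 0:
        raise FormatError(f"{path}: empty STAR document")
    return doc[0]


def _star_columns(block: gemmi.cif.Block, labels: list[str], path) -> dict[str, list[str]]:
    out = {}
    for lab in labels:
        col = block.find_loop(lab)
        vals = list(col)
        if not vals:
            raise FormatError(f"{path}: missing required STAR column {lab}")
        out[lab] = vals
    return out


def read_pose_table(path, column_map: dict[str, str] | None = None, with_z: bool = True) -> PoseTable:
    """Read a RELION-dialect multibody pose STAR file.

    ``column_map`` may override any canonical label (keys as in STAR_LABELS).
    """
    labels = dict(STAR_LABELS)
    if column_map:
        labels.update(column_map)
    block = _star_block(path)
    keys = ["particle", "body", "rot", "tilt", "psi", "ox", "oy"]
    if with_z and block.find_loop(labels["oz"]):
        keys.append("oz")
    cols = _star_columns(block, [labels[k] for k in keys], path)
    df = pd.DataFrame({k: cols[labels[k]] for k in keys})
    df["body"] = df["body"].astype(int)
    for c in ["rot", "tilt", "psi", "ox", "oy"] + (["oz"] if "oz" in df else []):
        df[c] = df[c].astype(float)
    if "oz" not in df:
        df["oz"] = 0.0
    cls = block.find_loop(labels["class"])
    cls_vals = list(cls)
    if cls_vals:
        df["class"] = [int(v) for v in cls_vals]
    return PoseTable(df)


def write_pose_table(table: PoseTable, path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    cols = ["particle", "body", "rot", "tilt", "psi", "ox", "oy", "oz"]
    labels = [STAR_LABELS[c].removeprefix("_rln") for c in cols]
    loop = block.init_loop("_rln", labels)
    for _, row in table.rows.iterrows():
        loop.add_row([str(row["particle"]), str(int(row["body"]))]
                     + [f"{row[c]:.6f}" for c in cols[2:]])
    doc.write_file(str(path))


def write_picks(picks: pd.DataFrame, path) -> None:
    """Write particle picks as a RELION coordinate STAR file.

    Expects columns ``x, y, class, score`` and optionally ``angle``.
    """
    for c in ("x", "y", "class", "score"):
        if c not in picks.columns:
            raise FormatError(f"picks table missing column {c!r}")
    doc = gemmi.cif.Document()
    block = doc.add_new_block("picks")
    labels = ["CoordinateX", "CoordinateY", "ClassNumber", "AutopickFigureOfMerit"]
    has_angle = "angle" in picks.columns
    if has_angle:
        labels.append("AnglePsi")
    loop = block.init_loop("_rln", labels)
    for _, row in picks.iterrows():
        vals = [f"{row['x']:.4f}", f"{row['y']:.4f}", str(int(row["class"])), f"{row['score']:.6f}"]
        if has_angle:
            vals.append(f"{row['angle']:.4f}")
        loop.add_row(vals)
    doc.write_file(str(path))


def read_picks(path) -> pd.DataFrame:
    block = _star_block(path)
    cols = _star_columns(
        block,
        ["_rlnCoordinateX", "_rlnCoordinateY", "_rlnClassNumber", "_rlnAutopickFigureOfMerit"],
        path,
    )
    df = pd.DataFrame(
        {
            "x": [float(v) for v in cols["_rlnCoordinateX"]],
            "y": [float(v) for v in cols["_rlnCoordinateY"]],
            "class": [int(v) for v in cols["_rlnClassNumber"]],
            "score": [float(v) for v in cols["_rlnAutopickFigureOfMerit"]],
        }
    )
    ang = list(block.find_loop("_rlnAnglePsi"))
    if ang:
        df["angle"] = [float(v) for v in ang]
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top-level config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
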