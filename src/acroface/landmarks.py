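"""Facial landmark model, scan I/O, Frankfort alignment, and reference planes.

Coordinate convention (fixed throughout the package): right-handed frame with
+x toward the subject's left, +y superior, +z anterior; units are millimetres.
A scan is "FH-aligned" when the best-fit plane through the two tragion and the
two inferior-orbital-groove landmarks is horizontal and the tragion midpoint
sits at the origin, which operationalises the Frankfort Horizontal Plane on
soft-tissue landmarks.

Landmarks are stored in a flat mapping keyed by ``code`` for midline points
and ``code_l`` / ``code_r`` for bilateral ones.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MIDLINE_CODES",
    "BILATERAL_CODES",
    "LANDMARK_CATALOG",
    "Landmark",
    "FaceScan",
    "RigidAlignment",
    "ReferencePlane",
    "PLANE_KINDS",
    "load_landmarks",
    "write_landmarks",
    "load_mesh",
    "align_frankfort",
    "build_reference_planes",
]


class ValidationError(ValueError):
    """Raised for invalid landmark files, codes, or scan geometry."""


class ParseError(ValueError):
    """Raised when a landmark file cannot be parsed."""


# ---------------------------------------------------------------------------
# Landmark catalog: the 35 soft-tissue landmarks plus bilateral preaurale.
# ---------------------------------------------------------------------------

#: Midline soft-tissue landmarks (11 points).
MIDLINE_CODES: dict[str, str] = {
    "g": "glabella",
    "n": "nasion",
    "prn": "pronasale",
    "sn": "subnasale",
    "ls": "labiale superius",
    "sto": "stomion",
    "li": "labiale inferius",
    "sm": "supramentale",
    "pg": "pogonion",
    "gn": "gnathion",
    "cm": "cervico-mandibular point",
}

#: Bilateral landmarks (12 pairs from the catalog + preaurale for clipping).
BILATERAL_CODES: dict[str, str] = {
    "en": "endocanthion",
    "ec": "ectocanthion",
    "im": "iridion mediale",
    "il": "iridion laterale",
    "ii": "iridion inferius",
    "or": "inferior orbital groove",
    "al": "alare",
    "ch": "chelion",
    "zy": "zygion",
    "tr": "tragion",
    "sba": "subaurale",
    "go": "gonion",
    "pra": "preaurale",
}

_SIDE_SUFFIX = {"left": "_l", "right": "_r"}


@dataclass(frozen=True)
class Landmark:
    """One catalog entry: a named anatomical point."""

    code: str
    name: str
    laterality: str  # midline | left | right

    def __post_init__(self) -> None:
        if self.laterality == "midline":
            if self.code not in MIDLINE_CODES:
                raise ValidationError(f"unknown midline landmark code {self.code!r}")
        elif self.laterality in ("left", "right"):
            if self.code not in BILATERAL_CODES:
                raise ValidationError(f"unknown bilateral landmark code {self.code!r}")
        else:
            raise ValidationError(f"invalid laterality {self.laterality!r}")

    @property
    def key(self) -> str:
        if self.laterality == "midline":
            return self.code
        return self.code + _SIDE_SUFFIX[self.laterality]


def _catalog() -> list[Landmark]:
    entries = [Landmark(c, n, "midline") for c, n in MIDLINE_CODES.items()]
    for c, n in BILATERAL_CODES.items():
        entries.append(Landmark(c, n, "left"))
        entries.append(Landmark(c, n, "right"))
    return entries


#: Every admissible landmark, keyed by its flat storage key.
LANDMARK_CATALOG: dict[str, Landmark] = {lm.key: lm for lm in _catalog()}


def landmark_key(code: str, laterality: str) -> str:
    """Validate a (code, laterality) pair and return its flat storage key."""
    return Landmark(code, MIDLINE_CODES.get(code) or BILATERAL_CODES.get(code, ""), laterality).key


# ---------------------------------------------------------------------------
# Scans and meshes
# ---------------------------------------------------------------------------


@dataclass
class FaceScan:
    """One subject's labelled 3D landmarks, optional surface mesh, metadata."""

    subject_id: str
    sex: str  # male | female
    group: str  # patient | control
    coords: dict[str, np.ndarray] = field(default_factory=dict)
    mesh_vertices: np.ndarray | None = None  # (V, 3) float, mm
    mesh_faces: np.ndarray | None = None  # (F, 3) int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.group not in ("patient", "control"):
            raise ValidationError(f"group must be patient/control, got {self.group!r}")
        for key, p in self.coords.items():
            if key not in LANDMARK_CATALOG:
                raise ValidationError(f"unknown landmark key {key!r}")
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {key!r} has invalid coordinates {p!r}")
            self.coords[key] = p
        if (self.mesh_vertices is None) != (self.mesh_faces is None):
            raise ValidationError("mesh vertices and faces must be given together")
        if self.mesh_vertices is not None:
            v = np.asarray(self.mesh_vertices, dtype=float)
            f = np.asarray(self.mesh_faces, dtype=int)
            if v.ndim != 2 or v.shape[1] != 3 or not np.all(np.isfinite(v)):
                raise ValidationError("mesh vertices must be a finite (V, 3) array")
            if f.ndim != 2 or f.shape[1] != 3:
                raise ValidationError("mesh faces must be triangles (F, 3)")
            if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
                raise ValidationError("mesh faces reference missing vertices")
            self.mesh_vertices, self.mesh_faces = v, f

    @property
    def has_mesh(self) -> bool:
        return self.mesh_vertices is not None

    def require(self, *keys: str) -> list[np.ndarray]:
        """Return coordinates for the given keys, or raise listing what is missing."""
        missing = [k for k in keys if k not in self.coords]
        if missing:
            raise ValidationError(f"scan {self.subject_id!r} missing landmarks: {missing}")
        return [self.coords[k] for k in keys]

    def point(self, key: str) -> np.ndarray:
        (p,) = self.require(key)
        return p

    def midpoint(self, key_a: str, key_b: str) -> np.ndarray:
        a, b = self.require(key_a, key_b)
        return 0.5 * (a + b)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FaceScan":
        """Apply ``x -> R x + t`` to all landmarks and mesh vertices."""
        coords = {k: rotation @ p + translation for k, p in self.coords.items()}
        mv = None
        if self.mesh_vertices is not None:
            mv = self.mesh_vertices @ rotation.T + translation
        return replace(
            self,
            coords=coords,
            mesh_vertices=mv,
            mesh_faces=None if mv is None else self.mesh_faces.copy(),
        )


@dataclass(frozen=True)
class RigidAlignment:
    """A proper rigid transform ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length-3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValidationError("rotation determinant is not +1 (improper transform)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidAlignment":
        return RigidAlignment(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "RigidAlignment":
        return cls(np.asarray(obj["rotation"], float), np.asarray(obj["translation"], float))


PLANE_KINDS = (
    "FH",
    "midsagittal",
    "esthetic",
    "TVL",
    "transglabellar",
    "midfacial",
    "transverse_nasal",
    "plumb_left",
    "plumb_right",
)


@dataclass(frozen=True)
class ReferencePlane:
    """An oriented plane: a point, a unit normal, and which half-space is positive."""

    kind: str
    point: np.ndarray
    normal: np.ndarray
    positive_sense: str

    def __post_init__(self) -> None:
        if self.kind not in PLANE_KINDS:
            raise ValidationError(f"unknown plane kind {self.kind!r}")
        p = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-12):
            raise ValidationError("plane normal must have unit length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point, float) - self.point, self.normal))


# ---------------------------------------------------------------------------
# Landmark file I/O (long-format CSV and an equivalent JSON dialect)
# ---------------------------------------------------------------------------

_CSV_HEADER = ["subject_id", "sex", "group", "code", "laterality", "x", "y", "z"]


def load_landmarks(path: str | Path) -> list[FaceScan]:
    """Read landmark scans from long-format CSV or JSON.

    CSV columns: ``subject_id,sex,group,code,laterality,x,y,z``; laterality is
    ``midline``, ``left`` or ``right``.  The JSON dialect is a list of objects
    ``{subject_id, sex, group, landmarks: {key: [x, y, z]}}``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        return _load_landmarks_json(path)
    return _load_landmarks_csv(path)


def _load_landmarks_csv(path: Path) -> list[FaceScan]:
    subjects: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CSV_HEADER:
            raise ParseError(f"{path}: expected header {','.join(_CSV_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 fields, got {len(row)}")
            sid, sex, group, code, lat, xs, ys, zs = (c.strip() for c in row)
            try:
                key = landmark_key(code, lat)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            try:
                p = np.array([float(xs), float(ys), float(zs)])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed coordinate") from exc
            rec = subjects.setdefault(sid, {"sex": sex, "group": group, "coords": {}})
            if key in rec["coords"]:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate landmark ({sid}, {code}, {lat})"
                )
            rec["coords"][key] = p
    return [
        FaceScan(sid, rec["sex"], rec["group"], rec["coords"])
        for sid, rec in subjects.items()
    ]


def _load_landmarks_json(path: Path) -> list[FaceScan]:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    scans = []
    for rec in data:
        coords = {k: np.asarray(v, float) for k, v in rec["landmarks"].items()}
        for k in coords:
            if k not in LANDMARK_CATALOG:
                raise ValidationError(f"{path}: unknown landmark key {k!r}")
        scans.append(FaceScan(rec["subject_id"], rec["sex"], rec["group"], coords))
    return scans


def write_landmarks(scans: Iterable[FaceScan], path: str | Path) -> None:
    """Write scans in the CSV or JSON dialect (chosen by file extension).

    Coordinates are written at 6 decimals, giving a bit-exact round-trip at
    that precision.
    """
    path = Path(path)
    scans = list(scans)
    if path.suffix.lower() == ".json":
        data = [
            {
                "subject_id": s.subject_id,
                "sex": s.sex,
                "group": s.group,
                "landmarks": {k: [round(float(c), 6) for c in p] for k, p in s.coords.items()},
            }
            for s in scans
        ]
        path.write_text(json.dumps(data, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for s in scans:
            for key in sorted(s.coords):
                lm = LANDMARK_CATALOG[key]
                p = s.coords[key]
                writer.writerow(
                    [s.subject_id, s.sex, s.group, lm.code, lm.laterality]
                    + [f"{c:.6f}" for c in p]
                )


def load_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a triangulated OBJ/PLY surface; quads or mixed polygons are rejected."""
    import trimesh

    loaded = trimesh.load(str(path), force="mesh", process=False)
    faces = np.asarray(loaded.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValidationError(f"{path}: mesh must be triangles only")
    return np.asarray(loaded.vertices, float), faces


# ---------------------------------------------------------------------------
# Frankfort Horizontal alignment
# ---------------------------------------------------------------------------

_FH_KEYS = ("tr_l", "tr_r", "or_l", "or_r")


def _best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (SVD)."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValidationError("degenerate (collinear) landmark configuration")
    return vt[2]


def align_frankfort(scan: FaceScan) -> tuple[FaceScan, RigidAlignment]:
    """Rotate/translate a scan into the Frankfort Horizontal frame.

    The least-squares plane through {tragion left/right, inferior orbital
    groove left/right} becomes horizontal (+y its upward normal), the tragion
    midpoint becomes the origin, and the right-to-left tragion direction spans
    the lateral (+x) axis.  The same rigid transform is applied to the mesh.
    Rigid: all pairwise distances are preserved exactly up to round-off.
    """
    tr_l, tr_r, or_l, or_r = scan.require(*_FH_KEYS)
    pts = np.vstack([tr_l, tr_r, or_l, or_r])
    normal = _best_fit_plane_normal(pts)
    # orient the FH normal superiorly: orbital landmarks sit above... the FH
    # plane passes near both; disambiguate with the ear-to-eye anterior axis
    # instead: up = normal oriented so that (lateral x up) points from the
    # tragion midpoint toward the orbital midpoint (anterior).
    lateral = tr_l - tr_r
    lateral = lateral - np.dot(lateral, normal) * normal
    norm = np.linalg.norm(lateral)
    if norm < 1e-9:
        raise ValidationError("degenerate tragion configuration")
    lateral /= norm
    anterior = np.cross(lateral, normal)
    mid_tr = 0.5 * (tr_l + tr_r)
    mid_or = 0.5 * (or_l + or_r)
    if np.dot(anterior, mid_or - mid_tr) < 0:
        normal = -normal
        anterior = -anterior
    R = np.vstack([lateral, normal, anterior])  # rows are new x, y, z axes
    t = -R @ mid_tr
    alignment = RigidAlignment(R, t)
    return scan.transformed(R, t), alignment


# ---------------------------------------------------------------------------
# Reference planes (in the FH-aligned frame)
# ---------------------------------------------------------------------------

_Y = np.array([0.0, 1.0, 0.0])


def build_reference_planes(scan: FaceScan) -> dict[str, ReferencePlane]:
    """Construct the measurement reference planes for an FH-aligned scan.

    Requires an FH-aligned scan (tragion midpoint at the origin, FH plane
    horizontal).  Planes whose landmarks are missing are simply omitted from
    the result; FH itself and the midsagittal plane are always built.
    """
    planes: dict[str, ReferencePlane] = {}
    planes["FH"] = ReferencePlane("FH", np.zeros(3), _Y, "superior")

    # Midsagittal: vertical plane minimizing squared signed distances of the
    # midline landmarks; its normal lies in the horizontal (xz) plane.
    mid_pts = np.array([scan.coords[k] for k in MIDLINE_CODES if k in scan.coords])
    if len(mid_pts) < 2:
        raise ValidationError("midsagittal plane needs at least two midline landmarks")
    xz = mid_pts[:, [0, 2]]
    centered = xz - xz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n2 = vt[-1]  # minor axis in xz
    normal = np.array([n2[0], 0.0, n2[1]])
    if normal[0] < 0 or (normal[0] == 0 and normal[2] < 0):
        normal = -normal  # positive sense: subject-left
    point = np.array([xz.mean(axis=0)[0], 0.0, xz.mean(axis=0)[1]])
    planes["midsagittal"] = ReferencePlane("midsagittal", point, normal, "left")
    ms_normal = planes["midsagittal"].normal

    def vertical_through(kind: str, p: np.ndarray, sense: str) -> ReferencePlane:
        return ReferencePlane(kind, p, np.array([0.0, 0.0, 1.0]), sense)

    # Esthetic plane: the pronasale-pogonion line viewed in the sagittal
    # (y, z) projection, extruded along the lateral axis so the plane is
    # perpendicular to the midsagittal plane; anterior side positive.
    if "prn" in scan.coords and "pg" in scan.coords:
        prn, pg = scan.coords["prn"], scan.coords["pg"]
        lateral = np.cross(ms_normal, _Y)  # in-midsagittal-plane... lateral axis
        lateral /= np.linalg.norm(lateral)
        d = prn - pg
        d_sag = d - np.dot(d, ms_normal) * ms_normal  # project into sagittal orientation
        if np.linalg.norm(d_sag) < 1e-9:
            raise ValidationError("esthetic plane degenerate: prn and pg coincide sagittally")
        n = np.cross(ms_normal, d_sag)
        n /= np.linalg.norm(n)
        if n[2] < 0:
            n = -n  # anterior positive
        planes["esthetic"] = ReferencePlane("esthetic", prn, n, "anterior")

    if "sn" in scan.coords:
        sn = scan.coords["sn"]
        tvl_n = np.cross(ms_normal, _Y)
        tvl_n /= np.linalg.norm(tvl_n)
        if tvl_n[2] < 0:
            tvl_n = -tvl_n
        planes["TVL"] = ReferencePlane("TVL", sn, tvl_n, "anterior")
        planes["transverse_nasal"] = ReferencePlane("transverse_nasal", sn, _Y, "superior")
    if "g" in scan.coords:
        planes["transglabellar"] = ReferencePlane("transglabellar", scan.coords["g"], _Y, "superior")
    if "or_l" in scan.coords and "or_r" in scan.coords:
        planes["midfacial"] = ReferencePlane(
            "midfacial", scan.midpoint("or_l", "or_r"), _Y, "superior"
        )
    if "pra_l" in scan.coords:
        planes["plumb_left"] = vertical_through("plumb_left", scan.coords["pra_l"], "anterior")
    if "pra_r" in scan.coords:
        planes["plumb_right"] = vertical_through("plumb_right", scan.coords["pra_r"], "anterior")
    return planes
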