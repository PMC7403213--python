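"""The 58-parameter measurement engine.

Evaluates a dependency-ordered catalog of craniofacial measurements on an
FH-aligned :class:`~acroface.landmarks.FaceScan`: Euclidean distances, curve
(polyline) lengths, angles, ×100 indices, signed reference-plane distances,
and mesh cross-section semi-perimeters at the transglabellar, midfacial and
transverse-nasal levels, clipped at the preaurale plumb planes.

The default catalog ships as ``data/catalog.json`` (catalog-as-data: operand
assignments can be edited without touching code).  Measurements that cannot
be evaluated — a missing landmark, no mesh for a section entry — yield a
missing value with a per-entry diagnostic instead of raising.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    FaceScan,
    ReferencePlane,
    ValidationError,
    align_frankfort,
    build_reference_planes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementDefinition",
    "MeasurementCatalog",
    "FeatureVector",
    "FeatureTable",
    "default_catalog",
    "linear_distance",
    "polyline_length",
    "angle_at",
    "index_value",
    "signed_plane_distance",
    "mesh_plane_section",
    "semi_perimeter",
    "extract_profile_curves",
    "measure_all",
    "measure_cohort",
]

KINDS = (
    "linear",
    "linear_avg",
    "curve",
    "angle",
    "index",
    "triangle_index",
    "plane_distance",
    "derived_difference",
    "semi_perimeter",
)

UNITS = ("mm", "degree", "index")


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementDefinition:
    id: str
    name: str
    kind: str
    units: str
    operands: dict[str, Any]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"{self.id}: unknown measurement kind {self.kind!r}")
        if self.units not in UNITS:
            raise ValidationError(f"{self.id}: unknown units {self.units!r}")

    def dependencies(self) -> set[str]:
        """Ids of other measurements this one depends on."""

        def refs(obj: Any) -> set[str]:
            if isinstance(obj, dict):
                out = set()
                if "measurement" in obj:
                    out.add(obj["measurement"])
                for v in obj.values():
                    out |= refs(v)
                return out
            if isinstance(obj, list):
                return set().union(*(refs(o) for o in obj)) if obj else set()
            return set()

        deps = refs(self.operands)
        if self.kind == "derived_difference":
            deps |= {self.operands["minuend"], self.operands["subtrahend"]}
        return deps


class MeasurementCatalog:
    """An ordered, validated, acyclic collection of measurement definitions."""

    def __init__(self, entries: Sequence[MeasurementDefinition]):
        ids = [e.id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate measurement ids in catalog")
        self.entries = list(entries)
        self._by_id = {e.id: e for e in entries}
        self._order = self._toposort()

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mid: str) -> MeasurementDefinition:
        return self._by_id[mid]

    def __contains__(self, mid: str) -> bool:
        return mid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def units(self) -> dict[str, str]:
        return {e.id: e.units for e in self.entries}

    def evaluation_order(self) -> list[str]:
        return list(self._order)

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(mid: str, stack: tuple[str, ...]) -> None:
            if state.get(mid) == 2:
                return
            if state.get(mid) == 1:
                raise ValidationError(f"measurement dependency cycle at {mid!r}")
            state[mid] = 1
            for dep in self._by_id[mid].dependencies():
                if dep not in self._by_id:
                    raise ValidationError(f"{mid}: unknown dependency {dep!r}")
                visit(dep, stack + (mid,))
            state[mid] = 2
            order.append(mid)

        for e in self.entries:
            visit(e.id, ())
        return order

    @classmethod
    def from_json(cls, path: str | Path) -> "MeasurementCatalog":
        with open(path) as fh:
            data = json.load(fh)
        return cls._from_obj(data)

    @classmethod
    def _from_obj(cls, data: dict) -> "MeasurementCatalog":
        entries = []
        for raw in data["entries"]:
            raw = dict(raw)
            mid = raw.pop("id")
            name = raw.pop("name", mid)
            kind = raw.pop("kind")
            units = raw.pop("units")
            entries.append(MeasurementDefinition(mid, name, kind, units, raw))
        return cls(entries)


def default_catalog() -> MeasurementCatalog:
    """The packaged 58-entry catalog (55 parameters + 3 semi-perimeters)."""
    text = resources.files("acroface.data").joinpath("catalog.json").read_text()
    return MeasurementCatalog._from_obj(json.loads(text))


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------


def linear_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two 3D points, in mm."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValidationError("non-finite point passed to linear_distance")
    return float(np.linalg.norm(p - q))


def polyline_length(points: Sequence[np.ndarray]) -> float:
    """Total length of an ordered 3D polyline."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValidationError("polyline needs at least two points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def angle_at(p: np.ndarray, vertex: np.ndarray, q: np.ndarray) -> float:
    """Angle p-vertex-q in degrees, in [0, 180]."""
    u = np.asarray(p, float) - np.asarray(vertex, float)
    v = np.asarray(q, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("zero-length arm in angle_at")
    # atan2 form: well-conditioned near 0 and 180 where arccos is not
    return math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


def index_value(numerator_id: str, denominator_id: str, table: "FeatureTable") -> pd.Series:
    """Per-subject ×100 ratio of two feature-table columns."""
    num = table.values[numerator_id]
    den = table.values[denominator_id]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * num / den
    bad = den == 0
    if bad.any():
        logger.warning("index %s/%s: %d zero denominators -> missing",
                       numerator_id, denominator_id, int(bad.sum()))
        out[bad] = np.nan
    return out


def signed_plane_distance(point: np.ndarray, plane: ReferencePlane) -> float:
    """Signed distance of a point to an oriented reference plane."""
    return plane.signed_distance(point)


# ---------------------------------------------------------------------------
# Mesh sectioning
# ---------------------------------------------------------------------------


def mesh_plane_section(
    vertices: np.ndarray,
    faces: np.ndarray,
    plane: ReferencePlane,
    chain_tol: float | None = None,
) -> list[np.ndarray]:
    """Intersect a triangulated mesh with a plane.

    Returns maximal polylines (arrays of 3D points), chained from per-triangle
    intersection segments by endpoint matching, ordered by arc length
    descending.  ``chain_tol`` defaults to 1e-6 x the bounding-box diagonal.
    """
    import trimesh

    vertices = np.asarray(vertices, float)
    segs = trimesh.intersections.mesh_plane(
        trimesh.Trimesh(vertices=vertices, faces=faces, process=False),
        plane_normal=plane.normal,
        plane_origin=plane.point,
    )
    if len(segs) == 0:
        return []
    if chain_tol is None:
        bbox = vertices.max(axis=0) - vertices.min(axis=0)
        chain_tol = 1e-6 * float(np.linalg.norm(bbox))
    polylines = _chain_segments(np.asarray(segs, float), chain_tol)
    polylines.sort(key=lambda pl: -polyline_length(pl) if len(pl) > 1 else 0.0)
    return polylines


def _chain_segments(segments: np.ndarray, tol: float) -> list[np.ndarray]:
    """Greedy endpoint-matching of (n, 2, 3) segments into polylines."""
    # drop degenerate segments
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    segments = segments[lengths > tol]
    unused = list(range(len(segments)))
    polylines: list[np.ndarray] = []
    while unused:
        i = unused.pop()
        chain = [segments[i, 0], segments[i, 1]]
        for endidx, push in ((1, chain.append), (0, lambda p: chain.insert(0, p))):
            while True:
                tip = chain[-1] if endidx == 1 else chain[0]
                hit = None
                for j in unused:
                    for k in (0, 1):
                        if np.linalg.norm(segments[j, k] - tip) <= tol:
                            hit = (j, k)
                            break
                    if hit:
                        break
                if hit is None:
                    break
                j, k = hit
                unused.remove(j)
                push(segments[j, 1 - k])
        polylines.append(np.asarray(chain))
    return polylines


def _clip_polyline_halfspaces(
    polyline: np.ndarray, planes: Sequence[ReferencePlane]
) -> float:
    """Arc length of the polyline portions on the non-negative side of all planes.

    Segments crossing a plane are split at the exact intersection point.
    """
    total = 0.0
    pts = np.asarray(polyline, float)
    for a, b in zip(pts[:-1], pts[1:]):
        lo, hi = 0.0, 1.0  # parametric kept interval of segment a->b
        for pl in planes:
            da, db = pl.signed_distance(a), pl.signed_distance(b)
            if da < 0 and db < 0:
                lo, hi = 1.0, 0.0
                break
            if da < 0 or db < 0:
                t = da / (da - db)  # crossing parameter
                if da < 0:
                    lo = max(lo, t)
                else:
                    hi = min(hi, t)
        if hi > lo:
            total += (hi - lo) * float(np.linalg.norm(b - a))
    return total


def semi_perimeter(
    vertices: np.ndarray,
    faces: np.ndarray,
    level_plane: ReferencePlane,
    plumb_planes: Sequence[ReferencePlane],
    anterior_axis: np.ndarray = (0.0, 0.0, 1.0),
) -> float:
    """Facial semi-perimeter at a horizontal level.

    Sections the mesh at ``level_plane``, keeps the component reaching
    furthest along the anterior axis (the facial loop), clips away everything
    posterior to either preaurale plumb plane, and returns the remaining arc
    length in mm.  Returns ``nan`` when the section is empty.
    """
    polylines = mesh_plane_section(vertices, faces, level_plane)
    polylines = [pl for pl in polylines if len(pl) > 1]
    if not polylines:
        return float("nan")
    ax = np.asarray(anterior_axis, float)
    front = max(polylines, key=lambda pl: float((pl @ ax).max()))
    return _clip_polyline_halfspaces(front, list(plumb_planes))


def extract_profile_curves(
    scan: FaceScan, planes: dict[str, ReferencePlane]
) -> dict[str, np.ndarray]:
    """Midsagittal profile polylines for the lip and chin windows.

    The lip window spans the heights of subnasale down to supramentale, the
    chin window supramentale down to the cervico-mandibular point; each is the
    anterior midsagittal mesh section clipped to that vertical band and
    ordered top-down.  Raises if a window's bounds are inverted; a window with
    no section points is reported missing (absent from the result).
    """
    if not scan.has_mesh:
        raise ValidationError("profile curves require a mesh")
    sn, sm, cm = scan.require("sn", "sm", "cm")
    out: dict[str, np.ndarray] = {}
    section = mesh_plane_section(scan.mesh_vertices, scan.mesh_faces, planes["midsagittal"])
    if not section:
        return out
    curve = max(section, key=lambda pl: float(pl[:, 2].max()))
    for name, top, bottom in (("lip", sn[1], sm[1]), ("chin", sm[1], cm[1])):
        if top <= bottom:
            raise ValidationError(f"{name} window bounds inverted ({top:.2f} <= {bottom:.2f})")
        pts = curve[(curve[:, 1] <= top) & (curve[:, 1] >= bottom) & (curve[:, 2] > 0)]
        if len(pts) < 2:
            logger.warning("scan %s: empty %s profile window", scan.subject_id, name)
            continue
        out[name] = pts[np.argsort(-pts[:, 1])]
    return out


# ---------------------------------------------------------------------------
# Feature containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """One subject's evaluated catalog: values, units, provenance, diagnostics."""

    subject_id: str
    values: dict[str, float]
    units: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)
    diagnostics: dict[str, str] = field(default_factory=dict)

    def n_missing(self) -> int:
        return sum(1 for v in self.values.values() if not np.isfinite(v))


@dataclass
class FeatureTable:
    """Subject × measurement matrix with cohort design labels and units."""

    values: pd.DataFrame  # index subject_id, columns measurement ids
    design: pd.DataFrame  # index subject_id, columns sex, group
    units: dict[str, str]

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.design.index):
            raise ValidationError("feature values and design labels disagree on subjects")
        if self.values.notna().sum(axis=1).eq(0).any():
            raise ValidationError("a subject row is entirely missing")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    def subset(self, sex: str | None = None) -> "FeatureTable":
        mask = np.ones(len(self.design), bool)
        if sex is not None:
            mask &= (self.design["sex"] == sex).to_numpy()
        return FeatureTable(self.values.loc[mask], self.design.loc[mask], dict(self.units))

    def to_csv(self, path: str | Path, provenance: dict | None = None) -> None:
        """Write values+design as CSV with a units header row, plus a JSON sidecar."""
        path = Path(path)
        df = pd.concat([self.design, self.values], axis=1)
        units_row = {c: self.units.get(c, "") for c in df.columns}
        out = pd.concat([pd.DataFrame([units_row], index=["#units"]), df])
        out.to_csv(path, index_label="subject_id")
        sidecar = {"units": self.units, "provenance": provenance or {}}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        raw = pd.read_csv(path, index_col="subject_id")
        units_row = raw.loc["#units"] if "#units" in raw.index else None
        df = raw.drop(index="#units", errors="ignore")
        design = df[["sex", "group"]].copy()
        values = df.drop(columns=["sex", "group"]).astype(float)
        units = {} if units_row is None else {c: units_row[c] for c in values.columns}
        return cls(values, design, units)


# ---------------------------------------------------------------------------
# Catalog evaluation
# ---------------------------------------------------------------------------


def _resolve_point(spec: Any, scan: FaceScan) -> np.ndarray:
    if isinstance(spec, str):
        return scan.point(spec)
    if isinstance(spec, dict) and "mid" in spec:
        a, b = spec["mid"]
        return scan.midpoint(a, b)
    raise ValidationError(f"bad point spec {spec!r}")


def _resolve_ref(ref: Any, scan: FaceScan, values: dict[str, float]) -> float:
    if isinstance(ref, dict):
        if "measurement" in ref:
            return values[ref["measurement"]]
        if "distance" in ref:
            a, b = ref["distance"]
            return linear_distance(scan.point(a), scan.point(b))
        if "sum" in ref:
            return sum(_resolve_ref(r, scan, values) for r in ref["sum"])
    raise ValidationError(f"bad measurement reference {ref!r}")


_LEVEL_TO_PLANE = {
    "transglabellar": "transglabellar",
    "midfacial": "midfacial",
    "transverse_nasal": "transverse_nasal",
}


def _curve_value(defn: MeasurementDefinition, scan: FaceScan,
                 planes: dict[str, ReferencePlane], fallback: bool) -> tuple[float, str]:
    window = defn.operands.get("mesh_window")
    if scan.has_mesh and window is not None:
        a, b = (scan.point(k) for k in window)
        section = mesh_plane_section(scan.mesh_vertices, scan.mesh_faces, planes["midsagittal"])
        section = [pl for pl in section if len(pl) > 1]
        if section:
            curve = max(section, key=lambda pl: float(pl[:, 2].max()))
            ia = int(np.argmin(np.linalg.norm(curve - a, axis=1)))
            ib = int(np.argmin(np.linalg.norm(curve - b, axis=1)))
            lo, hi = sorted((ia, ib))
            if hi > lo:
                return polyline_length(curve[lo : hi + 1]), "mesh_section"
    if not fallback and window is not None:
        return float("nan"), "missing_mesh"
    chain = [_resolve_point(s, scan) for s in defn.operands["chain"]]
    return polyline_length(chain), "landmark_chain"


def measure_all(
    scan: FaceScan,
    catalog: MeasurementCatalog | None = None,
    *,
    pre_aligned: bool = False,
    curve_fallback: bool = True,
) -> FeatureVector:
    """Evaluate the full catalog on one scan.

    The scan is Frankfort-aligned first unless ``pre_aligned`` is set (the
    alignment is idempotent, so aligning twice is harmless but wasteful).
    Entries whose landmarks or mesh are unavailable yield ``nan`` with a
    diagnostic; with ``curve_fallback`` (default) curve entries fall back to
    the straight landmark chain when no mesh is present.
    """
    catalog = catalog or default_catalog()
    if not pre_aligned:
        scan, _ = align_frankfort(scan)
    planes = build_reference_planes(scan)
    values: dict[str, float] = {}
    prov: dict[str, str] = {}
    diag: dict[str, str] = {}

    for mid in catalog.evaluation_order():
        defn = catalog[mid]
        op = defn.operands
        try:
            if defn.kind == "linear":
                a, b = (_resolve_point(s, scan) for s in op["points"])
                val, p = linear_distance(a, b), "landmarks"
            elif defn.kind == "linear_avg":
                ds = [linear_distance(scan.point(a), scan.point(b)) for a, b in op["pairs"]]
                val, p = float(np.mean(ds)), "landmarks"
            elif defn.kind == "curve":
                val, p = _curve_value(defn, scan, planes, curve_fallback)
            elif defn.kind == "angle":
                a, v, b = (_resolve_point(s, scan) for s in op["points"])
                val, p = angle_at(a, v, b), "landmarks"
            elif defn.kind == "index":
                num = _resolve_ref(op["numerator"], scan, values)
                den = _resolve_ref(op["denominator"], scan, values)
                val = 100.0 * num / den if den != 0 else float("nan")
                p = "derived"
            elif defn.kind == "triangle_index":
                apex = _resolve_point(op["apex"], scan)
                a, b = (scan.point(k) for k in op["base"])
                base_len = linear_distance(a, b)
                d = b - a
                height = float(np.linalg.norm(np.cross(apex - a, d)) / np.linalg.norm(d))
                val = 100.0 * height / base_len if base_len != 0 else float("nan")
                p = "derived"
            elif defn.kind == "plane_distance":
                plane = planes.get(op["plane"])
                if plane is None:
                    raise ValidationError(f"reference plane {op['plane']!r} unavailable")
                val, p = signed_plane_distance(_resolve_point(op["point"], scan), plane), "plane"
            elif defn.kind == "derived_difference":
                val = values[op["minuend"]] - values[op["subtrahend"]]
                p = "derived"
            elif defn.kind == "semi_perimeter":
                if not scan.has_mesh:
                    raise ValidationError("semi-perimeter requires a mesh")
                level = planes.get(_LEVEL_TO_PLANE[op["level"]])
                plumbs = [planes[k] for k in ("plumb_left", "plumb_right") if k in planes]
                if level is None or len(plumbs) != 2:
                    raise ValidationError("level or plumb planes unavailable")
                val = semi_perimeter(scan.mesh_vertices, scan.mesh_faces, level, plumbs)
                p = "mesh_section"
            else:  # pragma: no cover
                raise ValidationError(f"unhandled kind {defn.kind!r}")
        except (ValidationError, KeyError) as exc:
            val, p = float("nan"), "missing"
            diag[mid] = str(exc)
            logger.debug("scan %s, %s: %s", scan.subject_id, mid, exc)
        values[mid] = val
        prov[mid] = p

    ordered = {mid: values[mid] for mid in catalog.ids}
    return FeatureVector(scan.subject_id, ordered, catalog.units(), prov, diag)


def measure_cohort(
    scans: Sequence[FaceScan],
    catalog: MeasurementCatalog | None = None,
    **kwargs,
) -> FeatureTable:
    """Measure every scan and assemble the subject × measurement FeatureTable."""
    catalog = catalog or default_catalog()
    vectors = [measure_all(s, catalog, **kwargs) for s in scans]
    values = pd.DataFrame(
        [fv.values for fv in vectors], index=[s.subject_id for s in scans]
    )
    design = pd.DataFrame(
        {"sex": [s.sex for s in scans], "group": [s.group for s in scans]},
        index=[s.subject_id for s in scans],
    )
    return FeatureTable(values, design, catalog.units())
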