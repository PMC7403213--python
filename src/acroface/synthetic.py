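"""Synthetic cohorts with the statistical structure the analysis assumes.

Two levels of realism:

* **Feature-table level** — every sex × group cell is drawn from a
  multivariate normal with that cell's per-variable mean and SD and a
  configurable inter-feature correlation (independent, exchangeable, or
  block).  The packaged default :func:`package_table1` carries the published
  per-cell summary statistics of the 58 measurements for a 34/34 male and
  28/28 female patient/control cohort, so a generated table reproduces the
  study's first and second moments.  Gaussian cells are the minimal
  distributional assumption consistent with the t/ANOVA battery; draws are
  not truncated (SDs are small relative to the means for every variable).

* **Landmark level** — a neutral bilaterally-symmetric template face (with
  an optional ellipsoidal head mesh whose midline landmarks lie on the
  surface) is deformed by additive per-landmark displacement fields for the
  gender effect and the disease effect, plus i.i.d. isotropic landmark
  noise.  The default disease field encodes the characteristic pattern:
  nasal widening, vermilion thickening and eversion, mandibular enlargement,
  increased facial height and breadth.  Absolute template values are
  arbitrary; recovery tests are differential.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmarks import BILATERAL_CODES, MIDLINE_CODES, FaceScan
from .measure import FeatureTable
from .stats import CohortDesign

__all__ = [
    "GroupSpec",
    "TemplateFace",
    "load_table1",
    "package_table1",
    "generate_feature_table",
    "default_template",
    "DEFAULT_DISEASE_FIELD",
    "DEFAULT_GENDER_FIELD",
    "generate_landmark_cohort",
]

CELLS = ("mc", "mp", "fc", "fp")
DEFAULT_CELL_SIZES = {"mc": 34, "mp": 34, "fc": 28, "fp": 28}


# ---------------------------------------------------------------------------
# Feature-table generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-cell mean/SD specification plus a correlation model.

    ``correlation`` is one of ``("independent",)``, ``("exchangeable", rho)``
    or ``("block", group_labels, rho_within)`` where ``group_labels`` assigns
    each variable to a block (within-block correlation rho, zero between).
    """

    variables: tuple[str, ...]
    means: pd.DataFrame  # variables x CELLS
    sds: pd.DataFrame  # variables x CELLS
    units: dict[str, str] = field(default_factory=dict)
    correlation: tuple = ("exchangeable", 0.3)
    cell_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CELL_SIZES))

    def __post_init__(self) -> None:
        if (self.sds.to_numpy() < 0).any():
            raise ValueError("SDs must be non-negative")
        if any(n < 2 for n in self.cell_sizes.values()):
            raise ValueError("cell sizes must be >= 2")
        C = self.correlation_matrix()
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation specification is not positive semi-definite")

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.variables)
        kind = self.correlation[0]
        if kind == "independent":
            return np.eye(k)
        if kind == "exchangeable":
            rho = float(self.correlation[1])
            return (1 - rho) * np.eye(k) + rho * np.ones((k, k))
        if kind == "block":
            labels, rho = self.correlation[1], float(self.correlation[2])
            labels = np.asarray(labels)
            C = np.eye(k)
            same = labels[:, None] == labels[None, :]
            C[same & ~np.eye(k, dtype=bool)] = rho
            return C
        raise ValueError(f"unknown correlation model {kind!r}")


def load_table1() -> pd.DataFrame:
    """The packaged per-variable summary table: cell means/SDs and printed
    p-value columns (disease, gender, interaction, male and female post-hoc),
    indexed by acronym in catalog order."""
    with resources.files("acroface.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, index_col="acronym")


def package_table1(
    correlation: tuple = ("exchangeable", 0.3),
    cell_sizes: Mapping[str, int] | None = None,
) -> GroupSpec:
    """GroupSpec carrying the packaged cell means/SDs for all 58 variables."""
    t = load_table1()
    means = t[[f"{c}_mean" for c in CELLS]].copy()
    means.columns = list(CELLS)
    sds = t[[f"{c}_sd" for c in CELLS]].copy()
    sds.columns = list(CELLS)
    return GroupSpec(
        tuple(t.index),
        means,
        sds,
        units=dict(zip(t.index, t["units"])),
        correlation=correlation,
        cell_sizes=dict(cell_sizes or DEFAULT_CELL_SIZES),
    )


_CELL_LABELS = {
    "mc": ("male", "control"),
    "mp": ("male", "patient"),
    "fc": ("female", "control"),
    "fp": ("female", "patient"),
}


def generate_feature_table(spec: GroupSpec, seed: int) -> tuple[FeatureTable, CohortDesign]:
    """Draw a cohort feature table from the spec's per-cell Gaussians."""
    rng = np.random.default_rng(seed)
    C = spec.correlation_matrix()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    frames, sexes, groups, ids = [], [], [], []
    for cell in CELLS:
        n = spec.cell_sizes[cell]
        mu = spec.means[cell].to_numpy(float)
        sd = spec.sds[cell].to_numpy(float)
        z = rng.standard_normal((n, len(spec.variables)))
        X = mu + (z @ L.T) * sd
        frames.append(X)
        sex, grp = _CELL_LABELS[cell]
        sexes += [sex] * n
        groups += [grp] * n
        ids += [f"{cell}{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(np.vstack(frames), index=ids, columns=list(spec.variables))
    design = pd.DataFrame({"sex": sexes, "group": groups}, index=ids)
    table = FeatureTable(values, design, dict(spec.units))
    return table, CohortDesign(np.asarray(sexes), np.asarray(groups))


# ---------------------------------------------------------------------------
# Landmark-level generator
# ---------------------------------------------------------------------------

# Head ellipsoid semi-axes (mm): lateral, vertical, anterior.
_AX, _AY, _AZ = 77.5, 105.0, 95.0

#: Midline landmark heights on the template ellipsoid (x = 0); the anterior
#: z is solved from the ellipsoid equation so these points lie on the mesh.
_MIDLINE_Y = {
    "g": 32.0, "n": 25.0, "prn": -5.0, "sn": -12.0, "ls": -22.0, "sto": -28.0,
    "li": -33.0, "sm": -38.0, "pg": -45.0, "gn": -52.0, "cm": -62.0,
}

#: Bilateral landmark positions for the subject-left side (x, y, z); the
#: right side mirrors x.  Plausible adult geometry, mm.
_BILATERAL_LEFT = {
    "en": (17.0, 22.0, 60.0),
    "ec": (46.0, 20.0, 52.0),
    "im": (25.0, 21.0, 58.0),
    "il": (37.0, 21.0, 56.0),
    "ii": (31.0, 17.0, 57.0),
    "or": (33.0, 0.0, 55.0),
    "al": (21.0, -10.0, 70.0),
    "ch": (26.0, -28.0, 65.0),
    "zy": (65.0, 8.0, 15.0),
    "tr": (77.5, 0.0, 0.0),
    "sba": (70.0, -15.0, -5.0),
    "go": (60.0, -40.0, 10.0),
    "pra": (74.0, 0.0, 5.0),
}


@dataclass
class TemplateFace:
    """Canonical FH-aligned symmetric landmark set with an optional head mesh."""

    coords: dict[str, np.ndarray]
    mesh_vertices: np.ndarray | None = None
    mesh_faces: np.ndarray | None = None
    landmark_noise_sd: float = 0.5  # mm, isotropic

    def __post_init__(self) -> None:
        for key, p in self.coords.items():
            self.coords[key] = np.asarray(p, float)
        # bilateral symmetry check
        for code in BILATERAL_CODES:
            kl, kr = f"{code}_l", f"{code}_r"
            if kl in self.coords and kr in self.coords:
                mirrored = self.coords[kr] * np.array([-1.0, 1.0, 1.0])
                if not np.allclose(self.coords[kl], mirrored, atol=1e-6):
                    raise ValueError(f"template not bilaterally symmetric at {code}")


def default_template(with_mesh: bool = False, subdivisions: int = 4) -> TemplateFace:
    """The packaged neutral template; optionally with its ellipsoid head mesh.

    The mesh is an icosphere scaled to the head ellipsoid, so every midline
    landmark lies on the surface up to the mesh's chordal error.
    """
    coords: dict[str, np.ndarray] = {}
    for code, y in _MIDLINE_Y.items():
        z = _AZ * np.sqrt(max(0.0, 1.0 - (y / _AY) ** 2))
        coords[code] = np.array([0.0, y, z])
    for code, (x, y, z) in _BILATERAL_LEFT.items():
        coords[f"{code}_l"] = np.array([x, y, z])
        coords[f"{code}_r"] = np.array([-x, y, z])
    mv = mf = None
    if with_mesh:
        import trimesh

        sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
        mv = sphere.vertices * np.array([_AX, _AY, _AZ])
        mf = np.asarray(sphere.faces)
    return TemplateFace(coords, mv, mf)


#: Disease displacement field (mm): nasal widening, vermilion thickening and
#: eversion, mandibular enlargement, facial height/breadth increase.
DEFAULT_DISEASE_FIELD: dict[str, tuple[float, float, float]] = {
    "al_l": (2.5, 0.0, 0.0), "al_r": (-2.5, 0.0, 0.0),
    "prn": (0.0, 0.0, 1.5),
    "zy_l": (2.5, 0.0, 0.0), "zy_r": (-2.5, 0.0, 0.0),
    "tr_l": (2.0, 0.0, 0.0), "tr_r": (-2.0, 0.0, 0.0),
    "ec_l": (2.0, 0.0, 0.0), "ec_r": (-2.0, 0.0, 0.0),
    "ch_l": (2.0, 0.0, 0.0), "ch_r": (-2.0, 0.0, 0.0),
    "ls": (0.0, 2.0, 1.0), "li": (0.0, -2.5, 1.5),
    "sm": (0.0, -3.0, 0.0), "pg": (0.0, -4.0, 0.5),
    "gn": (0.0, -6.0, 0.0), "cm": (0.0, -6.0, 0.0),
    "go_l": (2.0, -3.0, 0.0), "go_r": (-2.0, -3.0, 0.0),
}

#: Gender (male) displacement field (mm): overall larger face.
DEFAULT_GENDER_FIELD: dict[str, tuple[float, float, float]] = {
    "g": (0.0, 2.0, 0.0), "n": (0.0, 2.0, 0.0),
    "gn": (0.0, -5.0, 0.0), "cm": (0.0, -6.0, 0.0),
    "tr_l": (4.0, 0.0, 0.0), "tr_r": (-4.0, 0.0, 0.0),
    "zy_l": (2.5, 0.0, 0.0), "zy_r": (-2.5, 0.0, 0.0),
    "ec_l": (2.5, 0.0, 0.0), "ec_r": (-2.5, 0.0, 0.0),
    "ch_l": (1.5, 0.0, 0.0), "ch_r": (-1.5, 0.0, 0.0),
    "al_l": (1.5, 0.0, 0.0), "al_r": (-1.5, 0.0, 0.0),
    "go_l": (4.0, -2.0, 0.0), "go_r": (-4.0, -2.0, 0.0),
}


def _deform_mesh(
    vertices: np.ndarray,
    coords: Mapping[str, np.ndarray],
    displacements: Mapping[str, np.ndarray],
    sigma: float = 15.0,
) -> np.ndarray:
    """Spread landmark displacements over mesh vertices with Gaussian weights.

    Each vertex moves by the weight-normalised average of nearby landmark
    displacements, so the mesh follows the landmarks smoothly.
    """
    out = vertices.copy()
    if not displacements:
        return out
    keys = list(displacements)
    P = np.vstack([coords[k] for k in keys])
    D = np.vstack([displacements[k] for k in keys])
    d2 = ((vertices[:, None, :] - P[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    wsum = w.sum(axis=1, keepdims=True)
    scale = np.minimum(wsum, 1.0)  # fade to zero far from any landmark
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(wsum > 1e-12, (w @ D) / np.maximum(wsum, 1e-12), 0.0)
    return out + avg * scale


def generate_landmark_cohort(
    template: TemplateFace | None = None,
    cell_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    disease_field: Mapping[str, Sequence[float]] | None = None,
    gender_field: Mapping[str, Sequence[float]] | None = None,
    noise_sd: float | None = None,
    include_mesh: bool = False,
) -> list[FaceScan]:
    """Generate a landmark-level cohort from the deformable template.

    Each subject is template + gender field (males) + disease field
    (patients) + i.i.d. isotropic Gaussian landmark noise; the optional mesh
    is deformed consistently with the subject's displacement field (noise is
    applied to landmarks only).
    """
    template = template or default_template(with_mesh=include_mesh)
    sizes = dict(cell_sizes or DEFAULT_CELL_SIZES)
    disease = {k: np.asarray(v, float) for k, v in
               (DEFAULT_DISEASE_FIELD if disease_field is None else disease_field).items()}
    gender = {k: np.asarray(v, float) for k, v in
              (DEFAULT_GENDER_FIELD if gender_field is None else gender_field).items()}
    sd = template.landmark_noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(seed)
    scans: list[FaceScan] = []
    keys = sorted(template.coords)
    for cell in CELLS:
        sex, grp = _CELL_LABELS[cell]
        for i in range(sizes[cell]):
            disp: dict[str, np.ndarray] = {}
            if sex == "male":
                for k, v in gender.items():
                    disp[k] = disp.get(k, 0.0) + v
            if grp == "patient":
                for k, v in disease.items():
                    disp[k] = disp.get(k, 0.0) + v
            coords = {
                k: template.coords[k] + disp.get(k, 0.0) + sd * rng.standard_normal(3)
                for k in keys
            }
            mv = mf = None
            if include_mesh and template.mesh_vertices is not None:
                mv = _deform_mesh(template.mesh_vertices, template.coords, disp)
                mf = template.mesh_faces.copy()
            scans.append(
                FaceScan(f"{cell}{i + 1:03d}", sex, grp, coords, mv, mf)
            )
    return scans
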