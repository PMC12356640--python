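"""Landmark data model, file I/O, Procrustes superimposition and limb assembly.

A hind limb is represented as a single labelled configuration of 3D points
partitioned into three bones (femur, tibia, fibula).  Points are either
*fixed* anatomical landmarks or *semilandmarks* that belong to a curve and
are allowed to slide along the curve's local tangent during superimposition.
Superimposition is classical Generalized Procrustes Analysis (GPA):
configurations are centred, scaled to unit centroid size and iteratively
rotated onto a consensus until the consensus stabilises.  Rotations are
proper (no reflections), because limb bones are handed objects.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

BONES = ("femur", "tibia", "fibula")
ROLES = ("fixed", "semilandmark")

CSV_COLUMNS = [
    "specimen_id", "taxon_id", "bone", "point_index",
    "role", "curve_id", "x", "y", "z",
]


class LandmarkError(ValueError):
    """Raised for malformed landmark data or invalid configurations."""


@dataclasses.dataclass
class LandmarkConfiguration:
    """One specimen's labelled 3D landmark set.

    Parameters
    ----------
    specimen_id, taxon_id:
        Identifiers; several specimens may share a taxon.
    points:
        (K, 3) float array of coordinates in mm.
    roles:
        Per-point tag, ``"fixed"`` or ``"semilandmark"``.
    bones:
        Per-point tag, one of ``"femur"``, ``"tibia"``, ``"fibula"``.
    curve_ids:
        Per-point curve membership; required for semilandmarks, optional
        for fixed points (curve anchors are fixed points that carry a
        curve id).
    """

    specimen_id: str
    taxon_id: str
    points: np.ndarray
    roles: list[str]
    bones: list[str]
    curve_ids: list[str | None]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: points must be (K, 3), "
                f"got {self.points.shape}")
        k = self.points.shape[0]
        if not (len(self.roles) == len(self.bones) == len(self.curve_ids) == k):
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: per-point annotations must "
                f"all have length {k}")
        if not np.all(np.isfinite(self.points)):
            raise LandmarkError(
                f"specimen {self.specimen_id!r}: non-finite coordinates")
        for i, (role, bone, cid) in enumerate(
                zip(self.roles, self.bones, self.curve_ids)):
            if role not in ROLES:
                raise LandmarkError(
                    f"specimen {self.specimen_id!r} point {i + 1}: unknown "
                    f"role {role!r}")
            if bone not in BONES:
                raise LandmarkError(
                    f"specimen {self.specimen_id!r} point {i + 1}: unknown "
                    f"bone tag {bone!r}")
            if role == "semilandmark" and not cid:
                raise LandmarkError(
                    f"specimen {self.specimen_id!r} point {i + 1}: "
                    f"semilandmark without a curve id")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray,
                    specimen_id: str | None = None,
                    taxon_id: str | None = None) -> "LandmarkConfiguration":
        """Copy of this configuration with replaced coordinates."""
        return LandmarkConfiguration(
            specimen_id=specimen_id or self.specimen_id,
            taxon_id=taxon_id or self.taxon_id,
            points=np.array(points, dtype=float),
            roles=list(self.roles),
            bones=list(self.bones),
            curve_ids=list(self.curve_ids),
        )


@dataclasses.dataclass
class SlidingScheme:
    """Curve index lists for semilandmark sliding.

    ``curves`` maps curve id -> ordered point indices including the two
    terminal anchors; anchors are fixed points and never slide.
    """

    curves: dict[str, list[int]]

    def validate(self, config: LandmarkConfiguration) -> None:
        for cid, idx in self.curves.items():
            if len(idx) != len(set(idx)):
                raise LandmarkError(f"curve {cid!r}: duplicate indices")
            if len(idx) < 3:
                raise LandmarkError(f"curve {cid!r}: needs >= 3 points")
            for j in (idx[0], idx[-1]):
                if config.roles[j] != "fixed":
                    raise LandmarkError(
                        f"curve {cid!r}: anchor point {j} must be fixed")

    def sliding_indices(self) -> list[tuple[str, int, int, int]]:
        """(curve_id, prev, point, next) for every interior semilandmark."""
        out = []
        for cid, idx in self.curves.items():
            for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
                out.append((cid, a, b, c))
        return out


@dataclasses.dataclass
class AssemblyConfig:
    """How separate bones are mounted into one composite limb.

    ``gap_fraction`` is the articular-cartilage gap between stylopod and
    zeugopod expressed as a fraction of femur proximodistal length.
    ``flip`` optionally reverses the automatic proximal orientation of an
    element's principal axis.
    """

    gap_fraction: float = 0.02
    lateral_offset_fraction: float = 0.35
    flip: dict[str, bool] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gap_fraction < 0:
            raise LandmarkError("gap_fraction must be >= 0")


@dataclasses.dataclass
class ProcrustesAlignment:
    """Result of GPA: aligned shapes, consensus and tangent coordinates."""

    aligned: list[LandmarkConfiguration]
    consensus: LandmarkConfiguration
    centroid_sizes: np.ndarray
    tangent_coords: np.ndarray
    n_iterations: int = 0

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.aligned]

    @property
    def taxon_ids(self) -> list[str]:
        return [c.taxon_id for c in self.aligned]


# ---------------------------------------------------------------------------
# File I/O

def _frame_to_configs(df: pd.DataFrame, source: str) -> list[LandmarkConfiguration]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkError(f"{source}: missing columns {missing}")
    configs: list[LandmarkConfiguration] = []
    expected_k: int | None = None
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise LandmarkError(
                f"{source}: specimen {spec_id!r} point_index must be "
                f"1..K without gaps")
        cids = [None if (pd.isna(c) or c == "") else str(c)
                for c in grp["curve_id"]]
        cfg = LandmarkConfiguration(
            specimen_id=str(spec_id),
            taxon_id=str(grp["taxon_id"].iloc[0]),
            points=grp[["x", "y", "z"]].to_numpy(dtype=float),
            roles=[str(r) for r in grp["role"]],
            bones=[str(b) for b in grp["bone"]],
            curve_ids=cids,
        )
        if expected_k is None:
            expected_k = cfg.n_points
        elif cfg.n_points != expected_k:
            raise LandmarkError(
                f"{source}: specimen {spec_id!r} has {cfg.n_points} points "
                f"but earlier specimens have {expected_k}")
        configs.append(cfg)
    if not configs:
        raise LandmarkError(f"{source}: no specimens found")
    return configs


def _parse_tps(text: str, source: str,
               default_bone: str = "femur") -> list[LandmarkConfiguration]:
    # Minimal TPS dialect: LM3=<k> blocks of "x y z" rows, ID=<name> keys.
    configs = []
    lines = text.splitlines()
    i = 0
    n_spec = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise LandmarkError(f"{source} line {i + 1}: expected LM3= block")
        k = int(line.split("=", 1)[1])
        pts = []
        i += 1
        for _ in range(k):
            try:
                pts.append([float(v) for v in lines[i].split()])
            except (IndexError, ValueError) as exc:
                raise LandmarkError(
                    f"{source} line {i + 1}: malformed coordinate row") from exc
            if len(pts[-1]) != 3:
                raise LandmarkError(
                    f"{source} line {i + 1}: expected 3 coordinates")
            i += 1
        spec_id = f"specimen_{n_spec + 1}"
        if i < len(lines) and lines[i].strip().upper().startswith("ID="):
            spec_id = lines[i].strip().split("=", 1)[1]
            i += 1
        configs.append(LandmarkConfiguration(
            specimen_id=spec_id, taxon_id=spec_id,
            points=np.array(pts), roles=["fixed"] * k,
            bones=[default_bone] * k, curve_ids=[None] * k))
        n_spec += 1
    if not configs:
        raise LandmarkError(f"{source}: no LM3 blocks found")
    ks = {c.n_points for c in configs}
    if len(ks) > 1:
        raise LandmarkError(f"{source}: inconsistent landmark counts {sorted(ks)}")
    return configs


def read_landmarks(path, format: str = "csv") -> list[LandmarkConfiguration]:
    """Read landmark configurations from a CSV (authoritative) or TPS file."""
    source = str(path)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        return _frame_to_configs(df, source)
    if format == "tps":
        with open(path, encoding="utf-8") as fh:
            return _parse_tps(fh.read(), source)
    raise LandmarkError(f"unknown landmark format {format!r}")


def configs_to_frame(configs: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    rows = []
    for cfg in configs:
        for i in range(cfg.n_points):
            rows.append({
                "specimen_id": cfg.specimen_id,
                "taxon_id": cfg.taxon_id,
                "bone": cfg.bones[i],
                "point_index": i + 1,
                "role": cfg.roles[i],
                "curve_id": cfg.curve_ids[i] or "",
                "x": cfg.points[i, 0],
                "y": cfg.points[i, 1],
                "z": cfg.points[i, 2],
            })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_landmarks(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations in the canonical one-row-per-point CSV dialect."""
    configs_to_frame(configs).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Size and superimposition

def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared distances of all points to their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if pts.shape[0] < 2:
        raise LandmarkError("centroid size needs K >= 2 points")
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs == 0.0:
        warnings.warn("all points coincide; centroid size is 0", stacklevel=2)
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||source @ R - target|| (no reflection)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.ones(3)
    s[-1] = d if d != 0 else 1.0
    return (u * s) @ vt


def _preshape(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centred = pts - pts.mean(axis=0)
    cs = np.sqrt((centred ** 2).sum())
    if cs == 0:
        raise LandmarkError("degenerate configuration: zero centroid size")
    return centred / cs, float(cs)


def gpa_align(configs: Sequence[LandmarkConfiguration],
              tol: float = 1e-10, max_iter: int = 100,
              project_to_tangent: bool = True) -> ProcrustesAlignment:
    """Generalized Procrustes Analysis of a set of configurations.

    Configurations are centred, scaled to unit centroid size and rotated
    (proper rotations only) onto the running consensus; the consensus is the
    arithmetic mean rescaled to unit centroid size.  Iteration stops when the
    RMS change of the consensus drops below ``tol``.

    ``tangent_coords`` are the flattened orthogonal projections of the
    aligned shapes onto the affine tangent plane of the unit pre-shape
    sphere at the consensus (switchable with ``project_to_tangent``).
    """
    if len(configs) < 2:
        raise LandmarkError("GPA needs at least 2 configurations")
    k = configs[0].n_points
    for c in configs:
        if c.n_points != k:
            raise LandmarkError(
                f"specimen {c.specimen_id!r} has {c.n_points} points, "
                f"expected {k}")
    shapes = []
    sizes = []
    for c in configs:
        pre, cs = _preshape(c.points)
        if np.linalg.matrix_rank(pre, tol=1e-10) < 2:
            raise LandmarkError(
                f"specimen {c.specimen_id!r} is degenerate (rank < 2)")
        shapes.append(pre)
        sizes.append(cs)
    X = np.array(shapes)                       # (n, K, 3)
    consensus = X[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus, _ = _preshape(X.mean(axis=0))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise LandmarkError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {change:.3e})")
    # final rotation pass onto the converged consensus
    for i in range(X.shape[0]):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)

    flat = X.reshape(X.shape[0], -1)
    cvec = consensus.ravel()
    if project_to_tangent:
        # projection onto the affine plane {y : y . c = 1} at unit-norm c
        flat = flat + (1.0 - flat @ cvec)[:, None] * cvec[None, :]
    aligned = [c.with_points(X[i]) for i, c in enumerate(configs)]
    cons_cfg = configs[0].with_points(consensus, specimen_id="consensus",
                                      taxon_id="consensus")
    return ProcrustesAlignment(
        aligned=aligned, consensus=cons_cfg,
        centroid_sizes=np.array(sizes), tangent_coords=flat,
        n_iterations=n_iter)


# ---------------------------------------------------------------------------
# Semilandmark sliding

def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a (K, 3) reference.

    Uses the 3D TPS kernel U(r) = -r (the sign that makes the energy
    quadratic form positive semidefinite).  Returns the K x K matrix B such
    that the bending energy of a displacement field y (per coordinate axis
    d) is sum_d y_d^T B y_d.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    K = -cdist(ref, ref)
    Q = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    B = Linv[:k, :k]
    return (B + B.T) / 2


@dataclasses.dataclass
class SlidingResult:
    configurations: list[LandmarkConfiguration]
    alignment: ProcrustesAlignment
    criterion_history: list[float]


def _curve_tangents(pts: np.ndarray,
                    scheme: SlidingScheme) -> tuple[np.ndarray, list[int]]:
    """Unit tangents at interior semilandmarks from flanking neighbours."""
    tangents = []
    indices = []
    for cid, a, b, c in scheme.sliding_indices():
        t = pts[c] - pts[a]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            raise LandmarkError(
                f"curve {cid!r}: coincident neighbours around point {b}; "
                f"tangent undefined")
        tangents.append(t / norm)
        indices.append(b)
    return np.array(tangents), indices


def _criterion_value(X: np.ndarray, consensus: np.ndarray,
                     criterion: str, B: np.ndarray | None) -> float:
    diff = X - consensus[None]
    if criterion == "procrustes_distance":
        return float((diff ** 2).sum())
    val = 0.0
    for i in range(X.shape[0]):
        for d in range(3):
            y = diff[i, :, d]
            val += float(y @ B @ y)
    return val


def slide_semilandmarks(configs: Sequence[LandmarkConfiguration],
                        scheme: SlidingScheme,
                        criterion: str = "bending_energy",
                        n_cycles: int = 3) -> SlidingResult:
    """Slide semilandmarks along their curve tangents against the consensus.

    Each cycle: GPA, estimate per-specimen curve tangents from flanking
    neighbours, then displace every interior semilandmark along its tangent
    by the closed-form minimiser of the chosen criterion (thin-plate-spline
    bending energy to the consensus, or summed squared Procrustes distance).
    Anchors and fixed landmarks never move.  A cycle whose criterion would
    exceed the previous cycle's value (possible once the consensus
    re-estimate has essentially converged) is discarded and iteration
    stops, so the reported criterion history is non-increasing.
    """
    if criterion not in ("bending_energy", "procrustes_distance"):
        raise LandmarkError(f"unknown sliding criterion {criterion!r}")
    scheme.validate(configs[0])
    current = list(configs)
    history: list[float] = []
    alignment = gpa_align(current, project_to_tangent=False)
    for _ in range(n_cycles):
        X = np.array([c.points for c in alignment.aligned])
        consensus = alignment.consensus.points
        B = bending_energy_matrix(consensus) if criterion == "bending_energy" else None
        for i in range(X.shape[0]):
            tangents, idx = _curve_tangents(X[i], scheme)
            if criterion == "procrustes_distance":
                # independent 1-D orthogonal projections onto tangent lines
                for t, j in zip(tangents, idx):
                    tau = float(t @ (consensus[j] - X[i, j]))
                    X[i, j] += tau * t
            else:
                m = len(idx)
                # stacked point-major coordinates; energy = y^T (B (x) I3) y
                y0 = (X[i] - consensus).ravel()
                Bk = np.kron(B, np.eye(3))
                U = np.zeros((3 * X.shape[1], m))
                for col, (t, j) in enumerate(zip(tangents, idx)):
                    U[3 * j:3 * j + 3, col] = t
                A = U.T @ Bk @ U
                b = -U.T @ (Bk @ y0)
                tau = np.linalg.lstsq(A, b, rcond=None)[0]
                for col, (t, j) in enumerate(zip(tangents, idx)):
                    X[i, j] += tau[col] * t
        value = _criterion_value(X, consensus, criterion, B)
        if history and value > history[-1]:
            break                      # converged: further cycles cannot help
        history.append(value)
        current = [c.with_points(X[i]) for i, c in enumerate(alignment.aligned)]
        alignment = gpa_align(current, project_to_tangent=False)
    # rescale slid shapes to their original centroid sizes for downstream use
    out = [c.with_points(a.points * s) for c, a, s in
           zip(configs, alignment.aligned, gpa_sizes(configs))]
    return SlidingResult(configurations=out, alignment=alignment,
                         criterion_history=history)


def gpa_sizes(configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
    return np.array([centroid_size(c) for c in configs])


# ---------------------------------------------------------------------------
# Taxon means and limb assembly

def taxon_mean_shape(configs: Sequence[LandmarkConfiguration]
                     ) -> list[LandmarkConfiguration]:
    """Per-taxon grand mean shapes of GPA-aligned configurations.

    The mean of each taxon's aligned shapes is rescaled to the taxon's mean
    centroid size (mm), so means remain size-comparable downstream.
    """
    if not configs:
        raise LandmarkError("empty configuration list")
    taxa: dict[str, list[int]] = {}
    for i, c in enumerate(configs):
        taxa.setdefault(c.taxon_id, []).append(i)
    if len(configs) == 1:
        only = configs[0]
        return [only.with_points(only.points, specimen_id=only.taxon_id)]
    alignment = gpa_align(configs, project_to_tangent=False)
    sizes = alignment.centroid_sizes
    out = []
    for taxon, idx in taxa.items():
        if not idx:
            raise LandmarkError(f"taxon {taxon!r} has no configurations")
        mean = np.mean([alignment.aligned[i].points for i in idx], axis=0)
        mean_cs = float(np.mean(sizes[idx]))
        pre, _ = _preshape(mean)
        out.append(configs[idx[0]].with_points(
            pre * mean_cs, specimen_id=taxon, taxon_id=taxon))
    return out


def _principal_frame(pts: np.ndarray) -> np.ndarray:
    """Rows = principal axes of a centred point cloud, deterministic signs."""
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axes = vt.copy()
    for a in range(axes.shape[0]):
        proj = centred @ axes[a]
        if proj[np.argmax(np.abs(proj))] < 0:
            axes[a] = -axes[a]
    if np.linalg.det(axes) < 0:
        axes[-1] = -axes[-1]
    return axes


def element_length(config: LandmarkConfiguration) -> float:
    """Proximodistal length: extent along the first principal axis."""
    centred = config.points - config.points.mean(axis=0)
    axis = _principal_frame(config.points)[0]
    proj = centred @ axis
    return float(proj.max() - proj.min())


def assemble_limb(femur: LandmarkConfiguration,
                  tibia: LandmarkConfiguration,
                  fibula: LandmarkConfiguration,
                  cfg: AssemblyConfig | None = None) -> LandmarkConfiguration:
    """Mount femur, tibia and fibula into one composite configuration.

    Each element is rotated into its principal frame with the proximodistal
    (first principal) axis mapped to -z, proximal end up.  The zeugopod
    elements are translated distally so the stylopod-zeugopod gap equals
    ``gap_fraction`` x femur length, and offset laterally (tibia medial,
    fibula lateral) so they do not interpenetrate.  No morphology is
    imputed: a missing element is an error.
    """
    cfg = cfg or AssemblyConfig()
    for el, name in ((femur, "femur"), (tibia, "tibia"), (fibula, "fibula")):
        if el is None:
            raise LandmarkError(f"missing element: {name}")

    def to_frame(el: LandmarkConfiguration, name: str) -> np.ndarray:
        centred = el.points - el.points.mean(axis=0)
        axes = _principal_frame(el.points)
        local = centred @ axes.T          # columns: PC1 (proximodistal), PC2, PC3
        if cfg.flip.get(name, False):
            local[:, 0] = -local[:, 0]
            local[:, 1] = -local[:, 1]    # keep handedness
        # x = lateral (PC2), y = anteroposterior (PC3), z = proximodistal up
        return np.column_stack([local[:, 1], local[:, 2], local[:, 0]])

    f = to_frame(femur, "femur")
    t = to_frame(tibia, "tibia")
    fb = to_frame(fibula, "fibula")
    lf = f[:, 2].max() - f[:, 2].min()
    gap = cfg.gap_fraction * lf
    width = f[:, 0].max() - f[:, 0].min()
    offset = cfg.lateral_offset_fraction * width

    f[:, 2] -= f[:, 2].max()                       # proximal femur at z = 0
    for el, sign in ((t, -1.0), (fb, +1.0)):
        el[:, 2] -= el[:, 2].max()                 # proximal end to z = 0
        el[:, 2] -= lf + gap                       # then below femur + gap
        el[:, 0] += sign * offset

    def relabel(el: LandmarkConfiguration, bone: str) -> list[str | None]:
        return [f"{bone}:{c}" if c else None for c in el.curve_ids]

    points = np.vstack([f, t, fb])
    return LandmarkConfiguration(
        specimen_id=femur.specimen_id,
        taxon_id=femur.taxon_id,
        points=points,
        roles=list(femur.roles) + list(tibia.roles) + list(fibula.roles),
        bones=["femur"] * femur.n_points + ["tibia"] * tibia.n_points
              + ["fibula"] * fibula.n_points,
        curve_ids=relabel(femur, "femur") + relabel(tibia, "tibia")
                  + relabel(fibula, "fibula"),
    )
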