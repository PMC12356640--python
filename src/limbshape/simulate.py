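"""Synthetic limb-shape datasets with known evolutionary ground truth.

The generator builds a deterministic parametric three-bone hind limb
template (28 fixed landmarks, 12 semilandmark curves, assembled with the
2% stylopod-zeugopod gap convention), defines a small set of orthonormal
latent deformation fields on it (stylopod arching, zeugopod shortening,
lateromedial widening), evolves the latent scores and a log centroid size
trait on a time tree under Brownian motion with tunable Pagel's lambda and
directional drift, and emits per-taxon landmark configurations with
independent observation noise.  Every downstream stage (GPA, PCA, signal,
allometry, trend) can therefore be checked against known truth.
"""

from __future__ import annotations

import dataclasses
import random
from importlib import resources

import numpy as np
import dendropy

from .landmarks import (LandmarkConfiguration, SlidingScheme, AssemblyConfig,
                        assemble_limb, centroid_size)
from .trees import TimeTree, Node, TreeError, read_newick, write_newick


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic dataset.

    Defaults emulate the study conditions this package is built around:
    a 17-taxon macronarian-scale sample, strong phylogenetic signal
    (lambda = 1, near the empirical log-size estimate), a mild negative
    size drift (phyletic size decrease), latent shape variance tuned so
    tip score spread is a few hundredths of a Procrustes unit, and small
    independent landmark noise.
    """

    n_tips: int = 17
    tree_source: str = "birth_death"          # or a newick string
    birth_rate: float = 0.12                  # 1/My
    death_rate: float = 0.06                  # 1/My
    tree_depth: float = 80.0                  # My, tree rescaled to this depth
    sigma2: float = 4.5e-5                    # latent score variance / My
    lambda_true: float = 1.0
    mu: float = 0.0                           # latent drift / My
    sigma2_size: float = 0.002                # log-size variance / My
    mu_size: float = -0.01                    # log-mm / My (size decrease)
    root_log_size: float = 7.44               # log mm, ~1700 mm limbs
    noise_sd: float = 0.003                   # shape units per coordinate
    n_latent: int = 3
    n_semilandmarks: int = 5                  # interior points per curve
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        for name in ("sigma2", "sigma2_size", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise SimulationError(f"{name} must be finite")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise SimulationError("lambda_true must be in [0, 1]")
        if not 1 <= self.n_latent <= 4:
            raise SimulationError("n_latent must be 1..4")


@dataclasses.dataclass
class SyntheticDataset:
    tree: TimeTree
    configurations: list[LandmarkConfiguration]
    scheme: SlidingScheme
    template: LandmarkConfiguration
    true_scores: np.ndarray            # (n_tips, n_latent), tip order
    true_log_sizes: np.ndarray         # (n_tips,), tip order
    true_node_log_sizes: dict[int, float]
    basis: np.ndarray                  # (n_latent, 3K) orthonormal fields
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Template limb

def _bone_template(n_fixed: int, length: float, rx: float, ry: float,
                   n_semi: int, bone: str) -> LandmarkConfiguration:
    """Schematic bone: fixed points on proximal/distal ends (+ mid-shaft for
    the femur), four longitudinal curves with slight radial bow.

    The cross-section is slightly elliptical (rx > ry) so the principal
    axes of the cloud are unambiguous.
    """
    pts: list[list[float]] = []
    roles: list[str] = []
    cids: list[str | None] = []
    h = length / 2.0

    def add(p, role, cid=None):
        pts.append(list(p))
        roles.append(role)
        cids.append(cid)

    # 4 fixed points per end: anterior/posterior on the sagittal plane,
    # lateral/medial as a bilateral pair
    for z in (h, -h):
        add((0.0, ry, z), "fixed", f"{bone}_ant")
        add((0.0, -ry, z), "fixed", f"{bone}_post")
        add((rx, 0.0, z), "fixed", f"{bone}_lat")
        add((-rx, 0.0, z), "fixed", f"{bone}_med")
    if n_fixed == 12:                          # femur: 4 extra mid-shaft points
        add((0.0, ry * 0.8, 0.0), "fixed")
        add((0.0, -ry * 0.8, 0.0), "fixed")
        add((rx * 0.8, 0.0, 0.0), "fixed")
        add((-rx * 0.8, 0.0, 0.0), "fixed")
    elif n_fixed != 8:
        raise SimulationError("bone template supports 8 or 12 fixed points")

    # curves: interior semilandmarks between matching proximal/distal anchors
    for ci, (x0, y0) in enumerate([(0.0, ry), (0.0, -ry),
                                   (rx, 0.0), (-rx, 0.0)]):
        cid = (f"{bone}_ant", f"{bone}_post", f"{bone}_lat", f"{bone}_med")[ci]
        for j in range(1, n_semi + 1):
            t = j / (n_semi + 1)
            bow = 0.15 * max(rx, ry) * np.sin(np.pi * t)
            nx = x0 + (np.sign(x0) if x0 else 0.0) * bow
            ny = y0 + (np.sign(y0) if y0 else 0.0) * bow
            add((nx, ny, h - t * length), "semilandmark", cid)
    return LandmarkConfiguration(
        specimen_id=bone, taxon_id="template", points=np.array(pts),
        roles=roles, bones=[bone] * len(pts), curve_ids=cids)


def make_template_limb(n_semilandmarks: int = 5
                       ) -> tuple[LandmarkConfiguration, SlidingScheme]:
    """Deterministic parametric limb with 28 fixed landmarks and 12 curves.

    The femur carries 12 fixed landmarks and the two zeugopod bones 8 each;
    every bone carries four longitudinal semilandmark curves anchored on
    fixed end landmarks, giving 12 curves in total.  Elements are assembled
    with the default 2% stylopod-zeugopod gap.  The template is bilaterally
    symmetric: mirroring the lateral axis and swapping the bilateral pair
    landmarks (see :func:`mirror_pair_map`) reproduces it exactly.
    """
    if n_semilandmarks < 3:
        raise SimulationError("need >= 3 semilandmarks per curve")
    # tibia and fibula share dimensions so the assembled template is an
    # exact bilateral object (mirroring swaps the two zeugopod elements)
    femur = _bone_template(12, 1.00, 0.13, 0.10, n_semilandmarks, "femur")
    tibia = _bone_template(8, 0.72, 0.10, 0.08, n_semilandmarks, "tibia")
    fibula = _bone_template(8, 0.72, 0.10, 0.08, n_semilandmarks, "fibula")
    limb = assemble_limb(femur, tibia, fibula, AssemblyConfig(gap_fraction=0.02))
    limb = limb.with_points(limb.points, specimen_id="template",
                            taxon_id="template")
    curves: dict[str, list[int]] = {}
    # anchors: the proximal/distal fixed landmarks that share the curve id
    for cid in sorted({c for c in limb.curve_ids if c}):
        anchor_idx = [i for i in range(limb.n_points)
                      if limb.curve_ids[i] == cid and limb.roles[i] == "fixed"]
        semi_idx = [i for i in range(limb.n_points)
                    if limb.curve_ids[i] == cid
                    and limb.roles[i] == "semilandmark"]
        curves[cid] = [anchor_idx[0]] + semi_idx + [anchor_idx[1]]
    scheme = SlidingScheme(curves=curves)
    scheme.validate(limb)
    return limb, scheme


def mirror_pair_map(template: LandmarkConfiguration) -> list[int]:
    """Index permutation pairing bilateral (+x / -x) landmarks.

    Mirroring x -> -x maps each landmark onto the position of its partner;
    applying this permutation restores the original labelling.
    """
    pts = template.points
    perm = list(range(template.n_points))
    used = set()
    for i in range(template.n_points):
        if i in used:
            continue
        mirrored = pts[i] * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(pts - mirrored, axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-9:
            raise SimulationError(
                f"template point {i} has no bilateral partner")
        perm[i], perm[j] = j, i
        used.update((i, j))
    return perm


# ---------------------------------------------------------------------------
# Latent deformation basis

def latent_basis(template: LandmarkConfiguration,
                 n_latent: int = 3) -> np.ndarray:
    """(n_latent, 3K) orthonormal deformation fields on the template.

    Fields mimic the principal shape contrasts of arched wide-gauge limbs:
    stylopod arching (lateral bowing of the femur), zeugopod proximodistal
    shortening, lateromedial widening, and (optionally) femoral distal
    twisting.  Each field is projected orthogonal to the similarity
    components (translations, rotations, scaling of the template) and then
    orthonormalized, so they are pure shape directions.
    """
    pts = template.points
    k = pts.shape[0]
    z = pts[:, 2]
    is_femur = np.array([b == "femur" for b in template.bones])
    is_zeug = ~is_femur
    fields = []

    arch = np.zeros((k, 3))
    zf = z[is_femur]
    arch[is_femur, 0] = np.sin(np.pi * (z[is_femur] - zf.min())
                               / (zf.max() - zf.min()))
    fields.append(arch)

    shorten = np.zeros((k, 3))
    zz = z[is_zeug]
    shorten[is_zeug, 2] = (zz.max() - zz)        # pull distal points proximally
    fields.append(shorten)

    widen = np.zeros((k, 3))
    widen[:, 0] = pts[:, 0]
    widen[is_zeug, 0] *= 2.0                     # zeugopod widens faster
    fields.append(widen)

    if n_latent >= 4:
        twist = np.zeros((k, 3))
        lever = (z - z.min()) / (z.max() - z.min())
        twist[:, 0] = -pts[:, 1] * lever
        twist[:, 1] = pts[:, 0] * lever
        fields.append(twist)

    flat = [f.ravel() for f in fields[:n_latent]]
    # similarity components to remove
    sim = []
    for d in range(3):
        tr = np.zeros((k, 3))
        tr[:, d] = 1.0
        sim.append(tr.ravel())
    centred = pts - pts.mean(axis=0)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        rot = np.zeros((k, 3))
        rot[:, a] = -centred[:, b]
        rot[:, b] = centred[:, a]
        sim.append(rot.ravel())
    sim.append(centred.ravel())                  # scaling
    basis = []
    for f in flat:
        v = f.copy()
        for s in sim:
            v -= (v @ s) / (s @ s) * s
        for prev in basis:
            v -= (v @ prev) * prev
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise SimulationError("degenerate latent field")
        basis.append(v / norm)
    return np.array(basis)


# ---------------------------------------------------------------------------
# Trait simulation on trees

def lambda_branch_lengths(tree: TimeTree, lam: float) -> dict[int, float]:
    """Per-branch lengths realising the Pagel's-lambda tip covariance.

    Internal branches are scaled by lambda; each terminal branch is
    lambda * b + (1 - lambda) * depth(tip), which leaves tip variances
    untouched while shrinking shared covariances.
    """
    depths = tree.depths()
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.is_leaf:
            out[node.id] = lam * node.length + (1 - lam) * depths[node.id]
        else:
            out[node.id] = lam * node.length
    return out


def simulate_traits(tree: TimeTree, sigma2: float, lambda_true: float = 1.0,
                    mu: float = 0.0, seed: int | None = None,
                    root_state: float = 0.0,
                    rng: np.random.Generator | None = None
                    ) -> dict[int, float]:
    """Recursive root-to-tip BM simulation; returns values for all nodes.

    Along a branch of length t the child value is
    parent + mu * t + N(0, sigma2 * t_lambda), where t_lambda is the
    lambda-transformed branch length (drift acts on real time).  Internal
    node truth is retained for ancestral-state validation.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lam_len = lambda_branch_lengths(tree, lambda_true)
    values = {tree.root.id: float(root_state)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length
        if t is None:
            raise SimulationError("tree must be calibrated (branch lengths)")
        values[node.id] = (values[node.parent.id] + mu * t
                           + rng.standard_normal()
                           * np.sqrt(max(sigma2 * lam_len[node.id], 0.0)))
    return values


# ---------------------------------------------------------------------------
# Trees

def birth_death_tree(n_tips: int, birth_rate: float, death_rate: float,
                     seed: int, depth: float | None = None) -> TimeTree:
    """Seeded constant-rate birth-death tree with n extant tips.

    Simulation (with resimulation until the tip count is reached) is
    delegated to dendropy; the tree is optionally rescaled to a fixed root
    depth in My and tips are labelled t1..tn.
    """
    rng = random.Random(seed)
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=rng)
    newick = dtree.as_string(schema="newick").strip()
    tree = read_newick(newick)
    for i, tip in enumerate(tree.tips):
        tip.label = f"t{i + 1}"
    tree = TimeTree(tree.root)          # re-index, re-check labels
    if depth is not None:
        d = tree.depths()
        scale = depth / max(d.values())
        for node in tree.preorder():
            if node.length is not None:
                node.length *= scale
    # the simulator stops exactly at the n-th birth, so the youngest
    # branches have zero length; floor them to keep BM covariances
    # positive definite
    d = tree.depths()
    floor = 1e-4 * max(d.values())
    for node in tree.preorder():
        if node.length is not None and node.length < floor:
            node.length = floor
    # ages from depths (extant tips at ~0)
    d = tree.depths()
    total = max(d.values())
    for node in tree.preorder():
        node.age = total - d[node.id]
    return tree


def fixture_tree() -> tuple[TimeTree, dict[str, float], dict[str, frozenset[str]]]:
    """The packaged 17-taxon macronarian fixture.

    Returns the uncalibrated topology, approximate tip ages (Ma) and the
    nested clade annotations (Titanosauriformes, Somphospondyli,
    Titanosauria, Lithostrotia incl. Antarctosaurus).  Ages are synthetic
    stratigraphic-midpoint stand-ins, not measured data.
    """
    data = resources.files("limbshape") / "data"
    tree = read_newick((data / "macronaria_17.nwk").read_text())
    import pandas as pd
    ages_df = pd.read_csv((data / "tip_ages.csv").open())
    ages = dict(zip(ages_df["taxon"], ages_df["age_Ma"].astype(float)))
    clades_df = pd.read_csv((data / "clades.csv").open())
    clades: dict[str, set[str]] = {}
    for clade, taxon in zip(clades_df["clade"], clades_df["taxon"]):
        clades.setdefault(clade, set()).add(taxon)
    tree.clades = {k: frozenset(v) for k, v in clades.items()}
    return tree, ages, tree.clades


# ---------------------------------------------------------------------------
# Full dataset

def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset from a seeded configuration.

    The tree is built (or parsed), latent deformation scores and log
    centroid size evolve on it, and each tip receives an assembled-limb
    configuration: template + sum(latent * basis) + iid noise, scaled to
    exp(log size) mm and placed in a random rigid orientation so that
    downstream GPA has real work to do.  Regeneration from the same config
    is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree_source == "birth_death":
        tree = birth_death_tree(config.n_tips, config.birth_rate,
                                config.death_rate,
                                seed=int(rng.integers(2 ** 31)),
                                depth=config.tree_depth)
    else:
        tree = read_newick(config.tree_source)
        if any(n.length is None for n in tree.preorder()
               if n.parent is not None):
            raise SimulationError("fixed_newick tree must have branch lengths")

    template, scheme = make_template_limb(config.n_semilandmarks)
    pre = template.points - template.points.mean(axis=0)
    pre = pre / np.sqrt((pre ** 2).sum())        # unit centroid size template
    basis = latent_basis(template, config.n_latent)

    tips = tree.tips
    scores = np.zeros((len(tips), config.n_latent))
    for a in range(config.n_latent):
        vals = simulate_traits(tree, config.sigma2, config.lambda_true,
                               config.mu, rng=rng)
        scores[:, a] = [vals[t.id] for t in tips]
    node_log_sizes = simulate_traits(tree, config.sigma2_size, 1.0,
                                     config.mu_size, rng=rng,
                                     root_state=config.root_log_size)
    log_sizes = np.array([node_log_sizes[t.id] for t in tips])

    configs = []
    for i, tip in enumerate(tips):
        flat = pre.ravel() + scores[i] @ basis
        flat = flat + config.noise_sd * rng.standard_normal(flat.size)
        shape = flat.reshape(-1, 3) * np.exp(log_sizes[i])
        # random rigid motion
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shape = shape @ q.T + rng.normal(scale=100.0, size=3)
        configs.append(template.with_points(
            shape, specimen_id=f"{tip.label}_s1", taxon_id=tip.label))
    return SyntheticDataset(
        tree=tree, configurations=configs, scheme=scheme, template=template,
        true_scores=scores, true_log_sizes=log_sizes,
        true_node_log_sizes=node_log_sizes, basis=basis, config=config)
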