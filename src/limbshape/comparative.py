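"""Brownian-motion comparative methods on time trees.

Implements the phylogenetic covariance matrix and its Pagel's-lambda
transform, profile maximum-likelihood estimation of lambda with a
simulation-based likelihood-ratio test, GLS ancestral character estimation
under Brownian motion, phylomorphospace projection, and a simulation-based
phylogenetic ANOVA.

Under Brownian motion with rate sigma^2 the trait covariance of two tips is
sigma^2 times the shared root-to-MRCA path length; Pagel's lambda rescales
the off-diagonal (shared) part only, so lambda = 1 is pure BM and
lambda = 0 is star-like independence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, linalg

from .trees import TimeTree, Node, TreeError, _subtree_tips


class ComparativeError(ValueError):
    pass


@dataclasses.dataclass
class PhyloCovariance:
    C: np.ndarray
    tip_labels: list[str]
    lam: float


@dataclasses.dataclass
class SignalFit:
    """Pagel's lambda fit for one trait on one tree."""

    lambda_hat: float
    sigma2_hat: float
    root_state: float
    loglik_at_hat: float
    loglik_at_zero: float
    LR: float
    p: float | None
    identifiable: bool = True


@dataclasses.dataclass
class AncestralStates:
    """Per-node BM estimates; tips carry their observed values (variance 0)."""

    estimates: dict[int, float]
    variances: dict[int, float]
    tip_ids: list[int]

    def value(self, node: Node) -> float:
        return self.estimates[node.id]


@dataclasses.dataclass
class PhyloANOVAResult:
    df_factor: int
    df_residual: int
    ss_factor: float
    ss_residual: float
    ss_total: float
    ms_factor: float
    ms_residual: float
    r_squared: float
    F: float
    Z: float
    p: float


# ---------------------------------------------------------------------------

def _tip_order(tree: TimeTree) -> list[Node]:
    return tree.tips


def bm_covariance(tree: TimeTree, lam: float = 1.0) -> PhyloCovariance:
    """Tip covariance of BM on the tree, off-diagonals scaled by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ComparativeError("lambda must be in [0, 1]")
    tips = _tip_order(tree)
    n = len(tips)
    depths = tree.depths()
    index = {t.id: i for i, t in enumerate(tips)}
    C = np.zeros((n, n))
    for node in tree.preorder():
        if node.is_leaf:
            C[index[node.id], index[node.id]] = depths[node.id]
            continue
        children_tipsets = [[index[t.id] for t in _subtree_tips(ch)]
                            for ch in node.children]
        d = depths[node.id]
        for a in range(len(children_tipsets)):
            for b in range(a + 1, len(children_tipsets)):
                for i in children_tipsets[a]:
                    for j in children_tipsets[b]:
                        C[i, j] = C[j, i] = d
    if lam != 1.0:
        diag = np.diag(C).copy()
        C = C * lam
        np.fill_diagonal(C, diag)
    return PhyloCovariance(C=C, tip_labels=[t.label for t in tips], lam=lam)


def _as_vector(tree: TimeTree, trait) -> np.ndarray:
    tips = tree.tip_labels
    if isinstance(trait, dict):
        missing = [t for t in tips if t not in trait]
        if missing:
            raise ComparativeError(f"trait missing for tips: {missing}")
        x = np.array([float(trait[t]) for t in tips])
    else:
        x = np.asarray(trait, float)
        if x.shape[0] != len(tips):
            raise ComparativeError(
                f"trait length {x.shape[0]} != number of tips {len(tips)}")
    if not np.all(np.isfinite(x)):
        raise ComparativeError("non-finite trait values")
    return x


def _gls_loglik(x: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """ML log-likelihood profile: (loglik, root_state, sigma2) for unit-rate V."""
    n = len(x)
    cf = linalg.cho_factor(V, lower=True)
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = float(x @ Vi1 / (ones @ Vi1))
    r = x - mu
    Vir = linalg.cho_solve(cf, r)
    s2 = float(r @ Vir) / n
    if s2 <= 0:
        raise ComparativeError("signal undefined: zero trait variance")
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, mu, s2


def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return _gls_loglik(x, V)[0]


def fit_lambda(tree: TimeTree, trait, n_sim: int = 1000,
               seed: int | None = None,
               xatol: float = 1e-6) -> SignalFit:
    """Profile-ML Pagel's lambda with a simulation-based LR test.

    At each lambda the root state and BM rate are profiled out by GLS; the
    scalar profile is maximised over [0, 1] by bounded Brent search.  The
    likelihood ratio LR = 2(l(lambda_hat) - l(0)) is referred to its null
    distribution obtained by simulating ``n_sim`` datasets under the
    lambda = 0 model (independent normal tips with the GLS-estimated mean
    and rate) and refitting; p is the fraction of null LRs >= observed.
    Set ``n_sim = 0`` to skip the test (p is then None).
    """
    if len(tree.tips) < 4:
        raise ComparativeError("lambda fit needs >= 4 tips")
    x = _as_vector(tree, trait)
    if np.ptp(x) == 0:
        raise ComparativeError("signal undefined: zero trait variance")
    C = bm_covariance(tree, 1.0).C
    off = C[~np.eye(C.shape[0], dtype=bool)]
    if np.all(off == 0):
        ll0, mu, s2 = _gls_loglik(x, np.diag(np.diag(C)))
        return SignalFit(lambda_hat=0.0, sigma2_hat=s2, root_state=mu,
                         loglik_at_hat=ll0, loglik_at_zero=ll0, LR=0.0,
                         p=1.0 if n_sim else None, identifiable=False)

    def observed_fit(xv: np.ndarray) -> tuple[float, float]:
        res = optimize.minimize_scalar(
            lambda lam: -_lambda_loglik(lam, C, xv),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": xatol})
        lam_hat, ll_hat = float(res.x), -float(res.fun)
        # the bounded optimiser never evaluates the exact endpoints
        for lam_edge in (0.0, 1.0):
            ll_edge = _lambda_loglik(lam_edge, C, xv)
            if ll_edge > ll_hat:
                lam_hat, ll_hat = lam_edge, ll_edge
        return lam_hat, ll_hat

    lam_hat, ll_hat = observed_fit(x)
    ll0, mu0, s20 = _gls_loglik(x, np.diag(np.diag(C)))
    LR = max(0.0, 2.0 * (ll_hat - ll0))
    _, mu_hat, s2_hat = _gls_loglik(
        x, _lambda_cov(C, lam_hat))

    p = None
    if n_sim:
        rng = np.random.default_rng(seed)
        sd0 = np.sqrt(s20 * np.diag(C))
        count = 0
        for _ in range(n_sim):
            xs = mu0 + sd0 * rng.standard_normal(len(x))
            _, ll_hat_s = observed_fit(xs)
            ll0_s = _gls_loglik(xs, np.diag(np.diag(C)))[0]
            if 2.0 * (ll_hat_s - ll0_s) >= LR - 1e-12:
                count += 1
        p = count / n_sim
    return SignalFit(lambda_hat=lam_hat, sigma2_hat=s2_hat, root_state=mu_hat,
                     loglik_at_hat=ll_hat, loglik_at_zero=ll0, LR=LR, p=p)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return V


# ---------------------------------------------------------------------------
# Ancestral states

def ace_bm(tree: TimeTree, trait) -> AncestralStates:
    """GLS/ML ancestral character estimates under Brownian motion.

    The root estimate is the GLS-weighted mean of the tips (weights from
    the inverse BM covariance); every other internal node is the
    conditional (BLUP) estimate given the tips, which coincides with the
    GLS root estimate of the tree rerooted at that node.
    """
    x = _as_vector(tree, trait)
    tips = tree.tips
    n = len(tips)
    depths = tree.depths()
    C = bm_covariance(tree, 1.0).C
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ComparativeError(
            "non-invertible phylogenetic covariance (duplicate zero-length "
            "tips?)") from exc
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cf, ones)
    mu = float(x @ Vi1 / (ones @ Vi1))
    r = x - mu
    Vir = linalg.cho_solve(cf, r)
    s2 = float(r @ Vir) / n

    tip_index = {t.id: i for i, t in enumerate(tips)}
    estimates: dict[int, float] = {}
    variances: dict[int, float] = {}
    # shared path length of internal node a with tip i = depth of MRCA(a, i);
    # computed from ancestor chains.
    ancestors: dict[int, list[int]] = {}
    for node in tree.preorder():
        chain = (ancestors[node.parent.id] + [node.parent.id]
                 if node.parent is not None else [])
        ancestors[node.id] = chain
    anc_sets = {nid: set(chain) | {nid} for nid, chain in ancestors.items()}

    for node in tree.preorder():
        if node.is_leaf:
            estimates[node.id] = float(x[tip_index[node.id]])
            variances[node.id] = 0.0
            continue
        if node is tree.root:
            estimates[node.id] = mu
            variances[node.id] = s2 / float(ones @ Vi1)
            continue
        cov = np.empty(n)
        own = anc_sets[node.id]
        for t in tips:
            shared = own & anc_sets[t.id]
            cov[tip_index[t.id]] = max(depths[a] for a in shared)
        w = linalg.cho_solve(cf, cov)
        estimates[node.id] = mu + float(w @ r)
        cvar = depths[node.id] - float(cov @ w)
        # uncertainty in the estimated root mean propagates into the BLUP
        h = 1.0 - float(w @ ones)
        cvar += h * h / float(ones @ Vi1)
        variances[node.id] = s2 * max(cvar, 0.0)
    return AncestralStates(estimates=estimates, variances=variances,
                           tip_ids=[t.id for t in tips])


def phylomorphospace(tree: TimeTree, scores) -> dict:
    """Project a tree into a 2D score space.

    ``scores`` maps tip label -> (PC_a, PC_b) (dict, DataFrame or (n, 2)
    array in tip order).  Internal nodes are placed at their per-axis BM
    ancestral estimates; output contains per-node coordinates and the
    parent-child segment list.
    """
    tips = tree.tip_labels
    if hasattr(scores, "loc"):          # DataFrame indexed by taxon
        missing = [t for t in tips if t not in scores.index]
        if missing:
            raise ComparativeError(f"scores missing for tips: {missing}")
        mat = {t: np.asarray(scores.loc[t], float)[:2] for t in tips}
    elif isinstance(scores, dict):
        missing = [t for t in tips if t not in scores]
        if missing:
            raise ComparativeError(f"scores missing for tips: {missing}")
        mat = {t: np.asarray(scores[t], float)[:2] for t in tips}
    else:
        arr = np.asarray(scores, float)
        if arr.shape[0] != len(tips):
            raise ComparativeError(
                f"scores rows {arr.shape[0]} != number of tips {len(tips)}")
        mat = {t: arr[i, :2] for i, t in enumerate(tips)}
    coords: dict[int, np.ndarray] = {}
    for axis in range(2):
        states = ace_bm(tree, {t: mat[t][axis] for t in tips})
        for node in tree.preorder():
            coords.setdefault(node.id, np.zeros(2))[axis] = \
                states.estimates[node.id]
    segments = [(n.parent.id, n.id) for n in tree.preorder()
                if n.parent is not None]
    labels = {n.id: n.label for n in tree.preorder()}
    return {"coordinates": coords, "segments": segments, "labels": labels}


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA

def _anova_f(x: np.ndarray, codes: np.ndarray, n_groups: int
             ) -> tuple[float, float, float]:
    """(SS_factor, SS_residual, F) of a one-way layout."""
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_factor = 0.0
    for g in range(n_groups):
        xg = x[codes == g]
        ss_factor += len(xg) * (xg.mean() - grand) ** 2
    ss_resid = ss_total - ss_factor
    df_f = n_groups - 1
    df_r = len(x) - n_groups
    if ss_resid <= 0 or df_r == 0:
        return ss_factor, ss_resid, np.inf
    F = (ss_factor / df_f) / (ss_resid / df_r)
    return ss_factor, ss_resid, F


def simulate_bm_tips(tree: TimeTree, sigma2: float, rng: np.random.Generator,
                     n_datasets: int = 1) -> np.ndarray:
    """(n_datasets, n_tips) BM tip values (root state 0) via branch increments."""
    tips = tree.tips
    values = {tree.root.id: np.zeros(n_datasets)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length
        if t is None or t < 0:
            raise ComparativeError("tree must have non-negative branch lengths")
        values[node.id] = values[node.parent.id] + \
            np.sqrt(sigma2 * t) * rng.standard_normal(n_datasets)
    return np.column_stack([values[t.id] for t in tips])


def phylo_anova(tree: TimeTree, response, groups,
                n_sim: int = 1000, seed: int | None = None
                ) -> PhyloANOVAResult:
    """Simulation-based one-way phylogenetic ANOVA (Garland-style).

    The observed F is the ordinary one-way statistic; its null distribution
    comes from ``n_sim`` BM simulations of the response on the tree with the
    ML rate of the observed data.  p is the fraction of simulated F >=
    observed; Z standardises the observed F against the simulated ones.
    """
    x = _as_vector(tree, response)
    tips = tree.tip_labels
    if isinstance(groups, dict):
        glabels = [groups[t] for t in tips]
    else:
        glabels = list(groups)
    uniq = sorted(set(glabels))
    if len(uniq) < 2:
        raise ComparativeError("phylogenetic ANOVA needs >= 2 groups")
    codes = np.array([uniq.index(g) for g in glabels])
    ng = len(uniq)

    ss_f, ss_r, F = _anova_f(x, codes, ng)
    ss_t = ss_f + ss_r
    df_f, df_r = ng - 1, len(x) - ng
    if ss_t == 0:
        return PhyloANOVAResult(df_factor=df_f, df_residual=df_r,
                                ss_factor=0.0, ss_residual=0.0, ss_total=0.0,
                                ms_factor=0.0, ms_residual=0.0,
                                r_squared=0.0, F=0.0, Z=0.0, p=1.0)

    C = bm_covariance(tree, 1.0).C
    _, _, s2 = _gls_loglik(x, C)
    rng = np.random.default_rng(seed)
    sims = simulate_bm_tips(tree, s2, rng, n_datasets=n_sim)
    f_sim = np.array([_anova_f(sims[i], codes, ng)[2] for i in range(n_sim)])
    p = float(np.mean(f_sim >= F))
    sd = f_sim.std(ddof=1)
    Z = float((F - f_sim.mean()) / sd) if sd > 0 else 0.0
    return PhyloANOVAResult(
        df_factor=df_f, df_residual=df_r, ss_factor=ss_f, ss_residual=ss_r,
        ss_total=ss_t, ms_factor=ss_f / df_f,
        ms_residual=ss_r / df_r if df_r else np.nan,
        r_squared=ss_f / ss_t, F=F, Z=Z, p=p)
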