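"""Shape PCA on tangent-space coordinates and component retention.

PCA is performed on the covariance of the flattened tangent-space
coordinates (Procrustes coordinates share a unit, so no correlation
scaling).  The number of meaningful components is chosen with Anderson's
sequential sphericity test on the trailing eigenvalues.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .landmarks import LandmarkConfiguration, ProcrustesAlignment


class OrdinationError(ValueError):
    pass


@dataclasses.dataclass
class ShapePCA:
    """Eigenstructure and scores of a shape PCA.

    eigenvalues are descending variances; eigenvectors is (3K, m) with
    unit-norm columns; scores is (n, m) and centred; proportion and
    cumulative are percentages over the nonzero components.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray
    proportion: np.ndarray
    cumulative: np.ndarray
    mean: np.ndarray
    n_retained: int
    specimen_ids: list[str]
    taxon_ids: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def shape_pca(alignment: ProcrustesAlignment | np.ndarray,
              alpha: float = 0.05,
              specimen_ids: list[str] | None = None,
              taxon_ids: list[str] | None = None) -> ShapePCA:
    """Covariance PCA of tangent coordinates with a deterministic sign fix.

    The sign of each component is chosen so its largest-magnitude loading
    is positive.  Eigenvalues numerically indistinguishable from zero
    (relative to the largest) are dropped; at most min(n-1, 3K-7)
    components can be nonzero for Procrustes data.
    """
    if isinstance(alignment, ProcrustesAlignment):
        X = alignment.tangent_coords
        specimen_ids = alignment.specimen_ids
        taxon_ids = alignment.taxon_ids
    else:
        X = np.asarray(alignment, float)
        specimen_ids = specimen_ids or [f"s{i}" for i in range(X.shape[0])]
        taxon_ids = taxon_ids or list(specimen_ids)
    n = X.shape[0]
    if n < 3:
        raise OrdinationError("shape PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = eig > (eig[0] * 1e-12 if eig[0] > 0 else 0)
    eig = eig[keep]
    vectors = vt[keep].T                      # (3K, m)
    scores = Xc @ vectors                     # (n, m)
    for j in range(vectors.shape[1]):
        imax = np.argmax(np.abs(vectors[:, j]))
        if vectors[imax, j] < 0:
            vectors[:, j] = -vectors[:, j]
            scores[:, j] = -scores[:, j]
    proportion = 100.0 * eig / eig.sum()
    cumulative = np.cumsum(proportion)
    n_retained = anderson_retention(eig, n, alpha=alpha)
    return ShapePCA(eigenvalues=eig, eigenvectors=vectors, scores=scores,
                    proportion=proportion, cumulative=cumulative, mean=mean,
                    n_retained=n_retained, specimen_ids=list(specimen_ids),
                    taxon_ids=list(taxon_ids))


def anderson_retention(eigenvalues: np.ndarray, n: int,
                       alpha: float = 0.05) -> int:
    """Sequential sphericity test on trailing eigenvalues (Anderson 1963).

    The trailing q eigenvalues are tested for equality with the statistic
    (n-1) * [q ln(mean) - sum(ln lambda)] against chi^2 with
    q(q+1)/2 - 1 degrees of freedom; components are retained until
    sphericity of the remainder is first not rejected.  A single nonzero
    eigenvalue is retained by convention.
    """
    eig = np.asarray(eigenvalues, float)
    if np.any(eig <= 0):
        warnings.warn("dropping nonpositive eigenvalues before Anderson test",
                      stacklevel=2)
        eig = eig[eig > 0]
    p = len(eig)
    if p == 0:
        return 0
    if p == 1:
        return 1
    for k in range(p - 1):
        trailing = eig[k:]
        q = len(trailing)
        stat = (n - 1) * (q * np.log(trailing.mean())
                          - np.log(trailing).sum())
        df = q * (q + 1) // 2 - 1
        if stat <= stats.chi2.isf(alpha, df):
            return k
    return p


def warp_along_pc(pca: ShapePCA,
                  consensus: LandmarkConfiguration | np.ndarray,
                  component: int, score: float) -> np.ndarray:
    """Shape at ``consensus + score * eigenvector`` reshaped to (K, 3).

    ``component`` is zero-based; a score of 0 returns the consensus.
    """
    if not 0 <= component < pca.n_components:
        raise OrdinationError(
            f"component {component} out of range (0..{pca.n_components - 1})")
    base = (consensus.points if isinstance(consensus, LandmarkConfiguration)
            else np.asarray(consensus, float))
    flat = base.ravel() + score * pca.eigenvectors[:, component]
    return flat.reshape(-1, 3)


def warp_full(pca: ShapePCA, scores: np.ndarray) -> np.ndarray:
    """Reconstruct a flattened shape from a full score vector."""
    return pca.mean + pca.eigenvectors @ np.asarray(scores, float)


def variance_table(pca: ShapePCA):
    """Per-PC explained and cumulative variance (%), one row per PC."""
    import pandas as pd
    return pd.DataFrame({
        "PC": [f"PC{i + 1}" for i in range(pca.n_components)],
        "explained_pct": np.round(pca.proportion, 2),
        "cumulative_pct": np.round(pca.cumulative, 2),
    })
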