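"""Pseudo-phylogenetic comparative analysis of regional diversity values.

Regions within a realm are not independent observations: the same flea and
host species recur across regions.  To control for this, a dendrogram of
regions is built from compositional dissimilarity (Bray–Curtis on the
combined flea+host incidence, complete linkage) and treated as a
pseudo-phylogeny: generalized least squares with a Brownian-motion
covariance on that tree replaces ordinary regression.  Forward stepwise
selection by AIC chooses among the host diversity component and the three
environmental composites, and residual spatial autocorrelation is checked
with Moran's I under inverse great-circle-distance weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .beta import great_circle
from .io import FormatError, IncidenceMatrix

logger = logging.getLogger("funclink")

__all__ = [
    "RegionTree",
    "PGLSFit",
    "MoranResult",
    "region_pseudotree",
    "bm_covariance",
    "pgls_fit",
    "phylostep_forward",
    "morans_i",
]


@dataclass
class RegionTree:
    """Ultrametric pseudo-phylogeny of regions.

    Stored via its cophenetic matrix of merge heights; with the leaf depth
    set to half the merge height, the patristic distance between two regions
    equals their cophenetic merge height and all root-to-leaf depths equal
    half the final merge height.
    """

    regions: list[str]
    coph: np.ndarray  # symmetric merge heights
    linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.regions)
        self.coph = np.asarray(self.coph, dtype=float)
        if self.coph.shape != (n, n):
            raise FormatError("cophenetic matrix shape mismatch")
        if not np.allclose(self.coph, self.coph.T, atol=1e-10):
            raise FormatError("cophenetic matrix not symmetric")

    @property
    def depth(self) -> float:
        """Root-to-leaf depth (half the final merge height)."""
        return float(self.coph.max() / 2.0)

    def patristic(self) -> np.ndarray:
        return self.coph.copy()

    def to_newick(self) -> str:
        if self.linkage is None:
            raise FormatError("no linkage stored; cannot serialize")
        tree = hierarchy.to_tree(self.linkage)

        def render(node, branch: float) -> str:
            if node.is_leaf():
                return f"{self.regions[node.id]}:{branch:.17g}"
            h = node.dist / 2.0
            inner = ",".join(render(c, h - c.dist / 2.0) for c in (node.left, node.right))
            return f"({inner}):{branch:.17g}"

        h_root = tree.dist / 2.0
        inner = ",".join(render(c, h_root - c.dist / 2.0) for c in (tree.left, tree.right))
        return f"({inner});"

    @classmethod
    def from_newick(cls, source: str, tol: float = 1e-8) -> "RegionTree":
        from .tree import FunctionalTree, patristic_matrix

        ft = FunctionalTree.from_newick(source)
        pm = patristic_matrix(ft)
        # ultrametricity: all root-to-leaf depths equal
        depths = {}
        parent = {child: (par, eid) for eid, (par, child) in enumerate(ft.edges)}
        for node, name in ft.leaf_name.items():
            d, u = 0.0, node
            while u in parent:
                par, eid = parent[u]
                d += ft.lengths[eid]
                u = par
            depths[name] = d
        dv = np.array([depths[name] for name in pm.labels])
        if dv.max() - dv.min() > tol:
            raise FormatError("region tree is not ultrametric")
        return cls(list(pm.labels), pm.values)


@dataclass
class PGLSFit:
    """GLS fit under a Brownian-motion covariance with ML sigma^2."""

    params: pd.DataFrame  # index=term; coef, se, t, p
    sigma2: float
    loglik: float
    aic: float
    residuals: np.ndarray
    n: int
    selection_path: list[dict] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)


@dataclass
class MoranResult:
    I: float
    expectation: float
    variance: float
    z: float
    p_value: float
    scheme: str


def region_pseudotree(
    flea_inc: IncidenceMatrix, host_inc: IncidenceMatrix
) -> RegionTree:
    """Cluster regions on combined flea+host composition.

    Columns of the two incidence matrices are concatenated, Bray–Curtis
    dissimilarity (for binary rows: 1 - 2a/(2a+b+c)) computed between
    regions, and a complete-linkage dendrogram built.  The dendrogram is
    read as an ultrametric tree with leaf depth equal to half the merge
    height, so patristic distance equals cophenetic merge height.
    """
    if set(flea_inc.regions) != set(host_inc.regions):
        raise FormatError("flea and host incidence have different region sets")
    host_inc = host_inc.align_regions(flea_inc.regions)
    combined = np.hstack([flea_inc.values, host_inc.values]).astype(float)
    cond = pdist(combined, metric="braycurtis")
    Z = hierarchy.linkage(cond, method="complete")
    coph = squareform(hierarchy.cophenet(Z))
    return RegionTree(list(flea_inc.regions), coph, Z)


def bm_covariance(tree: RegionTree) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-ancestor depth.

    ``C[i, j]`` is the depth of the most recent common ancestor of regions i
    and j below the root, i.e. ``(h_root - h_ij) / 2`` for merge heights h;
    the diagonal is the total depth.
    """
    h_root = float(tree.coph.max())
    C = (h_root - tree.coph) / 2.0
    np.fill_diagonal(C, h_root / 2.0)
    return C


def _prepare_design(X: pd.DataFrame | np.ndarray, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(names)


def pgls_fit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame | np.ndarray,
    C: np.ndarray,
    add_intercept: bool = True,
) -> PGLSFit:
    """Generalized least squares under covariance sigma^2 * C.

    beta = (X' C^-1 X)^-1 X' C^-1 y; sigma^2 by maximum likelihood
    (n denominator); t tests with n - k degrees of freedom on the
    coefficients (k regression coefficients).  A jitter of
    1e-10 * mean(diag(C)) is added if C is numerically singular.
    """
    y = np.asarray(y, dtype=float)
    X, names = _prepare_design(X)
    if add_intercept:
        X = np.hstack([np.ones((len(y), 1)), X])
        names = ["intercept"] + names
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        # name a minimal set of collinear columns
        bad = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise FormatError(f"rank-deficient design; collinear columns: {bad}")
    C = np.asarray(C, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(C)))
        logger.info("covariance singular; adding jitter %.3g", jitter)
        L = np.linalg.cholesky(C + jitter * np.eye(n))
    # whiten: solve L z = v
    from scipy.linalg import solve_triangular

    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    residw = yw - Xw @ beta
    rss = float(residw @ residw)
    sigma2 = rss / n  # ML
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())
    if sigma2 > 0:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetC + n)
    else:  # perfect fit
        loglik = np.inf
    n_par = k + 1  # coefficients + sigma^2
    aic = 2 * n_par - 2 * loglik
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    dof = n - k
    sigma2_u = rss / dof if dof > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2_u, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=max(dof, 1))
    params = pd.DataFrame({"coef": beta, "se": se, "t": tvals, "p": pvals}, index=names)
    return PGLSFit(params, sigma2, float(loglik), float(aic), resid, n)


def phylostep_forward(
    y: np.ndarray | pd.Series,
    candidates: pd.DataFrame,
    C: np.ndarray,
) -> PGLSFit:
    """Forward stepwise PGLS selection by AIC.

    Starts from the intercept-only model; at each step adds the candidate
    with the largest AIC decrease; stops when no addition decreases AIC.
    The selection path (AIC per step) is recorded on the returned fit.
    """
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    remaining = list(candidates.columns)
    current = pgls_fit(y, candidates[selected], C)
    path = [{"added": None, "model": [], "aic": current.aic}]
    while remaining:
        trials = []
        for name in remaining:
            fit = pgls_fit(y, candidates[selected + [name]], C)
            trials.append((fit.aic, name, fit))
        best_aic, best_name, best_fit = min(trials, key=lambda t: t[0])
        if best_aic < current.aic:
            selected.append(best_name)
            remaining.remove(best_name)
            current = best_fit
            path.append({"added": best_name, "model": list(selected), "aic": best_aic})
        else:
            break
    current.selection_path = path
    return current


def _moran_weights(coords: pd.DataFrame, scheme: str, knn: int = 5) -> np.ndarray:
    D = great_circle(coords).values
    n = len(D)
    off = ~np.eye(n, dtype=bool)
    if (D[off] == 0).any():
        raise FormatError(
            "coincident region coordinates give infinite weights; jitter the coordinates"
        )
    if scheme == "inverse_distance":
        W = np.zeros_like(D)
        W[off] = 1.0 / D[off]
    elif scheme == "knn":
        W = np.zeros_like(D)
        for i in range(n):
            order = np.argsort(D[i] + np.where(off[i], 0, np.inf))
            W[i, order[:knn]] = 1.0
    else:
        raise FormatError(f"unknown Moran weight scheme {scheme!r}")
    W /= W.sum(axis=1, keepdims=True)  # row-standardize
    return W


def morans_i(
    resid: np.ndarray,
    coords: pd.DataFrame,
    scheme: str = "inverse_distance",
    knn: int = 5,
) -> MoranResult:
    """Moran's I of residuals with a two-sided randomization-null p-value.

    I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    residuals; E[I] = -1/(n-1); the variance uses the standard
    randomization (permutation) moments with a normal approximation.
    """
    z = np.asarray(resid, dtype=float)
    n = len(z)
    if n < 4:
        raise FormatError("Moran's I needs at least 4 regions")
    W = _moran_weights(coords, scheme, knn)
    z = z - z.mean()
    W0 = W.sum()
    I = (n / W0) * float(z @ W @ z) / float(z @ z)
    EI = -1.0 / (n - 1)
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    m2 = float((z**2).mean())
    m4 = float((z**4).mean())
    b2 = m4 / m2**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * W0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * W0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * W0**2
    VI = num / den - EI**2
    zscore = (I - EI) / np.sqrt(VI)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(float(I), EI, float(VI), float(zscore), float(p), scheme)
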