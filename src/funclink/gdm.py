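"""Generalized dissimilarity modelling with monotone I-splines.

GDM regresses pairwise compositional (here: functional) dissimilarities on
monotone transforms of predictor differences through the link

    mu_ij = 1 - exp(-eta_ij),   eta_ij = a0 + sum_p sum_k b_pk * f_pk(i, j)

where each predictor contributes three order-3 (degree-2) I-spline basis
functions with knots at the 0th/50th/100th percentiles of its observed
values.  Scalar (per-region) predictors enter as |I(x_i) - I(x_j)|; matrix
predictors (host functional dissimilarity, geographic distance) enter as
I(d_ij) with knots on the distance distribution.  All coefficients,
including the intercept, are constrained non-negative, so each fitted
transform is non-decreasing with f(min) = 0 and predicted dissimilarities
lie in [0, 1).  Fitting minimizes the binomial-form deviance by iteratively
reweighted non-negative least squares; predictor importance is the percent
decrease in deviance explained when the predictor's region identities are
permuted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .beta import FunctionalBetaMatrix, GeoDistanceMatrix
from .io import FormatError

logger = logging.getLogger("funclink")

__all__ = [
    "SitePairTable",
    "GDMFit",
    "ImportanceTable",
    "build_site_pairs",
    "ispline_knots",
    "ispline_basis",
    "gdm_fit",
    "var_importance",
]

_EPS = 1e-10


@dataclass
class SitePairTable:
    """One record per unordered region pair.

    ``scalar_predictors`` holds region-level values (n_regions,) per name;
    ``matrix_predictors`` holds full symmetric matrices.  Pair enumeration
    is lexicographic in the stored region order: (0,1), (0,2), ...
    """

    regions: list[str]
    response: np.ndarray  # (n_pairs,)
    scalar_predictors: dict[str, np.ndarray]
    matrix_predictors: dict[str, np.ndarray]
    pair_i: np.ndarray = field(default=None)
    pair_j: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.regions)
        iu = np.triu_indices(n, k=1)
        if self.pair_i is None:
            self.pair_i, self.pair_j = iu
        if len(self.response) != n * (n - 1) // 2:
            raise FormatError("response length != n(n-1)/2")
        if ((self.response < 0) | (self.response > 1)).any():
            raise FormatError("response dissimilarities outside [0, 1]")

    @property
    def n_pairs(self) -> int:
        return len(self.response)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.scalar_predictors) + list(self.matrix_predictors)

    def permuted(self, names: list[str], perm: np.ndarray) -> "SitePairTable":
        """Copy with region identities permuted for the named predictors."""
        sp = dict(self.scalar_predictors)
        mp = dict(self.matrix_predictors)
        for name in names:
            if name in sp:
                sp[name] = sp[name][perm]
            elif name in mp:
                mp[name] = mp[name][np.ix_(perm, perm)]
            else:
                raise FormatError(f"unknown predictor {name!r}")
        return SitePairTable(
            list(self.regions), self.response, sp, mp, self.pair_i, self.pair_j
        )


@dataclass
class GDMPredictor:
    name: str
    kind: str  # scalar | matrix
    knots: np.ndarray
    coefs: np.ndarray

    @property
    def height(self) -> float:
        """Sum of the I-spline coefficients: total turnover on the gradient."""
        return float(self.coefs.sum())


@dataclass
class GDMFit:
    intercept: float
    predictors: list[GDMPredictor]
    fitted: np.ndarray
    deviance: float
    null_deviance: float
    deviance_explained: float  # percent
    converged: bool
    n_iter: int
    dropped: list[str] = field(default_factory=list)

    def height_table(self) -> pd.DataFrame:
        rows = {
            p.name: list(p.coefs) + [p.height] for p in self.predictors
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["ispline_1", "ispline_2", "ispline_3", "sum_isplines"]
        )


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # index=predictor; importance, p_value
    model_p_value: float
    n_permutations: int
    seed: int


def build_site_pairs(
    response: FunctionalBetaMatrix,
    scalar_predictors: pd.DataFrame | None = None,
    matrix_predictors: dict[str, FunctionalBetaMatrix | GeoDistanceMatrix | np.ndarray] | None = None,
) -> SitePairTable:
    """Assemble the site-pair table from a response dissimilarity matrix.

    ``scalar_predictors`` is a region-indexed data frame (e.g. environmental
    composites); ``matrix_predictors`` maps names to square matrices aligned
    to the same regions.
    """
    regions = list(response.regions)
    n = len(regions)
    iu = np.triu_indices(n, k=1)
    sp: dict[str, np.ndarray] = {}
    if scalar_predictors is not None:
        if set(map(str, scalar_predictors.index)) != set(regions):
            raise FormatError("scalar predictor regions differ from response regions")
        aligned = scalar_predictors.loc[regions]
        for c in aligned.columns:
            sp[str(c)] = aligned[c].to_numpy(float)
    mp: dict[str, np.ndarray] = {}
    if matrix_predictors:
        for name, m in matrix_predictors.items():
            if hasattr(m, "regions"):
                if list(m.regions) != regions:
                    if set(m.regions) != set(regions):
                        raise FormatError(f"matrix predictor {name!r} regions differ")
                    idx = [list(m.regions).index(r) for r in regions]
                    vals = np.asarray(m.values)[np.ix_(idx, idx)]
                else:
                    vals = np.asarray(m.values)
            else:
                vals = np.asarray(m, dtype=float)
            if vals.shape != (n, n):
                raise FormatError(f"matrix predictor {name!r} has wrong shape")
            mp[name] = vals.astype(float)
    return SitePairTable(regions, response.values[iu], sp, mp, iu[0], iu[1])


def ispline_knots(values: np.ndarray) -> np.ndarray:
    """Knots at the 0th, 50th and 100th percentiles of observed values."""
    return np.percentile(np.asarray(values, dtype=float), [0, 50, 100])


def ispline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Three monotone order-3 I-spline basis functions on [q0, q100].

    Each basis is 0 at the domain minimum, 1 at the maximum and
    non-decreasing; values outside the knot range are clamped.  Basis k uses
    the knot triple (q_{k-1}, q_k, q_{k+1}) with the end knots repeated.
    """
    q0, q50, q100 = (float(k) for k in knots)
    if not q0 <= q50 <= q100:
        raise FormatError("knots must be non-decreasing")
    if q100 - q0 <= 0:
        raise FormatError("degenerate knots: all values equal")
    x = np.clip(np.asarray(x, dtype=float), q0, q100)

    def piece(v, k1, k2, k3):
        out = np.zeros_like(v)
        out[v >= k3] = 1.0
        mid = (v > k1) & (v < k3)
        vm = v[mid]
        lo = vm < k2
        res = np.empty_like(vm)
        # rising quadratic below the middle knot, falling-complement above
        if k2 > k1:
            res[lo] = (vm[lo] - k1) ** 2 / ((k3 - k1) * (k2 - k1))
        else:
            res[lo] = 0.0
        if k3 > k2:
            res[~lo] = 1.0 - (k3 - vm[~lo]) ** 2 / ((k3 - k1) * (k3 - k2))
        else:
            res[~lo] = 1.0
        out[mid] = res
        return out

    triples = [(q0, q0, q50), (q0, q50, q100), (q50, q100, q100)]
    return np.column_stack([piece(x, *t) for t in triples])


def _design(table: SitePairTable) -> tuple[np.ndarray, list[tuple[str, str, np.ndarray]], list[str]]:
    """Design matrix of I-spline pair contributions plus per-predictor info.

    Returns (X without intercept, [(name, kind, knots)], dropped names).
    """
    cols = []
    info = []
    dropped = []
    for name, vals in table.scalar_predictors.items():
        if vals.max() - vals.min() <= 0:
            logger.warning("predictor %r is constant; dropped", name)
            dropped.append(name)
            continue
        knots = ispline_knots(vals)
        basis = ispline_basis(vals, knots)
        cols.append(np.abs(basis[table.pair_i] - basis[table.pair_j]))
        info.append((name, "scalar", knots))
    for name, mat in table.matrix_predictors.items():
        d = mat[table.pair_i, table.pair_j]
        if d.max() - d.min() <= 0:
            logger.warning("predictor %r is constant; dropped", name)
            dropped.append(name)
            continue
        knots = ispline_knots(d)
        cols.append(ispline_basis(d, knots))
        info.append((name, "matrix", knots))
    X = np.hstack(cols) if cols else np.empty((table.n_pairs, 0))
    return X, info, dropped


def binomial_deviance(d: np.ndarray, mu: np.ndarray) -> float:
    """Binomial-form deviance for continuous proportions; limit terms at 0/1."""
    mu = np.clip(mu, _EPS, 1 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1 - d) * np.log((1 - d) / (1 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _irls_nnls(
    d: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Minimize binomial deviance of mu = 1 - exp(-X b), b >= 0 (incl. intercept).

    X here includes the leading intercept column.  Returns
    (coefs, fitted, deviance, converged, n_iter).
    """
    n = len(d)
    beta = np.zeros(X.shape[1])
    mean_d = np.clip(d.mean(), _EPS, 1 - _EPS)
    beta[0] = -np.log1p(-mean_d)  # start at the null model
    dev = binomial_deviance(d, 1 - np.exp(-X @ beta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(1 - np.exp(-eta), _EPS, 1 - _EPS)
        dmu = 1 - mu  # d mu / d eta = exp(-eta)
        w = dmu**2 / (mu * (1 - mu))
        z = eta + (d - mu) / np.maximum(dmu, _EPS)
        sw = np.sqrt(w)
        beta_new, _ = nnls(X * sw[:, None], z * sw)
        dev_new = binomial_deviance(d, 1 - np.exp(-X @ beta_new))
        # step-halve if the NNLS step increased the deviance
        shrink = 0
        while dev_new > dev + 1e-12 and shrink < 30:
            beta_new = (beta + beta_new) / 2.0
            dev_new = binomial_deviance(d, 1 - np.exp(-X @ beta_new))
            shrink += 1
        if abs(dev - dev_new) < tol:
            beta, dev = beta_new, dev_new
            converged = True
            break
        beta, dev = beta_new, dev_new
    fitted = 1 - np.exp(-X @ beta)
    return beta, fitted, dev, converged, it


def gdm_fit(table: SitePairTable, tol: float = 1e-8, max_iter: int = 100) -> GDMFit:
    """Fit the GDM by iteratively reweighted non-negative least squares."""
    if table.n_pairs < 10:
        raise FormatError("need at least 10 site pairs")
    X, info, dropped = _design(table)
    Xfull = np.hstack([np.ones((table.n_pairs, 1)), X])
    d = table.response
    beta, fitted, dev, converged, it = _irls_nnls(d, Xfull, tol, max_iter)
    if not converged:
        logger.warning("GDM fit did not converge in %d iterations", max_iter)
    # null deviance: intercept-only model, optimum at mu = mean(d)
    null_beta, _, null_dev, _, _ = _irls_nnls(d, np.ones((table.n_pairs, 1)), tol, max_iter)
    de = 100.0 * (1.0 - dev / null_dev) if null_dev > 0 else 0.0
    preds = []
    for k, (name, kind, knots) in enumerate(info):
        coefs = beta[1 + 3 * k : 4 + 3 * k]
        preds.append(GDMPredictor(name, kind, knots, coefs))
    return GDMFit(
        float(beta[0]), preds, fitted, dev, null_dev, float(de), converged, it, dropped
    )


def var_importance(
    table: SitePairTable,
    n_perm: int = 100,
    seed: int = 0,
    fit: GDMFit | None = None,
) -> ImportanceTable:
    """Matrix-permutation importance and significance of each predictor.

    For each predictor, region identities are permuted for that predictor
    only (site values for scalars; rows and columns jointly for matrices),
    the model refitted, and the importance taken as the mean percent
    decrease in deviance explained relative to the full model.  The p-value
    is the fraction of permutations whose deviance explained is at least the
    full model's.  The model-level p-value permutes all predictors jointly.
    """
    if n_perm < 1:
        raise FormatError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if fit is None:
        fit = gdm_fit(table)
    de_full = fit.deviance_explained
    if de_full <= 0:
        raise FormatError("full model explains no deviance; importance undefined")
    n = len(table.regions)
    names = [p.name for p in fit.predictors]
    rows = {}
    for name in names:
        des = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            des[b] = gdm_fit(table.permuted([name], perm)).deviance_explained
        importance = float(100.0 * (de_full - des.mean()) / de_full)
        p = float((des >= de_full).mean())
        rows[name] = (importance, p)
    des_all = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        des_all[b] = gdm_fit(table.permuted(names, perm)).deviance_explained
    model_p = float((des_all >= de_full).mean())
    tab = pd.DataFrame.from_dict(rows, orient="index", columns=["importance", "p_value"])
    return ImportanceTable(tab, model_p, n_perm, seed)
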