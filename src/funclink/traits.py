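"""Trait preprocessing, Gower distances and environmental PCA composites.

Mixed species-by-trait tables are turned into numeric matrices: flagged
continuous columns are ln-transformed, continuous and ordinal columns are
standardized to zero mean and unit (sample) variance, nominal columns are
expanded into one dummy column per level and binary columns pass through as
0/1.  Pairwise functional distances between species are then Gower
distances over the prepared columns: the mean of per-column absolute
differences, each normalized by the column's observed range.

Region-level environmental variables grouped into categories (vegetation,
temperature, precipitation) are each reduced to the first principal
component of the standardized variables; the composite's sign is chosen so
that it increases with the category's raw variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import FormatError, TraitTable

logger = logging.getLogger("funclink")

__all__ = [
    "PreparedTraitMatrix",
    "DistanceMatrix",
    "EnvComposite",
    "prepare_traits",
    "gower_distance",
    "env_composites",
]


@dataclass
class PreparedTraitMatrix:
    """Numeric matrix ready for Gower distances.

    ``provenance`` maps each output column to its source trait and encoding;
    ``metadata`` records the conventions applied (variance denominator,
    dummy coding of nominal traits).
    """

    species: list[str]
    data: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric (tol 1e-12)")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise FormatError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise FormatError("negative distances")
        self.values = np.clip((v + v.T) / 2.0, 0.0, None)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class EnvComposite:
    """First-principal-component composite score per environmental category."""

    regions: list[str]
    scores: pd.DataFrame  # region x category PC1 scores, zero mean
    variance_explained: dict[str, float]
    loading_signs: dict[str, np.ndarray]


def _standardize(col: np.ndarray, name: str) -> np.ndarray:
    sd = col.std(ddof=1)
    if sd == 0:
        logger.warning("trait column %r is constant; kept as zeros", name)
        return np.zeros_like(col)
    return (col - col.mean()) / sd


def prepare_traits(raw: TraitTable) -> PreparedTraitMatrix:
    """Transform a mixed trait table into an analysis-ready numeric matrix.

    Columns flagged ``ln_transform`` are ln-transformed first (strictly
    positive values required); continuous and ordinal (integer-rank) columns
    are scaled to zero mean and unit sample variance; nominal columns with k
    levels yield exactly k 0/1 dummy columns; binary columns pass through.
    """
    out: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    for name in raw.data.columns:
        spec = raw.schema[name]
        col = raw.data[name]
        if spec.kind in ("continuous", "ordinal"):
            if spec.kind == "ordinal":
                levels = list(spec.levels)
                unknown = set(col.astype(str)) - set(levels)
                if unknown:
                    raise FormatError(
                        f"ordinal trait {name!r} has values outside its levels: {sorted(unknown)}"
                    )
                vals = col.astype(str).map({lv: i for i, lv in enumerate(levels)}).to_numpy(float)
            else:
                vals = col.to_numpy(float)
                if spec.ln_transform:
                    if (vals <= 0).any():
                        culprit = raw.species[int(np.argmax(vals <= 0))]
                        raise FormatError(
                            f"ln-transform of non-positive value in trait {name!r} "
                            f"for species {culprit!r}"
                        )
                    vals = np.log(vals)
            out[name] = _standardize(vals, name)
            provenance[name] = {"trait": name, "kind": spec.kind, "encoding": "scaled"}
        elif spec.kind == "binary":
            vals = col.to_numpy(float)
            if not np.isin(vals, (0.0, 1.0)).all():
                raise FormatError(f"binary trait {name!r} has non-0/1 values")
            out[name] = vals
            provenance[name] = {"trait": name, "kind": "binary", "encoding": "identity"}
        else:  # nominal
            levels = sorted(col.astype(str).unique())
            for lv in levels:
                cname = f"{name}={lv}"
                out[cname] = (col.astype(str) == lv).to_numpy(float)
                provenance[cname] = {"trait": name, "kind": "nominal", "encoding": "dummy", "level": lv}
    data = pd.DataFrame(out, index=raw.species)
    meta = {"variance_denominator": "n-1", "gower_input": "prepared columns (scaled + dummies)"}
    return PreparedTraitMatrix(list(raw.species), data, provenance, meta)


def gower_distance(prepared: PreparedTraitMatrix) -> DistanceMatrix:
    """Gower distance over the prepared columns.

    d(i, j) = mean over columns with nonzero observed range of
    ``|x_ik - x_jk| / range_k``; zero-range columns are skipped.  Distances
    lie in [0, 1].
    """
    X = prepared.data.to_numpy(float)
    if X.shape[0] < 2:
        raise FormatError("Gower distance needs at least 2 species")
    ranges = X.max(axis=0) - X.min(axis=0)
    valid = ranges > 0
    if not valid.any():
        raise FormatError("all columns have zero range; Gower distance undefined")
    if not valid.all():
        logger.warning("skipping %d zero-range columns in Gower distance", int((~valid).sum()))
    Xv = X[:, valid] / ranges[valid]
    d = pdist(Xv, metric="cityblock") / valid.sum()
    return DistanceMatrix(list(prepared.species), squareform(d))


def env_composites(env: pd.DataFrame, categories: dict[str, str]) -> EnvComposite:
    """Per-category PCA composites of environmental variables.

    ``categories`` maps each variable (column of ``env``) to its category.
    Variables are standardized, the first principal component extracted, and
    its sign fixed so the score correlates positively with the category mean
    of the raw variables.
    """
    missing = set(env.columns) - set(categories)
    if missing:
        raise FormatError(f"variables without a category: {sorted(missing)}")
    regions = [str(r) for r in env.index]
    scores: dict[str, np.ndarray] = {}
    varex: dict[str, float] = {}
    signs: dict[str, np.ndarray] = {}
    for cat in dict.fromkeys(categories.values()):
        cols = [c for c in env.columns if categories[c] == cat]
        X = env[cols].to_numpy(float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise FormatError(f"category {cat!r} has only zero-variance variables")
        if not keep.all():
            logger.warning("category %r: dropping zero-variance variables", cat)
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        load = vt[0]
        raw_mean = X[:, keep].mean(axis=1)
        if np.cov(pc1, raw_mean)[0, 1] < 0:
            pc1, load = -pc1, -load
        scores[cat] = pc1
        varex[cat] = float(s[0] ** 2 / (s**2).sum())
        signs[cat] = np.sign(load)
    return EnvComposite(regions, pd.DataFrame(scores, index=regions), varex, signs)
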