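"""Between-region functional dissimilarity and geographic distances.

Functional beta diversity replaces species with functional units: each
region is represented by the set of functional-tree branches lying on the
root-to-leaf paths of its species, weighted by branch length.  The
dissimilarity between two regions is the complement of the Ochiai
similarity (the S12 coefficient of the Gower–Legendre family for incidence
data) computed on shared versus unique branch length:

    a = shared branch length,  b, c = branch length unique to each region
    dissimilarity = 1 - a / sqrt((a + b) (a + c))

Geographic distances between region centres are haversine great-circle
distances on a sphere of mean Earth radius 6371.0 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError, IncidenceMatrix
from .tree import FunctionalTree

logger = logging.getLogger("funclink")

__all__ = [
    "FunctionalBetaMatrix",
    "GeoDistanceMatrix",
    "functional_dissimilarity",
    "great_circle",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class FunctionalBetaMatrix:
    regions: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.regions)
        if v.shape != (n, n):
            raise FormatError("beta matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise FormatError("beta matrix not symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise FormatError("beta dissimilarities outside [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class GeoDistanceMatrix:
    regions: list[str]
    values: np.ndarray  # km

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


def _branch_membership(tree: FunctionalTree, species: list[str]) -> np.ndarray:
    """Boolean (n_edges, n_species): species s lies below edge e."""
    M = np.zeros((len(tree.edges), len(species)), dtype=bool)
    for j, name in enumerate(species):
        node = tree.name_leaf.get(name)
        if node is None:
            raise FormatError(f"species {name!r} missing from tree")
        parent = {child: (par, eid) for eid, (par, child) in enumerate(tree.edges)}
        u = node
        while u in parent:
            par, eid = parent[u]
            M[eid, j] = True
            u = par
    return M


def functional_dissimilarity(
    tree: FunctionalTree, inc: IncidenceMatrix
) -> FunctionalBetaMatrix:
    """Branch-based Ochiai dissimilarity between all region pairs.

    Branch sets are taken on the tree as rooted at its construction root.
    For regions i, j with branch-length totals t_i, t_j and shared branch
    length a_ij the dissimilarity is 1 - a_ij / sqrt(t_i * t_j).
    """
    missing = sorted(set(inc.species) - set(tree.leaves))
    if missing:
        raise FormatError(f"species in incidence missing from tree: {missing}")
    if (inc.values.sum(axis=1) == 0).any():
        raise FormatError("region with zero species")
    # membership: edge e is on a root-to-leaf path of species j
    M = _branch_membership(tree, list(inc.species))
    # region r uses edge e iff any of its species lies below e
    P = ((M.astype(float) @ inc.values.T.astype(float)) > 0).astype(float)  # (n_edges, n_regions)
    L = tree.lengths
    shared = (P * L[:, None]).T @ P  # a_ij
    totals = np.diag(shared).copy()
    if (totals <= 0).any():
        bad = [r for r, t in zip(inc.regions, totals) if t <= 0]
        raise FormatError(f"regions with zero total branch length: {bad}")
    sim = shared / np.sqrt(np.outer(totals, totals))
    return FunctionalBetaMatrix(list(inc.regions), 1.0 - sim)


def great_circle(coords: pd.DataFrame) -> GeoDistanceMatrix:
    """Haversine great-circle distance matrix (km) from lat/lon degrees."""
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    if (np.abs(lat) > 90).any():
        raise FormatError("latitude outside [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise FormatError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return GeoDistanceMatrix([str(r) for r in coords.index], d)
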