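"""Readers, writers and core tabular domain types.

All tabular inputs are comma-separated UTF-8 text with a mandatory header
row.  Region-by-species incidence tables carry region identifiers in the
first column and species identifiers in the header; cells are strictly 0/1.
Results are serialized as JSON so that every estimate, seed and setting in a
pipeline output can be round-tripped losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("funclink")

__all__ = [
    "IncidenceMatrix",
    "TraitSpec",
    "TraitTable",
    "RunConfig",
    "FormatError",
    "read_incidence",
    "read_traits",
    "read_table",
    "read_coords",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} labels: {dups}")


@dataclass
class IncidenceMatrix:
    """Binary region x species occurrence matrix.

    ``values[r, s] == 1`` means species ``s`` was recorded in region ``r``.
    Every region hosts at least one species and every species occurs in at
    least one region; labels are unique.
    """

    regions: list[str]
    species: list[str]
    values: np.ndarray  # (n_regions, n_species), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.regions), len(self.species)):
            raise FormatError(
                f"incidence shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.species)} species"
            )
        _check_unique(self.regions, "region")
        _check_unique(self.species, "species")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            r, s = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary incidence value {self.values[r, s]!r} at "
                f"region {self.regions[r]!r}, species {self.species[s]!r}"
            )
        self.values = self.values.astype(np.int8)
        if len(self.regions) and (self.values.sum(axis=1) == 0).any():
            empty = [r for r, v in zip(self.regions, self.values.sum(axis=1)) if v == 0]
            raise FormatError(f"regions with no species: {empty}")
        if len(self.species) and (self.values.sum(axis=0) == 0).any():
            empty = [s for s, v in zip(self.species, self.values.sum(axis=0)) if v == 0]
            raise FormatError(f"species occurring in no region: {empty}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.species)

    def region_species(self, region: str) -> list[str]:
        i = self.regions.index(region)
        return [s for s, v in zip(self.species, self.values[i]) if v]

    def align_regions(self, order: Sequence[str]) -> "IncidenceMatrix":
        """Return a copy with regions reordered to ``order``."""
        if set(order) != set(self.regions):
            raise FormatError("region sets differ; cannot align")
        idx = [self.regions.index(r) for r in order]
        return IncidenceMatrix(list(order), list(self.species), self.values[idx])


@dataclass
class TraitSpec:
    """Schema entry for one trait column."""

    kind: str  # continuous | ordinal | nominal | binary
    ln_transform: bool = False
    levels: tuple[str, ...] | None = None  # explicit ordering for ordinal traits

    KINDS = ("continuous", "ordinal", "nominal", "binary")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise FormatError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and not self.levels:
            raise FormatError("ordinal trait requires an explicit level ordering")


@dataclass
class TraitTable:
    """Species x mixed-type trait table plus a schema covering every column."""

    species: list[str]
    data: pd.DataFrame  # index = species
    schema: dict[str, TraitSpec]

    def __post_init__(self) -> None:
        _check_unique(self.species, "species")
        missing = set(self.data.columns) - set(self.schema)
        if missing:
            raise FormatError(f"schema does not cover traits: {sorted(missing)}")
        extra = set(self.schema) - set(self.data.columns)
        if extra:
            raise FormatError(f"schema lists unknown traits: {sorted(extra)}")
        if list(self.data.index) != list(self.species):
            raise FormatError("trait table index does not match species list")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise FormatError(f"missing trait values in columns {bad}")


@dataclass
class RunConfig:
    """Settings shared across pipeline stages, recorded in every artifact."""

    seed: int = 0
    exclusions: list[str] = field(default_factory=list)
    regularity_metric: str = "evenness"  # evenness | variance
    moran_weights: str = "inverse_distance"  # inverse_distance | knn
    moran_knn: int = 5
    gdm_n_splines: int = 3
    gdm_n_permutations: int = 100
    gdm_tol: float = 1e-8
    reroot: str = "none"  # none | midpoint

    def __post_init__(self) -> None:
        for name in ("moran_knn", "gdm_n_splines", "gdm_n_permutations"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if self.gdm_tol <= 0:
            raise FormatError("gdm_tol must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_incidence(path: str | Path, exclusions: Sequence[str] = ()) -> IncidenceMatrix:
    """Read a region x species 0/1 table, dropping excluded species.

    Regions left with zero species after exclusion are dropped with a logged
    warning, as are species left with zero occurrences.  Exclusion is
    idempotent by construction.
    """
    df = pd.read_csv(path, index_col=0)
    regions = [str(r) for r in df.index]
    species = [str(s) for s in df.columns]
    _check_unique(regions, "region")
    _check_unique(species, "species")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, s = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary cell {values[r, s]!r} at row {regions[r]!r}, "
            f"column {species[s]!r}"
        )
    keep = [i for i, s in enumerate(species) if s not in set(exclusions)]
    if len(keep) < len(species):
        logger.info("excluded %d species", len(species) - len(keep))
    species = [species[i] for i in keep]
    values = values[:, keep].astype(np.int8)
    row_ok = values.sum(axis=1) > 0
    if not row_ok.all():
        dropped = [r for r, ok in zip(regions, row_ok) if not ok]
        logger.warning("dropping regions with no remaining species: %s", dropped)
        regions = [r for r, ok in zip(regions, row_ok) if ok]
        values = values[row_ok]
    col_ok = values.sum(axis=0) > 0
    if not col_ok.all():
        dropped = [s for s, ok in zip(species, col_ok) if not ok]
        logger.warning("dropping species with no occurrences: %s", dropped)
        species = [s for s, ok in zip(species, col_ok) if ok]
        values = values[:, col_ok]
    return IncidenceMatrix(regions, species, values)


def read_traits(
    traits_path: str | Path,
    schema_path: str | Path,
    exclusions: Sequence[str] = (),
) -> TraitTable:
    """Read a species x trait CSV plus its schema CSV.

    The schema has columns ``trait`` and ``kind``, optional ``ln_transform``
    (0/1) and ``levels`` (``<``-separated ordering for ordinal traits).
    """
    df = pd.read_csv(traits_path, index_col=0)
    df.index = df.index.astype(str)
    df = df.loc[[s for s in df.index if s not in set(exclusions)]]
    sdf = pd.read_csv(schema_path)
    if "trait" not in sdf.columns or "kind" not in sdf.columns:
        raise FormatError(f"{schema_path}: schema needs 'trait' and 'kind' columns")
    schema: dict[str, TraitSpec] = {}
    for _, row in sdf.iterrows():
        levels = None
        if "levels" in sdf.columns and isinstance(row.get("levels"), str):
            levels = tuple(part.strip() for part in row["levels"].split("<"))
        ln = bool(int(row["ln_transform"])) if "ln_transform" in sdf.columns and not pd.isna(row.get("ln_transform")) else False
        schema[str(row["trait"])] = TraitSpec(str(row["kind"]), ln, levels)
    return TraitTable(list(df.index), df, schema)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic region-indexed CSV (environment, alpha components...)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_coords(path: str | Path) -> pd.DataFrame:
    """Read region centre coordinates (columns ``lat``, ``lon``, degrees)."""
    df = read_table(path)
    if not {"lat", "lon"} <= set(df.columns):
        raise FormatError(f"{path}: coordinate table needs 'lat' and 'lon' columns")
    return df[["lat", "lon"]].astype(float)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__dataclass__": type(obj).__name__, **_jsonify(dataclasses.asdict(obj))}
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "__frame__": True,
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
            "data": obj.to_numpy().tolist(),
        }
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_frame())
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise TypeError(f"cannot serialize field of type {type(obj).__name__}")


def _dejsonify(obj):
    if isinstance(obj, dict):
        if obj.get("__frame__"):
            return pd.DataFrame(obj["data"], index=obj["index"], columns=obj["columns"])
        return {k: _dejsonify(v) for k, v in obj.items() if k != "__dataclass__"}
    if isinstance(obj, list):
        return [_dejsonify(v) for v in obj]
    return obj


def write_results(result, path: str | Path) -> None:
    """Serialize a finished fit/metric object to structured JSON text."""
    payload = _jsonify(result)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True)


def read_results(path: str | Path):
    """Read back a :func:`write_results` file (as nested dicts/frames)."""
    with open(path, "r", encoding="utf-8") as fh:
        return _dejsonify(json.load(fh))
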