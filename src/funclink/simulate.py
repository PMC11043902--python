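"""Synthetic biogeographic realms with known host–parasite coupling.

The generator emulates the structure of regional flea/host survey data: a
realm of regions on a jittered geographic grid, environmental variables
following spatial gradients plus noise, host species with mixed traits and
logistic environmental niches, and flea species whose geographic occurrence
is tied to their principal host and whose traits are coupled to host traits
with tunable strength.

Ground truth.  Every host has a latent 6-dimensional trait profile from
which its observed mixed traits are derived.  Each flea is anchored to a
principal host (anchors spread evenly over the host pool), carries a
preference profile (a jittered copy of the anchor's latent profile) and is
compatible with the quarter of the host pool closest to that preference in
latent space.  Flea latent traits are

    t_f = theta_match * (kernel-weighted mean of compatible hosts' profiles)
        + (1 - theta_match) * independent noise

with weights ``exp(-d^2 / 0.5)`` in latent distance, so ``theta_match``
tunes how strongly flea functional structure mirrors host functional
structure.  Regional host communities hold species richness fixed at half
the host pool, sampling species by their logistic environmental
suitability, so functional-diversity variation across regions is
compositional rather than count-driven.  A flea occurs in a region iff its
principal host occurs there (hence at least one compatible host is present)
and an environmental filter of strength ``theta_env`` (pass probability
``exp(-theta_env * squared distance to the flea's environmental optimum)``)
lets it through.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FormatError, IncidenceMatrix, TraitSpec, TraitTable, write_results

logger = logging.getLogger("funclink")

__all__ = ["SyntheticRealm", "simulate_realm", "truth_report", "write_realm"]

#: environmental gradient coefficients: value = a + b*lat_n + c*lon_n + noise
ENV_GRADIENTS = {
    "ndvi_wet": ("vegetation", 0.75, -0.45, 0.10, 0.06),
    "ndvi_dry": ("vegetation", 0.55, -0.35, 0.05, 0.06),
    "t_mean": ("temperature", 24.0, -14.0, 2.0, 1.0),
    "t_max": ("temperature", 33.0, -11.0, 1.5, 1.2),
    "prec_wet": ("precipitation", 600.0, 120.0, -320.0, 40.0),
    "prec_dry": ("precipitation", 180.0, 60.0, -110.0, 25.0),
}

_LATENT_DIM = 6
_HOST_NICHE_RADIUS = 0.5
_HOST_NICHE_SCALE = 0.04
_HOST_RICHNESS_FRACTION = 0.5
_PREFERENCE_JITTER = 0.3
_COMPAT_FRACTION = 0.25
_TRAIT_KERNEL = 0.5


@dataclass
class SyntheticRealm:
    host_incidence: IncidenceMatrix
    flea_incidence: IncidenceMatrix
    host_traits: TraitTable
    flea_traits: TraitTable
    env: pd.DataFrame
    env_categories: dict[str, str]
    coords: pd.DataFrame
    truth: dict


def _tertiles(values: np.ndarray, labels: tuple[str, str, str]) -> list[str]:
    lo, hi = np.quantile(values, [1 / 3, 2 / 3])
    return [labels[0] if v <= lo else (labels[1] if v <= hi else labels[2]) for v in values]


def simulate_realm(
    n_regions: int = 30,
    n_hosts: int = 30,
    n_fleas: int = 25,
    theta_match: float = 0.7,
    theta_env: float = 0.5,
    seed: int = 0,
) -> SyntheticRealm:
    """Generate one realm with known ground truth.

    ``theta_match`` in [0, 1] couples flea traits to host traits;
    ``theta_env`` >= 0 strengthens environmental filtering of flea
    occurrences.  The same seed always yields the identical realm.
    Incidence draws that leave a region or species empty are resampled, up
    to 100 times, before erroring.
    """
    if n_regions < 2 or n_hosts < 2 or n_fleas < 2:
        raise FormatError("counts must be >= 2")
    if not 0.0 <= theta_match <= 1.0:
        raise FormatError("theta_match must lie in [0, 1]")
    if theta_env < 0:
        raise FormatError("theta_env must be >= 0")
    rng = np.random.default_rng(seed)

    # --- regions on a jittered grid spanning 20 x 40 degrees -------------
    ncol = int(math.ceil(math.sqrt(2 * n_regions)))
    nrow = int(math.ceil(n_regions / ncol))
    cells = [(r, c) for r in range(nrow) for c in range(ncol)][:n_regions]
    lat_n = np.array([(r + rng.uniform(0.15, 0.85)) / nrow for r, _ in cells])
    lon_n = np.array([(c + rng.uniform(0.15, 0.85)) / ncol for _, c in cells])
    regions = [f"R{i+1:02d}" for i in range(n_regions)]
    coords = pd.DataFrame(
        {"lat": 10.0 + 20.0 * lat_n, "lon": 0.0 + 40.0 * lon_n}, index=regions
    )
    pos = np.column_stack([lat_n, lon_n])

    # --- environment: linear gradients + gaussian noise -------------------
    env = {}
    categories = {}
    for name, (cat, a, b, c, sd) in ENV_GRADIENTS.items():
        env[name] = a + b * lat_n + c * lon_n + rng.normal(0.0, sd, n_regions)
        categories[name] = cat
    env = pd.DataFrame(env, index=regions)

    # --- hosts: latent profiles, observed traits, logistic niches ---------
    hosts = [f"H{i+1:02d}" for i in range(n_hosts)]
    U = rng.normal(size=(n_hosts, _LATENT_DIM))
    host_traits = pd.DataFrame(
        {
            "social_group": _tertiles(U[:, 0], ("small", "medium", "large")),
            "nest_location": _tertiles(U[:, 1], ("below", "on", "above")),
            "body_mass": U[:, 2],
            "range_size": np.exp(2.0 + 0.7 * U[:, 3]),
            "brain_mass": U[:, 4],
            "activity": _tertiles(U[:, 5], ("nocturnal", "cathemeral", "diurnal")),
        },
        index=hosts,
    )
    host_schema = {
        "social_group": TraitSpec("ordinal", levels=("small", "medium", "large")),
        "nest_location": TraitSpec("nominal"),
        "body_mass": TraitSpec("continuous"),
        "range_size": TraitSpec("continuous", ln_transform=True),
        "brain_mass": TraitSpec("continuous"),
        "activity": TraitSpec("nominal"),
    }
    centers = rng.uniform(-0.05, 1.05, size=(n_hosts, 2))
    d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (region, host)
    suit = 1.0 / (1.0 + np.exp((d2 - _HOST_NICHE_RADIUS**2) / _HOST_NICHE_SCALE))

    # --- fleas: anchors, preferences, compatibility, coupled traits -------
    fleas = [f"F{i+1:02d}" for i in range(n_fleas)]
    host_cycle = rng.permutation(n_hosts)
    anchors = np.array([host_cycle[i % n_hosts] for i in range(n_fleas)])
    V = U[anchors] + rng.normal(0.0, _PREFERENCE_JITTER, size=(n_fleas, _LATENT_DIM))
    dist_fh = np.linalg.norm(V[:, None, :] - U[None, :, :], axis=2)
    n_compat = max(1, int(round(_COMPAT_FRACTION * n_hosts)))
    compat = np.zeros((n_fleas, n_hosts), dtype=bool)
    for f in range(n_fleas):
        compat[f, np.argsort(dist_fh[f])[:n_compat]] = True
    compat[np.arange(n_fleas), anchors] = True
    weights = np.where(compat, np.exp(-(dist_fh**2) / _TRAIT_KERNEL), 0.0)
    host_mean = weights @ U / weights.sum(axis=1, keepdims=True)
    noise = rng.normal(size=(n_fleas, _LATENT_DIM))
    T = theta_match * host_mean + (1.0 - theta_match) * noise
    flea_traits = pd.DataFrame(
        {
            "ctenidia": _tertiles(T[:, 0], ("none", "pronotal", "both")),
            "body_size": _tertiles(T[:, 1], ("small", "medium", "large")),
            "host_range": T[:, 2],
            "host_phylo_div": T[:, 3],
            "lat_span": T[:, 4],
            "microhabitat": _tertiles(T[:, 5], ("hair", "burrow", "none")),
        },
        index=fleas,
    )
    flea_schema = {
        "ctenidia": TraitSpec("ordinal", levels=("none", "pronotal", "both")),
        "body_size": TraitSpec("ordinal", levels=("small", "medium", "large")),
        "host_range": TraitSpec("continuous"),
        "host_phylo_div": TraitSpec("continuous"),
        "lat_span": TraitSpec("continuous"),
        "microhabitat": TraitSpec("nominal"),
    }
    optima = rng.uniform(0.0, 1.0, size=(n_fleas, 2))
    d2_flea = ((pos[:, None, :] - optima[None, :, :]) ** 2).sum(axis=2)  # (region, flea)
    env_pass_p = np.exp(-theta_env * d2_flea)

    # --- incidence draws, resampled until every region/species occupied ---
    k = max(2, int(round(_HOST_RICHNESS_FRACTION * n_hosts)))
    retries = -1
    for attempt in range(100):
        retries = attempt
        host_occ = np.zeros((n_regions, n_hosts), dtype=np.int8)
        for r in range(n_regions):
            w = suit[r] + 1e-9
            pick = rng.choice(n_hosts, size=k, replace=False, p=w / w.sum())
            host_occ[r, pick] = 1
        anchor_present = host_occ[:, anchors].astype(bool)  # (region, flea)
        env_ok = rng.uniform(size=env_pass_p.shape) < env_pass_p
        flea_occ = (anchor_present & env_ok).astype(np.int8)
        ok = (
            host_occ.sum(axis=0).min() > 0
            and flea_occ.sum(axis=1).min() > 0
            and flea_occ.sum(axis=0).min() > 0
        )
        if ok:
            break
    else:
        raise FormatError("could not realize a valid realm in 100 attempts")
    if retries:
        logger.info("realm realized after %d resampling retries", retries)

    truth = {
        "seed": int(seed),
        "theta_match": float(theta_match),
        "theta_env": float(theta_env),
        "n_regions": int(n_regions),
        "n_hosts": int(n_hosts),
        "n_fleas": int(n_fleas),
        "env_gradients": {
            name: {"category": cat, "intercept": a, "lat_slope": b, "lon_slope": c, "noise_sd": sd}
            for name, (cat, a, b, c, sd) in ENV_GRADIENTS.items()
        },
        "env_filter_coefficients": (theta_env * np.ones(n_fleas)).tolist(),
        # regional host richness is held fixed at k by design
        "expected_host_richness": [float(k)] * n_regions,
        "regional_host_richness": int(k),
        "retries": int(retries),
        "host_latent": U,
        "flea_latent": T,
        "flea_preference": V,
        "flea_anchor": anchors,
        "compatibility": compat,
        "compat_weights": weights,
        "host_niche_centers": centers,
        "flea_env_optima": optima,
    }
    return SyntheticRealm(
        IncidenceMatrix(regions, hosts, host_occ),
        IncidenceMatrix(regions, fleas, flea_occ),
        TraitTable(hosts, host_traits, host_schema),
        TraitTable(fleas, flea_traits, flea_schema),
        env,
        categories,
        coords,
        truth,
    )


def truth_report(realm: SyntheticRealm) -> dict:
    """Small JSON-serializable record of the generator's ground truth."""
    t = realm.truth
    return {
        "seed": t["seed"],
        "theta_match": t["theta_match"],
        "theta_env": t["theta_env"],
        "n_regions": t["n_regions"],
        "n_hosts": t["n_hosts"],
        "n_fleas": t["n_fleas"],
        "env_gradients": t["env_gradients"],
        "env_filter_coefficients": t["env_filter_coefficients"],
        "expected_host_richness": t["expected_host_richness"],
        "regional_host_richness": t["regional_host_richness"],
        "retries": t["retries"],
    }


def _schema_frame(schema: dict[str, TraitSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": list(schema),
            "kind": [s.kind for s in schema.values()],
            "ln_transform": [int(s.ln_transform) for s in schema.values()],
            "levels": ["<".join(s.levels) if s.levels else "" for s in schema.values()],
        }
    )


def write_realm(realm: SyntheticRealm, outdir: str | Path) -> None:
    """Write the full CSV bundle plus the truth record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    realm.host_incidence.to_frame().to_csv(out / "host_incidence.csv")
    realm.flea_incidence.to_frame().to_csv(out / "flea_incidence.csv")
    realm.host_traits.data.to_csv(out / "host_traits.csv")
    realm.flea_traits.data.to_csv(out / "flea_traits.csv")
    _schema_frame(realm.host_traits.schema).to_csv(out / "host_trait_schema.csv", index=False)
    _schema_frame(realm.flea_traits.schema).to_csv(out / "flea_trait_schema.csv", index=False)
    realm.env.to_csv(out / "env.csv")
    pd.DataFrame(
        {"variable": list(realm.env_categories), "category": list(realm.env_categories.values())}
    ).to_csv(out / "env_categories.csv", index=False)
    realm.coords.to_csv(out / "coords.csv")
    write_results(truth_report(realm), out / "truth.json")
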