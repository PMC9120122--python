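"""Synthetic urban landscapes, trait tables and trait-conditioned communities.

The generator emulates the structure of an urban pollinator survey: ~49 dry
grassland patches scattered over a ~30 x 30 km city extent with rectangular
building footprints, six environmental variables per site, a trait table per
taxon (wild bees or hoverflies), and a site x species abundance matrix.

Abundances follow the standard log-linear generative counterpart of the
fourth-corner model:

.. math:: \\log \\lambda_{ij} = \\beta_0 + a_i + b_j
          + \\sum_k \\sum_t c_{kt}\\, x_{ik} z_{jt}

with standardised environment values ``x``, coded trait values ``z``, site
effects ``a_i`` (normal) and species baselines ``b_j`` (normal on the log
scale, i.e. log-normal multipliers, producing the strong dominance structure
real pollinator data show).  Counts are Poisson draws; all outputs are fully
determined by the scenario seed.  The planted interaction coefficients
``c_kt`` are carried along as ground truth for calibration and power checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.affinity import rotate, translate
from shapely.geometry import Polygon, box

from .landscape import Landscape, write_landscape_geojson
from .traitenv import code_traits

__all__ = [
    "SyntheticScenario",
    "SyntheticDataset",
    "PlacementError",
    "generate_landscape",
    "generate_env",
    "generate_traits",
    "generate_community",
    "generate_dataset",
    "write_dataset",
]

ENV_VARIABLES = (
    "urbanisation_pct",
    "connectivity_S",
    "patch_size_m2",
    "herb_cover_pct",
    "nonnative_cover_pct",
    "mean_air_temp_C",
)

DEFAULT_ENV_RANGES = {
    "urbanisation_pct": (0.0, 100.0),
    "connectivity_S": (0.0, 0.30),
    "patch_size_m2": (500.0, 100_000.0),
    "herb_cover_pct": (0.0, 100.0),
    "nonnative_cover_pct": (0.0, 60.0),
    "mean_air_temp_C": (16.0, 26.0),
}

BEE_SOCIALITY = ("solitary", "eusocial", "cleptoparasitic")
BEE_NESTING = ("hypergeic", "endogeic", "hyper_endogeic", "cleptoparasitic")
BEE_DIET = ("oligolectic", "polylectic", "cleptoparasitic")
HOVERFLY_LARVAL_FOOD = (
    "phytophagous",
    "zoophagous",
    "terrestrial_saprophagous",
    "aquatic_saprophagous",
)

PLACEMENT_ATTEMPT_LIMIT = 1000

# sub-stream tags so each generator stage has an independent, reproducible rng
_TAG_LANDSCAPE, _TAG_ENV, _TAG_TRAITS, _TAG_COMMUNITY = 11, 12, 13, 14


class PlacementError(RuntimeError):
    pass


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic survey.

    Defaults mirror the real survey design: 49 sites across a 30 x 30 km
    extent, ~100 wild-bee-like species, six environmental variables with
    ranges spanning the class bins used downstream, log-normal species
    baselines (sigma 1) and a baseline log rate of -1 giving matrix grand
    totals of order 10^3 individuals.
    """

    n_sites: int = 49
    n_species: int = 100
    taxon: str = "wild_bee"
    extent: tuple[float, float, float, float] = (0.0, 0.0, 30_000.0, 30_000.0)
    building_density: float = 2.0  # buildings per km^2
    height_range: tuple[float, float] = (5.0, 30.0)
    patch_area_range: tuple[float, float] = (2_000.0, 50_000.0)
    env_ranges: dict = field(default_factory=lambda: dict(DEFAULT_ENV_RANGES))
    env_correlation: np.ndarray | None = None
    interaction_coeffs: dict = field(default_factory=dict)
    baseline_log_rate: float = -1.0
    site_sd: float = 0.3
    species_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_species < 1:
            raise ValueError("n_sites and n_species must be positive")
        if self.taxon not in ("wild_bee", "hoverfly"):
            raise ValueError(f"unknown taxon {self.taxon!r}")
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate extent")
        for name, (lo, hi) in self.env_ranges.items():
            if hi <= lo:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        for rng_pair in (self.height_range, self.patch_area_range):
            if rng_pair[1] <= rng_pair[0]:
                raise ValueError(f"degenerate range {rng_pair}")
        for key, val in self.interaction_coeffs.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite interaction coefficient for {key}")

    def site_ids(self) -> list[str]:
        return [f"s{i+1:03d}" for i in range(self.n_sites)]

    def species_ids(self) -> list[str]:
        return [f"sp{j+1:03d}" for j in range(self.n_species)]


@dataclass
class SyntheticDataset:
    landscape: Landscape
    env: pd.DataFrame
    traits: pd.DataFrame
    community: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        assert list(self.env.index) == list(self.community.index)
        assert list(self.traits.index) == list(self.community.columns)


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


def _random_convex_patch(rng: np.random.Generator, area: float) -> Polygon:
    """Convex polygon of (approximately, then rescaled exactly) given area,
    centred at the origin."""
    n_pts = 8
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_pts))
    radii = rng.uniform(0.7, 1.3, n_pts)
    pts = np.column_stack([np.cos(angles) * radii, np.sin(angles) * radii])
    hull = Polygon(pts).convex_hull
    scale = math.sqrt(area / hull.area)
    return Polygon(np.asarray(hull.exterior.coords) * scale)


def generate_landscape(scenario: SyntheticScenario) -> Landscape:
    """Non-overlapping convex patches plus Poisson-count rectangular
    buildings with uniform heights; deterministic given the scenario seed.

    Raises :class:`PlacementError` if a patch cannot be placed disjointly
    within the attempt limit (1000 tries per patch).
    """
    rng = _rng(_TAG_LANDSCAPE, scenario.seed)
    x0, y0, x1, y1 = scenario.extent
    patches: dict[str, Polygon] = {}
    placed: list[Polygon] = []
    for pid in scenario.site_ids():
        area = rng.uniform(*scenario.patch_area_range)
        shape0 = _random_convex_patch(rng, area)
        for _ in range(PLACEMENT_ATTEMPT_LIMIT):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            cand = translate(shape0, cx, cy)
            bx0, by0, bx1, by1 = cand.bounds
            if bx0 < x0 or by0 < y0 or bx1 > x1 or by1 > y1:
                continue
            if any(cand.intersects(p) for p in placed):
                continue
            patches[pid] = cand
            placed.append(cand)
            break
        else:
            raise PlacementError(
                f"could not place patch {pid} disjointly within "
                f"{PLACEMENT_ATTEMPT_LIMIT} attempts; extent too small"
            )
    area_km2 = (x1 - x0) * (y1 - y0) / 1e6
    n_buildings = rng.poisson(scenario.building_density * area_km2)
    bpolys: list[Polygon] = []
    bheights: list[float] = []
    for _ in range(n_buildings):
        w = rng.uniform(8.0, 30.0)
        d = rng.uniform(8.0, 30.0)
        theta = rng.uniform(0.0, 180.0)
        cx = rng.uniform(x0, x1)
        cy = rng.uniform(y0, y1)
        footprint = rotate(box(-w / 2, -d / 2, w / 2, d / 2), theta)
        bpolys.append(translate(footprint, cx, cy))
        bheights.append(float(rng.uniform(*scenario.height_range)))
    return Landscape(patches, bpolys, bheights, impervious=list(bpolys) or None)


def generate_env(scenario: SyntheticScenario) -> pd.DataFrame:
    """Site x environment table with each variable drawn over its range
    (independently by default; a Gaussian copula applies an optional
    correlation matrix)."""
    rng = _rng(_TAG_ENV, scenario.seed)
    names = list(scenario.env_ranges)
    n, k = scenario.n_sites, len(names)
    if scenario.env_correlation is not None:
        corr = np.asarray(scenario.env_correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError("env_correlation shape must match number of variables")
        z = rng.multivariate_normal(np.zeros(k), corr, size=n)
        from scipy.stats import norm

        u = norm.cdf(z)
    else:
        u = rng.uniform(size=(n, k))
    data = {}
    for j, name in enumerate(names):
        lo, hi = scenario.env_ranges[name]
        data[name] = lo + (hi - lo) * u[:, j]
    return pd.DataFrame(data, index=scenario.site_ids())


def generate_traits(n_species: int, taxon: str, seed: int = 0) -> pd.DataFrame:
    """Trait table for one taxon.

    Wild bees carry sociality, nesting, diet, flight months and body size;
    the three cleptoparasitic states co-occur in the same (brood-parasitic)
    species.  Hoverflies carry body size, flight months, migratory status
    (0/1) and larval food type.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(_TAG_TRAITS, seed)
    ids = [f"sp{j+1:03d}" for j in range(n_species)]
    if taxon == "wild_bee":
        clepto = rng.uniform(size=n_species) < 0.15
        sociality = np.where(
            clepto, "cleptoparasitic", rng.choice(["solitary", "eusocial"], n_species, p=[0.7, 0.3])
        )
        nesting = np.where(
            clepto,
            "cleptoparasitic",
            rng.choice(["endogeic", "hypergeic", "hyper_endogeic"], n_species, p=[0.55, 0.3, 0.15]),
        )
        diet = np.where(
            clepto,
            "cleptoparasitic",
            rng.choice(["polylectic", "oligolectic"], n_species, p=[0.65, 0.35]),
        )
        return pd.DataFrame(
            {
                "sociality": sociality,
                "nesting": nesting,
                "diet": diet,
                "flight_months": rng.integers(2, 10, n_species),
                "body_size_mm": np.round(np.exp(rng.normal(2.2, 0.35, n_species)), 1),
            },
            index=ids,
        )
    if taxon == "hoverfly":
        return pd.DataFrame(
            {
                "body_size_mm": np.round(np.exp(rng.normal(2.3, 0.25, n_species)), 1),
                "flight_months": rng.integers(3, 10, n_species),
                "migratory": rng.integers(0, 2, n_species),
                "larval_food": rng.choice(
                    list(HOVERFLY_LARVAL_FOOD), n_species, p=[0.1, 0.5, 0.2, 0.2]
                ),
            },
            index=ids,
        )
    raise ValueError(f"unknown taxon {taxon!r}")


def _coeff_matrix(
    interaction_coeffs, env_cols: list[str], coded_cols: list[str]
) -> np.ndarray:
    if isinstance(interaction_coeffs, dict):
        c = np.zeros((len(env_cols), len(coded_cols)))
        for (env_name, coded_name), val in interaction_coeffs.items():
            if env_name not in env_cols:
                raise ValueError(f"unknown environmental variable {env_name!r}")
            if coded_name not in coded_cols:
                raise ValueError(f"unknown coded trait column {coded_name!r}")
            c[env_cols.index(env_name), coded_cols.index(coded_name)] = val
        return c
    c = np.asarray(interaction_coeffs, dtype=float)
    if c.shape != (len(env_cols), len(coded_cols)):
        raise ValueError(
            f"interaction coefficient matrix shape {c.shape} does not match "
            f"({len(env_cols)} env variables, {len(coded_cols)} coded trait columns)"
        )
    return c


def generate_community(
    env: pd.DataFrame, traits: pd.DataFrame, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Poisson site x species counts from the log-linear interaction model.

    Expected log abundance is linear in the planted environment x trait
    interactions; with all coefficients zero, counts are independent of
    every environmental variable.
    """
    rng = _rng(_TAG_COMMUNITY, scenario.seed)
    coded, _ = code_traits(traits, standardize_quantitative=True)
    env_cols = list(env.columns)
    coded_cols = list(coded.columns)
    c = _coeff_matrix(scenario.interaction_coeffs, env_cols, coded_cols)
    x = env.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    z = coded.to_numpy(dtype=float)
    a = rng.normal(0.0, scenario.site_sd, size=len(env))
    b = rng.normal(0.0, scenario.species_sd, size=len(traits))
    log_lam = scenario.baseline_log_rate + a[:, None] + b[None, :] + x @ c @ z.T
    counts = rng.poisson(np.exp(log_lam))
    return pd.DataFrame(counts, index=env.index, columns=traits.index)


def generate_dataset(scenario: SyntheticScenario, with_landscape: bool = True) -> SyntheticDataset:
    """Full synthetic survey: landscape, environment, traits, community and
    the planted ground truth. Identical scenarios yield identical datasets."""
    landscape = generate_landscape(scenario) if with_landscape else Landscape({ }, [], [])
    env = generate_env(scenario)
    traits = generate_traits(scenario.n_species, scenario.taxon, scenario.seed)
    community = generate_community(env, traits, scenario)
    truth = {
        "interaction_coeffs": {
            f"{k}|{t}": v for (k, t), v in scenario.interaction_coeffs.items()
        }
        if isinstance(scenario.interaction_coeffs, dict)
        else np.asarray(scenario.interaction_coeffs).tolist(),
        "baseline_log_rate": scenario.baseline_log_rate,
        "seed": scenario.seed,
    }
    return SyntheticDataset(landscape, env, traits, community, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write community.csv, traits.csv, env.csv, landscape.geojson and
    truth.json to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.community.to_csv(out / "community.csv", index_label="site_id")
    dataset.traits.to_csv(out / "traits.csv", index_label="species_id")
    dataset.env.to_csv(out / "env.csv", index_label="site_id")
    if dataset.landscape.patches:
        write_landscape_geojson(dataset.landscape, out / "landscape.geojson")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
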