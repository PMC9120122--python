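"""End-to-end orchestration of the analysis stages.

Stage order follows the analysis design: landscape metrics, community
preparation (rarity/site filters, Wisconsin + square-root standardisation,
Bray-Curtis), NMDS with envfit, indicator-species analysis for the
environmental variables that envfit finds significant (urbanisation and
connectivity, classified into their low/medium/high bins), and finally
RLQ / fourth-corner trait-environment tests with Poisson-GLM direction
checks.  Every stage writes its outputs under the run directory and the run
is summarised in ``manifest.json`` (config hash, seeds, versions, row and
column counts at each stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import community as community_mod
from . import indval as indval_mod
from . import landscape as landscape_mod
from . import ordination, traitenv
from .synth import SyntheticScenario, generate_dataset, write_dataset

log = logging.getLogger("urbanfilter")

__all__ = ["RunConfig", "StageError", "run_pipeline", "scenario_from_dict"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Run configuration; every stochastic stage carries an explicit seed."""

    synth: dict | None = None  # scenario parameters, or None when inputs given
    community_csv: str | None = None
    env_csv: str | None = None
    traits_csv: str | None = None
    landscape_geojson: str | None = None
    alpha: float = landscape_mod.DEFAULT_ALPHA
    corridor_halfwidth_m: float = 25.0
    buffer_m: float = 500.0
    min_species_total: int = 3
    min_site_total: int = 3
    nmds_k: int = 2
    nmds_n_starts: int = 100
    nmds_tol: float = 1e-10
    envfit_n_perm: int = 99_999
    significance_alpha: float = 0.05
    indval_threshold: float = 0.3
    fourth_corner_n_perm: int = 9_999
    fourth_corner_model: int = 2
    seeds: dict = field(default_factory=lambda: {"synth": 0, "nmds": 1, "envfit": 2, "fourth_corner": 3})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("indval_threshold", "significance_alpha", "alpha", "corridor_halfwidth_m", "buffer_m"):
            if getattr(cfg, name) <= 0:
                raise ValueError(f"config value {name} must be positive")
        return cfg

    def hash(self) -> str:
        canon = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def scenario_from_dict(d: dict) -> SyntheticScenario:
    d = dict(d)
    if "interaction_coeffs" in d and isinstance(d["interaction_coeffs"], dict):
        coeffs = {}
        for key, val in d["interaction_coeffs"].items():
            if isinstance(key, str):  # "env|coded" form used in YAML / truth.json
                env_name, coded = key.split("|", 1)
                coeffs[(env_name, coded)] = float(val)
            else:
                coeffs[tuple(key)] = float(val)
        d["interaction_coeffs"] = coeffs
    for key in ("extent", "height_range", "patch_area_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "env_ranges" in d:
        d["env_ranges"] = {k: tuple(v) for k, v in d["env_ranges"].items()}
    return SyntheticScenario(**d)


def _load_inputs(config: RunConfig, outdir: Path, manifest: dict):
    if config.synth is not None:
        scen = scenario_from_dict({**config.synth, "seed": config.seeds.get("synth", 0)})
        ds = generate_dataset(scen)
        write_dataset(ds, outdir / "inputs")
        manifest["inputs"] = {"source": "synth", "scenario_seed": scen.seed}
        return ds.community, ds.env, ds.traits, ds.landscape
    if not (config.community_csv and config.env_csv and config.traits_csv):
        raise ValueError("either a synth scenario or community/env/traits CSV paths are required")
    comm = pd.read_csv(config.community_csv, index_col=0)
    env = pd.read_csv(config.env_csv, index_col=0)
    traits = pd.read_csv(config.traits_csv, index_col=0)
    lscape = (
        landscape_mod.read_landscape_geojson(config.landscape_geojson)
        if config.landscape_geojson
        else None
    )
    manifest["inputs"] = {"source": "files"}
    return comm, env, traits, lscape


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Any stage error halts the run with a :class:`StageError` naming the
    stage; outputs of earlier stages are retained on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seeds": dict(config.seeds),
        "versions": {"urbanfilter": __version__, "pandas": pd.__version__},
        "stages": {},
    }
    stage = "inputs"
    try:
        comm, env, traits, lscape = _load_inputs(config, out, manifest)
        manifest["stages"]["inputs"] = {
            "n_sites": int(comm.shape[0]),
            "n_species": int(comm.shape[1]),
            "total_individuals": int(comm.to_numpy().sum()),
        }

        stage = "landscape"
        if lscape is not None and lscape.patches:
            env_land = landscape_mod.landscape_env_table(
                lscape,
                alpha=config.alpha,
                halfwidth_m=config.corridor_halfwidth_m,
                radius_m=config.buffer_m,
            )
            env_land.to_csv(out / "env_landscape.csv")
            manifest["stages"]["landscape"] = {"n_patches": len(lscape.patches)}
        else:
            manifest["stages"]["landscape"] = {"skipped": True}

        stage = "prep"
        filt = community_mod.filter_rare(
            comm, config.min_species_total, config.min_site_total
        )
        (out / "dropped_species.txt").write_text("\n".join(map(str, filt.dropped_species)))
        (out / "dropped_sites.txt").write_text("\n".join(map(str, filt.dropped_sites)))
        l_matrix = filt.matrix
        std = community_mod.wisconsin_sqrt(l_matrix)
        bc = community_mod.bray_curtis(std)
        bc.to_csv(out / "bray_curtis.csv")
        manifest["stages"]["prep"] = {
            "n_sites": int(l_matrix.shape[0]),
            "n_species": int(l_matrix.shape[1]),
            "total_individuals": int(l_matrix.to_numpy().sum()),
            "dropped_species": len(filt.dropped_species),
            "dropped_sites": len(filt.dropped_sites),
        }

        stage = "nmds"
        env_used = env.loc[l_matrix.index]
        ordn = ordination.nmds(
            bc,
            k=config.nmds_k,
            n_starts=config.nmds_n_starts,
            tol=config.nmds_tol,
            seed=config.seeds.get("nmds", 1),
        )
        ordn.scores.to_csv(out / "nmds_scores.csv")
        fit = ordination.envfit(
            ordn, env_used, n_perm=config.envfit_n_perm, seed=config.seeds.get("envfit", 2)
        )
        fit.table.to_csv(out / "envfit.csv")
        manifest["stages"]["nmds"] = {
            "stress": ordn.stress,
            "converged": bool(ordn.converged),
            "significant_variables": fit.significant(config.significance_alpha),
        }

        stage = "indval"
        classifiers = {
            "urbanisation_pct": landscape_mod.classify_urbanisation,
            "connectivity_S": landscape_mod.classify_connectivity,
        }
        significant = set(fit.significant(config.significance_alpha))
        ran_indval = []
        for var, classify in classifiers.items():
            if var not in significant or var not in env_used.columns:
                continue
            classes = env_used[var].map(classify)
            if classes.nunique() < 2:
                log.warning("indval: variable %s yields a single class; skipped", var)
                continue
            table = indval_mod.indval(l_matrix, classes)
            long = table.to_frame()
            long["indicator_flag"] = long["IV"] >= config.indval_threshold
            long.insert(0, "variable", var)
            long.to_csv(out / f"indval_{var}.csv", index=False)
            ran_indval.append(var)
        manifest["stages"]["indval"] = (
            {"variables": ran_indval} if ran_indval else {"skipped": True}
        )

        stage = "traitenv"
        traits_used = traits.loc[l_matrix.columns]
        weights = l_matrix.sum(axis=0) / l_matrix.to_numpy().sum()
        coded, meta = traitenv.code_traits(traits_used, species_weights=weights)
        rlq_res = traitenv.rlq(env_used, l_matrix, coded)
        pd.DataFrame({"eigenvalue": rlq_res.eigenvalues}).to_csv(out / "rlq_eigen.csv")
        fc = traitenv.fourth_corner(
            env_used,
            l_matrix,
            coded,
            n_perm=config.fourth_corner_n_perm,
            model=config.fourth_corner_model,
            seed=config.seeds.get("fourth_corner", 3),
        )
        meta_named = meta.rename(columns={"trait": "source_trait", "coded_col": "trait"})
        fc_table = fc.table.reset_index().merge(meta_named, on="trait", how="left")
        fc_table.to_csv(out / "fourthcorner.csv", index=False)
        counts = traitenv.trait_counts_per_site(l_matrix, traits_used)
        glm = traitenv.trait_directions(counts, env_used)
        glm.to_csv(out / "glm_directions.csv")
        manifest["stages"]["traitenv"] = {
            "n_coded_traits": int(coded.shape[1]),
            "n_fourth_corner_tests": int(len(fc.table)),
            "n_significant": int((fc.table["p_perm"] < config.significance_alpha).sum()),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
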