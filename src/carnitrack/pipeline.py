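"""Orchestration: simulate -> match -> paired effects -> hurdle models.

Runs the full protected-area impact evaluation from a YAML config, writing
every intermediate artifact (CSV/JSON) plus a consolidated markdown + JSON
report.  A single global seed deterministically spawns per-stage seeds by
hashing the stage name, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import effects as eff
from . import hurdle as hd
from . import matching as mt
from . import synth
from .synth import COVARIATES, SPECIES, SimulationConfig

logger = logging.getLogger(__name__)

UNIT_COLUMNS = [
    "unit_id", "x_km", "y_km", "region", "protected", "pa_size_km2", *COVARIATES[:4]
]
OBS_COLUMNS = ["unit_id", "year", "species", "index"]


class SchemaError(ValueError):
    """Input table violates the survey-data schema."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: str = "carnitrack_out"
    units_path: str | None = None  # None -> simulate
    observations_path: str | None = None
    species: tuple = SPECIES
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    match_spec: mt.MatchSpec = field(default_factory=mt.MatchSpec)
    n_effect_iterations: int = 1000
    alpha: float = 0.05
    nodes: int = 15
    n_residual_sim: int = 250
    run_hurdle: bool = True
    run_model_selection: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        sp_raw = sim_raw.pop("species_params", None)
        if sp_raw is not None:
            sim_raw["species_params"] = {
                sp: synth.SpeciesParams(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in p.items()
                })
                for sp, p in sp_raw.items()
            }
        match_raw = raw.pop("match_spec", {})
        if "covariate_names" in match_raw:
            match_raw["covariate_names"] = tuple(match_raw["covariate_names"])
        if "species" in raw:
            raw["species"] = tuple(raw["species"])
        return cls(
            simulation=SimulationConfig(**sim_raw),
            match_spec=mt.MatchSpec(**match_raw),
            **raw,
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed xor a stage-name hash."""
    return int((global_seed ^ zlib.crc32(stage.encode())) % (2**31))


def validate_tables(units: pd.DataFrame, observations: pd.DataFrame) -> dict:
    """Validate schema, ranges and uniqueness of both tables.

    Returns a report dict with ``errors`` and ``warnings`` lists; any error
    means the tables are unusable downstream.
    """
    errors, warnings_ = [], []
    for col in ["unit_id", "protected", "pa_size_km2", "region", *COVARIATES]:
        if col not in units.columns:
            errors.append(f"units: missing column {col!r}")
    for col in OBS_COLUMNS:
        if col not in observations.columns:
            errors.append(f"observations: missing column {col!r}")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    if units["unit_id"].duplicated().any():
        errors.append("units: duplicated unit_id")
    bad_forest = ~units["forest_pct"].between(0, 100)
    if bad_forest.any():
        errors.append(
            f"units: forest_pct outside [0, 100] in rows {list(units.index[bad_forest][:5])}"
        )
    for col in ("ruggedness", "dist_settlement_km", "human_density", "pa_size_km2"):
        neg = units[col] < 0
        if neg.any():
            errors.append(f"units: negative {col} in rows {list(units.index[neg][:5])}")
    mismatch = units["protected"].astype(bool) != (units["pa_size_km2"] > 0)
    if mismatch.any():
        errors.append(
            "units: pa_size_km2 > 0 must hold iff protected "
            f"(rows {list(units.index[mismatch][:5])})"
        )

    dup = observations.duplicated(["unit_id", "year", "species"])
    if dup.any():
        errors.append(
            f"observations: duplicated (unit_id, year, species) rows "
            f"{list(observations.index[dup][:5])}"
        )
    neg = observations["index"] < 0
    if neg.any():
        errors.append(
            f"observations: negative index in rows {list(observations.index[neg][:5])}"
        )
    unknown = ~observations["unit_id"].isin(units["unit_id"])
    if unknown.any():
        errors.append(
            f"observations: unit_id not present in units table "
            f"(rows {list(observations.index[unknown][:5])})"
        )
    n_years = observations.groupby(["unit_id", "species"])["year"].nunique()
    thin = n_years[n_years < 2]
    if len(thin):
        warnings_.append(
            f"{len(thin)} (unit, species) series have < 2 observed years and "
            "cannot contribute to effect resampling"
        )
    return {"errors": errors, "warnings": warnings_}


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _load_or_simulate(config: RunConfig, out: Path):
    if config.units_path is not None:
        upath, opath = Path(config.units_path), Path(config.observations_path or "")
        if not upath.exists():
            raise SchemaError(f"units file not found: {upath}")
        if not opath.exists():
            raise SchemaError(f"observations file not found: {opath}")
        units = pd.read_csv(upath)
        obs = pd.read_csv(opath)
    else:
        sim_cfg = SimulationConfig(
            **{
                **config.simulation.__dict__,
                "seed": stage_seed(config.seed, "simulate"),
            }
        )
        units, obs = synth.simulate(sim_cfg)
        units.to_csv(out / "units.csv", index=False)
        obs.to_csv(out / "observations.csv", index=False)
    return units, obs


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the consolidated report dict.

    Artifacts are written under ``config.out_dir``: simulated tables (when
    simulating), ``pairs.csv``, ``balance.json``, national/regional effect
    JSON, annual effect CSV, per-species model-selection CSV and best-fit
    JSON, plus ``report.json`` and ``report.md``.  A stage failure aborts
    with the stage name while preserving completed artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "stages": {},
        },
        "species": {},
    }

    stage = "load"
    try:
        units, obs = _load_or_simulate(config, out)
        check = validate_tables(units, obs)
        if check["errors"]:
            raise SchemaError("; ".join(check["errors"]))
        for w in check["warnings"]:
            logger.warning(w)

        stage = "match"
        fit, result, balance = mt.match_units(units, config.match_spec)
        result.pairs.to_csv(out / "pairs.csv", index=False)
        (out / "balance.json").write_text(
            json.dumps(
                {
                    "caliper": result.caliper,
                    "match_rate": result.match_rate,
                    "n_pairs": len(result.pairs),
                    "n_unmatched": len(result.unmatched),
                    "balance": balance.table.to_dict(),
                },
                indent=2,
            )
        )
        report["matching"] = {
            "n_pairs": int(len(result.pairs)),
            "match_rate": float(result.match_rate),
            "n_unmatched": int(len(result.unmatched)),
            "mean_abs_smd_before": float(balance.table["smd_before"].abs().mean()),
            "mean_abs_smd_after": float(balance.table["smd_after"].abs().mean()),
        }

        region_map = units.set_index("unit_id")["region"]
        national, regional, annual_frames = {}, {}, []
        for sp in config.species:
            stage = f"effects[{sp}]"
            diffs = eff.pair_differences(result.pairs, obs, sp)
            est = eff.pooled_median_ci(
                diffs,
                n_iterations=config.n_effect_iterations,
                seed=stage_seed(config.seed, f"effects-{sp}"),
            )
            national[sp] = est.to_dict()
            regional[sp] = [
                r.to_dict()
                for r in eff.regional_estimates(
                    diffs,
                    region_map,
                    n_iterations=config.n_effect_iterations,
                    seed=stage_seed(config.seed, f"regional-{sp}"),
                )
            ]
            annual = eff.annual_effects(diffs, alpha=config.alpha)
            annual_frames.append(annual)
            report["species"].setdefault(sp, {})["national_effect"] = national[sp]
            report["species"][sp]["n_significant_years"] = (
                int(annual["significant"].sum()) if len(annual) else 0
            )
        (out / "effects_national.json").write_text(json.dumps(national, indent=2))
        (out / "effects_regional.json").write_text(json.dumps(regional, indent=2))
        if annual_frames:
            pd.concat(annual_frames, ignore_index=True).to_csv(
                out / "effects_annual.csv", index=False
            )

        if config.run_hurdle:
            for sp in config.species:
                stage = f"hurdle[{sp}]"
                frame = hd.build_model_frame(units, obs, sp)
                if config.run_model_selection:
                    fits = hd.fit_candidates(frame, nodes=config.nodes, se=False)
                    ranking = hd.aic_rank(fits)
                    ranking.to_csv(out / f"model_selection_{sp}.csv", index=False)
                    best_name = ranking.iloc[0]["model"]
                    best_spec = next(f.spec for f in fits if f.spec.name == best_name)
                else:
                    best_spec = hd.ModelSpec(name="base")
                    ranking = None
                best = hd.fit_two_part(frame, best_spec, nodes=config.nodes, se=True)
                marg = hd.marginal_coefficients(best)
                diag = hd.residual_diagnostics(
                    best,
                    n_sim=config.n_residual_sim,
                    seed=stage_seed(config.seed, f"residuals-{sp}"),
                )
                fit_json = {
                    "model": best.spec.name,
                    "gamma": best.gamma.to_dict(),
                    "beta": best.beta.to_dict(),
                    "sigma": best.sigma,
                    "sigma_b0": best.sigma_b0,
                    "sigma_b1": best.sigma_b1,
                    "loglik": best.loglik,
                    "aic": best.aic,
                    "k": best.k,
                    "converged": best.converged,
                    "marginal": marg.table.to_dict(orient="records"),
                    "diagnostics": {
                        "ks_pvalue": diag.ks_pvalue,
                        "dispersion_ratio": diag.dispersion_ratio,
                        "dispersion_pvalue": diag.dispersion_pvalue,
                    },
                }
                (out / f"fit_{sp}.json").write_text(json.dumps(fit_json, indent=2))
                pa_term = "pa" if "pa" in best.design.columns else None
                sp_report = report["species"].setdefault(sp, {})
                sp_report["best_model"] = best.spec.name
                sp_report["aic"] = best.aic
                if pa_term:
                    row = marg.part("continuous").loc[pa_term]
                    sp_report["pa_marginal"] = {
                        "estimate": float(row["estimate"]),
                        "z": float(row["z"]),
                        "p": float(row["p"]),
                    }
                sp_report["residual_ks_pvalue"] = diag.ks_pvalue
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    report["provenance"]["stages"] = "completed"
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Protected-area effect evaluation report", ""]
    m = report.get("matching")
    if m:
        lines += [
            "## Matching",
            f"- matched pairs: {m['n_pairs']} (match rate {m['match_rate']:.1%})",
            f"- mean |SMD| before -> after: "
            f"{m['mean_abs_smd_before']:.3f} -> {m['mean_abs_smd_after']:.3f}",
            "",
        ]
    for sp, info in report.get("species", {}).items():
        lines.append(f"## {sp}")
        ne = info.get("national_effect")
        if ne:
            lines.append(
                f"- national median absolute PA effect: {ne['median_effect']:.3f} "
                f"(95% CI {ne['ci_low']:.3f}, {ne['ci_high']:.3f}; "
                f"n = {ne['n_pairs']} pairs)"
            )
        if "best_model" in info:
            lines.append(f"- best hurdle model by AIC: {info['best_model']}")
        pm = info.get("pa_marginal")
        if pm:
            lines.append(
                f"- marginal protection coefficient (log scale): "
                f"{pm['estimate']:.4f} (z = {pm['z']:.2f}, p = {pm['p']:.3f})"
            )
        lines.append("")
    return "\n".join(lines)
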