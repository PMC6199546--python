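"""End-to-end experiment orchestration.

``run_experiment`` drives the full chain for every (site, crop, year):
generate the truth, control and ensemble-member weather series; run the
crop surrogate on each realization; derive the five verified variables
(growing-season precipitation, ET, yield, GWF, WPet); and write the
long-form outcome table plus the verification and Ignorance reports.
``verify_from_table`` runs only the verification/scoring stages on an
externally produced outcome table (e.g. genuine crop-model output).

Seeding: one master seed spawns an independent substream for every
(site, year, stage) through :class:`numpy.random.SeedSequence`, and the
member-noise streams are indexed per member, so re-running with the
same configuration is bit-reproducible and adding a member never
perturbs existing realizations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .crop_surrogate import CropParams, SoilParams, run_season
from .exceptions import CropFailureError, DegenerateEnsembleError, DomainError
from .green_water import green_water_footprint, water_productivity
from .ignorance import fit_gaussian, ignorance_score, summarize_scores
from .synthetic_weather import ClimateConfig, generate_truth, perturb_members
from .verification import VARIABLES, EnsembleOutcome, multi_year_summary, year_stats

__all__ = [
    "SiteSpec",
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "verify_from_table",
    "build_outcomes",
]

log = logging.getLogger("greencast")

OUTCOME_COLUMNS = ["year", "site", "crop", "realization", "variable", "value"]


@dataclass
class SiteSpec:
    """One simulation site: its synthetic climate and its soil."""

    site_id: str
    climate: ClimateConfig
    soil: SoilParams


@dataclass
class ExperimentConfig:
    """Everything needed for a deterministic experiment run."""

    sites: list[SiteSpec]
    crops: list[CropParams]
    years: list[int]
    seed: int = 0
    output_dir: str = "greencast_out"
    alpha: float = 0.05             # normality screening level
    closeness_band: float = 2.0     # skill criterion (b) ratio band
    sigma_ddof: int = 0             # 0 = population convention for RMSE/SPRD/fit
    high_score_threshold: float = 4.21
    high_sigma_threshold: float = 2.0
    write_weather: bool = False

    def __post_init__(self) -> None:
        if not self.sites or not self.crops:
            raise DomainError("need at least one site and one crop")
        if len(self.years) < 2:
            raise DomainError("need at least two years")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "ExperimentConfig":
        """Load a config file; ``seed`` (e.g. from the CLI) overrides the file's."""
        base = Path(path).parent
        with open(path) as fh:
            doc = yaml.safe_load(fh)

        years_spec = doc.get("years", {"start": 2006, "end": 2014})
        if isinstance(years_spec, dict):
            years = list(range(int(years_spec["start"]), int(years_spec["end"]) + 1))
        else:
            years = [int(y) for y in years_spec]

        scenario = doc.get("scenario", {})
        members_override = doc.get("members_per_year")

        def resolve_crop(entry):
            p = base / f"{entry}.yaml"
            if isinstance(entry, str) and not p.exists() and not Path(entry).exists():
                return gio.bundled_crop(entry)
            return gio.load_crop_params(p if p.exists() else entry)

        def resolve_soil(entry):
            p = base / f"{entry}.yaml"
            if isinstance(entry, str) and not p.exists() and not Path(entry).exists():
                return gio.bundled_soil(entry)
            return gio.load_soil_params(p if p.exists() else entry)

        sites = []
        for site_doc in doc["sites"]:
            climate_kwargs = dict(site_doc.get("climate", {}))
            if members_override:
                climate_kwargs["members_per_year"] = {
                    int(k): int(v) for k, v in members_override.items()
                }
            elif "members_per_year" in climate_kwargs:
                climate_kwargs["members_per_year"] = {
                    int(k): int(v)
                    for k, v in climate_kwargs["members_per_year"].items()
                }
            climate = ClimateConfig(**climate_kwargs).with_scenario(
                temp_bias=scenario.get("temp_bias"),
                precip_bias=scenario.get("precip_bias"),
                member_inflation=scenario.get("member_inflation"),
            )
            sites.append(
                SiteSpec(
                    site_id=str(site_doc["site_id"]),
                    climate=climate,
                    soil=resolve_soil(site_doc["soil"]),
                )
            )

        options = doc.get("options", {})
        sigma_ddof = 1 if options.get("sigma_convention") == "sample" else 0
        return cls(
            sites=sites,
            crops=[resolve_crop(c) for c in doc["crops"]],
            years=years,
            seed=int(seed if seed is not None else doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "greencast_out")),
            alpha=float(options.get("alpha", 0.05)),
            closeness_band=float(options.get("closeness_band", 2.0)),
            sigma_ddof=sigma_ddof,
            high_score_threshold=float(options.get("high_score_threshold", 4.21)),
            high_sigma_threshold=float(options.get("high_sigma_threshold", 2.0)),
            write_weather=bool(doc.get("write_weather", False)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one experiment run: inputs, outputs and warnings."""

    config_hash: str
    seed: int
    files: dict[str, str] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    complete: bool = False

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _derive_seed(master: int, *parts) -> int:
    entropy = [int(master)]
    for part in parts:
        entropy.append(zlib.crc32(str(part).encode()) if isinstance(part, str) else int(part))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def _season_rows(
    series, crop: CropParams, soil: SoilParams, warnings: list[str]
) -> list[dict]:
    result = run_season(series, crop, soil)
    if not result.matured:
        warnings.append(
            f"{series.site_id}/{crop.name}/{series.dates[0].year}/{series.realization}: "
            f"season ended before maturity (GDD {result.gdd_sum:.0f})"
        )
    values = {
        "precip": result.season_precip,
        "et": result.et_sum,
        "yield": result.yield_t_ha,
    }
    try:
        values["gwf"] = green_water_footprint(result.et_sum, result.yield_t_ha)
        values["wpet"] = water_productivity(result.yield_t_ha, result.et_sum)
    except (CropFailureError, DomainError):
        warnings.append(
            f"{series.site_id}/{crop.name}/{series.dates[0].year}/{series.realization}: "
            "crop failure, GWF/WPet undefined"
        )
        values["gwf"] = np.nan
        values["wpet"] = np.nan
    year = int(series.dates[0].year)
    return [
        {
            "year": year,
            "site": series.site_id,
            "crop": crop.name,
            "realization": series.realization,
            "variable": var,
            "value": values[var],
        }
        for var in VARIABLES
    ]


def simulate_outcomes(config: ExperimentConfig, out_dir: Path | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Run the generator and crop surrogate for the whole experiment."""
    rows: list[dict] = []
    warnings: list[str] = []
    for site in config.sites:
        for year in config.years:
            n_members = site.climate.n_members(year)
            truth_seed = _derive_seed(config.seed, site.site_id, year, "truth")
            member_seed = _derive_seed(config.seed, site.site_id, year, "members")
            truth = generate_truth(site.climate, year, truth_seed)
            truth.site_id = site.site_id
            members, control = perturb_members(truth, n_members, site.climate, member_seed)
            realizations = [truth, control, *members]
            if config.write_weather and out_dir is not None:
                weather_dir = out_dir / "weather"
                weather_dir.mkdir(parents=True, exist_ok=True)
                for series in realizations:
                    gio.write_weather_csv(
                        series, weather_dir / f"{site.site_id}_{year}_{series.realization}.csv"
                    )
            for crop in config.crops:
                for series in realizations:
                    rows.extend(_season_rows(series, crop, site.soil, warnings))
            log.info(
                "simulated site=%s year=%s members=%d crops=%d",
                site.site_id, year, n_members, len(config.crops),
            )
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS), warnings


def build_outcomes(
    outcomes_df: pd.DataFrame, warnings: list[str] | None = None
) -> list[EnsembleOutcome]:
    """Group a long-form outcome table into per-(site, crop, variable, year)
    ensembles.

    Non-finite member values (failed runs) are dropped with a warning;
    groups without an observed (OB) row or with fewer than two finite
    members are skipped and reported.  Raises :class:`DomainError` if no
    group at all is usable.
    """
    if warnings is None:
        warnings = []
    missing = [c for c in OUTCOME_COLUMNS if c not in outcomes_df.columns]
    if missing:
        raise DomainError(f"outcome table missing columns {missing}")
    outcomes: list[EnsembleOutcome] = []
    problems: list[str] = []
    grouped = outcomes_df.groupby(["site", "crop", "variable", "year"], sort=True)
    for (site, crop, variable, year), group in grouped:
        label = f"{site}/{crop}/{variable}/{year}"
        by_real = group.set_index("realization")["value"]
        if "OB" not in by_real.index:
            problems.append(f"{label}: no observed (OB) row")
            continue
        observed = float(by_real["OB"])
        control = float(by_real["CR"]) if "CR" in by_real.index else None
        member_vals = by_real[by_real.index.str.match(r"M\d+")].to_numpy(float)
        finite = np.isfinite(member_vals)
        if not finite.all():
            warnings.append(f"{label}: dropped {(~finite).sum()} non-finite member values")
            member_vals = member_vals[finite]
        if len(member_vals) < 2:
            problems.append(f"{label}: fewer than 2 usable members")
            continue
        if not np.isfinite(observed):
            problems.append(f"{label}: non-finite observed value")
            continue
        if control is not None and not np.isfinite(control):
            warnings.append(f"{label}: non-finite control value dropped")
            control = None
        outcomes.append(
            EnsembleOutcome(
                year=int(year), site=site, crop=crop, variable=variable,
                members=member_vals, control=control, observed=observed,
            )
        )
    for problem in problems:
        warnings.append(f"skipped group {problem}")
        log.warning("skipped group %s", problem)
    if not outcomes:
        raise DomainError(
            "no usable ensemble groups; problems: " + "; ".join(problems or ["empty table"])
        )
    return outcomes


def _verification_tables(
    outcomes: list[EnsembleOutcome], config: ExperimentConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    groups: dict[tuple, list[EnsembleOutcome]] = {}
    for outcome in outcomes:
        groups.setdefault((outcome.site, outcome.crop, outcome.variable), []).append(outcome)

    per_year_rows = []
    summary_rows = []
    for (site, crop, variable), group in sorted(groups.items()):
        group = sorted(group, key=lambda o: o.year)
        obs = np.array([o.observed for o in group])
        sigma_obs = float(np.std(obs, ddof=1)) if len(group) >= 2 else 0.0
        for outcome in group:
            stats = year_stats(
                outcome,
                sigma_obs=sigma_obs if sigma_obs > 0 else None,
                closeness_band=config.closeness_band,
                ddof=config.sigma_ddof,
            )
            per_year_rows.append(
                {
                    "year": outcome.year, "site": site, "crop": crop,
                    "variable": variable, "n_members": outcome.n,
                    "rmse": stats.rmse, "sprd": stats.sprd, "ea_error": stats.ea_error,
                    "skill_a": stats.skill_a, "skill_b": stats.skill_b,
                }
            )
        if len(group) >= 2:
            summary = multi_year_summary(group, closeness_band=config.closeness_band)
            row = {
                "site": site, "crop": crop, "variable": variable,
                "n_years": summary.n_years,
                "rmse_cr": summary.rmse_cr, "rmse_ea": summary.rmse_ea,
            }
            for name in ("OB", "CR", "EA"):
                stats_d = summary.datasets.get(name)
                row[f"mean_{name.lower()}"] = stats_d.mean if stats_d else np.nan
                row[f"sigma_{name.lower()}"] = stats_d.sigma if stats_d else np.nan
                row[f"cv_{name.lower()}"] = (
                    stats_d.cv if stats_d and stats_d.cv is not None else np.nan
                )
            for name in ("CR", "EA"):
                sk = summary.skill.get(name)
                row[f"skill_a_{name.lower()}"] = sk[0] if sk else None
                row[f"skill_b_{name.lower()}"] = sk[1] if sk else None
            summary_rows.append(row)
    return pd.DataFrame(per_year_rows), pd.DataFrame(summary_rows)


def _ignorance_tables(
    outcomes: list[EnsembleOutcome], config: ExperimentConfig, warnings: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_year_rows = []
    results_by_group: dict[tuple, list] = {}
    for outcome in sorted(outcomes, key=lambda o: (o.site, o.crop, o.variable, o.year)):
        key = (outcome.site, outcome.crop, outcome.variable)
        row = {
            "year": outcome.year, "site": outcome.site, "crop": outcome.crop,
            "variable": outcome.variable,
        }
        try:
            fit = fit_gaussian(outcome.members, alpha=config.alpha, ddof=config.sigma_ddof)
            result = ignorance_score(outcome.observed, fit)
            row.update(
                z=result.z, score_bits=result.score, category=result.category,
                normality_p=fit.normality_pvalue, valid=result.valid,
            )
            results_by_group.setdefault(key, []).append(result)
        except (DegenerateEnsembleError, DomainError) as exc:
            warnings.append(
                f"{outcome.site}/{outcome.crop}/{outcome.variable}/{outcome.year}: "
                f"ignorance not scored ({exc})"
            )
            row.update(
                z=np.nan, score_bits=np.nan, category="degenerate",
                normality_p=np.nan, valid=False,
            )
        per_year_rows.append(row)

    summary_rows = []
    for (site, crop, variable), results in sorted(results_by_group.items()):
        try:
            summary = summarize_scores(
                results,
                high_score_threshold=config.high_score_threshold,
                high_sigma_threshold=config.high_sigma_threshold,
            )
            summary_rows.append(
                {
                    "site": site, "crop": crop, "variable": variable,
                    "mean_score": summary.mean_score, "sigma_score": summary.sigma_score,
                    "n_years": summary.n_years, "n_excluded": summary.n_excluded,
                    "flag": summary.flag,
                }
            )
        except DomainError:
            summary_rows.append(
                {
                    "site": site, "crop": crop, "variable": variable,
                    "mean_score": np.nan, "sigma_score": np.nan,
                    "n_years": 0,
                    "n_excluded": len(results),
                    "flag": "insufficient_valid_years",
                }
            )
    return pd.DataFrame(per_year_rows), pd.DataFrame(summary_rows)


def _write_reports(
    outcomes: list[EnsembleOutcome],
    config: ExperimentConfig,
    out_dir: Path,
    warnings: list[str],
) -> dict[str, str]:
    verification_df, verification_summary = _verification_tables(outcomes, config)
    ignorance_df, ignorance_summary = _ignorance_tables(outcomes, config, warnings)
    files = {}
    for name, df in [
        ("verification", verification_df),
        ("verification_summary", verification_summary),
        ("ignorance", ignorance_df),
        ("ignorance_summary", ignorance_summary),
    ]:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        files[name] = str(path)
    return files


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full generate -> simulate -> derive -> verify -> score chain.

    Writes ``outcomes.csv``, the four report CSVs and ``manifest.json``
    to the output directory and returns the manifest.
    """
    out_path = Path(out_dir if out_dir is not None else config.output_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    try:
        outcomes_df, warnings = simulate_outcomes(config, out_path)
        outcomes_file = out_path / "outcomes.csv"
        outcomes_df.to_csv(outcomes_file, index=False)
        manifest.files["outcomes"] = str(outcomes_file)
        manifest.record_counts["outcome_rows"] = len(outcomes_df)

        outcomes = build_outcomes(outcomes_df, warnings)
        manifest.record_counts["ensemble_groups"] = len(outcomes)
        manifest.files.update(_write_reports(outcomes, config, out_path, warnings))
        manifest.warnings = warnings
        manifest.complete = True
    finally:
        manifest.write(out_path / "manifest.json")
    return manifest


def verify_from_table(
    outcomes_path: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    closeness_band: float = 2.0,
    sigma_ddof: int = 0,
    high_score_threshold: float = 4.21,
    high_sigma_threshold: float = 2.0,
) -> dict[str, str]:
    """Verify an externally produced outcome table (no simulation stage).

    The table must be long-form CSV with columns
    ``year,site,crop,realization,variable,value``; every usable group
    needs an ``OB`` row and at least two finite members.  Returns the
    mapping of report names to file paths.
    """
    df = pd.read_csv(outcomes_path)
    warnings: list[str] = []
    outcomes = build_outcomes(df, warnings)
    # minimal config object carrying the verification options
    config = ExperimentConfig.__new__(ExperimentConfig)
    config.alpha = alpha
    config.closeness_band = closeness_band
    config.sigma_ddof = sigma_ddof
    config.high_score_threshold = high_score_threshold
    config.high_sigma_threshold = high_sigma_threshold
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    files = _write_reports(outcomes, config, out_path, warnings)
    for warning in warnings:
        log.warning("%s", warning)
    return files
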