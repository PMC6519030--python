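"""CSV readers/writers, the Dataset container and the end-to-end pipeline.

All tables are plain CSV.  Laying dates and peak dates are on the April-day
scale (days since March 31; April 1 = day 1); calendar dates are ISO-8601.
An empty ``female_id`` marks an unknown-identity record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import Pedigree
from .synthdata import SimulationConfig, simulate_dataset

log = logging.getLogger("rnevo")

BREEDING_COLUMNS = ["female_id", "year", "nestbox", "laying_date",
                    "age_class", "recruits", "manipulated"]
ENV_COLUMNS = ["year", "cue_temp", "peak_date", "optimal_laying_date",
               "excluded"]


class TableFormatError(ValueError):
    pass


def read_breeding_table(path) -> pd.DataFrame:
    """Read breeding records; empty female_id -> unknown identity."""
    df = pd.read_csv(path, dtype={"female_id": "string"}, comment="#")
    missing = [c for c in BREEDING_COLUMNS if c not in df.columns and
               c not in ("manipulated",)]
    if missing:
        raise TableFormatError(f"breeding table missing columns {missing}")
    if "manipulated" not in df.columns:
        df["manipulated"] = False
    df["female_id"] = df["female_id"].where(
        df["female_id"].notna() & (df["female_id"].str.strip() != ""), None
    )
    df["age_class"] = df["age_class"].fillna("unknown")
    for col, kind in (("year", int), ("laying_date", float), ("recruits", int)):
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise TableFormatError(
                f"unparseable value in column {col!r} near file row {row}: {exc}"
            ) from exc
    neg = df.index[df["recruits"] < 0]
    if len(neg):
        raise TableFormatError(
            f"negative recruit count at file row {int(neg[0]) + 2}"
        )
    if not np.isfinite(df["laying_date"]).all():
        bad = df.index[~np.isfinite(df["laying_date"])][0]
        raise TableFormatError(f"non-finite laying date at file row {bad + 2}")
    dup = df[df["female_id"].notna()].duplicated(["female_id", "year"])
    if dup.any():
        raise TableFormatError(
            "duplicate female x year records: "
            f"{df.loc[dup[dup].index[:3], ['female_id', 'year']].to_dict('records')}"
        )
    df["manipulated"] = df["manipulated"].astype(bool)
    return df


def write_breeding_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["female_id"] = out["female_id"].fillna("")
    out[BREEDING_COLUMNS].to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    """Read a 3+ column pedigree CSV (id, dam, sire[, cohort, sex])."""
    df = pd.read_csv(path, dtype="string", comment="#")
    cols = list(df.columns)
    if len(cols) < 3:
        raise TableFormatError("pedigree CSV needs >= 3 columns (id, dam, sire)")
    rename = dict(zip(cols[:3], ["id", "dam", "sire"]))
    df = df.rename(columns=rename)
    for col in ("dam", "sire"):
        blank = df[col].isna() | (df[col].str.strip() == "") | (
            df[col].str.upper() == "NA")
        df[col] = df[col].where(~blank, None)
    if "cohort" in df.columns:
        df["cohort"] = pd.to_numeric(df["cohort"], errors="coerce")
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path) -> None:
    out = ped.table.copy()
    for col in ("dam", "sire"):
        out[col] = out[col].fillna("")
    out.to_csv(path, index=False)


def read_environments(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "year" not in df.columns or "cue_temp" not in df.columns:
        raise TableFormatError("environment table needs year and cue_temp")
    for col in ("peak_date", "optimal_laying_date"):
        if col not in df.columns:
            df[col] = np.nan
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool)
    return df


def read_daily_temperatures(path) -> pd.DataFrame:
    """Two-column CSV: ISO date, mean daily temperature."""
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    df = df.rename(columns=dict(zip(cols[:2], ["date", "value"])))
    df["date"] = pd.to_datetime(df["date"])
    df["value"] = df["value"].astype(float)
    return df


# ---------------------------------------------------------------------- #
@dataclass
class Dataset:
    """Breeding records + pedigree + environments, with integrity checks."""

    records: pd.DataFrame
    environments: pd.DataFrame
    pedigree: Pedigree | None = None
    daily_temperatures: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing_years = set(self.records["year"]) - set(self.environments["year"])
        if missing_years:
            raise TableFormatError(
                f"records reference years without an environment row: "
                f"{sorted(missing_years)[:5]}"
            )
        if self.pedigree is not None:
            known = set(self.pedigree.ids)
            fems = set(self.records["female_id"].dropna())
            orphans = fems - known
            if orphans:
                raise TableFormatError(
                    f"female ids missing from the pedigree: {sorted(orphans)[:5]}"
                )

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        write_breeding_table(self.records, out / "breeding_records.csv")
        files["breeding_records"] = "breeding_records.csv"
        self.environments.to_csv(out / "environments.csv", index=False)
        files["environments"] = "environments.csv"
        if self.pedigree is not None:
            write_pedigree(self.pedigree, out / "pedigree.csv")
            files["pedigree"] = "pedigree.csv"
        prov = dict(self.provenance)
        prov["package_version"] = __version__
        prov["files"] = files
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        return files

    @classmethod
    def read(cls, in_dir) -> "Dataset":
        p = Path(in_dir)
        ped = None
        if (p / "pedigree.csv").exists():
            ped = read_pedigree(p / "pedigree.csv")
        prov = {}
        if (p / "provenance.json").exists():
            prov = json.loads((p / "provenance.json").read_text())
        return cls(
            records=read_breeding_table(p / "breeding_records.csv"),
            environments=read_environments(p / "environments.csv"),
            pedigree=ped,
            provenance=prov,
        )


# ---------------------------------------------------------------------- #
@dataclass
class PipelineConfig:
    """Stages and inputs of the end-to-end run.

    With no input paths the pipeline simulates its own dataset.
    """

    out_dir: str = "rnevo_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    baseline_last_year: int | None = None
    n_boot_optimum: int = 1000
    n_boot_gradients: int = 200
    mcmc: dict = field(default_factory=dict)
    run_residual_sim: bool = False
    residual_sim: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> optimum -> RRAM -> gradients -> predict (-> residual sim).

    Returns a manifest of stage outputs; any stage failure raises with the
    stage name after writing the partial manifest.
    """
    from .mixedmodels import MCMCSettings, ModelSpec, ReactionNormAnimalModel
    from .optimum import fit_optimum_by_period, make_periods
    from .predict import compute_p_recr, predict_trajectory
    from .selection import SelectionConfig, annual_gradients, gradients_frame

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}
    t_all = time.time()

    def finish_stage(name, t0, **extra):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2),
                                    **extra}
        log.info("stage %s done in %.1fs", name, time.time() - t0)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    stage = "simulate"
    try:
        t0 = time.time()
        sim_cfg = SimulationConfig(**{"seed": config.seed,
                                      **config.simulation})
        data = simulate_dataset(sim_cfg)
        ds = Dataset(records=data.records, environments=data.environments,
                     pedigree=data.pedigree,
                     provenance={"seed": config.seed,
                                 "config": sim_cfg.to_dict()})
        ds.write(out / "data")
        data.breeders.to_csv(out / "data" / "breeders.csv", index=False)
        finish_stage(stage, t0, n_records=len(data.records))

        stage = "optimum"
        t0 = time.time()
        y0, y1 = sim_cfg.year_start, sim_cfg.year_start + sim_cfg.n_years - 1
        span = (y1 - y0 + 1) // 3
        periods = make_periods([
            (f"{y0}-{y0 + span - 1}", y0, y0 + span - 1),
            (f"{y0 + span}-{y0 + 2 * span - 1}", y0 + span, y0 + 2 * span - 1),
            (f"{y0 + 2 * span}-{y1}", y0 + 2 * span, y1),
        ])
        opt = fit_optimum_by_period(
            data.environments, periods, n_boot=config.n_boot_optimum,
            seed=config.seed,
        )
        opt.elevation.to_csv(out / "optimum_elevation.csv", index=False)
        opt.variance.to_csv(out / "optimum_variance.csv", index=False)
        finish_stage(stage, t0)

        stage = "fit-rram"
        t0 = time.time()
        settings = MCMCSettings(**config.mcmc) if config.mcmc else MCMCSettings()
        model = ReactionNormAnimalModel(
            data.records, data.environments, data.pedigree,
            ModelSpec(additive=True),
        )
        fit = model.fit(settings=settings, seed=config.seed)
        fit.summary().to_csv(out / "rram_summary.csv")
        fit.to_frame().to_csv(out / "rram_chains.csv", index=False)
        finish_stage(stage, t0)

        stage = "gradients"
        t0 = time.time()
        grads = gradients_frame(
            annual_gradients(
                data.records,
                SelectionConfig(n_boot=config.n_boot_gradients),
                seed=config.seed,
            )
        )
        grads.to_csv(out / "gradients.csv", index=False)
        finish_stage(stage, t0)

        stage = "predict"
        t0 = time.time()
        G = fit.covariance_median("G", ["intercept", "slope"])
        se_G = fit.covariance_se("G", ["intercept", "slope"])
        baseline = config.baseline_last_year or (y0 + span - 1)
        traj = predict_trajectory(
            G, se_G, grads, data.environments, compute_p_recr(data.breeders),
            baseline_last_year=baseline,
            grand_mean_temp=fit.meta["grand_mean_temp"],
        )
        traj.table.to_csv(out / "trajectory.csv", index=False)
        (out / "trajectory_summary.txt").write_text(traj.summary() + "\n")
        finish_stage(stage, t0)

        if config.run_residual_sim:
            stage = "residual-sim"
            t0 = time.time()
            from .residual_sim import (ResidualExperimentConfig,
                                       run_residual_experiment)
            rcfg = ResidualExperimentConfig(
                seed=config.seed, **config.residual_sim)
            res = run_residual_experiment(rcfg)
            res.per_replicate.to_csv(out / "residual_sim.csv", index=False)
            res.summary.to_csv(out / "residual_sim_summary.csv", index=False)
            finish_stage(stage, t0)
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        log.error("pipeline failed in stage %r", stage)
        raise
    manifest["total_seconds"] = round(time.time() - t_all, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
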