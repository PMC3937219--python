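"""End-to-end orchestration: simulate/load -> reduce -> fit -> report.

Runs the full analysis in order — strain table (synthetic or CSV),
expression-independence fit, multiplicative fitness null and epistasis
records, landscape fit with out-of-sample scoring, geometry — writing
each stage's table plus a JSON manifest with seeds, file hashes and
the headline qualitative findings.  Rerunning with the same config
reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .epistasis import (fit_multiplicative_fitness_null,
                        records_from_strain_table, s_epsilon_trend)
from .expression import fit_multiplicative_expression
from .geometry import DEFAULT_DOMAIN, direction_report, global_optimum
from .landscape import LandscapeParameters, fit_landscape, corrected_surface
from .nullsim import NullSimConfig, simulate_null_landscape, trend_summary

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

REQUIRED_STRAIN_COLUMNS = ("strain", "genotype", "category", "partition",
                           "flha_obs", "fgha_obs", "copy_obs", "fitness_obs")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    mode: str = "synthetic"              # "synthetic" | "csv"
    strains_csv: str | None = None       # required in csv mode
    outdir: str = "fitscape_run"
    seed: int = 0
    clamp: bool = True
    n_starts: int = 200
    noise: dict = field(default_factory=dict)   # NoiseModel overrides
    domain: tuple = DEFAULT_DOMAIN
    run_null_sim: bool = True
    null_sim: dict = field(default_factory=dict)  # NullSimConfig overrides
    make_figures: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not self.strains_csv:
            raise ValueError("csv mode requires strains_csv")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh,
                           sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_strains(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    if config.mode == "synthetic":
        design = synthetic.default_design()
        effects = synthetic.default_effects()
        params = synthetic.default_true_params()
        noise = synthetic.NoiseModel(**{"seed": config.seed, **config.noise})
        strains = synthetic.generate_study(design, effects, params, noise,
                                           clamp=config.clamp)
        truth = {"landscape_parameters": params.to_dict(),
                 "effects": [asdict(e) for e in effects],
                 "noise": asdict(noise)}
        return strains, truth
    strains = pd.read_csv(config.strains_csv, keep_default_na=False,
                          na_values=[""])
    strains["genotype"] = strains["genotype"].fillna("")
    missing = [c for c in REQUIRED_STRAIN_COLUMNS if c not in strains.columns]
    if missing:
        raise ValueError(
            f"stage 'load': strain table {config.strains_csv} is missing "
            f"required columns {missing}")
    return strains, {}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(asdict(config))),
                      "stages": {}, "outputs": {}, "findings": {}}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    def write_csv(name: str, df: pd.DataFrame) -> Path:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path)}
        return path

    try:
        stage("load")
        strains, truth = _load_strains(config)
        write_csv("strains", strains)
        if truth:
            tp = outdir / "ground_truth.json"
            tp.write_text(json.dumps(truth, indent=2))
            manifest["outputs"]["ground_truth"] = {"path": str(tp),
                                                   "sha256": _sha256(tp)}

        stage("expression_fit")
        efit = fit_multiplicative_expression(strains)
        write_csv("expression_residuals", efit.residuals)
        manifest["findings"]["expression_adj_r2"] = efit.adj_r2

        stage("epistasis")
        r2, adj_r2, null_resid = fit_multiplicative_fitness_null(strains)
        write_csv("fitness_null_residuals", null_resid)
        records = records_from_strain_table(strains)
        write_csv("epistasis_records", records)
        trend = s_epsilon_trend(records)
        manifest["findings"]["fitness_null_r2"] = r2
        manifest["findings"]["fitness_null_adj_r2"] = adj_r2
        manifest["findings"]["mean_epsilon"] = float(records["epsilon"].mean())
        manifest["findings"]["s_epsilon_slope"] = trend.slope
        manifest["findings"]["antagonism"] = bool(
            records["epsilon"].mean() < 0)

        stage("landscape_fit")
        lfit = fit_landscape(strains, n_starts=config.n_starts,
                             seed=config.seed, clamp=config.clamp)
        pp = outdir / "landscape_params.json"
        lfit.parameters.to_json(pp)
        manifest["outputs"]["landscape_params"] = {"path": str(pp),
                                                   "sha256": _sha256(pp)}
        write_csv("landscape_training_residuals", lfit.training_residuals)
        manifest["findings"]["oos_r2"] = lfit.oos_r2
        if truth:
            true_p = np.array(list(truth["landscape_parameters"].values()))
            rec_p = lfit.parameters.as_array()
            manifest["findings"]["param_recovery_max_rel_err"] = float(
                np.max(np.abs(rec_p - true_p) / true_p))

        stage("geometry")
        anc = strains[strains["category"] == "ancestor"].iloc[0]
        anc_pt = (float(anc["flha_obs"]), float(anc["fgha_obs"]))
        p_ref = float(anc["copy_obs"])
        # geometry on the relative scale: ancestor at (100, 100)
        scale = np.array([100.0 / anc_pt[0], 100.0 / anc_pt[1]])
        rel_params = _rescale_params(lfit.parameters, scale)
        reports = []
        singles = strains[strains["category"].isin(["single_A", "single_B"])]
        for _, row in singles.iterrows():
            mut_pt = np.array([row["flha_obs"], row["fgha_obs"]]) * scale
            rep = direction_report((100.0, 100.0), mut_pt, rel_params,
                                   config.domain, p_ref,
                                   mutation_id=row["strain"])
            reports.append(rep.as_dict())
        geom = pd.DataFrame(reports)
        write_csv("direction_reports", geom)
        manifest["findings"]["optimum"] = asdict(
            global_optimum(rel_params, config.domain, p_ref))
        manifest["findings"]["toward_optimum_fraction"] = float(
            (geom["angle_to_optimum"] < geom["angle_to_gradient"]).mean())

        if config.run_null_sim:
            stage("null_sim")
            ns_kwargs = {"seed": config.seed + 1,
                         "condition_on_beneficial": True, **config.null_sim}
            cond = simulate_null_landscape(NullSimConfig(**ns_kwargs))
            uncond = simulate_null_landscape(NullSimConfig(
                **{**ns_kwargs, "condition_on_beneficial": False}))
            both = pd.concat([cond, uncond], ignore_index=True)
            write_csv("null_sim_records", both)
            manifest["findings"]["null_sim"] = trend_summary(both)

        if config.make_figures:
            stage("figures")
            from . import plots
            figs = plots.standard_figures(strains, lfit, rel_params,
                                          config.domain, p_ref, outdir)
            for name, path in figs.items():
                manifest["outputs"][name] = {"path": str(path),
                                             "sha256": _sha256(path)}
    except Exception as exc:
        failed = [s for s in manifest["stages"]][-1] if manifest["stages"] \
            else "load"
        raise RuntimeError(f"pipeline aborted at stage {failed!r}: {exc}") \
            from exc

    # headline qualitative findings of the analysis
    manifest["findings"]["headline"] = {
        "fitness_antagonism": manifest["findings"]["antagonism"],
        "near_multiplicative_expression": all(
            v > 0.8 for v in manifest["findings"]["expression_adj_r2"].values()),
        "high_oos_landscape_r2": (manifest["findings"]["oos_r2"] or 0) > 0.9,
        "mutations_toward_global_optimum":
            manifest["findings"]["toward_optimum_fraction"] > 0.5,
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def _rescale_params(params: LandscapeParameters,
                    scale: np.ndarray) -> LandscapeParameters:
    """Convert parameters from the mU scale to the relative scale.

    Expression enters via Eh (same units as FlhA) and the two linear
    costs (per unit of each enzyme); rescaling axes by ``scale``
    divides Eh by the FlhA factor and the costs by their axis factors.
    """
    return LandscapeParameters(
        vmax=params.vmax,
        eh=params.eh * scale[0],
        ft=params.ft,
        cost_flha=params.cost_flha / scale[0],
        cost_fgha=params.cost_fgha / scale[1],
        cost_copy=params.cost_copy)
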