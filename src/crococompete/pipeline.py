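"""End-to-end pipeline: generate -> estimate -> budget -> simulate -> fit.

Each stage is an ordinary function over DataFrames/paths so it can be
driven from the CLI or from Python; :func:`run_pipeline` wires them in
order, halts on the first failing stage, and writes a manifest with the
config hash and SHA-256 checksums of every output so that re-running
with identical inputs is verifiably reproducible (timestamps excluded
from the hash).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .biomass_estimation import (
    BeadStandard,
    SizeCalibration,
    calibrate_size,
    drawdown_vs_biomass,
    estimate_biomass_table,
    ethylene_to_fixed_n,
    fixation_fraction_of_demand,
)
from .config import (
    config_hash,
    default_config,
    groups_from_config,
    load_config,
    zoo_from_config,
)
from .errors import ConfigurationError, CrocoError
from .model_core import EcosystemState
from .parameter_fitting import FitSpec, fit_parameters
from .simulation_engine import (
    NutrientForcing,
    fit_nutrient_forcing,
    run_incubation,
    scenario_suite,
)
from .synthetic_data import GeneratorConfig, generate_experiment

__all__ = [
    "calibrate_from_beads",
    "forcing_from_config",
    "budget_table",
    "fit_from_tables",
    "run_pipeline",
]


def calibrate_from_beads(beads: pd.DataFrame) -> SizeCalibration:
    """Size calibration from a beads table (columns diameter_um, fls)."""
    standards = [
        BeadStandard(diameter=row.diameter_um, fls=row.fls)
        for row in beads.itertuples(index=False)
    ]
    return calibrate_size(standards)


def forcing_from_config(block: Mapping[str, Any]) -> NutrientForcing:
    """Build a NutrientForcing from a config mapping.

    ``{"kind": "constant", "nh4": x, "no3": y}`` or
    ``{"kind": "quadratic", "nh4": [a, b, c], "no3": [a, b, c]}``.
    """
    kind = block.get("kind", "constant")
    if kind == "constant":
        return NutrientForcing.constant(float(block["nh4"]), float(block["no3"]))
    if kind == "quadratic":
        return NutrientForcing.quadratic(block["nh4"], block["no3"])
    raise ConfigurationError(f"forcing kind must be constant|quadratic, got {kind!r}")


def budget_table(
    nutrients: pd.DataFrame,
    biomass: pd.DataFrame,
    arr: Optional[pd.DataFrame] = None,
    day_start: float = 0.0,
    day_end: float = 3.0,
    mortality: float = 0.0,
    detection_limits: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-treatment nitrogen budgets over one interval.

    For every treatment present in both tables: combined-N drawdown,
    summed biomass-N increment and their ratio; when an acetylene
    reduction table is supplied, the diazotroph's fixation N input
    (trapezoid of the replicate-mean N-atom rates) and the percent of
    its N demand met by fixation.  Demand is gross assimilation: the
    *Crocosphaera* biomass increment plus its mortality loss
    (``mortality`` * trapezoid of the Cro pool).
    """
    rows = []
    for treatment in sorted(set(nutrients["treatment"]) & set(biomass["treatment"])):
        budget = drawdown_vs_biomass(
            nutrients, biomass, treatment, day_start, day_end, detection_limits
        )
        fixation_n = None
        percent = None
        if arr is not None and "Cro" in set(biomass["group"]):
            sub = arr[
                (arr["treatment"] == treatment)
                & (arr["day"] >= day_start)
                & (arr["day"] <= day_end)
            ]
            if not sub.empty:
                rates = sub.groupby("day")["ethylene_nmol_l_d"].mean()
                n_rates = [ethylene_to_fixed_n(r, output="atoms") for r in rates]
                fixation_n = float(np.trapezoid(n_rates, rates.index.to_numpy()))
                cro = (
                    biomass[biomass["treatment"] == treatment]
                    .query("group == 'Cro'")
                    .groupby("day")["n_nmol_l"]
                    .mean()
                )
                increment = float(cro.loc[day_end] - cro.loc[day_start])
                loss = mortality * float(
                    np.trapezoid(cro.to_numpy(), cro.index.to_numpy())
                )
                percent = fixation_fraction_of_demand(increment, loss, fixation_n)
        rows.append(
            {
                "treatment": treatment,
                "day_start": day_start,
                "day_end": day_end,
                "drawdown_nmol_l": budget.drawdown,
                "biomass_increment_nmol_l": budget.biomass_increment,
                "ratio": budget.ratio,
                "fixation_n_nmol_l": fixation_n,
                "percent_demand_fixation": percent,
                "censored_endpoint": budget.censored_endpoint,
                "flags": ";".join(budget.flags),
            }
        )
    return pd.DataFrame(rows)


def fit_from_tables(
    config: Mapping[str, Any],
    nutrients: pd.DataFrame,
    biomass: pd.DataFrame,
    treatment: str = "nh4",
) -> dict:
    """Fit the configured free parameters to one treatment's trajectory.

    The nutrient forcing is the quadratic fitted to the treatment's
    replicate-mean NH4+/NO3- series; the observation series is the
    estimated biomass N of the configured group.
    """
    fit_cfg = config.get("fit", default_config()["fit"])
    group_name = fit_cfg.get("group", "Cro")
    groups = groups_from_config(config)
    if group_name not in groups:
        raise ConfigurationError(f"fit.group {group_name!r} not in config groups")

    nut = nutrients[nutrients["treatment"] == treatment]
    means = (
        nut.groupby(["day", "nutrient"])["conc_nmol_l"].mean().unstack("nutrient")
    )
    forcing = fit_nutrient_forcing(
        means.index.to_numpy(), means["nh4"].to_numpy(), means["no3"].to_numpy()
    )
    obs = (
        biomass[(biomass["treatment"] == treatment) & (biomass["group"] == group_name)]
        .rename(columns={"day": "time_d"})[["time_d", "n_nmol_l"]]
        .reset_index(drop=True)
    )
    free = {k: tuple(v) for k, v in fit_cfg["free"].items()}
    spec = FitSpec(
        base=groups[group_name],
        free=free,
        n_starts=int(fit_cfg.get("n_starts", 10)),
        seed=int(fit_cfg.get("seed", 0)),
    )
    result = fit_parameters(spec, obs, forcing)
    out = result.to_dict()
    out["group"] = group_name
    out["treatment"] = treatment
    out["forcing"] = {
        "kind": "quadratic",
        "nh4": list(forcing.nh4_coeffs),
        "no3": list(forcing.no3_coeffs),
    }
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> dict:
    """Run every stage end to end and write a manifest.

    ``config`` may be a YAML path, a mapping, or ``None`` for the
    package defaults; ``seed`` overrides the synthetic-data seed.
    Returns the manifest dict.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {**default_config(), **dict(config)}

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn_cfg = cfg.get("synthetic", {})
    gen = GeneratorConfig(
        seed=int(seed if seed is not None else syn_cfg.get("seed", 0)),
        sink_fraction=float(syn_cfg.get("sink_fraction", 0.5)),
        noise_sigma=float(syn_cfg.get("noise_sigma", 0.1)),
    )

    stage = "generate-data"
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": gen.seed,
        "stages": [],
        "outputs": {},
    }
    try:
        data_dir = out / "data"
        experiment = generate_experiment(gen, out_dir=data_dir)
        manifest["stages"].append(stage)

        stage = "estimate-biomass"
        cal = calibrate_from_beads(experiment.beads)
        biomass = estimate_biomass_table(experiment.fcm, cal)
        biomass.to_csv(out / "biomass.csv", index=False, float_format="%.8g")
        manifest["stages"].append(stage)

        stage = "nitrogen-budget"
        budget_cfg = cfg.get("budget", {})
        budget = budget_table(
            experiment.nutrients,
            biomass,
            experiment.arr,
            day_start=float(budget_cfg.get("day_start", 0.0)),
            day_end=float(budget_cfg.get("day_end", 3.0)),
            mortality=float(budget_cfg.get("mortality", 0.0)),
        )
        budget.to_csv(out / "budget.csv", index=False, float_format="%.8g")
        manifest["stages"].append(stage)

        stage = "simulate"
        groups = groups_from_config(cfg)
        zoo = zoo_from_config(cfg)
        eco = cfg["ecosystem"]
        initial = EcosystemState(**eco["initial"])
        trajectories = scenario_suite(
            groups["Cro"],
            groups["Oth"],
            zoo,
            initial,
            t_end=float(eco.get("t_end", 10.0)),
            dt=float(eco.get("dt", 0.01)),
        )
        frames = [t.to_frame() for t in trajectories.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / "scenarios.csv", index=False, float_format="%.8g"
        )
        inc = cfg["incubation"]
        inc_traj = run_incubation(
            list(groups.values()),
            forcing_from_config(inc["forcing"]),
            {name: float(inc["initial"].get(name, 1.0)) for name in groups},
            t_end=float(inc.get("t_end", 3.0)),
            dt=float(inc.get("dt", 0.01)),
        )
        inc_traj.to_csv(out / "incubation.csv")
        manifest["stages"].append(stage)

        stage = "fit"
        fit_out = fit_from_tables(cfg, experiment.nutrients, biomass)
        with open(out / "fit.json", "w") as fh:
            json.dump(fit_out, fh, indent=1, sort_keys=True)
        manifest["stages"].append(stage)
    except CrocoError as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    top_manifest = out / "manifest.json"
    for path in sorted(out.rglob("*")):
        if path.is_file() and path != top_manifest:
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
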