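"""Seeded synthetic microcosm experiments for end-to-end testing.

Emulates a 3-day, triplicate, nutrient-addition incubation with four
pre-gated phytoplankton populations (*Prochlorococcus*, *Synechococcus*,
picoeukaryotes, *Crocosphaera*): exponential nutrient drawdown to the
analytical detection limits, group-specific Monod growth, cell-size
distributions feeding forward-scatter medians, bead calibration
standards, and acetylene-reduction rates for the diazotroph.  Every
table is derived from a forward simulation of the growth model coupled
to nutrient depletion, so parameter-recovery and budget tests have an
exact ground truth (written to a sidecar ``truth.json``).

The nutrient drawdown rate is the community's *net* N assimilation
divided by ``1 - sink_fraction``; with the default sink of 0.5, biomass
increments explain exactly half of the consumed N before noise — the
unexplained half stands in for luxury uptake and estimation gaps.  Noise
is multiplicative lognormal (counts and concentrations are positive and
right-skewed).  Each output table draws from its own random stream split
from the master seed, so adding a table never perturbs existing draws.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .biomass_estimation import (
    DEFAULT_CONVERSIONS,
    carbon_per_cell,
    nitrogen_per_cell,
)
from .model_core import (
    EcosystemState,
    NutrientPair,
    PhytoGroupParams,
    ZooParams,
    monod_growth_rate,
)
from .simulation_engine import (
    CANONICAL_SCENARIOS,
    NutrientForcing,
    ScenarioConfig,
    Trajectory,
    run_ecosystem_scenario,
)

__all__ = [
    "GroupTruth",
    "GeneratorConfig",
    "SyntheticExperiment",
    "BEAD_DIAMETERS_UM",
    "generate_experiment",
    "generate_bead_standards",
    "generate_ecosystem_truth",
]

#: Diameters of the monodisperse polystyrene bead standards, um.
BEAD_DIAMETERS_UM = (1.75, 2.0, 3.0, 6.0, 10.0)

TREATMENTS = ("control", "nh4", "no3", "p")


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth description of one phytoplankton group."""

    params: PhytoGroupParams
    diameter_um: float  # median cell diameter
    abundance0_cells_per_ml: float

    def per_cell_n_fmol(self) -> float:
        conv = DEFAULT_CONVERSIONS[self.params.name]
        volume = math.pi / 6.0 * self.diameter_um**3
        return nitrogen_per_cell(conv, carbon_per_cell(conv, volume))


def _default_groups() -> dict[str, GroupTruth]:
    # Oligotrophic western-Pacific-like community: Prochlorococcus most
    # abundant by cells, Crocosphaera (largest cells) most of the biomass,
    # picoeukaryotes second.  Crocosphaera has the high uptake maxima and
    # high half-saturations; mortality 0 (grazers removed by prefiltration,
    # 3-day window), which keeps the generated nutrient drawdown monotone.
    return {
        "Pro": GroupTruth(
            PhytoGroupParams("Pro", vmax_nh4=0.9, vmax_no3=0.4, k_nh4=30.0, k_no3=50.0),
            diameter_um=0.6,
            abundance0_cells_per_ml=3.0e4,
        ),
        "Syn": GroupTruth(
            PhytoGroupParams("Syn", vmax_nh4=1.0, vmax_no3=0.5, k_nh4=40.0, k_no3=60.0),
            diameter_um=1.0,
            abundance0_cells_per_ml=2.0e3,
        ),
        "PicoE": GroupTruth(
            PhytoGroupParams("PicoE", vmax_nh4=1.1, vmax_no3=0.8, k_nh4=60.0, k_no3=100.0),
            diameter_um=2.0,
            abundance0_cells_per_ml=3.0e2,
        ),
        "Cro": GroupTruth(
            PhytoGroupParams(
                "Cro",
                vmax_nh4=6.6,
                vmax_no3=3.0,
                k_nh4=500.0,
                k_no3=500.0,
                diazotroph_floor=0.31,
            ),
            diameter_um=3.5,
            abundance0_cells_per_ml=1.0e2,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design constants of the synthetic experiment.

    Ambient nutrients and additions follow a nanomolar N-addition
    bioassay: +100 nM NH4+ or NO3-, +10 nM phosphate, daily sampling of
    triplicates over days 0-3; detection limits 6 / 3 / 3 nM for NH4+,
    NO3-+NO2- and SRP.  ``fixation_rate`` is the diazotroph's specific
    N2-fixation rate (d^-1, N atoms per biomass N); ammonium suppresses
    it by up to ``fixation_inhibition`` with half-effect at
    ``fixation_inhibition_k`` nM.
    """

    seed: int = 0
    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    replicates: int = 3
    ambient_nh4: float = 15.0
    ambient_no3: float = 5.0
    ambient_srp: float = 60.0
    n_addition: float = 100.0
    p_addition: float = 10.0
    detection_limit_nh4: float = 6.0
    detection_limit_no3: float = 3.0
    detection_limit_srp: float = 3.0
    noise_sigma: float = 0.10
    sink_fraction: float = 0.5
    fixation_rate: float = 0.007
    fixation_inhibition: float = 0.8
    fixation_inhibition_k: float = 100.0
    bead_fls_scale: float = 80.0
    bead_fls_exponent: float = 2.0
    bead_noise_sigma: float = 0.02
    median_fls_sigma: float = 0.03
    truth_dt: float = 0.005
    groups: dict[str, GroupTruth] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 <= self.sink_fraction < 1.0):
            raise ValueError("sink_fraction must be in [0, 1)")
        for name in ("detection_limit_nh4", "detection_limit_no3", "detection_limit_srp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def initial_nutrients(self, treatment: str) -> tuple[float, float, float]:
        nh4, no3, srp = self.ambient_nh4, self.ambient_no3, self.ambient_srp
        if treatment == "nh4":
            nh4 += self.n_addition
        elif treatment == "no3":
            no3 += self.n_addition
        elif treatment == "p":
            srp += self.p_addition
        elif treatment != "control":
            raise ValueError(f"unknown treatment {treatment!r}")
        return nh4, no3, srp


@dataclass
class SyntheticExperiment:
    """Generated tables plus the pre-noise ground truth."""

    beads: pd.DataFrame
    fcm: pd.DataFrame
    nutrients: pd.DataFrame
    arr: pd.DataFrame
    truth: dict
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the four CSVs, truth.json and a manifest; returns checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "beads.csv": self.beads,
            "fcm.csv": self.fcm,
            "nutrients.csv": self.nutrients,
            "arr.csv": self.arr,
        }
        for name, table in tables.items():
            table.to_csv(out / name, index=False, float_format="%.8g")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        checksums = {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in [*tables, "truth.json"]
        }
        manifest = {
            "seed": self.config.seed,
            "config_hash": _config_hash(self.config),
            "files": checksums,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return checksums


def _config_hash(config: GeneratorConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _simulate_truth(config: GeneratorConfig, treatment: str):
    """RK4 forward simulation of pools + nutrient depletion for one bottle.

    Returns (sample days, pools[group][day], nh4[day], no3[day],
    cumulative net assimilation per nutrient) evaluated at config.days.
    """
    names = list(config.groups)
    truths = [config.groups[n] for n in names]
    y = np.array(
        [t.abundance0_cells_per_ml * 1000.0 * t.per_cell_n_fmol() * 1e-6 for t in truths]
        + list(config.initial_nutrients(treatment)[:2])
    )
    ngroups = len(names)
    keep = 1.0 - config.sink_fraction

    def deriv(y: np.ndarray) -> np.ndarray:
        pools = np.maximum(y[:ngroups], 0.0)
        nut = NutrientPair(nh4=max(0.0, y[ngroups]), no3=max(0.0, y[ngroups + 1]))
        d = np.zeros_like(y)
        for i, t in enumerate(truths):
            p = t.params
            mu_nh4 = p.vmax_nh4 * nut.nh4 / (nut.nh4 + p.k_nh4)
            mu_no3 = p.vmax_no3 * nut.no3 / (nut.no3 + p.k_no3)
            net = (mu_nh4 + mu_no3 - p.mortality) * pools[i]
            d[i] = net
            mu_sum = mu_nh4 + mu_no3
            if mu_sum > 0:
                d[ngroups] -= net * (mu_nh4 / mu_sum) / keep
                d[ngroups + 1] -= net * (mu_no3 / mu_sum) / keep
        return d

    dt = config.truth_dt
    t_end = max(config.days)
    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    states = np.empty((n_steps + 1, len(y)))
    states[0] = y
    clipped = False
    for step in range(1, n_steps + 1):
        k1 = deriv(y)
        k2 = deriv(y + dt / 2 * k1)
        k3 = deriv(y + dt / 2 * k2)
        k4 = deriv(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.any(y[ngroups:] < -1e-9):
            clipped = True
        y = np.maximum(y, 0.0)
        states[step] = y
    if clipped:
        warnings.warn(
            f"{treatment}: nutrient pool driven below zero and clipped", stacklevel=2
        )

    idx = [int(round(d / dt)) for d in config.days]
    pools = {n: states[idx, i] for i, n in enumerate(names)}
    nh4 = states[idx, ngroups]
    no3 = states[idx, ngroups + 1]
    return pools, nh4, no3


def generate_bead_standards(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Bead calibration table: the five standard diameters with FLS values
    drawn from the generator's true power law FLS = scale * d^exponent
    plus multiplicative lognormal noise."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    diameters = np.array(BEAD_DIAMETERS_UM)
    fls = config.bead_fls_scale * diameters**config.bead_fls_exponent
    if config.bead_noise_sigma > 0:
        fls = fls * rng.lognormal(0.0, config.bead_noise_sigma, size=len(fls))
    return pd.DataFrame({"diameter_um": diameters, "fls": fls})


def generate_experiment(
    config: GeneratorConfig = GeneratorConfig(),
    out_dir: Optional[str | Path] = None,
) -> SyntheticExperiment:
    """Generate a complete synthetic incubation experiment.

    Forward-simulates true biomass and nutrient drawdown per treatment,
    samples the four observation tables at the configured days with
    multiplicative lognormal noise, censors nutrient values below the
    detection limits (reported at the limit with a flag), and records
    the exact pre-noise truth.  Deterministic per seed; ``out_dir``
    optionally writes everything to disk.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_nut = np.random.default_rng(streams[0])
    rng_fcm = np.random.default_rng(streams[1])
    rng_arr = np.random.default_rng(streams[2])
    rng_beads = np.random.default_rng(streams[3])

    sigma = config.noise_sigma
    limits = {
        "nh4": config.detection_limit_nh4,
        "no3": config.detection_limit_no3,
        "srp": config.detection_limit_srp,
    }
    reps = [f"r{i + 1}" for i in range(config.replicates)]

    nut_rows, fcm_rows, arr_rows = [], [], []
    truth_biomass: dict[str, dict] = {}
    truth_nutrients: dict[str, dict] = {}
    truth_budget: dict[str, dict] = {}
    truth_fixation: dict[str, dict] = {}

    for treatment in TREATMENTS:
        pools, nh4_truth, no3_truth = _simulate_truth(config, treatment)
        srp_truth = np.full(len(config.days), config.initial_nutrients(treatment)[2])
        truth_biomass[treatment] = {
            f"{day:g}": {g: float(pools[g][di]) for g in pools}
            for di, day in enumerate(config.days)
        }
        truth_nutrients[treatment] = {
            f"{day:g}": {
                "nh4": float(nh4_truth[di]),
                "no3": float(no3_truth[di]),
                "srp": float(srp_truth[di]),
            }
            for di, day in enumerate(config.days)
        }

        # Interval budget truth (day 0 -> final day), pre-noise.
        drawdown = float(
            (nh4_truth[0] - nh4_truth[-1]) + (no3_truth[0] - no3_truth[-1])
        )
        increment = float(
            sum(pools[g][-1] for g in pools) - sum(pools[g][0] for g in pools)
        )
        truth_budget[treatment] = {
            "drawdown_nmol_l": drawdown,
            "biomass_increment_nmol_l": increment,
            "ratio": increment / drawdown if drawdown else None,
        }

        # Diazotroph fixation: specific rate suppressed by ambient NH4+.
        cro = pools["Cro"]
        inhibition = 1.0 - config.fixation_inhibition * nh4_truth / (
            nh4_truth + config.fixation_inhibition_k
        )
        fix_rate = config.fixation_rate * inhibition * cro  # nmol N L^-1 d^-1
        # trapezoid over the sampling days: total fixation input day 0 -> end
        fix_input = float(np.trapezoid(fix_rate, config.days))
        cro_increment = float(cro[-1] - cro[0])
        truth_fixation[treatment] = {
            "fixation_input_nmol_l": fix_input,
            "cro_increment_nmol_l": cro_increment,
            "percent_demand": 100.0 * fix_input / cro_increment
            if cro_increment > 0
            else None,
        }

        for di, day in enumerate(config.days):
            for rep in reps:
                for nutrient, series in (
                    ("nh4", nh4_truth),
                    ("no3", no3_truth),
                    ("srp", srp_truth),
                ):
                    true = float(series[di])
                    measured = true * float(rng_nut.lognormal(0.0, sigma)) if sigma else true
                    below = measured < limits[nutrient]
                    nut_rows.append(
                        {
                            "day": day,
                            "treatment": treatment,
                            "replicate": rep,
                            "nutrient": nutrient,
                            "conc_nmol_l": limits[nutrient] if below else measured,
                            "below_detection": below,
                        }
                    )
                for g, truth_g in config.groups.items():
                    npc = truth_g.per_cell_n_fmol()
                    true_cells_ml = pools[g][di] * 1e6 / npc / 1000.0
                    cells = (
                        true_cells_ml * float(rng_fcm.lognormal(0.0, sigma))
                        if sigma
                        else true_cells_ml
                    )
                    d_rep = truth_g.diameter_um * (
                        float(np.exp(rng_fcm.normal(0.0, config.median_fls_sigma)))
                        if config.median_fls_sigma
                        else 1.0
                    )
                    fls = config.bead_fls_scale * d_rep**config.bead_fls_exponent
                    fcm_rows.append(
                        {
                            "day": day,
                            "treatment": treatment,
                            "replicate": rep,
                            "group": g,
                            "abundance_cells_per_ml": cells,
                            "median_fls": fls,
                        }
                    )
                ethylene_true = 2.0 * float(fix_rate[di])
                ethylene = (
                    ethylene_true * float(rng_arr.lognormal(0.0, sigma))
                    if sigma
                    else ethylene_true
                )
                arr_rows.append(
                    {
                        "day": day,
                        "treatment": treatment,
                        "replicate": rep,
                        "ethylene_nmol_l_d": ethylene,
                    }
                )

    truth = {
        "seed": config.seed,
        "sink_fraction": config.sink_fraction,
        "fixation_rate_per_d": config.fixation_rate,
        "bead_law": {
            "scale": config.bead_fls_scale,
            "exponent": config.bead_fls_exponent,
        },
        "groups": {
            name: {
                "vmax_nh4": gt.params.vmax_nh4,
                "vmax_no3": gt.params.vmax_no3,
                "k_nh4": gt.params.k_nh4,
                "k_no3": gt.params.k_no3,
                "mortality": gt.params.mortality,
                "diazotroph_floor": gt.params.diazotroph_floor,
                "diameter_um": gt.diameter_um,
                "per_cell_n_fmol": gt.per_cell_n_fmol(),
                "abundance0_cells_per_ml": gt.abundance0_cells_per_ml,
            }
            for name, gt in config.groups.items()
        },
        "biomass_n_nmol_l": truth_biomass,
        "nutrients_nmol_l": truth_nutrients,
        "budget": truth_budget,
        "fixation": truth_fixation,
    }

    experiment = SyntheticExperiment(
        beads=generate_bead_standards(config, rng_beads),
        fcm=pd.DataFrame(fcm_rows),
        nutrients=pd.DataFrame(nut_rows),
        arr=pd.DataFrame(arr_rows),
        truth=truth,
        config=config,
    )
    if out_dir is not None:
        experiment.write(out_dir)
    return experiment


def generate_ecosystem_truth(
    scenario: str,
    cro: PhytoGroupParams,
    oth: PhytoGroupParams,
    zoo: ZooParams,
    initial: EcosystemState,
    t_end: float = 10.0,
    dt: float = 0.01,
) -> tuple[Trajectory, dict]:
    """Deterministic fixture for one canonical competition scenario.

    ``scenario`` is "A" (100/100 nM, no fixation), "B" (1/1 nM, no
    fixation) or "C" (1/1 nM with the diazotroph floor).  Returns the
    trajectory plus a provenance dict describing exactly what was run.
    """
    table = {label: (conc, fix) for label, conc, fix in CANONICAL_SCENARIOS}
    if scenario not in table:
        raise ValueError(f"scenario must be one of {sorted(table)}, got {scenario!r}")
    conc, fixation = table[scenario]
    cfg = ScenarioConfig(
        label=scenario,
        forcing=NutrientForcing.constant(conc, conc),
        initial=initial,
        fixation_enabled=fixation,
        t_end=t_end,
        dt=dt,
    )
    traj = run_ecosystem_scenario(cfg, cro, oth, zoo)
    provenance = {
        "scenario": scenario,
        "nh4_nmol_l": conc,
        "no3_nmol_l": conc,
        "fixation_enabled": fixation,
        "t_end_d": t_end,
        "dt_d": dt,
        "params_hash": traj.params_hash,
        "final": {pool: traj.final(pool) for pool in traj.pools},
    }
    return traj, provenance
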