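"""Forward integration of the incubation and ecosystem models.

Two modes:

* **Incubation** — each phytoplankton group obeys dN/dt = (mu - m) N with
  mu a Monod sum over NH4+ and NO3-, under an exogenous nutrient forcing
  (typically a quadratic fitted to measured drawdown).  Groups do not
  interact and there is no grazing.
* **Ecosystem** — two groups (*Crocosphaera* and "others") compete under
  constant nutrients while a zooplankton pool grazes them with the
  kill-the-winner response and suffers quadratic mortality.  An optional
  diazotrophic growth floor lets *Crocosphaera* keep growing when
  combined N is depleted.

Integration is classical fixed-step RK4: deterministic, reproducible,
and accurate for these smooth systems; pools are clipped at zero after
each step.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, IntegrationError
from .model_core import (
    EcosystemState,
    NutrientPair,
    PhytoGroupParams,
    ZooParams,
    ecosystem_derivatives,
    effective_growth_rate,
    monod_growth_rate,
)

__all__ = [
    "NutrientForcing",
    "ScenarioConfig",
    "Trajectory",
    "fit_quadratic_drawdown",
    "fit_nutrient_forcing",
    "run_incubation",
    "run_ecosystem_scenario",
    "scenario_suite",
    "CANONICAL_SCENARIOS",
]

CensoringPolicy = Literal["half-limit", "exclude", "zero"]


@dataclass(frozen=True)
class NutrientForcing:
    """Time-dependent ambient NH4+/NO3- concentrations.

    ``kind="constant"`` holds a fixed :class:`NutrientPair`;
    ``kind="quadratic"`` evaluates conc(t) = a t^2 + b t + c per nutrient
    (t in days) and clips negative values to zero, since a quadratic
    fitted to a drawdown can dip below zero late in the window.
    """

    kind: Literal["constant", "quadratic"]
    pair: Optional[NutrientPair] = None
    nh4_coeffs: Optional[tuple[float, float, float]] = None
    no3_coeffs: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.pair is None:
                raise DomainError("constant forcing requires a NutrientPair")
        elif self.kind == "quadratic":
            for name in ("nh4_coeffs", "no3_coeffs"):
                coeffs = getattr(self, name)
                if coeffs is None or len(coeffs) != 3:
                    raise DomainError(f"quadratic forcing requires 3 {name}")
                if not all(np.isfinite(coeffs)):
                    raise DomainError(f"{name} must be finite")
        else:
            raise DomainError(f"unknown forcing kind {self.kind!r}")

    @classmethod
    def constant(cls, nh4: float, no3: float) -> "NutrientForcing":
        return cls(kind="constant", pair=NutrientPair(nh4=nh4, no3=no3))

    @classmethod
    def quadratic(
        cls,
        nh4_coeffs: Sequence[float],
        no3_coeffs: Sequence[float],
    ) -> "NutrientForcing":
        return cls(
            kind="quadratic",
            nh4_coeffs=tuple(float(x) for x in nh4_coeffs),
            no3_coeffs=tuple(float(x) for x in no3_coeffs),
        )

    def at(self, t: float) -> NutrientPair:
        """Concentrations at time ``t`` (days), clipped at zero."""
        if self.kind == "constant":
            return self.pair  # type: ignore[return-value]
        a, b, c = self.nh4_coeffs  # type: ignore[misc]
        nh4 = max(0.0, a * t * t + b * t + c)
        a, b, c = self.no3_coeffs  # type: ignore[misc]
        no3 = max(0.0, a * t * t + b * t + c)
        return NutrientPair(nh4=nh4, no3=no3)


@dataclass(frozen=True)
class ScenarioConfig:
    """One ecosystem-model scenario (label, forcing, ICs, fixation, grid)."""

    label: str
    forcing: NutrientForcing
    initial: EcosystemState
    fixation_enabled: bool
    t_end: float = 10.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (self.t_end > 0 and self.dt > 0 and self.dt <= self.t_end):
            raise DomainError("require t_end > 0, dt > 0, dt <= t_end")


@dataclass
class Trajectory:
    """Integrated time series of nitrogen pools.

    ``pools`` maps pool name -> series (nmol N L^-1) on the common
    ``time`` grid (days); ``growth_rates`` holds the realized specific
    growth rate of each phytoplankton group at every step.
    """

    time: np.ndarray
    pools: dict[str, np.ndarray]
    growth_rates: dict[str, np.ndarray] = field(default_factory=dict)
    label: str = ""
    params_hash: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("trajectory time grid must be strictly increasing")
        for name, series in self.pools.items():
            if len(series) != len(self.time):
                raise DomainError(f"pool {name!r} length mismatch")
            if np.any(series < 0):
                raise DomainError(f"pool {name!r} has negative values")

    def final(self, pool: str) -> float:
        return float(self.pools[pool][-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_d, pool, value_nmolN_L, scenario."""
        frames = [
            pd.DataFrame(
                {
                    "time_d": self.time,
                    "pool": name,
                    "value_nmolN_L": series,
                    "scenario": self.label,
                }
            )
            for name, series in self.pools.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scenario: {self.label}\n")
            fh.write(f"# params_hash: {self.params_hash}\n")
            self.to_frame().to_csv(fh, index=False)


def _params_hash(*objects) -> str:
    return hashlib.sha256(repr(objects).encode()).hexdigest()[:16]


def fit_quadratic_drawdown(
    times: Sequence[float],
    concentrations: Sequence[float],
    detection_limit: float = 0.0,
    censoring: CensoringPolicy = "half-limit",
) -> tuple[float, float, float]:
    """Least-squares quadratic conc(t) = a t^2 + b t + c for one nutrient.

    Values at or below ``detection_limit`` are left-censored and handled
    per ``censoring``: replaced by limit/2 (default, the standard
    substitution heuristic), excluded from the fit, or replaced by zero.
    Needs at least three distinct time points after censoring.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape:
        raise DomainError("times and concentrations must have equal length")
    if np.any(c < 0):
        raise DomainError("concentrations must be >= 0")
    if detection_limit > 0:
        censored = c <= detection_limit
        if censoring == "half-limit":
            c = np.where(censored, detection_limit / 2.0, c)
        elif censoring == "zero":
            c = np.where(censored, 0.0, c)
        elif censoring == "exclude":
            t, c = t[~censored], c[~censored]
        else:
            raise DomainError(f"unknown censoring policy {censoring!r}")
    if len(np.unique(t)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct time points for a quadratic fit, got {len(np.unique(t))}"
        )
    a, b, c0 = np.polyfit(t, c, deg=2)
    return (float(a), float(b), float(c0))


def fit_nutrient_forcing(
    times: Sequence[float],
    nh4: Sequence[float],
    no3: Sequence[float],
    nh4_detection_limit: float = 6.0,
    no3_detection_limit: float = 3.0,
    censoring: CensoringPolicy = "half-limit",
) -> NutrientForcing:
    """Fit quadratic drawdown curves to both nutrients and return the forcing."""
    return NutrientForcing.quadratic(
        fit_quadratic_drawdown(times, nh4, nh4_detection_limit, censoring),
        fit_quadratic_drawdown(times, no3, no3_detection_limit, censoring),
    )


def _rk4_step(f, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(t, y)
    k2 = f(t + dt / 2.0, y + dt / 2.0 * k1)
    k3 = f(t + dt / 2.0, y + dt / 2.0 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _time_grid(t_end: float, dt: float) -> np.ndarray:
    n_steps = int(round(t_end / dt))
    return np.linspace(0.0, n_steps * dt, n_steps + 1)


def run_incubation(
    groups: Sequence[PhytoGroupParams],
    forcing: NutrientForcing,
    initial_n: Mapping[str, float] | Sequence[float],
    t_end: float,
    dt: float = 0.01,
    fixation_enabled: bool = False,
) -> Trajectory:
    """Integrate the incubation model for every group under one forcing.

    Groups evolve independently (nutrients are an exogenous forcing, not
    a depleted pool), so the system is integrated group-wise with RK4.
    Pools are clipped at zero after each step.  With ``fixation_enabled``
    the diazotroph floor applies to groups carrying one.
    """
    if isinstance(initial_n, Mapping):
        y0 = np.array([float(initial_n[g.name]) for g in groups])
    else:
        y0 = np.asarray(initial_n, dtype=float)
        if len(y0) != len(groups):
            raise DomainError("initial_n length must match number of groups")
    if np.any(y0 < 0):
        raise DomainError("initial cellular N must be >= 0")

    time = _time_grid(t_end, dt)
    pools = np.empty((len(groups), len(time)))
    rates = np.empty_like(pools)
    pools[:, 0] = y0

    def mu(g: PhytoGroupParams, t: float) -> float:
        return effective_growth_rate(
            g, forcing.at(t), fixation_enabled and g.diazotroph_floor is not None
        )

    for gi, g in enumerate(groups):
        rates[gi, 0] = mu(g, 0.0)

        def deriv(t: float, y: np.ndarray) -> np.ndarray:
            return (mu(g, t) - g.mortality) * y

        for step in range(1, len(time)):
            y_next = _rk4_step(deriv, time[step - 1], pools[gi, step - 1 : step], dt)
            if not np.all(np.isfinite(y_next)):
                raise IntegrationError(
                    f"non-finite state for group {g.name!r} at step {step} "
                    f"(t = {time[step]:.4f} d)"
                )
            pools[gi, step] = max(0.0, float(y_next[0]))
            rates[gi, step] = mu(g, time[step])

    return Trajectory(
        time=time,
        pools={g.name: pools[i] for i, g in enumerate(groups)},
        growth_rates={g.name: rates[i] for i, g in enumerate(groups)},
        label="incubation",
        params_hash=_params_hash(tuple(groups), forcing, tuple(y0), t_end, dt),
    )


def run_ecosystem_scenario(
    config: ScenarioConfig,
    cro: PhytoGroupParams,
    oth: PhytoGroupParams,
    zoo: ZooParams,
) -> Trajectory:
    """Integrate the two-prey + zooplankton KTW model for one scenario."""
    time = _time_grid(config.t_end, config.dt)
    y = np.array([config.initial.n_cro, config.initial.n_oth, config.initial.n_zoo])
    pools = np.empty((3, len(time)))
    rates = np.empty((2, len(time)))
    pools[:, 0] = y

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        state = EcosystemState(*(max(0.0, v) for v in y))
        return np.array(
            ecosystem_derivatives(
                state, cro, oth, zoo, config.forcing.at(t), config.fixation_enabled
            )
        )

    def realized_rates(t: float) -> tuple[float, float]:
        nut = config.forcing.at(t)
        return (
            effective_growth_rate(
                cro, nut, config.fixation_enabled and cro.diazotroph_floor is not None
            ),
            effective_growth_rate(
                oth, nut, config.fixation_enabled and oth.diazotroph_floor is not None
            ),
        )

    rates[:, 0] = realized_rates(0.0)
    for step in range(1, len(time)):
        y = _rk4_step(deriv, time[step - 1], y, config.dt)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite ecosystem state at step {step} "
                f"(t = {time[step]:.4f} d, scenario {config.label!r})"
            )
        y = np.maximum(y, 0.0)
        pools[:, step] = y
        rates[:, step] = realized_rates(time[step])

    return Trajectory(
        time=time,
        pools={cro.name: pools[0], oth.name: pools[1], "Zoo": pools[2]},
        growth_rates={cro.name: rates[0], oth.name: rates[1]},
        label=config.label,
        params_hash=_params_hash(config, cro, oth, zoo),
    )


#: The three canonical competition scenarios: (label, NH4 = NO3 conc, fixation).
CANONICAL_SCENARIOS: tuple[tuple[str, float, bool], ...] = (
    ("A", 100.0, False),
    ("B", 1.0, False),
    ("C", 1.0, True),
)


def scenario_suite(
    cro: PhytoGroupParams,
    oth: PhytoGroupParams,
    zoo: ZooParams,
    initial: EcosystemState,
    t_end: float = 10.0,
    dt: float = 0.01,
) -> dict[str, Trajectory]:
    """Run the three canonical scenarios with shared parameters.

    A: NH4+ = NO3- = 100 nmol L^-1, no fixation (high-nutrient dominance);
    B: both 1 nmol L^-1, no fixation (Crocosphaera slightly outcompeted);
    C: both 1 nmol L^-1 with the diazotrophic floor enabled.
    """
    out: dict[str, Trajectory] = {}
    for label, conc, fixation in CANONICAL_SCENARIOS:
        cfg = ScenarioConfig(
            label=label,
            forcing=NutrientForcing.constant(conc, conc),
            initial=initial,
            fixation_enabled=fixation,
            t_end=t_end,
            dt=dt,
        )
        out[label] = run_ecosystem_scenario(cfg, cro, oth, zoo)
    return out
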