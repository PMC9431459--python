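"""Recovery of Monod-uptake parameters from incubation trajectories.

Formalizes manual tuning of the incubation model as a reproducible
bounded optimization: sum-of-squared-error loss between the integrated
model and observed cellular-N time series, minimized by multistart
L-BFGS-B with seeded Latin-hypercube starting points.  Half-saturation
constants are searched in log10 space since they can span orders of
magnitude.  V_max and K are only weakly identifiable from a single
drawdown curve; :func:`profile_loss` exposes that flatness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .errors import ConfigurationError, FitFailureError, IntegrationError
from .model_core import PhytoGroupParams
from .simulation_engine import NutrientForcing, run_incubation

__all__ = ["FitSpec", "FitResult", "trajectory_loss", "fit_parameters", "profile_loss"]

#: PhytoGroupParams fields that are searched in log10 space.
LOG_SPACE_PARAMS = frozenset({"k_nh4", "k_no3"})

_FITTABLE = ("vmax_nh4", "vmax_no3", "k_nh4", "k_no3", "mortality")


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``base`` supplies every fixed parameter value; ``free`` maps the
    parameter names to be optimized onto finite (lower, upper) bounds.
    ``loss_space="log"`` compares log-transformed pools, useful when
    series span orders of magnitude.
    """

    base: PhytoGroupParams
    free: Mapping[str, tuple[float, float]]
    loss_space: str = "linear"
    n_starts: int = 10
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.free:
            raise ConfigurationError("need at least one free parameter")
        for name, (lo, hi) in self.free.items():
            if name not in _FITTABLE:
                raise ConfigurationError(
                    f"unknown free parameter {name!r}; fittable: {_FITTABLE}"
                )
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"bounds for {name!r} must be finite, lo < hi")
        if self.loss_space not in ("linear", "log"):
            raise ConfigurationError("loss_space must be 'linear' or 'log'")


@dataclass
class FitResult:
    """Best-fit parameters and per-start diagnostics."""

    params: PhytoGroupParams
    values: dict[str, float]
    loss: float
    starts: list[dict] = field(default_factory=list)
    at_bound: dict[str, bool] = field(default_factory=dict)
    residuals: Optional[pd.DataFrame] = None
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "loss": self.loss,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "at_bound": self.at_bound,
            "starts": self.starts,
        }


def _model_at_times(
    params: PhytoGroupParams,
    times: np.ndarray,
    forcing: NutrientForcing,
    initial_n: float,
    dt: float,
) -> np.ndarray:
    t_end = float(times.max())
    traj = run_incubation([params], forcing, [initial_n], t_end=max(t_end, dt), dt=dt)
    return np.interp(times, traj.time, traj.pools[params.name])


def trajectory_loss(
    params: PhytoGroupParams,
    observed: pd.DataFrame,
    forcing: NutrientForcing,
    initial_n: Optional[float] = None,
    dt: float = 0.01,
    loss_space: str = "linear",
) -> float:
    """Sum of squared residuals between model and observed cellular N.

    ``observed`` needs columns ``time_d`` and ``n_nmol_l`` (replicates
    appear as repeated time points).  The model starts from
    ``initial_n`` (default: mean observation at the earliest time) and
    is evaluated at the observed times by interpolation on the RK4 grid.
    Order of rows is irrelevant.
    """
    times = observed["time_d"].to_numpy(dtype=float)
    values = observed["n_nmol_l"].to_numpy(dtype=float)
    if initial_n is None:
        initial_n = float(values[times == times.min()].mean())
    model = _model_at_times(params, times, forcing, initial_n, dt)
    if loss_space == "log":
        eps = 1e-12
        resid = np.log(model + eps) - np.log(values + eps)
    else:
        resid = model - values
    return float(np.sum(resid**2))


def _to_internal(name: str, value: float) -> float:
    return np.log10(value) if name in LOG_SPACE_PARAMS else value


def _from_internal(name: str, value: float) -> float:
    return 10.0**value if name in LOG_SPACE_PARAMS else value


def fit_parameters(
    spec: FitSpec,
    observed: pd.DataFrame,
    forcing: NutrientForcing,
    initial_n: Optional[float] = None,
    dt: float = 0.01,
) -> FitResult:
    """Bounded multistart local optimization of the free parameters.

    Starting points come from a Latin hypercube over the (internally
    log-transformed) bounds, seeded for reproducibility; each start runs
    L-BFGS-B.  The returned loss is the minimum over starts, so adding
    starts can never worsen the result.
    """
    names = list(spec.free)
    lo = np.array([_to_internal(n, spec.free[n][0]) for n in names])
    hi = np.array([_to_internal(n, spec.free[n][1]) for n in names])

    times = observed["time_d"].to_numpy(dtype=float)
    values = observed["n_nmol_l"].to_numpy(dtype=float)
    if initial_n is None:
        initial_n = float(values[times == times.min()].mean())

    def build(x: np.ndarray) -> PhytoGroupParams:
        updates = {n: _from_internal(n, v) for n, v in zip(names, x)}
        return replace(spec.base, **updates)

    def objective(x: np.ndarray) -> float:
        try:
            return trajectory_loss(
                build(x), observed, forcing, initial_n, dt, spec.loss_space
            )
        except IntegrationError:
            return 1e30

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    x0s = qmc.scale(sampler.random(spec.n_starts), lo, hi)

    starts: list[dict] = []
    best: Optional[optimize.OptimizeResult] = None
    for x0 in x0s:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": spec.tol, "gtol": 1e-10},
        )
        starts.append(
            {
                "x0": {n: _from_internal(n, v) for n, v in zip(names, x0)},
                "x": {n: _from_internal(n, v) for n, v in zip(names, res.x)},
                "loss": float(res.fun),
                "success": bool(res.success),
            }
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"all {spec.n_starts} starts failed: {starts}")

    fitted = build(best.x)
    fitted_values = {n: _from_internal(n, v) for n, v in zip(names, best.x)}
    span = hi - lo
    at_bound = {
        n: bool(min(best.x[i] - lo[i], hi[i] - best.x[i]) < 1e-3 * span[i])
        for i, n in enumerate(names)
    }
    model = _model_at_times(fitted, times, forcing, initial_n, dt)
    residuals = pd.DataFrame(
        {"time_d": times, "observed": values, "model": model, "residual": model - values}
    )
    return FitResult(
        params=fitted,
        values=fitted_values,
        loss=float(best.fun),
        starts=starts,
        at_bound=at_bound,
        residuals=residuals,
        seed=spec.seed,
        bounds=dict(spec.free),
    )


def profile_loss(
    spec: FitSpec,
    observed: pd.DataFrame,
    forcing: NutrientForcing,
    param: str,
    grid: Sequence[float],
    initial_n: Optional[float] = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Loss profile along one free parameter.

    At each grid value the parameter is pinned and, if other free
    parameters remain, they are re-optimized (single start from the
    centre of their bounds).  Flat profiles expose the weak joint
    identifiability of V_max and K from a single drawdown curve.
    """
    if param not in spec.free:
        raise ConfigurationError(f"{param!r} is not a free parameter of this spec")
    others = {n: b for n, b in spec.free.items() if n != param}
    records = []
    for value in grid:
        pinned = replace(spec.base, **{param: value})
        if others:
            sub = FitSpec(
                base=pinned,
                free=others,
                loss_space=spec.loss_space,
                n_starts=1,
                seed=spec.seed,
            )
            result = fit_parameters(sub, observed, forcing, initial_n, dt)
            records.append({param: value, "loss": result.loss})
        else:
            loss = trajectory_loss(
                pinned, observed, forcing, initial_n, dt, spec.loss_space
            )
            records.append({param: value, "loss": loss})
    return pd.DataFrame(records)
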