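"""Rate equations for phytoplankton growth and kill-the-winner grazing.

The model describes competition for combined nitrogen (NH4+ and NO3-)
between the unicellular diazotroph *Crocosphaera* and the aggregate of
other phytoplankton.  Growth is the sum of one Monod term per nutrient;
when nitrogen fixation is enabled, the realized growth rate of a
diazotroph never falls below its diazotrophic floor rate.  Grazing by
zooplankton follows the kill-the-winner (KTW) functional response, in
which pressure on each prey is weighted by its squared relative
abundance (active prey switching).

Units are fixed package-wide: nmol N L^-1 for nutrient concentrations
and biomass pools, d^-1 for rates, days for time.  All functions here
are pure: no state, no side effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError, DomainError

__all__ = [
    "PhytoGroupParams",
    "ZooParams",
    "NutrientPair",
    "EcosystemState",
    "monod_growth_rate",
    "effective_growth_rate",
    "ktw_grazing_rates",
    "incubation_derivative",
    "ecosystem_derivatives",
]


@dataclass(frozen=True)
class PhytoGroupParams:
    """Kinetic and loss parameters of one phytoplankton group.

    Parameters
    ----------
    name
        Group label (e.g. ``"Cro"`` for *Crocosphaera*, ``"Oth"`` for
        the other-phytoplankton aggregate).
    vmax_nh4, vmax_no3
        Maximum specific uptake rates of NH4+ and NO3-,
        mol N (mol N)^-1 d^-1 (dimensionally d^-1).
    k_nh4, k_no3
        Half-saturation constants, nmol L^-1.
    mortality
        Linear mortality rate m, d^-1 (used by the incubation model only).
    diazotroph_floor
        Optional floor growth rate sustained by N2 fixation, d^-1.
        ``None`` for groups that cannot fix nitrogen.
    """

    name: str
    vmax_nh4: float
    vmax_no3: float
    k_nh4: float
    k_no3: float
    mortality: float = 0.0
    diazotroph_floor: Optional[float] = None

    def __post_init__(self) -> None:
        for field in ("vmax_nh4", "vmax_no3", "k_nh4", "k_no3", "mortality"):
            value = getattr(self, field)
            if not value >= 0.0:
                raise DomainError(f"{self.name}: {field} must be >= 0, got {value!r}")
        if self.k_nh4 <= 0.0 or self.k_no3 <= 0.0:
            raise DomainError(f"{self.name}: half-saturation constants must be > 0")
        if self.diazotroph_floor is not None:
            if not self.diazotroph_floor >= 0.0:
                raise DomainError(f"{self.name}: diazotroph_floor must be >= 0")
            if self.diazotroph_floor > self.vmax_nh4 + self.vmax_no3:
                raise DomainError(
                    f"{self.name}: diazotroph_floor exceeds vmax_nh4 + vmax_no3"
                )


@dataclass(frozen=True)
class ZooParams:
    """Zooplankton grazing parameters.

    ``g_max`` (d^-1) is the maximum grazing rate, ``k_g`` (nmol L^-1) the
    grazing half-saturation, and ``m_zoo`` ((nmol L^-1)^-1 d^-1) the
    quadratic mortality coefficient of zooplankton.
    """

    g_max: float
    k_g: float
    m_zoo: float

    def __post_init__(self) -> None:
        # k_g == 0 is an allowed degenerate case (saturation term -> 1).
        if min(self.g_max, self.k_g, self.m_zoo) < 0.0:
            raise DomainError("zooplankton parameters must be >= 0")


@dataclass(frozen=True)
class NutrientPair:
    """Ambient NH4+ and NO3- concentrations, nmol L^-1.

    Negative concentrations are rejected here; clipping of (for example)
    a fitted quadratic forcing that dips below zero is the forcing's job.
    """

    nh4: float
    no3: float

    def __post_init__(self) -> None:
        if self.nh4 < 0.0 or self.no3 < 0.0:
            raise DomainError(
                f"nutrient concentrations must be >= 0, got ({self.nh4}, {self.no3})"
            )


@dataclass(frozen=True)
class EcosystemState:
    """Cellular-nitrogen pools of the ecosystem model, nmol N L^-1."""

    n_cro: float
    n_oth: float
    n_zoo: float

    def __post_init__(self) -> None:
        if min(self.n_cro, self.n_oth, self.n_zoo) < 0.0:
            raise DomainError("ecosystem pools must be >= 0")


def monod_growth_rate(params: PhytoGroupParams, nutrients: NutrientPair) -> float:
    """Specific growth rate (d^-1) as the sum of one Monod term per nutrient.

    mu = V_nh4 [NH4]/([NH4]+K_nh4) + V_no3 [NO3]/([NO3]+K_no3)

    Bounded in [0, vmax_nh4 + vmax_no3], continuous, and monotone
    nondecreasing in each nutrient concentration.
    """
    return params.vmax_nh4 * nutrients.nh4 / (nutrients.nh4 + params.k_nh4) + (
        params.vmax_no3 * nutrients.no3 / (nutrients.no3 + params.k_no3)
    )


def effective_growth_rate(
    params: PhytoGroupParams, nutrients: NutrientPair, fixation_enabled: bool
) -> float:
    """Realized growth rate, applying the diazotrophic floor when enabled.

    With fixation enabled, a diazotroph grows at least at its floor rate
    (N2 fixation sustains growth when combined N is depleted); the floor
    is inactive whenever Monod uptake alone exceeds it.
    """
    mu = monod_growth_rate(params, nutrients)
    if not fixation_enabled:
        return mu
    if params.diazotroph_floor is None:
        raise ConfigurationError(
            f"fixation enabled but group {params.name!r} has no diazotroph_floor"
        )
    return max(mu, params.diazotroph_floor)


def ktw_grazing_rates(state: EcosystemState, zoo: ZooParams) -> tuple[float, float]:
    """Kill-the-winner grazing rates (G_cro, G_oth), d^-1.

    G_i = G_max * (N_i^2 / (N_cro^2 + N_oth^2))
                * (N_tot^2 / (N_tot^2 + K_G^2)),   N_tot = N_cro + N_oth

    The squared relative-abundance weight makes per-capita pressure rise
    with a prey's share of the community (prey switching).  With no prey
    at all the rates are (0, 0): no prey, no grazing.
    """
    sq_sum = state.n_cro**2 + state.n_oth**2
    if sq_sum == 0.0:
        return (0.0, 0.0)
    n_tot = state.n_cro + state.n_oth
    saturation = n_tot**2 / (n_tot**2 + zoo.k_g**2)
    scale = zoo.g_max * saturation / sq_sum
    return (scale * state.n_cro**2, scale * state.n_oth**2)


def incubation_derivative(
    state_n: float, params: PhytoGroupParams, nutrients: NutrientPair
) -> float:
    """dN/dt (nmol L^-1 d^-1) for one group in the incubation model.

    dN/dt = (mu - m) N with mu from :func:`monod_growth_rate`.  Groups do
    not interact in the incubation model; nutrients are exogenous.
    """
    if state_n < 0.0:
        raise DomainError(f"cellular N must be >= 0, got {state_n}")
    return (monod_growth_rate(params, nutrients) - params.mortality) * state_n


def ecosystem_derivatives(
    state: EcosystemState,
    cro: PhytoGroupParams,
    oth: PhytoGroupParams,
    zoo: ZooParams,
    nutrients: NutrientPair,
    fixation_enabled: bool,
) -> tuple[float, float, float]:
    """Time derivatives (d n_cro/dt, d n_oth/dt, d n_zoo/dt).

    dN_i/dt   = mu_i N_i - G_i N_zoo
    dN_zoo/dt = (G_cro + G_oth) N_zoo - m_zoo N_zoo^2

    Nitrogen lost by phytoplankton to grazing appears one-for-one as
    zooplankton gain, so the total-N budget closes exactly:
    d(N_cro+N_oth+N_zoo)/dt = mu_cro N_cro + mu_oth N_oth - m_zoo N_zoo^2.

    The fixation flag applies the diazotroph floor to any group carrying
    one; groups without a floor always grow at their Monod rate.
    """
    g_cro, g_oth = ktw_grazing_rates(state, zoo)
    mu_cro = effective_growth_rate(
        cro, nutrients, fixation_enabled and cro.diazotroph_floor is not None
    )
    mu_oth = effective_growth_rate(
        oth, nutrients, fixation_enabled and oth.diazotroph_floor is not None
    )
    d_cro = mu_cro * state.n_cro - g_cro * state.n_zoo
    d_oth = mu_oth * state.n_oth - g_oth * state.n_zoo
    d_zoo = (g_cro + g_oth) * state.n_zoo - zoo.m_zoo * state.n_zoo**2
    return (d_cro, d_oth, d_zoo)
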