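"""Core model of hydrogenotrophic methanogenesis in a closed gas/liquid reactor.

The reactor is a sealed bottle partially filled with culture medium under a
pressurized H2/CO2 headspace.  Archaea in the liquid phase run the Sabatier
metabolism (CO2 + 4 H2 -> CH4 + 2 H2O), so every reacted mole of CH4 removes
a net five moles of gas and the headspace pressure falls.  The model tracks
moles of H2, CO2 and CH4 in each phase plus the total cell number:

* growth follows a double Monod law in the two dissolved substrates, gated
  by a piecewise-linear lag ramp and opposed by a first-order decay term;
* dissolution follows two-film theory: the flux of each component across the
  interface is proportional to the departure of its liquid mole fraction
  from the Henry-law equilibrium value set by its current partial pressure;
* the headspace obeys the ideal gas law.

All quantities are strict SI (m3, mol, Pa, K, s, cells).  Unit conversion to
the presentation units (ml, mBar, degC) lives at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "COMPONENTS",
    "R_GAS",
    "WATER_MOLAR_DENSITY",
    "ReactorGeometry",
    "LagPhase",
    "SpeciesKinetics",
    "HenryEntry",
    "Stoichiometry",
    "SABATIER",
    "MassTransfer",
    "ReactorState",
    "lag_factor",
    "specific_growth_rate",
    "biomass_rate",
    "henry_at_temperature",
    "equilibrium_liquid_concentration",
    "partial_pressure",
    "total_pressure",
    "transfer_flux",
    "reaction_rates",
    "rhs",
]

#: Reactive gas components, in state-vector order.
COMPONENTS = ("H2", "CO2", "CH4")

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Molar density of liquid water, mol/m3; normalizes the transfer driving
#: force so that concentrations enter as mole fractions while the transfer
#: coefficient keeps units of mol/s.
WATER_MOLAR_DENSITY = 5.55e4


class InvalidTemperatureError(ValueError):
    """Raised for nonpositive absolute temperatures."""


@dataclass(frozen=True)
class ReactorGeometry:
    """Sealed reactor geometry; the gas volume is the head space above the liquid.

    Parameters
    ----------
    total_volume:
        Internal reactor volume, m3.
    liquid_volume:
        Culture medium volume, m3 (must leave a gas head space).
    gas_liquid_contact_area:
        Flat interface area between head space and liquid, m2.
    """

    total_volume: float
    liquid_volume: float
    gas_liquid_contact_area: float

    def __post_init__(self) -> None:
        if not 0.0 < self.liquid_volume < self.total_volume:
            raise ValueError(
                f"liquid_volume must lie in (0, total_volume); got "
                f"{self.liquid_volume} of {self.total_volume}"
            )
        if self.gas_liquid_contact_area <= 0.0:
            raise ValueError("gas_liquid_contact_area must be positive")

    @property
    def gas_volume(self) -> float:
        """Head-space volume, m3."""
        return self.total_volume - self.liquid_volume


@dataclass(frozen=True)
class LagPhase:
    """Lag-phase timing: no growth before ``t_L``, full growth after ``t_E``."""

    t_L: float
    t_E: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_L <= self.t_E:
            raise ValueError(f"require 0 <= t_L <= t_E; got ({self.t_L}, {self.t_E})")


#: No-lag sentinel used e.g. for refill cycles where adaptation is immediate.
NO_LAG = LagPhase(0.0, 0.0)


@dataclass(frozen=True)
class SpeciesKinetics:
    """Growth parameters of one archaeal strain.

    ``mu_max`` (1/s) is the maximum specific growth rate; ``K_H2`` and
    ``K_CO2`` (mol/m3) the dissolved-substrate half-saturation constants;
    ``decay_b`` (1/s) the maintenance/decay rate; ``yield_Y_H2`` (cells/mol)
    the cell yield per mole of H2 consumed, applied with the stoichiometric
    vector to all components.
    """

    mu_max: float
    K_H2: float
    K_CO2: float
    decay_b: float
    yield_Y_H2: float
    lag: LagPhase = NO_LAG

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_H2", "K_CO2", "decay_b"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.yield_Y_H2 <= 0.0:
            raise ValueError("yield_Y_H2 must be > 0")

    def with_lag(self, lag: LagPhase) -> "SpeciesKinetics":
        return replace(self, lag=lag)


@dataclass(frozen=True)
class HenryEntry:
    """Henry solubility of one component: ``H_ref`` mol/(m3 Pa) at ``T_ref`` K.

    ``vant_hoff_C`` is the van't Hoff constant -Delta_sol(H)/R in kelvin used
    to move the solubility away from the reference temperature.
    """

    component: str
    H_ref: float
    T_ref: float
    vant_hoff_C: float = 0.0

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.H_ref <= 0.0 or self.T_ref <= 0.0:
            raise ValueError("H_ref and T_ref must be positive")

    def at(self, T: float) -> float:
        return henry_at_temperature(self, T)


@dataclass(frozen=True)
class Stoichiometry:
    """Per-component stoichiometric vector relative to H2.

    For the Sabatier reaction CO2 + 4 H2 -> CH4 + 2 H2O the vector over
    (H2, CO2, CH4) is (-1, -1/4, +1/4): per mole of H2 consumed, a quarter
    mole of CO2 is consumed and a quarter mole of CH4 produced.
    """

    zeta: tuple = (-1.0, -0.25, 0.25)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.zeta, dtype=float)


SABATIER = Stoichiometry()
_ZETA = SABATIER.as_array()


@dataclass(frozen=True)
class MassTransfer:
    """Gas-liquid transfer parameters.

    ``k_gw`` (mol/s) multiplies the dimensionless driving force
    ``(C_eq - C_liq)/C_ref``; with ``C_ref`` the molar density of water the
    driving force is the liquid mole-fraction deficit relative to Henry
    equilibrium, and ``k_gw`` retains the magnitudes quoted for bottle
    reactors of this size.
    """

    k_gw: float
    C_ref: float = WATER_MOLAR_DENSITY

    def __post_init__(self) -> None:
        if self.k_gw < 0.0:
            raise ValueError("k_gw must be >= 0")
        if self.C_ref <= 0.0:
            raise ValueError("C_ref must be > 0")


@dataclass(frozen=True)
class ReactorState:
    """Moles per phase, total cells and temperature at one time point.

    ``N_gas`` and ``N_liq`` are arrays over ``COMPONENTS``; ``N_inert`` is an
    optional non-reactive, non-transferring head-space gas (residual N2 from
    flushing).
    """

    t: float
    N_gas: np.ndarray
    N_liq: np.ndarray
    X: float
    T: float
    N_inert: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "N_gas", np.asarray(self.N_gas, dtype=float))
        object.__setattr__(self, "N_liq", np.asarray(self.N_liq, dtype=float))
        if self.N_gas.shape != (3,) or self.N_liq.shape != (3,):
            raise ValueError("N_gas and N_liq must have one entry per component")
        if self.T <= 0.0:
            raise InvalidTemperatureError(f"T must be positive, got {self.T}")

    def total_gas_moles(self) -> float:
        return float(self.N_gas.sum()) + self.N_inert

    def pressure(self, geometry: ReactorGeometry) -> float:
        """Head-space pressure by the ideal gas law, Pa."""
        return total_pressure(self.total_gas_moles(), self.T, geometry.gas_volume)

    def cell_density(self, geometry: ReactorGeometry) -> float:
        """Cells per ml of liquid."""
        return self.X / (geometry.liquid_volume * 1e6)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.N_gas, self.N_liq, [self.X]])

    @classmethod
    def from_vector(
        cls, t: float, y: np.ndarray, T: float, N_inert: float = 0.0
    ) -> "ReactorState":
        return cls(t=t, N_gas=y[0:3], N_liq=y[3:6], X=float(y[6]), T=T, N_inert=N_inert)


def lag_factor(t: float, lag: LagPhase) -> float:
    """Piecewise-linear lag ramp: 0 before ``t_L``, 1 after ``t_E``.

    A degenerate lag (``t_L == t_E``) acts as a step at ``t_L``.
    """
    if t < lag.t_L:
        return 0.0
    if t > lag.t_E:
        return 1.0
    if lag.t_E == lag.t_L:
        return 1.0
    return (t - lag.t_L) / (lag.t_E - lag.t_L)


def specific_growth_rate(C_H2: float, C_CO2: float, kin: SpeciesKinetics) -> float:
    """Double Monod specific growth rate, 1/s.

    mu = mu_max * C_H2/(K_H2 + C_H2) * C_CO2/(K_CO2 + C_CO2); concentrations
    are clamped at zero so that transient small negative values from the
    integrator cannot produce spurious growth.
    """
    C_H2 = max(C_H2, 0.0)
    C_CO2 = max(C_CO2, 0.0)
    return (
        kin.mu_max
        * (C_H2 / (kin.K_H2 + C_H2))
        * (C_CO2 / (kin.K_CO2 + C_CO2))
    )


def biomass_rate(
    X: float, t: float, C_H2: float, C_CO2: float, kin: SpeciesKinetics
) -> float:
    """Net cell production rate, cells/s: lambda(t) * X * (mu - b).

    The lag factor gates decay as well as growth, so the population is
    strictly frozen during the lag phase.
    """
    lam = lag_factor(t, kin.lag)
    if lam == 0.0:
        return 0.0
    mu = specific_growth_rate(C_H2, C_CO2, kin)
    return lam * X * (mu - kin.decay_b)


def henry_at_temperature(entry: HenryEntry, T: float) -> float:
    """Van't Hoff corrected Henry solubility at temperature ``T``, mol/(m3 Pa)."""
    if T <= 0.0:
        raise InvalidTemperatureError(f"T must be positive, got {T}")
    return entry.H_ref * np.exp(entry.vant_hoff_C * (1.0 / T - 1.0 / entry.T_ref))


def equilibrium_liquid_concentration(H: float, p_partial: float) -> float:
    """Henry-law equilibrium dissolved concentration C_eq = H * p, mol/m3."""
    if p_partial < 0.0:
        raise ValueError(f"partial pressure must be >= 0, got {p_partial}")
    return H * p_partial


def partial_pressure(N_comp: float, N_total_gas: float, P_total: float) -> float:
    """Mole-fraction partial pressure, Pa."""
    if N_total_gas <= 0.0:
        raise ValueError("total gas moles must be positive")
    return (N_comp / N_total_gas) * P_total


def total_pressure(N_total_gas: float, T: float, V_gas: float) -> float:
    """Ideal-gas head-space pressure P = n R T / V, Pa."""
    if V_gas <= 0.0:
        raise ValueError("gas volume must be positive")
    if T <= 0.0:
        raise InvalidTemperatureError(f"T must be positive, got {T}")
    return N_total_gas * R_GAS * T / V_gas


def transfer_flux(C_liq: float, C_eq: float, mt: MassTransfer) -> float:
    """Two-film interphase flux, mol/s; positive transfers gas into liquid.

    J = k_gw * (C_eq - C_liq)/C_ref vanishes at Henry equilibrium and always
    pushes the liquid concentration toward it.  The gas phase receives -J,
    so transfer conserves moles exactly.
    """
    return mt.k_gw * (C_eq - C_liq) / mt.C_ref


def reaction_rates(
    mu: float,
    X: float,
    lag_lambda: float,
    kin: SpeciesKinetics,
    st: Stoichiometry = SABATIER,
) -> np.ndarray:
    """Per-component metabolic mole rates in the liquid phase, mol/s.

    rate_n = zeta_n * lambda * mu * X / Y_H2 — a single H2-referenced yield
    distributes the cell production over all components via the 4:1:1
    Sabatier stoichiometry.
    """
    if kin.yield_Y_H2 == 0.0:
        raise ValueError("yield_Y_H2 must be nonzero")
    return st.as_array() * (lag_lambda * mu * X / kin.yield_Y_H2)


def rhs(
    state: ReactorState,
    geometry: ReactorGeometry,
    kin: SpeciesKinetics,
    mt: MassTransfer,
    henry: dict,
    lag_origin: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full state vector (N_gas, N_liq, X).

    For each reactive component ``n``::

        dN_gas[n]/dt = -J_n
        dN_liq[n]/dt = reaction_n + J_n
        dX/dt        = lambda * X * (mu - b)

    where ``J_n`` is the two-film flux toward Henry equilibrium with the
    current partial pressure.  Inert head-space gas neither reacts nor
    transfers.  ``lag_origin`` shifts the lag clock (restarted on refills).
    """
    H = np.array([henry_at_temperature(henry[c], state.T) for c in COMPONENTS])
    return _rhs_vector(
        state.t,
        state.as_vector(),
        geometry.gas_volume,
        geometry.liquid_volume,
        state.T,
        kin,
        mt,
        H,
        state.N_inert,
        lag_origin,
    )


def _rhs_vector(
    t: float,
    y: np.ndarray,
    V_gas: float,
    V_liq: float,
    T: float,
    kin: SpeciesKinetics,
    mt: MassTransfer,
    H: np.ndarray,
    N_inert: float,
    lag_origin: float,
) -> np.ndarray:
    # Hot path shared with the ODE integrator: plain arrays, no dataclasses.
    N_gas = np.maximum(y[0:3], 0.0)
    C_liq = np.maximum(y[3:6], 0.0) / V_liq
    X = max(y[6], 0.0)

    p = N_gas * (R_GAS * T / V_gas)  # partial pressures, inert adds none
    C_eq = H * p
    J = mt.k_gw * (C_eq - C_liq) / mt.C_ref

    lam = lag_factor(t - lag_origin, kin.lag)
    mu = specific_growth_rate(C_liq[0], C_liq[1], kin)
    growth = lam * mu * X

    dy = np.empty(7)
    dy[0:3] = -J
    dy[3:6] = _ZETA * (growth / kin.yield_Y_H2) + J
    dy[6] = growth - lam * kin.decay_b * X
    return dy
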