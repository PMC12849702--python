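"""Coupled land–atmosphere–ocean carbon-cycle box model with δ¹³C tracking.

Five reservoirs — atmosphere, surface ocean, deep ocean, plant biomass and
soil organic matter — exchange carbon through a fixed flux set:

* injection of ¹³C-depleted "endogenic" carbon into the atmosphere (the CIE
  forcing);
* net primary production (atmosphere → plant, with photosynthetic
  fractionation ε_land) scaled by an imposed gross-primary-productivity
  (GPP) multiplier that collapses at the event onset and recovers linearly;
* litter fall (plant → soil) and soil respiration (soil → atmosphere,
  optionally Q10 temperature dependent);
* gross air–sea exchange driven by the atmospheric and Revelle-controlled
  surface-ocean pCO₂;
* surface–deep overturning on a mixing timescale τ_mix;
* kerogen oxidation (rock organic carbon → atmosphere), amplified in
  proportion to the terrestrial biosphere *deficit* — the diminished role of
  vegetation in stabilising landscapes — and by warming;
* a silicate-weathering sink balancing baseline kerogen oxidation.

Temperature follows pCO₂ logarithmically (S_clim per doubling). ¹³C is
carried as a normalised isotope mass m·(1 + δ/1000), so both carbon and ¹³C
are conserved to round-off: d(total)/dt = injection + kerogen − sink exactly.

Integration is explicit Euler at dt = 1 y; convergence under dt halving is
part of the test suite. All stocks in PgC, fluxes in PgC/yr, δ¹³C in ‰ VPDB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RESERVOIRS",
    "Reservoir",
    "ModelParams",
    "ScenarioConfig",
    "Trajectory",
    "Diagnostics",
    "pgc_from_pmol",
    "initialize_steady_state",
    "gpp_multiplier",
    "q10_factor",
    "kerogen_flux",
    "step",
    "run_scenario",
    "time_pco2_stops_rising",
    "compare_to_control",
    "delta_series",
]

RESERVOIRS = ("atmosphere", "surface_ocean", "deep_ocean", "plant", "soil")

#: Grams of carbon per mole; 1 Pmol C = 12.011 PgC.
GRAMS_PER_MOL_C = 12.011


def pgc_from_pmol(pmol: float) -> float:
    """Convert petamoles of carbon to PgC (12.011 g/mol)."""
    return pmol * GRAMS_PER_MOL_C


@dataclass
class Reservoir:
    """A carbon stock: mass in PgC and isotopic composition in ‰ VPDB."""

    name: str
    mass: float
    d13c: float

    def __post_init__(self) -> None:
        if self.name not in RESERVOIRS:
            raise ValueError(f"unknown reservoir {self.name!r}")
        if self.mass <= 0:
            raise ValueError(f"reservoir {self.name}: mass must be > 0")
        if not (-60.0 <= self.d13c <= 10.0):
            raise ValueError(f"reservoir {self.name}: d13c {self.d13c} outside [-60, 10]")


@dataclass(frozen=True)
class ModelParams:
    """Model constants. Stocks in PgC, times in years unless suffixed _ky.

    Plant and soil initial stocks are derived (``NPP_0 * tau_plant`` and
    ``NPP_0 * tau_soil``: 1,000 + 1,800 = 2,800 PgC under defaults, so a 50 %
    biosphere loss is ~1,400 PgC). The silicate-weathering baseline equals
    the kerogen-oxidation baseline — the only net exogenic input — so the
    pre-event state is an exact steady state.
    """

    M_A0: float = 2120.0          # atmosphere, PgC (1,000 ppm at 2.12 PgC/ppm)
    M_S0: float = 900.0           # surface ocean
    M_D0: float = 38000.0         # deep ocean
    NPP_0: float = 30.0           # PgC/yr
    tau_plant: float = 1000.0 / 30.0   # y (plant stock 1,000 PgC)
    tau_soil: float = 60.0             # y (soil stock 1,800 PgC)
    pCO2_0: float = 1000.0        # ppm
    ppm_per_pgc: float = 1.0 / 2.12
    q10: float = 2.0
    climate_sensitivity: float = 5.0   # degC per CO2 doubling
    revelle: float = 10.0
    k_gas: float = 0.06           # PgC/yr/ppm: 60 PgC/yr gross exchange at 1,000 ppm
    tau_mix: float = 1000.0       # y, deep-ocean overturning
    F_ker0: float = 0.06          # PgC/yr baseline kerogen oxidation
    d13c_ker: float = -25.0
    kerogen_gain: float = 1.2     # gamma: flux amplification per unit biosphere deficit
    kerogen_temp_sensitive: bool = False
    n_weather: float = 0.3        # silicate-sink pCO2 exponent
    eps_land: float = -19.0       # photosynthetic fractionation, permil
    eps_airsea: float = 9.0       # equilibrium air->sea fractionation, permil
    d13c_atm0: float = -6.5
    dt: float = 0.25              # y; see methods note on air-sea stiffness
    t_end_ky: float = 250.0
    spinup_ky: float = 20.0
    save_every: float = 10.0      # y between stored trajectory points

    def __post_init__(self) -> None:
        for name in ("M_A0", "M_S0", "M_D0", "NPP_0", "tau_plant", "tau_soil",
                     "pCO2_0", "tau_mix", "F_ker0", "k_gas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt <= 0 or self.dt > 1.0:
            raise ValueError("dt must be in (0, 1] years")

    @property
    def M_P0(self) -> float:
        return self.NPP_0 * self.tau_plant

    @property
    def M_L0(self) -> float:
        return self.NPP_0 * self.tau_soil

    @property
    def F_w0(self) -> float:
        """Baseline silicate-weathering sink; balances F_ker0."""
        return self.F_ker0

    @property
    def overturn0(self) -> float:
        """Baseline surface<->deep exchange flux, PgC/yr."""
        return self.M_D0 / self.tau_mix

    def initial_d13c(self) -> dict[str, float]:
        """Steady-state δ¹³C per reservoir given the atmospheric anchor:
        land = atm + ε_land; ocean = atm + ε_airsea (no biological pump in
        the flux set, so deep equals surface)."""
        return {
            "atmosphere": self.d13c_atm0,
            "surface_ocean": self.d13c_atm0 + self.eps_airsea,
            "deep_ocean": self.d13c_atm0 + self.eps_airsea,
            "plant": self.d13c_atm0 + self.eps_land,
            "soil": self.d13c_atm0 + self.eps_land,
        }


@dataclass(frozen=True)
class ScenarioConfig:
    """Forcing and feedback switches for one model run.

    ``gpp_reduction`` is the instantaneous fractional GPP collapse imposed at
    t = 0 (start of injection / base of the CIE); ``recovery_rate_per_ky`` is
    the linear GPP recovery in units of pre-event GPP per ky (0.003 = 0.3 %
    per millennium). The respiration Q10 feedback is available but off in the
    headline scenarios; the kerogen flux keeps its own temperature factor.
    """

    label: str = "scenario"
    injection_rate: float = 0.98          # PgC/yr
    injection_d13c: float = -28.0         # permil; calibrated downstream
    injection_duration_ky: float = 5.0
    gpp_reduction: float = 0.0
    recovery_rate_per_ky: float = 0.003
    feedback_biosphere: bool = True
    feedback_respiration: bool = False
    feedback_kerogen: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gpp_reduction < 1.0):
            raise ValueError("gpp_reduction must be in [0, 1)")
        if self.recovery_rate_per_ky < 0:
            raise ValueError("recovery_rate must be >= 0")
        if self.injection_rate < 0 or self.injection_duration_ky < 0:
            raise ValueError("injection rate and duration must be >= 0")

    @classmethod
    def control(cls, **kwargs) -> "ScenarioConfig":
        """Injection only: no GPP collapse, all feedbacks off."""
        kwargs.setdefault("label", "control")
        return cls(
            gpp_reduction=0.0,
            feedback_biosphere=False,
            feedback_respiration=False,
            feedback_kerogen=False,
            **kwargs,
        )

    @classmethod
    def feedback(cls, gpp_reduction: float, **kwargs) -> "ScenarioConfig":
        kwargs.setdefault("label", f"gpp-{int(round(100 * gpp_reduction))}pct")
        return cls(gpp_reduction=gpp_reduction, **kwargs)


# ---------------------------------------------------------------------------
# Pieces
# ---------------------------------------------------------------------------

def gpp_multiplier(t_ky: float, scenario: ScenarioConfig) -> float:
    """Imposed GPP as a fraction of pre-event GPP: 1 before the event, an
    instantaneous drop to (1 − reduction) at t = 0, then linear recovery at
    ``recovery_rate_per_ky``, capped at 1."""
    if t_ky < 0 or not scenario.feedback_biosphere:
        return 1.0
    return min(
        1.0,
        (1.0 - scenario.gpp_reduction) + scenario.recovery_rate_per_ky * t_ky,
    )


def q10_factor(dT: float, params: ModelParams) -> float:
    """Multiplicative rate increase for *dT* degrees of warming."""
    return params.q10 ** (dT / 10.0)


def kerogen_flux(
    biosphere_deficit: float,
    dT: float,
    params: ModelParams,
    enabled: bool = True,
) -> float:
    """Kerogen-oxidation flux, PgC/yr.

    ``F_ker0 * (1 + gamma * deficit) * q(dT)`` where the deficit is
    1 − (M_P + M_L)/(M_P0 + M_L0): destabilised, vegetation-poor landscapes
    erode and oxidise rock organic carbon faster. With *enabled* False the
    baseline flux is returned.
    """
    if not (0.0 <= biosphere_deficit <= 1.0):
        raise ValueError("biosphere deficit must be in [0, 1]")
    if not enabled:
        return params.F_ker0
    q = q10_factor(dT, params) if params.kerogen_temp_sensitive else 1.0
    return params.F_ker0 * (1.0 + params.kerogen_gain * biosphere_deficit) * q


def initialize_steady_state(
    params: ModelParams,
) -> tuple[dict[str, Reservoir], dict[str, float]]:
    """Pre-event equilibrium: reservoirs plus baseline fluxes with net carbon
    and ¹³C tendencies < 1e-9 PgC/yr in every box.

    Plant = NPP_0·τ_P and soil = (plant→soil flux)·τ_L (donor-controlled
    steady states); the silicate sink is set to balance baseline kerogen
    oxidation, the only net exogenic input.

    Raises
    ------
    ValueError
        If the parameter combination admits no physical steady state, with
        the offending balance in the message.
    """
    d13c = params.initial_d13c()
    masses = {
        "atmosphere": params.M_A0,
        "surface_ocean": params.M_S0,
        "deep_ocean": params.M_D0,
        "plant": params.M_P0,
        "soil": params.M_L0,
    }
    reservoirs = {
        name: Reservoir(name=name, mass=m, d13c=d13c[name]) for name, m in masses.items()
    }
    fluxes = {
        "npp": params.NPP_0,
        "litter": params.M_P0 / params.tau_plant,
        "soil_respiration": params.M_L0 / params.tau_soil,
        "airsea_in": params.k_gas * params.M_A0 * params.ppm_per_pgc,
        "airsea_out": params.k_gas * params.pCO2_0,
        "overturn_down": params.overturn0,
        "overturn_up": params.overturn0,
        "kerogen": params.F_ker0,
        "silicate_sink": params.F_w0,
    }
    # Feasibility: surface pCO2 must equal atmospheric pCO2 at baseline,
    # otherwise there is a standing air-sea imbalance.
    pco2_atm = params.M_A0 * params.ppm_per_pgc
    if abs(pco2_atm - params.pCO2_0) > 1e-9 * params.pCO2_0:
        raise ValueError(
            f"infeasible steady state: atmospheric pCO2 {pco2_atm:.6g} ppm != "
            f"pCO2_0 {params.pCO2_0:.6g} ppm (air-sea exchange unbalanced); "
            f"adjust M_A0 or ppm_per_pgc"
        )
    # The spec's explicit residual check (also exercised by tests).
    tend = _tendencies(masses, fluxes)
    worst = max(abs(v) for v in tend.values())
    if worst > 1e-9:
        raise ValueError(f"steady-state residual {worst:.3e} PgC/yr; balances: {tend}")
    return reservoirs, fluxes


def _tendencies(masses: dict[str, float], f: dict[str, float]) -> dict[str, float]:
    return {
        "atmosphere": f["soil_respiration"] + f["kerogen"] + f["airsea_out"]
        - f["npp"] - f["airsea_in"] - f["silicate_sink"],
        "surface_ocean": f["airsea_in"] + f["overturn_up"] - f["airsea_out"] - f["overturn_down"],
        "deep_ocean": f["overturn_down"] - f["overturn_up"],
        "plant": f["npp"] - f["litter"],
        "soil": f["litter"] - f["soil_respiration"],
    }


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _ratio(delta: float) -> float:
    """Normalised isotope-mass factor for a flux of composition *delta*."""
    return 1.0 + delta * 1e-3


def _delta(m: float, m13: float) -> float:
    return (m13 / m - 1.0) * 1e3


class _State:
    """Mutable integration state: masses and normalised ¹³C masses, plus
    exact cumulative source/sink integrals for conservation checks."""

    __slots__ = ("mA", "mS", "mD", "mP", "mL", "cA", "cS", "cD", "cP", "cL",
                 "cum_inj", "cum_ker", "cum_sil", "cum_inj13", "cum_ker13", "cum_sil13")

    def __init__(self, masses: dict[str, float], d13c: dict[str, float]):
        self.mA = masses["atmosphere"]
        self.mS = masses["surface_ocean"]
        self.mD = masses["deep_ocean"]
        self.mP = masses["plant"]
        self.mL = masses["soil"]
        self.cA = self.mA * _ratio(d13c["atmosphere"])
        self.cS = self.mS * _ratio(d13c["surface_ocean"])
        self.cD = self.mD * _ratio(d13c["deep_ocean"])
        self.cP = self.mP * _ratio(d13c["plant"])
        self.cL = self.mL * _ratio(d13c["soil"])
        self.cum_inj = self.cum_ker = self.cum_sil = 0.0
        self.cum_inj13 = self.cum_ker13 = self.cum_sil13 = 0.0


def _advance(
    s: _State,
    t_ky: float,
    dt: float,
    scenario: ScenarioConfig,
    p: ModelParams,
) -> dict[str, float]:
    """One explicit-Euler step; mutates *s* and returns the flux set used."""
    pco2 = s.mA * p.ppm_per_pgc
    dT = p.climate_sensitivity * math.log2(pco2 / p.pCO2_0)
    q = p.q10 ** (dT / 10.0)

    g = gpp_multiplier(t_ky, scenario)
    npp = p.NPP_0 * g
    litter = s.mP / p.tau_plant
    resp = (s.mL / p.tau_soil) * (q if scenario.feedback_respiration else 1.0)

    pco2_s = p.pCO2_0 * (s.mS / p.M_S0) ** p.revelle
    f_in = p.k_gas * pco2
    f_out = p.k_gas * pco2_s
    over = p.overturn0
    f_down = over * (s.mS / p.M_S0)
    f_up = over * (s.mD / p.M_D0)

    deficit = max(0.0, 1.0 - (s.mP + s.mL) / (p.M_P0 + p.M_L0))
    if scenario.feedback_kerogen:
        qk = q if p.kerogen_temp_sensitive else 1.0
        fker = p.F_ker0 * (1.0 + p.kerogen_gain * deficit) * qk
    else:
        fker = p.F_ker0
    fsil = p.F_w0 * (pco2 / p.pCO2_0) ** p.n_weather

    inj = (
        scenario.injection_rate
        if 0.0 <= t_ky < scenario.injection_duration_ky
        else 0.0
    )

    dA = _delta(s.mA, s.cA)
    dS = _delta(s.mS, s.cS)
    dD = _delta(s.mD, s.cD)
    dP = _delta(s.mP, s.cP)
    dL = _delta(s.mL, s.cL)

    # mass updates
    s.mA += dt * (inj + resp + fker + f_out - npp - f_in - fsil)
    s.mS += dt * (f_in + f_up - f_out - f_down)
    s.mD += dt * (f_down - f_up)
    s.mP += dt * (npp - litter)
    s.mL += dt * (litter - resp)

    # isotope-mass updates: flux composition = source delta (+ fractionation)
    r_inj = _ratio(scenario.injection_d13c)
    r_npp = _ratio(dA + p.eps_land)
    r_in = _ratio(dA + p.eps_airsea)
    r_ker = _ratio(p.d13c_ker)
    r_sil = _ratio(p.d13c_ker)  # sink closure matches the exogenic input
    s.cA += dt * (inj * r_inj + resp * _ratio(dL) + fker * r_ker + f_out * _ratio(dS)
                  - npp * r_npp - f_in * r_in - fsil * r_sil)
    s.cS += dt * (f_in * r_in + f_up * _ratio(dD) - f_out * _ratio(dS) - f_down * _ratio(dS))
    s.cD += dt * (f_down * _ratio(dS) - f_up * _ratio(dD))
    s.cP += dt * (npp * r_npp - litter * _ratio(dP))
    s.cL += dt * (litter * _ratio(dP) - resp * _ratio(dL))

    s.cum_inj += dt * inj
    s.cum_ker += dt * fker
    s.cum_sil += dt * fsil
    s.cum_inj13 += dt * inj * r_inj
    s.cum_ker13 += dt * fker * r_ker
    s.cum_sil13 += dt * fsil * r_sil

    for m, name in ((s.mA, "atmosphere"), (s.mS, "surface_ocean"),
                    (s.mD, "deep_ocean"), (s.mP, "plant"), (s.mL, "soil")):
        if m <= 0:
            raise RuntimeError(
                f"reservoir {name} mass went non-positive ({m:.4g} PgC) at t = "
                f"{t_ky:.3f} ky"
            )
    return {
        "injection": inj, "npp": npp, "litter": litter, "soil_respiration": resp,
        "airsea_net": f_in - f_out, "overturn_net": f_down - f_up,
        "kerogen": fker, "silicate_sink": fsil, "pco2": pco2, "dT": dT,
    }


def step(
    state: dict[str, Reservoir],
    t_ky: float,
    dt: float,
    scenario: ScenarioConfig,
    params: ModelParams,
) -> dict[str, Reservoir]:
    """Advance a reservoir dict by one Euler step of *dt* years (public
    single-step interface; :func:`run_scenario` uses the same kernel)."""
    if dt > 1.0 or dt <= 0:
        raise ValueError("dt must be in (0, 1] years")
    s = _State(
        {name: r.mass for name, r in state.items()},
        {name: r.d13c for name, r in state.items()},
    )
    _advance(s, t_ky, dt, scenario, params)
    return {
        "atmosphere": Reservoir("atmosphere", s.mA, _delta(s.mA, s.cA)),
        "surface_ocean": Reservoir("surface_ocean", s.mS, _delta(s.mS, s.cS)),
        "deep_ocean": Reservoir("deep_ocean", s.mD, _delta(s.mD, s.cD)),
        "plant": Reservoir("plant", s.mP, _delta(s.mP, s.cP)),
        "soil": Reservoir("soil", s.mL, _delta(s.mL, s.cL)),
    }


@dataclass
class Trajectory:
    """Stored time series of one run. Time is in ky with 0 at the start of
    injection (the CIE base); the grid includes a pre-event segment."""

    t_ky: np.ndarray
    mass: dict[str, np.ndarray]
    d13c: dict[str, np.ndarray]
    pco2: np.ndarray
    dT: np.ndarray
    fluxes: dict[str, np.ndarray]
    cum_injected: np.ndarray
    cum_kerogen: np.ndarray
    cum_silicate: np.ndarray
    conservation: np.ndarray        # relative carbon-budget residual
    conservation_13c: np.ndarray    # relative 13C-budget residual
    params: ModelParams = field(repr=False, default=None)
    scenario: ScenarioConfig = field(repr=False, default=None)

    @property
    def terrestrial_stock(self) -> np.ndarray:
        return self.mass["plant"] + self.mass["soil"]

    @property
    def terrestrial_stock0(self) -> float:
        return self.params.M_P0 + self.params.M_L0

    def baseline_d13c(self, reservoir: str = "surface_ocean") -> float:
        pre = self.t_ky <= 0
        return float(self.d13c[reservoir][pre].mean())

    def cie_magnitude(self, reservoir: str = "surface_ocean") -> float:
        """Excursion size: pre-event baseline minus the run minimum, ‰."""
        return self.baseline_d13c(reservoir) - float(self.d13c[reservoir].min())

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t_ky": self.t_ky, "pCO2_ppm": self.pco2, "dT_C": self.dT}
        for name in RESERVOIRS:
            data[f"mass_{name}"] = self.mass[name]
            data[f"d13c_{name}"] = self.d13c[name]
        for name, arr in self.fluxes.items():
            data[f"flux_{name}"] = arr
        data["cum_injected"] = self.cum_injected
        data["cum_kerogen"] = self.cum_kerogen
        data["cum_silicate"] = self.cum_silicate
        return pd.DataFrame(data)


def run_scenario(params: ModelParams, scenario: ScenarioConfig) -> Trajectory:
    """Integrate from the pre-event steady state through injection and
    feedbacks; t runs from −spinup_ky to +t_end_ky."""
    reservoirs, _ = initialize_steady_state(params)
    s = _State(
        {n: r.mass for n, r in reservoirs.items()},
        {n: r.d13c for n, r in reservoirs.items()},
    )
    dt = params.dt
    n_steps = int(round((params.t_end_ky + params.spinup_ky) * 1000.0 / dt))
    save_stride = max(1, int(round(params.save_every / dt)))
    n_save = n_steps // save_stride + 1

    t_arr = np.empty(n_save)
    mass = {name: np.empty(n_save) for name in RESERVOIRS}
    d13c = {name: np.empty(n_save) for name in RESERVOIRS}
    pco2_arr = np.empty(n_save)
    dT_arr = np.empty(n_save)
    flux_names = ("injection", "npp", "litter", "soil_respiration", "airsea_net",
                  "overturn_net", "kerogen", "silicate_sink")
    fluxes = {name: np.empty(n_save) for name in flux_names}
    cum_inj = np.empty(n_save)
    cum_ker = np.empty(n_save)
    cum_sil = np.empty(n_save)
    cons = np.empty(n_save)
    cons13 = np.empty(n_save)

    total0 = s.mA + s.mS + s.mD + s.mP + s.mL
    total13_0 = s.cA + s.cS + s.cD + s.cP + s.cL

    def record(k: int, t_ky: float, f: dict[str, float]) -> None:
        t_arr[k] = t_ky
        mass["atmosphere"][k] = s.mA
        mass["surface_ocean"][k] = s.mS
        mass["deep_ocean"][k] = s.mD
        mass["plant"][k] = s.mP
        mass["soil"][k] = s.mL
        d13c["atmosphere"][k] = _delta(s.mA, s.cA)
        d13c["surface_ocean"][k] = _delta(s.mS, s.cS)
        d13c["deep_ocean"][k] = _delta(s.mD, s.cD)
        d13c["plant"][k] = _delta(s.mP, s.cP)
        d13c["soil"][k] = _delta(s.mL, s.cL)
        pco2_arr[k] = f["pco2"]
        dT_arr[k] = f["dT"]
        for name in flux_names:
            fluxes[name][k] = f[name]
        cum_inj[k] = s.cum_inj
        cum_ker[k] = s.cum_ker
        cum_sil[k] = s.cum_sil
        total = s.mA + s.mS + s.mD + s.mP + s.mL
        cons[k] = (total - total0 - (s.cum_inj + s.cum_ker - s.cum_sil)) / total0
        total13 = s.cA + s.cS + s.cD + s.cP + s.cL
        cons13[k] = (total13 - total13_0 - (s.cum_inj13 + s.cum_ker13 - s.cum_sil13)) / total13_0

    t0_ky = -params.spinup_ky
    k = 0
    for i in range(n_steps):
        t_ky = t0_ky + i * dt / 1000.0
        f = _advance(s, t_ky, dt, scenario, params)
        if (i + 1) % save_stride == 0:
            record(k, t0_ky + (i + 1) * dt / 1000.0, f)
            k += 1

    return Trajectory(
        t_ky=t_arr[:k],
        mass={n: a[:k] for n, a in mass.items()},
        d13c={n: a[:k] for n, a in d13c.items()},
        pco2=pco2_arr[:k],
        dT=dT_arr[:k],
        fluxes={n: a[:k] for n, a in fluxes.items()},
        cum_injected=cum_inj[:k],
        cum_kerogen=cum_ker[:k],
        cum_silicate=cum_sil[:k],
        conservation=cons[:k],
        conservation_13c=cons13[:k],
        params=params,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class Diagnostics:
    """Control-relative summary of a feedback run (ppm, PgC, ‰, ky)."""

    label: str
    peak_delta_pco2: float
    time_of_peak_ky: float
    max_extra_d13c_deepening: float
    terrestrial_transfer_pgc: float
    min_stock_fraction: float
    body_max_delta_pco2: float
    body_mean_delta_pco2: float
    time_pco2_stops_rising_ky: float
    stock_fraction_at_stabilization: float
    recovery_time_to_70pct_ky: float | None


def _smooth(y: np.ndarray, t_ky: np.ndarray, window_ky: float) -> np.ndarray:
    if window_ky <= 0 or len(t_ky) < 3:
        return y
    step_ky = float(np.median(np.diff(t_ky)))
    n = max(1, int(round(window_ky / step_ky)))
    if n <= 1:
        return y
    kernel = np.ones(n) / n
    pad = n // 2
    yp = np.pad(y, pad, mode="edge")
    out = np.convolve(yp, kernel, mode="same")[pad:pad + len(y)]
    return out


def time_pco2_stops_rising(
    traj: Trajectory,
    smooth_ky: float = 1.0,
    sustain_ky: float = 5.0,
) -> float:
    """Time (ky after onset) at which pCO₂ stops rising for good.

    The post-injection spike is followed by a rapid ocean-uptake decline and,
    with an active kerogen feedback, a slow renewed rise through the CIE
    body; this returns the last time the smoothed pCO₂ derivative is
    positive — after it, pCO₂ declines (stays non-increasing) for at least
    *sustain_ky* and through the end of the run.
    """
    t = traj.t_ky
    y = _smooth(traj.pco2, t, smooth_ky)
    dy = np.gradient(y, t)
    rising = np.where(dy > 0)[0]
    if len(rising) == 0:
        return float(t[0])
    return float(t[rising[-1]])


def first_stall_after_injection(
    traj: Trajectory,
    smooth_ky: float = 1.0,
    sustain_ky: float = 5.0,
) -> float:
    """Alternative stall definition: first time after injection end with a
    non-positive smoothed derivative sustained for *sustain_ky*."""
    t = traj.t_ky
    y = _smooth(traj.pco2, t, smooth_ky)
    dy = np.gradient(y, t)
    t_end_inj = traj.scenario.injection_duration_ky
    step_ky = float(np.median(np.diff(t)))
    n_sustain = max(1, int(round(sustain_ky / step_ky)))
    candidates = np.where((t > t_end_inj) & (dy <= 0))[0]
    for i in candidates:
        if np.all(dy[i:i + n_sustain] <= 0):
            return float(t[i])
    return float(t[-1])


def delta_series(feedback: Trajectory, control: Trajectory) -> pd.DataFrame:
    """Pointwise feedback-minus-control differences (pCO₂ and surface δ¹³C)."""
    if len(feedback.t_ky) != len(control.t_ky) or not np.allclose(
        feedback.t_ky, control.t_ky
    ):
        raise ValueError("feedback and control runs must share the same time grid")
    return pd.DataFrame(
        {
            "t_ky": feedback.t_ky,
            "delta_pco2_ppm": feedback.pco2 - control.pco2,
            "delta_d13c_surface": feedback.d13c["surface_ocean"]
            - control.d13c["surface_ocean"],
        }
    )


def compare_to_control(
    feedback: Trajectory,
    control: Trajectory,
    body_window_ky: tuple[float, float] = (20.0, 120.0),
) -> Diagnostics:
    """Summarise a feedback run against its control (identical time grids).

    Peak ΔpCO₂ is the maximum over time of feedback-minus-control pCO₂;
    "extra δ¹³C deepening" the maximum of control-minus-feedback surface
    δ¹³C; the terrestrial transfer the maximum drawdown of plant+soil below
    the pre-event stock.
    """
    d = delta_series(feedback, control)
    t = feedback.t_ky
    dp = d["delta_pco2_ppm"].to_numpy()
    i_peak = int(np.argmax(dp))

    stock = feedback.terrestrial_stock
    stock0 = feedback.terrestrial_stock0
    min_frac = float(stock.min() / stock0)
    transfer = max(0.0, stock0 - float(stock.min()))

    lo, hi = body_window_ky
    body = (t >= lo) & (t <= hi)
    body_max = float(dp[body].max()) if body.any() else float("nan")
    body_mean = float(dp[body].mean()) if body.any() else float("nan")

    t_stab = time_pco2_stops_rising(feedback)
    frac_at_stab = float(stock[np.searchsorted(t, t_stab)] / stock0)

    rec = None
    i_min = int(np.argmin(stock))
    after = np.where(stock[i_min:] >= 0.7 * stock0)[0]
    if len(after):
        rec = float(t[i_min + after[0]])

    deepening = float(
        (control.d13c["surface_ocean"] - feedback.d13c["surface_ocean"]).max()
    )
    return Diagnostics(
        label=feedback.scenario.label,
        peak_delta_pco2=float(dp[i_peak]),
        time_of_peak_ky=float(t[i_peak]),
        max_extra_d13c_deepening=deepening,
        terrestrial_transfer_pgc=transfer,
        min_stock_fraction=min_frac,
        body_max_delta_pco2=body_max,
        body_mean_delta_pco2=body_mean,
        time_pco2_stops_rising_ky=t_stab,
        stock_fraction_at_stabilization=frac_at_stab,
        recovery_time_to_70pct_ky=rec,
    )
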