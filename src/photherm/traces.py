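"""Synthetic lumped-capacitance thermal traces.

A stirred cuvette of nanoparticle suspension under continuous laser
illumination behaves, to excellent approximation, as a single thermal mass
m*C exchanging heat with the surroundings at a rate proportional to its
temperature elevation (Newton cooling, time constant tau).  With the laser
on, the absorbed optical power I*eta*(1 - 10^-eps) plus any solvent/cuvette
baseline heating Q_blank drives an exponential approach to an equilibrium
elevation

    dT_eq = tau * (I * eta * (1 - 10^-eps) + Q_blank) / (m * C)

and with the laser off the elevation decays as exp(-t/tau).  The generator
here produces exactly these dynamics (optionally with i.i.d. Gaussian
measurement noise), which is the model the downstream estimators assume —
so estimator round trips on these traces are exact identities up to noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["TraceGenConfig", "ThermalTrace", "simulate_trace", "simulate_blank_trace"]


@dataclass(frozen=True)
class TraceGenConfig:
    """Parameters of the forward lumped-capacitance trace model.

    Defaults describe the benchmark cuvette experiment: 2 g of aqueous
    suspension (C = 4.182 J/g/K) under a 1 W, 808 nm beam at extinction
    0.1.  tau and the sampling interval are fixture choices; the heating
    window defaults to 10 tau so traces reach equilibrium.
    """

    eta_true: float = 0.66
    extinction: float = 0.1
    laser_power_W: float = 1.0
    sample_mass_g: float = 2.0
    heat_capacity_J_per_gK: float = 4.182
    tau_s: float = 600.0
    q_blank_W: float = 0.0
    t_ambient_C: float = 25.0
    heat_duration_s: float = 6000.0
    cool_duration_s: float = 3600.0
    sample_interval_s: float = 1.0
    noise_sd_C: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "eta_true": 0.0 <= self.eta_true <= 1.0,
            "extinction": self.extinction >= 0,
            "laser_power_W": self.laser_power_W >= 0,
            "sample_mass_g": self.sample_mass_g > 0,
            "heat_capacity_J_per_gK": self.heat_capacity_J_per_gK > 0,
            "tau_s": self.tau_s > 0,
            "q_blank_W": self.q_blank_W >= 0,
            "heat_duration_s": self.heat_duration_s > 0,
            "cool_duration_s": self.cool_duration_s >= 0,
            "sample_interval_s": self.sample_interval_s > 0,
            "noise_sd_C": self.noise_sd_C >= 0,
        }
        for name, ok in checks.items():
            v = getattr(self, name)
            if not (ok and math.isfinite(v)):
                raise ValueError(f"invalid {name}={v!r} in TraceGenConfig")
        if not math.isfinite(self.t_ambient_C):
            raise ValueError("t_ambient_C must be finite")

    @property
    def absorbed_fraction(self) -> float:
        """1 - 10^-eps: fraction of beam power extinguished by the sample."""
        return 1.0 - 10.0 ** (-self.extinction)

    @property
    def equilibrium_elevation_C(self) -> float:
        """Steady-state temperature elevation above ambient, deg C."""
        q_np = self.laser_power_W * self.eta_true * self.absorbed_fraction
        return self.tau_s * (q_np + self.q_blank_W) / (
            self.sample_mass_g * self.heat_capacity_J_per_gK
        )


@dataclass(frozen=True)
class ThermalTrace:
    """A timestamped temperature record with a laser-off phase marker."""

    times_s: np.ndarray
    temperatures_C: np.ndarray
    laser_off_time_s: float
    t_ambient_C: float
    sample_mass_g: float
    heat_capacity_J_per_gK: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        temp = np.asarray(self.temperatures_C, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "temperatures_C", temp)
        if t.ndim != 1 or t.shape != temp.shape:
            raise ValueError("times and temperatures must be 1-D and equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 samples")
        if not t[0] <= self.laser_off_time_s <= t[-1]:
            raise ValueError("laser_off_time_s must lie within the sampled time range")
        if self.sample_mass_g <= 0 or self.heat_capacity_J_per_gK <= 0:
            raise ValueError("mass and heat capacity must be positive")

    @property
    def heat_capacity_J_per_K(self) -> float:
        return self.sample_mass_g * self.heat_capacity_J_per_gK

    def heating_segment(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.times_s <= self.laser_off_time_s
        return self.times_s[m], self.temperatures_C[m]

    def cooling_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """Times (relative to laser-off) and temperatures after laser-off."""
        m = self.times_s > self.laser_off_time_s
        return self.times_s[m] - self.laser_off_time_s, self.temperatures_C[m]


def _noiseless_temperatures(config: TraceGenConfig, times: np.ndarray) -> np.ndarray:
    dt_eq = config.equilibrium_elevation_C
    t_off = config.heat_duration_s
    temps = np.empty_like(times)
    heating = times <= t_off
    temps[heating] = config.t_ambient_C + dt_eq * (-np.expm1(-times[heating] / config.tau_s))
    elevation_off = dt_eq * (-np.expm1(-t_off / config.tau_s))
    temps[~heating] = config.t_ambient_C + elevation_off * np.exp(
        -(times[~heating] - t_off) / config.tau_s
    )
    return temps


def simulate_trace(config: TraceGenConfig) -> ThermalTrace:
    """Simulate a heating/cooling trace under the lumped-capacitance model.

    Samples run from t=0 to heat_duration + cool_duration at the configured
    interval; the laser switches off at heat_duration.  When noise_sd_C > 0,
    i.i.d. Gaussian noise is added per sample, reproducibly under ``seed``.
    """
    total = config.heat_duration_s + config.cool_duration_s
    n = int(math.floor(total / config.sample_interval_s + 1e-9)) + 1
    times = np.arange(n) * config.sample_interval_s
    temps = _noiseless_temperatures(config, times)
    if config.noise_sd_C > 0:
        rng = np.random.default_rng(config.seed)
        temps = temps + rng.normal(0.0, config.noise_sd_C, size=temps.shape)
    return ThermalTrace(
        times_s=times,
        temperatures_C=temps,
        laser_off_time_s=config.heat_duration_s,
        t_ambient_C=config.t_ambient_C,
        sample_mass_g=config.sample_mass_g,
        heat_capacity_J_per_gK=config.heat_capacity_J_per_gK,
    )


def simulate_blank_trace(config: TraceGenConfig) -> ThermalTrace:
    """Simulate the water-only blank: same model with the particle term zeroed.

    Only q_blank_W (direct solvent/cuvette heating) drives the trace; the
    plateau elevation is tau * Q_blank / (m * C).
    """
    return simulate_trace(replace(config, eta_true=0.0))
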