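"""Idealized voxel heating rates and hyperthermia ramp times.

Combines the mass conversion efficiency eta_m of a nanoparticle, the
Monte Carlo fluence map, and a tissue nanoparticle concentration into the
peak heating rate of a single nanoparticle-loaded voxel,

    dT/dt = eta_m * P(z) * m_NPs / (m * C)     [K/s]

where P(z) is the beam power reaching depth z (surface power density x
beam area x relative photon density), m_NPs the nanoparticle mass in the
voxel and m*C the voxel's thermal mass.  No conduction, perfusion or
inter-voxel shading is modelled, so the resulting 37 -> 43 deg C ramp
times are strict minima ("best case"): real tissue heats more slowly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc import FluenceMap, depth_profile

__all__ = ["HeatingScenario", "RampTimeTable", "heating_rate", "ramp_time", "ramp_time_table"]

IDEALIZATION_WARNING = (
    "Idealized model: no heat loss, perfusion or conduction, and no beam "
    "attenuation by nanoparticles outside the target voxel; ramp times are minima."
)


@dataclass(frozen=True)
class HeatingScenario:
    """One point of the depth x concentration x power heating grid."""

    np_concentration_mg_per_g: float = 0.01
    surface_power_density_W_per_cm2: float = 1.0
    depth_mm: float = 0.0
    voxel_mass_ug: float = 7.47
    heat_capacity_J_per_gK: float = 4.186
    t_body_C: float = 37.0
    t_target_C: float = 43.0
    eta_m_per_ug: float = 0.771

    def __post_init__(self) -> None:
        positives = (
            "np_concentration_mg_per_g",
            "surface_power_density_W_per_cm2",
            "voxel_mass_ug",
            "heat_capacity_J_per_gK",
            "eta_m_per_ug",
        )
        for name in positives:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.voxel_mass_ug == 0:
            raise ValueError("voxel mass must be positive")
        if self.depth_mm < 0:
            raise ValueError("depth must be >= 0")
        if not self.t_target_C > self.t_body_C:
            raise ValueError("target temperature must exceed body temperature")

    @property
    def np_mass_in_voxel_ug(self) -> float:
        """Nanoparticle mass in the voxel, ug (tissue density 1 g/cm^3)."""
        # mg NP per g tissue x voxel mass in g -> mg, x 1e3 -> ug
        return self.np_concentration_mg_per_g * self.voxel_mass_ug * 1e-3


def heating_rate(scenario: HeatingScenario, power_at_depth_W: float) -> float:
    """Peak voxel heating rate dT/dt, K/s, for beam power P reaching the voxel."""
    if power_at_depth_W < 0:
        raise ValueError("power must be >= 0")
    thermal_mass_J_per_K = scenario.voxel_mass_ug * 1e-6 * scenario.heat_capacity_J_per_gK
    return (
        scenario.eta_m_per_ug
        * power_at_depth_W
        * scenario.np_mass_in_voxel_ug
        / thermal_mass_J_per_K
    )


def ramp_time(rate_K_per_s: float, t_body_C: float = 37.0, t_target_C: float = 43.0) -> float:
    """Seconds to ramp from body to target temperature at a constant rate.

    A zero rate returns ``inf`` (target unreachable) rather than raising.
    """
    if rate_K_per_s < 0:
        raise ValueError("heating rate must be >= 0")
    if t_target_C <= t_body_C:
        raise ValueError("target temperature must exceed body temperature")
    if rate_K_per_s == 0:
        return math.inf
    return (t_target_C - t_body_C) / rate_K_per_s


@dataclass(frozen=True)
class RampTimeTable:
    """Grid of 37 -> 43 deg C ramp times (s) over depth x concentration x power."""

    times_s: np.ndarray  # shape (n_depth, n_conc, n_power)
    depths_mm: np.ndarray
    concentrations_mg_per_g: np.ndarray
    power_densities_W_per_cm2: np.ndarray
    eta_m_per_ug: float
    map_seed: int
    warning: str = IDEALIZATION_WARNING

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (depth, concentration, power)."""
        rows = []
        for i, z in enumerate(self.depths_mm):
            for j, c in enumerate(self.concentrations_mg_per_g):
                for k, p in enumerate(self.power_densities_W_per_cm2):
                    rows.append((z, c, p, self.times_s[i, j, k]))
        return pd.DataFrame(
            rows,
            columns=[
                "depth_mm",
                "concentration_mg_per_g",
                "power_density_W_per_cm2",
                "ramp_time_s",
            ],
        )

    def pivot(self, concentration_mg_per_g: float) -> pd.DataFrame:
        """Depth x power-density table for one concentration (report shape)."""
        j = int(np.argmin(np.abs(self.concentrations_mg_per_g - concentration_mg_per_g)))
        if not math.isclose(
            self.concentrations_mg_per_g[j], concentration_mg_per_g, rel_tol=1e-9
        ):
            raise ValueError(f"concentration {concentration_mg_per_g} not in table")
        return pd.DataFrame(
            self.times_s[:, j, :],
            index=pd.Index(self.depths_mm, name="depth_mm"),
            columns=[f"{p:g} W/cm2" for p in self.power_densities_W_per_cm2],
        )


def ramp_time_table(
    fluence: FluenceMap,
    eta_m_per_ug: float,
    concentrations_mg_per_g=(0.005, 0.010, 0.015, 0.020),
    power_densities_W_per_cm2=(1.0, 3.0, 5.0),
    depths_mm=(0.0, 10.0, 20.0, 30.0),
    voxel_mass_ug: float = 7.47,
    heat_capacity_J_per_gK: float = 4.186,
    t_body_C: float = 37.0,
    t_target_C: float = 43.0,
) -> RampTimeTable:
    """Minimum ramp-time grid over depth x concentration x surface power."""
    depths = np.asarray(depths_mm, dtype=float)
    concs = np.asarray(concentrations_mg_per_g, dtype=float)
    powers = np.asarray(power_densities_W_per_cm2, dtype=float)
    max_depth = fluence.dims_cm[2] * 10.0
    if depths.min() < 0 or depths.max() > max_depth:
        raise ValueError(f"requested depths outside the fluence map (0-{max_depth} mm)")

    profile_depths, profile = depth_profile(fluence, 0.0)
    rel = np.interp(depths, profile_depths, profile)

    times = np.empty((depths.size, concs.size, powers.size))
    for i, z in enumerate(depths):
        for j, c in enumerate(concs):
            for k, p in enumerate(powers):
                scen = HeatingScenario(
                    np_concentration_mg_per_g=c,
                    surface_power_density_W_per_cm2=p,
                    depth_mm=z,
                    voxel_mass_ug=voxel_mass_ug,
                    heat_capacity_J_per_gK=heat_capacity_J_per_gK,
                    t_body_C=t_body_C,
                    t_target_C=t_target_C,
                    eta_m_per_ug=eta_m_per_ug,
                )
                power_W = p * fluence.beam.area_cm2 * rel[i]
                times[i, j, k] = ramp_time(
                    heating_rate(scen, power_W), t_body_C, t_target_C
                )
    return RampTimeTable(
        times_s=times,
        depths_mm=depths,
        concentrations_mg_per_g=concs,
        power_densities_W_per_cm2=powers,
        eta_m_per_ug=eta_m_per_ug,
        map_seed=fluence.seed,
    )
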