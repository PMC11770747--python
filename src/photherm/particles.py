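"""Nanoparticle suspension metadata and shell-geometry mass bookkeeping.

Plasmonic gold nanoparticles are compared at a fixed decadic extinction
(optical depth 0.1 at the 808 nm laser line) so that every suspension
attenuates the beam identically and heating differences reflect particle
properties alone.  For silica-core gold nanoshells the optically relevant
gold shell carries a passive silica core, so the gold mass measured by
ICP-MS must be corrected upward before mass-normalized metrics are
computed; the helpers here do that volume/density arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "NanoparticleSuspension",
    "preset_suspension",
    "PRESET_NAMES",
    "silica_volume_fraction",
    "core_mass_fraction",
    "core_mass_correction",
]

#: Densities used for the core-mass correction, g/cm^3.
DENSITY_SILICA = 2.65
DENSITY_GOLD = 19.32


@dataclass(frozen=True)
class NanoparticleSuspension:
    """A nanoparticle colloid characterized at the laser wavelength.

    Parameters
    ----------
    name
        Label, e.g. ``"AuNR"``.
    extinction_808
        Decadic optical depth of the suspension at 808 nm (dimensionless).
    mass_concentration_mg_per_mL
        Total nanoparticle mass concentration (gold plus any passive core),
        mg/mL.
    mass_ext_coeff_cm2_per_mg
        Mass extinction coefficient at 808 nm, cm^2/mg.
    path_length_cm
        Optical path length of the cuvette, cm.
    shell_r1_nm, shell_r2_nm
        Inner (core) and outer radii for core-shell particles, nm.
    density_core_g_per_cm3, density_shell_g_per_cm3
        Densities of the core and shell materials, g/cm^3.
    reference_eta
        Photothermal conversion efficiency reported for this particle
        type, stored as a reference value for simulation presets.
    """

    name: str
    extinction_808: float
    mass_concentration_mg_per_mL: float
    mass_ext_coeff_cm2_per_mg: float
    path_length_cm: float = 1.0
    shell_r1_nm: float | None = None
    shell_r2_nm: float | None = None
    density_core_g_per_cm3: float | None = None
    density_shell_g_per_cm3: float | None = None
    reference_eta: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.extinction_808) and self.extinction_808 >= 0):
            raise ValueError(f"extinction_808 must be finite and >= 0, got {self.extinction_808}")
        for attr in ("mass_concentration_mg_per_mL", "mass_ext_coeff_cm2_per_mg", "path_length_cm"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{attr} must be finite and >= 0, got {v}")
        r1, r2 = self.shell_r1_nm, self.shell_r2_nm
        if (r1 is None) != (r2 is None):
            raise ValueError("shell radii must be given together")
        if r1 is not None and not (0 < r1 < r2):
            raise ValueError(f"shell radii require 0 < r1 < r2, got r1={r1}, r2={r2}")


# The three archetypal 808-nm plasmonic heaters, all diluted to a decadic
# extinction of 0.1 at 808 nm.  Mass concentration follows from the mass
# Beer-Lambert law, C = eps / (eps_m * L).
_PRESETS: dict[str, dict] = {
    "AuNShell": dict(
        mass_ext_coeff_cm2_per_mg=31.7,
        shell_r1_nm=59.9,
        shell_r2_nm=76.4,
        density_core_g_per_cm3=DENSITY_SILICA,
        density_shell_g_per_cm3=DENSITY_GOLD,
        reference_eta=0.20,
    ),
    "AuNR": dict(mass_ext_coeff_cm2_per_mg=46.1, reference_eta=0.66),
    "AuNStar": dict(mass_ext_coeff_cm2_per_mg=24.7, reference_eta=0.34),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_suspension(name: str) -> NanoparticleSuspension:
    """Return one of the benchmark suspensions (AuNShell, AuNR, AuNStar).

    All presets share extinction 0.1 at 808 nm in a 1 cm cuvette; the mass
    concentration is derived from the measured mass extinction coefficient.
    """
    try:
        params = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown suspension preset {name!r}; known presets: {', '.join(_PRESETS)}"
        ) from None
    extinction = 0.1
    path = 1.0
    conc = extinction / (params["mass_ext_coeff_cm2_per_mg"] * path)
    return NanoparticleSuspension(
        name=name,
        extinction_808=extinction,
        mass_concentration_mg_per_mL=conc,
        path_length_cm=path,
        **params,
    )


def silica_volume_fraction(r1_nm: float, r2_nm: float) -> float:
    """Volume fraction of the core in a core-shell sphere, (r1/r2)^3."""
    if not (0 <= r1_nm <= r2_nm) or r2_nm <= 0:
        raise ValueError(f"require 0 <= r1 <= r2 and r2 > 0, got r1={r1_nm}, r2={r2_nm}")
    return (r1_nm / r2_nm) ** 3


def core_mass_fraction(volume_fraction_core: float, rho_core: float, rho_shell: float) -> float:
    """Added core mass per unit shell-metal mass for a given core volume fraction.

    f_v * rho_core / ((1 - f_v) * rho_shell); this is the factor by which an
    ICP-MS gold mass must be increased to obtain total particle mass.
    """
    if not 0 <= volume_fraction_core < 1:
        raise ValueError(f"volume fraction must lie in [0, 1), got {volume_fraction_core}")
    if rho_core <= 0 or rho_shell <= 0:
        raise ValueError("densities must be positive")
    f = volume_fraction_core
    return f * rho_core / ((1.0 - f) * rho_shell)


def core_mass_correction(
    r1_nm: float,
    r2_nm: float,
    rho_core: float = DENSITY_SILICA,
    rho_shell: float = DENSITY_GOLD,
) -> float:
    """Core-mass correction computed from the shell radii directly."""
    f = silica_volume_fraction(r1_nm, r2_nm)
    if r1_nm == 0:
        return 0.0
    return core_mass_fraction(f, rho_core, rho_shell)
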