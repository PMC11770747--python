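"""Shared fixtures: expensive Monte Carlo maps are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from photherm import mc


@pytest.fixture(scope="session")
def breast_map():
    """High-statistics fluence map for the breast-tissue configuration.

    Default tissue optics (mu_a = 0.035 /cm, mu_s' = 11.7 /cm, isotropic
    similarity reduction), 10 mm flat beam, 1e6 packets.
    """
    return mc.run_mc(mc.TissueModel(), mc.BeamModel(), n_packets=1_000_000, seed=20260)


@pytest.fixture(scope="session")
def breast_map_hg():
    """Same tissue with explicit Henyey-Greenstein g = 0.9 scattering."""
    model = mc.TissueModel(anisotropy_g=0.9)
    return mc.run_mc(model, mc.BeamModel(), n_packets=250_000, seed=20261)


@pytest.fixture(scope="session")
def small_map():
    """Cheap map for conservation / plumbing checks."""
    return mc.run_mc(mc.TissueModel(), mc.BeamModel(), n_packets=50_000, seed=77)


def on_axis(fmap, depths_mm):
    """On-axis relative density interpolated at the requested depths."""
    d, p = mc.depth_profile(fmap, 0.0)
    return np.interp(np.asarray(depths_mm, dtype=float), d, p)
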