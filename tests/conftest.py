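"""Shared fixtures: synthetic spectra and field geometries.

Everything is generated programmatically at test time; the session-scoped
wheat-shoot spectrum (all 21 catalogued multiplets with seed-42 random
areas, full processing chain) is reused across annotation, deconvolution
and acceptance tests.
"""

import numpy as np
import pytest

from geometab import (AcquisitionParams, FieldSpec, MultipletFit,
                      positions_to_local_meters, sample_positions,
                      synthesize_fid, wheat_shoots_catalog)
from geometab.nmr import process_fid


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def shoots_catalog():
    return wheat_shoots_catalog()


@pytest.fixture(scope="session")
def shoot_amplitudes(shoots_catalog):
    """Seed-42 random multiplet areas, uniform in [0.5, 2]."""
    rng = np.random.default_rng(42)
    return rng.uniform(0.5, 2.0, len(shoots_catalog))


@pytest.fixture(scope="session")
def shoot_spectrum(shoots_catalog, shoot_amplitudes, acq):
    """Noise-free wheat-shoot spectrum through the full processing chain."""
    fid = synthesize_fid(shoots_catalog, shoot_amplitudes, acq)
    return process_fid(fid, phi0_deg=0.0, phi1_deg=0.0)


@pytest.fixture(scope="session")
def shoot_fit(shoot_spectrum, shoots_catalog):
    """Joint multiplet deconvolution of the session spectrum."""
    return MultipletFit(shoot_spectrum, shoots_catalog.models()).fit()


@pytest.fixture(scope="session")
def field_coords():
    """60 jittered quasi-grid positions on a 500 × 200 m field, in meters."""
    spec = FieldSpec(n_sites=60, extent_m=(500.0, 200.0), seed=11)
    latlon = sample_positions(spec)
    return positions_to_local_meters(latlon, spec.origin_deg)
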