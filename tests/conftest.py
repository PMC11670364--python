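"""Shared fixtures: spectra, detectors, small geometries, and the reduced
CT study used by the image-pipeline property tests."""

import numpy as np
import pytest
from hypothesis import settings

from mvkvct import physics as ph
from mvkvct.cli import RunConfig, ct_study

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis():
    return ph.tissue_bone_basis()


@pytest.fixture(scope="session")
def kv_spectrum():
    return ph.build_kv_spectrum()


@pytest.fixture(scope="session")
def mv_spectrum():
    return ph.build_detuned_mv_spectrum()


@pytest.fixture(scope="session")
def spectra(mv_spectrum, kv_spectrum):
    return (mv_spectrum, kv_spectrum)


@pytest.fixture(scope="session")
def pcd():
    return ph.DetectorModel.pcd()


@pytest.fixture(scope="session")
def eid():
    return ph.DetectorModel.eid()


@pytest.fixture(scope="session")
def reduced_ct_config():
    """The reduced IQ-phantom DE-CT study: 360 views, 256^2 matrix, five
    noisy realizations per detector at 10 mGy with r = 0.85."""
    return RunConfig(n_views=360, matrix_size=256, n_realizations=5,
                     seed=7, mv_fraction=0.85,
                     vmi_energies_kev=tuple(float(e) for e in range(20, 121, 10)))


@pytest.fixture(scope="session")
def reduced_ct_results(reduced_ct_config):
    """Run the reduced CT study once per session (several minutes)."""
    return ct_study(reduced_ct_config)


def monoenergetic(energy_kev: float, photons: float, label: str = "mono"):
    """Single-bin spectrum helper used by closed-form oracles."""
    return ph.Spectrum(np.array([energy_kev]), np.array([photons]), label)
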