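import numpy as np
import pytest

from nrpore.materials import default_materials
from nrpore.synthetic import fixture_catalog


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def catalog(materials):
    return fixture_catalog(materials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def parratt_reflectivity(q, sld, thickness, roughness):
    """Independent Parratt recursion (bottom-up), with Nevot-Croce factors.

    Deliberately coded differently from the packaged Abeles matrix product:
    recursive combination of interface reflectances starting at the backing
    half-space.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    n = len(sld)
    k = [np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (s - sld[0]) + 0j) for s in sld]
    r_tot = np.zeros_like(q, dtype=complex)
    for j in range(n - 2, -1, -1):
        fresnel = (k[j] - k[j + 1]) / (k[j] + k[j + 1]) * np.exp(
            -2.0 * k[j] * k[j + 1] * roughness[j + 1] ** 2
        )
        if j == n - 2:
            r_tot = fresnel
        else:
            phase = np.exp(2j * k[j + 1] * thickness[j + 1])
            r_tot = (fresnel + r_tot * phase) / (1.0 + fresnel * r_tot * phase)
    return np.abs(r_tot) ** 2
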