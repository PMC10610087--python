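import numpy as np
import pytest

from imscan.demography import DemographyParams, KmaxSpec, Model
from imscan.inference import GridSpec, makegrid


@pytest.fixture(scope="session")
def global_model_params():
    """The fitted butterfly background demography used as the reference
    parameter point throughout: N_A = 5.49e5, N_B = 1.415e6,
    N_anc = 9.279e5 diploids, T = 4.216e6 generations (1.054 Myr at four
    generations per year), m_e = 7.41e-7 per generation, mu = 2.9e-9 per
    bp per generation, 64-bp blocks. Gene flow runs forwards in time from
    the large population (B) into the small one (A), i.e. backwards in
    time A's lineages may trace into B; this orientation reproduces the
    published per-taxon heterozygosities and d_xy."""
    return DemographyParams(
        model=Model.IM_BtoA, N_A=5.49e5, N_B=1.415e6, N_anc=9.279e5,
        T=4.216e6, m_e=7.41e-7, mu=2.9e-9, block_length=64,
    )


@pytest.fixture(scope="session")
def kmax():
    return KmaxSpec(2, 2, 2, 2)


@pytest.fixture(scope="session")
def scan_grid(global_model_params, kmax):
    """Small IM likelihood grid around the background model with T fixed:
    4 x 3 x 2 population-size values and an m_e ladder containing 0,
    m_hat/4, m_hat/2, m_hat and 2 m_hat (the global estimate must be a
    grid value for barrier support to be defined)."""
    p = global_model_params
    m_hat = p.m_e
    spec = GridSpec(
        model=p.model,
        axes={
            "N_A": p.N_A * np.array([0.5, 1.0, 2.0, 4.0]),
            "N_B": p.N_B * np.array([0.5, 1.0, 2.0]),
            "N_anc": p.N_anc * np.array([0.5, 1.0]),
            "m_e": m_hat * np.array([0.0, 0.25, 0.5, 1.0, 2.0]),
        },
        fixed={"T": p.T},
        mu=p.mu,
        block_length=p.block_length,
        kmax=kmax,
    )
    return makegrid(spec)
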