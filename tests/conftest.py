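import numpy as np
import pytest

from mutrescue import Trajectory, integrate_de_novo
from mutrescue.experiments_cli import make_params


@pytest.fixture(scope="session")
def ref_params_n2():
    """Reference parameter set: nu=1e-3, F=5, n=2, theta=500, g=0.1, K=1e4."""
    return make_params(nu=1e-3, F=5.0, n=2.0, theta=500.0, E=500.0)


@pytest.fixture(scope="session")
def ref_traj_n2(ref_params_n2):
    return integrate_de_novo(ref_params_n2)


def constant_growth_trajectory(f, *, crowd=0.0, T=2000.0, m=20001):
    """Synthetic trajectory realizing a constant rescue-lineage effective
    growth rate: cost factor f, tiny theta (rising Hill == 1 beyond t~0),
    optional constant crowding to push the lineage subcritical."""
    params = make_params(
        nu=(1.0 - f), F=1.0, E=0.0, theta=1e-6, n=2.0, alpha=0.0, K=1e4
    )
    t = np.linspace(0.0, T, m)
    NW = np.full_like(t, crowd * params.dem.K)
    return params, Trajectory(
        times=t, NW=NW, NM=np.zeros_like(t), scenario="de_novo", params=params
    )
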