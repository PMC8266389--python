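import numpy as np
import pytest

from nodalgrad.image_analysis import segment_stack
from nodalgrad.simulator import Geometry1D, RateParams, simulate_receptor_dynamics_1d
from nodalgrad.synthetic_data import StackSpec, make_phantom_stack


@pytest.fixture(scope="session")
def wt_params() -> RateParams:
    return RateParams()


@pytest.fixture(scope="session")
def wt_series_1d(wt_params):
    """Wild-type 1D run: receptor replacement on, 2.5 h."""
    return simulate_receptor_dynamics_1d(Geometry1D(), wt_params, duration=9000.0)


@pytest.fixture(scope="session")
def zoep_series_1d(wt_params):
    """Zygotic-mutant 1D run: finite maternal receptor pool, no replacement."""
    p = wt_params.with_(k3=0.0)
    return simulate_receptor_dynamics_1d(
        Geometry1D(), p, R_init=wt_params.k3 / wt_params.delta_R,
        duration=9000.0, warn_no_steady_state=False)


@pytest.fixture(scope="session")
def phantom60():
    """60-nucleus phantom stack with ground truth at the default SNR."""
    spec = StackSpec(n_nuclei=60, seed=3)
    stack, truth, trace = make_phantom_stack(spec)
    return spec, stack, truth, trace


@pytest.fixture(scope="session")
def phantom60_table(phantom60):
    _, stack, _, trace = phantom60
    return segment_stack(stack, trace)


def match_detections(table, truth, radius=9.0):
    """Greedy nearest-centroid matching of detections to ground truth."""
    from scipy.spatial import cKDTree

    det = table[["centroid_y", "centroid_x"]].to_numpy()
    tru = truth[["centroid_y", "centroid_x"]].to_numpy()
    if len(det) == 0:
        return np.zeros(len(tru), dtype=bool), np.array([], dtype=int)
    d, i = cKDTree(det).query(tru)
    matched = d < radius
    return matched, i
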