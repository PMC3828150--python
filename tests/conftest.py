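import numpy as np
import pytest
import scipy.sparse as sp

from homeoplast.params import NetworkConfig, TripletParams
from homeoplast.spikenet import Network


@pytest.fixture(scope="session")
def triplet_unit() -> TripletParams:
    """Triplet rule at the biological learning rate."""
    return TripletParams(eta=1.0)


@pytest.fixture(scope="session")
def triplet_unbounded() -> TripletParams:
    """Triplet rule with bounds wide open, for raw-accumulation
    comparisons against the oracles."""
    return TripletParams(eta=1.0, w_min=-1e9, w_max=1e9)


def make_pair_network(w0: float = 0.16, w_ext: float = 4.0) -> Network:
    """Two excitatory neurons with a single plastic synapse 0 -> 1, each
    driven by its own external source (strong enough that every scheduled
    external spike triggers a postsynaptic spike)."""
    cfg = NetworkConfig(N_exc=2, N_inh=1, N_ext=2, ext_rate=2.0,
                        p_conn=0.5, p_ext=0.5, w_ee=w0, w_ext=w_ext, seed=0)
    ee = sp.csr_matrix(np.array([[0.0, w0], [0.0, 0.0]]))
    empty = lambda m, n: sp.csr_matrix((m, n))
    ext = sp.csr_matrix(np.array([[w_ext, 0.0], [0.0, w_ext]]))
    return Network(config=cfg, ee=ee, ei=empty(2, 1), ie=empty(1, 2),
                   ii=empty(1, 1), ext=ext)
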