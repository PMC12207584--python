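import numpy as np
import pytest

from scfopt._linalg import random_hermitian, random_unitary
from scfopt.core import BlockState, IterationEntry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_entry(
    rng,
    dim: int = 3,
    E: float = 0.0,
    iteration: int = 0,
    n_blocks: int = 1,
    complex_field: bool = False,
):
    """A structurally valid history entry with random Hermitian payloads."""
    states, F, P, err = [], [], [], []
    for _ in range(n_blocks):
        C = random_unitary(rng, dim, complex_field)
        f = np.zeros(dim)
        f[0] = 2.0
        states.append(BlockState(C=C, E_orb=np.arange(dim, dtype=float), f=f))
        Fb = random_hermitian(rng, dim, complex_field)
        Pb = (C * f) @ C.conj().T
        F.append(Fb)
        P.append(Pb)
        err.append(Fb @ Pb - Pb @ Fb)
    return IterationEntry(
        states=states, F=F, P=P, E_total=E, err=err, iteration_index=iteration
    )
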