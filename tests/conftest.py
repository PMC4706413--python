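import numpy as np
import pytest

from curlimc.chain import Conformation, PeptideSequence, SystemState
from curlimc.constants import N_CHI


def make_state(seqs, phi_psi=None, box_side=100.0, separation=30.0):
    """Build a SystemState with given (phi, psi) torsions for every chain."""
    seqs = [PeptideSequence(f"c{i}", s) if isinstance(s, str) else s
            for i, s in enumerate(seqs)]
    if phi_psi is None:
        return SystemState.from_sequences(seqs, box_side,
                                          separation=separation)
    phi, psi, omega, chi, trans, rots = [], [], [], [], [], []
    for c, (seq, (p, s)) in enumerate(zip(seqs, phi_psi)):
        n = len(seq)
        phi.append(np.full(n, p, dtype=float) if np.isscalar(p)
                   else np.asarray(p, dtype=float))
        psi.append(np.full(n, s, dtype=float) if np.isscalar(s)
                   else np.asarray(s, dtype=float))
        omega.append(np.full(n, 180.0))
        chi.append(np.full(sum(N_CHI[a] for a in seq.residues), 180.0))
        trans.append([box_side / 2 + c * separation, box_side / 2,
                      box_side / 2])
        rots.append([0.0, 0.0, 0.0, 1.0])
    conf = Conformation(phi, psi, omega, chi, np.array(trans),
                        np.array(rots), box_side)
    return SystemState(seqs, conf)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def helix12():
    return make_state(["A" * 12], [( -57.0, -47.0)])


@pytest.fixture
def gly5():
    return make_state(["G" * 5], [(-150.0, 150.0)])
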