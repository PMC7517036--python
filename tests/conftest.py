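import math

import numpy as np
import pytest

from gazechannel import ChainSpec, make_grid_partition


@pytest.fixture
def grid33():
    """The 9-AOI grid on a full-HD stimulus."""
    return make_grid_partition(3, 3, 1920, 1080)


@pytest.fixture
def chain3():
    """An ergodic 3-state chain with known transition matrix."""
    P = np.array([[0.7, 0.2, 0.1],
                  [0.3, 0.5, 0.2],
                  [0.1, 0.3, 0.6]])
    return ChainSpec(P=P, pi0=np.full(3, 1 / 3), n_fix=2000, seed=1234)


def brute_channel_measures(C, log_base=2.0):
    """Term-by-term Shannon measures of a count matrix.

    Independent oracle: every sum is written out directly from the joint
    and marginal frequencies with scalar ``math.log`` — no shared code
    with the implementation. The joint entropy is computed straight from
    the joint distribution rather than as Hs + Ht, and the mutual
    information straight from the p(i,j) log p(i,j)/(p_i q_j) sum.
    """
    C = np.asarray(C, dtype=float)
    s = C.shape[0]
    N = C.sum()
    Ni = C.sum(axis=1)
    Nj = C.sum(axis=0)
    pi = Ni / N
    q = Nj / N

    def lg(v):
        return math.log(v, log_base)

    Hs = -sum(pi[i] * lg(pi[i]) for i in range(s) if pi[i] > 0)
    HY = -sum(q[j] * lg(q[j]) for j in range(s) if q[j] > 0)
    Ht = 0.0
    for i in range(s):
        if Ni[i] == 0:
            continue
        for j in range(s):
            if C[i, j] > 0:
                pij = C[i, j] / Ni[i]
                Ht -= pi[i] * pij * lg(pij)
    Hxy = -sum(
        (C[i, j] / N) * lg(C[i, j] / N)
        for i in range(s) for j in range(s) if C[i, j] > 0
    )
    I = sum(
        (C[i, j] / N) * lg((C[i, j] / N) / (pi[i] * q[j]))
        for i in range(s) for j in range(s) if C[i, j] > 0
    )
    return {"Hs": Hs, "Ht": Ht, "Hxy": Hxy, "HY": HY, "I": I}
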