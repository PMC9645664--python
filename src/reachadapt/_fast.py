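"""Optional numba-accelerated kernels.

Model 2 re-derives the feedback controller at every time step, which
makes the backward Riccati recursion the inner loop of session
simulations.  The JIT kernel below is algorithmically identical to
:func:`reachadapt.lqg.riccati_gains`; equivalence is asserted in the
test suite.  Falls back to the pure-numpy implementation when numba is
unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def riccati_gains_jit(A, B, Qs, R):
    """Backward Riccati pass; returns all gains L[t], t = 0..horizon-1."""
    n = A.shape[0]
    m = B.shape[1]
    horizon = Qs.shape[0] - 1
    L = np.zeros((horizon, m, n))
    S = Qs[horizon].copy()
    for t in range(horizon - 1, -1, -1):
        SB = S @ B
        G = R + B.T @ SB
        L[t] = np.linalg.solve(G, SB.T @ A)
        S = Qs[t] + A.T @ S @ (A - B @ L[t])
        S = 0.5 * (S + S.T)
    return L
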