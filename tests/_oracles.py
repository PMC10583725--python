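"""Independent oracles used by the test suite."""

import itertools

import numpy as np


def brute_force_qp(V, R, C, b, alpha_old):
    """Exhaustive active-set oracle for min ||R - V d|| s.t. C(a+d) >= b.

    Enumerates every subset of constraints as equalities, solves the
    KKT system, and keeps the best feasible stationary candidate.
    """
    h = b - C @ alpha_old
    p = V.shape[1]
    best, best_obj = None, np.inf
    for k in range(C.shape[0] + 1):
        for subset in itertools.combinations(range(C.shape[0]), k):
            A = C[list(subset)]
            K = np.block([[V.T @ V, A.T], [A, np.zeros((k, k))]])
            rhs = np.concatenate([V.T @ R, h[list(subset)]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            d = sol[:p]
            if np.all(C @ d >= h - 1e-9):
                obj = float(np.sum((R - V @ d) ** 2))
                if obj < best_obj - 1e-12:
                    best, best_obj = d, obj
    return best
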