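"""Compiled inner loop of the coupled gain solver.

The coordinate-descent solver spends its time in many short 8x8 matrix
recursions; this module provides a numba-compiled implementation of the full
iteration.  `reachofc.lqg` falls back to the pure-numpy passes when numba is
not installed, and the test suite asserts both paths agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def coupled_solve(A, B, H, c2, Om_obs, Q, R, x0, tol, max_iter):
    """Alternate control and estimator sweeps until the gains are stationary.

    Returns (L, K, iterations, delta, converged).  Mirrors
    ``lqg._control_pass`` / ``lqg._estimator_pass`` exactly.
    """
    n = A.shape[0]
    m = B.shape[1]
    k = H.shape[0]
    N = R.shape[0]

    L = np.zeros((N, m, n))
    K = np.zeros((N, n, k))
    L_prev = np.zeros((N, m, n))
    Im = np.eye(m)
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # ---- control pass (backward), K fixed ----
        S_x = Q[N].copy()
        S_e = np.zeros((n, n))
        for t in range(N - 1, -1, -1):
            BtS = B.T @ S_x
            G = R[t] * Im + BtS @ B
            if c2 > 0.0:
                M = B.T @ (S_x + S_e) @ B
                tr = 0.0
                for i in range(m):
                    tr += M[i, i]
                G = G + c2 * tr * Im
            L[t] = np.linalg.solve(G, BtS @ A)
            AKH = A - K[t] @ H
            S_e_new = A.T @ S_x @ B @ L[t] + AKH.T @ S_e @ AKH
            S_x_new = Q[t] + A.T @ S_x @ (A - B @ L[t])
            S_x = 0.5 * (S_x_new + S_x_new.T)
            S_e = 0.5 * (S_e_new + S_e_new.T)

        # ---- estimator pass (forward), L fixed ----
        Sig_e = np.zeros((n, n))
        Sig_xh = np.outer(x0, x0)
        Sig_xe = np.zeros((n, n))
        dK = 0.0
        maxK = 0.0
        for t in range(N):
            Mio = H @ Sig_e @ H.T + Om_obs
            tr_io = 0.0
            for i in range(k):
                tr_io += Mio[i, i]
            # ridge keeps the solve defined for noiseless channels (K -> 0)
            for i in range(k):
                Mio[i, i] += 1e-14 * (1.0 + tr_io)
            K_new = np.linalg.solve(Mio.T, (A @ Sig_e @ H.T).T).T
            d = np.max(np.abs(K_new - K[t]))
            if d > dK:
                dK = d
            mk = np.max(np.abs(K_new))
            if mk > maxK:
                maxK = mk
            K[t] = K_new
            AKH = A - K_new @ H
            ABL = A - B @ L[t]
            Sig_e_new = AKH @ Sig_e @ A.T
            if c2 > 0.0:
                M = L[t] @ Sig_xh @ L[t].T
                tr = 0.0
                for i in range(m):
                    tr += M[i, i]
                Sig_e_new = Sig_e_new + c2 * tr * (B @ B.T)
            cross = ABL @ Sig_xe @ H.T @ K_new.T
            Sig_xh_new = K_new @ H @ Sig_e @ A.T + ABL @ Sig_xh @ ABL.T + cross + cross.T
            Sig_xe = ABL @ Sig_xe @ AKH.T
            Sig_e = 0.5 * (Sig_e_new + Sig_e_new.T)
            Sig_xh = 0.5 * (Sig_xh_new + Sig_xh_new.T)

        dL = np.max(np.abs(L - L_prev))
        maxL = np.max(np.abs(L))
        delta = max(dL / max(1.0, maxL), dK / max(1.0, maxK))
        L_prev[:] = L
        if delta < tol:
            return L, K, it, delta, True
    return L, K, it, delta, False
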