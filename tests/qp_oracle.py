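"""Independent brute-force oracle for the per-frame redundancy QP.

Enumerates every assignment of the box constraints' active set (each
muscle at its lower bound, at its upper bound, or free), solves the
resulting unconstrained quadratic in the free forces with the reserves
eliminated, and keeps the feasible candidate with the smallest objective.
The global optimum of the convex QP has *some* active set, so it appears
among the candidates.  Exponential in the muscle count — for small test
problems only — and entirely independent of the dual Newton solver.
"""

import itertools

import numpy as np

LOWER, UPPER, FREE = 0, 1, 2


def brute_force_qp(A, b, f_iso, muscle_w, reserve_w):
    """Return (objective, forces, reserves) of the global optimum."""
    n_j, n_m = A.shape
    best = (np.inf, None, None)
    for combo in itertools.product((LOWER, UPPER, FREE), repeat=n_m):
        combo = np.array(combo)
        f = np.where(combo == UPPER, f_iso, 0.0).astype(float)
        free = combo == FREE
        rhs = b - A[:, ~free] @ f[~free]
        Af = A[:, free]
        # minimize sum (x/w)^2 + ||(rhs - Af x)/wr||^2 over free x
        Wf = muscle_w[free]
        H = 2.0 * np.diag(1.0 / Wf**2) + (2.0 / reserve_w**2) * (Af.T @ Af)
        g = (2.0 / reserve_w**2) * (Af.T @ rhs)
        if free.any():
            try:
                x = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                continue
            if np.any(x < -1e-9) or np.any(x > f_iso[free] + 1e-9):
                continue
            f[free] = np.clip(x, 0.0, f_iso[free])
        r = rhs - Af @ f[free] if free.any() else rhs
        obj = float(np.sum((f / muscle_w) ** 2) + np.sum((r / reserve_w) ** 2))
        if obj < best[0]:
            best = (obj, f, r)
    return best


def random_frame_problem(rng):
    """A random 1-2-joint, 2-4-muscle instance with plausible scales."""
    n_j = int(rng.integers(1, 3))
    n_m = int(rng.integers(2, 5))
    A = np.zeros((n_j, n_m))
    for i in range(n_m):
        joints = rng.choice(n_j, size=int(rng.integers(1, n_j + 1)), replace=False)
        A[joints, i] = rng.uniform(0.02, 0.1, joints.size) * rng.choice([-1.0, 1.0], joints.size)
    # guarantee every joint is spanned by at least one muscle
    for j in range(n_j):
        if not np.any(A[j]):
            A[j, rng.integers(0, n_m)] = rng.uniform(0.02, 0.1) * rng.choice([-1.0, 1.0])
    f_iso = rng.uniform(300.0, 3000.0, n_m)
    b = rng.uniform(-60.0, 60.0, n_j)
    return A, b, f_iso, f_iso.copy(), 1.0
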