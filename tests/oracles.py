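"""Independent brute-force oracles for tests.

The TM-score oracle maximises the score directly by numerical optimisation
over the six rigid-body degrees of freedom (rotation vector + translation),
multi-started from a rotation grid and from Kabsch superpositions on every
contiguous fragment.  It shares no code path with the iterative-inclusion
search in the package.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def tm_d0_oracle(L: int) -> float:
    d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8 if L > 15 else 0.5
    return max(d0, 0.5)


def _tm_at(params, Q, R, d0, L):
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    moved = Q @ rot.T + params[3:]
    d2 = np.sum((moved - R) ** 2, axis=1)
    return np.sum(1.0 / (1.0 + d2 / d0**2)) / L


def _kabsch_params(P, Q):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    rot = Vt.T @ D @ U.T
    return np.concatenate([Rotation.from_matrix(rot).as_rotvec(), qc - rot @ pc])


def tm_score_oracle(Q: np.ndarray, R: np.ndarray, L_norm: int) -> float:
    """Maximum TM-score of aligned coordinate arrays over rigid transforms."""
    d0 = tm_d0_oracle(L_norm)
    n = len(Q)
    starts = []
    # Kabsch superpositions on contiguous fragments (all offsets, len >= 4)
    for frag in range(4, n + 1, 2):
        for s in range(0, n - frag + 1, 2):
            idx = slice(s, s + frag)
            starts.append(_kabsch_params(Q[idx], R[idx]))
    # rotation grid (octahedral group + random), centroid-matched translation
    qc, rc = Q.mean(axis=0), R.mean(axis=0)
    grid = list(Rotation.create_group("O")) + list(
        Rotation.random(40, random_state=0)
    )
    for rot in grid:
        m = rot.as_matrix()
        starts.append(np.concatenate([rot.as_rotvec(), rc - m @ qc]))
    best = -np.inf
    for p0 in starts:
        res = minimize(
            lambda p: -_tm_at(p, Q, R, d0, L_norm),
            p0,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-10},
        )
        best = max(best, -res.fun)
    return float(best)
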