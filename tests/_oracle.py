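"""Brute-force mapping oracle, independent of the package's Kabsch path.

Enumerates every kind-compatible injective correspondence with itertools,
finds the least-squares rigid alignment by direct numerical minimization
over rotation vectors (multi-start Nelder-Mead; translation in closed form),
and applies the same feasibility rule and fit formula as the contract:
every mapped displacement within its tolerance, fit = Σ w(1 − (d/tol)²).
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _aligned_displacements(P, Q, w, n_starts=24, seed=0):
    """Displacements |P - (R Q + t)| at the numerically optimal weighted
    rigid superposition of Q onto P."""
    wn = np.asarray(w, dtype=float)
    wn = wn / wn.sum()
    rng = np.random.default_rng(seed)

    def ssd(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        t = wn @ P - (wn @ Q) @ R.T
        diff = P - (Q @ R.T + t)
        return float(np.sum(wn * np.sum(diff * diff, axis=1)))

    best = None
    starts = [np.zeros(3)] + [Rotation.random(random_state=rng).as_rotvec()
                              for _ in range(n_starts)]
    for x0 in starts:
        res = minimize(ssd, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    R = Rotation.from_rotvec(best.x).as_matrix()
    t = wn @ P - (wn @ Q) @ R.T
    return np.linalg.norm(P - (Q @ R.T + t), axis=1)


def brute_force_best_mapping(points, hypo, max_omitted=0):
    """(fit, correspondence) of the best feasible mapping, or None."""
    k = len(hypo.features)
    centers = hypo.centers
    tols = hypo.tolerances
    weights = hypo.weights
    feat_kinds = [f.kind for f in hypo.features]
    pts = np.array([p.xyz for p in points]) if points else np.zeros((0, 3))
    pt_kinds = [p.kind for p in points]
    n = len(points)

    best = None  # (-fit, rmsd, lexkey, corr)
    options = [
        [p for p in range(n) if pt_kinds[p] == feat_kinds[i]] + [None]
        for i in range(k)
    ]
    for corr in itertools.product(*options):
        mapped = [(i, c) for i, c in enumerate(corr) if c is not None]
        used = [c for _, c in mapped]
        if len(set(used)) != len(used):
            continue
        omitted = k - len(mapped)
        if omitted > max_omitted or not mapped:
            continue
        P = centers[[i for i, _ in mapped]]
        Q = pts[used]
        w = weights[[i for i, _ in mapped]]
        tol = tols[[i for i, _ in mapped]]
        d = _aligned_displacements(P, Q, w)
        if np.any(d > tol + 1e-9):
            continue
        fit = float(np.sum(w * np.maximum(0.0, 1.0 - (d / tol) ** 2)))
        rmsd = float(np.sqrt(np.sum(w * d**2) / w.sum()))
        key = (-fit, rmsd, tuple(-1 if c is None else c for c in corr))
        if best is None or key < best[:3]:
            best = (*key, corr)
    if best is None:
        return None
    return -best[0], best[3]
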