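"""3D pharmacophore features, rigid alignment, and fit-value scoring.

A pharmacophore hypothesis is a set of at most five typed feature spheres
(hydrogen-bond donor HBD, acceptor HBA, hydrophobic HBic, ring-aromatic
RingArom), each with a center, a tolerance radius (Å) and a weight.  A
molecule maps the hypothesis when a kind-compatible, injective assignment of
its perceived feature points to the hypothesis features exists such that,
after an optimal weighted rigid superposition, every mapped point lies
inside its feature's tolerance sphere.  The fit value of a mapping is

    fit = sum over mapped features of  w_f * (1 - (d_f / tol_f)^2)

where d_f is the post-alignment displacement; it is bounded by the summed
weights and reaches the bound only for a perfect superposition.  Feature
directionality (donor vectors, aromatic normals) is perceived but not
scored: this is a distance-only model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .chemio import ConformerSet

__all__ = [
    "FeatureKind",
    "FeaturePoint",
    "PharmFeature",
    "Pharmacophore",
    "FitLine",
    "MappingResult",
    "MAX_FEATURES",
    "DEFAULT_TOLERANCE",
    "fit_value",
    "perceive_features",
    "kabsch_align",
    "map_conformer",
    "best_fit",
    "read_pharmacophore",
    "write_pharmacophore",
]

MAX_FEATURES = 5
DEFAULT_TOLERANCE = 1.6


def fit_value(displacements, tolerances, weights) -> float:
    """fit = Σ w_f · max(0, 1 − (d_f/tol_f)²) over mapped features.

    A displacement at exactly its tolerance contributes nothing; a perfect
    superposition scores the full summed weight.
    """
    d = np.asarray(displacements, dtype=float)
    tol = np.asarray(tolerances, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * np.maximum(0.0, 1.0 - (d / tol) ** 2)))


class FeatureKind(str, Enum):
    HBD = "HBD"
    HBA = "HBA"
    HBIC = "HBic"
    RING_AROM = "RingArom"


@dataclass(frozen=True)
class FeaturePoint:
    """A perceived chemical feature on one conformer."""

    kind: FeatureKind
    position: tuple[float, float, float]
    atom_indices: tuple[int, ...] = ()
    direction: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in self.position):
            raise ValueError("feature position must be finite")
        if self.direction is not None:
            norm = math.sqrt(sum(x * x for x in self.direction))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"direction must be unit norm, got |v| = {norm}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class PharmFeature:
    """One toleranced, weighted hypothesis feature sphere."""

    kind: FeatureKind
    center: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        self.center = tuple(float(x) for x in self.center)
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class FitLine:
    """Linear map from fit value to predicted pIC50."""

    slope: float
    intercept: float

    def __call__(self, fit: float) -> float:
        return self.slope * fit + self.intercept


@dataclass
class Pharmacophore:
    """A quantitative hypothesis: features plus an optional fit→activity line."""

    features: list[PharmFeature] = field(default_factory=list)
    fit_line: Optional[FitLine] = None
    costs: Optional[object] = None  # CostReport, attached by hypogen
    train_r: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.features) > MAX_FEATURES:
            raise ValueError(
                f"hypothesis has {len(self.features)} features; maximum is {MAX_FEATURES}"
            )

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.xyz for f in self.features], dtype=float)

    @property
    def tolerances(self) -> np.ndarray:
        return np.array([f.tolerance for f in self.features], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features], dtype=float)

    @property
    def total_weight(self) -> float:
        return float(sum(f.weight for f in self.features))

    def kind_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(f.kind.value for f in self.features))


@dataclass
class MappingResult:
    """One molecule↔hypothesis correspondence with alignment and fit value."""

    molecule_id: str
    conformer_index: int
    correspondence: tuple[Optional[int], ...]  # per hypothesis feature: point index or None
    fit: float
    rmsd: float
    omitted_count: int
    rotation: Optional[np.ndarray] = None
    translation: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# feature perception

# The shipped perception dictionary lives in _smarts (shared with descriptor
# counting).  Aromatic carbons are expressed through RingArom, not HBic.
from ._smarts import HBA_SMARTS, HBD_SMARTS, HBIC_ATOM_SMARTS  # noqa: E402


def _conf_coords(mol: Chem.Mol, coords, conf_id: int) -> np.ndarray:
    if coords is not None:
        return np.asarray(coords, dtype=float)
    if mol.GetNumConformers() == 0:
        raise ValueError("no 3D coordinates: molecule has no conformer")
    return np.array(mol.GetConformer(conf_id).GetPositions(), dtype=float)


def perceive_features(
    mol: Chem.Mol, coords: Optional[np.ndarray] = None, conf_id: int = 0
) -> list[FeaturePoint]:
    """Perceive typed feature points on one conformer of a molecule.

    Donors and acceptors sit on their heavy atom (donors carry the
    heavy-atom→H direction when resolvable), ring-aromatic features at the
    aromatic-ring centroid with the ring normal, hydrophobic features at the
    centroid of each contiguous apolar atom cluster.
    """
    xyz = _conf_coords(mol, coords, conf_id)
    points: list[FeaturePoint] = []

    def _matches(smarts_list) -> set[int]:
        atoms: set[int] = set()
        for smarts in smarts_list:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                atoms.add(match[0])
        return atoms

    for idx in sorted(_matches(HBD_SMARTS)):
        atom = mol.GetAtomWithIdx(idx)
        direction = None
        h_neighbors = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        if h_neighbors:
            v = xyz[h_neighbors[0]] - xyz[idx]
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                direction = tuple(v / norm)
        points.append(
            FeaturePoint(
                kind=FeatureKind.HBD,
                position=tuple(xyz[idx]),
                atom_indices=(idx,),
                direction=direction,
            )
        )

    for idx in sorted(_matches(HBA_SMARTS)):
        points.append(
            FeaturePoint(
                kind=FeatureKind.HBA, position=tuple(xyz[idx]), atom_indices=(idx,)
            )
        )

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            ring_xyz = xyz[list(ring)]
            centroid = ring_xyz.mean(axis=0)
            centered = ring_xyz - centroid
            _, _, vt = np.linalg.svd(centered)
            normal = vt[2]
            normal = normal / np.linalg.norm(normal)
            points.append(
                FeaturePoint(
                    kind=FeatureKind.RING_AROM,
                    position=tuple(centroid),
                    atom_indices=tuple(sorted(ring)),
                    direction=tuple(normal),
                )
            )

    hbic_atoms = sorted(_matches((HBIC_ATOM_SMARTS,)))
    if hbic_atoms:
        remaining = set(hbic_atoms)
        while remaining:
            seed_atom = min(remaining)
            cluster = {seed_atom}
            frontier = [seed_atom]
            while frontier:
                a = frontier.pop()
                for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                    j = nb.GetIdx()
                    if j in remaining and j not in cluster:
                        cluster.add(j)
                        frontier.append(j)
            remaining -= cluster
            members = sorted(cluster)
            centroid = xyz[members].mean(axis=0)
            points.append(
                FeaturePoint(
                    kind=FeatureKind.HBIC,
                    position=tuple(centroid),
                    atom_indices=tuple(members),
                )
            )

    return points


# ---------------------------------------------------------------------------
# rigid superposition


def kabsch_align(
    P: np.ndarray, Q: np.ndarray, weights: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted proper rigid superposition of points Q onto targets P.

    Returns (R, t, rmsd) with det(R) = +1 minimizing
    sum_i w_i |P_i - (R Q_i + t)|^2; rmsd is the weighted RMSD at the optimum.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 1:
        raise ValueError(f"point sets must both be (n, 3) with n >= 1, got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    pc = wn @ P
    qc = wn @ Q
    H = (Q - qc).T @ ((P - pc) * wn[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt(np.sum(wn * np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def _batch_kabsch(P: np.ndarray, Q: np.ndarray, W: np.ndarray):
    """Vectorized weighted Kabsch over a stack of correspondences.

    P, Q: (N, m, 3); W: (N, m).  Returns (R (N,3,3), t (N,3), disp (N,m)).
    """
    wsum = W.sum(axis=1, keepdims=True)
    wn = W / wsum
    pc = np.einsum("nm,nmk->nk", wn, P)
    qc = np.einsum("nm,nmk->nk", wn, Q)
    Pc = P - pc[:, None, :]
    Qc = Q - qc[:, None, :]
    H = np.einsum("nmi,nmj->nij", Qc * wn[:, :, None], Pc)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,nkj->nik", Vt.transpose(0, 2, 1), U))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = np.where(det == 0, 1.0, np.sign(det))
    R = np.einsum("nji,njk,nlk->nil", Vt, D, U)
    t = pc - np.einsum("nij,nj->ni", R, qc)
    aligned = np.einsum("nij,nmj->nmi", R, Q) + t[:, None, :]
    disp = np.linalg.norm(P - aligned, axis=2)
    return R, t, disp


# ---------------------------------------------------------------------------
# correspondence search


def _enumerate_correspondences(
    centers: np.ndarray,
    tols: np.ndarray,
    feat_kinds: list[FeatureKind],
    pts: np.ndarray,
    pt_kinds: list[FeatureKind],
    max_omitted: int,
) -> list[tuple[Optional[int], ...]]:
    """Kind-compatible injective assignments with distance-compatibility pruning.

    A partial assignment survives only while every mapped pair (i, j) obeys
    |d_model(i,j) - d_points(i,j)| <= tol_i + tol_j.
    """
    k = len(feat_kinds)
    n = len(pt_kinds)
    candidates = [
        [p for p in range(n) if pt_kinds[p] == feat_kinds[i]] for i in range(k)
    ]
    # cheap global feasibility: every feature must be mappable or omittable
    shortfall = sum(1 for c in candidates if not c)
    if shortfall > max_omitted:
        return []
    d_model = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    d_pts = (
        np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        if n
        else np.zeros((0, 0))
    )
    tol_pair = tols[:, None] + tols[None, :]
    out: list[tuple[Optional[int], ...]] = []
    assign: list[Optional[int]] = [None] * k
    used = [False] * n

    def recurse(i: int, omitted: int) -> None:
        if i == k:
            if omitted < k:  # at least one mapped feature
                out.append(tuple(assign))
            return
        if omitted < max_omitted:
            assign[i] = None
            recurse(i + 1, omitted + 1)
            assign[i] = None
        for p in candidates[i]:
            if used[p]:
                continue
            ok = True
            for j in range(i):
                q = assign[j]
                if q is None:
                    continue
                if abs(d_model[j, i] - d_pts[q, p]) > tol_pair[j, i]:
                    ok = False
                    break
            if ok:
                assign[i] = p
                used[p] = True
                recurse(i + 1, omitted)
                used[p] = False
                assign[i] = None

    recurse(0, 0)
    return out


def _as_points(conformer) -> list[FeaturePoint]:
    if isinstance(conformer, (list, tuple)) and (
        len(conformer) == 0 or isinstance(conformer[0], FeaturePoint)
    ):
        return list(conformer)
    raise TypeError("expected a sequence of FeaturePoint")


def map_conformer(
    points: Sequence[FeaturePoint],
    hypo: Pharmacophore,
    max_omitted: int = 0,
    molecule_id: str = "",
    conformer_index: int = 0,
    refine: bool = False,
) -> Optional[MappingResult]:
    """Best feasible mapping of one conformer's feature points onto a hypothesis.

    Enumerates kind-compatible injective correspondences (allowing up to
    ``max_omitted`` omissions), prunes by pairwise-distance compatibility,
    aligns each by weighted Kabsch, discards correspondences with any
    post-alignment displacement above its tolerance, and returns the
    correspondence maximizing the fit value.  Ties break on lower RMSD then
    lexicographic correspondence.  Returns None when nothing maps (NO_MATCH).

    With ``refine=True`` a fit-optimal re-alignment (weights w/tol²) is also
    evaluated for each correspondence and the better feasible result kept.
    """
    if max_omitted < 0:
        raise ValueError(f"max_omitted must be >= 0, got {max_omitted}")
    if not hypo.features:
        raise ValueError("hypothesis has no features")
    points = _as_points(points)
    k = len(hypo.features)
    centers = hypo.centers
    tols = hypo.tolerances
    weights = hypo.weights
    feat_kinds = [f.kind for f in hypo.features]
    pts = (
        np.array([p.xyz for p in points], dtype=float)
        if points
        else np.zeros((0, 3))
    )
    pt_kinds = [p.kind for p in points]
    corrs = _enumerate_correspondences(
        centers, tols, feat_kinds, pts, pt_kinds, min(max_omitted, k - 1)
    )
    if not corrs:
        return None

    # group by mapped-feature count for batched alignment
    best: Optional[tuple] = None  # (-fit, rmsd, lexkey, corr, R, t, omitted)
    by_size: dict[int, list[tuple[Optional[int], ...]]] = {}
    for corr in corrs:
        m = sum(1 for c in corr if c is not None)
        by_size.setdefault(m, []).append(corr)

    # descending mapped count: a group whose total mappable weight cannot beat
    # the best fit found so far is skipped outright (fit <= sum of weights)
    for m in sorted(by_size, reverse=True):
        group = by_size[m]
        feat_idx = np.array(
            [[i for i, c in enumerate(corr) if c is not None] for corr in group],
            dtype=np.intp,
        )
        pt_idx = np.array(
            [[c for c in corr if c is not None] for corr in group], dtype=np.intp
        )
        Wstack = weights[feat_idx]
        if best is not None and float(Wstack.sum(axis=1).max()) < -best[0] - 1e-12:
            continue
        Pstack = centers[feat_idx]
        Qstack = pts[pt_idx]
        Tstack = tols[feat_idx]
        passes = [Wstack] if not refine else [Wstack, Wstack / Tstack**2]
        for Walign in passes:
            if np.any(Walign.sum(axis=1) <= 0):
                continue
            R, t, disp = _batch_kabsch(Pstack, Qstack, Walign)
            feasible = np.all(disp <= Tstack + 1e-12, axis=1)
            if not feasible.any():
                continue
            ratio2 = (disp / Tstack) ** 2
            fits = np.sum(Wstack * np.maximum(0.0, 1.0 - ratio2), axis=1)
            wsum = Wstack.sum(axis=1)
            rmsd = np.sqrt(np.sum(Wstack * disp**2, axis=1) / np.where(wsum > 0, wsum, 1.0))
            idx = np.nonzero(feasible)[0]
            order = np.lexsort((rmsd[idx], -fits[idx]))
            # resolve exact (-fit, rmsd) ties lexicographically on the correspondence
            top = idx[order[0]]
            tie = idx[(fits[idx] == fits[top]) & (rmsd[idx] == rmsd[top])]
            g = min(
                tie,
                key=lambda g: tuple(-1 if c is None else c for c in group[g]),
            )
            key = (-fits[g], rmsd[g], tuple(-1 if c is None else c for c in group[g]))
            if best is None or key < (best[0], best[1], best[2]):
                best = (*key, group[g], R[g].copy(), t[g].copy(), k - m)
    if best is None:
        return None
    _, rmsd, _, corr, R, t, omitted = best
    return MappingResult(
        molecule_id=molecule_id,
        conformer_index=conformer_index,
        correspondence=corr,
        fit=float(-best[0]),
        rmsd=float(rmsd),
        omitted_count=int(omitted),
        rotation=R,
        translation=t,
    )


def best_fit(
    cs,
    hypo: Pharmacophore,
    mode: str = "fast",
    max_omitted: int = 0,
    molecule_id: Optional[str] = None,
) -> Optional[MappingResult]:
    """Maximum-fit mapping across a conformer ensemble.

    ``cs`` may be a chemio.ConformerSet (features are perceived per
    conformer) or a sequence of per-conformer FeaturePoint lists (abstract
    pseudo-ligands).  mode="fast" scores stored conformers as-is;
    mode="best" additionally refines each candidate alignment for fit.
    """
    if mode not in ("fast", "best"):
        raise ValueError(f"mode must be 'fast' or 'best', got {mode!r}")
    refine = mode == "best"
    if isinstance(cs, ConformerSet):
        if cs.mol is None:
            raise ValueError(f"{cs.molecule_id}: ensemble lacks structure for perception")
        point_sets = [perceive_features(cs.mol, coords=xyz) for xyz in cs.conformers]
        mol_id = molecule_id or cs.molecule_id
    else:
        point_sets = [_as_points(c) for c in cs]
        mol_id = molecule_id or ""
    if not point_sets:
        raise ValueError("empty conformer set")
    best: Optional[MappingResult] = None
    for idx, pts in enumerate(point_sets):
        res = map_conformer(
            pts,
            hypo,
            max_omitted=max_omitted,
            molecule_id=mol_id,
            conformer_index=idx,
            refine=refine,
        )
        if res is None:
            continue
        if best is None or (-res.fit, res.rmsd, res.conformer_index) < (
            -best.fit,
            best.rmsd,
            best.conformer_index,
        ):
            best = res
    return best


# ---------------------------------------------------------------------------
# model file I/O (JSON schema)


def write_pharmacophore(hypo: Pharmacophore, path) -> None:
    payload = {
        "features": [
            {
                "kind": f.kind.value,
                "center": list(f.center),
                "tolerance": f.tolerance,
                "weight": f.weight,
            }
            for f in hypo.features
        ],
        "fit_line": (
            {"slope": hypo.fit_line.slope, "intercept": hypo.fit_line.intercept}
            if hypo.fit_line
            else None
        ),
        "costs": _costs_to_dict(hypo.costs),
        "train_r": hypo.train_r,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _costs_to_dict(costs):
    if costs is None:
        return None
    from dataclasses import asdict, is_dataclass

    if is_dataclass(costs):
        return asdict(costs)
    return dict(costs)


def read_pharmacophore(path) -> Pharmacophore:
    with open(path) as fh:
        payload = json.load(fh)
    if "features" not in payload:
        raise ValueError("pharmacophore file: missing field 'features'")
    feats = []
    for i, f in enumerate(payload["features"]):
        for key in ("kind", "center"):
            if key not in f:
                raise ValueError(f"pharmacophore file: feature {i} missing field {key!r}")
        try:
            kind = FeatureKind(f["kind"])
        except ValueError:
            raise ValueError(f"pharmacophore file: feature {i} has unknown kind {f['kind']!r}")
        feats.append(
            PharmFeature(
                kind=kind,
                center=tuple(f["center"]),
                tolerance=float(f.get("tolerance", DEFAULT_TOLERANCE)),
                weight=float(f.get("weight", 1.0)),
            )
        )
    fit_line = None
    if payload.get("fit_line") is not None:
        fl = payload["fit_line"]
        for key in ("slope", "intercept"):
            if key not in fl:
                raise ValueError(f"pharmacophore file: fit_line missing field {key!r}")
        fit_line = FitLine(slope=float(fl["slope"]), intercept=float(fl["intercept"]))
    costs = payload.get("costs")
    if costs is not None:
        from .hypogen import CostReport

        costs = CostReport(**costs)
    return Pharmacophore(
        features=feats,
        fit_line=fit_line,
        costs=costs,
        train_r=payload.get("train_r"),
    )
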