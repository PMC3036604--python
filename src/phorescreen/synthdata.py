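"""Seeded generators for planted-pharmacophore benchmarks.

Pseudo-ligands are abstract typed feature-point sets — chemistry-free
carriers that exercise mapping, hypothesis generation, and screening without
conformer embedding.  A *planted* benchmark starts from a known ground-truth
pharmacophore: actives are jittered copies of its feature points plus
distractor points under a random rigid motion, decoys are property-matched
point sets (same point count and spatial extent) with shuffled kinds and
geometry, resampled until they do not fully map the truth.

Simulated activities follow the same generative law the quantitative model
assumes: pIC50 = slope·fit + intercept + Gaussian noise, where fit is the
ligand's best fit value against the planted truth.  Training sets are drawn
in feature-completeness classes (0–4 planted features removed), emulating a
potency gradient in which weaker binders engage fewer pharmacophore sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemio import DescriptorSet, MoleculeRecord
from .hypogen import TrainingItem, TrainingSet
from .pharmacophore import (
    DEFAULT_TOLERANCE,
    FeatureKind,
    FeaturePoint,
    PharmFeature,
    Pharmacophore,
    best_fit,
)

__all__ = [
    "PseudoLigand",
    "PlantedBenchmark",
    "DEFAULT_KIND_WEIGHTS",
    "make_pharmacophore",
    "make_actives",
    "make_decoys",
    "simulate_activities",
    "make_benchmark",
    "make_training_ligands",
    "make_training_set",
    "random_rigid_transform",
]

DEFAULT_KIND_WEIGHTS = {
    FeatureKind.HBIC: 0.45,
    FeatureKind.HBD: 0.2,
    FeatureKind.HBA: 0.2,
    FeatureKind.RING_AROM: 0.15,
}

#: default distractor count for benchmark ligands; rich enough that an
#: arbitrary five-feature query retrieves a few percent of the library,
#: the order of magnitude of real screens on decoy-matched databases
BENCHMARK_DISTRACTORS = 10


@dataclass
class PseudoLigand:
    """An abstract ligand: one or more conformers given as feature-point sets."""

    id: str
    conformers: list[list[FeaturePoint]]
    descriptors: Optional[DescriptorSet] = None
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"pseudo-ligand {self.id!r} needs at least one conformer")


@dataclass
class PlantedBenchmark:
    """A labeled screening library with its ground-truth pharmacophore."""

    library: list[PseudoLigand]
    truth: Pharmacophore
    generator_params: dict = field(default_factory=dict)

    @property
    def actives(self) -> list[PseudoLigand]:
        return [l for l in self.library if l.role == "active"]

    @property
    def decoys(self) -> list[PseudoLigand]:
        return [l for l in self.library if l.role == "decoy"]


# ---------------------------------------------------------------------------
# primitives


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 20.0):
    """A uniformly random proper rotation (quaternion method) and translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, 3)
    return R, t


def _sample_kind(rng: np.random.Generator, kind_weights: dict) -> FeatureKind:
    kinds = list(kind_weights)
    probs = np.array([kind_weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    return kinds[int(rng.choice(len(kinds), p=probs))]


def _random_descriptors(rng: np.random.Generator) -> DescriptorSet:
    """Drug-like descriptor records for the rule-of-five stage."""
    return DescriptorSet(
        mw=float(rng.uniform(250.0, 480.0)),
        logp=float(rng.uniform(0.5, 4.5)),
        hbd_count=int(rng.integers(0, 5)),
        hba_count=int(rng.integers(1, 9)),
    )


def make_pharmacophore(
    n_features: int,
    kinds: Optional[Sequence[FeatureKind]] = None,
    kind_weights: Optional[dict] = None,
    seed: int = 0,
    tolerance: float = DEFAULT_TOLERANCE,
    weight: float = 1.0,
    box: float = 10.0,
    max_tries: int = 5000,
) -> Pharmacophore:
    """A random hypothesis with pairwise center separation ≥ 2×tolerance."""
    if not (1 <= n_features <= 5):
        raise ValueError(f"n_features must be in [1, 5], got {n_features}")
    rng = np.random.default_rng(seed)
    if kinds is not None:
        if len(kinds) != n_features:
            raise ValueError("kinds must have length n_features")
        chosen = [FeatureKind(k) for k in kinds]
    else:
        kw = kind_weights or DEFAULT_KIND_WEIGHTS
        chosen = [_sample_kind(rng, kw) for _ in range(n_features)]
    min_sep = 2.0 * tolerance
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_features:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_features} centers with separation >= {min_sep} Å "
                f"in a {box} Å box after {max_tries} tries"
            )
        cand = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    feats = [
        PharmFeature(kind=k, center=tuple(c), tolerance=tolerance, weight=weight)
        for k, c in zip(chosen, centers)
    ]
    return Pharmacophore(features=feats)


def _planted_points(
    truth: Pharmacophore,
    rng: np.random.Generator,
    jitter_sd: float,
    n_distractors: int,
    omit: Sequence[int] = (),
    box_pad: float = 3.0,
) -> list[FeaturePoint]:
    """Jittered copies of the truth's features (minus ``omit``) + distractors.

    Distractors stay at least 2×tolerance from every truth center (in the
    ligand frame) so they cannot stand in for an omitted planted feature.
    """
    centers = truth.centers
    tols = truth.tolerances
    points: list[FeaturePoint] = []
    for i, f in enumerate(truth.features):
        if i in omit:
            continue
        pos = centers[i] + rng.normal(0.0, jitter_sd, 3)
        points.append(FeaturePoint(kind=f.kind, position=tuple(pos)))
    lo = centers.min(axis=0) - box_pad
    hi = centers.max(axis=0) + box_pad
    min_sep = 2.0 * float(tols.max())
    placed = 0
    tries = 0
    while placed < n_distractors:
        tries += 1
        if tries > 200 * max(1, n_distractors):
            break  # crowded box; accept fewer distractors
        pos = rng.uniform(lo, hi)
        if all(np.linalg.norm(pos - c) >= min_sep for c in centers):
            points.append(
                FeaturePoint(kind=_sample_kind(rng, DEFAULT_KIND_WEIGHTS), position=tuple(pos))
            )
            placed += 1
    return points


def _apply_rigid(points: list[FeaturePoint], R: np.ndarray, t: np.ndarray) -> list[FeaturePoint]:
    out = []
    for p in points:
        pos = R @ p.xyz + t
        direction = None
        if p.direction is not None:
            direction = tuple(R @ np.asarray(p.direction))
        out.append(
            FeaturePoint(kind=p.kind, position=tuple(pos), atom_indices=p.atom_indices,
                         direction=direction)
        )
    return out


# ---------------------------------------------------------------------------
# generators


def make_actives(
    truth: Pharmacophore,
    n: int,
    jitter_sd: float = 0.4,
    seed: int = 0,
    n_distractors: int = BENCHMARK_DISTRACTORS,
    fit_threshold: Optional[float] = None,
    max_resample: int = 50,
    id_prefix: str = "active",
    with_descriptors: bool = True,
) -> list[PseudoLigand]:
    """Actives: jittered truth points + distractors under a random rigid motion.

    Every active is verified to map the truth in full with best_fit at least
    ``fit_threshold`` (default 70% of the truth's total weight); failing
    draws are resampled.
    """
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be >= 0, got {jitter_sd}")
    threshold = 0.7 * truth.total_weight if fit_threshold is None else fit_threshold
    rng = np.random.default_rng(seed)
    ligands: list[PseudoLigand] = []
    for i in range(n):
        for attempt in range(max_resample):
            points = _planted_points(truth, rng, jitter_sd, n_distractors)
            R, t = random_rigid_transform(rng)
            points = _apply_rigid(points, R, t)
            res = best_fit([points], truth, max_omitted=0)
            if res is not None and res.fit >= threshold:
                break
        else:
            raise ValueError(
                f"could not draw an active with fit >= {threshold:.2f} at jitter "
                f"{jitter_sd} Å after {max_resample} tries; use a smaller jitter_sd"
            )
        ligands.append(
            PseudoLigand(
                id=f"{id_prefix}-{i:04d}",
                conformers=[points],
                descriptors=_random_descriptors(rng) if with_descriptors else None,
                role="active",
            )
        )
    return ligands


def make_decoys(
    truth: Pharmacophore,
    n: int,
    seed: int = 0,
    n_points: Optional[int] = None,
    max_map_fraction: float = 0.05,
    max_resample: int = 50,
    id_prefix: str = "decoy",
    with_descriptors: bool = True,
    box: float = 10.0,
) -> list[PseudoLigand]:
    """Property-matched decoys: same point count and spatial statistics as
    actives, but a shuffled, independently drawn feature arrangement.

    Each decoy is built exactly like an active of its *own* random
    pharmacophore — a fresh well-separated core (truth kinds shuffled) plus
    distractors — so a generic query retrieves actives and decoys at
    comparable rates, while decoys are resampled until none fully maps the
    planted truth (the guaranteed rate is bounded by ``max_map_fraction``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    k = len(truth.features)
    if n_points is None:
        n_points = k + BENCHMARK_DISTRACTORS
    n_distractors = max(0, n_points - k)
    tolerance = float(truth.tolerances.max())
    kind_pool = [f.kind for f in truth.features]
    ligands: list[PseudoLigand] = []
    n_mapping = 0
    for i in range(n):
        for attempt in range(max_resample):
            kinds = [kind_pool[j] for j in rng.permutation(k)]
            fake = make_pharmacophore(
                k, kinds=kinds, seed=int(rng.integers(2**31)),
                tolerance=tolerance, box=box,
            )
            points = _planted_points(fake, rng, 0.0, n_distractors)
            R, t = random_rigid_transform(rng)
            points = _apply_rigid(points, R, t)
            if best_fit([points], truth, max_omitted=0) is None:
                break
        else:
            n_mapping += 1
            if n_mapping > max_map_fraction * n:
                raise ValueError(
                    f"could not keep the decoy→truth mapping rate <= "
                    f"{max_map_fraction:.0%} after {max_resample} resamples per decoy"
                )
        ligands.append(
            PseudoLigand(
                id=f"{id_prefix}-{i:04d}",
                conformers=[points],
                descriptors=_random_descriptors(rng) if with_descriptors else None,
                role="decoy",
            )
        )
    return ligands


def simulate_activities(
    truth: Pharmacophore,
    ligands: Sequence[PseudoLigand],
    slope: float = 1.3,
    intercept: float = 3.5,
    noise_sd: float = 0.3,
    seed: int = 0,
    max_omitted: Optional[int] = None,
) -> dict[str, float]:
    """pIC50 = slope·best_fit(ligand, truth) + intercept + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if max_omitted is None:
        max_omitted = len(truth.features) - 1
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for lig in ligands:
        res = best_fit(lig.conformers, truth, max_omitted=max_omitted)
        fit = 0.0 if res is None else res.fit
        out[lig.id] = slope * fit + intercept + float(rng.normal(0.0, noise_sd))
    return out


def make_benchmark(
    D: int,
    A: int,
    truth: Pharmacophore,
    seed: int = 0,
    jitter_sd: float = 0.4,
) -> PlantedBenchmark:
    """A labeled library of A planted actives and D−A matched decoys, shuffled."""
    if not (1 <= A < D):
        raise ValueError(f"need 1 <= A < D, got A={A}, D={D}")
    rng = np.random.default_rng(seed)
    actives = make_actives(truth, A, jitter_sd=jitter_sd, seed=int(rng.integers(2**31)))
    decoys = make_decoys(truth, D - A, seed=int(rng.integers(2**31)))
    library = actives + decoys
    order = rng.permutation(len(library))
    library = [library[i] for i in order]
    return PlantedBenchmark(
        library=library,
        truth=truth,
        generator_params={
            "D": D,
            "A": A,
            "jitter_sd": jitter_sd,
            "n_distractors": BENCHMARK_DISTRACTORS,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# training sets


def make_training_ligands(
    truth: Pharmacophore,
    n: int = 62,
    seed: int = 0,
    n_distractors: int = 2,
    jitter_full: float = 0.15,
    jitter_partial: float = 0.3,
    id_prefix: str = "train",
) -> list[PseudoLigand]:
    """Pseudo-ligands in feature-completeness classes (0–4 features removed).

    The most potent class keeps all planted features at low jitter; weaker
    classes lose successively more features, producing the graded activity
    range a quantitative model needs.
    """
    k = len(truth.features)
    rng = np.random.default_rng(seed)
    classes = [min(m, k - 1) for m in range(5)]
    ligands: list[PseudoLigand] = []
    for i in range(n):
        n_missing = classes[i % len(classes)]
        jitter = jitter_full if n_missing == 0 else jitter_partial
        omit = tuple(rng.choice(k, size=n_missing, replace=False)) if n_missing else ()
        points = _planted_points(truth, rng, jitter, n_distractors, omit=omit)
        R, t = random_rigid_transform(rng)
        points = _apply_rigid(points, R, t)
        ligands.append(
            PseudoLigand(id=f"{id_prefix}-{i:04d}", conformers=[points], role="train")
        )
    return ligands


def make_training_set(
    truth: Pharmacophore,
    n: int = 62,
    seed: int = 0,
    slope: float = 1.3,
    intercept: float = 3.5,
    noise_sd: float = 0.3,
    uncertainty: float = 3.0,
    n_distractors: int = 2,
    role: str = "train",
) -> TrainingSet:
    """A complete activity-annotated training set over planted pseudo-ligands."""
    rng = np.random.default_rng(seed)
    ligands = make_training_ligands(
        truth, n=n, seed=int(rng.integers(2**31)), n_distractors=n_distractors,
        id_prefix=role,
    )
    activities = simulate_activities(
        truth, ligands, slope=slope, intercept=intercept, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    items = []
    for lig in ligands:
        pic50 = activities[lig.id]
        rec = MoleculeRecord(id=lig.id, structure="*", pic50=pic50, role=role)
        items.append(TrainingItem(record=rec, conformers=lig.conformers))
    return TrainingSet(items=items, uncertainty=uncertainty, allow_small=n < 16)
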