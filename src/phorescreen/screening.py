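"""The virtual-screening funnel and consensus aggregation of docking scores.

The funnel stages a library through (1) a rule-of-five drug-likeness filter,
(2) conformer generation / feature perception, and (3) pharmacophore mapping
with a configurable omitted-feature budget (zero by default: a hit must
satisfy every feature of the query).  Hits are ranked by fit value, ties
broken by molecule id for reproducibility.

Consensus scoring aggregates a molecules × scoring-functions matrix into a
single activity prediction: each scorer column is z-normalized (orientation
corrected so higher is always better), averaged under non-negative weights
summing to one, and calibrated to pIC50 by least squares against molecules
of known activity.  Rankings are therefore invariant to any positive affine
rescaling of an individual scorer column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemio import (
    MoleculeRecord,
    compute_descriptors,
    generate_conformers,
    lipinski_filter,
)
from .pharmacophore import Pharmacophore, best_fit

__all__ = [
    "ScreeningConfig",
    "FunnelReport",
    "HitRecord",
    "ScoreMatrix",
    "ConsensusModel",
    "screen_library",
    "load_score_matrix",
    "fit_consensus",
    "predict_consensus",
]


@dataclass
class ScreeningConfig:
    """Knobs of the screening funnel."""

    mode: str = "best"
    max_omitted: int = 0
    fit_threshold: Optional[float] = None
    max_conformers: int = 250
    energy_window: float = 20.0
    seed: int = 0
    lipinski: bool = True
    #: rule-of-five violations tolerated before rejection (0 = single-violation
    #: rejection, the default; some screening protocols allow one)
    lipinski_max_violations: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "best"):
            raise ValueError(f"mode must be 'fast' or 'best', got {self.mode!r}")
        if self.max_omitted < 0:
            raise ValueError(f"max_omitted must be >= 0, got {self.max_omitted}")
        if self.fit_threshold is not None and not np.isfinite(self.fit_threshold):
            raise ValueError("fit_threshold must be finite")
        if self.lipinski_max_violations < 0:
            raise ValueError("lipinski_max_violations must be >= 0")


@dataclass
class FunnelReport:
    """Ordered stage names with surviving counts; counts never increase."""

    stages: list[tuple[str, int]]
    rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("funnel counts must be non-increasing")

    def count(self, stage: str) -> int:
        for name, c in self.stages:
            if name == stage:
                return c
        raise KeyError(stage)


@dataclass
class HitRecord:
    id: str
    fit: float
    conformer_index: int
    rmsd: float
    estimated_pic50: Optional[float] = None


def _library_entry(record):
    """Normalize a library member to (id, descriptors-or-None, conformers).

    Pseudo-ligands carry feature-point conformers directly; molecule records
    are parsed, described and embedded on demand.
    """
    if hasattr(record, "conformers") and not isinstance(record, MoleculeRecord):
        return record.id, getattr(record, "descriptors", None), record.conformers
    return record.id, None, None


def screen_library(
    library: Sequence,
    hypo: Pharmacophore,
    cfg: Optional[ScreeningConfig] = None,
) -> tuple[list[HitRecord], FunnelReport]:
    """Run the screening funnel over a library of molecules or pseudo-ligands.

    Returns hits sorted by fit descending (ties: id ascending) and a stage
    report.  Unparseable or unembeddable records are counted as rejected at
    their stage, never silently dropped.
    """
    cfg = cfg or ScreeningConfig()
    if not hypo.features:
        raise ValueError("hypothesis has no features")
    if not len(library):
        raise ValueError("empty library")

    rejected: dict[str, int] = {"unparseable": 0, "embedding_failed": 0}
    stages: list[tuple[str, int]] = [("library", len(library))]

    # stage 1: drug-likeness
    survivors = []
    for record in library:
        rid, desc, confs = _library_entry(record)
        if confs is None:  # chemistry path: needs parse + descriptors
            try:
                desc = compute_descriptors(record)
            except ValueError:
                rejected["unparseable"] += 1
                continue
        if cfg.lipinski and desc is not None:
            _, violations = lipinski_filter(desc)
            if len(violations) > cfg.lipinski_max_violations:
                continue
        survivors.append((rid, record, confs))
    stages.append(("lipinski", len(survivors)))

    # stage 2: conformers / feature points
    with_confs = []
    for rid, record, confs in survivors:
        if confs is None:
            try:
                cs = generate_conformers(
                    record,
                    max_conformers=cfg.max_conformers,
                    energy_window=cfg.energy_window,
                    seed=cfg.seed,
                )
            except ValueError:
                rejected["embedding_failed"] += 1
                continue
            with_confs.append((rid, cs))
        else:
            with_confs.append((rid, confs))
    stages.append(("conformers", len(with_confs)))

    # stage 3: pharmacophore mapping
    hits: list[HitRecord] = []
    for rid, confs in with_confs:
        res = best_fit(confs, hypo, mode=cfg.mode, max_omitted=cfg.max_omitted,
                       molecule_id=rid)
        if res is None:
            continue
        est = hypo.fit_line(res.fit) if hypo.fit_line is not None else None
        hits.append(
            HitRecord(id=rid, fit=res.fit, conformer_index=res.conformer_index,
                      rmsd=res.rmsd, estimated_pic50=est)
        )
    stages.append(("mapped", len(hits)))

    if cfg.fit_threshold is not None:
        hits = [h for h in hits if h.fit >= cfg.fit_threshold]
        stages.append(("fit_threshold", len(hits)))

    hits.sort(key=lambda h: (-h.fit, h.id))
    return hits, FunnelReport(stages=stages, rejected=rejected)


# ---------------------------------------------------------------------------
# score matrices and consensus


@dataclass
class ScoreMatrix:
    """Molecules × named scoring functions; orientation True = higher is better."""

    data: pd.DataFrame
    orientation: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scorer in self.data.columns:
            self.orientation.setdefault(scorer, True)
        if self.data.isna().any().any():
            na = self.data.isna()
            row = na.any(axis=1).idxmax()
            col = na.loc[row].idxmax()
            raise ValueError(f"score matrix has a missing cell at ({row}, {col})")

    @property
    def molecules(self) -> list[str]:
        return list(self.data.index)

    @property
    def scorers(self) -> list[str]:
        return list(self.data.columns)


def load_score_matrix(path, higher_is_better: Optional[Mapping[str, bool]] = None) -> ScoreMatrix:
    """Load a CSV score matrix (first column: molecule id; header: scorer names).

    Every cell must parse to a finite number; a blank or malformed cell is an
    error naming its (row, column).
    """
    raw = pd.read_csv(path, dtype=str)
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str).str.strip()
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate molecule ids {dups}")
    scorers = list(raw.columns[1:])
    values = np.empty((len(raw), len(scorers)))
    for j, col in enumerate(scorers):
        for i, cell in enumerate(raw[col]):
            cell_s = (cell or "").replace(",", "").strip() if isinstance(cell, str) else cell
            try:
                v = float(cell_s)
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise ValueError(f"{path}: missing or invalid cell at ({ids.iloc[i]}, {col})")
            values[i, j] = v
    df = pd.DataFrame(values, index=ids.tolist(), columns=scorers)
    orientation = dict(higher_is_better or {})
    return ScoreMatrix(data=df, orientation=orientation)


@dataclass
class ConsensusModel:
    """Orientation-corrected z-average of scorers with a linear pIC50 calibration."""

    scorers: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    weights: dict[str, float]
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        w = np.array([self.weights[s] for s in self.scorers])
        if np.any(w < 0):
            raise ValueError("scorer weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("scorer weights must sum to 1")
        for s in self.scorers:
            if self.weights[s] > 0 and self.sds[s] <= 0:
                raise ValueError(f"scorer {s!r} has non-positive sd but positive weight")


def _consensus_scores(model: ConsensusModel, matrix: ScoreMatrix, ids) -> np.ndarray:
    z = np.zeros(len(ids))
    for s in model.scorers:
        w = model.weights[s]
        if w == 0:
            continue
        sign = 1.0 if matrix.orientation.get(s, True) else -1.0
        col = matrix.data.loc[ids, s].to_numpy(dtype=float)
        z = z + w * sign * (col - model.means[s]) / model.sds[s]
    return z


def fit_consensus(
    matrix: ScoreMatrix, known: Mapping[str, float], strict: bool = False
) -> ConsensusModel:
    """Fit the consensus model on molecules of known pIC50.

    Each scorer is z-normalized over the calibration rows; zero-variance
    scorers are excluded with a warning (weight 0) or rejected under
    ``strict``.  Remaining scorers receive equal weights, and the averaged
    z-score is calibrated to pIC50 by least squares.
    """
    ids = [i for i in matrix.molecules if i in known]
    if len(ids) < 3:
        raise ValueError(f"need at least 3 calibration molecules, got {len(ids)}")
    missing = set(known) - set(matrix.molecules)
    if missing:
        raise ValueError(f"calibration ids not in score matrix: {sorted(missing)}")
    sub = matrix.data.loc[ids]
    means, sds, active = {}, {}, []
    for s in matrix.scorers:
        col = sub[s].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=0))
        means[s], sds[s] = mu, sd
        if sd <= 1e-12:
            if strict:
                raise ValueError(f"scorer {s!r} has zero variance on calibration rows")
            warnings.warn(
                f"scorer {s!r} has zero variance on calibration rows; excluded (weight 0)",
                stacklevel=2,
            )
            sds[s] = 1.0  # placeholder; weight stays 0
        else:
            active.append(s)
    if not active:
        raise ValueError("all scorers have zero variance on calibration rows")
    weights = {s: (1.0 / len(active) if s in active else 0.0) for s in matrix.scorers}
    model = ConsensusModel(
        scorers=matrix.scorers, means=means, sds=sds, weights=weights,
        slope=1.0, intercept=0.0,
    )
    z = _consensus_scores(model, matrix, ids)
    y = np.array([known[i] for i in ids], dtype=float)
    if np.ptp(z) <= 1e-12:
        raise ValueError("consensus score has zero variance on calibration molecules")
    reg = stats.linregress(z, y)
    model.slope = float(reg.slope)
    model.intercept = float(reg.intercept)
    return model


def predict_consensus(model: ConsensusModel, matrix: ScoreMatrix) -> dict[str, float]:
    """Predicted pIC50 per molecule id; errors if a model scorer is absent."""
    for s in model.scorers:
        if s not in matrix.scorers:
            raise ValueError(f"score matrix is missing scorer {s!r} required by the model")
    ids = matrix.molecules
    z = _consensus_scores(model, matrix, ids)
    return {i: float(model.slope * zi + model.intercept) for i, zi in zip(ids, z)}
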