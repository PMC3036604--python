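"""Quantitative pharmacophore hypothesis generation from an activity-annotated
training set.

Three phases mirror the classic activity-driven generation scheme:

* **constructive** — enumerate feature configurations shared by the most
  potent compounds (the "leads"),
* **subtractive** — discard configurations that the least active compounds
  also match in full,
* **optimization** — seeded simulated annealing over feature centers,
  tolerances and weights, scored by a total cost in bits.

The cost model trades goodness of fit against model complexity:

    error_cost  = k_e * sum_i max(0, |pIC50_i - est_i| - log10(uncertainty))^2
    weight_cost = k_w * sum_f (w_f - 1)^2
    config_cost = log2(n_configs)
    total_cost  = error_cost + weight_cost + config_cost

Residuals inside the multiplicative uncertainty band (default ×3, i.e.
±log10(3) ≈ 0.477 log units) cost nothing.  The null cost is the error cost
of the constant mean-activity predictor; the residual cost (null − total)
measures how unlikely the fit→activity correlation is to be a random
occurrence.  The fixed cost is the complexity floor of a zero-error model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .chemio import MoleculeRecord, to_ic50
from .pharmacophore import (
    DEFAULT_TOLERANCE,
    FeatureKind,
    FeaturePoint,
    FitLine,
    PharmFeature,
    Pharmacophore,
    best_fit,
    map_conformer,
)

__all__ = [
    "TrainingItem",
    "TrainingSet",
    "CostReport",
    "RankedHypothesis",
    "HypothesisRanking",
    "AnnealSchedule",
    "partition_by_activity",
    "constructive_phase",
    "subtractive_phase",
    "molecule_fits",
    "fit_activity_line",
    "error_cost",
    "total_costs",
    "optimize",
    "estimate_activity",
    "build_hypotheses",
]

DEFAULT_UNCERTAINTY = 3.0
DEFAULT_SIGMA = 0.3  # log units; sets the error-cost scale k_e = 1/(2 ln2 sigma^2)
DEFAULT_KW = 1.0  # bits per squared unit of weight deviation
LEAD_SPAN_EXPONENT = 3.5  # inactives: IC50 >= 10^3.5 x min IC50


@dataclass
class TrainingItem:
    """One training molecule: its record plus per-conformer feature points."""

    record: MoleculeRecord
    conformers: Sequence[Sequence[FeaturePoint]]

    @property
    def pic50(self) -> float:
        if self.record.pic50 is None:
            raise ValueError(f"record {self.record.id!r} has no activity")
        return self.record.pic50

    @property
    def ic50(self) -> float:
        if self.record.ic50 is not None:
            return self.record.ic50
        return to_ic50(self.pic50)


@dataclass
class TrainingSet:
    """Activity-annotated training molecules with an uncertainty factor.

    The multiplicative ``uncertainty`` (default 3) means an observed activity
    is trusted only to within a factor of 3 up or down.  A sound training set
    has at least 16 molecules spanning at least four orders of magnitude in
    activity; ``allow_small`` overrides both checks for toy inputs.
    """

    items: list[TrainingItem]
    uncertainty: float = DEFAULT_UNCERTAINTY
    allow_small: bool = False

    def __post_init__(self) -> None:
        if self.uncertainty <= 1:
            raise ValueError(f"uncertainty must be > 1, got {self.uncertainty}")
        if not self.allow_small:
            if len(self.items) < 16:
                raise ValueError(
                    f"training set has {len(self.items)} molecules; at least 16 required "
                    "(pass allow_small=True to override)"
                )
            span = max(i.pic50 for i in self.items) - min(i.pic50 for i in self.items)
            if span < 4.0:
                raise ValueError(
                    f"activity span {span:.2f} log units; at least 4 required "
                    "(pass allow_small=True to override)"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def activities(self) -> np.ndarray:
        return np.array([i.pic50 for i in self.items], dtype=float)

    def with_activities(self, pic50s: Sequence[float]) -> "TrainingSet":
        """New training set with reassigned activities (same structures)."""
        items = []
        for item, p in zip(self.items, pic50s):
            rec = MoleculeRecord(
                id=item.record.id,
                structure=item.record.structure,
                pic50=float(p),
                role=item.record.role,
            )
            items.append(TrainingItem(record=rec, conformers=item.conformers))
        return TrainingSet(items=items, uncertainty=self.uncertainty, allow_small=True)


@dataclass
class CostReport:
    """Cost decomposition in bits; see module docstring for the model."""

    error_cost: float
    weight_cost: float
    config_cost: float
    total_cost: float
    fixed_cost: float
    null_cost: float
    residual_cost: float

    def __post_init__(self) -> None:
        for name in ("error_cost", "weight_cost", "config_cost"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.total_cost - (self.error_cost + self.weight_cost + self.config_cost)) > 1e-6:
            raise ValueError("total_cost must equal error + weight + config costs")
        if abs(self.residual_cost - (self.null_cost - self.total_cost)) > 1e-6:
            raise ValueError("residual_cost must equal null_cost - total_cost")


@dataclass
class RankedHypothesis:
    hypothesis: Pharmacophore
    costs: CostReport
    rmsd: float  # RMS of activity-estimate residuals, log units
    train_r: float


@dataclass
class HypothesisRanking:
    """Up to ten hypotheses sorted by ascending total cost."""

    entries: list[RankedHypothesis]

    def __post_init__(self) -> None:
        if len(self.entries) > 10:
            raise ValueError("ranking holds at most 10 hypotheses")
        totals = [e.costs.total_cost for e in self.entries]
        if any(a > b + 1e-9 for a, b in zip(totals, totals[1:])):
            raise ValueError("ranking must be sorted by ascending total cost")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best(self) -> RankedHypothesis:
        if not self.entries:
            raise ValueError("empty ranking")
        return self.entries[0]


# ---------------------------------------------------------------------------
# activity partition


@dataclass
class ActivityPartition:
    leads: list[TrainingItem]
    moderates: list[TrainingItem]
    inactives: list[TrainingItem]


def partition_by_activity(ts: TrainingSet) -> ActivityPartition:
    """Split the training set into leads, moderates and inactives.

    Leads are within uncertainty² of the most potent IC50 (inclusive);
    inactives are at least 10^3.5-fold less potent than the most potent
    compound (inclusive); the rest are moderates.
    """
    if not ts.items:
        raise ValueError("empty training set")
    ic50s = np.array([item.ic50 for item in ts.items])
    lo = float(ic50s.min())
    lead_cut = ts.uncertainty**2 * lo
    inactive_cut = 10.0**LEAD_SPAN_EXPONENT * lo
    leads, moderates, inactives = [], [], []
    for item, ic in zip(ts.items, ic50s):
        if ic <= lead_cut * (1 + 1e-12):
            leads.append(item)
        elif ic >= inactive_cut * (1 - 1e-12):
            inactives.append(item)
        else:
            moderates.append(item)
    return ActivityPartition(leads=leads, moderates=moderates, inactives=inactives)


# ---------------------------------------------------------------------------
# constructive / subtractive phases


def _maps_fully(item: TrainingItem, hypo: Pharmacophore) -> bool:
    for pts in item.conformers:
        if map_conformer(pts, hypo, max_omitted=0) is not None:
            return True
    return False


def _signature(hypo: Pharmacophore) -> tuple:
    kinds = hypo.kind_multiset()
    centers = hypo.centers
    dists = sorted(
        round(float(np.linalg.norm(centers[i] - centers[j])), 1)
        for i, j in itertools.combinations(range(len(centers)), 2)
    )
    return (kinds, tuple(dists))


def constructive_phase(
    leads: Sequence[TrainingItem],
    max_features: int = 5,
    min_features: int = 3,
    allowed_kinds: Optional[Sequence[FeatureKind]] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    weight: float = 1.0,
) -> list[Pharmacophore]:
    """Candidate hypotheses common to every lead.

    Point subsets of a reference lead (the one with the fewest feature
    points) seed candidate configurations; a candidate survives only if every
    other lead maps all of its features (no omissions).  Candidates are
    deduplicated by kind multiset plus a rounded pairwise-distance signature.
    """
    if len(leads) < 2:
        raise ValueError("constructive phase requires at least 2 leads")
    if not (1 <= max_features <= 5):
        raise ValueError(f"max_features must be in [1, 5], got {max_features}")
    min_features = max(1, min(min_features, max_features))
    kinds_ok = set(FeatureKind(k) for k in allowed_kinds) if allowed_kinds else set(FeatureKind)

    ref = min(leads, key=lambda item: min(len(c) for c in item.conformers))
    ref_points = [
        p for p in min(ref.conformers, key=len) if p.kind in kinds_ok
    ]
    others = [item for item in leads if item is not ref]

    seen: set[tuple] = set()
    candidates: list[Pharmacophore] = []
    for size in range(min(max_features, len(ref_points)), min_features - 1, -1):
        for combo in itertools.combinations(range(len(ref_points)), size):
            feats = [
                PharmFeature(
                    kind=ref_points[i].kind,
                    center=ref_points[i].position,
                    tolerance=tolerance,
                    weight=weight,
                )
                for i in combo
            ]
            cand = Pharmacophore(features=feats)
            sig = _signature(cand)
            if sig in seen:
                continue
            if all(_maps_fully(item, cand) for item in others):
                seen.add(sig)
                candidates.append(cand)
    return candidates


def subtractive_phase(
    candidates: Sequence[Pharmacophore], inactives: Sequence[TrainingItem]
) -> list[Pharmacophore]:
    """Drop candidates fully matched by more than half of the inactives."""
    if not inactives:
        return list(candidates)
    kept = []
    for cand in candidates:
        n_mapped = sum(1 for item in inactives if _maps_fully(item, cand))
        if n_mapped <= 0.5 * len(inactives):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# regression and costs


def molecule_fits(
    hypo: Pharmacophore, ts: TrainingSet, max_omitted: Optional[int] = None
) -> np.ndarray:
    """Best fit value per training molecule (NO_MATCH scores 0)."""
    if max_omitted is None:
        max_omitted = len(hypo.features) - 1
    fits = np.zeros(len(ts.items))
    for i, item in enumerate(ts.items):
        res = best_fit(item.conformers, hypo, max_omitted=max_omitted,
                       molecule_id=item.record.id)
        if res is not None:
            fits[i] = res.fit
    return fits


def fit_activity_line(
    hypo: Pharmacophore, ts: TrainingSet, max_omitted: Optional[int] = None
) -> tuple[FitLine, np.ndarray, np.ndarray]:
    """Least-squares line pIC50 ≈ slope·fit + intercept over the training set.

    Returns (line, estimates, fits); attaches the line and the training
    correlation to the hypothesis.  A hypothesis whose fit values have zero
    variance is degenerate and rejected.
    """
    fits = molecule_fits(hypo, ts, max_omitted=max_omitted)
    y = ts.activities
    if np.ptp(fits) <= 1e-12:
        raise ValueError("degenerate hypothesis: zero variance in fit values")
    reg = stats.linregress(fits, y)
    line = FitLine(slope=float(reg.slope), intercept=float(reg.intercept))
    estimates = line.slope * fits + line.intercept
    hypo.fit_line = line
    hypo.train_r = float(reg.rvalue)
    return line, estimates, fits


def _banded_error_bits(residuals: np.ndarray, uncertainty: float, sigma: float) -> float:
    band = math.log10(uncertainty)
    excess = np.maximum(0.0, np.abs(residuals) - band)
    k_e = 1.0 / (2.0 * math.log(2.0) * sigma**2)
    return float(k_e * np.sum(excess**2))


def error_cost(
    hypo: Pharmacophore,
    ts: TrainingSet,
    sigma: float = DEFAULT_SIGMA,
    estimates: Optional[np.ndarray] = None,
) -> float:
    """Error cost in bits; residuals inside the uncertainty band are free."""
    if estimates is None:
        _, estimates, _ = fit_activity_line(hypo, ts)
    residuals = ts.activities - estimates
    return _banded_error_bits(residuals, ts.uncertainty, sigma)


def total_costs(
    hypo: Pharmacophore,
    ts: TrainingSet,
    n_configs: int,
    sigma: float = DEFAULT_SIGMA,
    k_w: float = DEFAULT_KW,
    estimates: Optional[np.ndarray] = None,
) -> CostReport:
    """Full cost decomposition for a hypothesis against a training set."""
    if n_configs < 1:
        raise ValueError(f"n_configs must be >= 1, got {n_configs}")
    e_cost = error_cost(hypo, ts, sigma=sigma, estimates=estimates)
    w_cost = float(k_w * np.sum((hypo.weights - 1.0) ** 2))
    c_cost = math.log2(n_configs)
    total = e_cost + w_cost + c_cost
    y = ts.activities
    null = _banded_error_bits(y - y.mean(), ts.uncertainty, sigma)
    fixed = w_cost + c_cost
    report = CostReport(
        error_cost=e_cost,
        weight_cost=w_cost,
        config_cost=c_cost,
        total_cost=total,
        fixed_cost=fixed,
        null_cost=null,
        residual_cost=null - total,
    )
    hypo.costs = report
    return report


# ---------------------------------------------------------------------------
# annealing optimization


@dataclass
class AnnealSchedule:
    """Geometric-cooling schedule; t0=None calibrates from pilot proposals so
    roughly half of uphill moves are accepted initially."""

    steps: int = 30
    pilot: int = 10
    cooling: float = 0.93
    t0: Optional[float] = None
    step_center: float = 0.5  # Å, Gaussian sd for center moves
    step_tolerance: float = 0.1  # Å
    step_weight: float = 0.1
    min_tolerance: float = 0.5
    kind_swap: bool = False


def _clone_hypo(hypo: Pharmacophore) -> Pharmacophore:
    return Pharmacophore(
        features=[
            PharmFeature(kind=f.kind, center=tuple(f.center), tolerance=f.tolerance,
                         weight=f.weight)
            for f in hypo.features
        ]
    )


def _propose(hypo: Pharmacophore, rng: np.random.Generator, sched: AnnealSchedule) -> Pharmacophore:
    new = _clone_hypo(hypo)
    i = int(rng.integers(len(new.features)))
    f = new.features[i]
    moves = ["center", "tolerance", "weight"] + (["kind"] if sched.kind_swap else [])
    move = moves[int(rng.integers(len(moves)))]
    if move == "center":
        f.center = tuple(np.asarray(f.center) + rng.normal(0.0, sched.step_center, 3))
    elif move == "tolerance":
        f.tolerance = max(sched.min_tolerance, f.tolerance + rng.normal(0.0, sched.step_tolerance))
    elif move == "weight":
        f.weight = max(0.0, f.weight + rng.normal(0.0, sched.step_weight))
    else:
        choices = [k for k in FeatureKind if k != f.kind]
        f.kind = choices[int(rng.integers(len(choices)))]
    return new


def _evaluate(hypo: Pharmacophore, ts: TrainingSet, n_configs: int,
              sigma: float, k_w: float) -> Optional[tuple[CostReport, float, float]]:
    """(costs, rmsd, train_r) or None when the hypothesis is degenerate."""
    try:
        _, estimates, _ = fit_activity_line(hypo, ts)
    except ValueError:
        return None
    residuals = ts.activities - estimates
    rmsd = float(np.sqrt(np.mean(residuals**2)))
    costs = total_costs(hypo, ts, n_configs, sigma=sigma, k_w=k_w, estimates=estimates)
    return costs, rmsd, float(hypo.train_r)


def optimize(
    candidates: Sequence[Pharmacophore],
    ts: TrainingSet,
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
    n_anneal: int = 3,
    sigma: float = DEFAULT_SIGMA,
    k_w: float = DEFAULT_KW,
) -> HypothesisRanking:
    """Anneal candidate hypotheses and rank by ascending total cost.

    The ``n_anneal`` lowest-cost candidates are refined by seeded simulated
    annealing (feature centers, tolerances, weights); the best state ever
    visited per candidate is kept, so the ranking never falls below the best
    unoptimized candidate.  Returns at most ten entries.
    """
    if not candidates:
        raise ValueError(
            "no candidate hypotheses to optimize; relax feature-perception or "
            "constructive-phase settings"
        )
    sched = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    n_configs = len(candidates)

    scored: list[RankedHypothesis] = []
    for cand in candidates:
        ev = _evaluate(cand, ts, n_configs, sigma, k_w)
        if ev is None:
            continue
        costs, rmsd, r = ev
        scored.append(RankedHypothesis(hypothesis=cand, costs=costs, rmsd=rmsd, train_r=r))
    if not scored:
        raise ValueError(
            "all candidate hypotheses are degenerate (constant fit values); relax "
            "constructive-phase settings"
        )
    scored.sort(key=lambda e: e.costs.total_cost)

    results: list[RankedHypothesis] = list(scored[n_anneal:])
    for entry in scored[:n_anneal]:
        best = entry
        current = entry
        # pilot proposals calibrate the start temperature
        uphill = []
        for _ in range(sched.pilot):
            prop = _propose(current.hypothesis, rng, sched)
            ev = _evaluate(prop, ts, n_configs, sigma, k_w)
            if ev is None:
                continue
            delta = ev[0].total_cost - current.costs.total_cost
            if delta > 0:
                uphill.append(delta)
        if sched.t0 is not None:
            temp = sched.t0
        elif uphill:
            temp = float(np.mean(uphill)) / math.log(2.0)
        else:
            temp = 1.0
        for _ in range(sched.steps):
            prop = _propose(current.hypothesis, rng, sched)
            ev = _evaluate(prop, ts, n_configs, sigma, k_w)
            if ev is not None:
                costs, rmsd, r = ev
                delta = costs.total_cost - current.costs.total_cost
                if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
                    current = RankedHypothesis(hypothesis=prop, costs=costs, rmsd=rmsd, train_r=r)
                    if costs.total_cost < best.costs.total_cost:
                        best = current
            temp *= sched.cooling
        # restore regression state of the best hypothesis (mutated by proposals)
        _evaluate(best.hypothesis, ts, n_configs, sigma, k_w)
        results.append(best)

    results.sort(key=lambda e: e.costs.total_cost)
    return HypothesisRanking(entries=results[:10])


def estimate_activity(
    hypo: Pharmacophore, conformers, max_omitted: Optional[int] = None
) -> float:
    """Predicted pIC50 = slope·best_fit + intercept (NO_MATCH → intercept)."""
    if hypo.fit_line is None:
        raise ValueError("hypothesis has no fit→activity line; run fit_activity_line first")
    if max_omitted is None:
        max_omitted = len(hypo.features) - 1
    res = best_fit(conformers, hypo, max_omitted=max_omitted)
    fit = 0.0 if res is None else res.fit
    return hypo.fit_line(fit)


# ---------------------------------------------------------------------------
# pipeline


def build_hypotheses(
    ts: TrainingSet,
    max_features: int = 5,
    min_features: int = 3,
    seed: int = 0,
    schedule: Optional[AnnealSchedule] = None,
    anneal: bool = True,
    n_anneal: int = 3,
) -> HypothesisRanking:
    """Full generation pipeline: partition → constructive → subtractive → optimize."""
    part = partition_by_activity(ts)
    candidates = constructive_phase(part.leads, max_features=max_features,
                                    min_features=min_features)
    candidates = subtractive_phase(candidates, part.inactives)
    sched = schedule if anneal else AnnealSchedule(steps=0, pilot=0)
    return optimize(candidates, ts, schedule=sched, seed=seed,
                    n_anneal=n_anneal if anneal else 0)
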