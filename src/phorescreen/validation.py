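"""Statistical validation of pharmacophore hypotheses.

Three complementary checks are implemented:

* **Güner-Henry / enrichment scoring** of a retrieval experiment on a
  labeled database of D molecules containing A actives, of which a query
  retrieves Ht hits with Ha actives among them:

      %Y = 100·Ha/Ht            (yield of actives, precision of the hit list)
      %A = 100·Ha/A             (ratio of actives retrieved, recall)
      E  = (Ha/Ht)/(A/D)        (enrichment over random retrieval)
      GH = (Ha(3A+Ht)/(4HtA))·(1 − (Ht−Ha)/(D−A))

  GH lies in [0, 1] by construction; 1 signifies the ideal screen
  (every active retrieved, no decoys).

* **Fischer randomization** — the hypothesis-generation procedure is re-run
  on activity-scrambled copies of the training set; at a confidence level c
  the number of scrambles is round(100/(100−c)) − 1 (19 at 95%), and the
  result is significant when no scrambled run beats the original.

* **Test-set prediction** — squared Pearson correlation between estimated
  and observed pIC50 on held-out molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .hypogen import TrainingSet, build_hypotheses, estimate_activity
from .pharmacophore import Pharmacophore

__all__ = [
    "EnrichmentCounts",
    "EnrichmentReport",
    "FischerReport",
    "enrichment_metrics",
    "fischer_count",
    "fischer_randomization",
    "default_builder",
    "test_set_correlation",
]

SUPPORTED_CONFIDENCES = (90, 95, 98, 99)


@dataclass(frozen=True)
class EnrichmentCounts:
    """Retrieval counts: database size D, actives A, hits Ht, active hits Ha."""

    D: int
    A: int
    Ht: int
    Ha: int

    def __post_init__(self) -> None:
        for name in ("D", "A", "Ht", "Ha"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"count {name} must be an integer, got {v!r}")
        if self.A < 1:
            raise ValueError(f"count invariant violated: A >= 1 (got A={self.A})")
        if self.Ht < 0:
            raise ValueError(f"count invariant violated: Ht >= 0 (got Ht={self.Ht})")
        if self.A > self.D:
            raise ValueError(f"count invariant violated: A <= D (got A={self.A}, D={self.D})")
        if self.Ht > self.D:
            raise ValueError(f"count invariant violated: Ht <= D (got Ht={self.Ht}, D={self.D})")
        if not (0 <= self.Ha <= min(self.A, self.Ht)):
            raise ValueError(
                f"count invariant violated: 0 <= Ha <= min(A, Ht) "
                f"(got Ha={self.Ha}, A={self.A}, Ht={self.Ht})"
            )
        if self.Ht - self.Ha > self.D - self.A:
            raise ValueError(
                f"count invariant violated: false positives Ht - Ha cannot exceed "
                f"the decoy count D - A (got Ht={self.Ht}, Ha={self.Ha}, "
                f"D={self.D}, A={self.A})"
            )


@dataclass
class EnrichmentReport:
    """The six retrieval statistics derived from EnrichmentCounts."""

    counts: EnrichmentCounts
    yield_pct: float  # %Y
    ratio_pct: float  # %A
    enrichment: float  # E
    gh: float
    false_neg: int
    false_pos: int


def enrichment_metrics(c: EnrichmentCounts) -> EnrichmentReport:
    """Compute %Y, %A, E, GH, FN, FP from retrieval counts."""
    if c.Ht == 0:
        raise ValueError("Ht = 0: yield of actives is undefined (no hits retrieved)")
    if c.A >= c.D:
        raise ValueError(f"A must be < D for enrichment metrics (got A={c.A}, D={c.D})")
    D, A, Ht, Ha = float(c.D), float(c.A), float(c.Ht), float(c.Ha)
    yield_pct = 100.0 * Ha / Ht
    ratio_pct = 100.0 * Ha / A
    enrichment = (Ha / Ht) / (A / D)
    gh = (Ha * (3.0 * A + Ht) / (4.0 * Ht * A)) * (1.0 - (Ht - Ha) / (D - A))
    return EnrichmentReport(
        counts=c,
        yield_pct=yield_pct,
        ratio_pct=ratio_pct,
        enrichment=enrichment,
        gh=gh,
        false_neg=c.A - c.Ha,
        false_pos=c.Ht - c.Ha,
    )


def fischer_count(confidence: float) -> int:
    """Number of scrambled datasets for a confidence level: round(100/(100−c)) − 1."""
    if not (0 < confidence < 100):
        raise ValueError(f"confidence must be in (0, 100), got {confidence}")
    ratio = 100.0 / (100.0 - confidence)
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"unsupported confidence level {confidence}; supported levels: "
            f"{', '.join(str(c) for c in SUPPORTED_CONFIDENCES)}"
        )
    return int(round(ratio)) - 1


@dataclass
class FischerReport:
    """Outcome of an activity-scrambling significance test."""

    confidence: float
    n_scrambles: int
    original_stat: float
    scrambled_stats: list[float]
    significant: bool
    statistic: str = "train_r"

    def __post_init__(self) -> None:
        if self.n_scrambles != len(self.scrambled_stats):
            raise ValueError("n_scrambles must match the number of scrambled statistics")


#: builder protocol: callable(ts, seed) -> (train_r, total_cost)
Builder = Callable[[TrainingSet, int], tuple[float, float]]


def default_builder(ts: TrainingSet, seed: int) -> tuple[float, float]:
    """Constructive + subtractive pipeline without annealing; returns the top
    hypothesis's (train_r, total_cost), or (−inf, +inf) when no hypothesis
    can be built (e.g. scrambled leads share no configuration)."""
    try:
        ranking = build_hypotheses(ts, seed=seed, anneal=False)
    except ValueError:
        return (-math.inf, math.inf)
    best = ranking.best
    return (best.train_r, best.costs.total_cost)


def _better(stat_a: tuple[float, float], stat_b: tuple[float, float], compare: str) -> bool:
    """Is a strictly better than b?"""
    ra, ca = stat_a
    rb, cb = stat_b
    if compare == "train_r":
        if ra != rb:
            return ra > rb
        return ca < cb
    elif compare == "total_cost":
        if ca != cb:
            return ca < cb
        return ra > rb
    raise ValueError(f"compare must be 'train_r' or 'total_cost', got {compare!r}")


def fischer_randomization(
    ts: TrainingSet,
    builder: Builder = default_builder,
    confidence: float = 95,
    seed: int = 0,
    compare: str = "train_r",
) -> FischerReport:
    """Re-derive hypotheses on activity-permuted training sets.

    Activities are permuted uniformly at random (seeded) ``n_scrambles``
    times, the builder re-run on each scramble, and the original statistic
    compared against every scrambled one; the model is significant at the
    given confidence iff no scramble is strictly better.
    """
    n = fischer_count(confidence)
    rng = np.random.default_rng(seed)
    original = builder(ts, int(rng.integers(2**31)))
    scrambled: list[tuple[float, float]] = []
    y = ts.activities
    for _ in range(n):
        perm = rng.permutation(len(y))
        ts_scr = ts.with_activities(y[perm])
        scrambled.append(builder(ts_scr, int(rng.integers(2**31))))
    built = math.isfinite(original[0]) and math.isfinite(original[1])
    significant = built and not any(_better(s, original, compare) for s in scrambled)
    stat_idx = 0 if compare == "train_r" else 1
    return FischerReport(
        confidence=confidence,
        n_scrambles=n,
        original_stat=original[stat_idx],
        scrambled_stats=[s[stat_idx] for s in scrambled],
        significant=significant,
        statistic=compare,
    )


def test_set_correlation(
    hypo: Pharmacophore,
    test_items: Sequence,
    max_omitted: Optional[int] = None,
) -> float:
    """R² between estimated and observed pIC50 on a held-out test set.

    ``test_items`` are hypogen.TrainingItem-like objects (record + conformer
    feature-point sets); unmapped molecules are estimated at the intercept.
    """
    if len(test_items) < 3:
        raise ValueError(f"need at least 3 test records, got {len(test_items)}")
    observed = np.array([item.pic50 for item in test_items], dtype=float)
    estimated = np.array(
        [estimate_activity(hypo, item.conformers, max_omitted=max_omitted)
         for item in test_items]
    )
    if np.ptp(observed) <= 1e-12 or np.ptp(estimated) <= 1e-12:
        raise ValueError("zero variance in observed or estimated activities")
    r, _ = stats.pearsonr(estimated, observed)
    return float(r * r)
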