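"""Enrichment metric panel for ranked virtual screens.

Implements the standard retrospective-evaluation panel on a labeled ranking
of N entries containing n actives at 1-based ranks r_i (relative ranks
x_i = r_i/N, prevalence pi = n/N):

* **ROC AUC** — probability that a random active outranks a random inactive;
  ties credited 0.5.  Computed in the Mann–Whitney average-rank form, which
  equals the trapezoidal area under the ROC polygon with tie blocks drawn as
  diagonal segments.
* **RIE** (robust initial enhancement) — exponentially rank-weighted sum
  over actives, normalized by its exact mean under uniform random placement:

      RIE = sum_i exp(-alpha x_i) / [ (n/N) (1 - e^-alpha) / (e^(alpha/N) - 1) ]

  Values > 1 indicate earlier-than-random recognition of actives.
* **BEDROC** — min-max rescaling of RIE to [0, 1], computed exactly from
  the best and worst possible placements (actives at ranks 1..n and at
  N-n+1..N respectively).  Perfect ranking gives exactly 1, fully inverted
  exactly 0.
* **Total gain (TG)** — standardized mean absolute deviation of the
  predictiveness curve (local probability of activity along the rank axis)
  from the global prevalence:

      TG = [ (1/N) sum_i |Rhat(v_i) - pi| ] / [ 2 pi (1 - pi) ]

  with Rhat estimated by a centered moving-window proportion of actives
  (window truncated at the list ends, then averaged within score-tie
  blocks so that a fully tied list yields exactly 0).
* **Screening percentage** — percent of the list that must be physically
  screened to reach a given active (worst-tie ranks: one cannot stop
  mid-tie-block), 100 * rank / N.
* **Fold enrichment** — recovery fraction divided by the screened fraction
  at which it is achieved; 1 = random performance.
* **Hit rate** — percent of screened compounds that are hits.

The exponential weight alpha sets the early-recognition horizon: roughly
the top 1/alpha fraction of the list contributes 80% of the RIE/BEDROC
weight.  The conventional screening default alpha = 20 (top ~5% emphasis)
is used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ParameterError, UndefinedMetricError
from .ranking import (
    AVERAGE,
    NO_DUPLICATES,
    REDUNDANT,
    WORST,
    ActivityTable,
    LabeledRanking,
    RankedScreen,
    append_missing_actives,
    collapse_no_duplicates,
    label_ranking,
)

__all__ = [
    "MetricParams",
    "EnrichmentReport",
    "roc_auc",
    "rie",
    "bedroc",
    "total_gain",
    "screening_percentage",
    "enrichment_factor",
    "hit_rate",
    "evaluate_screen",
    "roc_points",
]


@dataclass(frozen=True)
class MetricParams:
    """Tunable metric parameters.

    alpha
        Exponential early-recognition weight for RIE/BEDROC (> 0).
    tg_window
        Moving-window width (entries) of the predictiveness-curve estimator;
        ``None`` selects max(20, N // 25) at evaluation time.
    """

    alpha: float = 20.0
    tg_window: int | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.tg_window is not None and self.tg_window < 2:
            raise ParameterError(f"tg_window must be >= 2, got {self.tg_window}")

    def resolved_window(self, N: int) -> int:
        return self.tg_window if self.tg_window is not None else max(20, N // 25)


def _require_actives(ranking: LabeledRanking) -> None:
    if ranking.n == 0:
        raise UndefinedMetricError("metric undefined: ranking contains no actives")


def _require_both_classes(ranking: LabeledRanking) -> None:
    _require_actives(ranking)
    if ranking.n == ranking.N:
        raise UndefinedMetricError("metric undefined: ranking contains no inactives")


def roc_auc(ranking: LabeledRanking) -> float:
    """ROC AUC: fraction of (active, inactive) pairs where the active scores
    better, ties counting half — the Mann–Whitney statistic on average
    ranks, identical to the trapezoidal area under the ROC polygon."""
    _require_both_classes(ranking)
    N, n = ranking.N, ranking.n
    # ascending ranks in score (higher score -> higher rank), average ties
    asc = (N + 1) - ranking.ranks(AVERAGE)
    auc = (asc[ranking.labels].sum() - n * (n + 1) / 2.0) / (n * (N - n))
    return float(auc)


def _rie_denominator(N: int, n: int, alpha: float) -> float:
    # exact mean of sum_i exp(-alpha r_i / N) under uniform random placement
    return (n / N) * (1.0 - math.exp(-alpha)) / (math.expm1(alpha / N))


def rie(ranking: LabeledRanking, params: MetricParams = MetricParams()) -> float:
    """Robust initial enhancement at ``params.alpha``.

    Active ranks are the 1-based positions in the stable best-first order.
    Equals 1 in expectation under uniform random active placement (the
    denominator is exactly that exhaustive mean).
    """
    _require_actives(ranking)
    N = ranking.N
    x = ranking.ranks_of_actives / N
    num = float(np.exp(-params.alpha * x).sum())
    return num / _rie_denominator(N, ranking.n, params.alpha)


def _rie_extremes(N: int, n: int, alpha: float) -> tuple[float, float]:
    """RIE at the worst (ranks N-n+1..N) and best (ranks 1..n) placements."""
    denom = _rie_denominator(N, n, alpha)
    ranks_best = np.arange(1, n + 1)
    ranks_worst = np.arange(N - n + 1, N + 1)
    lo = float(np.exp(-alpha * ranks_worst / N).sum()) / denom
    hi = float(np.exp(-alpha * ranks_best / N).sum()) / denom
    return lo, hi


def bedroc(ranking: LabeledRanking, params: MetricParams = MetricParams()) -> float:
    """BEDROC at ``params.alpha``: RIE rescaled onto [0, 1] between its
    exact minimum (all actives last) and maximum (all actives first).

    For alpha * (n/N) > 1 the exponential weight saturates within the
    active-sized head of the list and the metric loses early-recognition
    contrast; a warning is emitted.
    """
    _require_both_classes(ranking)
    N, n = ranking.N, ranking.n
    ra = n / N
    if params.alpha * ra > 1.0:
        warnings.warn(
            f"alpha * (n/N) = {params.alpha * ra:.3g} > 1: BEDROC is "
            "poorly conditioned at this prevalence/alpha combination",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi = _rie_extremes(N, n, params.alpha)
    value = (rie(ranking, params) - lo) / (hi - lo)
    return float(min(1.0, max(0.0, value)))


def _tie_block_ids(scores: np.ndarray) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(np.diff(scores) != 0)]).astype(int)


def _predictiveness(labels: np.ndarray, scores: np.ndarray, window: int) -> np.ndarray:
    """Tie-aware centered moving proportion of actives.

    One estimate per score-tie block: the proportion of actives in the
    union of the block with the ``window``-entry span centered on it,
    truncated at the list ends.  With all-distinct scores this is the plain
    centered moving window; a block wider than the window contributes its
    own label proportion (rank order inside a tie block is arbitrary, so
    the estimate must not depend on it).
    """
    N = labels.size
    half = window // 2
    blocks = _tie_block_ids(scores)
    n_blocks = blocks[-1] + 1
    counts = np.bincount(blocks, minlength=n_blocks)
    block_hi = np.cumsum(counts)  # exclusive
    block_lo = block_hi - counts
    center = (block_lo + block_hi - 1) // 2
    lo = np.minimum(block_lo, np.maximum(0, center - half))
    hi = np.maximum(block_hi, np.minimum(N, center + half + 1))
    csum = np.concatenate([[0.0], np.cumsum(labels, dtype=float)])
    rhat_block = (csum[hi] - csum[lo]) / (hi - lo)
    return rhat_block[blocks]


def total_gain(ranking: LabeledRanking, params: MetricParams = MetricParams()) -> float:
    """Standardized total gain of the predictiveness curve.

    The local activity probability along the rank axis is estimated by the
    tie-aware centered moving-window proportion of
    :func:`_predictiveness`.  TG = 0 when scores carry no information about
    activity (flat predictiveness: a fully tied list gives exactly 0), 1
    when the curve separates the classes completely (all actives in one
    better-scoring tie block give exactly 1).
    """
    _require_both_classes(ranking)
    N, n = ranking.N, ranking.n
    window = params.resolved_window(N)
    if N < window:
        raise ParameterError(
            f"total gain needs N >= window ({window}), got N = {N}"
        )
    pi = n / N
    rhat = _predictiveness(ranking.labels.astype(float), ranking.scores, window)
    tg = float(np.mean(np.abs(rhat - pi)) / (2.0 * pi * (1.0 - pi)))
    return min(1.0, max(0.0, tg))


def _best_rank_by_parent(ranking: LabeledRanking) -> dict[str, int]:
    """Worst-tie rank of each parent's best entry."""
    worst = ranking.ranks(WORST)
    out: dict[str, int] = {}
    for pid, r in zip(ranking.parent_ids, worst):
        r = int(r)
        if pid not in out or r < out[pid]:
            out[pid] = r
    return out


def screening_percentage(ranking: LabeledRanking, parent: str) -> float:
    """Percent of the list that must be screened to reach ``parent``:
    100 * rank / N, using the parent's best entry under worst-tie ranks."""
    worst = ranking.ranks(WORST)
    mask = ranking.parent_ids == parent
    if not mask.any():
        raise LookupError(f"parent {parent!r} not present in the ranking")
    return float(100.0 * worst[mask].min() / ranking.N)


def enrichment_factor(
    ranking: LabeledRanking,
    recovery_fraction: float = 0.5,
    active_subset: Iterable[str] | None = None,
) -> float:
    """Fold enrichment over random selection at a target recovery fraction.

    EF = f / s where s is the screened fraction (worst-tie rank / N) at
    which the ceil(f * m)-th of the m subset actives appears.  Random
    placement yields EF = 1 in expectation; EF = 28 means the required
    fraction of the collection was 28 times smaller than random selection
    would need.
    """
    if not 0.0 < recovery_fraction <= 1.0:
        raise ParameterError(
            f"recovery_fraction must lie in (0, 1], got {recovery_fraction}"
        )
    if active_subset is None:
        subset = ranking.active_parent_ids()
    else:
        subset = list(dict.fromkeys(active_subset))
    if not subset:
        raise UndefinedMetricError("enrichment factor undefined: empty active subset")
    best = _best_rank_by_parent(ranking)
    try:
        ranks = sorted(best[p] for p in subset)
    except KeyError as exc:
        raise LookupError(f"active {exc.args[0]!r} not present in the ranking") from None
    k = math.ceil(recovery_fraction * len(subset))
    s = ranks[k - 1] / ranking.N
    return float(recovery_fraction / s)


def hit_rate(n_hits: int, n_screened: int) -> float:
    """Hit rate as a percent, reported to two decimals (e.g. 4 actives out
    of 1364 screened compounds -> 0.29)."""
    if n_screened <= 0:
        raise ParameterError(f"n_screened must be positive, got {n_screened}")
    if not 0 <= n_hits <= n_screened:
        raise ParameterError(
            f"n_hits must lie in [0, n_screened], got {n_hits}/{n_screened}"
        )
    return round(100.0 * n_hits / n_screened, 2)


def roc_points(ranking: LabeledRanking) -> np.ndarray:
    """ROC polygon vertices (FPR, TPR), one vertex per distinct score, tie
    blocks as single diagonal segments.  For plotting/CSV export."""
    _require_both_classes(ranking)
    blocks = _tie_block_ids(ranking.scores)
    tp = np.bincount(blocks, weights=ranking.labels.astype(float))
    fp = np.bincount(blocks, weights=(~ranking.labels).astype(float))
    tpr = np.concatenate([[0.0], np.cumsum(tp)]) / ranking.n
    fpr = np.concatenate([[0.0], np.cumsum(fp)]) / (ranking.N - ranking.n)
    return np.column_stack([fpr, tpr])


@dataclass
class EnrichmentReport:
    """Full metric panel for one screen under one redundancy treatment."""

    auc: float
    rie: float
    bedroc: float
    tg: float
    screening_pct_per_active: Mapping[str, float]
    fold_enrichment: Mapping[str, float]  # keyed by recovery percent, e.g. "50"
    hit_rate_pct: float
    N: int
    n: int
    treatment: str
    name: str = ""
    template_id: str = ""
    screen_type: str = ""
    alpha: float = 20.0
    tg_window: int = 0
    tg_estimator: str = "centered_moving_window"
    n_appended_actives: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 and 0.0 <= self.bedroc <= 1.0 and 0.0 <= self.tg <= 1.0):
            raise ParameterError("bounded metric outside [0, 1]")
        if self.rie < 0 or self.n > self.N:
            raise ParameterError("inconsistent report fields")

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "rie": self.rie,
            "bedroc": self.bedroc,
            "tg": self.tg,
            "screening_pct_per_active": dict(self.screening_pct_per_active),
            "fold_enrichment": dict(self.fold_enrichment),
            "hit_rate_pct": self.hit_rate_pct,
            "N": self.N,
            "n": self.n,
            "treatment": self.treatment,
            "name": self.name,
            "template_id": self.template_id,
            "screen_type": self.screen_type,
            "alpha": self.alpha,
            "tg_window": self.tg_window,
            "tg_estimator": self.tg_estimator,
            "n_appended_actives": self.n_appended_actives,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnrichmentReport":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if not k.startswith("_") and k in d})


def evaluate_screen(
    screen: RankedScreen,
    activity: ActivityTable,
    params: MetricParams = MetricParams(),
    treatment: str = REDUNDANT,
    active_subset: Iterable[str] | None = None,
    missing_actives: str = "append",
    recovery_fractions: tuple[float, ...] = (0.5, 1.0),
) -> EnrichmentReport:
    """Label a screen, apply the requested redundancy treatment, and compute
    the full metric panel in one pass.

    ``active_subset`` restricts the active definition to an explicit parent
    list (e.g. the potent hits only); by default every compound at or below
    the activity threshold is active.  Actives missing from the screen are
    appended at the bottom (``missing_actives='append'``, the default) or
    raise (``'error'``).  Field-by-field the report equals the individually
    invoked metric functions on the same labeled ranking.
    """
    subset = list(dict.fromkeys(active_subset)) if active_subset is not None else None
    wanted_actives = subset if subset is not None else activity.active_ids()
    lr = label_ranking(screen, activity, active_ids=subset)
    if treatment == NO_DUPLICATES:
        lr = collapse_no_duplicates(lr)
    elif treatment != REDUNDANT:
        raise ParameterError(f"unknown treatment {treatment!r}")
    lr = append_missing_actives(lr, activity, active_ids=wanted_actives, policy=missing_actives)

    pct = {
        pid: round(screening_percentage(lr, pid), 2) for pid in wanted_actives
    }
    ef = {
        f"{int(round(100 * f))}": enrichment_factor(lr, f, wanted_actives)
        for f in recovery_fractions
    }
    distinct_parents = len(set(lr.parent_ids.astype(str)))
    return EnrichmentReport(
        auc=roc_auc(lr),
        rie=rie(lr, params),
        bedroc=bedroc(lr, params),
        tg=total_gain(lr, params),
        screening_pct_per_active=pct,
        fold_enrichment=ef,
        hit_rate_pct=hit_rate(len(wanted_actives), distinct_parents),
        N=lr.N,
        n=lr.n,
        treatment=treatment,
        name=screen.name,
        template_id=screen.template_id,
        screen_type=screen.screen_type,
        alpha=params.alpha,
        tg_window=params.resolved_window(lr.N),
        n_appended_actives=lr.n_appended,
    )
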