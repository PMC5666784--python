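"""Canonical data model for ranked screens and binary activity labels.

A virtual screen scores every *enumerated state* (tautomer, protonation
state, stereoisomer, possibly conformer) of every parent compound, so a raw
rank list carries redundancy: one parent may occupy many rows.  Enrichment
can be evaluated over the full state population (the ``redundant``
treatment) or after collapsing each parent to its single best-scoring state
(the ``no_duplicates`` treatment).  This module holds the screen/activity
containers, applies activity labels, performs the best-state collapse, and
materializes ranks under the two tie policies the metric panel needs.

Score direction is normalized once at ingestion: internally every ranking
stores scores on a "higher is better" scale, so all downstream metrics
consume a single convention regardless of whether the screen was
docking-like (lower raw score better) or similarity-like (higher better).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import MetadataError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"
DIRECTIONS = (LOWER_BETTER, HIGHER_BETTER)

STRUCTURE_BASED = "structure_based"
LIGAND_BASED = "ligand_based"

REDUNDANT = "redundant"
NO_DUPLICATES = "no_duplicates"
TREATMENTS = (REDUNDANT, NO_DUPLICATES)

#: Residual-activity cutoff (percent) separating actives from inactives.
DEFAULT_THRESHOLD_PCT = 40.0


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise MetadataError(
            f"score direction must be one of {DIRECTIONS}, got {direction!r}"
        )


@dataclass(frozen=True)
class StateRecord:
    """One enumerated ligand state with its screen score."""

    state_id: str
    parent_id: str
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValidationError(
                f"state {self.state_id!r}: score must be finite, got {self.score!r}"
            )


@dataclass
class RankedScreen:
    """An ordered screen output: one row per enumerated state, best first.

    ``records`` is a DataFrame with columns ``state_id``, ``parent_id``,
    ``score`` sorted best-first according to ``direction`` with a stable
    (input-order-preserving) tie order.
    """

    records: pd.DataFrame
    direction: str
    screen_type: str = STRUCTURE_BASED
    template_id: str = ""
    name: str = ""

    REQUIRED_COLUMNS = ("state_id", "parent_id", "score")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        direction: str,
        screen_type: str = STRUCTURE_BASED,
        template_id: str = "",
        name: str = "",
    ) -> "RankedScreen":
        """Validate a raw state table and sort it best-first.

        Ties keep the original row order (stable sort), which downstream
        fixes the tie order recorded by the ranking.
        """
        _check_direction(direction)
        missing = [c for c in cls.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"screen table is missing column(s) {missing}")
        df = frame.loc[:, list(cls.REQUIRED_COLUMNS)].copy()

        scores = pd.to_numeric(df["score"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(scores.to_numpy(dtype=float, na_value=np.nan)))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"row {i + 1} (state_id={df['state_id'].iloc[i]!r}): "
                f"non-numeric or non-finite score {df['score'].iloc[i]!r}"
            )
        df["score"] = scores.astype(float)
        df["state_id"] = df["state_id"].astype(str)
        df["parent_id"] = df["parent_id"].astype(str)

        dup = df["state_id"].duplicated()
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"row {i + 1}: duplicate state_id {df['state_id'].iloc[i]!r}"
            )

        ascending = direction == LOWER_BETTER
        df = df.sort_values("score", ascending=ascending, kind="stable")
        df = df.reset_index(drop=True)
        logger.debug("ingested screen %r: %d state rows", name, len(df))
        return cls(
            records=df,
            direction=direction,
            screen_type=screen_type,
            template_id=template_id,
            name=name,
        )

    @classmethod
    def from_records(
        cls, records: Iterable[StateRecord], direction: str, **kwargs
    ) -> "RankedScreen":
        frame = pd.DataFrame(
            [(r.state_id, r.parent_id, r.score) for r in records],
            columns=list(cls.REQUIRED_COLUMNS),
        )
        return cls.from_frame(frame, direction, **kwargs)

    def __len__(self) -> int:
        return len(self.records)

    def internal_scores(self) -> np.ndarray:
        """Scores mapped onto the internal higher-is-better scale."""
        s = self.records["score"].to_numpy(dtype=float)
        return -s if self.direction == LOWER_BETTER else s


@dataclass
class ActivityTable:
    """Per-parent residual kinase activities (percent of uninhibited enzyme
    activity remaining) and the active/inactive threshold rule.

    A compound is *active* on the primary kinase iff its residual activity is
    at or below ``threshold_pct`` (inclusive boundary).
    """

    rows: pd.DataFrame  # index: compound_id; one column per kinase, percent
    primary_kinase: str
    threshold_pct: float = DEFAULT_THRESHOLD_PCT

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_pct < 100.0:
            raise ParameterError(
                f"threshold_pct must lie in (0, 100), got {self.threshold_pct}"
            )
        if self.primary_kinase not in self.rows.columns:
            raise ValidationError(
                f"primary kinase {self.primary_kinase!r} not among kinase "
                f"columns {list(self.rows.columns)}"
            )
        vals = self.rows.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"compound {self.rows.index[r]!r}: missing residual for "
                f"kinase {self.rows.columns[c]!r}"
            )
        if (vals < 0).any() or (vals > 100).any():
            r, c = np.argwhere((vals < 0) | (vals > 100))[0]
            raise ValidationError(
                f"compound {self.rows.index[r]!r}, kinase "
                f"{self.rows.columns[c]!r}: residual activity "
                f"{vals[r, c]} outside [0, 100]"
            )

    @classmethod
    def from_mapping(
        cls,
        residuals: Mapping[str, Mapping[str, float]],
        primary_kinase: str,
        threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    ) -> "ActivityTable":
        df = pd.DataFrame.from_dict(residuals, orient="index")
        df.index.name = "compound_id"
        return cls(rows=df, primary_kinase=primary_kinase, threshold_pct=threshold_pct)

    def is_active(self, compound_id: str) -> bool:
        return bool(
            self.rows.at[compound_id, self.primary_kinase] <= self.threshold_pct
        )

    def active_ids(self, threshold_pct: float | None = None) -> list[str]:
        """Compound ids active on the primary kinase, in table order.

        ``threshold_pct`` overrides the table's threshold (e.g. a stricter
        cutoff selecting only the potent subset).
        """
        t = self.threshold_pct if threshold_pct is None else threshold_pct
        mask = self.rows[self.primary_kinase] <= t
        return [str(i) for i in self.rows.index[mask]]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.rows.index

    def __len__(self) -> int:
        return len(self.rows)


WORST = "worst"
AVERAGE = "average"
TIE_POLICIES = (WORST, AVERAGE)


@dataclass
class LabeledRanking:
    """The ordered binary label sequence every enrichment metric consumes.

    ``scores`` are on the internal higher-is-better scale and are sorted
    non-increasing; entries with equal scores form contiguous tie blocks in a
    stable, recorded order.  ``n_appended`` counts pseudo-entries added for
    actives that the screen never reported (treated as screened last).
    """

    ids: np.ndarray
    parent_ids: np.ndarray
    labels: np.ndarray  # bool: True = active
    scores: np.ndarray  # internal higher-is-better
    treatment: str
    name: str = ""
    template_id: str = ""
    screen_type: str = ""
    n_appended: int = 0
    _rank_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ParameterError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        self.ids = np.asarray(self.ids, dtype=object)
        self.parent_ids = np.asarray(self.parent_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.ids) == len(self.parent_ids) == len(self.labels) == len(self.scores)):
            raise ParameterError("LabeledRanking field lengths differ")
        if np.any(np.diff(self.scores) > 0):
            raise ParameterError("scores must be non-increasing (best first)")

    @property
    def N(self) -> int:
        """Total entries."""
        return len(self.labels)

    @property
    def n(self) -> int:
        """Active entries."""
        return int(self.labels.sum())

    @property
    def ranks_of_actives(self) -> np.ndarray:
        """1-based positions of active entries in the stable best-first
        order; strictly increasing.  This is the rank convention the
        exponential early-recognition metrics use."""
        return np.flatnonzero(self.labels) + 1

    def ranks(self, tie_policy: str = WORST) -> np.ndarray:
        """Materialize 1-based ranks for every entry under a tie policy.

        ``worst``: all members of a tie block receive the block's maximal
        position (pessimistic; used for screening percentage — ties mean you
        cannot stop screening mid-block).  ``average``: block members receive
        the mean position (the Mann–Whitney convention the AUC uses).
        """
        if tie_policy not in TIE_POLICIES:
            raise ParameterError(
                f"tie_policy must be one of {TIE_POLICIES}, got {tie_policy!r}"
            )
        if tie_policy not in self._rank_cache:
            method = "max" if tie_policy == WORST else "average"
            self._rank_cache[tie_policy] = rankdata(-self.scores, method=method)
        return self._rank_cache[tie_policy]

    def active_parent_ids(self) -> list[str]:
        """Distinct parent ids labeled active, in ranking order."""
        seen: dict[str, None] = {}
        for pid, lab in zip(self.parent_ids, self.labels):
            if lab and pid not in seen:
                seen[pid] = None
        return list(seen)


def label_ranking(
    screen: RankedScreen,
    activity: ActivityTable,
    on_missing: str = "error",
    active_ids: Iterable[str] | None = None,
) -> LabeledRanking:
    """Attach activity labels to every state of a screen (redundant form).

    Every state inherits its parent's label: active iff the parent's
    residual activity on the primary kinase is at or below the table's
    threshold.  ``active_ids`` overrides the threshold rule with an explicit
    active set (all listed parents active, everything else inactive) — used
    e.g. to restrict evaluation to the potent subset.

    Parents absent from the activity table are a hard error by default
    (silent drops corrupt the total count N); ``on_missing='drop'`` excludes
    them with a logged count instead.
    """
    if on_missing not in ("error", "drop"):
        raise ParameterError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
    df = screen.records
    parent = df["parent_id"].to_numpy(dtype=object)
    known = np.fromiter((p in activity for p in parent), dtype=bool, count=len(parent))
    if not known.all():
        n_missing = int((~known).sum())
        if on_missing == "error":
            first = parent[~known][0]
            raise ValidationError(
                f"{n_missing} state(s) reference parents absent from the "
                f"activity table (first: {first!r}); pass on_missing='drop' "
                "to exclude them"
            )
        logger.warning(
            "dropping %d state(s) whose parents are absent from the activity table",
            n_missing,
        )
    keep = np.flatnonzero(known)
    parent = parent[keep]
    if active_ids is not None:
        active_set = set(active_ids)
        labels = np.fromiter((p in active_set for p in parent), dtype=bool, count=len(parent))
    else:
        residual = activity.rows[activity.primary_kinase]
        labels = np.fromiter(
            (residual.at[p] <= activity.threshold_pct for p in parent),
            dtype=bool,
            count=len(parent),
        )
    scores = screen.internal_scores()[keep]
    return LabeledRanking(
        ids=df["state_id"].to_numpy(dtype=object)[keep],
        parent_ids=parent,
        labels=labels,
        scores=scores,
        treatment=REDUNDANT,
        name=screen.name,
        template_id=screen.template_id,
        screen_type=screen.screen_type,
    )


def collapse_no_duplicates(ranking: LabeledRanking) -> LabeledRanking:
    """Collapse a redundant ranking to one entry per parent: its best state.

    Because the input is sorted best-first with a stable tie order, the first
    occurrence of each parent is its best-scoring state, and within-parent
    score ties keep the earlier state in the input order.  The output order
    is the order induced by the kept scores.  Idempotent.
    """
    if ranking.treatment == NO_DUPLICATES:
        return ranking
    _, first = np.unique(ranking.parent_ids.astype(str), return_index=True)
    first.sort()  # unique() returns indices of first occurrence; keep ranking order
    return LabeledRanking(
        ids=ranking.ids[first],
        parent_ids=ranking.parent_ids[first],
        labels=ranking.labels[first],
        scores=ranking.scores[first],
        treatment=NO_DUPLICATES,
        name=ranking.name,
        template_id=ranking.template_id,
        screen_type=ranking.screen_type,
        n_appended=ranking.n_appended,
    )


def assign_ranks(ranking: LabeledRanking, tie_policy: str = WORST) -> np.ndarray:
    """1-based ranks for every entry of ``ranking`` under ``tie_policy``
    (see :meth:`LabeledRanking.ranks`)."""
    return ranking.ranks(tie_policy)


def append_missing_actives(
    ranking: LabeledRanking,
    activity: ActivityTable,
    active_ids: Iterable[str] | None = None,
    policy: str = "append",
) -> LabeledRanking:
    """Append actives the screen never reported as bottom-ranked entries.

    A compound a screen failed to place (e.g. a docking failure) still had
    to be screened last in any physical follow-up, so for recovery
    arithmetic it is appended below every reported entry, one pseudo-entry
    per missing active, in stable (activity-table) order with distinct
    sentinel scores.  ``policy='error'`` raises instead.
    """
    if policy not in ("append", "error"):
        raise ParameterError(f"policy must be 'append' or 'error', got {policy!r}")
    wanted = list(active_ids) if active_ids is not None else activity.active_ids()
    present = set(ranking.parent_ids.astype(str))
    missing = [a for a in wanted if a not in present]
    if not missing:
        return ranking
    if policy == "error":
        raise ValidationError(
            f"{len(missing)} active(s) absent from the screen (first: {missing[0]!r})"
        )
    logger.warning(
        "appending %d unreported active(s) at the bottom of %r", len(missing), ranking.name
    )
    floor = ranking.scores.min() if ranking.N else 0.0
    extra_scores = floor - 1.0 - np.arange(len(missing), dtype=float)
    return replace(
        ranking,
        ids=np.concatenate([ranking.ids, np.array([f"{m}::unreported" for m in missing], dtype=object)]),
        parent_ids=np.concatenate([ranking.parent_ids, np.array(missing, dtype=object)]),
        labels=np.concatenate([ranking.labels, np.ones(len(missing), dtype=bool)]),
        scores=np.concatenate([ranking.scores, extra_scores]),
        n_appended=ranking.n_appended + len(missing),
        _rank_cache={},
    )
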