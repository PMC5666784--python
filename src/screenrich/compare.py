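"""Comparative analyses over enrichment reports.

Three comparisons recur when benchmarking virtual screens against one
experimentally screened collection:

* redundant vs no-duplicates deltas for one screen (how much of the
  apparent enrichment is redundancy inflation);
* sensitivity of a method to the query/template choice across a panel of
  screens of the same collection;
* sequential-screening transfer — does the template ranking established by
  a fast first-stage (ligand-based) screen predict second-stage
  (structure-based) performance on the same templates?

AUC deltas are additionally expressed as a percent of the 0.5 dynamic range
between random (0.5) and ideal (1.0) performance, which is the natural
scale for statements like "redundancy moved the result by 20% of the
achievable range".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ComparisonError, ParameterError
from .metrics import EnrichmentReport
from .ranking import NO_DUPLICATES, REDUNDANT

__all__ = [
    "RedundancyComparison",
    "TemplateSensitivity",
    "TransferReport",
    "compare_redundancy",
    "template_sensitivity",
    "evaluate_transfer",
]

#: Dynamic range of ROC AUC between random (0.5) and ideal (1.0).
AUC_RANGE = 0.5

_PAIRED_METRICS = ("auc", "rie", "bedroc", "tg")


@dataclass
class RedundancyComparison:
    """Metric-wise (redundant, no_duplicates, delta) triples for one screen."""

    name: str
    template_id: str
    metrics: Mapping[str, tuple[float, float, float]]  # metric -> (red, dedup, delta)
    auc_delta_pct_of_range: float
    n_red: int
    n_dedup: int
    N_red: int
    N_dedup: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "template_id": self.template_id,
            "metrics": {k: list(v) for k, v in self.metrics.items()},
            "auc_delta_pct_of_range": self.auc_delta_pct_of_range,
            "n_red": self.n_red,
            "n_dedup": self.n_dedup,
            "N_red": self.N_red,
            "N_dedup": self.N_dedup,
        }


def compare_redundancy(
    report_red: EnrichmentReport, report_dedup: EnrichmentReport
) -> RedundancyComparison:
    """Delta panel between the two redundancy treatments of one screen.

    Antisymmetric in its arguments up to the treatment roles: swapping the
    reports negates every delta.  Both reports must come from the same
    screen (name and template), differing only in treatment.
    """
    if report_red.treatment != REDUNDANT or report_dedup.treatment != NO_DUPLICATES:
        raise ComparisonError(
            "expected (redundant, no_duplicates) reports, got "
            f"({report_red.treatment!r}, {report_dedup.treatment!r})"
        )
    if (report_red.name, report_red.template_id) != (
        report_dedup.name,
        report_dedup.template_id,
    ):
        raise ComparisonError(
            "reports come from different screens: "
            f"{report_red.name!r}/{report_red.template_id!r} vs "
            f"{report_dedup.name!r}/{report_dedup.template_id!r}"
        )
    metrics = {}
    for m in _PAIRED_METRICS:
        a, b = getattr(report_red, m), getattr(report_dedup, m)
        metrics[m] = (a, b, a - b)
    delta_auc = metrics["auc"][2]
    return RedundancyComparison(
        name=report_red.name,
        template_id=report_red.template_id,
        metrics=metrics,
        auc_delta_pct_of_range=100.0 * delta_auc / AUC_RANGE,
        n_red=report_red.n,
        n_dedup=report_dedup.n,
        N_red=report_red.N,
        N_dedup=report_dedup.N,
    )


@dataclass
class TemplateSensitivity:
    """Per-template metric table with range/mean/min/max summaries."""

    table: pd.DataFrame  # index: template_id; columns: metrics
    summary: Mapping[str, Mapping[str, float]]  # metric -> {mean,min,max,range}
    min_auc_template: str
    max_auc_template: str

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="index"),
            "summary": {k: dict(v) for k, v in self.summary.items()},
            "min_auc_template": self.min_auc_template,
            "max_auc_template": self.max_auc_template,
        }


def template_sensitivity(reports: Sequence[EnrichmentReport]) -> TemplateSensitivity:
    """Impact of query/template selection on a panel of screens.

    All reports must share the redundancy treatment and the activity ground
    truth (checked via the active count n).  The per-metric mean is the
    plain arithmetic mean over templates.
    """
    if len(reports) < 2:
        raise ParameterError("template sensitivity needs >= 2 reports")
    treatments = {r.treatment for r in reports}
    if len(treatments) != 1:
        raise ComparisonError(f"reports mix redundancy treatments: {sorted(treatments)}")
    # the active *entry* count n legitimately differs across redundant
    # screens (state expansion is screen-specific); the active parent set,
    # when recorded, must not
    key_sets = {frozenset(r.screening_pct_per_active) for r in reports if r.screening_pct_per_active}
    if len(key_sets) > 1:
        raise ComparisonError(
            "reports track different active compounds; different activity tables?"
        )
    table = pd.DataFrame(
        {m: [getattr(r, m) for r in reports] for m in _PAIRED_METRICS},
        index=pd.Index([r.template_id for r in reports], name="template_id"),
    )
    summary = {
        m: {
            "mean": float(table[m].mean()),
            "min": float(table[m].min()),
            "max": float(table[m].max()),
            "range": float(table[m].max() - table[m].min()),
        }
        for m in _PAIRED_METRICS
    }
    return TemplateSensitivity(
        table=table,
        summary=summary,
        min_auc_template=str(table["auc"].idxmin()),
        max_auc_template=str(table["auc"].idxmax()),
    )


@dataclass
class TransferReport:
    """Does stage-1 (ligand-based) template performance predict stage-2
    (structure-based) performance on the same templates?"""

    template_ids: list[str]
    stage1_auc: list[float]
    stage2_auc: list[float]
    spearman_rho: float
    best_template_agreement: bool
    stage1_best: str
    stage2_best: str

    def to_dict(self) -> dict:
        return {
            "template_ids": self.template_ids,
            "stage1_auc": self.stage1_auc,
            "stage2_auc": self.stage2_auc,
            "spearman_rho": self.spearman_rho,
            "best_template_agreement": self.best_template_agreement,
            "stage1_best": self.stage1_best,
            "stage2_best": self.stage2_best,
        }


def evaluate_transfer(
    stage1: Sequence[EnrichmentReport], stage2: Sequence[EnrichmentReport]
) -> TransferReport:
    """Rank-correlate stage-1 and stage-2 AUCs over shared templates.

    The agreement flag is True iff the best-AUC template coincides across
    stages — the practical question when the first stage is used to pick
    the single template for the slower second stage.
    """
    s1 = {r.template_id: r for r in stage1}
    s2 = {r.template_id: r for r in stage2}
    shared = [t for t in s1 if t in s2]
    if not shared:
        raise ComparisonError("stage-1 and stage-2 reports share no template ids")
    if len(shared) < 3:
        raise ParameterError(
            f"need >= 3 shared templates for a rank correlation, got {len(shared)}"
        )
    a1 = [s1[t].auc for t in shared]
    a2 = [s2[t].auc for t in shared]
    rho = float(spearmanr(a1, a2).statistic)
    best1 = shared[int(np.argmax(a1))]
    best2 = shared[int(np.argmax(a2))]
    return TransferReport(
        template_ids=list(shared),
        stage1_auc=a1,
        stage2_auc=a2,
        spearman_rho=rho,
        best_template_agreement=best1 == best2,
        stage1_best=best1,
        stage2_best=best2,
    )
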