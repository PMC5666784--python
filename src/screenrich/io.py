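"""File interchange: screen/activity CSVs, JSON sidecars and reports.

CSV is the canonical interchange format (headered, comma-delimited, ``.``
decimal).  A screen CSV has columns ``state_id, parent_id, score``; its
JSON sidecar carries the metadata a bare rank list cannot: score direction,
screen type, template id and, for synthetic screens, the generating config
and seed.  An activity CSV has a ``compound_id`` column plus one column per
kinase with residual activities in percent.

Report JSONs are written with sorted keys and full double precision so that
a rerun with the same inputs and seed is byte-identical; display CSVs round
to two decimals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .errors import MetadataError, ValidationError
from .metrics import EnrichmentReport
from .ranking import DIRECTIONS, ActivityTable, RankedScreen, DEFAULT_THRESHOLD_PCT

logger = logging.getLogger(__name__)

__all__ = [
    "read_screen_csv",
    "write_screen_csv",
    "read_activity_csv",
    "write_activity_csv",
    "write_report",
    "read_report",
    "write_json",
    "sha256_of",
]


def sidecar_path(screen_path: str | Path) -> Path:
    return Path(screen_path).with_suffix(".json")


def read_screen_csv(
    path: str | Path,
    sidecar: str | Path | None = None,
    direction: str | None = None,
    screen_type: str | None = None,
    template_id: str | None = None,
    name: str | None = None,
) -> RankedScreen:
    """Read a screen CSV (+ optional JSON sidecar) into a RankedScreen.

    Metadata resolution order: explicit keyword > sidecar > error (direction
    is mandatory; screen_type defaults to structure_based).  The file may be
    unsorted; rows are sorted best-first on ingestion and the original
    order remains recoverable from the per-state sidecar-independent
    state_id column.
    """
    path = Path(path)
    meta: dict = {}
    sc = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    direction = direction or meta.get("direction")
    if direction is None:
        raise MetadataError(
            f"{path}: score direction not given and no sidecar at {sc}; "
            "pass direction= or provide a sidecar"
        )
    if direction not in DIRECTIONS:
        raise MetadataError(f"{path}: invalid direction {direction!r}")
    try:
        frame = pd.read_csv(path, dtype={"state_id": str, "parent_id": str})
    except Exception as exc:  # noqa: BLE001 - surface parser failures uniformly
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    screen = RankedScreen.from_frame(
        frame,
        direction=direction,
        screen_type=screen_type or meta.get("screen_type", "structure_based"),
        template_id=template_id if template_id is not None else meta.get("template_id", ""),
        name=name if name is not None else meta.get("name", path.stem),
    )
    logger.info("read %d state rows from %s", len(screen), path)
    return screen


def write_screen_csv(
    screen: RankedScreen, path: str | Path, extra_meta: dict | None = None
) -> Path:
    """Write a screen CSV plus its JSON metadata sidecar; returns the
    sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    screen.records.to_csv(path, index=False)
    meta = {
        "direction": screen.direction,
        "screen_type": screen.screen_type,
        "template_id": screen.template_id,
        "name": screen.name,
        "n_rows": len(screen),
    }
    if extra_meta:
        meta.update(extra_meta)
    sc = sidecar_path(path)
    write_json(meta, sc)
    return sc


def read_activity_csv(
    path: str | Path,
    primary_kinase: str | None = None,
    threshold: float = DEFAULT_THRESHOLD_PCT,
) -> ActivityTable:
    """Read an activity CSV (compound_id + one residual column per kinase).

    ``primary_kinase`` defaults to the first kinase column.  Values must be
    percentages in [0, 100]; empty or out-of-range cells raise a validation
    error naming the compound.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'compound_id'")
    kinases = [c for c in df.columns if c != "compound_id"]
    if not kinases:
        raise ValidationError(f"{path}: needs at least one kinase column")
    dup = df["compound_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate compound_id {df['compound_id'][dup].iloc[0]!r}"
        )
    rows = df.set_index("compound_id")[kinases].apply(pd.to_numeric, errors="coerce")
    table = ActivityTable(
        rows=rows,
        primary_kinase=primary_kinase or kinases[0],
        threshold_pct=threshold,
    )
    logger.info(
        "read %d compounds from %s (%d active at threshold %.4g%%)",
        len(table),
        path,
        len(table.active_ids()),
        threshold,
    )
    return table


def write_activity_csv(activity: ActivityTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = activity.rows.reset_index()
    out = out.rename(columns={out.columns[0]: "compound_id"})
    out.to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    """Canonical JSON writer: sorted keys, full precision, trailing newline
    — byte-identical across reruns of the same computation."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n")
    return path


def write_report(
    report: EnrichmentReport, path: str | Path, provenance: dict | None = None
) -> Path:
    """Serialize a report as JSON (full precision) and a sibling display CSV
    rounded to two decimals."""
    path = Path(path)
    payload = report.to_dict()
    if provenance:
        payload["provenance"] = provenance
    write_json(payload, path)
    row = {
        k: (round(v, 4) if isinstance(v, float) else v)
        for k, v in report.to_dict().items()
        if not isinstance(v, dict)
    }
    for pid, pct in report.screening_pct_per_active.items():
        row[f"screening_pct[{pid}]"] = round(pct, 2)
    for frac, ef in report.fold_enrichment.items():
        row[f"fold_enrichment[{frac}%]"] = round(ef, 2)
    pd.DataFrame([row]).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_report(path: str | Path) -> EnrichmentReport:
    return EnrichmentReport.from_dict(json.loads(Path(path).read_text()))


def write_roc_csv(points, path: str | Path) -> Path:
    """ROC polygon vertices as a two-column CSV (fpr, tpr) for plotting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, index=False)
    return path


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
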