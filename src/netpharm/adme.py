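"""ADME bioactivity screening of herb components.

Stage 1 of the pipeline: constituent components of a multi-herb formula are
filtered to *bioactive* components by two absorption/distribution proxies —
oral bioavailability (OB, a percentage) and drug-likeness (DL, a unitless
0-1 score).  The screening rule is inclusive on both thresholds
(OB >= 20 % and DL >= 0.18 by default).  Components may additionally carry a
``manual_keep`` flag marking curation-based retention regardless of their
ADME values (e.g. constituents retained for their reported pharmacology);
the flag is table data, not algorithm.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("component_id", "name", "herb", "ob", "dl")

_TRUE = {"1", "true", "yes", "y"}


class SchemaError(ValueError):
    """A required column is missing from a component table."""


@dataclass(frozen=True)
class ComponentRecord:
    """One herb component with its ADME properties and provenance."""

    component_id: str
    name: str
    herb: str
    ob: float | None  # oral bioavailability, percent; None = not reported
    dl: float | None  # drug-likeness, 0-1; None = not reported
    manual_keep: bool = False


def _parse_float(field: str) -> float | None:
    field = field.strip()
    if field in ("", "NA", "na", "NaN", "nan", "."):
        return None
    return float(field)


def read_component_table(path: str | Path) -> list[ComponentRecord]:
    """Read a tab-separated component table.

    Required columns: component_id, name, herb, ob, dl; optional manual_keep.
    Blank OB/DL cells parse as absent (``None``), never as zero.
    """
    path = Path(path)
    with path.open() as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].lstrip().startswith("#")]
    if not rows:
        return []
    header = [h.strip() for h in rows[0]]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}
    records = []
    seen: set[str] = set()
    for r in rows[1:]:
        cid = r[idx["component_id"]].strip()
        if cid in seen:
            raise SchemaError(f"{path}: duplicate component_id {cid!r}")
        seen.add(cid)
        manual = False
        if "manual_keep" in idx and len(r) > idx["manual_keep"]:
            manual = r[idx["manual_keep"]].strip().lower() in _TRUE
        records.append(ComponentRecord(
            component_id=cid,
            name=r[idx["name"]].strip(),
            herb=r[idx["herb"]].strip(),
            ob=_parse_float(r[idx["ob"]]),
            dl=_parse_float(r[idx["dl"]]),
            manual_keep=manual,
        ))
    return records


def write_component_table(records: list[ComponentRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("component_id\tname\therb\tob\tdl\tmanual_keep\n")
        for r in records:
            ob = "" if r.ob is None else repr(r.ob)
            dl = "" if r.dl is None else repr(r.dl)
            fh.write(f"{r.component_id}\t{r.name}\t{r.herb}\t{ob}\t{dl}\t"
                     f"{'true' if r.manual_keep else 'false'}\n")


def screen_bioactive(
    records: list[ComponentRecord],
    ob_min: float = 20.0,
    dl_min: float = 0.18,
    keep_manual: bool = True,
) -> list[ComponentRecord]:
    """Filter components to those with OB >= ob_min and DL >= dl_min.

    Both comparisons are inclusive.  Records with an absent OB or DL fail the
    numeric filter (screening is on stated values only) but are retained when
    flagged ``manual_keep`` and ``keep_manual`` is on.  Input order is
    preserved; per-herb retention counts are logged.  Idempotent.
    """
    if ob_min < 0 or dl_min < 0:
        raise ValueError("ob_min and dl_min must be non-negative")
    kept = []
    for r in records:
        passes = r.ob is not None and r.dl is not None and r.ob >= ob_min and r.dl >= dl_min
        if passes or (keep_manual and r.manual_keep):
            kept.append(r)
    by_herb: dict[str, int] = {}
    for r in kept:
        by_herb[r.herb] = by_herb.get(r.herb, 0) + 1
    for herb in sorted(by_herb):
        logger.info("adme_screen: retained %d component(s) from %s", by_herb[herb], herb)
    return kept
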