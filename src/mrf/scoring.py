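"""Per-patient MRF scoring.

Each medication on a patient's list contributes the points of the highest-risk
catalog class it resolves to (high = 3, moderate = 2, low = 1); drugs outside
the catalog contribute 0 but are reported, never dropped. The patient's overall
medication-related falls risk is the sum of these contributions over the
distinct medications on the list. Any high- or moderate-risk medication raises a
referral flag prompting a medication review and fall-prevention strategies; no
numeric total threshold is built in because the interpretation and risk
threshold of the summed score remain to be established, so a threshold is only
available as an explicit caller option.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .catalog import MrfCatalog, TIER_SCORES, lookup_drug

__all__ = [
    "MedicationEntry",
    "PatientScore",
    "score_medication",
    "score_patient",
    "render_report",
    "read_med_list",
]

_TIER_ORDER = ("high", "moderate", "low")


@dataclass(frozen=True)
class MedicationEntry:
    """One scored medication: resolution outcome and score contribution."""

    raw_name: str
    normalized_name: str
    resolved_classes: tuple[str, ...]  # class_ids, sorted
    contribution: int  # max tier score over resolved classes; 0 if unresolved
    resolved: bool
    contributing_tier: str | None  # tier that supplied the max, None if unresolved

    def to_dict(self) -> dict:
        return {
            "raw_name": self.raw_name,
            "normalized_name": self.normalized_name,
            "resolved_classes": list(self.resolved_classes),
            "contribution": self.contribution,
            "resolved": self.resolved,
            "contributing_tier": self.contributing_tier,
        }


@dataclass(frozen=True)
class PatientScore:
    """Per-patient result: entries, total score, tier breakdown, referral flag."""

    entries: tuple[MedicationEntry, ...]
    total: int
    tier_counts: dict[str, int] = field(default_factory=dict)
    unresolved_count: int = 0
    referral_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "entries": [e.to_dict() for e in self.entries],
            "total": self.total,
            "tier_counts": dict(self.tier_counts),
            "unresolved_count": self.unresolved_count,
            "referral_flag": self.referral_flag,
        }


def score_medication(catalog: MrfCatalog, raw_name: str) -> MedicationEntry:
    """Score one medication: highest tier score over all classes it belongs to.

    A drug falling into more than one medication class is assigned the highest
    of the class scores. An unresolved drug contributes 0.
    """
    result = lookup_drug(catalog, raw_name)
    if result.classes:
        best = max(result.classes, key=lambda c: TIER_SCORES[c.tier])
        contribution = TIER_SCORES[best.tier]
        tier = best.tier
    else:
        contribution, tier = 0, None
    return MedicationEntry(
        raw_name=raw_name,
        normalized_name=result.generic_name,
        resolved_classes=tuple(c.class_id for c in result.classes),
        contribution=contribution,
        resolved=bool(result.classes),
        contributing_tier=tier,
    )


def score_patient(catalog: MrfCatalog, med_list: Sequence[str]) -> PatientScore:
    """Score a patient's medication list by summing per-medication contributions.

    Medications are deduplicated by normalized generic name before summation —
    the score counts medications, not prescription lines, so the same drug
    supplied as two products is counted once. The empty list is a valid
    zero-score patient.
    """
    entries: list[MedicationEntry] = []
    seen: set[str] = set()
    for raw in med_list:
        entry = score_medication(catalog, raw)
        if entry.normalized_name in seen:
            continue
        seen.add(entry.normalized_name)
        entries.append(entry)
    tier_counts = {t: 0 for t in _TIER_ORDER}
    for e in entries:
        if e.contributing_tier is not None:
            tier_counts[e.contributing_tier] += 1
    return PatientScore(
        entries=tuple(entries),
        total=sum(e.contribution for e in entries),
        tier_counts=tier_counts,
        unresolved_count=sum(1 for e in entries if not e.resolved),
        referral_flag=any(
            e.contributing_tier in ("high", "moderate") for e in entries
        ),
    )


def _text_report(score: PatientScore, catalog: MrfCatalog | None) -> str:
    lines = ["Medication-related falls risk report", "=" * 36]
    for e in score.entries:
        if e.resolved:
            class_bits = []
            for cid in e.resolved_classes:
                if catalog is not None:
                    c = catalog.get_class(cid)
                    class_bits.append(f"{c.name} [{c.tier}]")
                else:
                    class_bits.append(cid)
            lines.append(
                f"  {e.raw_name}: {', '.join(class_bits)} -> {e.contribution} point(s)"
            )
            if catalog is not None:
                for cid in e.resolved_classes:
                    lines.append(f"      mechanism: {catalog.get_class(cid).mechanism}")
        else:
            lines.append(
                f"  {e.raw_name}: WARNING not in catalog (unresolved) -> 0 points"
            )
    lines.append("-" * 36)
    lines.append(f"Total MRF score: {score.total}")
    lines.append(
        "Tier breakdown: "
        + ", ".join(f"{t}={score.tier_counts.get(t, 0)}" for t in _TIER_ORDER)
    )
    lines.append(f"Unresolved medications: {score.unresolved_count}")
    if score.referral_flag:
        lines.append(
            "Referral: patient is taking high- or moderate-risk medication(s); "
            "refer for medication review and fall prevention strategies."
        )
    else:
        lines.append("Referral: not indicated by medication list.")
    return "\n".join(lines) + "\n"


def render_report(
    score: PatientScore,
    format: str = "text",
    catalog: MrfCatalog | None = None,
) -> str:
    """Serialize a patient score as ``text``, ``json`` or ``tsv``.

    The json form round-trips losslessly (parse then re-render gives the
    identical string); passing the catalog enriches text output with class
    names, tiers and mechanism notes.
    """
    if format == "json":
        return json.dumps(score.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "tsv":
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["raw_name", "normalized_name", "classes", "tier", "contribution", "resolved"]
        )
        for e in score.entries:
            writer.writerow([
                e.raw_name, e.normalized_name, ";".join(e.resolved_classes),
                e.contributing_tier or "", e.contribution, e.resolved,
            ])
        writer.writerow(["TOTAL", "", "", "", score.total, ""])
        return buf.getvalue()
    if format == "text":
        return _text_report(score, catalog)
    raise ValueError(f"unknown report format {format!r} (expected text, json or tsv)")


def read_med_list(path: str | Path) -> list[str]:
    """Read a medication list: CSV with a ``medication`` column, else one per line."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".csv":
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames and "medication" in reader.fieldnames:
            return [row["medication"].strip() for row in reader if row["medication"].strip()]
        raise ValueError(f"CSV medication list {path} must have a 'medication' column")
    return [line.strip() for line in text.splitlines() if line.strip()]
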