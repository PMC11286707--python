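"""Medication-Related Fall (MRF) risk catalog: types, loading, validation, lookup.

The catalog is a versioned list of medication classes, each carrying a falls-risk
tier (high / moderate / low), the mechanism by which the class increases falls
risk, its member generic drug names and an alias table (brand names, alternative
spellings, salt-form spellings) mapping onto those generics.

The tier-to-points mapping is fixed: high-risk medications score three points,
moderate-risk two and low-risk one. A drug may belong to more than one class;
the scoring layer resolves that with a highest-score-wins rule.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "TierLabel",
    "TIER_SCORES",
    "TIER_DEFINITIONS",
    "MedicationClass",
    "MrfCatalog",
    "CatalogError",
    "LookupResult",
    "normalize_drug_name",
    "load_catalog",
    "packaged_catalog",
    "packaged_catalog_path",
    "validate_catalog",
    "lookup_drug",
    "ValidationReport",
]

TierLabel = Literal["high", "moderate", "low"]

#: Fixed, total tier -> points mapping.
TIER_SCORES: dict[str, int] = {"high": 3, "moderate": 2, "low": 1}

#: Tier definitions as presented to raters in every survey round.
TIER_DEFINITIONS: dict[str, str] = {
    "high": "Medications that may commonly cause or contribute to falling risk, "
            "on their own or in combination.",
    "moderate": "Medications that may cause falls, especially in combination.",
    "low": "Medications that possibly cause falls, particularly in combination.",
}


class CatalogError(ValueError):
    """Raised when a catalog file or object violates the catalog schema."""


# --- drug-name normalization -------------------------------------------------

_UNIT = r"(?:mg|ml|mcg|microgram(?:s)?|g|iu|units?|%)"
_STRENGTH = rf"\d+(?:[.,]\d+)?{_UNIT}?"
# a bare number/unit, a strength ("40mg"), or a compound strength ("10mg/5ml")
_DOSE_RE = re.compile(rf"^(?:{_STRENGTH}(?:/{_STRENGTH})?|{_UNIT})$")

_FORM_TOKENS = frozenset({
    "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap", "caps",
    "injection", "inj", "solution", "syrup", "suspension", "liquid", "elixir",
    "patch", "patches", "cream", "ointment", "gel", "spray", "drops",
    "suppository", "suppositories", "sachet", "sachets", "inhaler",
    "m/r", "mr", "sr", "xl", "la", "cr", "er", "od", "bd", "tds", "qds", "prn",
    "oral", "modified", "release", "modified-release", "slow", "retard",
})

_SALT_TOKENS = frozenset({
    "hydrochloride", "hcl", "sodium", "potassium", "calcium", "maleate",
    "tartrate", "bitartrate", "sulfate", "sulphate", "citrate", "besilate",
    "besylate", "mesilate", "mesylate", "fumarate", "succinate", "phosphate",
    "acetate", "hydrobromide", "dihydrate", "monohydrate",
})


def normalize_drug_name(raw_name: str) -> str:
    """Normalize a free-text medication name for catalog lookup.

    Case-folds, trims, then strips *trailing* dose/strength tokens (numbers and
    units such as ``40mg``, ``%``), pharmaceutical-form tokens (``tablets``,
    ``capsules``, ``m/r`` ...) and common salt suffixes (``hydrochloride``,
    ``sodium`` ...). Leading tokens are never stripped, so ``sodium valproate``
    survives intact and is resolved through the alias table instead.

    Idempotent: ``normalize_drug_name(normalize_drug_name(x)) == normalize_drug_name(x)``.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise ValueError("medication name must be a non-empty string")
    tokens = raw_name.casefold().strip().split()
    while len(tokens) > 1 and (
        _DOSE_RE.match(tokens[-1]) or tokens[-1] in _FORM_TOKENS
    ):
        tokens.pop()
    while len(tokens) > 1 and tokens[-1] in _SALT_TOKENS:
        tokens.pop()
    return " ".join(tokens)


# --- schema models ------------------------------------------------------------


class MedicationClass(BaseModel):
    """One catalog entry: a medication class with tier, mechanism and members."""

    model_config = ConfigDict(frozen=True)

    class_id: str
    name: str
    tier: TierLabel
    mechanism: str
    members: tuple[str, ...]
    synonyms: dict[str, str] = {}
    # Optional redundant score in the file; must agree with the tier mapping.
    score: int | None = None

    @field_validator("class_id", "name", "mechanism")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be non-empty")
        return v

    @field_validator("members")
    @classmethod
    def _members_non_empty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("members must be non-empty")
        return tuple(normalize_drug_name(m) for m in v)

    @field_validator("synonyms")
    @classmethod
    def _normalize_synonyms(cls, v: dict[str, str]) -> dict[str, str]:
        return {normalize_drug_name(k): normalize_drug_name(t) for k, t in v.items()}

    @model_validator(mode="after")
    def _check_consistency(self) -> "MedicationClass":
        if self.score is not None and self.score != TIER_SCORES[self.tier]:
            raise ValueError(
                f"class {self.class_id!r}: score {self.score} contradicts tier "
                f"{self.tier!r} (must be {TIER_SCORES[self.tier]})"
            )
        for alias, target in self.synonyms.items():
            if target not in self.members:
                raise ValueError(
                    f"class {self.class_id!r}: synonym {alias!r} maps to "
                    f"{target!r}, which is not a member"
                )
        return self

    @property
    def tier_score(self) -> int:
        return TIER_SCORES[self.tier]

    @property
    def tier_definition(self) -> str:
        return TIER_DEFINITIONS[self.tier]


class MrfCatalog(BaseModel):
    """A versioned MRF medication catalog with a normalized drug-name index."""

    model_config = ConfigDict(frozen=True)

    version: str
    provenance: str
    classes: tuple[MedicationClass, ...]
    drug_index: dict[str, frozenset[str]] = {}
    synonym_index: dict[str, str] = {}

    @model_validator(mode="after")
    def _build_indexes(self) -> "MrfCatalog":
        seen: set[str] = set()
        for c in self.classes:
            if c.class_id in seen:
                raise ValueError(f"duplicate class_id {c.class_id!r}")
            seen.add(c.class_id)
        if not self.drug_index:
            index: dict[str, set[str]] = {}
            synonyms: dict[str, str] = {}
            for c in self.classes:
                for m in c.members:
                    index.setdefault(m, set()).add(c.class_id)
                for alias, target in c.synonyms.items():
                    if synonyms.get(alias, target) != target:
                        raise ValueError(
                            f"alias {alias!r} maps to conflicting generics "
                            f"{synonyms[alias]!r} and {target!r}"
                        )
                    synonyms[alias] = target
            object.__setattr__(
                self, "drug_index", {k: frozenset(v) for k, v in index.items()}
            )
            object.__setattr__(self, "synonym_index", synonyms)
        return self

    def get_class(self, class_id: str) -> MedicationClass:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    def tier_counts(self) -> dict[str, int]:
        counts = {"high": 0, "moderate": 0, "low": 0}
        for c in self.classes:
            counts[c.tier] += 1
        return counts

    def members_of_tier(self, tier: str) -> list[str]:
        """All distinct member generic names in classes of the given tier."""
        out: set[str] = set()
        for c in self.classes:
            if c.tier == tier:
                out.update(c.members)
        return sorted(out)


# --- loading ------------------------------------------------------------------


def load_catalog(path: str | Path) -> MrfCatalog:
    """Load and validate a catalog from a JSON file.

    Raises :class:`CatalogError` naming the offending field on any schema
    violation, duplicate class id, or empty file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise CatalogError(f"catalog file {path} is empty")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"catalog file {path} is not valid JSON: {exc}") from exc
    try:
        return MrfCatalog.model_validate(payload)
    except ValidationError as exc:
        locs = "; ".join(
            " -> ".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise CatalogError(f"catalog file {path} failed validation: {locs}") from exc


_PACKAGED_NAME = "mrf_catalog_v1_synthetic.json"


def packaged_catalog_path() -> Path:
    """Filesystem path of the catalog shipped with the package."""
    return Path(str(resources.files("mrf.data").joinpath(_PACKAGED_NAME)))


def packaged_catalog() -> MrfCatalog:
    """Load the packaged v1 catalog (19 classes: 10 high, 8 moderate, 1 low)."""
    return load_catalog(packaged_catalog_path())


# --- validation report --------------------------------------------------------


class ValidationReport(BaseModel):
    """Outcome of every invariant check run against a catalog."""

    checks: list[dict]
    tier_counts: dict[str, int]

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def failures(self) -> list[dict]:
        return [c for c in self.checks if not c["passed"]]


def validate_catalog(
    catalog: MrfCatalog, expected_counts: Mapping[str, int] | None = None
) -> ValidationReport:
    """Re-check every catalog invariant and return a pass/fail report.

    ``expected_counts`` optionally pins the per-tier class counts (the packaged
    v1 catalog must be 10 high / 8 moderate / 1 low). Failures are carried in
    the report, never raised.
    """
    checks: list[dict] = []

    def check(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"name": name, "passed": bool(passed), "detail": detail})

    ids = [c.class_id for c in catalog.classes]
    check("unique_class_ids", len(ids) == len(set(ids)),
          "class_id values must be unique")
    check("version_present", bool(str(catalog.version).strip()), "version non-empty")
    for c in catalog.classes:
        check(f"class:{c.class_id}:name", bool(c.name.strip()), "name non-empty")
        check(f"class:{c.class_id}:members", len(c.members) > 0,
              "members non-empty")
        check(f"class:{c.class_id}:mechanism", bool(c.mechanism.strip()),
              "mechanism non-empty")
        check(f"class:{c.class_id}:tier_score",
              TIER_SCORES.get(c.tier) in {1, 2, 3},
              "tier maps onto a score in {3,2,1}")

    # drug_index consistency: every indexed name appears in exactly the classes
    # that list it, and every member is indexed.
    consistent = True
    detail = ""
    listed: dict[str, set[str]] = {}
    for c in catalog.classes:
        for m in c.members:
            listed.setdefault(m, set()).add(c.class_id)
    for name, class_ids in catalog.drug_index.items():
        if listed.get(name, set()) != set(class_ids):
            consistent = False
            detail = f"index entry {name!r} disagrees with class member lists"
            break
    if consistent and set(listed) != set(catalog.drug_index):
        consistent = False
        detail = "member lists and drug_index cover different drugs"
    check("drug_index_consistent", consistent, detail)

    counts = catalog.tier_counts()
    if expected_counts is not None:
        check(
            "tier_counts",
            all(counts.get(t, 0) == n for t, n in expected_counts.items()),
            f"expected {dict(expected_counts)}, found {counts}",
        )
    return ValidationReport(checks=checks, tier_counts=counts)


# --- lookup -------------------------------------------------------------------


class LookupResult(BaseModel):
    """Result of resolving one raw medication name against the catalog."""

    model_config = ConfigDict(frozen=True)

    raw_name: str
    normalized_name: str
    generic_name: str
    classes: tuple[MedicationClass, ...]
    status: Literal["resolved", "unresolved"]


def lookup_drug(catalog: MrfCatalog, raw_name: str) -> LookupResult:
    """Resolve a raw medication name to the set of catalog classes listing it.

    The name is normalized (case-fold; dose/strength/form tokens and salt
    suffixes stripped), aliases are mapped to their generic names via the
    catalog's synonym table, and the generic is looked up. An unmatched name
    yields an empty class set with status ``unresolved`` — never an error, since
    real medication lists routinely contain drugs outside the catalog.
    """
    normalized = normalize_drug_name(raw_name)
    generic = catalog.synonym_index.get(normalized, normalized)
    class_ids = catalog.drug_index.get(generic, frozenset())
    classes = tuple(
        sorted((catalog.get_class(cid) for cid in class_ids), key=lambda c: c.class_id)
    )
    return LookupResult(
        raw_name=raw_name,
        normalized_name=normalized,
        generic_name=generic,
        classes=classes,
        status="resolved" if classes else "unresolved",
    )
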