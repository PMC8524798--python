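"""Consensus rule base for potentially clinically significant DDIs.

The screening engine works from a table of 66 interaction rules for people
aged 65 and over, established by European expert consensus.  Each rule is
either *pairwise* (drug from group 1 plus drug from group 2, e.g. "oral
anticoagulant + an antiplatelet drug") or a *cardinality* rule (at least k
drugs from one group, e.g. "concomitant use of >=3 centrally-acting drugs").
Groups are expressed purely as sets of ATC prefixes with optional exclusion
prefixes; no dose, route or duration information is modelled.

The packaged rule table is a versioned CSV; :func:`load_default_rules`
returns it parsed and validated.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .atc import ATCFormatError, canonical_atc, is_prefix_of

__all__ = [
    "Mechanism",
    "HarmCategory",
    "DrugGroup",
    "DDIRule",
    "RuleSet",
    "RuleTableError",
    "atc_matches",
    "parse_rule_table",
    "serialize_rule_table",
    "validate_ruleset",
    "load_default_rules",
    "DEFAULT_RULES_RESOURCE",
]

DEFAULT_RULES_RESOURCE = "ddi_rules_synthetic.csv"

CONSENSUS_SIZE = 66


class RuleTableError(ValueError):
    """Raised for malformed or invalid rule-table input."""


class Mechanism(str, enum.Enum):
    """Interaction mechanism: pharmacodynamic, pharmacokinetic or both."""

    PHARMACODYNAMIC = "pharmacodynamic"
    PHARMACOKINETIC = "pharmacokinetic"
    BOTH = "both"


class HarmCategory(str, enum.Enum):
    """Principal potential harm of an interaction (six-way classification)."""

    CARDIOVASCULAR = "cardiovascular"
    NEUROLOGICAL = "neurological"
    BLEEDING = "bleeding"
    RENAL_HYPERKALEMIA = "renal_hyperkalemia"
    HEMATOLOGIC = "hematologic"
    OTHER = "other"


def _canon_prefix(p: str) -> str:
    # group prefixes obey the same level grammar as full codes
    try:
        return canonical_atc(p)
    except ATCFormatError as exc:
        raise RuleTableError(str(exc)) from exc


@dataclass(frozen=True)
class DrugGroup:
    """A set of drugs defined by ATC include/exclude prefixes.

    A code belongs to the group iff some include prefix is an ancestor of it
    and no exclude prefix is.
    """

    name: str
    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        inc = frozenset(_canon_prefix(p) for p in self.include)
        exc = frozenset(_canon_prefix(p) for p in self.exclude)
        if not inc:
            raise RuleTableError(f"group {self.name!r}: empty include set")
        if inc & exc:
            raise RuleTableError(
                f"group {self.name!r}: include and exclude share a prefix"
            )
        object.__setattr__(self, "include", inc)
        object.__setattr__(self, "exclude", exc)

    def contains(self, code: str) -> bool:
        c = canonical_atc(code)
        if any(is_prefix_of(q, c) for q in self.exclude):
            return False
        return any(is_prefix_of(p, c) for p in self.include)


def atc_matches(code: str, group: DrugGroup) -> bool:
    """Membership test of an ATC code in a drug group (prefix semantics)."""
    return group.contains(code)


@dataclass(frozen=True)
class DDIRule:
    """One consensus interaction rule.

    ``kind='pairwise'`` requires one drug from each of two groups (distinct
    codes); ``kind='cardinality'`` requires at least ``min_count`` distinct
    codes from a single group.
    """

    rule_id: int
    label: str
    kind: str  # 'pairwise' | 'cardinality'
    groups: tuple[DrugGroup, ...]
    min_count: int
    mechanism: Mechanism
    harm: HarmCategory
    management: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("pairwise", "cardinality"):
            raise RuleTableError(f"rule {self.rule_id}: unknown kind {self.kind!r}")
        if self.kind == "pairwise":
            if len(self.groups) != 2:
                raise RuleTableError(
                    f"rule {self.rule_id}: pairwise rule needs exactly 2 groups"
                )
            if self.min_count != 1:
                raise RuleTableError(
                    f"rule {self.rule_id}: pairwise rule has min_count per group = 1"
                )
        else:
            if len(self.groups) != 1:
                raise RuleTableError(
                    f"rule {self.rule_id}: cardinality rule needs exactly 1 group"
                )
            if self.min_count < 2:
                raise RuleTableError(f"rule {self.rule_id}: min_count<2")
        if not (1 <= self.rule_id):
            raise RuleTableError(f"rule id must be positive, got {self.rule_id}")


@dataclass
class RuleSet:
    """A validated collection of interaction rules plus provenance."""

    rules: list[DDIRule]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleTableError(f"duplicate rule_id(s): {dup}")
        self.rules = sorted(self.rules, key=lambda r: r.rule_id)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def by_id(self, rule_id: int) -> DDIRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(f"no rule with id {rule_id}")


_COLUMNS = [
    "rule_id",
    "label",
    "kind",
    "group1_include",
    "group1_exclude",
    "group2_include",
    "group2_exclude",
    "min_count",
    "mechanism",
    "harm",
    "management",
]


def _split_prefixes(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(p.strip() for p in cell.split("|") if p.strip())


def _parse_row(row: dict, rownum: int) -> DDIRule:
    def fail(fieldname: str, msg: str) -> RuleTableError:
        return RuleTableError(f"row {rownum}, field {fieldname!r}: {msg}")

    try:
        rule_id = int(row["rule_id"])
    except (TypeError, ValueError):
        raise fail("rule_id", f"not an integer: {row.get('rule_id')!r}")
    label = (row.get("label") or "").strip()
    if not label:
        raise fail("label", "empty")
    kind = (row.get("kind") or "").strip().lower()
    try:
        mechanism = Mechanism((row.get("mechanism") or "").strip().lower())
    except ValueError:
        raise fail("mechanism", f"unknown value {row.get('mechanism')!r}")
    try:
        harm = HarmCategory((row.get("harm") or "").strip().lower())
    except ValueError:
        raise fail("harm", f"unknown value {row.get('harm')!r}")
    try:
        min_count = int(row["min_count"]) if (row.get("min_count") or "").strip() else 1
    except (TypeError, ValueError):
        raise fail("min_count", f"not an integer: {row.get('min_count')!r}")

    g1_inc = _split_prefixes(row.get("group1_include", ""))
    g1_exc = _split_prefixes(row.get("group1_exclude", ""))
    g2_inc = _split_prefixes(row.get("group2_include", ""))
    g2_exc = _split_prefixes(row.get("group2_exclude", ""))
    if not g1_inc:
        raise fail("group1_include", "empty include set")
    try:
        if kind == "pairwise":
            if not g2_inc:
                raise fail("group2_include", "empty include set for pairwise rule")
            groups = (
                DrugGroup(f"rule{rule_id}.group1", g1_inc, g1_exc),
                DrugGroup(f"rule{rule_id}.group2", g2_inc, g2_exc),
            )
        else:
            if g2_inc:
                raise fail("group2_include", "cardinality rule must not have group2")
            groups = (DrugGroup(f"rule{rule_id}.group", g1_inc, g1_exc),)
        return DDIRule(
            rule_id=rule_id,
            label=label,
            kind=kind,
            groups=groups,
            min_count=min_count,
            mechanism=mechanism,
            harm=harm,
            management=(row.get("management") or "").strip(),
        )
    except RuleTableError as exc:
        raise RuleTableError(f"row {rownum}: {exc}") from exc


def _read_table_text(text: str) -> tuple[list[dict], str]:
    version = "unversioned"
    data_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("version:"):
                version = stripped.split(":", 1)[1].strip()
            continue
        if line.strip():
            data_lines.append(line)
    if not data_lines:
        raise RuleTableError("no rules: file is empty")
    delimiter = "\t" if "\t" in data_lines[0] else ","
    reader = csv.DictReader(io.StringIO("\n".join(data_lines)), delimiter=delimiter)
    header = reader.fieldnames or []
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise RuleTableError(f"missing column(s): {missing}")
    return list(reader), version


def parse_rule_table(path: str | Path) -> RuleSet:
    """Parse a rule-table CSV/TSV file into a validated :class:`RuleSet`.

    ``#``-prefixed lines are provenance comments; a ``# version:`` line sets
    the rule-set version string.  Multi-prefix cells use ``|`` separators.
    """
    text = Path(path).read_text(encoding="utf-8")
    rows, version = _read_table_text(text)
    if not rows:
        raise RuleTableError("no rules: table has a header but no rows")
    rules = [_parse_row(row, i + 2) for i, row in enumerate(rows)]
    return RuleSet(rules=rules, version=version)


def serialize_rule_table(rs: RuleSet, path: str | Path) -> None:
    """Write a RuleSet back to the CSV schema (round-trips with parse)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# version: {rs.version}\n")
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
        writer.writeheader()
        for r in rs:
            g1 = r.groups[0]
            g2 = r.groups[1] if len(r.groups) > 1 else None
            writer.writerow(
                {
                    "rule_id": r.rule_id,
                    "label": r.label,
                    "kind": r.kind,
                    "group1_include": "|".join(sorted(g1.include)),
                    "group1_exclude": "|".join(sorted(g1.exclude)),
                    "group2_include": "|".join(sorted(g2.include)) if g2 else "",
                    "group2_exclude": "|".join(sorted(g2.exclude)) if g2 else "",
                    "min_count": r.min_count,
                    "mechanism": r.mechanism.value,
                    "harm": r.harm.value,
                    "management": r.management,
                }
            )


def validate_ruleset(rs: RuleSet, expected_size: int | None = CONSENSUS_SIZE) -> list[str]:
    """Return a list of findings (empty when the rule set is internally valid).

    Structural invariants are enforced at construction time; this reports
    set-level expectations such as the consensus size and contiguous ids.
    """
    findings: list[str] = []
    ids = [r.rule_id for r in rs.rules]
    if expected_size is not None and len(rs) != expected_size:
        findings.append(f"{len(rs)} rules, expected {expected_size}")
    if expected_size is not None and ids and set(ids) != set(range(1, expected_size + 1)):
        missing = sorted(set(range(1, expected_size + 1)) - set(ids))
        extra = sorted(set(ids) - set(range(1, expected_size + 1)))
        if missing:
            findings.append(f"missing rule ids: {missing}")
        if extra:
            findings.append(f"unexpected rule ids: {extra}")
    for r in rs.rules:
        if r.kind == "cardinality" and r.min_count < 2:
            findings.append(f"rule {r.rule_id}: min_count<2")
    return findings


def load_default_rules() -> RuleSet:
    """Load the packaged 66-rule consensus encoding."""
    ref = resources.files("ddiscreen.data").joinpath(DEFAULT_RULES_RESOURCE)
    with resources.as_file(ref) as p:
        return parse_rule_table(p)
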