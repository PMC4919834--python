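"""Diff two provenance logs: which environment differences could affect
(or explain) differing results between two executions?

Modules are matched by name, not by position — load order is environment
noise.  Timestamps (``Start``/``End``/``Elapsed``) are ignored by
default because they differ between any two runs; exit status and
arguments are compared by default because they plausibly explain
divergent behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

from .logformat import LogDocument, parse_module_payload

#: Tags excluded from comparison unless the caller overrides the set.
DEFAULT_IGNORE = frozenset({"Start", "End", "Elapsed"})

CATEGORIES = (
    "module-added",
    "module-removed",
    "module-version",
    "module-path",
    "module-checksum",
    "interpreter",
    "system",
    "search-path",
    "user",
    "program",
    "args",
    "exit-status",
    "extra",
)

_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}

# singleton/repeatable tag -> category
_TAG_CATEGORY = {
    "INC": "search-path",
    "UNAME": "system",
    "INTERP": "interpreter",
    "INTERPVer": "interpreter",
    "INTERPSum": "interpreter",
    "LIBC": "interpreter",
    "LIBCSum": "interpreter",
    "User": "user",
    "Group": "user",
    "ProgDir": "program",
    "Program": "program",
    "Version": "program",
    "ProgSUM": "program",
    "Args": "args",
    "EndStat": "exit-status",
}


@dataclass(frozen=True)
class DiffEntry:
    """One classified difference. ``before``/``after`` are absent only for
    module additions/removals."""

    category: str
    tag: str
    before: str | None
    after: str | None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_RANK:
            raise ValueError(f"unknown diff category {self.category!r}")
        if self.category == "module-added" and self.before is not None:
            raise ValueError("module-added entries have no 'before'")
        if self.category == "module-removed" and self.after is not None:
            raise ValueError("module-removed entries have no 'after'")


@dataclass(frozen=True)
class DiffReport:
    entries: tuple[DiffEntry, ...]
    ignored_tags: frozenset[str]

    @property
    def environments_match(self) -> bool:
        return not self.entries


def _module_table(doc: LogDocument) -> dict[str, tuple[str, str, str]]:
    table: dict[str, tuple[str, str, str]] = {}
    for payload in doc.get_all("MODULE"):
        rec = parse_module_payload(payload)
        table[rec.name] = (rec.version, rec.path, rec.checksum)
    return table


def _diff_modules(a: LogDocument, b: LogDocument) -> list[DiffEntry]:
    ta, tb = _module_table(a), _module_table(b)
    entries: list[DiffEntry] = []
    for name in sorted(set(ta) | set(tb)):
        if name not in tb:
            entries.append(DiffEntry("module-removed", name, " ".join(ta[name]), None))
        elif name not in ta:
            entries.append(DiffEntry("module-added", name, None, " ".join(tb[name])))
        else:
            (va, pa, ca), (vb, pb, cb) = ta[name], tb[name]
            if va != vb:
                entries.append(DiffEntry("module-version", name, va, vb))
            if pa != pb:
                entries.append(DiffEntry("module-path", name, pa, pb))
            if ca != cb:
                entries.append(DiffEntry("module-checksum", name, ca, cb))
    return entries


def _list_payload(payloads: Iterable[str]) -> str:
    return " | ".join(payloads)


def diff_documents(
    a: LogDocument,
    b: LogDocument,
    ignore: AbstractSet[str] = DEFAULT_IGNORE,
) -> DiffReport:
    """Classified comparison of two parsed log documents.

    MODULE records are matched by module name; version/path/checksum
    mismatches and additions/removals are reported per module.  Repeated
    tags (INC, Group, program-specified) are compared as ordered lists;
    PROC records per index, with a count mismatch reported once.  All
    other tags are compared literally unless listed in ``ignore``.
    """
    entries: list[DiffEntry] = []
    if "MODULE" not in ignore:
        entries.extend(_diff_modules(a, b))

    proc_a = [(rec.tag, rec.payload) for rec in a.records if rec.tag.startswith("PROC")]
    proc_b = [(rec.tag, rec.payload) for rec in b.records if rec.tag.startswith("PROC")]
    other_tags = sorted(
        (set(a.tags()) | set(b.tags()))
        - {"MODULE"}
        - {t for t, _ in proc_a}
        - {t for t, _ in proc_b}
        - set(ignore)
    )

    proc_entries: list[DiffEntry] = []
    if "PROC" not in ignore:
        if len(proc_a) != len(proc_b):
            proc_entries.append(
                DiffEntry("system", "PROC-count", str(len(proc_a)), str(len(proc_b)))
            )
        for (tag_a, pay_a), (_, pay_b) in zip(proc_a, proc_b):
            if pay_a != pay_b:
                proc_entries.append(DiffEntry("system", tag_a, pay_a, pay_b))

    for tag in other_tags:
        la, lb = a.get_all(tag), b.get_all(tag)
        if la != lb:
            category = _TAG_CATEGORY.get(tag, "extra")
            entries.append(DiffEntry(category, tag, _list_payload(la), _list_payload(lb)))
    entries.extend(proc_entries)

    entries.sort(key=lambda e: (_CATEGORY_RANK[e.category], e.tag, e.before or "", e.after or ""))
    return DiffReport(entries=tuple(entries), ignored_tags=frozenset(ignore))


def summarize_report(report: DiffReport) -> str:
    """Human-readable one-line-per-difference summary, grouped by category."""
    if report.environments_match:
        return "environments match"
    lines: list[str] = []
    current = None
    for entry in report.entries:
        if entry.category != current:
            current = entry.category
            lines.append(f"[{current}]")
        if entry.category == "module-added":
            lines.append(f"  {entry.tag}: added ({entry.after})")
        elif entry.category == "module-removed":
            lines.append(f"  {entry.tag}: removed ({entry.before})")
        else:
            lines.append(f"  {entry.tag}: {entry.before!r} -> {entry.after!r}")
    return "\n".join(lines)
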