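"""The ``.runinfo`` log format: document model, writer, parser, naming.

Grammar
-------
A log is UTF-8 text, LF line endings.  Each logical record is::

    TAG: payload

where ``TAG`` matches ``[A-Za-z][A-Za-z0-9-]*``.  When a maximum line
width is requested, long payloads are wrapped at whitespace onto
continuation lines that begin with ``"+ "``; the parser joins each
continuation to its predecessor with a single space, so wrapping is
lossless.  Two ``META-*`` header records make every log self-describing:

    META-Version: 1.0
    META-Hash: sha256

Canonical record order is: the META header, then ``MODULE*``, ``INC*``,
``UNAME``, ``PROC0..PROCn``, ``INTERP``, ``INTERPVer``, ``INTERPSum``,
``LIBC``, ``LIBCSum``, ``User``, ``Group*``, ``ProgDir``, ``Program``,
``Version``, ``ProgSUM``, ``Args``, ``Start``, ``End``, ``Elapsed``,
``EndStat``, then any program-specified records.

The ``INTERP*``/``LIBC*`` tags are the runtime-neutral spelling of the
interpreter and C-library fields; the mapping is one-to-one with an
interpreter-specific naming scheme (interpreter path, version, binary
checksum; libc version and checksum).
"""

from __future__ import annotations

import os
import re
import shlex
from dataclasses import dataclass, replace
from datetime import datetime
from typing import Iterable, Sequence

from .capture import (
    ExecutionWindow,
    InterpreterInfo,
    ModuleRecord,
    ProgramIdentity,
    SearchPath,
    SystemInfo,
    UserContext,
)

FORMAT_VERSION = "1.0"
LOG_SUFFIX = ".runinfo"
CONTINUATION = "+ "

TAG_RE = re.compile(r"^[A-Za-z][A-Za-z0-9-]*$")
_LINE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9-]*):(.*)$")

#: Tags that may legitimately repeat within one document.
REPEATABLE_TAGS = frozenset({"MODULE", "INC", "Group"})

#: Canonical order of the standard sections (PROCn handled positionally).
_SINGLETON_ORDER = (
    "UNAME",
    "INTERP",
    "INTERPVer",
    "INTERPSum",
    "LIBC",
    "LIBCSum",
    "User",
    "ProgDir",
    "Program",
    "Version",
    "ProgSUM",
    "Args",
    "Start",
    "End",
    "Elapsed",
    "EndStat",
)

MANDATORY_TAGS = ("INC",) + _SINGLETON_ORDER + ("Group",)

_PROC_RE = re.compile(r"^PROC(\d+)$")


class LogParseError(ValueError):
    """Raised on malformed log text; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class LogRecord:
    tag: str
    payload: str

    def __post_init__(self) -> None:
        if not TAG_RE.match(self.tag):
            raise ValueError(f"invalid record tag: {self.tag!r}")
        if "\n" in self.payload or "\r" in self.payload:
            raise ValueError("record payload must be a single logical line")


@dataclass(frozen=True)
class LogDocument:
    """An ordered sequence of tagged records describing one execution."""

    records: tuple[LogRecord, ...]
    format_version: str = FORMAT_VERSION
    hash_algorithm: str = "sha256"

    def get(self, tag: str) -> str | None:
        """Payload of the first record bearing ``tag``, or None."""
        for rec in self.records:
            if rec.tag == tag:
                return rec.payload
        return None

    def get_all(self, tag: str) -> list[str]:
        return [rec.payload for rec in self.records if rec.tag == tag]

    def tags(self) -> list[str]:
        return [rec.tag for rec in self.records]


# ---------------------------------------------------------------------------
# field quoting


def quote_field(value: str) -> str:
    """Quote a whitespace-separated field if it needs it.

    Fields containing whitespace, quotes or backslashes (or empty fields)
    are wrapped in double quotes with backslash escaping, which
    :func:`split_fields` reverses exactly.
    """
    if value and not re.search(r'[\s"\\]', value):
        return value
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def split_fields(payload: str) -> list[str]:
    """Quote-aware whitespace split (inverse of :func:`quote_field`)."""
    lex = shlex.shlex(payload, posix=True)
    lex.whitespace_split = True
    lex.commenters = ""
    return list(lex)


# ---------------------------------------------------------------------------
# naming


def default_log_filename(program_name: str, timestamp: datetime) -> str:
    """``<program>.<YYYYMMDD-HHMMSS>.runinfo`` with a local-time stamp.

    Path separators in the program name are replaced by underscores so
    the result is always a plain filename.
    """
    if not program_name:
        raise ValueError("program_name must be non-empty")
    safe = program_name.replace(os.sep, "_").replace("/", "_")
    return f"{safe}.{timestamp.strftime('%Y%m%d-%H%M%S')}{LOG_SUFFIX}"


# ---------------------------------------------------------------------------
# building


def render_module_payload(record: ModuleRecord) -> str:
    return " ".join(
        quote_field(f) for f in (record.name, record.version, record.path, record.checksum)
    )


def parse_module_payload(payload: str) -> ModuleRecord:
    """Split a MODULE payload into name / version / path / checksum."""
    try:
        fields = split_fields(payload)
    except ValueError as exc:
        raise ValueError(f"malformed MODULE payload {payload!r}: {exc}") from None
    if len(fields) != 4:
        raise ValueError(
            f"MODULE payload must have 4 fields, got {len(fields)}: {payload!r}"
        )
    name, version, path, checksum = fields
    return ModuleRecord(name=name, version=version, path=path, checksum=checksum)


def render_args_payload(argv: Sequence[str]) -> str:
    """Argument count followed by each argument, individually quoted."""
    parts = [str(len(argv))]
    parts += ['"' + a.replace("\\", "\\\\").replace('"', '\\"') + '"' for a in argv]
    return " ".join(parts)


def parse_args_payload(payload: str) -> list[str]:
    fields = split_fields(payload)
    if not fields:
        raise ValueError("empty Args payload")
    count = int(fields[0])
    argv = fields[1:]
    if count != len(argv):
        raise ValueError(f"Args count {count} != {len(argv)} arguments")
    return argv


def _attrs_payload(attributes: Iterable[tuple[str, str]]) -> str:
    return " ".join(f"{k}={quote_field(v)}" for k, v in attributes)


def _timestamp(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M:%S%z")


def build_document(
    modules: Sequence[ModuleRecord],
    search_path: SearchPath,
    system: SystemInfo,
    interpreter: InterpreterInfo,
    user: UserContext,
    program: ProgramIdentity,
    window: ExecutionWindow,
    extra_records: Sequence[LogRecord] = (),
    hash_algorithm: str = "sha256",
) -> LogDocument:
    """Assemble emission-time snapshots into a canonical-order document."""
    records: list[LogRecord] = [
        LogRecord("META-Version", FORMAT_VERSION),
        LogRecord("META-Hash", hash_algorithm),
    ]
    for mod in sorted(modules, key=lambda m: m.name):
        records.append(LogRecord("MODULE", render_module_payload(mod)))
    for entry in search_path.entries:
        records.append(LogRecord("INC", entry))
    records.append(
        LogRecord(
            "UNAME",
            " ".join(
                quote_field(f)
                for f in (
                    system.os_name,
                    system.node_name,
                    system.os_release,
                    system.os_version,
                    system.machine,
                )
            ),
        )
    )
    for proc in system.processors:
        records.append(LogRecord(f"PROC{proc.index}", _attrs_payload(proc.attributes)))
    records.append(LogRecord("INTERP", interpreter.executable_path))
    records.append(LogRecord("INTERPVer", interpreter.version))
    records.append(LogRecord("INTERPSum", interpreter.checksum))
    records.append(LogRecord("LIBC", interpreter.libc_version))
    records.append(LogRecord("LIBCSum", interpreter.libc_checksum))
    user_payload = user.effective_user
    if user.real_user is not None:
        user_payload += f" real={user.real_user}"
    records.append(LogRecord("User", user_payload))
    for group in user.effective_groups:
        records.append(LogRecord("Group", group))
    if user.real_groups:
        records.append(LogRecord("Group", "real=" + " ".join(user.real_groups)))
    records.append(LogRecord("ProgDir", program.directory))
    records.append(LogRecord("Program", program.name))
    records.append(LogRecord("Version", program.declared_version))
    records.append(LogRecord("ProgSUM", program.checksum))
    records.append(LogRecord("Args", render_args_payload(program.argv)))
    records.append(LogRecord("Start", _timestamp(window.start)))
    records.append(LogRecord("End", _timestamp(window.end)))
    records.append(LogRecord("Elapsed", f"{window.elapsed_seconds:.3f}"))
    records.append(LogRecord("EndStat", str(window.exit_status)))
    if window.warning:
        records.append(LogRecord("WARNING", window.warning))
    records.extend(extra_records)
    return LogDocument(records=tuple(records), hash_algorithm=hash_algorithm)


# ---------------------------------------------------------------------------
# rendering


def _wrap_record(tag: str, payload: str, width: int) -> list[str]:
    # Break only at single space characters inside the payload (never in
    # the "TAG: " head); the parser re-joins continuations with a single
    # space, so each break consumes exactly one space and the payload
    # round-trips byte-for-byte.
    out: list[str] = []
    prefix = f"{tag}: "
    rest = payload
    while True:
        limit = width - len(prefix)
        if len(rest) <= limit:
            out.append(prefix + rest)
            return out
        cut = rest.rfind(" ", 0, max(limit, 0) + 1)
        if cut == -1:
            cut = rest.find(" ")
            if cut == -1:  # single token longer than width: emit unbroken
                out.append(prefix + rest)
                return out
        out.append(prefix + rest[:cut])
        rest = rest[cut + 1 :]
        prefix = CONTINUATION


def render_document(doc: LogDocument, width: int | None = None) -> str:
    """Render to text; ``width`` enables whitespace wrapping with ``"+ "``
    continuation lines.  ``parse_document(render_document(doc))`` equals
    ``doc``."""
    if width is not None and width < 8:
        raise ValueError("width must be at least 8")
    lines: list[str] = []
    for rec in doc.records:
        if width is None:
            lines.append(f"{rec.tag}: {rec.payload}")
        else:
            lines.extend(_wrap_record(rec.tag, rec.payload, width))
    return "\n".join(lines) + "\n"


def write_document(doc: LogDocument, path: str | os.PathLike, width: int | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(render_document(doc, width))


# ---------------------------------------------------------------------------
# parsing


def parse_document(text: str) -> LogDocument:
    """Parse log text back into a :class:`LogDocument`.

    Continuation lines are joined to their predecessor with one space.
    Unknown tags are preserved (program-specified records are open-ended).
    Raises :class:`LogParseError` with a line number on malformed input.
    """
    records: list[LogRecord] = []
    current: tuple[str, str] | None = None

    def flush() -> None:
        nonlocal current
        if current is not None:
            records.append(LogRecord(*current))
            current = None

    lines = text.split("\n")  # strictly LF; payloads may hold other Unicode separators
    if lines and lines[-1] == "":
        lines.pop()
    for lineno, line in enumerate(lines, start=1):
        if line.endswith("\r"):  # tolerate CRLF in hand-edited logs
            line = line[:-1]
        if line.startswith(CONTINUATION) or line == "+":
            if current is None:
                raise LogParseError("continuation line with no preceding record", lineno)
            current = (current[0], current[1] + " " + line[2:])
            continue
        m = _LINE_RE.match(line)
        if m is None:
            if not line.strip():
                continue  # blank lines tolerated between records
            raise LogParseError(f"not a 'TAG: payload' line: {line!r}", lineno)
        flush()
        payload = m.group(2)
        if payload.startswith(" "):
            payload = payload[1:]
        current = (m.group(1), payload)
    flush()

    doc = LogDocument(records=tuple(records))
    version = doc.get("META-Version")
    algorithm = doc.get("META-Hash")
    if version is not None:
        doc = replace(doc, format_version=version)
    if algorithm is not None:
        doc = replace(doc, hash_algorithm=algorithm)
    return doc


def read_document(path: str | os.PathLike) -> LogDocument:
    with open(path, encoding="utf-8") as fh:
        return parse_document(fh.read())


# ---------------------------------------------------------------------------
# validation


def check_canonical_order(doc: LogDocument) -> list[str]:
    """Return a list of order/repetition problems (empty == canonical)."""
    problems: list[str] = []
    order = (
        "META-Version",
        "META-Hash",
        "MODULE",
        "INC",
        "UNAME",
        "PROC",  # stands for the whole PROC0..PROCn block
        "INTERP",
        "INTERPVer",
        "INTERPSum",
        "LIBC",
        "LIBCSum",
        "User",
        "Group",
        "ProgDir",
        "Program",
        "Version",
        "ProgSUM",
        "Args",
        "Start",
        "End",
        "Elapsed",
        "EndStat",
        "WARNING",
    )
    rank = {tag: i for i, tag in enumerate(order)}
    extra_rank = len(order)  # program-specified records come last

    last_rank = -1
    last_proc = -1
    counts: dict[str, int] = {}
    prev_module = ""
    for rec in doc.records:
        m = _PROC_RE.match(rec.tag)
        if m:
            r = rank["PROC"]
            idx = int(m.group(1))
            if idx != last_proc + 1:
                problems.append(f"processor records not contiguous at {rec.tag}")
            last_proc = idx
        else:
            r = rank.get(rec.tag, extra_rank)
        if r < last_rank:
            problems.append(f"record {rec.tag} out of canonical order")
        last_rank = max(last_rank, r)
        counts[rec.tag] = counts.get(rec.tag, 0) + 1
        if rec.tag == "MODULE":
            try:
                name = parse_module_payload(rec.payload).name
                if name < prev_module:
                    problems.append(f"MODULE records not sorted at {name}")
                prev_module = name
            except ValueError as exc:
                problems.append(str(exc))
    for tag, count in counts.items():
        if count > 1 and tag in rank and tag not in REPEATABLE_TAGS:
            problems.append(f"tag {tag} repeated {count} times")
    return problems
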