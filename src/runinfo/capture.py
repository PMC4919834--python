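"""Snapshots of the running program's environment.

Every public function in this module is best-effort by contract: an
attribute that cannot be obtained is reported with the sentinel
``"UNKNOWN"`` instead of raising, because provenance capture must never
abort the host program it is documenting.
"""

from __future__ import annotations

import hashlib
import os
import platform
import re
import sys
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

UNKNOWN = "UNKNOWN"
BUILTIN = "BUILTIN"

#: Default content hash. Recorded in every log header so a parser can
#: verify digest widths without guessing.
DEFAULT_HASH = "sha256"

_CHUNK = 1 << 20


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ModuleRecord:
    """One loaded library module: name, version, file location, checksum."""

    name: str
    version: str = UNKNOWN
    path: str = BUILTIN
    checksum: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.name or re.search(r"\s", self.name):
            raise ValueError(f"module name must be non-empty, no whitespace: {self.name!r}")


@dataclass(frozen=True)
class SearchPath:
    """The ordered module search path, exactly as the runtime reports it."""

    entries: tuple[str, ...]


@dataclass(frozen=True)
class ProcessorRecord:
    """Attributes of one logical processor (model, cores, clock, ...)."""

    index: int
    attributes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ValueError("processor attributes must not be empty")


@dataclass(frozen=True)
class SystemInfo:
    os_name: str = UNKNOWN
    node_name: str = UNKNOWN
    os_release: str = UNKNOWN
    os_version: str = UNKNOWN
    machine: str = UNKNOWN
    processors: tuple[ProcessorRecord, ...] = ()
    total_memory_bytes: int | None = None


@dataclass(frozen=True)
class InterpreterInfo:
    executable_path: str
    version: str = UNKNOWN
    checksum: str = UNKNOWN
    libc_version: str = UNKNOWN
    libc_checksum: str = UNKNOWN


@dataclass(frozen=True)
class UserContext:
    effective_user: str = UNKNOWN
    real_user: str | None = None          # present only when != effective
    effective_groups: tuple[str, ...] = ()
    real_groups: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ProgramIdentity:
    directory: str
    name: str
    declared_version: str = UNKNOWN
    checksum: str = UNKNOWN
    argv: tuple[str, ...] = ()

    @property
    def arg_count(self) -> int:
        return len(self.argv)


@dataclass(frozen=True)
class ExecutionWindow:
    """Start/end/elapsed/exit-status of the instrumented run.

    ``exit_status`` is an integer for normal exits and a signal name
    (e.g. ``"SIGTERM"``) for signal-triggered termination.
    """

    start: datetime
    end: datetime
    elapsed_seconds: float
    exit_status: int | str
    warning: str | None = None


# ---------------------------------------------------------------------------
# operations


def checksum_file(path: str | os.PathLike, algorithm: str = DEFAULT_HASH) -> str:
    """Hex digest of a file's bytes, or ``"UNKNOWN"`` if it cannot be read."""
    try:
        h = hashlib.new(algorithm)
        with open(path, "rb") as fh:
            while chunk := fh.read(_CHUNK):
                h.update(chunk)
        return h.hexdigest()
    except (OSError, ValueError, TypeError):
        return UNKNOWN


_DIST_VERSIONS: dict[str, str] | None = None


def _dist_versions() -> dict[str, str]:
    # one scan of installed distributions, cached: maps importable
    # top-level names (and normalised project names) to versions
    global _DIST_VERSIONS
    if _DIST_VERSIONS is None:
        mapping: dict[str, str] = {}
        try:
            from importlib import metadata

            for dist in metadata.distributions():
                try:
                    version = dist.version
                    if not version:
                        continue
                    tops = (dist.read_text("top_level.txt") or "").split()
                    for top in tops:
                        mapping.setdefault(top, version)
                    name = dist.metadata["Name"] or ""
                    if name:
                        mapping.setdefault(name.replace("-", "_").lower(), version)
                except Exception:
                    continue
        except Exception:
            pass
        _DIST_VERSIONS = mapping
    return _DIST_VERSIONS


def _module_version(name: str, mod: object) -> str:
    version = getattr(mod, "__version__", None)
    if not (isinstance(version, str) and version):
        version = _dist_versions().get(name.partition(".")[0], UNKNOWN)
    # version strings become single whitespace-free payload fields
    return "_".join(version.split()) or UNKNOWN


def snapshot_modules(
    module_registry: Mapping[str, object] | None = None,
    with_checksums: bool = False,
    algorithm: str = DEFAULT_HASH,
) -> list[ModuleRecord]:
    """One record per distinct loaded module, sorted by name.

    ``module_registry`` defaults to ``sys.modules``; call at emission time
    so modules loaded late in the run are included.  Checksums are
    computed only on request (they cost one file read per module).
    """
    registry = sys.modules if module_registry is None else module_registry
    records = []
    for name, mod in sorted(registry.items()):
        if mod is None or re.search(r"\s", name):
            continue
        path = getattr(mod, "__file__", None) or BUILTIN
        if with_checksums and path != BUILTIN:
            digest = checksum_file(path, algorithm)
        else:
            digest = UNKNOWN
        records.append(
            ModuleRecord(
                name=name,
                version=_module_version(name, mod),
                path=path,
                checksum=digest,
            )
        )
    return records


def snapshot_search_path(path: Sequence[str] | None = None) -> SearchPath:
    """The module search path at emission time, order and duplicates preserved."""
    return SearchPath(entries=tuple(sys.path if path is None else path))


def _read_cpuinfo() -> list[dict[str, str]]:
    # Linux per-processor table; empty list elsewhere.
    procs: list[dict[str, str]] = []
    try:
        with open("/proc/cpuinfo", encoding="utf-8", errors="replace") as fh:
            current: dict[str, str] = {}
            for line in fh:
                line = line.strip()
                if not line:
                    if current:
                        procs.append(current)
                        current = {}
                    continue
                key, _, value = line.partition(":")
                current[key.strip()] = value.strip()
            if current:
                procs.append(current)
    except OSError:
        return []
    return [p for p in procs if "processor" in p]


def _total_memory_bytes() -> int | None:
    try:
        return os.sysconf("SC_PAGE_SIZE") * os.sysconf("SC_PHYS_PAGES")
    except (OSError, ValueError, AttributeError):
        return None


def snapshot_system() -> SystemInfo:
    """Operating system identification plus one record per logical processor."""
    try:
        uname = platform.uname()
        os_name, node, release, version, machine = (
            uname.system or UNKNOWN,
            uname.node or UNKNOWN,
            uname.release or UNKNOWN,
            uname.version or UNKNOWN,
            uname.machine or UNKNOWN,
        )
    except Exception:
        os_name = node = release = version = machine = UNKNOWN

    memory = _total_memory_bytes()
    processors: list[ProcessorRecord] = []
    for entry in _read_cpuinfo():
        attrs: list[tuple[str, str]] = []
        model = entry.get("model name") or entry.get("Model") or UNKNOWN
        attrs.append(("model", model))
        if "cpu cores" in entry:
            attrs.append(("cores", entry["cpu cores"]))
        if "cpu MHz" in entry:
            attrs.append(("mhz", entry["cpu MHz"]))
        try:
            index = int(entry["processor"])
        except (KeyError, ValueError):
            index = len(processors)
        processors.append(ProcessorRecord(index=index, attributes=tuple(attrs)))
    # re-index 0..n-1 with no gaps, preserving table order
    processors = [
        ProcessorRecord(index=i, attributes=p.attributes)
        for i, p in enumerate(sorted(processors, key=lambda p: p.index))
    ]
    if not processors:
        # no per-processor table: one aggregate record
        attrs = [("model", platform.processor() or UNKNOWN)]
        count = os.cpu_count()
        if count:
            attrs.append(("cores", str(count)))
        processors = [ProcessorRecord(index=0, attributes=tuple(attrs))]
    if memory is not None:
        first = processors[0]
        processors[0] = ProcessorRecord(
            index=first.index, attributes=first.attributes + (("memory", str(memory)),)
        )
    return SystemInfo(
        os_name=os_name,
        node_name=node,
        os_release=release,
        os_version=version,
        machine=machine,
        processors=tuple(processors),
        total_memory_bytes=memory,
    )


def _find_libc_path() -> str | None:
    # The process has libc mapped already; /proc/self/maps names the file.
    try:
        with open("/proc/self/maps", encoding="utf-8", errors="replace") as fh:
            for line in fh:
                path = line.split(None, 5)[-1].strip() if line.count("/") else ""
                if re.search(r"/libc[.-][^/]*$", path) and os.path.isfile(path):
                    return path
    except OSError:
        pass
    for candidate in (
        "/lib/x86_64-linux-gnu/libc.so.6",
        "/lib64/libc.so.6",
        "/usr/lib/libc.so.6",
    ):
        if os.path.isfile(candidate):
            return candidate
    return None


def snapshot_interpreter(algorithm: str = DEFAULT_HASH) -> InterpreterInfo:
    """Interpreter path/version/checksum plus best-effort C-library identity.

    C-library introspection is inherently approximate: the version is the
    one the platform reports for the running binary, and both fields fall
    back to ``"UNKNOWN"`` where the platform exposes nothing.
    """
    executable = sys.executable or UNKNOWN
    libc_name, libc_ver = ("", "")
    try:
        libc_name, libc_ver = platform.libc_ver()
    except Exception:
        pass
    libc_version = f"{libc_name} {libc_ver}".strip() or UNKNOWN
    libc_path = _find_libc_path()
    return InterpreterInfo(
        executable_path=executable,
        version=platform.python_version(),
        checksum=checksum_file(executable, algorithm) if executable != UNKNOWN else UNKNOWN,
        libc_version=libc_version,
        libc_checksum=checksum_file(libc_path, algorithm) if libc_path else UNKNOWN,
    )


def _id_name(idnum: int, lookup) -> str:
    try:
        return f"{idnum}({lookup(idnum)})"
    except Exception:
        return str(idnum)


def snapshot_user() -> UserContext:
    """Effective user/groups; real identities only when they differ."""
    try:
        import grp
        import pwd

        def uname(uid: int) -> str:
            return _id_name(uid, lambda u: pwd.getpwuid(u).pw_name)

        def gname(gid: int) -> str:
            return _id_name(gid, lambda g: grp.getgrgid(g).gr_name)

        euid, ruid = os.geteuid(), os.getuid()
        egid, rgid = os.getegid(), os.getgid()
        supplementary = [g for g in os.getgroups() if g != egid]
        effective_groups = tuple([gname(egid)] + [gname(g) for g in supplementary])
        return UserContext(
            effective_user=uname(euid),
            real_user=uname(ruid) if ruid != euid else None,
            effective_groups=effective_groups,
            real_groups=(gname(rgid),) if rgid != egid else None,
        )
    except Exception:
        return UserContext(effective_user=UNKNOWN, effective_groups=(UNKNOWN,))


def snapshot_program(
    argv_at_activation: Sequence[str],
    main_path: str,
    declared_version: str | None = None,
    algorithm: str = DEFAULT_HASH,
) -> ProgramIdentity:
    """Identity of the instrumented program itself.

    ``argv_at_activation`` must be the copy taken when the logger was
    activated, so later mutation of the host's argument vector does not
    leak into the log.
    """
    directory, name = os.path.split(os.path.abspath(main_path))
    return ProgramIdentity(
        directory=directory,
        name=name or UNKNOWN,
        declared_version=declared_version or UNKNOWN,
        checksum=checksum_file(main_path, algorithm),
        argv=tuple(argv_at_activation),
    )


def finalize_window(start: datetime, end: datetime, status: int | str) -> ExecutionWindow:
    """Close the execution window; clock skew clamps elapsed to zero."""
    delta = (end - start) / timedelta(seconds=1)
    warning = None
    if delta < 0:
        warning = f"end precedes start by {-delta:.3f}s; elapsed clamped to 0"
        delta = 0.0
    return ExecutionWindow(
        start=start, end=end, elapsed_seconds=delta, exit_status=status, warning=warning
    )
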