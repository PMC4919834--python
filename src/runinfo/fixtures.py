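"""Deterministic synthetic log documents for testing the format, parser
and diff without touching the real host environment.

:func:`generate_fixture` builds a plausible document (module manifest
with versions/paths/checksums, search path, system and interpreter
records, timing window) from a seed, and optionally a second document
derived from the first by a controlled set of perturbations.  The
perturbation list is the ground truth an environment diff must recover
exactly, which is what makes the diff testable end to end.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

from .capture import (
    ExecutionWindow,
    InterpreterInfo,
    ModuleRecord,
    ProcessorRecord,
    ProgramIdentity,
    SearchPath,
    SystemInfo,
    UserContext,
    finalize_window,
)
from .logformat import LogDocument, LogRecord, build_document

#: perturbation category -> diff categories it must produce (count 1 each);
#: timestamp shifts must be invisible under the default ignore set.
PERTURBATION_EFFECTS = {
    "module-version": ("module-version",),
    "module-path": ("module-path",),
    "module-checksum": ("module-checksum",),
    "module-added": ("module-added",),
    "module-removed": ("module-removed",),
    "interpreter": ("interpreter",),
    "system": ("system",),
    "search-path": ("search-path",),
    "user": ("user",),
    "program": ("program",),
    "args": ("args",),
    "exit-status": ("exit-status",),
    "extra": ("extra",),
    "timestamps": (),
}

_SYLLABLES = ["bio", "seq", "align", "stat", "gen", "var", "map", "core", "util", "io"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_modules: int = 8
    n_processors: int = 2
    perturbations: tuple[tuple[str, dict], ...] = ()


@dataclass
class _Snapshots:
    modules: list[ModuleRecord]
    search_path: list[str]
    system: SystemInfo
    interpreter: InterpreterInfo
    user: UserContext
    program: ProgramIdentity
    window: ExecutionWindow
    extra: list[LogRecord] = field(default_factory=list)

    def to_document(self) -> LogDocument:
        return build_document(
            modules=self.modules,
            search_path=SearchPath(tuple(self.search_path)),
            system=self.system,
            interpreter=self.interpreter,
            user=self.user,
            program=self.program,
            window=self.window,
            extra_records=tuple(self.extra),
        )


def _hex(rng: random.Random, n: int = 64) -> str:
    return "".join(rng.choice("0123456789abcdef") for _ in range(n))


def _version(rng: random.Random) -> str:
    return f"{rng.randint(0, 5)}.{rng.randint(0, 20)}.{rng.randint(0, 9)}"


def _module_name(rng: random.Random, taken: set[str]) -> str:
    while True:
        name = rng.choice(_SYLLABLES) + rng.choice(_SYLLABLES) + str(rng.randint(0, 99))
        if name not in taken:
            taken.add(name)
            return name


def _base_snapshots(rng: random.Random, spec: FixtureSpec) -> _Snapshots:
    taken: set[str] = set()
    modules = [
        ModuleRecord(
            name=(name := _module_name(rng, taken)),
            version=_version(rng),
            path=f"/opt/site/lib/{name}/__init__.py",
            checksum=_hex(rng),
        )
        for _ in range(spec.n_modules)
    ]
    search_path = ["/opt/site/lib", "/usr/lib/site", f"/home/user{rng.randint(1, 9)}/lib"]
    processors = tuple(
        ProcessorRecord(
            index=i,
            attributes=(
                ("model", f"SimCPU {rng.randint(1000, 9999)}"),
                ("cores", str(rng.choice([2, 4, 8]))),
                ("mhz", f"{rng.randint(1200, 3600)}.000"),
            ),
        )
        for i in range(spec.n_processors)
    )
    system = SystemInfo(
        os_name="Linux",
        node_name=f"node{rng.randint(1, 99)}",
        os_release=f"5.{rng.randint(0, 19)}.0",
        os_version=f"#1 SMP build {rng.randint(100, 999)}",
        machine="x86_64",
        processors=processors,
        total_memory_bytes=rng.choice([8, 16, 32]) * 2**30,
    )
    interpreter = InterpreterInfo(
        executable_path="/opt/bin/python3",
        version=f"3.{rng.randint(8, 12)}.{rng.randint(0, 9)}",
        checksum=_hex(rng),
        libc_version=f"glibc 2.{rng.randint(27, 38)}",
        libc_checksum=_hex(rng),
    )
    uid = rng.randint(1000, 1999)
    user = UserContext(
        effective_user=f"{uid}(user{uid})",
        effective_groups=(f"{uid}(group{uid})", "100(users)"),
    )
    program = ProgramIdentity(
        directory="/opt/pipeline",
        name="analyse.py",
        declared_version=_version(rng),
        checksum=_hex(rng),
        argv=("--input", f"run{rng.randint(1, 99)}.dat", "--threads", "4"),
    )
    start = datetime(2016, 6, 24, 10, 0, 0, tzinfo=timezone.utc) + timedelta(
        seconds=rng.randint(0, 10_000)
    )
    window = finalize_window(start, start + timedelta(seconds=rng.randint(1, 3600)), 0)
    extra = [LogRecord("SAMPLES", str(rng.randint(1, 500)))]
    return _Snapshots(
        modules=modules,
        search_path=search_path,
        system=system,
        interpreter=interpreter,
        user=user,
        program=program,
        window=window,
        extra=extra,
    )


def _pick_module(rng: random.Random, snaps: _Snapshots, params: dict) -> int:
    name = params.get("name")
    if name is not None:
        for i, mod in enumerate(snaps.modules):
            if mod.name == name:
                return i
        raise ValueError(f"perturbation names unknown module {name!r}")
    if not snaps.modules:
        raise ValueError("perturbation needs at least one module in the fixture")
    return rng.randrange(len(snaps.modules))


def _apply_perturbation(rng: random.Random, snaps: _Snapshots, category: str, params: dict) -> None:
    from dataclasses import replace

    if category == "module-version":
        i = _pick_module(rng, snaps, params)
        mod = snaps.modules[i]
        snaps.modules[i] = replace(mod, version=params.get("version", mod.version + ".post1"))
    elif category == "module-path":
        i = _pick_module(rng, snaps, params)
        mod = snaps.modules[i]
        snaps.modules[i] = replace(mod, path=f"/alt/site/{mod.name}/__init__.py")
    elif category == "module-checksum":
        i = _pick_module(rng, snaps, params)
        snaps.modules[i] = replace(snaps.modules[i], checksum=_hex(rng))
    elif category == "module-removed":
        i = _pick_module(rng, snaps, params)
        del snaps.modules[i]
    elif category == "module-added":
        taken = {m.name for m in snaps.modules}
        name = params.get("name") or _module_name(rng, taken)
        snaps.modules.append(
            ModuleRecord(
                name=name,
                version=_version(rng),
                path=f"/opt/site/lib/{name}/__init__.py",
                checksum=_hex(rng),
            )
        )
    elif category == "interpreter":
        snaps.interpreter = replace(
            snaps.interpreter, version=snaps.interpreter.version + ".final"
        )
    elif category == "system":
        snaps.system = replace(snaps.system, os_release=snaps.system.os_release + "-generic")
    elif category == "search-path":
        snaps.search_path = snaps.search_path + [params.get("entry", "/extra/lib")]
    elif category == "user":
        snaps.user = replace(snaps.user, effective_user="2000(otheruser)")
    elif category == "program":
        snaps.program = replace(snaps.program, checksum=_hex(rng))
    elif category == "args":
        snaps.program = replace(
            snaps.program, argv=snaps.program.argv + (params.get("arg", "--verbose"),)
        )
    elif category == "exit-status":
        snaps.window = replace(snaps.window, exit_status=params.get("status", 1))
    elif category == "extra":
        snaps.extra = [LogRecord("SAMPLES", snaps.extra[0].payload + "0")]
    elif category == "timestamps":
        shift = timedelta(seconds=params.get("shift", 3600))
        snaps.window = finalize_window(
            snaps.window.start + shift,
            snaps.window.end + shift + timedelta(seconds=5),
            snaps.window.exit_status,
        )
    else:
        raise ValueError(f"unknown perturbation category {category!r}")


def generate_fixture(spec: FixtureSpec) -> tuple[LogDocument, LogDocument | None]:
    """Build a deterministic document, plus a perturbed sibling when
    ``spec.perturbations`` is non-empty.  Identical specs yield
    byte-identical rendered fixtures."""
    for category, _ in spec.perturbations:
        if category not in PERTURBATION_EFFECTS:
            raise ValueError(f"unknown perturbation category {category!r}")
    rng = random.Random(spec.seed)
    base = _base_snapshots(rng, spec)
    doc_a = base.to_document()
    if not spec.perturbations:
        return doc_a, None
    mutated = _base_snapshots(random.Random(spec.seed), spec)  # independent copy
    for category, params in spec.perturbations:
        _apply_perturbation(rng, mutated, category, dict(params))
    return doc_a, mutated.to_document()


def base_module_names(spec: FixtureSpec) -> list[str]:
    """Module names of the unperturbed fixture document for ``spec``."""
    plain = FixtureSpec(seed=spec.seed, n_modules=spec.n_modules, n_processors=spec.n_processors)
    snaps = _base_snapshots(random.Random(plain.seed), plain)
    return [m.name for m in snaps.modules]


def make_perturbed_spec(
    seed: int,
    rng: random.Random,
    n_perturbations: int = 2,
    n_modules: int = 8,
    n_processors: int = 2,
) -> FixtureSpec:
    """A :class:`FixtureSpec` with ``n_perturbations`` randomly chosen,
    mutually independent perturbations.

    Categories are drawn without replacement and module-targeting
    perturbations are pinned to distinct module names, so the injected
    set maps one-to-one onto the diff entries a correct comparison must
    report (no perturbation can mask another).
    """
    categories = [c for c in PERTURBATION_EFFECTS if c != "timestamps"]
    module_categories = {
        "module-version",
        "module-path",
        "module-checksum",
        "module-removed",
    }
    chosen = rng.sample(categories, min(n_perturbations, len(categories)))
    names = base_module_names(FixtureSpec(seed=seed, n_modules=n_modules, n_processors=n_processors))
    rng.shuffle(names)
    perturbations: list[tuple[str, dict]] = []
    for category in chosen:
        params: dict = {}
        if category in module_categories:
            if not names:
                continue
            params["name"] = names.pop()
        perturbations.append((category, params))
    return FixtureSpec(
        seed=seed,
        n_modules=n_modules,
        n_processors=n_processors,
        perturbations=tuple(perturbations),
    )


def expected_diff_categories(spec: FixtureSpec) -> list[str]:
    """Diff categories (with multiplicity) a correct diff must report for
    the fixture pair, under the default ignore set."""
    out: list[str] = []
    for category, _ in spec.perturbations:
        out.extend(PERTURBATION_EFFECTS[category])
    return sorted(out)
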