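# Methods

## What the logger does and assumes

`runinfo` treats a program run as an observable object: at activation it
freezes the facts that can only be captured early (the argument vector,
the start time, the `RUNINFO_*` environment snapshot), and at
termination it snapshots everything that should be read as late as
possible (the loaded-module table, the search path, system, interpreter
and user identity), assembles one canonical-order document, and writes
it exactly once. The design assumptions are:

- **Capture must never harm the host.** Every introspection failure
  yields the sentinel `UNKNOWN` rather than an exception; `activate()`
  and emission are infallible by contract. The sentinel (instead of an
  empty string) keeps parsed documents free of missing-vs-empty
  ambiguity.
- **Termination is observable for catchable signals only.** Handlers
  are installed for `TERM`, `INT`, `HUP`, `QUIT` where the platform
  defines them. `KILL`, power loss, or a host that later resets a
  handler to the default disposition are out of scope: in those cases
  no log appears, which is acceptable because such a run was not a
  publishable result anyway.
- **Once-only emission.** The emitted flag is test-and-set under a lock
  *before* any I/O, so a signal arriving during emission (or several
  signals, or a signal during interpreter shutdown) cannot produce a
  second log. The file is written to a temporary name and atomically
  renamed, so an interrupted emission leaves zero complete logs rather
  than a truncated one.
- **Signal transparency.** After emission the handler chains to a
  previously installed host handler if one exists (the host decides
  whether to continue); if the prior disposition was the default, the
  signal is re-raised with default disposition so the parent observes a
  true signal death (`128+signum` convention), not a disguised exit
  code. A previously ignored signal stays ignored.

## Option model

Precedence is *defaults < activation layers in call order < environment
variables*, re-applied after every `activate()` call; the environment
snapshot is taken at first activation, so later mutations of
`os.environ` by the host do not change logging behaviour mid-run.
Defaults: enabled, log to the current directory, auto-generated name
`<program>.<YYYYMMDD-HHMMSS>.runinfo` (local time, second precision),
announce the path on stderr, no forwarding, module checksums off.

Module checksums default off because hashing every loaded module file
costs one full file read each; the `module_checksums` option (or
`RUNINFO_MODULE_CHECKSUMS=1`) turns them on, and the `MODULE` checksum
field holds `UNKNOWN` when off. The content hash is SHA-256 everywhere
(64 hex characters), recorded in the `META-Hash` header so a consumer
can verify digest widths without guessing.

## Format choices

The grammar is deliberately minimal: `TAG: payload` lines, UTF-8, LF,
with long payloads wrapped at single spaces onto `+ ` continuation
lines. Wrapping only ever breaks at a space inside the payload (never
inside the `TAG: ` head), each break consumes exactly one space, and
the parser re-joins with exactly one space — so
`parse(render(doc, w)) == doc` holds for any width, including payloads
with runs of spaces, and a token longer than the width is emitted
unbroken rather than split. Fields inside structured payloads
(`MODULE`, `Args`, `PROCn` attributes) are quoted with backslash
escaping when they contain whitespace or quotes. Timestamps are
ISO-8601 with a numeric UTC offset at second precision; elapsed time is
decimal seconds at millisecond precision. Unknown tags parse cleanly
and are preserved, because program-specified records are open-ended.

`EndStat` is `0` for any normal termination: an exit hook runs before
the process's final status exists and cannot observe `sys.exit(n)`'s
argument, the same vantage point an END-block logger has. Signal deaths
record the signal name instead.

## Diff semantics

Modules are matched by name, not list position — load order is
environment noise. Per-module differences are classified as
`module-version`, `module-path`, `module-checksum`, `module-added`,
`module-removed`. Repeated tags (`INC`, `Group`, program-specified) are
compared as ordered lists and reported as a single entry; `PROCn`
records are compared per index with a count mismatch reported once as a
`system` entry. All other tags are compared literally. The default
ignore set is `{Start, End, Elapsed}` — timestamps differ between any
two runs — while `EndStat` and `Args` *are* compared, because differing
arguments or exit status plausibly explain differing results. The
report orders entries by (category, tag, value), making output
deterministic; enlarging the ignore set can only remove entries.

## The synthetic-fixture generator

`runinfo.fixtures.generate_fixture` emulates a realistic log document —
a module manifest with plausible names, versions, install paths and
digest-width checksums, a multi-entry search path, per-processor
records, interpreter/libc identity, user and program records, a timing
window, one program-specified record — entirely from a seed, so the
format, parser and diff are testable with no external data and
byte-identical across runs and platforms. A second document can be
derived by a list of perturbations (one per category the diff
classifies, plus `timestamps`, which must be invisible under the
default ignore set); `make_perturbed_spec` draws perturbation sets with
distinct categories and distinct target modules so the injected set
maps one-to-one onto the entries a correct diff must report.

What the generator does **not** emulate: real version-string diversity
(epochs, local version tags), paths with exotic encodings, logs
hand-edited into non-canonical order, or hosts whose module table
changes concurrently during emission. Passing the fixture-based tests
therefore demonstrates format/diff correctness, not robustness to
arbitrary real-world logs; the subprocess tests (which log the real
environment of a live interpreter) cover the capture side.

## Problem sizes and numerical choices

The verification runs use 1000 generated documents × wrap widths
{40, 80, ∞} for the round-trip law, 500 fixture pairs for diff
fidelity, 50 subprocess trials for the signal/exit race, and 100 random
files (0–4 KiB) for the checksum oracle (`sha256sum`) — sizes at which
every property is exercised densely while the whole suite stays in the
tens of seconds. Elapsed-time arithmetic clamps negative durations
(clock skew) to zero and attaches a `WARNING` record; second-precision
timestamps mean `Elapsed` and `End − Start` may disagree by up to one
second.

## Known limitations

- C-library introspection is approximate: the version comes from the
  platform's report for the running binary and the checksummed file is
  the mapped `libc` found via `/proc/self/maps`; on platforms exposing
  neither, both fields are `UNKNOWN`. No attempt is made to enumerate
  other linked native libraries.
- Module records cannot prove a file matches its distribution-archive
  original; a checksum only detects change between two logged runs.
- A module version is the module's own `__version__` or the installed
  distribution's version; namespace packages without either report
  `UNKNOWN`.
- Logs forwarded into a host logging framework are decorated by that
  framework and are not re-parseable as written; the native file is
  still produced for that reason.
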