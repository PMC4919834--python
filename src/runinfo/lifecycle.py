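"""One-line activation, option resolution and once-only log emission.

A host program enables provenance logging with::

    import runinfo
    runinfo.activate()

The first activation copies the argument vector, records the start time,
snapshots the ``RUNINFO_*`` environment variables, installs a
normal-termination hook and handlers for the catchable termination
signals, and sets option defaults.  Later activations merge their options
over the current ones (a shared configuration module can set a common
policy and the main program can override parts of it).  Environment
variables always win over everything, so a single run can be suppressed
or redirected without touching code:

=========================  =================================================
variable                   effect
=========================  =================================================
``RUNINFO_SUPPRESS``       boolean; ``1`` disables writing the log
``RUNINFO_DIR``            directory the log is written to
``RUNINFO_NAME``           log filename (default: program name + timestamp)
``RUNINFO_ANNOUNCE``       boolean; report the log path on stderr
``RUNINFO_MODULE_CHECKSUMS``  boolean; checksum every loaded module file
``RUNINFO_FORWARD``        name of a :mod:`logging` logger to forward to
=========================  =================================================

Boolean values are ``0/1/true/false``, case-insensitive.
"""

from __future__ import annotations

import atexit
import logging
import os
import signal
import sys
import threading
import warnings
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timezone
from typing import Any, Callable, Mapping, Sequence

from . import capture, logformat
from .logformat import LogDocument, LogRecord

ENV_PREFIX = "RUNINFO_"

#: Signals trapped at activation, where the platform defines them.
CATCHABLE_SIGNALS = ("SIGTERM", "SIGINT", "SIGHUP", "SIGQUIT")

AUTO = "AUTO"


@dataclass(frozen=True)
class Options:
    """Resolved logging configuration (default < activation < environment)."""

    enabled: bool = True
    log_dir: str = "."
    log_name: str = AUTO
    announce: bool = True
    forward_target: Any = None  # logging.Logger, callable(line), logger name, or None
    module_checksums: bool = False


_OPTION_NAMES = {f.name for f in fields(Options)}

_BOOL_VALUES = {"1": True, "true": True, "0": False, "false": False}

# env key -> (option name, parser, invert)
_ENV_KEYS = {
    "SUPPRESS": ("enabled", "bool", True),
    "DIR": ("log_dir", "str", False),
    "NAME": ("log_name", "str", False),
    "ANNOUNCE": ("announce", "bool", False),
    "MODULE_CHECKSUMS": ("module_checksums", "bool", False),
    "FORWARD": ("forward_target", "str", False),
}


def _parse_bool(value: str) -> bool | None:
    return _BOOL_VALUES.get(value.strip().lower())


def resolve_options(
    defaults: Options,
    activation_layers: Sequence[Mapping[str, Any]] = (),
    env: Mapping[str, str] | None = None,
) -> Options:
    """Apply option precedence: defaults < activation layers (in order) < env.

    Unknown option names and malformed environment values produce a
    warning and are ignored; resolution never fails.
    """
    resolved = defaults
    for layer in activation_layers:
        known = {}
        for key, value in layer.items():
            if key not in _OPTION_NAMES:
                warnings.warn(f"runinfo: unknown option {key!r} ignored", stacklevel=2)
                continue
            known[key] = value
        resolved = replace(resolved, **known)
    for key, value in (env or {}).items():
        if not key.startswith(ENV_PREFIX):
            continue
        short = key[len(ENV_PREFIX) :]
        spec = _ENV_KEYS.get(short)
        if spec is None:
            warnings.warn(f"runinfo: unknown environment variable {key} ignored", stacklevel=2)
            continue
        name, kind, invert = spec
        if kind == "bool":
            parsed = _parse_bool(value)
            if parsed is None:
                warnings.warn(
                    f"runinfo: {key}={value!r} is not a boolean (0/1/true/false); ignored",
                    stacklevel=2,
                )
                continue
            resolved = replace(resolved, **{name: (not parsed) if invert else parsed})
        else:
            resolved = replace(resolved, **{name: value})
    return resolved


@dataclass
class ActivationState:
    """Mutable per-process state of the logger."""

    activated: bool = False
    emitted: bool = False
    start_time: datetime | None = None
    argv_copy: tuple[str, ...] = ()
    main_path: str = ""
    saved_env: dict[str, str] = field(default_factory=dict)
    activation_layers: list[dict[str, Any]] = field(default_factory=list)
    extra_loggers: list[Callable] = field(default_factory=list)
    resolved: Options = field(default_factory=Options)
    previous_handlers: dict[int, Any] = field(default_factory=dict)
    emit_lock: threading.Lock = field(default_factory=threading.Lock)
    install_hooks: bool = True


_STATE = ActivationState()


def _snapshot_env() -> dict[str, str]:
    return {k: v for k, v in os.environ.items() if k.startswith(ENV_PREFIX)}


def activate(state: ActivationState | None = None, **options: Any) -> ActivationState:
    """Enable provenance logging; safe to call any number of times.

    The first call performs setup (argv copy, start time, environment
    snapshot, exit/signal hooks, defaults) and then applies ``options``;
    later calls only merge ``options`` over the current configuration.
    Environment overrides are re-applied last after every merge.
    Activation never raises.
    """
    st = _STATE if state is None else state
    if not st.activated:
        st.activated = True
        st.start_time = datetime.now(timezone.utc).astimezone()
        st.argv_copy = tuple(sys.argv[1:])
        st.main_path = sys.argv[0] if sys.argv and sys.argv[0] else sys.executable
        st.saved_env = _snapshot_env()
        if st.install_hooks:
            _install_termination_hooks(st)
    if options:
        st.activation_layers.append(dict(options))
    st.resolved = resolve_options(Options(), st.activation_layers, st.saved_env)
    return st


def register_extra_logger(
    callback: Callable[[Callable[[str, str], None]], None],
    state: ActivationState | None = None,
) -> None:
    """Register a callback run at emission time.

    The callback receives an appender ``add(tag, payload)``; records it
    appends follow all standard records, in registration order.  A
    callback that raises cannot prevent the log from being written — a
    diagnostic record is appended instead.
    """
    st = _STATE if state is None else state
    if not callable(callback):
        raise TypeError("extra logger must be callable")
    st.extra_loggers.append(callback)


add_extra_logger = register_extra_logger  # conventional alias


# ---------------------------------------------------------------------------
# hooks


def _install_termination_hooks(st: ActivationState) -> None:
    atexit.register(_atexit_emit, st)
    for name in CATCHABLE_SIGNALS:
        signum = getattr(signal, name, None)
        if signum is None:
            continue
        try:
            st.previous_handlers[signum] = signal.getsignal(signum)
            signal.signal(signum, _make_signal_handler(st))
        except (OSError, ValueError, RuntimeError):
            continue  # signal not trappable here (platform or non-main thread)


def _atexit_emit(st: ActivationState) -> None:
    try:
        emit(st, reason=None)
    except Exception:
        pass  # never disturb interpreter shutdown


def _make_signal_handler(st: ActivationState):
    def handler(signum, frame):
        try:
            name = signal.Signals(signum).name
        except ValueError:
            name = f"SIG{signum}"
        try:
            emit(st, reason=name)
        except Exception:
            pass
        previous = st.previous_handlers.get(signum)
        if callable(previous):
            # chain to the host's handler; it decides whether to continue
            previous(signum, frame)
        elif previous is signal.SIG_IGN:
            return
        else:
            # restore default disposition and re-deliver, so the parent
            # observes a true signal death rather than a disguised exit
            signal.signal(signum, signal.SIG_DFL)
            os.kill(os.getpid(), signum)

    return handler


# ---------------------------------------------------------------------------
# emission


def _resolve_forward(target: Any) -> Callable[[str], None] | None:
    if target is None:
        return None
    if isinstance(target, str):
        target = logging.getLogger(target)
    if isinstance(target, logging.Logger):
        return lambda line: target.info(line)
    if callable(target):
        return target
    return None


def build_current_document(st: ActivationState, reason: str | None) -> LogDocument:
    """Capture all snapshots now and assemble the log document."""
    opts = st.resolved
    algorithm = capture.DEFAULT_HASH
    end = datetime.now(timezone.utc).astimezone()
    start = st.start_time or end
    window = capture.finalize_window(start, end, reason if reason is not None else 0)

    main_mod = sys.modules.get("__main__")
    declared = getattr(main_mod, "__version__", None) if main_mod else None
    program = capture.snapshot_program(
        st.argv_copy, st.main_path, declared_version=declared, algorithm=algorithm
    )

    extra: list[LogRecord] = []

    def appender(tag: str, payload: str) -> None:
        extra.append(LogRecord(tag, str(payload).replace("\n", " ").replace("\r", " ")))

    for callback in st.extra_loggers:
        try:
            callback(appender)
        except Exception as exc:
            extra.append(
                LogRecord("EXTRA-ERROR", f"extra logger {callback!r} failed: {exc}")
            )

    return logformat.build_document(
        modules=capture.snapshot_modules(with_checksums=opts.module_checksums),
        search_path=capture.snapshot_search_path(),
        system=capture.snapshot_system(),
        interpreter=capture.snapshot_interpreter(algorithm),
        user=capture.snapshot_user(),
        program=program,
        window=window,
        extra_records=extra,
        hash_algorithm=algorithm,
    )


def emit(state: ActivationState | None = None, reason: str | None = None) -> str | None:
    """Write the log exactly once; subsequent calls are no-ops.

    ``reason`` is ``None`` for normal termination or a signal name.
    Returns the written path, or ``None`` when nothing was written
    (already emitted, or logging disabled).
    """
    st = _STATE if state is None else state
    # test-and-set before any I/O: a signal arriving during emission
    # finds the flag already set and returns immediately
    with st.emit_lock:
        if st.emitted or not st.activated:
            return None
        st.emitted = True

    opts = st.resolved
    if not opts.enabled:
        return None

    document = build_current_document(st, reason)
    program_name = document.get("Program") or "program"
    if opts.log_name == AUTO:
        end_stamp = datetime.now(timezone.utc).astimezone()
        name = logformat.default_log_filename(program_name, end_stamp)
    else:
        name = opts.log_name
    path = os.path.join(opts.log_dir or ".", name)

    text = logformat.render_document(document, width=None)

    written = None
    try:
        # write-then-rename so an interrupted emission never leaves a
        # partially written .runinfo file
        tmp = f"{path}.tmp{os.getpid()}"
        with open(tmp, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
        written = path
    except OSError as exc:
        print(f"runinfo: cannot write log to {path}: {exc}", file=sys.stderr)

    forward = _resolve_forward(opts.forward_target)
    if forward is not None:
        try:
            for line in text.splitlines():
                forward(line)
        except Exception as exc:
            print(f"runinfo: forwarding failed: {exc}", file=sys.stderr)

    if written and opts.announce:
        print(f"runinfo: log written to {written}", file=sys.stderr, flush=True)
    return written


def _reset_state_for_tests() -> ActivationState:
    """Replace the process-global state (test support only)."""
    global _STATE
    _STATE = ActivationState()
    return _STATE
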