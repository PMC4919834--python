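import os
import signal
import subprocess
import sys
import time
from pathlib import Path

import pytest

DEMO = [sys.executable, "-m", "runinfo._demo"]


@pytest.fixture
def state():
    """A fresh, hook-free activation state (no atexit/signal side effects)."""
    from runinfo.lifecycle import ActivationState

    return ActivationState(install_hooks=False)


@pytest.fixture
def clean_env(monkeypatch):
    """Strip RUNINFO_* variables so tests control the environment exactly."""
    for key in list(os.environ):
        if key.startswith("RUNINFO_"):
            monkeypatch.delenv(key)
    return monkeypatch


def run_demo(log_dir: Path, *flags: str, check: bool = True) -> subprocess.CompletedProcess:
    proc = subprocess.run(
        DEMO + ["--dir", str(log_dir), *flags],
        capture_output=True,
        text=True,
        timeout=60,
    )
    if check:
        assert proc.returncode == 0, proc.stderr
    return proc


def spawn_demo_and_signal(
    log_dir: Path, signum: int, *flags: str, delay: float = 0.0
) -> subprocess.Popen:
    """Start the demo, wait until it has printed its output line (so the
    logger is active), then deliver ``signum`` after ``delay`` seconds."""
    proc = subprocess.Popen(
        DEMO + ["--dir", str(log_dir), *flags],
        stdout=subprocess.PIPE,
        stderr=subprocess.PIPE,
        text=True,
    )
    assert proc.stdout is not None
    proc.stdout.readline()  # "demo: analysis finished" -> activation done
    if delay:
        time.sleep(delay)
    try:
        proc.send_signal(signum)
    except ProcessLookupError:
        pass  # already exited: that is a legitimate race outcome
    proc.wait(timeout=60)
    return proc


def logs_in(directory: Path) -> list[Path]:
    return sorted(directory.glob("*.runinfo"))
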