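"""Tiny instrumented program used by ``runinfo demo`` and the test suite.

It prints exactly one line of "program output", and the logger adds one
announcement line naming the log it wrote.  Flags exercise the logger's
signal, extra-logger and forwarding behaviour from a real subprocess.
"""

__version__ = "0.3"

import argparse
import logging
import sys
import time

import runinfo


def _extra(add):
    add("SAMPLES", "42")
    add("STAGE", "demo complete")


def _broken_extra(add):
    raise RuntimeError("intentional extra-logger failure")


def main() -> int:
    parser = argparse.ArgumentParser(prog="runinfo-demo")
    parser.add_argument("--dir", default=".", help="directory to write the log into")
    parser.add_argument("--sleep", type=float, default=0.0, help="seconds to idle before exiting")
    parser.add_argument("--extra", action="store_true", help="register extra loggers")
    parser.add_argument("--broken-extra", action="store_true", help="register a raising extra logger")
    parser.add_argument("--forward", metavar="FILE", help="also forward log lines to FILE via logging")
    parser.add_argument("--checksums", action="store_true", help="enable per-module checksums")
    parser.add_argument("--mutate-argv", action="store_true", help="rewrite sys.argv after activation")
    parser.add_argument("--exit-code", type=int, default=0)
    args = parser.parse_args()

    options = {"log_dir": args.dir, "module_checksums": args.checksums}
    if args.forward:
        logger = logging.getLogger("runinfo.forwarded")
        logger.setLevel(logging.INFO)
        logger.addHandler(logging.FileHandler(args.forward))
        logger.propagate = False
        options["forward_target"] = logger
    runinfo.activate(**options)

    if args.extra:
        runinfo.add_extra_logger(_extra)
    if args.broken_extra:
        runinfo.add_extra_logger(_broken_extra)
    if args.mutate_argv:
        sys.argv[:] = ["overwritten", "bogus-arg"]

    print("demo: analysis finished", flush=True)
    if args.sleep:
        time.sleep(args.sleep)
    return args.exit_code


if __name__ == "__main__":
    sys.exit(main())
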