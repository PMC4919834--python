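# runinfo

Runtime provenance logging for reproducible computational pipelines.

Reproducing a bioinformatics analysis takes more than the raw data and a
copy of the script: the result depends on the exact interpreter, every
loaded library and its version, the C runtime, the machine, the user,
the command-line arguments. `runinfo` documents all of that with one
line added to the host program:

```python
import runinfo
runinfo.activate()
```

At program termination — normal exit *or* death by a catchable signal
(`TERM`, `INT`, `HUP`, `QUIT`) — the logger writes a machine-parseable
`.runinfo` file describing the complete execution environment. The
package also provides the parser for that format and a diff tool that
compares two runs' logs to find environment differences that might
affect, or explain, differing results.

## What is logged

One `TAG: payload` record per line (long payloads wrap onto `+ `
continuation lines):

| tag | contents |
|---|---|
| `META-Version`, `META-Hash` | format version, checksum algorithm (SHA-256) |
| `MODULE` | every loaded module: name, version, file location, checksum |
| `INC` | the module search path, one entry per record, order preserved |
| `UNAME`, `PROC0..n` | operating system, and per-processor model/cores/clock/memory |
| `INTERP`, `INTERPVer`, `INTERPSum` | interpreter path, version, binary checksum |
| `LIBC`, `LIBCSum` | C-runtime-library version and checksum (best effort) |
| `User`, `Group` | effective user and groups; real IDs only when different |
| `ProgDir`, `Program`, `Version`, `ProgSUM` | the program's location, name, declared version, checksum |
| `Args` | argument count, then each argument individually quoted |
| `Start`, `End`, `Elapsed`, `EndStat` | the execution window; `EndStat` is the exit code or the signal name |
| program-specified | anything appended by `runinfo.add_extra_logger(callback)` |

Unobtainable values are the sentinel `UNKNOWN`, never empty — capture is
best-effort by contract and can never abort the host program. Module
checksums are off by default (they cost a file read per module); enable
with `activate(module_checksums=True)` or `RUNINFO_MODULE_CHECKSUMS=1`.

Options resolve with the precedence *defaults < activation calls (in
order) < environment variables*, so a single run can be suppressed,
redirected or renamed without touching code: `RUNINFO_SUPPRESS`,
`RUNINFO_DIR`, `RUNINFO_NAME`, `RUNINFO_ANNOUNCE`,
`RUNINFO_MODULE_CHECKSUMS`, `RUNINFO_FORWARD` (booleans are
`0/1/true/false`). `forward_target` additionally sends the rendered
lines to a `logging` logger while still writing the native file.

## Worked example

```
$ runinfo demo --dir wk
runinfo: log written to wk/_demo.py.20260924-072426.runinfo
demo: analysis finished
```

Two lines: the first is the instrumented program's own output, the
second reports where the log was written (program name plus a
timestamp, so separate runs stay distinct). The log begins:

```
META-Version: 1.0
META-Hash: sha256
MODULE: __future__ UNKNOWN /opt/conda/envs/bio/lib/python3.11/__future__.py UNKNOWN
...
UNAME: Linux vm 6.18.44-fc-v40 "#1 SMP PREEMPT_DYNAMIC @0" x86_64
INTERPVer: 3.11.15
LIBC: glibc 2.35
User: 0(root)
Program: _demo.py
Args: 2 "--dir" "wk"
EndStat: 0
```

Comparing two runs (here a synthetic pair where one module version was
bumped):

```
$ runinfo fixture --seed 1 --modules 2 --perturb module-version --out a.runinfo --out-b b.runinfo
$ runinfo diff a.runinfo b.runinfo
[module-version]
  genio75: '4.12.2' -> '4.12.2.post1'
$ echo $?
1
```

Exit status 0 means the environments match (timestamps are ignored by
default), 1 means differences were found; `--ignore TAG` widens the
ignore set. `runinfo validate FILE` checks that a log parses and is in
canonical record order; `runinfo show FILE` re-renders it unwrapped.

## Library surface

- `runinfo.activate(**options)`, `runinfo.add_extra_logger(cb)`,
  `runinfo.emit()` — lifecycle (`runinfo.lifecycle`)
- `runinfo.parse_document` / `render_document` / `read_document` /
  `write_document`, `default_log_filename` — the format
  (`runinfo.logformat`)
- `runinfo.diff_documents`, `runinfo.summarize_report`
  (`runinfo.compare`)
- `runinfo.fixtures.generate_fixture` — deterministic synthetic logs
  with controlled perturbations, for testing parsers and diffs

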