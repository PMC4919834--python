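"""Option precedence, activation merging, extra loggers, forwarding and
once-only emission — exercised in-process on injected state objects."""

import logging
import os
import sys

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runinfo import lifecycle, logformat
from runinfo.lifecycle import Options, activate, emit, register_extra_logger, resolve_options

D = Options()


class TestResolveOptions:
    def test_identity_without_layers_or_env(self):
        assert resolve_options(D, [], {}) == D

    def test_later_layer_wins(self):
        got = resolve_options(D, [{"log_dir": "/a"}, {"log_dir": "/b"}], {})
        assert got.log_dir == "/b"

    def test_env_suppress_overrides_activation_enable(self):
        got = resolve_options(D, [{"enabled": True}], {"RUNINFO_SUPPRESS": "1"})
        assert got.enabled is False

    def test_env_can_reenable(self):
        got = resolve_options(D, [{"enabled": False}], {"RUNINFO_SUPPRESS": "false"})
        assert got.enabled is True

    def test_env_redirect(self):
        got = resolve_options(D, [], {"RUNINFO_DIR": "/elsewhere", "RUNINFO_NAME": "run.log"})
        assert got.log_dir == "/elsewhere"
        assert got.log_name == "run.log"

    def test_malformed_bool_warned_and_ignored(self):
        with pytest.warns(UserWarning, match="not a boolean"):
            got = resolve_options(D, [], {"RUNINFO_SUPPRESS": "maybe"})
        assert got.enabled is True

    def test_unknown_env_key_warned_not_fatal(self):
        with pytest.warns(UserWarning, match="unknown environment variable"):
            got = resolve_options(D, [], {"RUNINFO_FROBNICATE": "1"})
        assert got == D

    def test_unknown_activation_option_warned_and_ignored(self):
        with pytest.warns(UserWarning, match="unknown option"):
            got = resolve_options(D, [{"bogus": 1, "log_dir": "/a"}], {})
        assert got.log_dir == "/a"

    def test_unrelated_env_untouched(self):
        assert resolve_options(D, [], {"PATH": "/bin"}) == D

    layer = st.fixed_dictionaries(
        {},
        optional={
            "enabled": st.booleans(),
            "log_dir": st.sampled_from(["/a", "/b", "."]),
            "log_name": st.sampled_from(["AUTO", "x.log"]),
            "announce": st.booleans(),
        },
    )
    env = st.fixed_dictionaries(
        {},
        optional={
            "RUNINFO_SUPPRESS": st.sampled_from(["0", "1", "true"]),
            "RUNINFO_DIR": st.sampled_from(["/e", "/f"]),
            "RUNINFO_ANNOUNCE": st.sampled_from(["0", "1"]),
        },
    )

    @settings(max_examples=100, deadline=None)
    @given(layers=st.lists(layer, max_size=4), env=env)
    def test_env_applies_last_idempotently(self, layers, env):
        direct = resolve_options(D, layers, env)
        staged = resolve_options(resolve_options(D, layers, {}), [], env)
        assert direct == staged


class TestActivate:
    def test_first_activation_sets_state(self, state, clean_env):
        st_ = activate(state)
        assert st_.activated
        assert st_.start_time is not None
        assert st_.argv_copy == tuple(sys.argv[1:])
        assert st_.resolved == Options()

    def test_later_call_wins_on_merge(self, state, clean_env):
        activate(state, enabled=False)
        activate(state, enabled=True)
        assert state.resolved.enabled is True

    def test_env_override_reapplied_after_merge(self, state, clean_env):
        clean_env.setenv("RUNINFO_SUPPRESS", "1")
        activate(state, enabled=True)
        assert state.resolved.enabled is False

    def test_start_time_and_argv_fixed_at_first_activation(self, state, clean_env):
        activate(state)
        t0, argv0 = state.start_time, state.argv_copy
        activate(state, log_dir="/tmp")
        assert state.start_time is t0
        assert state.argv_copy == argv0


def _emit_to(state, tmp_path, **options):
    activate(state, log_dir=str(tmp_path), announce=False, **options)
    return emit(state)


class TestEmit:
    def test_writes_parseable_canonical_log(self, state, clean_env, tmp_path):
        path = _emit_to(state, tmp_path)
        assert path is not None and os.path.exists(path)
        doc = logformat.read_document(path)
        assert logformat.check_canonical_order(doc) == []
        for tag in logformat.MANDATORY_TAGS:
            assert tag in doc.tags(), tag

    def test_second_emit_is_noop(self, state, clean_env, tmp_path):
        first = _emit_to(state, tmp_path)
        assert first is not None
        assert emit(state) is None
        assert len(list(tmp_path.glob("*.runinfo"))) == 1

    def test_disabled_writes_nothing(self, state, clean_env, tmp_path):
        assert _emit_to(state, tmp_path, enabled=False) is None
        assert list(tmp_path.iterdir()) == []

    def test_env_suppression_beats_activation(self, state, clean_env, tmp_path):
        clean_env.setenv("RUNINFO_SUPPRESS", "1")
        assert _emit_to(state, tmp_path, enabled=True) is None
        assert list(tmp_path.iterdir()) == []

    def test_env_redirect_moves_log(self, state, clean_env, tmp_path):
        target = tmp_path / "redirected"
        target.mkdir()
        clean_env.setenv("RUNINFO_DIR", str(target))
        path = _emit_to(state, tmp_path / "ignored_default")
        assert path is not None and path.startswith(str(target))

    def test_explicit_log_name(self, state, clean_env, tmp_path):
        path = _emit_to(state, tmp_path, log_name="fixed.runinfo")
        assert os.path.basename(path) == "fixed.runinfo"

    def test_auto_name_contains_program_and_stamp(self, state, clean_env, tmp_path):
        path = _emit_to(state, tmp_path)
        name = os.path.basename(path)
        program = logformat.read_document(path).get("Program")
        assert name.startswith(program + ".")
        assert name.endswith(".runinfo")

    def test_announce_line_on_stderr(self, state, clean_env, tmp_path, capsys):
        activate(state, log_dir=str(tmp_path))
        path = emit(state)
        err = capsys.readouterr().err
        assert err.strip() == f"runinfo: log written to {path}"

    def test_unwritable_destination_does_not_raise(self, state, clean_env, tmp_path, capsys):
        activate(state, log_dir=str(tmp_path / "missing_dir"), announce=False)
        assert emit(state) is None
        assert "cannot write log" in capsys.readouterr().err
        assert emit(state) is None  # emitted flag still set: no retry storm

    def test_argv_copy_immune_to_host_mutation(self, state, clean_env, tmp_path, monkeypatch):
        monkeypatch.setattr(sys, "argv", ["prog.py", "orig1", "orig2"])
        activate(state, log_dir=str(tmp_path), announce=False)
        sys.argv[:] = ["prog.py", "rewritten"]
        doc = logformat.read_document(emit(state))
        assert logformat.parse_args_payload(doc.get("Args")) == ["orig1", "orig2"]

    def test_signal_reason_recorded_in_endstat(self, state, clean_env, tmp_path):
        activate(state, log_dir=str(tmp_path), announce=False)
        doc = logformat.read_document(emit(state, reason="SIGTERM"))
        assert doc.get("EndStat") == "SIGTERM"

    def test_module_checksums_option(self, state, clean_env, tmp_path):
        activate(state, log_dir=str(tmp_path), announce=False, module_checksums=True)
        doc = logformat.read_document(emit(state))
        recs = [logformat.parse_module_payload(p) for p in doc.get_all("MODULE")]
        with_sums = [r for r in recs if r.checksum != "UNKNOWN"]
        assert with_sums, "expected at least some file-backed modules to be checksummed"
        assert all(len(r.checksum) == 64 for r in with_sums)


class TestExtraLoggers:
    def test_records_follow_standard_records_in_order(self, state, clean_env, tmp_path):
        register_extra_logger(lambda add: add("SAMPLES", "42"), state)
        register_extra_logger(lambda add: add("STAGE", "two"), state)
        doc = logformat.read_document(_emit_to(state, tmp_path))
        assert doc.tags()[-2:] == ["SAMPLES", "STAGE"]
        assert doc.get("SAMPLES") == "42"

    def test_extra_records_survive_roundtrip(self, state, clean_env, tmp_path):
        register_extra_logger(lambda add: add("NOTE", "free text with spaces"), state)
        doc = logformat.read_document(_emit_to(state, tmp_path))
        again = logformat.parse_document(logformat.render_document(doc, width=40))
        assert again == doc
        assert again.get("NOTE") == "free text with spaces"

    def test_raising_callback_cannot_block_emission(self, state, clean_env, tmp_path):
        def broken(add):
            raise RuntimeError("boom")

        register_extra_logger(broken, state)
        register_extra_logger(lambda add: add("AFTER", "ok"), state)
        path = _emit_to(state, tmp_path)
        doc = logformat.read_document(path)
        assert any(r.tag == "EXTRA-ERROR" for r in doc.records)
        assert doc.get("AFTER") == "ok"

    def test_non_callable_rejected(self, state):
        with pytest.raises(TypeError):
            register_extra_logger("not callable", state)


class TestForwarding:
    def test_callable_target_gets_lines_and_file_still_written(
        self, state, clean_env, tmp_path
    ):
        received = []
        path = _emit_to(state, tmp_path, forward_target=received.append)
        assert path is not None and os.path.exists(path)
        native = open(path, encoding="utf-8").read().splitlines()
        assert received == native

    def test_logging_logger_target(self, state, clean_env, tmp_path):
        logger = logging.getLogger("test.runinfo.forward")
        records = []

        class Capture(logging.Handler):
            def emit(self, record):
                records.append(record.getMessage())

        logger.addHandler(Capture())
        logger.setLevel(logging.INFO)
        logger.propagate = False
        path = _emit_to(state, tmp_path, forward_target=logger)
        assert path is not None
        assert any(line.startswith("META-Version:") for line in records)
        assert any(line.startswith("EndStat:") for line in records)

    def test_forwarding_failure_does_not_block_file(self, state, clean_env, tmp_path, capsys):
        def bad(line):
            raise OSError("forward broken")

        path = _emit_to(state, tmp_path, forward_target=bad)
        assert path is not None and os.path.exists(path)
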