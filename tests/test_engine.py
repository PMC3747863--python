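"""Execution engine: binding, lazy provide/run, caching, invalidation,
trust/untrust, persistence, file tracking and parallel scheduling."""

import pickle
import random

import pytest

from frond import (
    BindingError,
    CyclicGraphError,
    FileResourceError,
    NoResourceError,
    ProjectSpec,
    Protocol,
    UnknownNodeError,
    bind,
    make_string_pipeline,
    modify_node_source,
    naive_execute,
    random_dag,
)
from frond.engine import (
    STATE_AVAILABLE,
    STATE_DUMPED,
    STATE_TO_BE_BUILT,
    STATE_UNAVAILABLE,
)

from conftest import make_chain, make_diamond


def open_project(pipe, project_dir, **kw):
    check = kw.pop("check_consistency", True)
    spec = ProjectSpec(pipe.lgl, pipe.functions(), project_dir, **kw)
    return bind(spec, check_consistency=check)


class TestBinding:
    def test_fixture_binds_three_nodes(self, protocol):
        assert len(protocol.bindings) == 3
        assert sorted(protocol.labels()) == [
            "first_task",
            "second_task",
            "third_task",
        ]

    def test_missing_function_named_in_error(self, string_pipeline, tmp_path):
        funcs = string_pipeline.functions()
        del funcs["second_task"]
        with pytest.raises(BindingError, match="second_task"):
            bind(ProjectSpec(string_pipeline.lgl, funcs, tmp_path))

    def test_arity_mismatch_is_binding_error(self, tmp_path):
        funcs = {"A": lambda: 1, "B": lambda: 2, "C": lambda x: x}
        with pytest.raises(BindingError, match="C"):
            bind(ProjectSpec("A -> C; B -> C;", funcs, tmp_path))

    def test_var_positional_accepts_any_arity(self, tmp_path):
        funcs = {"A": lambda: 1, "B": lambda: 2, "C": lambda *xs: sum(xs)}
        pr = bind(ProjectSpec("A -> C; B -> C;", funcs, tmp_path))
        assert pr.provide("C") == 3

    def test_cyclic_graph_rejected(self, tmp_path):
        funcs = {"X": lambda x: x}
        with pytest.raises(CyclicGraphError):
            bind(ProjectSpec("X -> X;", funcs, tmp_path))

    def test_unknown_label_lookup(self, protocol):
        with pytest.raises(UnknownNodeError):
            protocol.provide("nonexistent")


class TestLazyProvide:
    def test_provide_builds_only_needed_path(self, protocol):
        assert protocol.provide("second_task") == "hello-2"
        assert protocol.execution_counts["third_task"] == 0
        assert protocol.execution_counts["first_task"] == 1

    def test_repeat_provide_executes_nothing(self, protocol):
        protocol.provide("second_task")
        before = dict(protocol.execution_counts)
        assert protocol.provide("second_task") == "hello-2"
        assert protocol.execution_counts == before

    def test_cleared_chain_rebuilds_everything_in_order(self, tmp_path):
        chain = make_chain(5)
        pr = open_project(chain, tmp_path)
        pr.run()
        pr.clearall()
        pr.undumpall()
        pr.execution_counts = {k: 0 for k in pr.execution_counts}
        assert pr.provide("c4") == chain.expected["c4"]
        assert all(v == 1 for v in pr.execution_counts.values())

    def test_run_provides_all_leaves(self, protocol, string_pipeline):
        result = protocol.run()
        assert result == {
            "second_task": "hello-2",
            "third_task": "hello-3",
        }
        assert protocol.execution_counts["first_task"] == 1

    def test_single_node_run_equals_provide(self, tmp_path):
        funcs = {"only": lambda: 42}
        pr = bind(ProjectSpec("only;", funcs, tmp_path))
        assert pr.run() == {"only": 42}
        assert pr.provide("only") == 42

    def test_fan_out_children_receive_identical_resource(self, tmp_path):
        seen = []
        funcs = {
            "root": lambda: ["shared"],
            "kid1": lambda x: seen.append(id(x)) or x[0],
            "kid2": lambda x: seen.append(id(x)) or x[0],
        }
        pr = bind(
            ProjectSpec("root -> kid1, kid2;", funcs, tmp_path, workers=1)
        )
        pr.run()
        assert len(set(seen)) == 1


class TestScheduling:
    def test_diamond_waves(self, diamond_pipeline, tmp_path):
        pr = open_project(diamond_pipeline, tmp_path)
        assert pr.schedule(["D"]) == [["A"], ["B", "C"], ["D"]]

    def test_cached_request_gives_empty_plan(self, protocol):
        protocol.provide("second_task")
        assert protocol.schedule(["second_task"]) == []

    def test_middle_cached_prunes_ancestors(self, tmp_path):
        chain = make_chain(3)
        pr = open_project(chain, tmp_path)
        pr.provide("c1")
        assert pr.schedule(["c2"]) == [["c2"]]

    def test_parallel_run_equals_sequential(self, tmp_path):
        blobs = set()
        for rep in range(20):
            for workers in (1, 4):
                pipe = make_diamond()
                pr = open_project(
                    pipe, tmp_path / f"p{rep}_{workers}", workers=workers
                )
                blobs.add(pickle.dumps(pr.run()))
        assert len(blobs) == 1


class TestStatesAndCaches:
    def test_fresh_project_all_to_be_built(self, protocol):
        assert set(protocol.list_states().values()) == {STATE_TO_BE_BUILT}

    def test_state_walk(self, protocol):
        protocol.run()
        assert set(protocol.list_states().values()) == {STATE_AVAILABLE}
        protocol.clear("second_task")
        states = protocol.list_states()
        assert states["second_task"] == STATE_DUMPED
        assert states["first_task"] == STATE_AVAILABLE

    def test_clear_then_provide_reloads_from_disk(self, protocol):
        protocol.run()
        protocol.clear("second_task")
        before = dict(protocol.execution_counts)
        assert protocol.provide("second_task") == "hello-2"
        assert protocol.execution_counts == before

    def test_undump_and_clear_all(self, protocol):
        protocol.run()
        protocol.undumpall()
        protocol.clearall()
        assert set(protocol.list_states().values()) == {STATE_TO_BE_BUILT}

    def test_clear_on_never_built_node_is_noop(self, protocol):
        protocol.clear("third_task")
        protocol.undump("third_task")
        assert protocol.list_states()["third_task"] == STATE_TO_BE_BUILT

    def test_persistence_round_trip(self, string_pipeline, tmp_path):
        pr1 = open_project(string_pipeline, tmp_path / "proj")
        pr1.run()
        pr2 = open_project(string_pipeline, tmp_path / "proj")
        assert pr2.list_states() == pr1_reloaded_states(pr1, pr2)
        assert set(pr2.list_states().values()) == {STATE_DUMPED}
        assert pr2.provide("second_task") == "hello-2"
        assert all(v == 0 for v in pr2.execution_counts.values())

    def test_dumping_off_persists_nothing(self, string_pipeline, tmp_path):
        pr1 = open_project(string_pipeline, tmp_path / "proj", dumping=False)
        pr1.run()
        assert set(pr1.list_states().values()) == {STATE_AVAILABLE}
        pr2 = open_project(string_pipeline, tmp_path / "proj", dumping=False)
        assert set(pr2.list_states().values()) == {STATE_TO_BE_BUILT}

    def test_dumping_toggle_restores_behavior(self, protocol):
        protocol.dump_off()
        protocol.dump_on()
        protocol.run()
        protocol.clearall()
        assert set(protocol.list_states().values()) == {STATE_DUMPED}

    def test_rebuild_forces_re_execution(self, protocol):
        protocol.run()
        assert protocol.rebuild("second_task") == "hello-2"
        assert protocol.execution_counts["second_task"] == 2
        assert protocol.execution_counts["first_task"] == 1


class TestGetInputs:
    def test_inputs_of_mid_node(self, protocol):
        assert protocol.getinputs("second_task") == ["hello"]

    def test_root_has_no_inputs(self, protocol):
        assert protocol.getinputs("first_task") == []

    def test_returned_copies_do_not_alias_cache(self, tmp_path):
        funcs = {
            "src": lambda: {"key": [1, 2]},
            "dst": lambda d: sorted(d),
        }
        pr = bind(ProjectSpec("src -> dst;", funcs, tmp_path))
        inputs = pr.getinputs("dst")
        inputs[0]["key"].append(99)
        assert pr.provide("src") == {"key": [1, 2]}


class TestInvalidation:
    def test_modify_leaf_invalidates_only_leaf(self, string_pipeline, tmp_path):
        pr = open_project(string_pipeline, tmp_path)
        pr.run()
        edited = string_pipeline.with_source(
            modify_node_source(string_pipeline.module_source, "second_task")
        )
        pr2 = open_project(edited, tmp_path, check_consistency=False)
        assert pr2.detect_code_changes(refresh=False) == {"second_task"}
        states = pr2.list_states()
        assert states["second_task"] == STATE_TO_BE_BUILT
        assert states["first_task"] == STATE_DUMPED
        assert states["third_task"] == STATE_DUMPED

    def test_modify_root_invalidates_descendant_closure(
        self, string_pipeline, tmp_path
    ):
        pr = open_project(string_pipeline, tmp_path)
        pr.run()
        edited = string_pipeline.with_source(
            modify_node_source(string_pipeline.module_source, "first_task")
        )
        pr2 = open_project(edited, tmp_path, check_consistency=False)
        assert pr2.detect_code_changes(refresh=False) == {
            "first_task",
            "second_task",
            "third_task",
        }

    def test_no_modification_detects_nothing(self, protocol):
        protocol.run()
        assert protocol.detect_code_changes(refresh=False) == set()

    def test_bind_auto_clears_stale_resources(self, string_pipeline, tmp_path):
        open_project(string_pipeline, tmp_path).run()
        edited = string_pipeline.with_source(
            modify_node_source(string_pipeline.module_source, "first_task")
        )
        pr2 = open_project(edited, tmp_path)  # consistency check on by default
        assert set(pr2.list_states().values()) == {STATE_TO_BE_BUILT}

    def test_trust_suppresses_cascade(self, string_pipeline, tmp_path):
        pr = open_project(string_pipeline, tmp_path)
        pr.run()
        edited = string_pipeline.with_source(
            modify_node_source(string_pipeline.module_source, "second_task")
        )
        pr2 = open_project(edited, tmp_path, check_consistency=False)
        pr2.trust("second_task")
        assert pr2.detect_code_changes(refresh=False) == set()

    def test_trust_on_unchanged_node_is_noop(self, protocol):
        protocol.run()
        protocol.trust("second_task")
        assert protocol.detect_code_changes(refresh=False) == set()

    def test_trust_then_second_edit_reinvalidates(
        self, string_pipeline, tmp_path
    ):
        pr = open_project(string_pipeline, tmp_path)
        pr.run()
        once = string_pipeline.with_source(
            modify_node_source(string_pipeline.module_source, "second_task")
        )
        pr2 = open_project(once, tmp_path, check_consistency=False)
        pr2.trust("second_task")
        twice = once.with_source(
            modify_node_source(once.module_source, "second_task")
        )
        pr3 = open_project(twice, tmp_path, check_consistency=False)
        assert pr3.detect_code_changes(refresh=False) == {"second_task"}

    def test_trust_without_resource_raises(self, protocol):
        with pytest.raises(NoResourceError):
            protocol.trust("second_task")

    def test_untrust_clears_descendants(self, string_pipeline, tmp_path):
        pr = open_project(string_pipeline, tmp_path)
        pr.run()
        pr.untrust("first_task")
        assert set(pr.list_states().values()) == {STATE_TO_BE_BUILT}

    def test_untrust_leaf_touches_only_leaf(self, protocol):
        protocol.run()
        protocol.untrust("second_task")
        states = protocol.list_states()
        assert states["second_task"] == STATE_TO_BE_BUILT
        assert states["first_task"] == STATE_AVAILABLE

    def test_untrust_idempotent(self, protocol):
        protocol.run()
        protocol.untrust("first_task")
        protocol.untrust("first_task")
        assert set(protocol.list_states().values()) == {STATE_TO_BE_BUILT}

    @pytest.mark.parametrize("seed", range(25))
    def test_invalidation_matches_descendant_closure_oracle(
        self, seed, tmp_path
    ):
        rng = random.Random(seed)
        pipe = random_dag(rng.randint(2, 10), 0.4, seed)
        pr = open_project(pipe, tmp_path)
        pr.run()
        target = rng.choice(pipe.node_names)
        edited = pipe.with_source(
            modify_node_source(pipe.module_source, target)
        )
        pr2 = open_project(edited, tmp_path, check_consistency=False)
        invalidated = pr2.detect_code_changes(refresh=False)
        closure = {target}
        grew = True
        while grew:
            grew = False
            for s, d in pipe.edges:
                if s in closure and d not in closure:
                    closure.add(d)
                    grew = True
        assert invalidated == closure


class TestFileTracking:
    def _file_pipeline(self, tmp_path):
        out = tmp_path / "out.txt"
        lgl = "writer[F];"

        def writer():
            out.write_text("payload")
            return str(out)

        return out, bind(
            ProjectSpec(lgl, {"writer": writer}, tmp_path / "proj")
        )

    def test_fresh_after_build(self, tmp_path):
        _, pr = self._file_pipeline(tmp_path)
        pr.provide("writer")
        assert pr.check_file_outputs("writer").fresh

    def test_touched_file_reported_stale(self, tmp_path):
        out, pr = self._file_pipeline(tmp_path)
        pr.provide("writer")
        out.write_text("tampered")
        report = pr.check_file_outputs("writer")
        assert not report.fresh
        assert report.stale[0][0] == str(out)

    def test_deleted_file_triggers_rebuild(self, tmp_path):
        out, pr = self._file_pipeline(tmp_path)
        pr.provide("writer")
        out.unlink()
        pr.provide("writer")
        assert pr.execution_counts["writer"] == 2
        assert out.exists()

    def test_non_filename_resource_is_type_error(self, tmp_path):
        pr = bind(
            ProjectSpec("bad[F];", {"bad": lambda: 123}, tmp_path / "proj")
        )
        with pytest.raises(FileResourceError):
            pr.provide("bad")


class TestFailurePolicy:
    def test_node_error_propagates_unmodified(self, tmp_path):
        def boom():
            raise ValueError("kaput")

        pr = bind(ProjectSpec("boom;", {"boom": boom}, tmp_path))
        with pytest.raises(ValueError, match="kaput"):
            pr.provide("boom")
        assert pr.list_states()["boom"] == STATE_UNAVAILABLE

    def test_failure_aborts_descendants_not_siblings(self, tmp_path):
        def A():
            return "a"

        def B(x):
            raise RuntimeError("node B failed")

        def C(x):
            return x + "c"

        def D(b, c):
            return b + c

        funcs = {"A": A, "B": B, "C": C, "D": D}
        pr = bind(
            ProjectSpec(
                "A -> B, C; B -> D; C -> D;", funcs, tmp_path, workers=1
            )
        )
        with pytest.raises(RuntimeError):
            pr.run()
        states = pr.list_states()
        assert states["A"] == STATE_AVAILABLE
        assert states["C"] == STATE_AVAILABLE
        assert states["B"] == STATE_UNAVAILABLE
        assert states["D"] == STATE_TO_BE_BUILT


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_random_operation_interleavings(self, seed, tmp_path):
        rng = random.Random(seed + 1000)
        pipe = random_dag(rng.randint(1, 10), 0.35, seed)
        pr = open_project(pipe, tmp_path)
        for _ in range(12):
            op = rng.choice(["provide", "clear", "undump", "run"])
            label = rng.choice(pipe.node_names)
            if op == "provide":
                pr.provide(label)
            elif op == "clear":
                pr.clear(label)
            elif op == "undump":
                pr.undump(label)
            else:
                pr.run()
        assert {
            lbl: pr.provide(lbl) for lbl in pipe.node_names
        } == naive_execute(pipe)

    def test_execution_counters_never_exceed_one(self, tmp_path):
        pipe = random_dag(8, 0.4, 7)
        pr = open_project(pipe, tmp_path)
        pr.run()
        for lbl in pipe.node_names:
            pr.provide(lbl)
        assert all(v <= 1 for v in pr.execution_counts.values())


def pr1_reloaded_states(pr1: Protocol, pr2: Protocol):
    """States pr1's cache should present to a fresh session: everything it
    dumped shows as dumped."""
    return {
        lbl: STATE_DUMPED if state in (STATE_AVAILABLE, STATE_DUMPED) else state
        for lbl, state in pr1.list_states().items()
    }
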