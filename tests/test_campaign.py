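"""Variant notation, libraries, plan arithmetic, resumable execution."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from evbscreen import (
    EVBParameters,
    EffectModel,
    ProtocolPlan,
    ResultStore,
    SurrogateModel,
    SurrogateTaskRunner,
    Variant,
    alanine_scan_library,
    build_manifest,
    combinatorial_library,
    default_schedule,
    execute,
    parse_variant,
    plan_totals,
    site_saturation_library,
)
from evbscreen.errors import InvalidInputError, InvalidPlanError, VariantParseError
from evbscreen.variants import AMINO_ACIDS, LibraryNotice


class TestVariantNotation:
    def test_single_substitution(self):
        v = parse_variant("L93A")
        assert v.substitutions == ((93, "L", "A"),)
        assert v.label == "L93A"

    def test_wild_type_is_empty(self):
        v = parse_variant("WT")
        assert v.is_wild_type and v.label == "WT"

    def test_multi_substitution_canonicalized_by_position(self):
        v = parse_variant("T172D+L93A+Y164S")
        assert v.label == "L93A+Y164S+T172D"
        assert parse_variant(v.label) == v  # round-trip

    @pytest.mark.parametrize("bad", ["L93", "93A", "L93A+L93G", "L93L",
                                     "", "L93A++T172D", "l93a"])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(VariantParseError):
            parse_variant(bad)

    @given(st.lists(
        st.tuples(st.integers(1, 400),
                  st.sampled_from(AMINO_ACIDS),
                  st.sampled_from(AMINO_ACIDS)),
        min_size=1, max_size=5,
        unique_by=lambda t: t[0],
    ).filter(lambda subs: all(w != n for _, w, n in subs)))
    @settings(max_examples=100, derandomize=True)
    def test_label_round_trips(self, subs):
        v = Variant(tuple(subs))
        assert parse_variant(v.label) == v


class TestLibraries:
    def test_alanine_scan_counts(self):
        positions = [(i, "L") for i in range(1, 51)]
        lib = alanine_scan_library(positions, exclusions={10, 20})
        assert len(lib) == 48
        assert all(v.substitutions[0].new_aa == "A" for v in lib)

    def test_alanine_scan_skips_ala_gly_with_notice(self):
        with pytest.warns(LibraryNotice):
            lib = alanine_scan_library([(1, "A"), (2, "L"), (3, "G")])
        assert [v.label for v in lib] == ["L2A"]

    def test_all_excluded_gives_empty_library(self):
        assert alanine_scan_library([(1, "L")], exclusions={1}) == []

    def test_site_saturation_full_alphabet(self):
        lib = site_saturation_library(93, "L")
        assert len(lib) == 19
        assert "L93L" not in [v.label for v in lib]

    def test_site_saturation_explicit_choices(self):
        lib = site_saturation_library(93, "L", alphabet=["A", "G", "H", "L"])
        assert [v.label for v in lib] == ["L93A", "L93G", "L93H"]

    def test_combinatorial_product_of_round_choices(self):
        choices = {
            93: ("L", ["A", "G", "H"]),
            164: ("Y", ["S", "C", "A", "H", "E", "P"]),
            172: ("T", ["L", "W", "D", "R", "S"]),
        }
        lib = combinatorial_library(choices)
        assert len(lib) == 90  # 3 x 6 x 5
        assert all(len(v.substitutions) == 3 for v in lib)
        assert len({v.label for v in lib}) == 90

    def test_combinatorial_removes_wt_from_choices(self):
        with pytest.warns(LibraryNotice):
            lib = combinatorial_library({5: ("T", ["T", "S"])})
        assert [v.label for v in lib] == ["T5S"]


class TestSchedule:
    def test_default_has_26_windows_excluding_midpoint(self, schedule):
        assert schedule.n_windows == 26
        assert 0.5 not in schedule.thetas
        assert schedule.includes_md_window
        assert schedule.thetas[0] == 0.0 and schedule.thetas[-1] == 1.0
        diffs = [b - a for a, b in zip(schedule.thetas, schedule.thetas[1:])]
        assert all(d > 0 for d in diffs)

    def test_md_stream_spliced_between_bracketing_windows(self, schedule):
        acc = schedule.accumulation_thetas()
        assert len(acc) == 27
        i = acc.index(0.5)
        assert acc[i - 1] == 0.45 and acc[i + 1] == 0.55


class TestPlanArithmetic:
    def test_default_protocol_yields_24_tasks_per_variant(self):
        plan = ProtocolPlan(n_replicas=4, md_length_ns=8.0,
                            snapshot_interval_ns=1.0,
                            discard_initial_ns=2.0)
        man = build_manifest([parse_variant("WT")], plan)
        assert len(man.tasks) == 24  # 4 replicas x 6 kept snapshots
        totals = plan_totals(man)
        assert totals.per_run_ps == pytest.approx(520.0)  # 26 x 20 ps
        assert totals.per_system_ns == pytest.approx(12.48)

    def test_no_discard_keeps_all_snapshots(self):
        plan = ProtocolPlan(n_replicas=4, md_length_ns=8.0,
                            snapshot_interval_ns=1.0,
                            discard_initial_ns=0.0)
        man = build_manifest([parse_variant("WT")], plan)
        assert len(man.tasks) == 32

    def test_empty_variant_list_gives_empty_manifest(self):
        man = build_manifest([], ProtocolPlan())
        assert len(man.tasks) == 0
        assert plan_totals(man) == (0.0, 0.0, 0)

    def test_task_count_scales_with_library(self):
        plan = ProtocolPlan(n_replicas=2, md_length_ns=4.0,
                            discard_initial_ns=2.0)
        lib = [parse_variant(v) for v in ("WT", "L93A", "T172D")]
        man = build_manifest(lib, plan)
        assert len(man.tasks) == 3 * 2 * 2

    def test_seeds_are_pure_function_of_identity(self):
        plan = ProtocolPlan(master_seed=42)
        lib = [parse_variant("L93A")]
        a = build_manifest(lib, plan)
        b = build_manifest(lib, plan)
        assert [t.seed for t in a.tasks] == [t.seed for t in b.tasks]
        c = build_manifest(lib, ProtocolPlan(master_seed=43))
        assert [t.seed for t in c.tasks] != [t.seed for t in a.tasks]

    def test_invalid_plans_rejected(self):
        with pytest.raises(InvalidPlanError):
            ProtocolPlan(discard_initial_ns=9.0, md_length_ns=8.0)
        with pytest.raises(InvalidPlanError):
            ProtocolPlan(md_length_ns=8.0, snapshot_interval_ns=2.5,
                         discard_initial_ns=2.0)


def _tiny_campaign(tmp_path, master_seed=5):
    base = SurrogateModel.from_targets(lam=40.0, dG0=2.0)
    eff = EffectModel(shifts={"L93A": (-3.0, 0.0)}, master_seed=1)
    plan = ProtocolPlan(n_replicas=2, md_length_ns=2.0,
                        snapshot_interval_ns=1.0, discard_initial_ns=0.0,
                        master_seed=master_seed)
    lib = [parse_variant(v) for v in ("WT", "L93A", "T172D")]
    manifest = build_manifest(lib, plan)
    runner = SurrogateTaskRunner(
        base_model=base, effects=eff, params=EVBParameters(),
        n_steps_per_window=1500, min_frames=10,
    )
    return manifest, runner


class TestExecute:
    def test_all_tasks_done_and_persisted(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)
        store = ResultStore(tmp_path / "store")
        results = execute(manifest, runner, store)
        assert len(results) == 12
        assert all(r["status"] == "done" for r in results.values())
        on_disk = store.load_results()
        assert on_disk == results

    def test_interrupt_and_resume_is_byte_identical(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)

        # uninterrupted reference run
        ref_store = ResultStore(tmp_path / "ref")
        execute(manifest, runner, ref_store)

        # interrupted after 5 tasks, then resumed
        class Kill(Exception):
            pass

        calls = {"n": 0}

        def flaky(task):
            if calls["n"] == 5:
                raise KeyboardInterrupt  # simulates a kill signal
            calls["n"] += 1
            return runner(task)

        store = ResultStore(tmp_path / "resumed")
        with pytest.raises(KeyboardInterrupt):
            execute(manifest, flaky, store)
        assert len(store.load_results()) == 5
        execute(manifest, runner, store)  # resume

        assert (store.results_path.read_bytes()
                == ref_store.results_path.read_bytes())
        assert (store.status_path.read_bytes()
                == ref_store.status_path.read_bytes())

    def test_resume_skips_done_tasks(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)
        store = ResultStore(tmp_path / "store")
        execute(manifest, runner, store)

        def exploding(task):  # must never be called on resume
            raise AssertionError("completed task re-executed")

        results = execute(manifest, exploding, store)
        assert all(r["status"] == "done" for r in results.values())

    def test_worker_count_does_not_change_results(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)
        s1 = ResultStore(tmp_path / "w1")
        s4 = ResultStore(tmp_path / "w4")
        execute(manifest, runner, s1, workers=1)
        execute(manifest, runner, s4, workers=4)
        assert (s1.results_path.read_bytes()
                == s4.results_path.read_bytes())

    def test_failing_task_is_isolated(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)
        bad_key = manifest.tasks[3].key

        def sometimes(task):
            if task.key == bad_key:
                raise RuntimeError("engine blew up")
            return runner(task)

        store = ResultStore(tmp_path / "store")
        results = execute(manifest, sometimes, store)
        assert results[bad_key]["status"] == "failed"
        assert "engine blew up" in results[bad_key]["error"]
        done = [k for k, r in results.items() if r["status"] == "done"]
        assert len(done) == len(manifest.tasks) - 1

    def test_result_records_carry_the_task_identity(self, tmp_path):
        manifest, runner = _tiny_campaign(tmp_path)
        store = ResultStore(tmp_path / "store")
        results = execute(manifest, runner, store)
        rec = results[manifest.tasks[0].key]
        assert {"variant", "replica", "snapshot", "seed", "dG_act",
                "dG_rxn", "lambda_est", "x_rs", "x_ts", "x_ps",
                "n_frames"} <= set(rec)
        # records are valid JSON lines on disk
        lines = store.results_path.read_text().splitlines()
        assert len(lines) == len(manifest.tasks)
        assert all(json.loads(l) for l in lines)
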