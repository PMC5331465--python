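"""Campaign planning and resumable ensemble execution.

A screening campaign is a lattice of independent EVB tasks: one task per
(variant, replica, snapshot).  Each replica is an independent MD
equilibration; snapshots are taken at the end of every interval, the
early (equilibration) snapshots are discarded, and each surviving
snapshot seeds one full EVB-FEP/US run.  With the default plan — four
replicas, 8 ns of MD, snapshots every 1 ns, first 2 ns discarded — that
is 24 tasks per variant, each a 520 ps EVB run over 26 mapping windows
of 20 ps, i.e. 12.48 ns of EVB time per variant.

Execution follows a work-queue contract: tasks run independently (at
most ``workers`` at a time), every completion is persisted atomically,
failures are recorded without aborting the campaign, and re-invocation
skips already-completed tasks, so an interrupted campaign resumes to a
result store identical to an uninterrupted one.
"""

from __future__ import annotations

import json
import os
import tempfile
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, NamedTuple, Optional, Sequence

from .core import EVBParameters, MappingSchedule
from .errors import EVBError, InvalidPlanError, NoBarrierError
from .seeds import derive_seed
from .variants import Variant

__all__ = [
    "DEFAULT_THETAS",
    "default_schedule",
    "ProtocolPlan",
    "Task",
    "CampaignManifest",
    "PlanTotals",
    "build_manifest",
    "plan_totals",
    "ResultStore",
    "execute",
    "SurrogateTaskRunner",
]

#: The 26 mapping-window θ values of the default schedule.  θ = 0.5 is
#: deliberately absent: frames there come from the preceding MD stream,
#: which is run at the midpoint mapping potential.  Spacing is finer near
#: the endpoints and around the transition-state region.
DEFAULT_THETAS = (
    0.0, 0.05, 0.075, 0.1, 0.125, 0.15, 0.2, 0.25, 0.30, 0.35, 0.40,
    0.425, 0.45, 0.55, 0.575, 0.6, 0.65, 0.70, 0.75, 0.80, 0.85, 0.875,
    0.90, 0.925, 0.95, 1.0,
)


def default_schedule() -> MappingSchedule:
    """26 windows of 20 ps with the θ = 0.5 MD stream spliced in."""
    return MappingSchedule(
        thetas=DEFAULT_THETAS, window_length=20.0, includes_md_window=True
    )


@dataclass(frozen=True)
class ProtocolPlan:
    """Replica/snapshot/window arithmetic plus carried MD metadata.

    The heating schedule, restraint scheme, thermostat coupling and time
    step are plan *metadata*: they are passed through to external-engine
    manifests verbatim and never interpreted here.
    """

    n_replicas: int = 4
    md_length_ns: float = 8.0
    snapshot_interval_ns: float = 1.0
    discard_initial_ns: float = 2.0
    schedule: MappingSchedule = field(default_factory=default_schedule)
    md_theta: float = 0.5
    master_seed: int = 0
    heating: tuple = (0.01, 300.0, 90.0)  # (start K, end K, duration ps)
    restraint_scheme: dict = field(default_factory=lambda: {
        "mobile": 0.0, "boundary": 10.0, "frozen": 200.0,
    })
    thermostat: str = "berendsen(100fs)"
    time_step_fs: float = 1.0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise InvalidPlanError("n_replicas must be >= 1")
        if not (0 <= self.discard_initial_ns < self.md_length_ns):
            raise InvalidPlanError(
                "discard_initial_ns must lie in [0, md_length_ns)"
            )
        span = self.md_length_ns - self.discard_initial_ns
        ratio = span / self.snapshot_interval_ns
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidPlanError(
                "snapshot_interval_ns must divide md_length_ns - "
                "discard_initial_ns"
            )

    def snapshot_times_ns(self) -> List[float]:
        """Snapshot times: end of each interval, equilibration discarded."""
        times = []
        t = self.snapshot_interval_ns
        while t <= self.md_length_ns + 1e-9:
            if t > self.discard_initial_ns + 1e-9:
                times.append(round(t, 9))
            t += self.snapshot_interval_ns
        return times

    @property
    def snapshots_per_replica(self) -> int:
        return len(self.snapshot_times_ns())


class Task(NamedTuple):
    variant: str  # canonical label
    replica: int  # 1-based
    snapshot: int  # 1-based index into the kept snapshots
    snapshot_time_ns: float
    seed: int

    @property
    def key(self) -> str:
        return f"{self.variant}/r{self.replica}/s{self.snapshot}"


@dataclass(frozen=True)
class CampaignManifest:
    tasks: tuple
    plan: ProtocolPlan
    round_label: str = "round1"

    @property
    def variants(self) -> List[str]:
        seen = dict.fromkeys(t.variant for t in self.tasks)
        return list(seen)


def build_manifest(
    variants: Sequence[Variant],
    plan: ProtocolPlan,
    round_label: str = "round1",
) -> CampaignManifest:
    """One task per (variant, replica, kept snapshot), seeds derived.

    Seeds are a pure function of (master seed, variant label, replica,
    snapshot): rebuilding the manifest reproduces them exactly.
    """
    times = plan.snapshot_times_ns()
    tasks = []
    for v in variants:
        label = v.label if isinstance(v, Variant) else str(v)
        for rep in range(1, plan.n_replicas + 1):
            for snap, t in enumerate(times, start=1):
                tasks.append(Task(
                    variant=label, replica=rep, snapshot=snap,
                    snapshot_time_ns=t,
                    seed=derive_seed(plan.master_seed, label, rep, snap),
                ))
    return CampaignManifest(tasks=tuple(tasks), plan=plan,
                            round_label=round_label)


class PlanTotals(NamedTuple):
    per_run_ps: float  # EVB simulation length of one task
    per_system_ns: float  # EVB time per variant over all its tasks
    task_count: int


def plan_totals(manifest: CampaignManifest) -> PlanTotals:
    """Aggregate EVB simulation-time bookkeeping for a manifest."""
    plan = manifest.plan
    per_run = plan.schedule.window_length * plan.schedule.n_windows
    tasks_per_variant = plan.n_replicas * plan.snapshots_per_replica
    n = len(manifest.tasks)
    if n == 0:
        return PlanTotals(0.0, 0.0, 0)
    return PlanTotals(
        per_run_ps=per_run,
        per_system_ns=per_run * tasks_per_variant / 1000.0,
        task_count=n,
    )


# ---------------------------------------------------------------------------
# result store and executor


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent),
                               prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _dumps(record: dict) -> str:
    return json.dumps(record, sort_keys=True, ensure_ascii=True)


class ResultStore:
    """JSON-lines result store with atomic write-rename updates.

    ``results.jsonl`` always holds the completed tasks' records in
    canonical manifest order, so its bytes depend only on which tasks have
    completed — never on completion order or interruptions.
    """

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.results_path = self.dir / "results.jsonl"
        self.manifest_path = self.dir / "manifest.jsonl"
        self.status_path = self.dir / "status.json"

    def write_manifest(self, manifest: CampaignManifest) -> None:
        lines = [_dumps(t._asdict()) for t in manifest.tasks]
        _atomic_write(self.manifest_path, "".join(l + "\n" for l in lines))

    def load_results(self) -> Dict[str, dict]:
        if not self.results_path.exists():
            return {}
        out = {}
        with open(self.results_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rec = json.loads(line)
                    key = f"{rec['variant']}/r{rec['replica']}/s{rec['snapshot']}"
                    out[key] = rec
        return out

    def persist(self, manifest: CampaignManifest,
                results: Dict[str, dict]) -> None:
        ordered = [results[t.key] for t in manifest.tasks
                   if t.key in results]
        _atomic_write(self.results_path,
                      "".join(_dumps(r) + "\n" for r in ordered))
        status = {t.key: results.get(t.key, {}).get("status", "pending")
                  for t in manifest.tasks}
        _atomic_write(self.status_path, _dumps(status) + "\n")


def execute(
    manifest: CampaignManifest,
    runner: Callable[[Task], dict],
    store: ResultStore,
    workers: int = 1,
) -> Dict[str, dict]:
    """Run every pending task of the manifest through ``runner``.

    ``runner(task)`` returns a result record (dict); it may raise — the
    task is then recorded as failed with the error message and the
    campaign continues.  At most ``workers`` tasks run concurrently.
    Completion is persisted after every task, and tasks already present in
    the store are skipped, so killing and re-invoking this function yields
    the same final store as an uninterrupted run.
    """
    store.write_manifest(manifest)
    results = store.load_results()
    pending = [t for t in manifest.tasks if t.key not in results]

    def run_one(task: Task) -> dict:
        try:
            rec = runner(task)
            rec.setdefault("status", "done")
        except (KeyboardInterrupt, SystemExit):
            raise
        except Exception as exc:  # noqa: BLE001 - isolation contract
            rec = {
                "variant": task.variant, "replica": task.replica,
                "snapshot": task.snapshot, "seed": task.seed,
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
            }
        return rec

    if workers <= 1:
        for task in pending:
            results[task.key] = run_one(task)
            store.persist(manifest, results)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = {pool.submit(run_one, t): t for t in pending}
            not_done = set(futures)
            while not_done:
                done, not_done = wait(not_done,
                                      return_when=FIRST_COMPLETED)
                for fut in done:
                    results[futures[fut].key] = fut.result()
                store.persist(manifest, results)
    return results


@dataclass
class SurrogateTaskRunner:
    """Task-execution contract backed by the built-in surrogate sampler.

    Builds the variant's surrogate model through the effect model, runs
    the full window protocol with the task seed, and analyzes it with the
    FEP/US pipeline.  A profile without a barrier yields a ``no_barrier``
    record (data, not a failure).
    """

    base_model: "SurrogateModel"
    effects: "EffectModel"
    params: EVBParameters
    schedule: MappingSchedule = field(default_factory=default_schedule)
    n_steps_per_window: int = 4000
    bins: int = 50
    min_count: int = 10
    min_frames: int = 50

    def __call__(self, task: Task) -> dict:
        from .fepus import analyze_frames
        from .surrogate import run_evb_protocol, variant_model
        from .variants import parse_variant

        model = variant_model(self.base_model, parse_variant(task.variant),
                              self.effects)
        frames = run_evb_protocol(model, self.schedule, self.params,
                                  self.n_steps_per_window, task.seed)
        base = {
            "variant": task.variant, "replica": task.replica,
            "snapshot": task.snapshot, "seed": task.seed,
        }
        try:
            result, _ = analyze_frames(
                frames, self.params, self.schedule,
                bins=self.bins, min_count=self.min_count,
                min_frames=self.min_frames,
            )
        except NoBarrierError:
            base.update({"no_barrier": True, "status": "done",
                         "n_frames": int(len(frames))})
            return base
        base.update({k: round(v, 6) if isinstance(v, float) else v
                     for k, v in result.as_dict().items()})
        base["status"] = "done"
        return base
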