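"""Workflow orchestration: configuration, task graph, backends, report.

The full workflow — quality trimming, pair merging, ribosomal screening,
binning, per-bin export and the final report — is expressed as a
dependency-driven task graph.  Two backends execute it: ``serial`` and
``parallel`` (a local thread pool).  The determinism contract is that both
backends produce byte-identical artifacts; distribution changes wall-clock
time, never results.  After the binning task completes it fans out one
task per reported bin (original-read FASTA export, degree histogram,
ready-to-run assembler command emission), and the report task aggregates
per-stage counts, the bin table and — when a truth table is supplied —
ground-truth scores into TSVs and one HTML page.

Configuration is a flat ``key = value`` text file; the minimum viable
configuration names the input file, its format and the output directory,
with everything else defaulted (first binning pass at b = 70 bp, schedule
70/50/30, Q30/60 bp trimming).  Unknown keys are rejected outright.

Re-execution is restart-safe: a task whose outputs already exist and are
newer than its inputs is skipped and its recorded counts are reloaded.
"""

from __future__ import annotations

import html
import json
import sys
import threading
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

from .binning import (
    BinningParams,
    BinSet,
    block_binning,
    write_bin_members,
    write_bin_table,
    write_degree_histogram,
)
from .errors import ConfigurationError, ContractError, OvbinError
from .evaluation import evaluate_bins, write_bin_scores, write_genome_scores
from .pair_prep import (
    MergedRead,
    MergeParams,
    pair_up,
    prepare_binning_input,
    restore_original,
    write_provenance,
)
from .rrna_screen import (
    ScreenParams,
    build_reference_index,
    partition_rrna,
    write_partition,
)
from .sequence_io import Read, TrimParams, read_sequences, trim_reads, write_sequences
from .synthetic_community import TruthTable

_MANDATORY_KEYS = ("input_path", "input_format", "output_dir")
_VALID_KEYS = {
    "input_path": str,
    "input_format": str,
    "output_dir": str,
    "reference_path": str,
    "truth_path": str,
    "trim": bool,
    "merge_pairs": bool,
    "rrna_screen": bool,
    "evaluate": bool,
    "assemble": bool,
    "min_quality": int,
    "min_length": int,
    "min_overlap": int,
    "max_mismatch_rate": float,
    "seed_k": int,
    "min_identity": float,
    "min_aligned": int,
    "b_schedule": "int_list",
    "max_mismatches": int,
    "min_bin_size": int,
    "mad_cutoff": float,
    "block_size": int,
    "workers": int,
    "seed": int,
}


@dataclass
class PipelineConfig:
    """Validated configuration for one workflow run."""

    input_path: str
    input_format: str
    output_dir: str
    reference_path: str | None = None
    truth_path: str | None = None
    do_trim: bool = True
    do_merge_pairs: bool = True
    do_rrna_screen: bool | None = None  # None: auto (on iff reference given)
    do_evaluate: bool | None = None  # None: auto (on iff truth given)
    do_assemble: bool = False
    trim: TrimParams = field(default_factory=TrimParams)
    merge: MergeParams = field(default_factory=MergeParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    binning: BinningParams = field(default_factory=BinningParams)
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_format not in ("fasta", "fastq"):
            raise ConfigurationError(
                f"input_format must be fasta or fastq, got {self.input_format!r}"
            )
        if self.do_rrna_screen and not self.reference_path:
            raise ConfigurationError(
                "rrna_screen enabled but no reference_path configured"
            )
        if self.do_evaluate and not self.truth_path:
            raise ConfigurationError("evaluate enabled but no truth_path configured")

    @property
    def screen_enabled(self) -> bool:
        if self.do_rrna_screen is None:
            return self.reference_path is not None
        return self.do_rrna_screen

    @property
    def evaluate_enabled(self) -> bool:
        if self.do_evaluate is None:
            return self.truth_path is not None
        return self.do_evaluate


def _parse_value(key: str, raw: str):
    kind = _VALID_KEYS[key]
    if kind is str:
        return raw
    if kind is bool:
        low = raw.lower()
        if low in ("true", "yes", "1", "on"):
            return True
        if low in ("false", "no", "0", "off"):
            return False
        raise ConfigurationError(f"key {key!r}: expected a boolean, got {raw!r}")
    if kind is int:
        return int(raw)
    if kind is float:
        return float(raw)
    if kind == "int_list":
        return tuple(int(tok) for tok in raw.replace(",", " ").split())
    raise AssertionError(kind)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file.

    Lines starting with ``#`` and blank lines are ignored.  Missing
    mandatory keys and unknown keys are configuration errors.
    """
    values: dict[str, object] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in _VALID_KEYS:
                raise ConfigurationError(
                    f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                    + ", ".join(sorted(_VALID_KEYS))
                )
            values[key] = _parse_value(key, raw)
    for key in _MANDATORY_KEYS:
        if key not in values:
            raise ConfigurationError(f"{path}: missing mandatory key {key!r}")
    return config_from_values(values)


def config_from_values(values: dict) -> PipelineConfig:
    trim = TrimParams(
        min_quality=int(values.get("min_quality", 30)),
        min_length=int(values.get("min_length", 60)),
    )
    merge = MergeParams(
        min_overlap=int(values.get("min_overlap", 10)),
        max_mismatch_rate=float(values.get("max_mismatch_rate", 0.1)),
    )
    screen = ScreenParams(
        seed_k=int(values.get("seed_k", 21)),
        min_identity=float(values.get("min_identity", 0.9)),
        min_aligned=int(values.get("min_aligned", 50)),
    )
    schedule = tuple(values.get("b_schedule", (70, 50, 30)))
    binning = BinningParams(
        b=schedule[0] if schedule else 70,
        b_schedule=schedule,
        max_mismatches=int(values.get("max_mismatches", 0)),
        min_bin_size=int(values.get("min_bin_size", 2000)),
        mad_cutoff=float(values.get("mad_cutoff", 3.0)),
        block_size=int(values.get("block_size", 20_000_000)),
    )
    return PipelineConfig(
        input_path=str(values["input_path"]),
        input_format=str(values["input_format"]),
        output_dir=str(values["output_dir"]),
        reference_path=values.get("reference_path"),
        truth_path=values.get("truth_path"),
        do_trim=bool(values.get("trim", True)),
        do_merge_pairs=bool(values.get("merge_pairs", True)),
        do_rrna_screen=values.get("rrna_screen"),
        do_evaluate=values.get("evaluate"),
        do_assemble=bool(values.get("assemble", False)),
        trim=trim,
        merge=merge,
        screen=screen,
        binning=binning,
        workers=int(values.get("workers", 1)),
        seed=int(values.get("seed", 0)),
    )


@dataclass
class Task:
    name: str
    fn: Callable[["RunContext"], dict]
    deps: tuple[str, ...] = ()
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    #: rehydrates the task's in-memory products from its artifacts when the
    #: task is skipped as up to date
    restore: Callable[["RunContext"], None] | None = None


class TaskGraph:
    """A small DAG of named tasks with artifact dependencies."""

    def __init__(self) -> None:
        self.tasks: dict[str, Task] = {}
        self._lock = threading.Lock()

    def add_task(self, task: Task) -> None:
        with self._lock:
            if task.name in self.tasks:
                raise ContractError(f"duplicate task name {task.name!r}")
            for dep in task.deps:
                if dep not in self.tasks:
                    raise ContractError(
                        f"task {task.name!r} depends on unknown task {dep!r}"
                    )
            self.tasks[task.name] = task
        self._check_acyclic()

    def add_dependency(self, name: str, dep: str) -> None:
        with self._lock:
            task = self.tasks[name]
            if dep not in task.deps:
                self.tasks[name] = replace(task, deps=task.deps + (dep,))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: dict[str, int] = {}

        def visit(name: str) -> None:
            state = seen.get(name, 0)
            if state == 1:
                raise ContractError(f"task graph contains a cycle through {name!r}")
            if state == 2:
                return
            seen[name] = 1
            for dep in self.tasks[name].deps:
                visit(dep)
            seen[name] = 2

        for name in list(self.tasks):
            visit(name)


@dataclass
class RunManifest:
    """Machine-readable record of one run: statuses, counts, artifacts.

    Deliberately contains no timestamps so that identical runs serialize to
    identical bytes.
    """

    task_status: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s in ("done", "skipped") for s in self.task_status.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "task_status": self.task_status,
                "counts": self.counts,
                "artifacts": self.artifacts,
                "errors": self.errors,
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            task_status=data.get("task_status", {}),
            counts=data.get("counts", {}),
            artifacts=data.get("artifacts", {}),
            errors=data.get("errors", {}),
        )


class RunContext:
    """Shared state passed to task functions during one execution."""

    def __init__(self, config: PipelineConfig, graph: TaskGraph) -> None:
        self.config = config
        self.graph = graph
        self.out = Path(config.output_dir)
        self.data: dict[str, object] = {}
        self._lock = threading.Lock()

    def path(self, *parts: str) -> Path:
        return self.out.joinpath(*parts)


# ---------------------------------------------------------------- stages


def _restore_trim(ctx: RunContext) -> None:
    cfg = ctx.config
    ctx.data["kept_reads"] = read_sequences(
        ctx.path(f"trimmed.{cfg.input_format}"), cfg.input_format
    )


def _restore_merge(ctx: RunContext) -> None:
    from .pair_prep import read_provenance

    provenance = read_provenance(ctx.path("provenance.tsv"))
    merged = [
        MergedRead(
            merged_id=r.read_id,
            sequence=r.sequence,
            source_ids=provenance[r.read_id],
        )
        for r in read_sequences(ctx.path("merged.fasta"), "fasta")
    ]
    ctx.data["merged_reads"] = merged
    ctx.data["provenance"] = provenance


def _restore_screen(ctx: RunContext) -> None:
    provenance = ctx.data["provenance"]
    ctx.data["binning_input"] = [
        MergedRead(
            merged_id=r.read_id,
            sequence=r.sequence,
            source_ids=provenance[r.read_id],  # type: ignore[index]
        )
        for r in read_sequences(ctx.path("passthrough.fasta"), "fasta")
    ]


def _restore_binning(ctx: RunContext) -> None:
    from .binning import Bin, mad

    members: dict[int, list[str]] = {}
    leftover: list[str] = []
    with open(ctx.path("bin_members.tsv")) as fh:
        next(fh, None)
        for line in fh:
            bin_id, rid = line.rstrip("\n").split("\t")
            if int(bin_id) < 0:
                leftover.append(rid)
            else:
                members.setdefault(int(bin_id), []).append(rid)
    bins = []
    for bin_id in sorted(members):
        histogram: dict[int, int] = {}
        hist_path = ctx.path(f"bin_{bin_id:04d}.histogram.tsv")
        if hist_path.exists():
            with open(hist_path) as fh:
                next(fh, None)
                for line in fh:
                    degree, count = line.split("\t")
                    histogram[int(degree)] = int(count)
        sample = [d for d, c in histogram.items() for _ in range(c)] or [0]
        bins.append(
            Bin(
                bin_id=bin_id,
                read_ids=tuple(members[bin_id]),
                b_used=0,
                degree_histogram=histogram,
                spread=mad(sample),
            )
        )
    binset = BinSet(bins=bins, leftover_ids=tuple(leftover))
    ctx.data["binset"] = binset
    _emit_bin_tasks(ctx, binset)


def _task_trim(ctx: RunContext) -> dict:
    cfg = ctx.config
    reads = read_sequences(cfg.input_path, cfg.input_format)
    record: dict = {"reads_in": len(reads)}
    if cfg.do_trim and cfg.input_format == "fastq":
        kept, stats = trim_reads(reads, cfg.trim)
        record["bases_trimmed"] = stats.trimmed_bases
        record["reads_dropped"] = stats.dropped
    else:
        kept = reads
        record["bases_trimmed"] = 0
        record["reads_dropped"] = 0
    record["reads_kept"] = len(kept)
    out = ctx.path(f"trimmed.{cfg.input_format}")
    write_sequences(kept, out, cfg.input_format)
    ctx.data["kept_reads"] = kept
    return record


def _task_merge(ctx: RunContext) -> dict:
    cfg = ctx.config
    kept: list[Read] = ctx.data["kept_reads"]  # type: ignore[assignment]
    if cfg.do_merge_pairs:
        pairs, singles = pair_up(kept)
    else:
        pairs, singles = [], list(kept)
    merged, provenance = prepare_binning_input(pairs, singles, cfg.merge)
    write_sequences(merged, ctx.path("merged.fasta"), "fasta")
    write_provenance(provenance, ctx.path("provenance.tsv"))
    ctx.data["merged_reads"] = merged
    ctx.data["provenance"] = provenance
    return {
        "pairs": len(pairs),
        "singles": len(singles),
        "merged_total": len(merged),
        "forced_merges": sum(1 for m in merged if m.forced),
    }


def _task_screen(ctx: RunContext) -> dict:
    cfg = ctx.config
    merged: list[MergedRead] = ctx.data["merged_reads"]  # type: ignore[assignment]
    index = build_reference_index(cfg.reference_path, cfg.screen.seed_k)
    partition = partition_rrna(merged, index, cfg.screen)
    write_partition(
        merged,
        partition,
        ctx.path("ribosomal.fasta"),
        ctx.path("passthrough.fasta"),
        ctx.path("rrna_classes.tsv"),
    )
    flagged = set(partition.ribosomal_ids)
    ctx.data["binning_input"] = [m for m in merged if m.merged_id not in flagged]
    return {
        "ribosomal": len(partition.ribosomal_ids),
        "passthrough": len(partition.passthrough_ids),
    }


def _emit_bin_tasks(ctx: RunContext, binset: BinSet) -> None:
    for bn in binset.bins:
        name = f"bin_{bn.bin_id:04d}"
        ctx.graph.add_task(
            Task(
                name=name,
                fn=_make_bin_task(bn),
                deps=("binning",),
                inputs=(str(ctx.path("bin_members.tsv")),),
                outputs=(
                    str(ctx.path(f"{name}.reads.fasta")),
                    str(ctx.path(f"{name}.histogram.tsv")),
                ),
            )
        )
        ctx.graph.add_dependency("report", name)


def _make_bin_task(bn) -> Callable[[RunContext], dict]:
    def run(ctx: RunContext) -> dict:
        cfg = ctx.config
        provenance = ctx.data["provenance"]
        kept: list[Read] = ctx.data["kept_reads"]  # type: ignore[assignment]
        by_id = {r.read_id: r for r in kept}
        original_ids = restore_original(bn.read_ids, provenance)  # type: ignore[arg-type]
        name = f"bin_{bn.bin_id:04d}"
        fasta = ctx.path(f"{name}.reads.fasta")
        write_sequences([by_id[r] for r in original_ids], fasta, "fasta")
        write_degree_histogram(bn, ctx.path(f"{name}.histogram.tsv"))
        # adapter: emit a ready-to-run assembler command instead of invoking one
        ctx.path(f"{name}.assemble.sh").write_text(
            f"spades.py -s {fasta} -o {ctx.path(name + '.assembly')}\n"
        )
        if cfg.do_assemble:
            contigs = assemble_greedy([by_id[r] for r in original_ids])
            with open(ctx.path(f"{name}.contigs.fasta"), "w") as out:
                for i, seq in enumerate(contigs):
                    out.write(f">{name}_contig_{i:04d}\n{seq}\n")
        return {f"{name}_original_reads": len(original_ids)}

    return run


def _task_binning(ctx: RunContext) -> dict:
    cfg = ctx.config
    if "binning_input" not in ctx.data:
        ctx.data["binning_input"] = ctx.data["merged_reads"]
    reads = ctx.data["binning_input"]
    binset = block_binning(reads, cfg.binning)  # type: ignore[arg-type]
    ctx.data["binset"] = binset
    write_bin_table(binset, ctx.path("bin_table.tsv"))
    write_bin_members(binset, ctx.path("bin_members.tsv"))
    _emit_bin_tasks(ctx, binset)
    return {
        "n_bins": len(binset.bins),
        "binned": sum(b.size for b in binset.bins),
        "leftover": len(binset.leftover_ids),
    }


def _task_report(ctx: RunContext) -> dict:
    cfg = ctx.config
    binset: BinSet = ctx.data.get("binset", BinSet([], ()))  # type: ignore[assignment]
    record: dict = {}
    scores = None
    if cfg.evaluate_enabled:
        truth = TruthTable.load(cfg.truth_path)
        scores = evaluate_bins(binset, truth, ctx.data.get("provenance"))  # type: ignore[arg-type]
        write_bin_scores(scores[0], ctx.path("bin_scores.tsv"))
        write_genome_scores(scores[1], ctx.path("genome_scores.tsv"))
        record["n_scored_bins"] = len(scores[0])
    ctx.data["scores"] = scores
    return record


def build_task_graph(config: PipelineConfig) -> TaskGraph:
    """Assemble the upstream chain; per-bin fan-out is added by the binning
    task once the bins are known."""
    out = Path(config.output_dir)
    trimmed = str(out / f"trimmed.{config.input_format}")
    merged = str(out / "merged.fasta")
    graph = TaskGraph()
    graph.add_task(
        Task(
            "trim", _task_trim,
            inputs=(config.input_path,), outputs=(trimmed,), restore=_restore_trim,
        )
    )
    graph.add_task(
        Task(
            "merge", _task_merge, deps=("trim",),
            inputs=(trimmed,),
            outputs=(merged, str(out / "provenance.tsv")),
            restore=_restore_merge,
        )
    )
    upstream, upstream_out = "merge", merged
    if config.screen_enabled:
        graph.add_task(
            Task(
                "screen", _task_screen, deps=("merge",),
                inputs=(merged, str(config.reference_path)),
                outputs=(
                    str(out / "ribosomal.fasta"),
                    str(out / "passthrough.fasta"),
                    str(out / "rrna_classes.tsv"),
                ),
                restore=_restore_screen,
            )
        )
        upstream, upstream_out = "screen", str(out / "passthrough.fasta")
    graph.add_task(
        Task(
            "binning", _task_binning, deps=(upstream,),
            inputs=(upstream_out,),
            outputs=(str(out / "bin_table.tsv"), str(out / "bin_members.tsv")),
            restore=_restore_binning,
        )
    )
    graph.add_task(Task("report", _task_report, deps=("binning",)))
    return graph


# ---------------------------------------------------------------- executor


def _is_fresh(task: Task) -> bool:
    if not task.outputs:
        return False
    outs = [Path(p) for p in task.outputs]
    if not all(p.exists() for p in outs):
        return False
    ins = [Path(p) for p in task.inputs if Path(p).exists()]
    newest_in = max((p.stat().st_mtime for p in ins), default=0.0)
    oldest_out = min(p.stat().st_mtime for p in outs)
    return oldest_out >= newest_in


def execute(
    graph: TaskGraph,
    config: PipelineConfig,
    backend: str = "serial",
    workers: int | None = None,
    allow_skip: bool = False,
) -> RunManifest:
    """Run the task graph to completion (or first failure) and return the
    manifest.

    ``backend`` is ``"serial"`` or ``"parallel"``; the parallel backend uses
    a local thread pool of ``workers`` slots.  Outputs are byte-identical
    between backends.  A failing task marks all transitive dependents as
    ``not_run``.  With ``allow_skip``, tasks whose outputs are fresh are not
    re-executed (their recorded counts are reloaded).
    """
    if backend not in ("serial", "parallel"):
        raise ConfigurationError(f"unknown backend {backend!r}")
    n_workers = workers if workers is not None else config.workers
    ctx = RunContext(config, graph)
    ctx.out.mkdir(parents=True, exist_ok=True)
    tasks_dir = ctx.path("tasks")
    tasks_dir.mkdir(exist_ok=True)
    manifest = RunManifest()
    status: dict[str, str] = {}
    log_lines: list[str] = []

    def snapshot() -> dict[str, Task]:
        with graph._lock:
            return dict(graph.tasks)

    def runnable() -> list[str]:
        return sorted(
            name
            for name, task in snapshot().items()
            if name not in status
            and all(status.get(d) in ("done", "skipped") for d in task.deps)
        )

    def blocked() -> list[str]:
        return [
            name
            for name, task in snapshot().items()
            if name not in status
            and any(status.get(d) in ("failed", "not_run") for d in task.deps)
        ]

    def run_task(name: str) -> tuple[str, str, dict | None, str | None]:
        task = graph.tasks[name]
        sidecar = tasks_dir / f"{name}.json"
        if allow_skip and sidecar.exists() and _is_fresh(task):
            try:
                if task.restore is not None:
                    task.restore(ctx)
            except Exception as exc:  # noqa: BLE001 - fall through to re-run
                pass
            else:
                return name, "skipped", json.loads(sidecar.read_text()), None
        try:
            record = task.fn(ctx)
        except Exception as exc:  # noqa: BLE001 - reported in the manifest
            return name, "failed", None, f"{type(exc).__name__}: {exc}"
        sidecar.write_text(json.dumps(record, sort_keys=True) + "\n")
        return name, "done", record, None

    def settle(name: str, state: str, record: dict | None, error: str | None) -> None:
        status[name] = state
        line = f"task={name} status={state} counts={json.dumps(record or {}, sort_keys=True)}"
        print(line, file=sys.stderr)
        log_lines.append(line)
        if record:
            manifest.counts.update(record)
        if error:
            manifest.errors[name] = error

    if backend == "serial":
        while True:
            ready = runnable()
            for name in blocked():
                settle(name, "not_run", None, None)
            ready = runnable()
            if not ready:
                break
            settle(*run_task(ready[0]))
    else:
        with ThreadPoolExecutor(max_workers=max(1, n_workers)) as pool:
            futures = {}
            while True:
                for name in blocked():
                    settle(name, "not_run", None, None)
                for name in runnable():
                    if name not in futures:
                        futures[name] = pool.submit(run_task, name)
                pending = [f for n, f in futures.items() if n not in status]
                if not pending:
                    if not runnable():
                        break
                    continue
                done, _ = wait(pending, return_when=FIRST_COMPLETED)
                for fut in done:
                    settle(*fut.result())

    for name in snapshot():
        if name not in status:
            settle(name, "not_run", None, None)
    manifest.task_status = dict(sorted(status.items()))
    # log file sorted by task name: byte-identical across backends
    log_lines.sort()
    for p in sorted(ctx.out.iterdir()):
        if p.is_file():
            manifest.artifacts[p.name] = str(p)
    manifest.save(ctx.path("manifest.json"))
    ctx.path("run.log").write_text("\n".join(log_lines) + "\n")
    if manifest.ok:
        write_report(manifest, ctx.data.get("scores"), ctx.out)
    return manifest


def run_pipeline(
    config: PipelineConfig,
    backend: str = "serial",
    workers: int | None = None,
    allow_skip: bool = False,
) -> RunManifest:
    """Convenience wrapper: build the task graph and execute it."""
    graph = build_task_graph(config)
    return execute(graph, config, backend=backend, workers=workers, allow_skip=allow_skip)


# ---------------------------------------------------------------- reporting


def _html_table(headers: Sequence[str], rows: Sequence[Sequence]) -> str:
    head = "".join(f"<th>{html.escape(str(h))}</th>" for h in headers)
    body = "\n".join(
        "<tr>" + "".join(f"<td>{html.escape(str(c))}</td>" for c in row) + "</tr>"
        for row in rows
    )
    return f"<table>\n<tr>{head}</tr>\n{body}\n</table>"


def write_report(manifest: RunManifest, scores, output_dir: str | Path) -> Path:
    """Write the per-stage counts TSV and the HTML summary.

    Regenerating the report from the same manifest produces byte-identical
    files (no timestamps, stable ordering).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "stage_counts.tsv", "w") as fh:
        fh.write("stat\tvalue\n")
        for key in sorted(manifest.counts):
            fh.write(f"{key}\t{manifest.counts[key]}\n")

    count_rows = [(k, manifest.counts[k]) for k in sorted(manifest.counts)]
    status_rows = [(k, v) for k, v in sorted(manifest.task_status.items())]
    sections = [
        "<h1>ovbin run report</h1>",
        "<h2>Stage counts</h2>",
        _html_table(["stat", "value"], count_rows),
        "<h2>Tasks</h2>",
        _html_table(["task", "status"], status_rows),
    ]
    bin_table = out / "bin_table.tsv"
    if bin_table.exists():
        rows = [line.split("\t") for line in bin_table.read_text().splitlines()]
        if rows:
            sections += ["<h2>Bins</h2>", _html_table(rows[0], rows[1:])]
    if scores is not None:
        bin_scores, genome_scores = scores
        sections += [
            "<h2>Bin scores</h2>",
            _html_table(
                ["bin_id", "dominant_genome", "purity", "n_reads"],
                [
                    (s.bin_id, s.dominant_genome, f"{s.purity:.4f}", s.n_reads)
                    for s in bin_scores
                ],
            ),
            "<h2>Genome scores</h2>",
            _html_table(
                ["genome", "completeness", "best_bin_id"],
                [
                    (s.genome, f"{s.completeness:.4f}", s.best_bin_id)
                    for s in genome_scores
                ],
            ),
        ]
    if manifest.errors:
        sections += [
            "<h2>Errors</h2>",
            _html_table(["task", "error"], sorted(manifest.errors.items())),
        ]
    page = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>ovbin report</title></head><body>\n"
        + "\n".join(sections)
        + "\n</body></html>\n"
    )
    path = out / "report.html"
    path.write_text(page)
    return path


def assemble_greedy(reads: Sequence[Read], min_overlap: int = 30) -> list[str]:
    """Tiny greedy overlap-consensus assembler for end-to-end tests.

    Repeatedly extends a seed read with the unused read whose prefix best
    matches the current contig's suffix.  Not a production assembler: it
    exists so that pipeline tests can produce contigs without external
    tools.
    """
    sequences = sorted({r.sequence for r in reads})
    unused = set(range(len(sequences)))
    contigs: list[str] = []
    while unused:
        seed = min(unused)
        unused.discard(seed)
        contig = sequences[seed]
        grew = True
        while grew:
            grew = False
            best: tuple[int, int] | None = None
            for idx in sorted(unused):
                seq = sequences[idx]
                max_o = min(len(contig), len(seq))
                for olap in range(max_o, min_overlap - 1, -1):
                    if contig.endswith(seq[:olap]):
                        if best is None or olap > best[0]:
                            best = (olap, idx)
                        break
            if best is not None:
                olap, idx = best
                contig += sequences[idx][olap:]
                unused.discard(idx)
                grew = True
        contigs.append(contig)
    return contigs
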