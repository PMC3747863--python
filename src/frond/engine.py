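"""Lazy, cached, provenance-tracked execution of an LGL pipeline.

A :class:`Protocol` binds each node of a DAG to a host function of the same
name (a node with N incoming edges binds to an N-argument function, called
with its parents' outputs in edge-creation order) and executes nodes on
demand:

* ``provide(label)`` builds only the uncached ancestors of the requested
  node, returning a RAM-cached or disk-dumped value where one exists;
* every freshly produced resource is kept in RAM and, when dumping is on,
  pickled under the project directory, so a later session reopens with all
  states ``dumped`` and re-executes nothing;
* the source text of the function that produced each resource is hashed
  into the resource record; a changed fingerprint invalidates the node and,
  through :meth:`Protocol.detect_code_changes`, its whole descendant
  closure — unless the user ``trust``s the existing resource;
* nodes flagged ``F`` return the name(s) of file(s) they wrote; the files'
  modification timestamps are recorded and any later mismatch makes the
  resource stale;
* independent ready nodes run concurrently in topological waves, with
  results identical to sequential execution.

Project directory layout (stable): ``metadata.json`` with one record per
node, ``resources/<uid>.blob`` pickled values, ``srcdb/<uid>.txt`` source
snapshots.  Timestamps are ISO-8601, digests hex SHA-256.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.util
import inspect
import json
import os
import pickle
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from types import ModuleType
from typing import Any, Callable, Mapping

from . import graphs
from .graphs import Graph, Registry, compile_lgl

__all__ = [
    "ProjectSpec",
    "Protocol",
    "ResourceRecord",
    "MetadataStore",
    "FileReport",
    "EngineError",
    "BindingError",
    "CyclicGraphError",
    "UnknownNodeError",
    "NoResourceError",
    "FileResourceError",
    "bind",
    "STATE_AVAILABLE",
    "STATE_DUMPED",
    "STATE_TO_BE_BUILT",
    "STATE_UNAVAILABLE",
]

STATE_AVAILABLE = "available"
STATE_DUMPED = "dumped"
STATE_TO_BE_BUILT = "to be built"
STATE_UNAVAILABLE = "unavailable"


class EngineError(Exception):
    """Base class for pipeline execution errors."""


class BindingError(EngineError):
    """A node could not be bound to a function (missing name or bad arity)."""


class CyclicGraphError(EngineError):
    """The pipeline graph contains a directed cycle."""


class UnknownNodeError(EngineError):
    """A label that names no pipeline node."""


class NoResourceError(EngineError):
    """The operation needs a stored resource that does not exist."""


class FileResourceError(EngineError, TypeError):
    """An F-node returned something that is not a file name or list of them."""


@dataclass
class ProjectSpec:
    """What is needed to open a pipeline project.

    ``source`` locates the node implementations: a path to a ``.py`` file,
    an imported module, or a plain mapping of name → callable.  ``lgl`` is
    the pipeline text (all graphs in the program are unioned into one
    executable DAG, so both single-statement and edge-list styles work).
    """

    lgl: str
    source: str | Path | ModuleType | Mapping[str, Callable]
    project_dir: str | Path
    workers: int | None = None
    dumping: bool = True


@dataclass
class ResourceRecord:
    """Persistent provenance for one node's resource."""

    label: str
    fingerprint: str | None = None
    files: list = field(default_factory=list)  # [{path, mtime_ns, size}]
    cpu_time: float = 0.0
    wall_time: float = 0.0
    built_at: str | None = None  # ISO-8601

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "fingerprint": self.fingerprint,
            "files": self.files,
            "cpu_time": self.cpu_time,
            "wall_time": self.wall_time,
            "built_at": self.built_at,
        }

    @classmethod
    def from_json(cls, data: dict) -> "ResourceRecord":
        return cls(
            label=data["label"],
            fingerprint=data.get("fingerprint"),
            files=data.get("files", []),
            cpu_time=data.get("cpu_time", 0.0),
            wall_time=data.get("wall_time", 0.0),
            built_at=data.get("built_at"),
        )


@dataclass(frozen=True)
class FileReport:
    """Freshness report for an F-node's tracked files."""

    fresh: bool
    stale: tuple = ()  # (path, reason) pairs

    def __bool__(self) -> bool:
        return self.fresh


class MetadataStore:
    """On-disk store: one JSON metadata file plus one pickle blob per
    dumped resource.  A fresh :class:`Protocol` over the same project
    directory reconstructs every state without executing anything."""

    def __init__(self, project_dir: str | Path):
        self.root = Path(project_dir)
        self.resources = self.root / "resources"
        self.srcdb = self.root / "srcdb"
        self.meta_path = self.root / "metadata.json"
        for d in (self.root, self.resources, self.srcdb):
            d.mkdir(parents=True, exist_ok=True)
        self.records: dict[str, ResourceRecord] = {}
        self._lock = threading.Lock()
        self.load()

    def load(self) -> None:
        if self.meta_path.exists():
            data = json.loads(self.meta_path.read_text(encoding="utf-8"))
            self.records = {
                uid: ResourceRecord.from_json(rec)
                for uid, rec in data.get("records", {}).items()
            }

    def save(self) -> None:
        with self._lock:
            payload = {
                "records": {
                    uid: rec.to_json() for uid, rec in sorted(self.records.items())
                }
            }
            tmp = self.meta_path.with_suffix(".json.tmp")
            tmp.write_text(
                json.dumps(payload, indent=2) + "\n", encoding="utf-8"
            )
            tmp.replace(self.meta_path)

    # -- value blobs -------------------------------------------------------

    def blob_path(self, uid: str) -> Path:
        return self.resources / f"{uid}.blob"

    def has_blob(self, uid: str) -> bool:
        return self.blob_path(uid).exists()

    def write_blob(self, uid: str, value: Any) -> None:
        with open(self.blob_path(uid), "wb") as fh:
            pickle.dump(value, fh)

    def read_blob(self, uid: str) -> Any:
        with open(self.blob_path(uid), "rb") as fh:
            return pickle.load(fh)

    def drop_blob(self, uid: str) -> None:
        self.blob_path(uid).unlink(missing_ok=True)

    def write_source(self, uid: str, source: str) -> None:
        (self.srcdb / f"{uid}.txt").write_text(source, encoding="utf-8")

    def drop_record(self, uid: str) -> None:
        self.records.pop(uid, None)
        self.drop_blob(uid)
        (self.srcdb / f"{uid}.txt").unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# Binding
# ---------------------------------------------------------------------------


def fingerprint(func: Callable) -> str:
    """Hex digest of the function's extracted source text.  Raw text is
    hashed (comments and formatting included): a false invalidation is
    cheaper than a silently stale resource.  Falls back to bytecode when
    source is unavailable."""
    try:
        source = inspect.getsource(func)
    except (OSError, TypeError):
        code = func.__code__
        source = repr((code.co_code, code.co_consts, code.co_names))
    return hashlib.sha256(source.encode("utf-8")).hexdigest()


def _load_namespace(source) -> tuple[dict, Path | None, ModuleType | None]:
    if isinstance(source, Mapping):
        return dict(source), None, None
    if isinstance(source, ModuleType):
        return vars(source), None, source
    path = Path(source)
    spec = importlib.util.spec_from_file_location(
        f"_frond_nodes_{abs(hash(str(path.resolve())))}", path
    )
    if spec is None or spec.loader is None:
        raise BindingError(f"cannot import node source {path}")
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    return vars(module), path, module


def _arity_range(func: Callable) -> tuple[int, float]:
    """(min, max) positional argument counts; max is inf for *args."""
    sig = inspect.signature(func)
    lo, hi = 0, 0.0
    for p in sig.parameters.values():
        if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD):
            hi += 1
            if p.default is p.empty:
                lo += 1
        elif p.kind == p.VAR_POSITIONAL:
            return lo, float("inf")
    return lo, hi


class Protocol:
    """A bound, executable pipeline: DAG + function bindings + metadata.

    Normally obtained through :func:`bind`.
    """

    def __init__(
        self,
        graph: Graph,
        bindings: dict[str, Callable],
        store: MetadataStore,
        *,
        registry: Registry | None = None,
        source_path: Path | None = None,
        source_module: ModuleType | None = None,
        workers: int | None = None,
        dumping: bool = True,
    ):
        self.graph = graph
        self.registry = registry
        self.bindings = bindings  # uid -> callable
        self.store = store
        self.source_path = source_path
        self.source_module = source_module
        self.workers = workers or min(os.cpu_count() or 1, 8)
        self.dumping = dumping
        self.ram: dict[str, Any] = {}
        self.failed: set[str] = set()
        self.execution_counts: dict[str, int] = {
            n.label: 0 for n in graph.nodes.values()
        }
        self._by_label = {n.label: n.uid for n in graph.nodes.values()}
        self._parents: dict[str, list[str]] = {uid: [] for uid in graph.nodes}
        self._children: dict[str, list[str]] = {uid: [] for uid in graph.nodes}
        for s, d in graph.edges:  # edge creation order = argument order
            self._parents[d].append(s)
            self._children[s].append(d)
        self._ram_lock = threading.Lock()

    # -- small helpers -----------------------------------------------------

    def uid(self, label: str) -> str:
        try:
            return self._by_label[label]
        except KeyError:
            raise UnknownNodeError(f"no pipeline node named {label!r}") from None

    def label(self, uid: str) -> str:
        return self.graph.nodes[uid].label

    def labels(self) -> list[str]:
        return [n.label for n in self.graph.nodes.values()]

    def is_file_node(self, label: str) -> bool:
        return "F" in self.graph.nodes[self.uid(label)].flags

    def parents_of(self, label: str) -> list[str]:
        return [self.label(u) for u in self._parents[self.uid(label)]]

    def _descendants(self, uid: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self._children[uid])
        while stack:
            cur = stack.pop()
            if cur not in seen:
                seen.add(cur)
                stack.extend(self._children[cur])
        return seen

    def _topo_uids(self) -> list[str]:
        indeg = {u: len(ps) for u, ps in self._parents.items()}
        ready = [u for u in self.graph.nodes if indeg[u] == 0]
        order: list[str] = []
        while ready:
            u = ready.pop(0)
            order.append(u)
            for c in self._children[u]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        return order

    # -- cache validity ----------------------------------------------------

    def _current_fingerprint(self, uid: str) -> str:
        return fingerprint(self.bindings[uid])

    def _has_value(self, uid: str) -> bool:
        return uid in self.ram or self.store.has_blob(uid)

    def _is_valid(self, uid: str) -> bool:
        """A resource is valid when it exists, was produced by the current
        source, and (for F-nodes) its tracked files are untouched."""
        rec = self.store.records.get(uid)
        if rec is None or not self._has_value(uid):
            return False
        if rec.fingerprint != self._current_fingerprint(uid):
            return False
        label = self.label(uid)
        if self.is_file_node(label) and not self._file_report(rec).fresh:
            return False
        return True

    def _value(self, uid: str) -> Any:
        if uid in self.ram:
            return self.ram[uid]
        if self.store.has_blob(uid):
            value = self.store.read_blob(uid)
            with self._ram_lock:
                self.ram[uid] = value
            return value
        raise NoResourceError(f"no stored resource for {self.label(uid)!r}")

    # -- scheduling --------------------------------------------------------

    def schedule(self, labels: list[str] | str) -> list[list[str]]:
        """Execution plan for the requested nodes: ordered waves of
        mutually independent labels covering exactly the needed, uncached
        ancestors (lazy pruning: a valid cached node cuts the walk)."""
        if isinstance(labels, str):
            labels = [labels]
        needed: set[str] = set()
        stack = [self.uid(lbl) for lbl in labels]
        while stack:
            uid = stack.pop()
            if uid in needed or self._is_valid(uid):
                continue
            needed.add(uid)
            stack.extend(self._parents[uid])
        if not needed:
            return []
        order = [u for u in self._topo_uids() if u in needed]
        level: dict[str, int] = {}
        for u in order:
            deps = [level[p] for p in self._parents[u] if p in needed]
            level[u] = 1 + max(deps, default=-1)
        waves: list[list[str]] = [[] for _ in range(max(level.values()) + 1)]
        for u in order:
            waves[level[u]].append(self.label(u))
        return waves

    # -- execution ---------------------------------------------------------

    def _build(self, uid: str) -> None:
        func = self.bindings[uid]
        args = [self._value(p) for p in self._parents[uid]]
        t_wall = time.perf_counter()
        t_cpu = time.thread_time()
        value = func(*args)  # node errors propagate unmodified
        cpu = time.thread_time() - t_cpu
        wall = time.perf_counter() - t_wall
        label = self.label(uid)
        self.execution_counts[label] += 1
        rec = ResourceRecord(
            label=label,
            fingerprint=self._current_fingerprint(uid),
            cpu_time=cpu,
            wall_time=wall,
            built_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
        if self.is_file_node(label):
            rec.files = _stat_files(_as_file_list(label, value))
        with self._ram_lock:
            self.ram[uid] = value
            self.store.records[uid] = rec
        self.failed.discard(uid)
        if self.dumping:
            self.store.write_blob(uid, value)
        try:
            self.store.write_source(uid, inspect.getsource(func))
        except (OSError, TypeError):
            pass

    def _execute(self, plan: list[list[str]]) -> None:
        """Run a plan wave by wave; a failing node aborts its descendants
        but lets unrelated branches finish, then the first error is
        re-raised."""
        first_error: BaseException | None = None
        dead: set[str] = set()
        try:
            for wave in plan:
                jobs = [lbl for lbl in wave if self.uid(lbl) not in dead]
                if not jobs:
                    continue
                errors: dict[str, BaseException] = {}

                def run_one(lbl: str) -> None:
                    try:
                        self._build(self.uid(lbl))
                    except BaseException as exc:  # recorded, then re-raised
                        errors[lbl] = exc

                if self.workers > 1 and len(jobs) > 1:
                    with ThreadPoolExecutor(max_workers=self.workers) as pool:
                        list(pool.map(run_one, jobs))
                else:
                    for lbl in jobs:
                        run_one(lbl)
                for lbl in jobs:
                    if lbl in errors:
                        uid = self.uid(lbl)
                        self.failed.add(uid)
                        dead.add(uid)
                        dead |= self._descendants(uid)
                        if first_error is None:
                            first_error = errors[lbl]
        finally:
            self.store.save()
        if first_error is not None:
            raise first_error

    # -- Table-style public API -------------------------------------------

    def provide(self, label: str) -> Any:
        """Return the node's resource: from RAM if available, loaded from
        disk if dumped, built on the fly (with all needed ancestors)
        otherwise."""
        uid = self.uid(label)
        self._execute(self.schedule([label]))
        return self._value(uid)

    def run(self) -> dict[str, Any]:
        """Provide all leaf (final) resources; independent ready nodes run
        concurrently."""
        leaf_labels = [n.label for n in graphs.leaves(self.graph)]
        self._execute(self.schedule(leaf_labels))
        return {lbl: self._value(self.uid(lbl)) for lbl in leaf_labels}

    def rebuild(self, label: str) -> Any:
        """Clear a resource (RAM and disk), then provide it afresh."""
        uid = self.uid(label)
        with self._ram_lock:
            self.ram.pop(uid, None)
        self.store.drop_record(uid)
        self.store.save()
        return self.provide(label)

    def getinputs(self, label: str) -> list[Any]:
        """Copies of the node's input resources in argument order,
        producing missing parents on the fly.  Mutating a returned copy
        never changes the cache."""
        uid = self.uid(label)
        parents = [self.label(p) for p in self._parents[uid]]
        return [copy.deepcopy(self.provide(p)) for p in parents]

    def list_states(self) -> dict[str, str]:
        """State of every resource: available (in RAM), dumped (on disk
        only), unavailable (its build failed this session) or to be
        built."""
        out: dict[str, str] = {}
        for uid, node in self.graph.nodes.items():
            if uid in self.ram:
                state = STATE_AVAILABLE
            elif self.store.has_blob(uid):
                state = STATE_DUMPED
            elif uid in self.failed:
                state = STATE_UNAVAILABLE
            else:
                state = STATE_TO_BE_BUILT
            out[node.label] = state
        return out

    # -- cache management --------------------------------------------------

    def clear(self, label: str) -> None:
        """Drop the RAM copy only; a dumped blob (if any) remains."""
        self.ram.pop(self.uid(label), None)

    def clearall(self) -> None:
        self.ram.clear()

    def undump(self, label: str) -> None:
        """Drop the disk blob only; a RAM copy (if any) remains."""
        self.store.drop_blob(self.uid(label))

    def undumpall(self) -> None:
        for uid in self.graph.nodes:
            self.store.drop_blob(uid)

    def set_dumping(self, enabled: bool) -> None:
        """When off, newly produced resources stay in RAM only (metadata is
        still persisted)."""
        self.dumping = enabled

    def dump_on(self) -> None:
        self.set_dumping(True)

    def dump_off(self) -> None:
        self.set_dumping(False)

    # -- consistency -------------------------------------------------------

    def refresh_bindings(self) -> None:
        """Re-read node functions from the project's source file/module so
        fingerprints reflect the source as it is now on disk."""
        if self.source_path is not None:
            ns, _, module = _load_namespace(self.source_path)
            self.source_module = module
        elif self.source_module is not None:
            importlib.reload(self.source_module)
            ns = vars(self.source_module)
        else:
            return
        for uid, node in self.graph.nodes.items():
            func = ns.get(node.label)
            if callable(func):
                self.bindings[uid] = func

    def detect_code_changes(self, refresh: bool = True) -> set[str]:
        """Invalidate every node whose current source differs from the
        fingerprint stored with its resource, together with all its
        descendants; the cleared labels are returned."""
        if refresh:
            self.refresh_bindings()
        changed = {
            uid
            for uid, rec in self.store.records.items()
            if uid in self.bindings
            and rec.fingerprint is not None
            and rec.fingerprint != self._current_fingerprint(uid)
        }
        closure: set[str] = set()
        for uid in changed:
            closure.add(uid)
            closure |= self._descendants(uid)
        for uid in closure:
            self.ram.pop(uid, None)
            self.store.drop_record(uid)
        if closure:
            self.store.save()
        return {self.label(uid) for uid in closure}

    def trust(self, label: str) -> None:
        """Accept the stored resource despite a source change: the stored
        fingerprint (and F-file timestamps) are updated to the current
        state, so no cascade invalidation follows."""
        uid = self.uid(label)
        rec = self.store.records.get(uid)
        if rec is None or not self._has_value(uid):
            raise NoResourceError(
                f"cannot trust {label!r}: no stored resource"
            )
        rec.fingerprint = self._current_fingerprint(uid)
        if self.is_file_node(label):
            rec.files = _stat_files([f["path"] for f in rec.files])
        self.store.save()

    def untrust(self, label: str) -> None:
        """Clear the node's resource and every descendant's (RAM + disk)."""
        uid = self.uid(label)
        for u in {uid} | self._descendants(uid):
            self.ram.pop(u, None)
            self.store.drop_record(u)
        self.store.save()

    # -- F-node file tracking ---------------------------------------------

    def _file_report(self, rec: ResourceRecord) -> FileReport:
        stale: list[tuple[str, str]] = []
        for entry in rec.files:
            path = Path(entry["path"])
            if not path.exists():
                stale.append((str(path), "missing"))
            elif path.stat().st_mtime_ns != entry["mtime_ns"]:
                stale.append((str(path), "modified"))
        return FileReport(not stale, tuple(stale))

    def check_file_outputs(self, label: str) -> FileReport:
        """Freshness of an F-node's tracked files: every recorded file must
        exist with its recorded modification timestamp."""
        if not self.is_file_node(label):
            raise EngineError(f"{label!r} does not carry the F flag")
        rec = self.store.records.get(self.uid(label))
        if rec is None:
            raise NoResourceError(f"{label!r} has no stored resource")
        return self._file_report(rec)


def _as_file_list(label: str, value: Any) -> list[str]:
    if isinstance(value, (str, os.PathLike)):
        return [os.fspath(value)]
    if isinstance(value, (list, tuple)) and all(
        isinstance(v, (str, os.PathLike)) for v in value
    ):
        return [os.fspath(v) for v in value]
    raise FileResourceError(
        f"F-node {label!r} must return a file name or a list of file names, "
        f"got {type(value).__name__}"
    )


def _stat_files(paths: list[str]) -> list[dict]:
    out = []
    for path in paths:
        p = Path(path)
        if p.exists():
            st = p.stat()
            out.append(
                {"path": str(p), "mtime_ns": st.st_mtime_ns, "size": st.st_size}
            )
        else:
            out.append({"path": str(p), "mtime_ns": None, "size": None})
    return out


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------


def bind(spec: ProjectSpec, *, check_consistency: bool = True) -> Protocol:
    """Compile the LGL text, validate the DAG, bind every node label to the
    function of the same name (checking arity against in-degree), load any
    prior session's metadata and — unless disabled — clear resources whose
    source has changed since they were built."""
    registry = compile_lgl(spec.lgl)
    graph = registry.pipeline()
    report = graphs.validate_dag(graph)
    if not report.is_dag:
        raise CyclicGraphError(
            "pipeline graph has a cycle: " + " -> ".join(report.cycle)
        )
    ns, source_path, module = _load_namespace(spec.source)
    bindings: dict[str, Callable] = {}
    indeg: dict[str, int] = {uid: 0 for uid in graph.nodes}
    for _, d in graph.edges:
        indeg[d] += 1
    for uid, node in graph.nodes.items():
        func = ns.get(node.label)
        if not callable(func):
            raise BindingError(
                f"no function named {node.label!r} found for pipeline node "
                f"{node.label!r}"
            )
        lo, hi = _arity_range(func)
        if not (lo <= indeg[uid] <= hi):
            raise BindingError(
                f"node {node.label!r} has {indeg[uid]} incoming edge(s) but "
                f"function {node.label!r} accepts between {lo} and {hi} "
                "arguments"
            )
        bindings[uid] = func
    store = MetadataStore(spec.project_dir)
    protocol = Protocol(
        graph,
        bindings,
        store,
        registry=registry,
        source_path=source_path,
        source_module=module,
        workers=spec.workers,
        dumping=spec.dumping,
    )
    if check_consistency:
        protocol.detect_code_changes(refresh=False)
    return protocol
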