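"""Deterministic example pipelines and an engine-independent reference
executor.

Every generated node function is pure and returns a string of the shape
``"label(input,input,...)"`` so that any caching, ordering or fan-out bug
is visible in the value itself.  :func:`naive_execute` recomputes the whole
pipeline from the stored edge list with no caching and no use of the graph
or engine machinery — it is the ground truth the engine is checked against.
"""

from __future__ import annotations

import hashlib
import linecache
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

__all__ = [
    "SyntheticPipeline",
    "make_string_pipeline",
    "random_dag",
    "naive_execute",
    "modify_node_source",
]


@dataclass
class SyntheticPipeline:
    """A self-contained pipeline: LGL text, the source of its node
    functions, the edge list it encodes, and the expected outputs."""

    lgl: str
    module_source: str
    node_names: list[str]
    edges: list  # of (src label, dst label), creation order
    seed: int = 0
    expected: dict = field(default_factory=dict)

    def parents(self, label: str) -> list[str]:
        """Parents of *label* in edge-creation (= argument) order."""
        return [s for s, d in self.edges if d == label]

    def functions(self) -> dict[str, Callable]:
        """Execute the module source and return its functions.

        The source is registered in :mod:`linecache` under a synthetic
        filename, so ``inspect.getsource`` — and therefore engine
        fingerprinting — works exactly as for a real file.
        """
        digest = hashlib.sha256(self.module_source.encode()).hexdigest()[:12]
        filename = f"<pipeline-fixture-{self.seed}-{digest}>"
        linecache.cache[filename] = (
            len(self.module_source),
            None,
            self.module_source.splitlines(True),
            filename,
        )
        ns: dict = {"__name__": f"fixture_{self.seed}_{digest}"}
        exec(compile(self.module_source, filename, "exec"), ns)
        return {name: ns[name] for name in self.node_names}

    def write_module(self, directory: str | Path) -> Path:
        """Write the node functions as a real importable module file."""
        path = Path(directory) / f"nodes_{self.seed}.py"
        path.write_text(self.module_source, encoding="utf-8")
        return path

    def with_source(self, module_source: str) -> "SyntheticPipeline":
        """Same pipeline, different node source (for code-change tests)."""
        return SyntheticPipeline(
            lgl=self.lgl,
            module_source=module_source,
            node_names=list(self.node_names),
            edges=list(self.edges),
            seed=self.seed,
            expected=dict(self.expected),
        )


def make_string_pipeline() -> SyntheticPipeline:
    """The canonical three-node string-passing pipeline: ``first_task``
    hands a greeting to ``second_task`` and ``third_task``, which each
    append a distinct suffix."""
    lgl = "first_task -> second_task, third_task;\n"
    module_source = (
        "def first_task():\n"
        '    """Emit the greeting string passed to both downstream tasks."""\n'
        '    return "hello"\n'
        "\n"
        "def second_task(s):\n"
        '    """Append the -2 suffix."""\n'
        '    return s + "-2"\n'
        "\n"
        "def third_task(s):\n"
        '    """Append the -3 suffix."""\n'
        '    return s + "-3"\n'
    )
    pipe = SyntheticPipeline(
        lgl=lgl,
        module_source=module_source,
        node_names=["first_task", "second_task", "third_task"],
        edges=[("first_task", "second_task"), ("first_task", "third_task")],
    )
    pipe.expected = naive_execute(pipe)
    return pipe


def random_dag(n: int, edge_probability: float, seed: int) -> SyntheticPipeline:
    """A random pipeline, acyclic by construction (edges only run from
    lower to higher node rank).  Same seed, same pipeline."""
    if n < 1:
        raise ValueError("need at least one node")
    if not 0.0 <= edge_probability <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    rng = random.Random(seed)
    names = [f"n{i}" for i in range(n)]
    edges: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_probability:
                edges.append((names[i], names[j]))
    statements = [f"{s} -> {d};" for s, d in edges]
    connected = {x for e in edges for x in e}
    statements += [f"{name};" for name in names if name not in connected]
    parts = []
    for name in names:
        params = [f"a{k}" for k in range(sum(1 for _, d in edges if d == name))]
        joiner = ' + "," + '.join(params) if params else '""'
        parts.append(
            f"def {name}({', '.join(params)}):\n"
            f'    """Deterministic test node {name}."""\n'
            f'    return "{name}(" + {joiner} + ")"\n'
        )
    pipe = SyntheticPipeline(
        lgl="\n".join(statements) + "\n",
        module_source="\n".join(parts),
        node_names=names,
        edges=edges,
        seed=seed,
    )
    pipe.expected = naive_execute(pipe)
    return pipe


def naive_execute(pipeline: SyntheticPipeline) -> dict:
    """Reference executor: run every node exactly once in topological
    order, no caching, straight off the stored edge list.  Raises on a
    cyclic edge list."""
    funcs = pipeline.functions()
    values: dict[str, object] = {}
    remaining = list(pipeline.node_names)
    while remaining:
        progressed = False
        for name in list(remaining):
            parents = pipeline.parents(name)
            if all(p in values for p in parents):
                values[name] = funcs[name](*(values[p] for p in parents))
                remaining.remove(name)
                progressed = True
        if not progressed:
            raise ValueError(f"cycle among nodes: {sorted(remaining)}")
    return values


def modify_node_source(module_source: str, label: str) -> str:
    """Return the module source with one function's body textually changed
    (a trailing marker comment) without changing its behaviour — enough to
    shift the source fingerprint."""
    out: list[str] = []
    changed = False
    for line in module_source.splitlines(True):
        out.append(line)
        if not changed and line.startswith(f"def {label}("):
            out.append("    # edited\n")
            changed = True
    if not changed:
        raise KeyError(f"no function {label!r} in module source")
    return "".join(out)
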