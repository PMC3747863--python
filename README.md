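# frond

Pipelines for exploratory scientific data analysis, declared in a tiny
embedded graph language and executed lazily with transparent disk caching,
source-change invalidation and hypertext protocol publishing.

Custom bioinformatic analyses grow incrementally: a loop of "compute,
inspect, refine" where a rigid, plan-first workflow system gets in the way,
but a pile of ad-hoc scripts loses reproducibility and provenance. frond
adds a thin layer of structure on top of ordinary Python code. You declare
the *shape* of the analysis — a directed acyclic graph of processing steps —
as a short text program whose layout visually resembles the graph, keep the
steps themselves as plain Python functions in the same source file, and let
the engine handle everything mechanical: which steps actually need to run
for a requested result, saving and restoring intermediate data across
sessions, detecting when an edited function has silently invalidated
downstream results, and rendering the finished analysis as a browsable HTML
*protocol* with per-step source, timings and produced files.

## The model

An analysis is a DAG `G = (V, E)`: nodes are *processors* (functions),
and each processor produces exactly one *resource* (any Python object).
Root nodes import or generate primary resources — the ground truth of the
analysis; interior nodes produce intermediate (raw) resources; leaf nodes
produce final resources. A node with *N* incoming edges binds to a function
of *N* parameters, called with its parents' resources in edge-creation
order; a node with several outgoing edges hands the same resource to each
child.

The graph is written in LGL, a small formal language embedded as a string
in the host source file. The essential constructs:

| LGL | meaning |
|---|---|
| `A -> B, C;` | edges {(A,B), (A,C)} — comma binds tighter than the arrow |
| `A <- B, C;` | edges {(B,A), (C,A)} |
| `G1: A -> B, C;` | a named graph; using `G1` later pastes a fresh **copy** |
| `D -> @G1;` | `@` references the stored object and extends it in place |
| `A < /B \C;` | fork arrow: a visually tree-shaped spelling of `A -> B, C;` |
| `B[F]` | flag F: B's resource is the name(s) of file(s) it wrote |
| `.` | void item: a fork placeholder whose children attach to the parent |

`\|` and newlines are ignored, so statements can be drawn as ASCII art
around the structure they encode. Execution is *lazy*: requesting a
resource runs only the nodes on paths from primary resources to it whose
outputs are not already cached with a matching source fingerprint.

## Worked example

`demo.py` — the pipeline declaration and its three processors live in one
file:

```python
PIPELINE = """
first_task -> second_task, third_task;
"""

def first_task():
    """Emit the greeting string passed to both downstream tasks."""
    return "hello"

def second_task(s):
    """Append the -2 suffix."""
    return s + "-2"

def third_task(s):
    """Append the -3 suffix."""
    return s + "-3"
```

```console
$ frond list demo.py
first_task	to be built
second_task	to be built
third_task	to be built

$ frond provide demo.py second_task
hello-2

$ frond run demo.py
second_task: 'hello-2'
third_task: 'hello-3'

$ frond list demo.py
first_task	dumped
second_task	dumped
third_task	dumped
```

`provide` built only `first_task` and `second_task` — `third_task` stayed
untouched until `run` requested every final resource. After the session,
all three resources are `dumped`: pickled under `demo.frond/`, so a new
session (or `frond publish demo.py protocol/`) reuses them without
re-executing anything. The same API is available in Python:

```python
from frond import ProjectSpec, bind
protocol = bind(ProjectSpec(lgl, "demo.py", "demo.frond"))
protocol.provide("second_task")   # -> 'hello-2'
protocol.list_states()            # -> {'first_task': 'available', ...}
```

If you later edit `second_task`, `bind` (or
`protocol.detect_code_changes()`) notices the changed source fingerprint
and clears that node's resource together with all of its descendants —
unless you `trust("second_task")` to keep the existing result.

`frond compile demo.py` prints the graph as Graphviz DOT:

```console
$ frond compile demo.py
digraph {
  "p0" [label="first_task", shape=ellipse];
  "p1" [label="second_task", shape=ellipse];
  "p2" [label="third_task", shape=ellipse];
  "p0" -> "p1";
  "p0" -> "p2";
}
```

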