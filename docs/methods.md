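# Methods

This note records how frond's language, engine and publisher are defined —
the semantics, the defaults and the deliberate design choices — and what
the synthetic test pipelines do and do not establish.

## Language semantics

**Statements and graph objects.** An LGL program is a sequence of
`;`-terminated statements. Each statement without an `@` reference creates
its own graph object: named if prefixed `label:`, anonymous otherwise.
Using a previously named label as an item pastes a *copy* with fresh node
instances; `@label` instead extends the stored object in place, and a
reference always denotes that graph *as it stood before the current
statement* (so `D -> @G1; @G1 -> D;` attaches the same `D` on both sides
without manufacturing self-edges). Within one graph object, plain items
with the same label are the same node; named-graph expansion always mints
fresh instances. Because one statement is one object, a pipeline written
as a flat edge list (`a -> b; b -> c; ...`) spans many small graphs;
`Registry.pipeline()` unions all graphs of a program with same-label
unification (first occurrence supplies the instance, flags are merged,
edge order is global creation order) to recover the single executable DAG.
This union is also why the engine addresses nodes by label: after
unification, labels are unique in the executable graph.

**Arrows and operands.** The comma builds item sets; an arrow adds one
edge per (source, target) pair. Graph-valued operands participate through
snapshots taken at resolution time: an arrow *into* a graph targets its
roots (in-degree 0), an arrow *out of* one leaves from its leaves
(out-degree 0), and graph→graph connects leaves to roots (the natural
composition of the two single-sided rules, which the elementary forms do
not pin down). Mixed-direction chains (`A -> B <- C`) are evaluated
left-to-right pairwise. Re-declared edges are no-ops — the edge collection
is a set with a remembered creation order.

**Forks.** The adopted concrete grammar is `parent < /branch ... \branch;`
— one or more `/`-branches followed by exactly one `\`-branch, where a
branch is an item, an item set, or a nested fork; arbitrary arity and depth
come from nesting. A void branch `.` is elided; a fork whose parent is
void attaches its children directly to the enclosing parent. A void item
anywhere else is an evaluation error. Flags are single letters stored on
the node; only `F` carries engine semantics, the rest are preserved for
forward compatibility.

**Errors.** Lexical, syntactic and semantic errors all carry the 1-based
source line; parsing stops at the first error and returns nothing partial.
Identifiers follow host-language function-name rules (letters, digits,
underscore, no leading digit) because node labels must bind to function
names; `#` comments and the whitespace status of `|`/newline exist for
embedding pipeline text inside host source files.

## Execution engine

**Binding.** `bind` compiles the LGL, validates acyclicity (an iterative
DFS that returns one witnessing cycle), and binds each node label to the
same-named callable from a module file, an imported module, or a plain
mapping. Arity is checked against in-degree using the signature's
positional-parameter range, so defaults and `*args` behave naturally.

**Laziness and scheduling.** A request walks backwards from the requested
nodes, stopping at any node whose cached resource is *valid*: a stored
record whose source fingerprint matches the currently bound function, a
value present in RAM or on disk, and — for F-nodes — tracked files whose
modification timestamps equal the recorded ones. The needed set is
levelled into topological waves; nodes within a wave are mutually
independent and may run on a thread pool (worker default: CPU count capped
at 8). The semantics are defined entirely by the wave contract, so a
sequential executor is an equally valid implementation; thread-based
parallelism was chosen because node callables need not be picklable.
"Independent" means neither node is an ancestor of the other — two nodes
may well share ancestors and still run in parallel.

**Caching and persistence.** Every produced resource is kept in RAM and,
while dumping is enabled (the default), pickled to
`<project>/resources/<uid>.blob`. Records (fingerprint, file list with
`st_mtime_ns` timestamps and sizes, CPU/wall build times, ISO-8601 build
timestamp) live in a single `metadata.json`; source snapshots go to
`srcdb/<uid>.txt`. Metadata is always persisted, values only while dumping
is on — so a dump-off session leaves a project that reopens with everything
"to be built". Node uids are assigned deterministically during evaluation,
which is what makes records stable across sessions. States reported by
`list_states` are: *available* (in RAM), *dumped* (on disk only), *to be
built* (no stored value), *unavailable* (the build failed in this session).

**Invalidation, trust, untrust.** The fingerprint is a SHA-256 of the
function's extracted source text, unnormalised: formatting or comment
edits do invalidate, which errs on the side of rebuilding rather than
silently serving stale results. `detect_code_changes` (run automatically
at bind) clears every fingerprint-mismatched node plus its descendant
closure and reports the cleared labels; `trust` re-stamps a stored
resource with the current fingerprint (and current file timestamps for
F-nodes) to suppress exactly that cascade; `untrust` force-clears a node
and its descendants. `provide` additionally re-checks the fingerprint
per node, so even without an explicit consistency pass a modified node is
rebuilt when requested.

**Copies vs references.** `provide` returns the cached object itself (a
deliberate asymmetry: cheap, and mutation hazards are the caller's
responsibility), while `getinputs` returns deep copies, so experimenting
with a node's inputs can never corrupt the cache.

**Failure policy.** A raising node propagates its original exception; the
node is marked unavailable, its pending descendants are dropped from the
plan, unrelated branches complete, and previously cached resources are
never rolled back.

## Publisher

`compute_statistics` re-measures file sizes at publish time and sums
per-node CPU times; the whole-analysis block reports exactly: number of
nodes, number of F-nodes, total number of output files, total size of
output files (binary prefixes, two decimals, e.g. `2.32G`), and total CPU
time (`HH:MM:SS.cc`). Node pages carry the description (first docstring
line in tables, full docstring on the page), source code, state, last
build time, CPU time and file links with sizes. HTML is static with
inline CSS and no script; when Graphviz `dot` is available the index
embeds an SVG map whose nodes hyperlink to their pages, and a plain node
table provides the same links regardless, so reachability never depends on
an external renderer. A pinned `generated_at` makes republication
byte-identical. `export_graphics` always writes DOT (F-nodes as
straight-cornered boxes, docstring tooltips on request) and shells out to
`dot` only for rendered formats, warning instead of failing when the
renderer is absent.

## Synthetic pipelines and what the tests show

The fixtures module generates pipelines whose node functions return
strings of the form `label(input,input)`, so any caching, argument-order
or fan-out defect is visible in the value itself. `make_string_pipeline`
is the canonical three-node example (one root passing a string to two
suffix-appending leaves); `random_dag(n, p, seed)` draws edges only from
lower to higher rank, making acyclicity structural, and emits the pipeline
in the flat edge-list LGL style; `naive_execute` recomputes every node
exactly once from the raw edge list, independent of both the graph
evaluator and the engine, and serves as the oracle for equivalence tests.
Property and acceptance tests use DAGs of up to 10 nodes, 100 random
seeds per property, 10-step operation interleavings and 20 repetitions of
the parallel/sequential comparison — sizes at which the oracle's full
recomputation stays trivially cheap while exercising every cache state
transition. These pipelines are pure, fast and in-memory; they do not
emulate real analyses' long runtimes, external tools, large files or
nondeterministic nodes, so passing tests demonstrate the bookkeeping
(laziness, invalidation, persistence, ordering), not robustness against
impure node implementations, which the engine does not attempt to detect
beyond F-node file timestamps.

## Known limitations

- Multiple `@` references to *different* named graphs in one statement
  merge the later graphs into the first — a rare construct the elementary
  forms leave open; both names then denote the merged object.
- Duplicate-label node copies are meaningful at the language level but
  collapse under pipeline unification; the multi-copy style of reusing one
  function with different inputs is therefore limited to distinct labels
  wrapping the same implementation.
- Thread-based parallelism interleaves CPU-bound pure-Python nodes without
  speedup; it exists for correctness of concurrent scheduling and for
  I/O- or subprocess-bound nodes.
- RAM-cached values returned by `provide` are shared references; callers
  who mutate them mutate the cache (use `getinputs` for copies).
- Cluster/distributed execution and protocol variants are out of scope.
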