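"""Publishing an executed pipeline as a hypertext protocol.

A *protocol document* is the analysis as a reader consumes it: the pipeline
drawing, per-node pages with source code, documentation, build times and
links to produced files (with sizes), and whole-pipeline statistics —
number of nodes, number of file-producing (F) nodes, total output files,
their total size and the total CPU time spent.

Sizes are rendered with binary prefixes ("2.32G") and CPU times as
``HH:MM:SS.cc``.  The HTML is static with inline CSS; the pipeline map is
an SVG produced by the external Graphviz ``dot`` renderer when one is on
PATH, and always backed by a plain node table so every node page is one
link away from the index regardless.
"""

from __future__ import annotations

import html
import inspect
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .engine import Protocol
from .graphs import to_dot

__all__ = [
    "NodeStats",
    "ProtocolStats",
    "compute_statistics",
    "publish_html",
    "export_graphics",
    "format_size",
    "format_cpu_time",
]


def format_size(n_bytes: int) -> str:
    """Human-readable byte count with binary prefixes, two decimals
    (``2432 -> '2.38K'``); plain digits below 1 KiB."""
    if n_bytes < 1024:
        return str(n_bytes)
    value = float(n_bytes)
    for prefix in ("K", "M", "G", "T", "P"):
        value /= 1024.0
        if value < 1024.0:
            return f"{value:.2f}{prefix}"
    return f"{value:.2f}E"


def format_cpu_time(seconds: float) -> str:
    """Seconds as ``HH:MM:SS.cc`` (centisecond precision)."""
    total_cs = round(seconds * 100)
    cs = total_cs % 100
    total_s = total_cs // 100
    s = total_s % 60
    m = (total_s // 60) % 60
    h = total_s // 3600
    return f"{h:02d}:{m:02d}:{s:02d}.{cs:02d}"


@dataclass
class NodeStats:
    label: str
    description: str  # first docstring line
    docstring: str
    source: str
    files: list = field(default_factory=list)  # [(path, size or None)]
    last_build: str | None = None
    cpu_time: float = 0.0
    state: str = "to be built"
    is_file_node: bool = False


@dataclass
class ProtocolStats:
    """Whole-pipeline statistics plus the per-node breakdown."""

    node_count: int
    file_node_count: int
    total_files: int
    total_bytes: int
    total_cpu_time: float
    nodes: list = field(default_factory=list)  # of NodeStats

    @property
    def total_size_human(self) -> str:
        return format_size(self.total_bytes)

    @property
    def total_cpu_human(self) -> str:
        return format_cpu_time(self.total_cpu_time)


def _doc_parts(func) -> tuple[str, str]:
    doc = inspect.getdoc(func) or ""
    first = doc.strip().splitlines()[0] if doc.strip() else ""
    return first, doc


def compute_statistics(protocol: Protocol) -> ProtocolStats:
    """Measure the protocol: node/F-node counts, output files with their
    current on-disk sizes (re-measured now, not at build time), and summed
    CPU time.  Unbuilt nodes contribute zero time and files."""
    states = protocol.list_states()
    nodes: list[NodeStats] = []
    total_files = 0
    total_bytes = 0
    total_cpu = 0.0
    for uid, node in protocol.graph.nodes.items():
        func = protocol.bindings[uid]
        first, doc = _doc_parts(func)
        try:
            source = inspect.getsource(func)
        except (OSError, TypeError):
            source = "<source unavailable>"
        rec = protocol.store.records.get(uid)
        files: list = []
        cpu = 0.0
        last_build = None
        if rec is not None:
            cpu = rec.cpu_time
            last_build = rec.built_at
            for entry in rec.files:
                path = Path(entry["path"])
                size = path.stat().st_size if path.exists() else entry["size"]
                files.append((str(path), size))
        total_cpu += cpu
        total_files += len(files)
        total_bytes += sum(sz or 0 for _, sz in files)
        nodes.append(
            NodeStats(
                label=node.label,
                description=first,
                docstring=doc,
                source=source,
                files=files,
                last_build=last_build,
                cpu_time=cpu,
                state=states[node.label],
                is_file_node="F" in node.flags,
            )
        )
    return ProtocolStats(
        node_count=len(protocol.graph.nodes),
        file_node_count=sum(1 for n in nodes if n.is_file_node),
        total_files=total_files,
        total_bytes=total_bytes,
        total_cpu_time=total_cpu,
        nodes=nodes,
    )


_CSS = """
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #aaa; padding: 0.3em 0.8em; text-align: left; }
th { background: #eee; }
pre { background: #f6f6f6; padding: 1em; overflow-x: auto; }
h1, h2 { color: #2a4d2a; }
""".strip()


def _page(title: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title>"
        f"<style>{_CSS}</style></head>\n<body>\n{body}\n</body></html>\n"
    )


def stats_table_html(stats: ProtocolStats) -> str:
    """The whole-analysis statistics block of the protocol document."""
    rows = [
        ("Number of nodes", str(stats.node_count)),
        ("Number of F-nodes", str(stats.file_node_count)),
        ("Total number of output files", str(stats.total_files)),
        ("Total size of output files", stats.total_size_human),
        ("Total CPU time required", stats.total_cpu_human),
    ]
    cells = "\n".join(
        f"<tr><td>{html.escape(k)}</td><td>{html.escape(v)}</td></tr>"
        for k, v in rows
    )
    return (
        "<h2>Statistics for the entire analysis</h2>\n"
        f"<table>\n{cells}\n</table>"
    )


def node_page_html(ns: NodeStats) -> str:
    file_rows = "\n".join(
        f"<tr><td><a href='{html.escape(p)}'>{html.escape(Path(p).name)}</a>"
        f"</td><td>{format_size(sz) if sz is not None else '?'}</td></tr>"
        for p, sz in ns.files
    )
    files_block = (
        f"<h2>Output files</h2>\n<table><tr><th>File</th><th>Size</th></tr>\n"
        f"{file_rows}\n</table>"
        if ns.files
        else ""
    )
    doc_block = (
        f"<h2>Documentation</h2>\n<pre>{html.escape(ns.docstring)}</pre>"
        if ns.docstring
        else ""
    )
    body = (
        f"<h1>Node {html.escape(ns.label)}</h1>\n"
        f"<p>{html.escape(ns.description)}</p>\n"
        "<table>\n"
        f"<tr><td>State</td><td>{html.escape(ns.state)}</td></tr>\n"
        f"<tr><td>Last build time</td><td>{html.escape(ns.last_build or '-')}"
        "</td></tr>\n"
        f"<tr><td>Required CPU time</td><td>{format_cpu_time(ns.cpu_time)}"
        "</td></tr>\n"
        "</table>\n"
        f"{doc_block}\n"
        f"<h2>Source code</h2>\n<pre>{html.escape(ns.source)}</pre>\n"
        f"{files_block}\n"
        "<p><a href='../index.html'>Back to protocol</a></p>"
    )
    return _page(f"Node {ns.label}", body)


def _render_svg_map(protocol: Protocol, outdir: Path) -> str:
    """Pipeline drawing as inline SVG with node hyperlinks, when Graphviz
    is available; empty string otherwise."""
    dot = shutil.which("dot")
    if dot is None:
        return ""
    annotated = to_dot(protocol.graph)
    # attach per-node URLs so the SVG doubles as an image map
    lines = []
    for line in annotated.splitlines():
        for node in protocol.graph.nodes.values():
            needle = f'"{node.uid}" ['
            if line.strip().startswith(needle):
                line = line.replace(
                    "[", f'[URL="nodes/{node.label}.html", ', 1
                )
                break
        lines.append(line)
    try:
        proc = subprocess.run(
            [dot, "-Tsvg"],
            input="\n".join(lines).encode(),
            capture_output=True,
            check=True,
        )
    except (OSError, subprocess.CalledProcessError):  # pragma: no cover
        return ""
    svg = proc.stdout.decode(errors="replace")
    return svg[svg.find("<svg") :] if "<svg" in svg else ""


def publish_html(
    protocol: Protocol,
    output_dir: str | Path,
    *,
    generated_at: str | None = None,
) -> Path:
    """Write the protocol document tree (``index.html`` plus one
    ``nodes/<label>.html`` per node) and return the index path.

    ``generated_at`` pins the timestamp shown on the index so repeated
    publishing of an unchanged protocol is byte-identical.
    """
    outdir = Path(output_dir)
    nodes_dir = outdir / "nodes"
    nodes_dir.mkdir(parents=True, exist_ok=True)
    stats = compute_statistics(protocol)
    svg = _render_svg_map(protocol, outdir)
    map_rows = "\n".join(
        "<tr>"
        f"<td><a href='nodes/{html.escape(ns.label)}.html'>"
        f"{html.escape(ns.label)}</a></td>"
        f"<td>{html.escape(ns.description)}</td>"
        f"<td>{html.escape(ns.state)}</td>"
        f"<td>{format_cpu_time(ns.cpu_time)}</td>"
        "</tr>"
        for ns in stats.nodes
    )
    map_block = (
        "<h2>Pipeline</h2>\n"
        + (svg + "\n" if svg else "")
        + "<table>\n<tr><th>Node</th><th>Description</th><th>State</th>"
        "<th>CPU time</th></tr>\n"
        f"{map_rows}\n</table>"
    )
    stamp = (
        f"<p><small>Generated {html.escape(generated_at)}</small></p>"
        if generated_at
        else ""
    )
    body = (
        "<h1>Bioinformatic protocol</h1>\n"
        f"{map_block}\n"
        f"{stats_table_html(stats)}\n"
        f"{stamp}"
    )
    (outdir / "index.html").write_text(_page("Protocol", body), encoding="utf-8")
    for ns in stats.nodes:
        (nodes_dir / f"{ns.label}.html").write_text(
            node_page_html(ns), encoding="utf-8"
        )
    return outdir / "index.html"


def export_graphics(
    protocol: Protocol,
    path: str | Path,
    include_docs: bool = False,
) -> Path:
    """Export the pipeline drawing.

    DOT text is always written next to *path*; if *path* asks for a
    rendered format (.pdf/.svg/.png) and the external ``dot`` renderer is
    on PATH the rendering is delegated to it, otherwise a warning is issued
    and the DOT path is returned.  With ``include_docs`` each node carries
    the first line of its function's docstring as a tooltip.
    """
    path = Path(path)
    annotations = {}
    if include_docs:
        for uid, node in protocol.graph.nodes.items():
            first, _ = _doc_parts(protocol.bindings[uid])
            if first:
                annotations[node.label] = first
    dot_text = to_dot(protocol.graph, annotations)
    dot_path = path if path.suffix == ".dot" else path.with_suffix(".dot")
    dot_path.parent.mkdir(parents=True, exist_ok=True)
    dot_path.write_text(dot_text, encoding="utf-8")
    if path.suffix in (".pdf", ".svg", ".png"):
        renderer = shutil.which("dot")
        if renderer is None:
            warnings.warn(
                f"Graphviz 'dot' not found; wrote DOT text to {dot_path}",
                stacklevel=2,
            )
            return dot_path
        subprocess.run(
            [renderer, f"-T{path.suffix[1:]}", "-o", str(path), str(dot_path)],
            check=True,
        )
        return path
    return dot_path
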