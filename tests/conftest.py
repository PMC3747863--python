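import pytest

from frond import ProjectSpec, bind, make_string_pipeline, naive_execute
from frond.fixtures import SyntheticPipeline


@pytest.fixture
def string_pipeline():
    return make_string_pipeline()


@pytest.fixture
def protocol(string_pipeline, tmp_path):
    spec = ProjectSpec(
        string_pipeline.lgl, string_pipeline.functions(), tmp_path / "proj"
    )
    return bind(spec)


def make_diamond() -> SyntheticPipeline:
    """A -> {B, C} -> D; D receives (B, C) in edge-creation order."""
    pipe = SyntheticPipeline(
        lgl="A -> B, C; B -> D; C -> D;\n",
        module_source=(
            "def A():\n"
            '    """Root of the diamond."""\n'
            '    return "A()"\n'
            "\n"
            "def B(x):\n"
            '    return "B(" + x + ")"\n'
            "\n"
            "def C(x):\n"
            '    return "C(" + x + ")"\n'
            "\n"
            "def D(b, c):\n"
            '    return "D(" + b + "," + c + ")"\n'
        ),
        node_names=["A", "B", "C", "D"],
        edges=[("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")],
    )
    pipe.expected = naive_execute(pipe)
    return pipe


def make_chain(n: int) -> SyntheticPipeline:
    """c0 -> c1 -> ... -> c{n-1}, each node appending its own tag."""
    names = [f"c{i}" for i in range(n)]
    edges = [(names[i], names[i + 1]) for i in range(n - 1)]
    parts = [
        "def c0():\n"
        '    return "c0()"\n'
    ]
    for i in range(1, n):
        parts.append(
            f"def c{i}(x):\n"
            f'    return "c{i}(" + x + ")"\n'
        )
    pipe = SyntheticPipeline(
        lgl="\n".join(f"{s} -> {d};" for s, d in edges) + "\n",
        module_source="\n".join(parts),
        node_names=names,
        edges=edges,
    )
    pipe.expected = naive_execute(pipe)
    return pipe


@pytest.fixture
def diamond_pipeline():
    return make_diamond()
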