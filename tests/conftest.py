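import pytest

from rdf2json.model import load_graph


@pytest.fixture
def load_source(tmp_path):
    """Write an RDF source string to a temp file and load it."""

    counter = {"n": 0}

    def _load(text: str, fmt: str = "turtle"):
        ext = ".ttl" if fmt == "turtle" else ".rdf"
        counter["n"] += 1
        p = tmp_path / f"src{counter['n']}{ext}"
        p.write_text(text, encoding="utf-8")
        return load_graph(p, "auto")

    return _load
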