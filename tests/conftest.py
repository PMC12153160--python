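import numpy as np
import pytest

from scatddi import ScatConfig, SyntheticSpec, generate_toy_corpus


@pytest.fixture
def tiny_config():
    """Miniature architecture (Gd = 8) for fast exact-math tests."""
    return ScatConfig(d_w=6, d_d=4, d_g=2, gru_hidden=4, gru_layers=1,
                      head_dim=4, n_heads=2, dropout=0.0, seed=3)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def toy_corpus_dir(tmp_path_factory):
    """A written-out synthetic corpus with planted filter-rule violations."""
    spec = SyntheticSpec(n_sentences=12, seed=7, planted_r1=3, planted_r2=2)
    corpus = generate_toy_corpus(spec)
    out = tmp_path_factory.mktemp("toycorpus")
    paths = corpus.write(out)
    return {"spec": spec, "corpus": corpus, "paths": paths}


CORPUS_XML = """<?xml version="1.0" encoding="UTF-8"?>
<corpus>
  <document id="d1">
    <sentence id="d1.s1" text="Aspirin increases the effect of Warfarin.">
      <entity id="d1.s1.e0" charOffset="0-6" type="brand" text="Aspirin"/>
      <entity id="d1.s1.e1" charOffset="32-39" type="brand" text="Warfarin"/>
      <pair id="d1.s1.p0" e1="d1.s1.e0" e2="d1.s1.e1" ddi="true" type="effect"/>
    </sentence>
  </document>
</corpus>
"""


@pytest.fixture
def simple_corpus_file(tmp_path):
    path = tmp_path / "corpus.xml"
    path.write_text(CORPUS_XML)
    return path
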