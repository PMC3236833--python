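import numpy as np
import pytest

from adrtopics import Corpus, TermLexicon


@pytest.fixture
def liver_lexicon() -> TermLexicon:
    """Terms with single- and multi-word entries sharing a leading token."""
    return TermLexicon(
        [
            ("t1", "hepatitis"),
            ("t2", "hepatic failure"),
            ("t3", "hepatotoxicity"),
            ("t4", "renal failure"),
        ]
    )


@pytest.fixture
def tiny_corpus() -> Corpus:
    """The enumerable 4-token benchmark: docs [0,0] and [1,1] over 2 words."""
    return Corpus(vocabulary=["w0", "w1"], docs=[np.array([0, 0]), np.array([1, 1])])
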