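import numpy as np
import pytest

from oncothemes import GeneText


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_gene_texts():
    """Three tiny gene documents with overlapping vocabularies."""
    return [
        GeneText("TP53", ["TP53", "p53"], "p53 apoptosis tumor suppressor apoptosis dna repair"),
        GeneText("MDM2", ["MDM2"], "mdm2 inhibits p53 ubiquitin degradation tumor"),
        GeneText("TTN", ["TTN", "titin"], "titin muscle sarcomere elastic protein muscle"),
    ]


@pytest.fixture(scope="session")
def planted_tree_corpus():
    """200 documents drawn from a known 1-root + 3-children topic tree."""
    from scipy import sparse

    gen = np.random.default_rng(7)
    V = 60
    root = np.zeros(V)
    root[:15] = 1 / 15
    children = []
    for i in range(3):
        p = np.zeros(V)
        p[15 + 15 * i : 30 + 15 * i] = 1 / 15
        children.append(p)
    rows = [
        gen.multinomial(80, 0.4 * root + 0.6 * children[d % 3]) for d in range(200)
    ]
    X = sparse.csr_matrix(np.array(rows, dtype=float))
    return X, root, children
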