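import io

import numpy as np
import pandas as pd
import pytest

import stressrcr as s

TINY_NET_TSV = """source\trelation\ttarget\tcausal_flag\tspecies\ttissue\tpmids\tblocks
taof(TF1)\tincreases\tr(g1)\tcausal\thuman\tlung\t111\toxidative
taof(TF1)\tincreases\tr(g2)\tcausal\thuman\tlung\t111;222\toxidative
taof(TF1)\tdecreases\tr(g3)\tcausal\tmouse\tliver\t333\toxidative
taof(TF1)\tincreases\tr(g4)\tcausal\thuman\tlung\t222\toxidative
taof(TF2)\tincreases\tr(g3)\tcausal\trat\tkidney\t444\tosmotic
taof(TF2)\tdecreases\tr(g3)\tcausal\trat\tkidney\t444\tosmotic
taof(TF2)\tincreases\tr(g5)\tcausal\thuman\tcardiovascular\t555\tosmotic
p(TF1)\tincreases\ttaof(TF1)\tcausal\thuman\tlung\t111\toxidative
r(TF1)\tincreases\tp(TF1)\tnon-causal\tunspecified\t\t\t
"""


@pytest.fixture
def tiny_network():
    """4-regulator toy network: TF1 with 4 transcript targets (one negative),
    TF2 with an ambiguous target (both signs to g3) plus g5."""
    return s.parse_network_tsv(io.StringIO(TINY_NET_TSV), name="tiny")


@pytest.fixture
def tiny_scs():
    """State changes matching TF1-increase on g1/g2/g3, contradicting on g4."""
    pop = frozenset({"g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8"})
    changes = [
        s.StateChange("g1", "increased", 2.0, 0.01),
        s.StateChange("g2", "increased", 1.8, 0.02),
        s.StateChange("g3", "decreased", 1.6, 0.03),
        s.StateChange("g4", "decreased", 1.5, 0.04),
    ]
    return s.StateChangeSet("tiny", pop, changes)


@pytest.fixture
def toy_matrix():
    """3v3 fixed-value matrix for hand-checked differential testing."""
    values = pd.DataFrame(
        {
            "t1": [8.0, 10.0, 5.0],
            "t2": [8.4, 10.5, 5.2],
            "t3": [7.8, 9.8, 4.9],
            "c1": [6.0, 10.1, 5.1],
            "c2": [6.5, 10.3, 5.0],
            "c3": [5.9, 9.9, 5.3],
        },
        index=["pA", "pB", "pC"],
    )
    return s.ExpressionMatrix(values, log2=True)


@pytest.fixture
def toy_design():
    return s.ComparisonDesign("toy", ("t1", "t2", "t3"), ("c1", "c2", "c3"))
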