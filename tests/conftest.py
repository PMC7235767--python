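import numpy as np
import pandas as pd
import pytest

from digestor.amplicon_profiles import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(counts, taxa, samples, lineages=None, metadata=None):
    df = pd.DataFrame(np.asarray(counts), index=samples, columns=taxa)
    meta = None
    if metadata is not None:
        meta = pd.DataFrame(metadata, index=samples)
    return AbundanceTable(counts=df, lineages=lineages or {}, metadata=meta)


@pytest.fixture
def small_table():
    lineages = {
        "otu1": ("Bacteria", "Firmicutes", "Clostridia", "O1", "F1", "GenusA"),
        "otu2": ("Bacteria", "Firmicutes", "Clostridia", "O1", "F1", "GenusB"),
        "otu3": ("Bacteria", "Bacteroidetes", "C2", "O2", "F2", "GenusC"),
        "otu4": ("Bacteria", "Bacteroidetes"),
    }
    return make_table(
        [[3, 5, 2, 0], [1, 0, 4, 2], [0, 0, 0, 0]],
        ["otu1", "otu2", "otu3", "otu4"],
        ["s1", "s2", "s3"],
        lineages=lineages,
        metadata={
            "condition": ["control", "control", "GABA"],
            "day": [0, 56, 56],
            "replicate": [1, 2, 1],
        },
    )
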