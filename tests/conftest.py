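import numpy as np
import pandas as pd
import pytest

from taxbridge.model import FeatureTable, Lineage, SampleMetadata, SeqRecord, SequenceSet


def make_lineage(*labels):
    """Lineage helper: pass up to 7 labels, None for unclassified slots."""
    taxa = list(labels) + [None] * (7 - len(labels))
    return Lineage(tuple(taxa))


def make_table(features, samples, counts, lineages=None):
    frame = pd.DataFrame(
        np.asarray(counts, dtype=np.int64), index=pd.Index(features), columns=samples
    )
    if lineages is None:
        lineages = [
            make_lineage("Bacteria", f"P{i}", f"C{i}", f"O{i}", f"F{i}", f"G{i}", f"S{i}")
            for i in range(len(features))
        ]
    return FeatureTable(frame, lineages)


def make_metadata(sample_ids, **columns):
    if not columns:
        columns = {"group": ["g"] * len(sample_ids)}
    frame = pd.DataFrame(columns, index=pd.Index(sample_ids))
    return SampleMetadata(frame)


@pytest.fixture
def small_table():
    return make_table(
        ["f1", "f2", "f3"],
        ["S_1", "S_2"],
        [[5, 1], [0, 3], [2, 4]],
    )


@pytest.fixture
def small_meta(small_table):
    return make_metadata(small_table.sample_ids, group=["A", "B"])


@pytest.fixture
def small_seqs(small_table):
    return SequenceSet([SeqRecord(f, "ACGT" * 10) for f in small_table.feature_ids])


# The printed worked example of a lineage violating the strict hierarchy:
# classified at genus beneath an unclassified family.
WORKED_EXAMPLE = Lineage(
    (
        "Bacteria",
        "Proteobacteria",
        "Gammaproteobacteria",
        "Enterobacteriales",
        None,
        "Escherichia",
        None,
    )
)


@pytest.fixture
def worked_example():
    return WORKED_EXAMPLE
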