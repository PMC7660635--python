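"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from antsel import (
    MotifSpec,
    TabularSpec,
    load_property_table,
    make_sequences,
    make_tabular,
)
from antsel.encoding import extract_fragments, encode, read_annotations, read_fasta


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture(scope="session")
def planted():
    """Planted-feature tabular benchmark: 5 informative among 50."""
    X, y, informative = make_tabular(TabularSpec(seed=11))
    return X, y, informative


@pytest.fixture(scope="session")
def separable():
    """Linearly separable two-class data (one perfectly separating feature)."""
    rng = np.random.default_rng(7)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.random((n, 6))
    X[:, 2] = y * 0.5 + 0.25 + 0.1 * (rng.random(n) - 0.5)  # margin at 0.5
    perm = rng.permutation(n)
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def motif_dataset(tmp_path_factory, property_table):
    """Sequences with a planted proline at +1, encoded at window 21."""
    fasta, tsv = make_sequences(MotifSpec(motif={1: {"P": 1.0}}, seed=42))
    d = tmp_path_factory.mktemp("motif")
    (d / "seqs.fasta").write_text(fasta)
    (d / "sites.tsv").write_text(tsv)
    sequences = read_fasta(d / "seqs.fasta")
    annotations = read_annotations(d / "sites.tsv")
    fragments = extract_fragments(sequences, annotations, window=21)
    dataset = encode(fragments, property_table)
    return {
        "dir": d,
        "sequences": sequences,
        "annotations": annotations,
        "fragments": fragments,
        "dataset": dataset,
    }
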