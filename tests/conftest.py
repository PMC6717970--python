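import numpy as np
import pandas as pd
import pytest

from mpraglm import MPRADataset


def make_paired_dataset(
    counts_dna, counts_rna, barcodes=None, batches=None, classes=None
):
    """Small hand-built paired dataset; counts are (n_seq, n_obs) arrays."""
    counts_dna = np.asarray(counts_dna)
    counts_rna = np.asarray(counts_rna)
    n_seq, n_obs = counts_dna.shape
    ids = [f"s{i + 1}" for i in range(n_seq)]
    obs = [f"o{j + 1}" for j in range(n_obs)]
    annot = pd.DataFrame(index=pd.Index(obs, name="obs"))
    if barcodes is not None:
        annot["barcode"] = barcodes
    if batches is not None:
        annot["batch"] = batches
    cls = None
    if classes is not None:
        cls = pd.Series(classes, index=ids, name="class")
    return MPRADataset(
        dna_counts=pd.DataFrame(counts_dna, index=ids, columns=obs),
        rna_counts=pd.DataFrame(counts_rna, index=ids, columns=obs),
        dna_annotation=annot,
        rna_annotation=annot.copy(),
        sequence_class=cls,
    )


@pytest.fixture
def tiny_dataset():
    return make_paired_dataset(
        [[5, 8, 3], [10, 2, 7]],
        [[10, 16, 6], [5, 1, 4]],
        barcodes=["b1", "b2", "b3"],
    )
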