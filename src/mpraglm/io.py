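"""Delimited-text readers and writers for counts, annotations, and results.

Canonical on-disk form is TSV (gzip transparently supported through pandas):
count tables carry the sequence id in the first column and one column per
observation; annotation tables carry the observation id plus one column per
factor; the class table maps sequence id to candidate/control labels.
Parsing is strict: ragged rows, non-integer counts, and duplicate ids are
errors that name the offender.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data_model import CorrectionFactors, MPRADataset, SequenceClass

__all__ = [
    "read_counts",
    "read_annotation",
    "read_classes",
    "write_results",
    "read_factors",
    "write_factors",
    "read_dataset",
    "write_dataset",
]


def read_counts(path) -> pd.DataFrame:
    """Read a count table; validates nonnegative integers and unique ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sequence ids {dup}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count table")
    bad = np.argwhere((arr < 0) | (np.mod(arr, 1) != 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: count for {df.index[i]!r} / {df.columns[j]!r} is not a "
            f"nonnegative integer ({arr[i, j]}), data line {i + 2}"
        )
    return df.astype(np.int64).rename_axis(None)


def read_annotation(path) -> pd.DataFrame:
    """Read a factor table indexed by observation id (first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate observation ids {dup}")
    return df


def read_classes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    s = df.iloc[:, 0]
    unknown = set(s.unique()) - set(SequenceClass)
    if unknown:
        raise ValueError(f"{path}: unknown sequence classes {sorted(unknown)}")
    return s.rename("class").rename_axis(None)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV; floats use the shortest exact
    representation, so values round-trip bit-identically."""
    table.to_csv(path, sep="\t", index=False)


def write_factors(factors: pd.Series, path) -> None:
    factors.rename("factor").rename_axis("library").to_csv(path, sep="\t")


def read_factors(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    if np.any(~(s > 0)):
        bad = s.index[~(s > 0)].tolist()
        raise ValueError(f"{path}: non-positive factors for {bad}")
    return s


_FILES = {
    "dna_counts": "counts_dna.tsv",
    "rna_counts": "counts_rna.tsv",
    "dna_annotation": "annot_dna.tsv",
    "rna_annotation": "annot_rna.tsv",
    "classes": "classes.tsv",
    "map": "rna_to_dna.tsv",
}


def write_dataset(ds: MPRADataset, directory) -> None:
    """Write all dataset components as TSVs into ``directory``."""
    os.makedirs(directory, exist_ok=True)
    j = lambda name: os.path.join(directory, _FILES[name])
    ds.dna_counts.rename_axis("sequence_id").to_csv(j("dna_counts"), sep="\t")
    ds.rna_counts.rename_axis("sequence_id").to_csv(j("rna_counts"), sep="\t")
    ds.dna_annotation.rename_axis("obs").to_csv(j("dna_annotation"), sep="\t")
    ds.rna_annotation.rename_axis("obs").to_csv(j("rna_annotation"), sep="\t")
    ds.sequence_class.rename("class").rename_axis("sequence_id").to_csv(
        j("classes"), sep="\t"
    )
    ds.rna_to_dna_map.rename("dna_obs").rename_axis("rna_obs").to_csv(
        j("map"), sep="\t"
    )


def read_dataset(directory) -> MPRADataset:
    """Inverse of :func:`write_dataset`."""
    j = lambda name: os.path.join(directory, _FILES[name])
    return MPRADataset(
        dna_counts=read_counts(j("dna_counts")),
        rna_counts=read_counts(j("rna_counts")),
        dna_annotation=read_annotation(j("dna_annotation")),
        rna_annotation=read_annotation(j("rna_annotation")),
        sequence_class=read_classes(j("classes")),
        rna_to_dna_map=pd.read_csv(j("map"), sep="\t", index_col=0, dtype=str)
        .iloc[:, 0]
        .rename_axis(None),
    )
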