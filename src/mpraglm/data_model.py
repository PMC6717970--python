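"""Typed containers for MPRA count data, annotations, and model designs.

An MPRA experiment produces two count matrices over the same candidate
sequences: DNA (construct abundance) and RNA (transcript abundance), one
column per observation (a barcode within a replicate/batch, possibly within
a condition or timepoint).  Columns carry factor annotations; sequences carry
a class label (candidate / negative control / positive control).  Paired
designs have one DNA column per RNA column; un-paired designs (DNA sequenced
once, pre-transduction) map many RNA columns onto a single shared DNA column
via ``rna_to_dna_map``.

Model designs are symbolic term lists (:class:`DesignSpec`) compiled into
full-rank treatment-coded numeric matrices (:class:`DesignMatrix`): an
intercept of ones, then for each factor one 0/1 column per non-reference
level, the lexically first level serving as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceClass",
    "MPRADataset",
    "DesignSpec",
    "DesignMatrix",
    "CorrectionFactors",
    "DesignError",
    "build_design_matrix",
    "parse_formula",
    "validate_dataset",
]

CANDIDATE = "candidate"
NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
SequenceClass = (CANDIDATE, NEGATIVE_CONTROL, POSITIVE_CONTROL)

INTERCEPT = "(Intercept)"


class DesignError(ValueError):
    """Raised for unusable model designs (unknown factors, collinearity)."""


@dataclass
class MPRADataset:
    """Paired DNA/RNA count matrices with column annotations and labels.

    Parameters
    ----------
    dna_counts, rna_counts
        Nonnegative integer DataFrames, rows indexed by sequence id, columns
        by observation id.  Both matrices share the same row index.
    dna_annotation, rna_annotation
        One row per observation column (index = observation id), one column
        per experimental factor (barcode, batch, condition, ...).
    sequence_class
        Series mapping sequence id to one of ``SequenceClass``.  Defaults to
        ``candidate`` for every sequence.
    rna_to_dna_map
        Series mapping each RNA observation id to the DNA observation id it
        shares constructs with.  Defaults to the identity (paired design);
        many-to-one maps encode un-paired designs.
    """

    dna_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    dna_annotation: pd.DataFrame
    rna_annotation: pd.DataFrame
    sequence_class: pd.Series = None
    rna_to_dna_map: pd.Series = None

    def __post_init__(self) -> None:
        if self.sequence_class is None:
            self.sequence_class = pd.Series(
                CANDIDATE, index=self.dna_counts.index, name="class"
            )
        if self.rna_to_dna_map is None:
            self.rna_to_dna_map = pd.Series(
                self.rna_counts.columns, index=self.rna_counts.columns, name="dna_obs"
            )

    @property
    def sequence_ids(self) -> pd.Index:
        return self.dna_counts.index

    @property
    def n_sequences(self) -> int:
        return len(self.dna_counts.index)

    def dna_indices_for_rna(self) -> np.ndarray:
        """Integer position in the DNA columns for each RNA column, in order."""
        pos = pd.Index(self.dna_counts.columns).get_indexer(
            self.rna_to_dna_map.loc[self.rna_counts.columns]
        )
        if np.any(pos < 0):
            missing = self.rna_counts.columns[pos < 0].tolist()
            raise KeyError(f"RNA columns map to unknown DNA columns: {missing}")
        return pos

    def sequences_of_class(self, cls: str) -> pd.Index:
        return self.sequence_ids[self.sequence_class.loc[self.sequence_ids] == cls]

    def subset_sequences(self, ids) -> "MPRADataset":
        ids = pd.Index(ids)
        return MPRADataset(
            dna_counts=self.dna_counts.loc[ids],
            rna_counts=self.rna_counts.loc[ids],
            dna_annotation=self.dna_annotation,
            rna_annotation=self.rna_annotation,
            sequence_class=self.sequence_class.loc[ids],
            rna_to_dna_map=self.rna_to_dna_map,
        )

    def subset_rna_columns(self, cols) -> "MPRADataset":
        """Restrict the RNA side to a subset of observation columns.

        The DNA side is left intact (relevant for un-paired designs where a
        shared DNA column serves several RNA columns).
        """
        cols = pd.Index(cols)
        return MPRADataset(
            dna_counts=self.dna_counts,
            rna_counts=self.rna_counts[cols],
            dna_annotation=self.dna_annotation,
            rna_annotation=self.rna_annotation.loc[cols],
            sequence_class=self.sequence_class,
            rna_to_dna_map=self.rna_to_dna_map.loc[cols],
        )


@dataclass(frozen=True)
class DesignSpec:
    """Symbolic model terms for the DNA and RNA GLMs.

    ``dna_terms`` usually include barcode identity (per-barcode construct
    abundance); ``rna_terms`` never do, because barcodes are replicates that
    share a single transcription rate.  Interactions are written ``"a:b"``.
    """

    dna_terms: tuple = ()
    rna_terms: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna_terms", tuple(self.dna_terms))
        object.__setattr__(self, "rna_terms", tuple(self.rna_terms))
        if any("barcode" in t.split(":") for t in self.rna_terms):
            raise DesignError(
                "RNA design must not encode barcode identity; barcodes are "
                "replicates sharing one transcription rate"
            )


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric full-rank design: values, column labels, term bookkeeping."""

    values: np.ndarray
    column_names: tuple
    column_terms: tuple  # which symbolic term produced each column
    encoding: dict  # factor -> (reference_level, all_levels)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_coef(self) -> int:
        return self.values.shape[1]

    def columns_for_term(self, term: str) -> list:
        return [i for i, t in enumerate(self.column_terms) if t == term]


@dataclass(frozen=True)
class CorrectionFactors:
    """External multiplicative correction factors (e.g. library size).

    Enter the model as offsets: ``log mu = X beta + log(s)``.
    """

    s_dna: pd.Series
    s_rna: pd.Series

    def __post_init__(self) -> None:
        for name, s in (("s_dna", self.s_dna), ("s_rna", self.s_rna)):
            if np.any(~(np.asarray(s, dtype=float) > 0)):
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def ones(cls, dna_columns, rna_columns) -> "CorrectionFactors":
        return cls(
            s_dna=pd.Series(1.0, index=pd.Index(dna_columns)),
            s_rna=pd.Series(1.0, index=pd.Index(rna_columns)),
        )


def parse_formula(formula: str) -> tuple:
    """Parse a minimal ``~a+b+a:b`` model-formula string into a term tuple.

    ``~1``, ``~`` and the empty string all denote the intercept-only model.
    """
    s = formula.strip()
    if s.startswith("~"):
        s = s[1:]
    terms = [t.strip() for t in s.split("+") if t.strip() and t.strip() != "1"]
    return tuple(terms)


def _factor_levels(annotation: pd.DataFrame, factor: str):
    if factor not in annotation.columns:
        raise DesignError(
            f"unknown factor {factor!r}; annotation has {list(annotation.columns)}"
        )
    return sorted(annotation[factor].astype(str).unique())


def _dummies(annotation: pd.DataFrame, factor: str):
    """0/1 indicator columns for every non-reference level (lexical order)."""
    levels = _factor_levels(annotation, factor)
    vals = annotation[factor].astype(str).to_numpy()
    cols = [(lvl, (vals == lvl).astype(float)) for lvl in levels[1:]]
    return levels, cols


def build_design_matrix(annotation: pd.DataFrame, terms) -> DesignMatrix:
    """Compile symbolic terms into a full-rank treatment-coded matrix.

    Column order is deterministic: intercept, then terms in declaration
    order, levels in lexical order within each term.  Raises
    :class:`DesignError` on unknown factors or a rank-deficient encoding
    (naming the collinear columns).
    """
    n = len(annotation)
    if n == 0:
        raise DesignError("annotation has no observations")
    columns = [np.ones(n)]
    names = [INTERCEPT]
    col_terms = [INTERCEPT]
    encoding: dict = {}
    for term in terms:
        parts = term.split(":")
        if len(parts) == 1:
            levels, dummies = _dummies(annotation, term)
            encoding[term] = (levels[0], tuple(levels))
            for lvl, col in dummies:
                columns.append(col)
                names.append(f"{term}[{lvl}]")
                col_terms.append(term)
        else:
            blocks = []
            for f in parts:
                levels, dummies = _dummies(annotation, f)
                encoding.setdefault(f, (levels[0], tuple(levels)))
                blocks.append([(f"{f}[{lvl}]", col) for lvl, col in dummies])
            prod = [("", np.ones(n))]
            for block in blocks:
                prod = [
                    (f"{nm}:{bn}" if nm else bn, col * bcol)
                    for nm, col in prod
                    for bn, bcol in block
                ]
            for nm, col in prod:
                columns.append(col)
                names.append(nm)
                col_terms.append(term)

    X = np.column_stack(columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy QR pass to name the columns that add no rank
        kept: list = []
        bad: list = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                bad.append(names[j])
        raise DesignError(
            f"design is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns: {bad}"
        )
    return DesignMatrix(
        values=X,
        column_names=tuple(names),
        column_terms=tuple(col_terms),
        encoding=encoding,
    )


def _check_counts(counts: pd.DataFrame, side: str, out: list) -> None:
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        out.append(f"{side} counts are not numeric")
        return
    bad = np.argwhere((arr < 0) | (np.mod(arr, 1) != 0))
    for i, j in bad[:50]:
        out.append(
            f"{side} count for sequence {counts.index[i]!r}, column "
            f"{counts.columns[j]!r} is not a nonnegative integer ({arr[i, j]})"
        )


def validate_dataset(ds: MPRADataset) -> list:
    """Check every container invariant; return one diagnostic string per violation.

    Returns an empty list for a well-formed dataset.  Never raises: callers
    decide whether diagnostics are fatal.
    """
    out: list = []
    _check_counts(ds.dna_counts, "DNA", out)
    _check_counts(ds.rna_counts, "RNA", out)
    if not ds.dna_counts.index.equals(ds.rna_counts.index):
        out.append("DNA and RNA matrices have different sequence indices")
    if ds.dna_counts.index.has_duplicates:
        dups = ds.dna_counts.index[ds.dna_counts.index.duplicated()].unique().tolist()
        out.append(f"duplicate sequence ids: {dups}")
    if not ds.dna_annotation.index.equals(pd.Index(ds.dna_counts.columns)):
        out.append("DNA annotation rows do not match DNA matrix columns")
    if not ds.rna_annotation.index.equals(pd.Index(ds.rna_counts.columns)):
        out.append("RNA annotation rows do not match RNA matrix columns")
    unknown = set(ds.sequence_class.unique()) - set(SequenceClass)
    if unknown:
        out.append(f"unknown sequence classes: {sorted(unknown)}")
    mapped = ds.rna_to_dna_map.reindex(ds.rna_counts.columns)
    for col, tgt in mapped.items():
        if pd.isna(tgt):
            out.append(f"RNA column {col!r} has no DNA mapping")
        elif tgt not in ds.dna_counts.columns:
            out.append(f"RNA column {col!r} maps to unknown DNA column {tgt!r}")
    return out
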