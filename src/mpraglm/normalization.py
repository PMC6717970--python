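"""Library-size correction factors via upper-quartile normalization.

Each library's factor is the 75th percentile of its nonzero counts, centred
so the factors have geometric mean 1; DNA and RNA libraries are normalized
separately.  Factors enter the model multiplicatively (as log offsets) and
scale the counts for the ratio-based estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CorrectionFactors, MPRADataset

__all__ = ["upper_quartile_factors", "dataset_correction_factors"]


def upper_quartile_factors(counts: pd.DataFrame, sequences=None) -> pd.Series:
    """Per-column upper-quartile size factors with geometric mean 1.

    The quartile is taken over the nonzero counts of each column
    (linear-interpolation quantile definition).  ``sequences`` optionally
    restricts the rows used to compute the factors, so factors may be derived
    from a superset or subset of the sequences subsequently analysed.
    Raises ``ValueError`` naming any all-zero library.
    """
    if sequences is not None:
        counts = counts.loc[pd.Index(sequences)]
    q75 = {}
    for col in counts.columns:
        vals = counts[col].to_numpy(dtype=float)
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ValueError(f"library {col!r} has no nonzero counts")
        q75[col] = np.quantile(nz, 0.75)
    s = pd.Series(q75, name="size_factor")
    return s / np.exp(np.mean(np.log(s)))


def dataset_correction_factors(ds: MPRADataset, sequences=None) -> CorrectionFactors:
    """Upper-quartile factors for both sides of an :class:`MPRADataset`."""
    return CorrectionFactors(
        s_dna=upper_quartile_factors(ds.dna_counts, sequences),
        s_rna=upper_quartile_factors(ds.rna_counts, sequences),
    )
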