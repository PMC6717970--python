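"""Classification of transcriptionally active sequences.

A sequence is called active when its transcription rate exceeds the null
rate induced by the minimal promoter alone.  The null is a robust
location/scale model on ``log alpha``:

* **controls-based** — median and scaled MAD (x1.4826, the consistency
  constant for the normal) of the negative-control rates;
* **mode-based** (conservative, no controls) — the mode of a kernel density
  estimate of all ``log alpha`` values is taken as the null centre; values
  below the mode are assumed null-generated, reflected about the mode to a
  symmetric sample whose scaled MAD gives the null spread.

Each sequence's MAD score ``z = (log alpha - location)/scale`` is referred
to a standard normal: one-sided (greater) for inducers — the default —
one-sided (less) for repressors, or two-sided.  P-values are BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NullModel",
    "null_from_controls",
    "null_mode_based",
    "classify",
    "bh_adjust",
]

MAD_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class NullModel:
    """Location/scale of the null distribution of ``log alpha``."""

    location: float
    scale: float
    transform: str = "log"
    source: str = "controls"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"degenerate null scale ({self.scale}); cannot test")


def null_from_controls(alphas_controls) -> NullModel:
    """Robust null from negative-control transcription rates.

    Requires at least 3 controls with finite positive rates; raises with a
    pointer to the mode-based null otherwise.
    """
    a = np.asarray(alphas_controls, dtype=float)
    a = a[np.isfinite(a) & (a > 0)]
    if a.size < 3:
        raise ValueError(
            "need >= 3 negative controls with finite transcription rates; "
            "use the mode-based null instead"
        )
    loga = np.log(a)
    loc = float(np.median(loga))
    scale = MAD_CONSISTENCY * float(np.median(np.abs(loga - loc)))
    return NullModel(location=loc, scale=scale, source="controls")


def null_mode_based(alphas_all, n_grid: int = 1024) -> NullModel:
    """Conservative null when no negative controls exist.

    Assumes the mode of the ``log alpha`` distribution is the null mode and
    that sub-mode values are broadly null-generated; those values are
    reflected about the mode to form a symmetric sample from which the null
    spread is estimated.  Requires >= 20 sequences.  With several
    near-equal-height density peaks the smallest-rate mode is used
    (conservative: lower null), with a warning.
    """
    a = np.asarray(alphas_all, dtype=float)
    a = a[np.isfinite(a) & (a > 0)]
    if a.size < 20:
        raise ValueError("mode-based null needs >= 20 sequences with finite rates")
    loga = np.log(a)
    if np.ptp(loga) == 0:
        raise ValueError("degenerate null scale: all transcription rates identical")
    kde = stats.gaussian_kde(loga, bw_method="silverman")
    grid = np.linspace(loga.min(), loga.max(), n_grid)
    dens = kde(grid)
    peaks = np.flatnonzero(
        (dens >= np.roll(dens, 1)) & (dens >= np.roll(dens, -1))
    )
    peaks = peaks[(peaks > 0) & (peaks < n_grid - 1)]
    top = float(dens.max())
    near = [i for i in peaks if dens[i] >= 0.95 * top]
    if len(near) > 1:
        warnings.warn(
            f"{len(near)} near-equal density modes; using the smallest-rate mode"
        )
        mode = grid[min(near)]
    else:
        mode = grid[int(np.argmax(dens))]
    sub = loga[loga <= mode]
    scale = MAD_CONSISTENCY * float(np.median(mode - sub))
    return NullModel(location=float(mode), scale=scale, source="mode_based")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through and do not
    count toward the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def classify(
    alphas, null: NullModel, alternative: str = "greater", sequence_ids=None
) -> pd.DataFrame:
    """MAD-score test of each transcription rate against the null.

    Returns a DataFrame with ``statistic`` (the MAD score), ``logfc``
    (log alpha minus the null location, natural log), ``pvalue`` and BH
    ``fdr``.  NaN rates yield NaN rows excluded from the BH denominator.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(alphas, dtype=float)
    if sequence_ids is None:
        sequence_ids = (
            alphas.index if isinstance(alphas, pd.Series) else np.arange(a.size)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        loga = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), -np.inf)
    loga = np.where(np.isfinite(a) & (a >= 0), loga, np.nan)
    z = (loga - null.location) / null.scale
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(z), np.nan, np.clip(p, 0.0, 1.0))
    return pd.DataFrame(
        {
            "sequence_id": np.asarray(sequence_ids),
            "statistic": z,
            "logfc": loga - null.location,
            "pvalue": p,
            "fdr": bh_adjust(p),
        }
    )
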