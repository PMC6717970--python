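"""Transcription-rate estimation: model-based alpha and ratio baselines.

The model-based estimate ``alpha`` comes from the nested GLM fit; the two
ratio-based summaries it is benchmarked against are computed over the set
``S`` of barcodes with nonzero DNA *and* RNA counts::

    mean ratio        = (1/|S|) sum_{i in S} R_i / D_i
    aggregated ratio  = sum_{i in S} R_i / sum_{j in S} D_j

Ratios are computed on library-size-normalized counts (counts divided by
the column's size factor); the GLM uses the same factors as offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CorrectionFactors, DesignSpec, MPRADataset
from .fitting import FitContext, FitOptions, extract_alpha, fit_sequence

__all__ = [
    "mean_ratio",
    "aggregated_ratio",
    "default_design",
    "quantify",
    "subsample_barcodes",
]


def _nonzero_set(r, d):
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    if r.shape != d.shape:
        raise ValueError(f"length mismatch: RNA {r.shape} vs DNA {d.shape}")
    return r, d, (r != 0) & (d != 0)


def mean_ratio(r, d) -> float:
    """Mean of per-barcode RNA/DNA ratios over the nonzero set; NaN if empty."""
    r, d, mask = _nonzero_set(r, d)
    if not mask.any():
        return float("nan")
    return float(np.mean(r[mask] / d[mask]))


def aggregated_ratio(r, d) -> float:
    """Ratio of summed RNA to summed DNA over the nonzero set; NaN if empty."""
    r, d, mask = _nonzero_set(r, d)
    if not mask.any():
        return float("nan")
    return float(r[mask].sum() / d[mask].sum())


def default_design(ds: MPRADataset, condition: str = None) -> DesignSpec:
    """Standard quantification design: barcode and batch (and, for paired
    multi-condition DNA, condition) effects in the DNA model; only the
    condition of interest in the RNA model."""
    dna_terms = [
        t for t in ("barcode", "batch", "condition") if t in ds.dna_annotation.columns
    ]
    dna_terms = [t for t in dna_terms if ds.dna_annotation[t].nunique() > 1]
    rna_terms = []
    if condition is not None:
        if condition not in ds.rna_annotation.columns:
            raise KeyError(f"condition factor {condition!r} not in RNA annotation")
        rna_terms = [condition]
    return DesignSpec(dna_terms=tuple(dna_terms), rna_terms=tuple(rna_terms))


def quantify(
    ds: MPRADataset,
    spec: DesignSpec = None,
    cf: CorrectionFactors = None,
    condition: str = None,
    opts: FitOptions = FitOptions(),
    sequence_ids=None,
) -> pd.DataFrame:
    """Per-sequence, per-condition transcription-rate table.

    Returns one row per (sequence, condition level) with columns ``alpha``,
    ``mean_ratio``, ``aggregated_ratio``, ``n_barcodes_used``, ``converged``.
    Individual fit failures are recorded in the table, never raised.
    """
    if spec is None:
        spec = default_design(ds, condition)
    if cf is None:
        cf = CorrectionFactors.ones(ds.dna_counts.columns, ds.rna_counts.columns)
    ctx = FitContext(ds, spec, cf)
    if sequence_ids is None:
        sequence_ids = ds.sequence_ids
    s_d = cf.s_dna.reindex(ds.dna_counts.columns).to_numpy(float)
    s_r = cf.s_rna.reindex(ds.rna_counts.columns).to_numpy(float)
    map_idx = ctx.map_idx

    if condition is not None:
        cond_vals = ds.rna_annotation[condition].astype(str)
        levels = sorted(cond_vals.unique())
        groups = {lvl: np.flatnonzero((cond_vals == lvl).to_numpy()) for lvl in levels}
    else:
        groups = {"all": np.arange(len(ds.rna_counts.columns))}

    rows = []
    for sid in sequence_ids:
        d, r = ctx.counts(sid)
        fit = fit_sequence(ctx, d, r, opts)
        alphas = extract_alpha(fit, condition) if fit.converged else None
        d_norm = d / s_d
        r_norm = r / s_r
        for lvl, idx in groups.items():
            r_sub = r_norm[idx]
            d_sub = d_norm[map_idx[idx]]
            mask = (r_sub != 0) & (d_sub != 0)
            rows.append(
                {
                    "sequence_id": sid,
                    "condition": lvl,
                    "alpha": alphas.get(lvl, np.nan) if alphas else np.nan,
                    "mean_ratio": mean_ratio(r_sub, d_sub),
                    "aggregated_ratio": aggregated_ratio(r_sub, d_sub),
                    "n_barcodes_used": int(mask.sum()),
                    "converged": bool(fit.converged),
                }
            )
    return pd.DataFrame(rows)


def subsample_barcodes(
    ds: MPRADataset, rates, n_reps: int, seed: int, barcode_factor: str = "barcode"
) -> list:
    """Down-sample barcodes to each rate, ``n_reps`` independent draws each.

    Returns a list of ``(rate, replicate, dataset)`` tuples; combined
    analyses should include the original dataset alongside these so that
    library-size correction is shared.  A rate above the available barcode
    count is an error; a rate equal to it returns the full barcode set.
    """
    rng = np.random.default_rng(seed)
    barcodes = sorted(ds.rna_annotation[barcode_factor].astype(str).unique())
    out = []
    for rate in rates:
        if rate > len(barcodes):
            raise ValueError(
                f"subsample rate {rate} exceeds available barcodes ({len(barcodes)})"
            )
        for rep in range(n_reps):
            chosen = set(rng.choice(barcodes, size=rate, replace=False))
            rna_cols = ds.rna_annotation.index[
                ds.rna_annotation[barcode_factor].astype(str).isin(chosen)
            ]
            sub = ds.subset_rna_columns(rna_cols)
            dna_cols = ds.dna_annotation.index[
                ds.dna_annotation[barcode_factor].astype(str).isin(chosen)
            ]
            sub = MPRADataset(
                dna_counts=sub.dna_counts[dna_cols],
                rna_counts=sub.rna_counts,
                dna_annotation=sub.dna_annotation.loc[dna_cols],
                rna_annotation=sub.rna_annotation,
                sequence_class=sub.sequence_class,
                rna_to_dna_map=sub.rna_to_dna_map,
            )
            out.append((rate, rep, sub))
    return out
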