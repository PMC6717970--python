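"""Differential-activity testing across conditions, time, and alleles.

Any hypothesis expressible as nested RNA-model term sets is tested by a
likelihood-ratio test: per sequence, the full and reduced models are fitted
(dispersion re-estimated under each) and ``2 * (ll_full - ll_reduced)`` is
referred to a chi-square with df equal to the difference in coefficient
count.  Single coefficients can instead be tested by a Wald test with
standard errors from the inverse observed Fisher information.

Library-size correction alone cannot remove global condition biases when
most sequences are differential, so an optional negative-control correction
fits a joint model over the controls (distinct DNA models, one shared RNA
coefficient vector — the basal behaviour per condition) and injects those
shared coefficients as fixed offsets into every candidate's RNA linear
predictor; tested effects are then relative to the basal condition
behaviour.

Effect sizes are reported in log2 (fitting is in natural log).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CorrectionFactors, DesignSpec, MPRADataset, parse_formula
from .fitting import (
    FitContext,
    FitOptions,
    SequenceFit,
    fit_controls_joint,
    fit_sequence,
)
from .classification import bh_adjust

__all__ = [
    "Hypothesis",
    "lrt",
    "wald",
    "compare_conditions",
    "temporal_test",
    "allelic_test",
]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Hypothesis:
    """Nested pair of RNA-model term sets (full vs reduced)."""

    full_rna_terms: tuple
    reduced_rna_terms: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_rna_terms", tuple(self.full_rna_terms))
        object.__setattr__(self, "reduced_rna_terms", tuple(self.reduced_rna_terms))
        if not set(self.reduced_rna_terms) <= set(self.full_rna_terms):
            raise ValueError("reduced terms must be a subset of full terms")

    @classmethod
    def from_formulas(cls, full: str, reduced: str) -> "Hypothesis":
        return cls(parse_formula(full), parse_formula(reduced))


def lrt(fit_full: SequenceFit, fit_reduced: SequenceFit, df: int):
    """Likelihood-ratio statistic and chi-square(df) upper-tail p-value.

    A full-model likelihood below the reduced one (an optimizer artefact in
    a correctly nested pair) is clipped to statistic 0 with a warning if the
    shortfall exceeds numerical tolerance.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if delta < -1e-4:
        warnings.warn(
            f"full-model likelihood below reduced by {-delta / 2:.3g}; "
            "statistic clipped to 0 (consider a reduced-start refit)"
        )
    stat = max(delta, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def _observed_information(ctx: FitContext, d, r, fit: SequenceFit, step=1e-5):
    """Observed Fisher information over (beta, gamma, log k) by central
    finite differences of the analytic gradient."""
    from .fitting import _objective

    f, _ = _objective(ctx, np.asarray(d, float), np.asarray(r, float))
    x = np.concatenate([fit.beta_dna, fit.gamma_rna, [np.log(fit.k_dispersion)]])
    n = x.size
    H = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = step * max(1.0, abs(x[j]))
        _, gp = f(x + e)
        _, gm = f(x - e)
        H[:, j] = (gp - gm) / (2 * e[j])
    return 0.5 * (H + H.T)


def wald(ctx: FitContext, d, r, fit: SequenceFit, coef_name: str):
    """Wald z-statistic and two-sided normal p-value for one RNA coefficient."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    if coef_name not in fit.xr.column_names:
        raise KeyError(f"no RNA coefficient {coef_name!r}; have {fit.xr.column_names}")
    j = fit.xd.n_coef + fit.xr.column_names.index(coef_name)
    H = _observed_information(ctx, d, r, fit)
    try:
        cov = np.linalg.inv(H)
        var = cov[j, j]
    except np.linalg.LinAlgError:
        var = np.nan
    if not np.isfinite(var) or var <= 0:
        warnings.warn("singular observed information; Wald statistic is NaN")
        return np.nan, np.nan
    gamma_c = fit.gamma_rna[fit.xr.column_names.index(coef_name)]
    z = float(gamma_c / np.sqrt(var))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _logfc(fit_full: SequenceFit, fit_reduced: SequenceFit) -> float:
    """log2 contrast over the coefficients present only in the full model.

    For a single extra coefficient this is that coefficient; for multi-df
    hypotheses (e.g. temporal) it is the range of the extra effects
    (including the reference level's implicit 0)."""
    extra = [
        i
        for i, name in enumerate(fit_full.xr.column_names)
        if name not in fit_reduced.xr.column_names
    ]
    if not extra:
        return 0.0
    vals = fit_full.gamma_rna[extra]
    if len(extra) == 1:
        return float(vals[0] / _LN2)
    return float((max(vals.max(), 0.0) - min(vals.min(), 0.0)) / _LN2)


def compare_conditions(
    ds: MPRADataset,
    hypothesis: Hypothesis,
    dna_terms=None,
    cf: CorrectionFactors = None,
    use_controls: bool = False,
    opts: FitOptions = FitOptions(),
    sequence_ids=None,
) -> pd.DataFrame:
    """Per-sequence LRT of the full vs reduced RNA model.

    With ``use_controls=True`` the shared negative-control RNA coefficients
    (full design) are supplied as fixed offsets to both models, so tested
    effects are relative to basal condition behaviour.  Returns one row per
    candidate with ``logfc`` (log2), ``statistic``, ``df``, ``pvalue`` and
    ``fdr`` (BH over converged candidates).
    """
    if dna_terms is None:
        dna_terms = tuple(
            t
            for t in ("barcode", "batch", "condition")
            if t in ds.dna_annotation.columns and ds.dna_annotation[t].nunique() > 1
        )
    spec_full = DesignSpec(dna_terms=dna_terms, rna_terms=hypothesis.full_rna_terms)
    spec_red = DesignSpec(dna_terms=dna_terms, rna_terms=hypothesis.reduced_rna_terms)

    offset = None
    if use_controls:
        gamma_shared = fit_controls_joint(ds, spec_full, cf, opts)
        ctx_tmp = FitContext(ds, spec_full, cf)
        # basal behaviour beyond the intercept: the intercept itself is
        # absorbed by each candidate's own rate, so only relative condition
        # structure is injected
        gamma_off = gamma_shared.copy()
        gamma_off[0] = 0.0
        offset = ctx_tmp.xr.values @ gamma_off

    ctx_full = FitContext(ds, spec_full, cf, rna_coef_offset=offset)
    ctx_red = FitContext(ds, spec_red, cf, rna_coef_offset=offset)
    df = ctx_full.xr.n_coef - ctx_red.xr.n_coef
    if df < 1:
        raise ValueError("hypothesis has no extra full-model coefficients")

    if sequence_ids is None:
        sequence_ids = ds.sequences_of_class("candidate")
    rows = []
    for sid in sequence_ids:
        d, r = ctx_full.counts(sid)
        # dispersion estimated once, from the full model (Cox-Reid adjusted
        # when opts.cr_adjust); both models are then compared at that common
        # k so the pair stays properly nested
        fit_full = fit_sequence(ctx_full, d, r, opts)
        if fit_full.converged and opts.fix_k is None:
            opts_k = replace(opts, fix_k=fit_full.k_dispersion, cr_adjust=False)
        else:
            opts_k = opts
        fit_red = fit_sequence(ctx_red, d, r, opts_k)
        ok = fit_full.converged and fit_red.converged
        if ok and fit_full.loglik < fit_red.loglik - 1e-4:
            fit_full = fit_sequence(ctx_full, d, r, opts_k, init=fit_red)
        if ok:
            stat, p = lrt(fit_full, fit_red, df)
            lfc = _logfc(fit_full, fit_red)
        else:
            stat, p, lfc = np.nan, np.nan, np.nan
        rows.append(
            {
                "sequence_id": sid,
                "logfc": lfc,
                "statistic": stat,
                "df": df,
                "pvalue": p,
                "converged": ok,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def temporal_test(
    ds: MPRADataset,
    time_factor: str = "time",
    batch_factor: str = "batch",
    **kwargs,
) -> pd.DataFrame:
    """LRT of ``~batch + time`` against ``~batch``: is activity
    time-dependent?  With two timepoints this reduces to a plain
    two-condition comparison (df = number of timepoints - 1)."""
    if time_factor not in ds.rna_annotation.columns:
        raise KeyError(f"no {time_factor!r} factor in RNA annotation")
    reduced = ()
    if (
        batch_factor in ds.rna_annotation.columns
        and ds.rna_annotation[batch_factor].nunique() > 1
    ):
        reduced = (batch_factor,)
    hyp = Hypothesis(full_rna_terms=reduced + (time_factor,), reduced_rna_terms=reduced)
    return compare_conditions(ds, hyp, **kwargs)


def allelic_test(
    ds: MPRADataset,
    allele_factor: str = "allele",
    celltype_factor: str = None,
    mode: str = "per_condition",
    **kwargs,
) -> pd.DataFrame:
    """Allelic comparison within a condition, or allele-by-cell-type
    interaction across conditions.

    ``per_condition``: LRT of ``~allele`` vs intercept-only.  ``interaction``:
    LRT of ``~allele + celltype + allele:celltype`` vs ``~allele + celltype``
    — the interaction model is the alternative.  The two alleles may carry
    different barcode sets; with a single shared (pre-transduction) DNA
    replicate the DNA model should encode only barcode effects
    (``dna_terms=("barcode",)``), the default here.
    """
    ann = ds.rna_annotation
    if allele_factor not in ann.columns:
        raise KeyError(f"no {allele_factor!r} factor in RNA annotation")
    levels = sorted(ann[allele_factor].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"allelic comparison needs exactly 2 alleles, got {levels}")
    kwargs.setdefault(
        "dna_terms",
        tuple(
            t
            for t in ("barcode",)
            if t in ds.dna_annotation.columns and ds.dna_annotation[t].nunique() > 1
        ),
    )
    if mode == "per_condition":
        hyp = Hypothesis(full_rna_terms=(allele_factor,), reduced_rna_terms=())
    elif mode == "interaction":
        if celltype_factor is None:
            raise ValueError("interaction mode requires celltype_factor")
        hyp = Hypothesis(
            full_rna_terms=(
                allele_factor,
                celltype_factor,
                f"{allele_factor}:{celltype_factor}",
            ),
            reduced_rna_terms=(allele_factor, celltype_factor),
        )
    else:
        raise ValueError("mode must be 'per_condition' or 'interaction'")
    return compare_conditions(ds, hyp, **kwargs)
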