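"""Per-sequence maximum-likelihood estimation of the nested GLM.

For one candidate sequence with DNA counts ``d`` and RNA counts ``r``::

    log mu_D = X_D beta + log S_D
    log mu_R = X_D beta (mapped to RNA obs) + X_R gamma + log S_R [+ offset]

Both layers are negative binomial with a single shared size parameter ``k``
(the Gamma-Poisson mixture ties the NB size to the Gamma shape).  The DNA
design usually encodes barcode identity (per-barcode construct abundance);
the RNA design never does: barcodes are replicates sharing one transcription
rate.  The transcription rate per condition is ``alpha = exp(gamma
intercept + condition coefficients)``.

Estimation is joint quasi-Newton (L-BFGS-B) over ``(beta, gamma, log k)``
with analytic gradients; initialisation is least squares on ``log(d + 0.5)``
for ``beta``, the log aggregated ratio for the ``gamma`` intercept, and
``log k = 0``.  No randomness anywhere: fits are deterministic functions of
the data and options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .data_model import (
    CorrectionFactors,
    DesignMatrix,
    DesignSpec,
    MPRADataset,
    build_design_matrix,
)
from .likelihood import nb_logpmf_mu

__all__ = [
    "FitOptions",
    "SequenceFit",
    "FitContext",
    "sequence_loglik",
    "fit_sequence",
    "extract_alpha",
    "fit_controls_joint",
]

_LOGK_BOUNDS = (-12.0, 16.0)
_ETA_MAX = 500.0  # linear predictors are clipped here to keep exp() finite


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls.

    ``tol`` is the relative log-likelihood improvement below which the
    optimizer stops; ``fix_k`` pins the dispersion (used by grid-search
    oracles); ``cr_adjust`` refines the dispersion by Cox-Reid adjusted
    profile likelihood after the joint fit, removing the downward bias in
    the variance estimate caused by the many estimated mean parameters;
    ``debug`` records the monotone negative-log-likelihood trace.
    """

    tol: float = 1e-6
    max_iter: int = 200
    fix_k: float = None
    cr_adjust: bool = True
    debug: bool = False


@dataclass
class SequenceFit:
    """Fitted nested GLM for one sequence."""

    beta_dna: np.ndarray
    gamma_rna: np.ndarray
    k_dispersion: float
    loglik: float
    converged: bool
    n_iterations: int
    fitted_dna: np.ndarray  # exp(X_D beta) * S_D per DNA observation
    xd: DesignMatrix = None
    xr: DesignMatrix = None
    trace: list = None  # nll per iteration when opts.debug

    def alpha_by_condition(self, condition: str = None) -> dict:
        return extract_alpha(self, condition)


class FitContext:
    """Shared per-dataset fitting state: designs, offsets, column mapping.

    Built once per (dataset, design) pair, then applied to every sequence.
    ``rna_coef_offset`` is an optional fixed per-RNA-observation addition to
    the linear predictor (used for negative-control correction).
    """

    def __init__(
        self,
        ds: MPRADataset,
        spec: DesignSpec,
        cf: CorrectionFactors = None,
        rna_coef_offset: np.ndarray = None,
    ):
        self.ds = ds
        self.spec = spec
        self.xd = build_design_matrix(ds.dna_annotation, spec.dna_terms)
        self.xr = build_design_matrix(ds.rna_annotation, spec.rna_terms)
        self.map_idx = ds.dna_indices_for_rna()
        if cf is None:
            cf = CorrectionFactors.ones(ds.dna_counts.columns, ds.rna_counts.columns)
        self.log_sd = np.log(cf.s_dna.reindex(ds.dna_counts.columns).to_numpy(float))
        self.log_sr = np.log(cf.s_rna.reindex(ds.rna_counts.columns).to_numpy(float))
        if rna_coef_offset is None:
            rna_coef_offset = np.zeros(len(ds.rna_counts.columns))
        self.rna_offset = np.asarray(rna_coef_offset, dtype=float)

    def counts(self, seq_id):
        return (
            self.ds.dna_counts.loc[seq_id].to_numpy(float),
            self.ds.rna_counts.loc[seq_id].to_numpy(float),
        )

    def with_offset(self, rna_coef_offset: np.ndarray) -> "FitContext":
        new = FitContext.__new__(FitContext)
        new.__dict__.update(self.__dict__)
        new.rna_offset = np.asarray(rna_coef_offset, dtype=float)
        return new

    @property
    def combined_design(self) -> np.ndarray:
        """Stacked mean-parameter design over DNA then RNA observations:
        ``[[X_D, 0], [X_D[map], X_R]]``; used by the Cox-Reid adjustment."""
        Z = getattr(self, "_combined", None)
        if Z is None:
            top = np.hstack(
                [self.xd.values, np.zeros((self.xd.n_obs, self.xr.n_coef))]
            )
            bottom = np.hstack([self.xd.values[self.map_idx], self.xr.values])
            Z = np.vstack([top, bottom])
            self._combined = Z
        return Z


def _means(ctx: FitContext, beta, gamma):
    eta_d_lin = np.clip(ctx.xd.values @ beta, -_ETA_MAX, _ETA_MAX)
    eta_r = np.clip(
        eta_d_lin[ctx.map_idx] + ctx.xr.values @ gamma + ctx.rna_offset + ctx.log_sr,
        -_ETA_MAX,
        _ETA_MAX,
    )
    return np.exp(eta_d_lin + ctx.log_sd), np.exp(eta_r)


def sequence_loglik(ctx: FitContext, d, r, beta, gamma, k) -> float:
    """Joint DNA + RNA log-likelihood at the given parameters."""
    if not np.isfinite(beta).all() or not np.isfinite(gamma).all():
        raise FloatingPointError("non-finite linear predictor coefficients")
    mu_d, mu_r = _means(ctx, beta, gamma)
    return float(np.sum(nb_logpmf_mu(d, mu_d, k)) + np.sum(nb_logpmf_mu(r, mu_r, k)))


def _nb_w(y, mu, k):
    """d logpmf / d log(mu), per observation."""
    return y - (y + k) * mu / (k + mu)


def _nb_dk(y, mu, k):
    """d logpmf / d k, per observation."""
    return (
        special.digamma(y + k)
        - special.digamma(k)
        + np.log(k)
        + 1.0
        - np.log(k + mu)
        - (y + k) / (k + mu)
    )


def _objective(ctx: FitContext, d, r, fix_k=None, free_beta=True, free_gamma=True):
    """Negative log-likelihood and gradient over the free-parameter vector.

    Layout: [beta (if free), gamma (if free), log k (if fix_k is None)].
    """
    p = ctx.xd.n_coef
    q = ctx.xr.n_coef
    n_dna = ctx.xd.n_obs

    def unpack(theta):
        i = 0
        beta = theta[i : i + p] if free_beta else unpack.beta0
        i += p if free_beta else 0
        gamma = theta[i : i + q] if free_gamma else unpack.gamma0
        i += q if free_gamma else 0
        k = fix_k if fix_k is not None else float(np.exp(theta[i]))
        return beta, gamma, k

    unpack.beta0 = np.zeros(p)
    unpack.gamma0 = np.zeros(q)

    def f(theta):
        beta, gamma, k = unpack(theta)
        mu_d, mu_r = _means(ctx, beta, gamma)
        nll = -(np.sum(nb_logpmf_mu(d, mu_d, k)) + np.sum(nb_logpmf_mu(r, mu_r, k)))
        w_d = _nb_w(d, mu_d, k)
        w_r = _nb_w(r, mu_r, k)
        grads = []
        if free_beta:
            w_total = w_d + np.bincount(ctx.map_idx, weights=w_r, minlength=n_dna)
            grads.append(-(ctx.xd.values.T @ w_total))
        if free_gamma:
            grads.append(-(ctx.xr.values.T @ w_r))
        if fix_k is None:
            dk = np.sum(_nb_dk(d, mu_d, k)) + np.sum(_nb_dk(r, mu_r, k))
            grads.append(np.array([-dk * k]))  # chain rule for log k
        if not np.isfinite(nll):
            nll = 1e300
        g = np.concatenate(grads)
        g[~np.isfinite(g)] = 0.0
        return nll, g

    return f, unpack


def _cr_dispersion(ctx: FitContext, d, r, beta, gamma, k0: float) -> float:
    """Cox-Reid adjusted profile estimate of the dispersion.

    Maximizes ``loglik(k) - 0.5 log det(Z' W(k) Z)`` over ``k`` with the
    mean parameters held at their current estimates; ``W`` are the NB
    working weights ``k mu / (k + mu)``.  The adjustment penalises the
    degrees of freedom spent on the mean, removing the systematic
    underestimation of variance (overestimation of ``k``) that plain ML
    suffers when the mean design is wide.
    """
    mu_d, mu_r = _means(ctx, beta, gamma)
    y = np.concatenate([d, r])
    mu = np.concatenate([mu_d, mu_r])
    Z = ctx.combined_design

    def nobj(logk):
        k = float(np.exp(logk))
        w = k * mu / (k + mu)
        sign, logdet = np.linalg.slogdet(Z.T @ (Z * w[:, None]))
        if sign <= 0:
            return 1e300
        return -float(np.sum(nb_logpmf_mu(y, mu, k))) + 0.5 * logdet

    res = optimize.minimize_scalar(
        nobj,
        bounds=(max(_LOGK_BOUNDS[0], np.log(k0) - 6), min(_LOGK_BOUNDS[1], np.log(k0) + 6)),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(np.exp(res.x))


def _init_params(ctx: FitContext, d, r):
    """Spec initialisation: log-least-squares beta, log aggregated ratio gamma."""
    y = np.log(d + 0.5) - ctx.log_sd
    beta0, *_ = np.linalg.lstsq(ctx.xd.values, y, rcond=None)
    gamma0 = np.zeros(ctx.xr.n_coef)
    d_for_r = d[ctx.map_idx] / np.exp(ctx.log_sd)[ctx.map_idx]
    r_norm = r / np.exp(ctx.log_sr + ctx.rna_offset)
    mask = (d_for_r > 0) & (r_norm > 0)
    if mask.any():
        gamma0[0] = np.log(r_norm[mask].sum() / d_for_r[mask].sum())
    return beta0, gamma0


def fit_sequence(
    ctx: FitContext,
    d: np.ndarray,
    r: np.ndarray,
    opts: FitOptions = FitOptions(),
    init: SequenceFit = None,
) -> SequenceFit:
    """Maximize the joint likelihood for one sequence.

    All-zero DNA counts make the construct abundance unidentifiable: the fit
    is flagged (``converged=False``) and downstream rates are NaN.
    ``init`` warm-starts the optimizer from another fit's parameters (used
    when retrying a full model from a reduced-model optimum).
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.sum() == 0:
        return SequenceFit(
            beta_dna=np.full(ctx.xd.n_coef, np.nan),
            gamma_rna=np.full(ctx.xr.n_coef, np.nan),
            k_dispersion=np.nan,
            loglik=np.nan,
            converged=False,
            n_iterations=0,
            fitted_dna=np.full(ctx.xd.n_obs, np.nan),
            xd=ctx.xd,
            xr=ctx.xr,
        )
    if init is not None and np.isfinite(init.loglik):
        beta0 = init.beta_dna.copy()
        gamma0 = np.zeros(ctx.xr.n_coef)
        common = min(len(init.gamma_rna), 1)  # intercept always shared
        gamma0[:common] = init.gamma_rna[:common]
        for j, name in enumerate(ctx.xr.column_names):
            if init.xr is not None and name in init.xr.column_names:
                gamma0[j] = init.gamma_rna[init.xr.column_names.index(name)]
        logk0 = float(np.log(init.k_dispersion))
    else:
        beta0, gamma0 = _init_params(ctx, d, r)
        logk0 = 0.0

    f, unpack = _objective(ctx, d, r, fix_k=opts.fix_k)
    x0 = np.concatenate([beta0, gamma0] + ([] if opts.fix_k else [[logk0]]))
    bounds = [(None, None)] * (ctx.xd.n_coef + ctx.xr.n_coef)
    if opts.fix_k is None:
        bounds.append(_LOGK_BOUNDS)

    trace = [] if opts.debug else None
    if opts.debug:
        raw_f = f

        def f(theta, _rf=raw_f):  # noqa: F811 - debug wrapper
            val, g = _rf(theta)
            return val, g

        def cb(theta):
            trace.append(raw_f(theta)[0])

    res = optimize.minimize(
        f,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=cb if opts.debug else None,
        options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-7},
    )
    beta, gamma, k = unpack(res.x)
    loglik = -float(res.fun)
    converged = bool(res.success) and np.isfinite(loglik)
    n_iter = int(res.nit)

    if opts.fix_k is None and opts.cr_adjust and converged:
        # Cox-Reid dispersion refinement: adjusted-profile k, then mean
        # parameters re-maximised at that k (two passes are plenty; the
        # means are nearly invariant to k)
        beta = np.asarray(beta, float)
        gamma = np.asarray(gamma, float)
        for _ in range(2):
            k = _cr_dispersion(ctx, d, r, beta, gamma, k)
            f2, unpack2 = _objective(ctx, d, r, fix_k=k)
            res2 = optimize.minimize(
                f2,
                np.concatenate([beta, gamma]),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-7},
            )
            beta, gamma, _ = unpack2(res2.x)
            n_iter += int(res2.nit)
        loglik = -float(res2.fun)
        converged = converged and bool(res2.success) and np.isfinite(loglik)
    fitted = np.exp(np.clip(ctx.xd.values @ beta, -_ETA_MAX, _ETA_MAX) + ctx.log_sd)
    return SequenceFit(
        beta_dna=np.asarray(beta, float).copy(),
        gamma_rna=np.asarray(gamma, float).copy(),
        k_dispersion=float(k),
        loglik=loglik,
        converged=converged,
        n_iterations=n_iter,
        fitted_dna=fitted,
        xd=ctx.xd,
        xr=ctx.xr,
        trace=trace,
    )


def extract_alpha(fit: SequenceFit, condition: str = None) -> dict:
    """Transcription rate per condition level from the RNA coefficients.

    ``alpha(level) = exp(intercept + coefficients of that condition level)``;
    the reference level's rate is ``exp(intercept)``.  With no condition
    factor a single rate is returned under the key ``"all"``.  Unconverged
    fits propagate NaN with a warning.
    """
    if not fit.converged:
        warnings.warn("extracting transcription rate from an unconverged fit")
        if condition is None or fit.xr is None or condition not in fit.xr.encoding:
            return {"all": np.nan}
        _, levels = fit.xr.encoding[condition]
        return {lvl: np.nan for lvl in levels}
    inter = float(fit.gamma_rna[0])
    if condition is None or condition not in fit.xr.encoding:
        return {"all": float(np.exp(inter))}
    ref, levels = fit.xr.encoding[condition]
    out = {}
    for lvl in levels:
        extra = 0.0
        name = f"{condition}[{lvl}]"
        if name in fit.xr.column_names:
            extra = float(fit.gamma_rna[fit.xr.column_names.index(name)])
        out[lvl] = float(np.exp(inter + extra))
    return out


def fit_controls_joint(
    ds: MPRADataset,
    spec: DesignSpec,
    cf: CorrectionFactors = None,
    opts: FitOptions = FitOptions(),
    control_ids=None,
    max_outer: int = 25,
) -> np.ndarray:
    """Joint fit over negative controls: per-sequence DNA models, one shared
    RNA coefficient vector.

    The shared vector captures basal (minimal-promoter) behaviour per
    condition and is used to correct comparative analyses for global shifts.
    Optimized by block coordinate ascent: per-sequence ``(beta, k)`` updates
    given the shared ``gamma``, then a joint ``gamma`` update given all
    per-sequence parameters, until the total likelihood stabilises.
    """
    if control_ids is None:
        control_ids = ds.sequences_of_class("negative_control")
    control_ids = pd.Index(control_ids)
    if len(control_ids) < 2:
        raise ValueError(
            "need >= 2 negative-control sequences for a joint control model; "
            "run the analysis without control correction instead"
        )
    ctx = FitContext(ds, spec, cf)
    seqs = []
    for sid in control_ids:
        d, r = ctx.counts(sid)
        if d.sum() > 0:
            seqs.append((np.asarray(d, float), np.asarray(r, float)))
    if len(seqs) < 2:
        raise ValueError("fewer than 2 controls with nonzero DNA counts")

    # shared-gamma state per sequence: (beta, log k)
    gamma = np.zeros(ctx.xr.n_coef)
    agg_num = agg_den = 0.0
    for d, r in seqs:
        dd = d[ctx.map_idx] / np.exp(ctx.log_sd)[ctx.map_idx]
        rr = r / np.exp(ctx.log_sr)
        m = (dd > 0) & (rr > 0)
        agg_num += rr[m].sum()
        agg_den += dd[m].sum()
    if agg_num > 0 and agg_den > 0:
        gamma[0] = np.log(agg_num / agg_den)

    states = []
    for d, r in seqs:
        beta0, _ = _init_params(ctx, d, r)
        states.append([beta0, 0.0])

    def total_loglik():
        tot = 0.0
        for (d, r), (beta, logk) in zip(seqs, states):
            tot += sequence_loglik(ctx, d, r, beta, gamma, float(np.exp(logk)))
        return tot

    prev = -np.inf
    for _ in range(max_outer):
        # per-sequence (beta, log k) given gamma
        for i, (d, r) in enumerate(seqs):
            f, unpack = _objective(ctx, d, r, fix_k=None, free_gamma=False)
            unpack.gamma0 = gamma
            x0 = np.concatenate([states[i][0], [states[i][1]]])
            res = optimize.minimize(
                f,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(None, None)] * ctx.xd.n_coef + [_LOGK_BOUNDS],
                options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-7},
            )
            states[i][0] = res.x[: ctx.xd.n_coef].copy()
            states[i][1] = float(res.x[-1])

        # shared gamma given everything else
        def g_obj(gvec):
            tot = 0.0
            grad = np.zeros_like(gvec)
            for (d, r), (beta, logk) in zip(seqs, states):
                k = float(np.exp(logk))
                mu_d, mu_r = _means(ctx, beta, gvec)
                tot -= np.sum(nb_logpmf_mu(r, mu_r, k))
                grad -= ctx.xr.values.T @ _nb_w(r, mu_r, k)
            return tot, grad

        res = optimize.minimize(
            g_obj,
            gamma,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-7},
        )
        gamma = res.x.copy()
        cur = total_loglik()
        if np.isfinite(prev) and abs(cur - prev) <= opts.tol * (abs(prev) + 1.0):
            break
        prev = cur
    return gamma
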