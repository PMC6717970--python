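"""Synthetic MPRA data generators.

Two generators are provided:

:func:`simulate`
    The log-normal generator.  Per sequence it draws GLM coefficients
    ``beta = [beta0, beta_batch, beta_bc]`` with ``beta0 ~ N(K, sigma0^2)``,
    ``beta_batch ~ N(0, sigma_batch^2)``, ``beta_bc ~ N(0, sigma_bc^2)``,
    forms latent counts ``D_true = nint(exp(X beta))`` and
    ``R_true = nint(exp(alpha * X beta))`` and adds multiplicative log-normal
    observation noise: ``log D_obs ~ N(X beta, sigma_D^2)`` (median-centred),
    likewise for RNA with ``sigma_R``.  This noise model deliberately differs
    from the gamma-Poisson model fitted downstream, so that benchmarks on
    these data are not biased toward the estimator.

:func:`simulate_nb`
    The model-matched generator: observed counts drawn directly from the
    negative binomial observation model the fitting layer assumes
    (``D ~ NB(exp(X beta), k)``, ``R ~ NB(alpha * exp(X beta), k)``),
    for exact parameter-recovery and test-calibration studies.

By default the transcription rate multiplies the linear predictor inside the
exponent (``R_true = nint(exp(alpha * X beta))``), so the effective RNA/DNA
ratio is barcode dependent; set ``alpha_placement="multiplier"`` for the
conventional ``alpha * exp(X beta)`` form.  ``nint`` is round-half-to-even.

Multi-condition designs replicate each (barcode, batch) RNA observation per
condition and add a per-condition log effect to the RNA log-mean; DNA is by
default sequenced once and shared across conditions (un-paired design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CANDIDATE, NEGATIVE_CONTROL, MPRADataset

__all__ = ["SimConfig", "SimOutput", "simulate", "simulate_nb", "default_paper_config"]


@dataclass
class SimConfig:
    """Parameters of the generative process.

    ``alphas`` is either an explicit sequence of transcription rates or a
    ``(start, stop, step)`` grid, one rate per simulated candidate sequence.
    ``condition_logfc`` gives per-condition additive effects on the RNA
    log-mean: a length-``n_conditions`` vector applied to every sequence
    (first entry conventionally 0), or an ``(n_sequences + n_controls,
    n_conditions)`` matrix for per-sequence effects.
    """

    n_sequences: int = None  # derived from alphas unless alphas is a single rate
    alphas: object = (0.2, 3.0, 0.01)  # explicit vector, or (start, stop, step)
    n_barcodes: int = 30
    n_batches: int = 3
    K_intercept: float = 5.0
    sigma0: float = 0.5
    sigma_batch: float = 0.5
    sigma_bc: float = 0.5
    sigma_D: float = 0.5
    sigma_R: float = 0.5
    seed: int = 0
    alpha_placement: str = "exponent"  # "exponent" | "multiplier"
    n_conditions: int = 1
    condition_logfc: object = None
    paired_dna: bool = False  # multi-condition only: DNA per condition vs shared
    n_controls: int = 0
    control_alpha: float = 1.0
    nb_dispersion: float = 10.0  # size parameter for simulate_nb only

    def __post_init__(self) -> None:
        if self.n_barcodes < 1 or self.n_batches < 1 or self.n_conditions < 1:
            raise ValueError("n_barcodes, n_batches, n_conditions must be >= 1")
        for name in ("sigma0", "sigma_batch", "sigma_bc", "sigma_D", "sigma_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.alpha_placement not in ("exponent", "multiplier"):
            raise ValueError("alpha_placement must be 'exponent' or 'multiplier'")

    def alpha_values(self) -> np.ndarray:
        """Candidate transcription rates (grid expanded; controls excluded).

        Grids are written as a 3-tuple ``(start, stop, step)`` or, in YAML
        configs, as a mapping ``{start, stop, step}``; anything else is an
        explicit vector of rates.
        """
        a = self.alphas
        if isinstance(a, dict):
            a = (a["start"], a["stop"], a["step"])
        if isinstance(a, tuple) and len(a) == 3 and np.isscalar(a[0]):
            start, stop, step = a
            if step <= 0:
                raise ValueError("grid step must be positive")
            n = int(round((stop - start) / step)) + 1
            vals = start + step * np.arange(n)
        else:
            vals = np.asarray(a, dtype=float)
        if np.any(vals <= 0):
            raise ValueError("transcription rates must be positive")
        return vals


@dataclass
class SimOutput:
    """Observed dataset plus ground truth (rates, coefficients, latent counts)."""

    dataset: MPRADataset
    truth: pd.DataFrame  # per sequence: alpha, class, per-condition logfc
    dna_true: pd.DataFrame
    rna_true: pd.DataFrame
    config: SimConfig = None


def default_paper_config(seed: int = 0) -> SimConfig:
    """The benchmark simulation setting: three batches, ``K=5``, all noise
    scales 0.5, and the 281-point transcription-rate grid 0.2..3.0 (step 0.01)."""
    return SimConfig(
        n_sequences=281,
        alphas=(0.2, 3.0, 0.01),
        n_barcodes=30,
        n_batches=3,
        K_intercept=5.0,
        sigma0=0.5,
        sigma_batch=0.5,
        sigma_bc=0.5,
        sigma_D=0.5,
        sigma_R=0.5,
        seed=seed,
    )


def _layout(cfg: SimConfig):
    """Observation ids and annotations for both sides of the experiment."""
    bcs = [f"bc{i:03d}" for i in range(cfg.n_barcodes)]
    bats = [f"batch{j + 1}" for j in range(cfg.n_batches)]
    conds = [f"c{t + 1}" for t in range(cfg.n_conditions)]
    base = [(bc, bt) for bt in bats for bc in bcs]

    def annot(rows, cols):
        return pd.DataFrame(rows, columns=cols).set_index("obs")

    multi = cfg.n_conditions > 1
    if multi:
        rna_rows = [
            {"obs": f"{bc}:{bt}:{cd}", "barcode": bc, "batch": bt, "condition": cd}
            for cd in conds
            for (bc, bt) in base
        ]
        if cfg.paired_dna:
            dna_rows = [dict(r) for r in rna_rows]
            mapping = {r["obs"]: r["obs"] for r in rna_rows}
        else:
            dna_rows = [
                {"obs": f"{bc}:{bt}", "barcode": bc, "batch": bt} for (bc, bt) in base
            ]
            mapping = {r["obs"]: f"{r['barcode']}:{r['batch']}" for r in rna_rows}
    else:
        dna_rows = [
            {"obs": f"{bc}:{bt}", "barcode": bc, "batch": bt} for (bc, bt) in base
        ]
        rna_rows = [dict(r) for r in dna_rows]
        mapping = {r["obs"]: r["obs"] for r in rna_rows}

    dna_annot = annot(dna_rows, list(dna_rows[0].keys()))
    rna_annot = annot(rna_rows, list(rna_rows[0].keys()))
    return dna_annot, rna_annot, pd.Series(mapping, name="dna_obs"), bcs, bats, conds


def _coefficients(cfg: SimConfig, rng, n_seq):
    beta0 = rng.normal(cfg.K_intercept, cfg.sigma0, size=n_seq)
    beta_batch = rng.normal(0.0, cfg.sigma_batch, size=(n_seq, cfg.n_batches))
    beta_bc = rng.normal(0.0, cfg.sigma_bc, size=(n_seq, cfg.n_barcodes))
    return beta0, beta_batch, beta_bc


def _eta(beta0, beta_batch, beta_bc, annot, bcs, bats):
    """Linear predictor X beta per sequence (rows) x observation (cols)."""
    bc_idx = pd.Index(bcs).get_indexer(annot["barcode"])
    bat_idx = pd.Index(bats).get_indexer(annot["batch"])
    return beta0[:, None] + beta_batch[:, bat_idx] + beta_bc[:, bc_idx]


def _condition_logfc_matrix(cfg: SimConfig, n_seq: int) -> np.ndarray:
    if cfg.condition_logfc is None:
        return np.zeros((n_seq, cfg.n_conditions))
    arr = np.asarray(cfg.condition_logfc, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != cfg.n_conditions:
            raise ValueError("condition_logfc vector length must equal n_conditions")
        return np.broadcast_to(arr, (n_seq, cfg.n_conditions)).copy()
    if arr.shape != (n_seq, cfg.n_conditions):
        raise ValueError(
            f"condition_logfc matrix must be {(n_seq, cfg.n_conditions)}, got {arr.shape}"
        )
    return arr


def _assemble(cfg: SimConfig, placement: str = None):
    placement = placement or cfg.alpha_placement
    rng = np.random.default_rng(cfg.seed)
    dna_annot, rna_annot, mapping, bcs, bats, conds = _layout(cfg)
    alphas = cfg.alpha_values()
    if cfg.n_sequences is not None and len(alphas) == 1:
        alphas = np.repeat(alphas, cfg.n_sequences)
    n_cand = len(alphas)
    n_seq = n_cand + cfg.n_controls
    alphas = np.concatenate([alphas, np.full(cfg.n_controls, cfg.control_alpha)])
    ids = [f"seq_{i + 1:04d}" for i in range(n_cand)] + [
        f"ctrl_{i + 1:04d}" for i in range(cfg.n_controls)
    ]
    classes = pd.Series(
        [CANDIDATE] * n_cand + [NEGATIVE_CONTROL] * cfg.n_controls,
        index=ids,
        name="class",
    )
    beta0, beta_batch, beta_bc = _coefficients(cfg, rng, n_seq)
    eta_dna = _eta(beta0, beta_batch, beta_bc, dna_annot, bcs, bats)
    eta_rna_base = _eta(beta0, beta_batch, beta_bc, rna_annot, bcs, bats)
    logfc = _condition_logfc_matrix(cfg, n_seq)
    if cfg.n_conditions > 1:
        cond_idx = pd.Index(conds).get_indexer(rna_annot["condition"])
        rna_shift = logfc[:, cond_idx]
    else:
        rna_shift = np.zeros_like(eta_rna_base)
    if placement == "exponent":
        log_rna_median = alphas[:, None] * eta_rna_base + rna_shift
    else:
        log_rna_median = np.log(alphas)[:, None] + eta_rna_base + rna_shift

    truth = pd.DataFrame(
        {"alpha": alphas, "class": classes, "beta0": beta0}, index=pd.Index(ids)
    )
    for t, cd in enumerate(conds):
        truth[f"logfc_{cd}"] = logfc[:, t]
    return (
        rng,
        dna_annot,
        rna_annot,
        mapping,
        ids,
        classes,
        eta_dna,
        log_rna_median,
        truth,
    )


def _nint(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)  # round-half-to-even


def simulate(cfg: SimConfig) -> SimOutput:
    """Draw a dataset from the log-normal generative process (see module docs)."""
    (rng, dna_annot, rna_annot, mapping, ids, classes, eta_dna, log_rna_median, truth) = (
        _assemble(cfg)
    )
    d_true = _nint(np.exp(eta_dna))
    r_true = _nint(np.exp(log_rna_median))
    d_obs = _nint(np.exp(rng.normal(eta_dna, cfg.sigma_D)))
    r_obs = _nint(np.exp(rng.normal(log_rna_median, cfg.sigma_R)))
    if np.all(d_obs == 0) or np.all(r_obs == 0):
        import warnings

        warnings.warn("degenerate configuration: all simulated counts are zero")
    ds = MPRADataset(
        dna_counts=pd.DataFrame(d_obs, index=ids, columns=dna_annot.index),
        rna_counts=pd.DataFrame(r_obs, index=ids, columns=rna_annot.index),
        dna_annotation=dna_annot,
        rna_annotation=rna_annot,
        sequence_class=classes,
        rna_to_dna_map=mapping,
    )
    return SimOutput(
        dataset=ds,
        truth=truth,
        dna_true=pd.DataFrame(d_true, index=ids, columns=dna_annot.index),
        rna_true=pd.DataFrame(r_true, index=ids, columns=rna_annot.index),
        config=cfg,
    )


def simulate_nb(cfg: SimConfig) -> SimOutput:
    """Draw a dataset from the fitted model's own NB observation layer.

    ``D ~ NB(mu = exp(X beta), k)`` and ``R ~ NB(mu = alpha * exp(X beta), k)``
    with ``k = cfg.nb_dispersion`` shared between layers.  The transcription
    rate always scales the RNA mean here (the model's own semantics;
    ``alpha_placement`` is ignored); latent "true" counts are the NB means
    rounded to nearest integer.
    """
    (rng, dna_annot, rna_annot, mapping, ids, classes, eta_dna, log_rna_median, truth) = (
        _assemble(cfg, placement="multiplier")
    )
    k = cfg.nb_dispersion
    mu_d = np.exp(eta_dna)
    mu_r = np.exp(log_rna_median)
    # numpy's negative_binomial(n, p): mean = n(1-p)/p -> p = k/(k+mu)
    d_obs = rng.negative_binomial(k, k / (k + mu_d)).astype(np.int64)
    r_obs = rng.negative_binomial(k, k / (k + mu_r)).astype(np.int64)
    ds = MPRADataset(
        dna_counts=pd.DataFrame(d_obs, index=ids, columns=dna_annot.index),
        rna_counts=pd.DataFrame(r_obs, index=ids, columns=rna_annot.index),
        dna_annotation=dna_annot,
        rna_annotation=rna_annot,
        sequence_class=classes,
        rna_to_dna_map=mapping,
    )
    return SimOutput(
        dataset=ds,
        truth=truth,
        dna_true=pd.DataFrame(_nint(mu_d), index=ids, columns=dna_annot.index),
        rna_true=pd.DataFrame(_nint(mu_r), index=ids, columns=rna_annot.index),
        config=cfg,
    )
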