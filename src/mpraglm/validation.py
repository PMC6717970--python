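"""Self-validation benchmarks: simulation studies exercising the whole
pipeline and returning summary statistics.

Each function runs a complete generate -> analyse -> measure cycle at a
stated problem size and returns plain numbers (correlations, calibration
p-values, error rates).  They back the acceptance-style test suite and the
reproduction script, and double as templates for user power analyses.
All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, spearmanr

from .classification import classify, null_from_controls
from .comparative import Hypothesis, compare_conditions
from .data_model import DesignSpec
from .fitting import FitContext, extract_alpha, fit_sequence
from .likelihood import GammaParams, NBParams, gamma_poisson_marginal, nb_logpmf
from .normalization import dataset_correction_factors
from .quantification import quantify, subsample_barcodes
from .simulator import SimConfig, default_paper_config, simulate, simulate_nb

__all__ = [
    "grid_sequence_count",
    "closed_form_max_error",
    "null_lrt_calibration",
    "rate_recovery",
    "estimator_variance_ordering",
    "classification_null_calibration",
    "subsampling_bias",
    "control_offset_correction",
]


def grid_sequence_count() -> int:
    """Number of sequences produced by the benchmark transcription-rate grid
    (0.2 to 3.0 in 0.01 steps)."""
    return len(default_paper_config().alpha_values())


def closed_form_max_error() -> float:
    """Largest absolute gap (log scale) between the numerically integrated
    gamma-Poisson mixture and the closed-form NB across a parameter grid."""
    worst = 0.0
    for r in (0, 1, 5, 50):
        for alpha in (0.5, 2.0):
            for k in (0.5, 1.0, 4.0):
                for b in (0.5, 2.0):
                    lhs = gamma_poisson_marginal(r, alpha, GammaParams(k, b))
                    rhs = nb_logpmf(r, NBParams(mu=alpha * k / b, psi=k))
                    worst = max(worst, abs(lhs - rhs))
    return worst


def null_lrt_calibration(seed: int, n_sequences: int = 1000) -> dict:
    """Uniformity of LRT p-values when no condition effect exists.

    Two-condition un-paired design, model-matched generator, 30 barcodes x
    3 batches; returns the KS test against Uniform(0,1) and the fraction of
    p-values below 0.05.
    """
    rng = np.random.default_rng(seed * 8 + 1)
    cfg = SimConfig(
        alphas=rng.uniform(0.5, 2.0, n_sequences),
        n_barcodes=30,
        n_batches=3,
        n_conditions=2,
        seed=seed * 8 + 2,
    )
    out = simulate_nb(cfg)
    res = compare_conditions(out.dataset, Hypothesis(("condition",), ()))
    p = res["pvalue"].dropna().to_numpy()
    return {
        "ks_pvalue": float(kstest(p, "uniform").pvalue),
        "frac_below_05": float((p < 0.05).mean()),
        "n": int(p.size),
    }


def rate_recovery(seed: int, n_sequences: int = 200, n_barcodes: int = 30) -> dict:
    """Transcription-rate recovery on the model-matched generator."""
    rng = np.random.default_rng(seed * 8 + 3)
    cfg = SimConfig(
        alphas=rng.uniform(0.2, 3.0, n_sequences),
        n_barcodes=n_barcodes,
        n_batches=3,
        seed=seed * 8 + 4,
    )
    out = simulate_nb(cfg)
    ctx = FitContext(out.dataset, DesignSpec(("barcode", "batch"), ()))
    est = np.array(
        [
            extract_alpha(fit_sequence(ctx, *ctx.counts(s)))["all"]
            for s in out.dataset.sequence_ids
        ]
    )
    tru = out.truth["alpha"].to_numpy()
    ok = np.isfinite(est)
    return {
        "spearman": float(spearmanr(est[ok], tru[ok]).statistic),
        "median_rel_err": float(np.median(np.abs(est[ok] / tru[ok] - 1))),
        "n": int(ok.sum()),
    }


def estimator_variance_ordering(seed: int, barcode_counts=(5, 15, 30, 60)) -> dict:
    """SD of (estimate - truth) across the benchmark grid, per estimator and
    barcode count, on the log-normal generator."""
    out_stats = {}
    for i, nbc in enumerate(barcode_counts):
        cfg = default_paper_config(seed=seed * 8 + 5 + i)
        cfg.n_barcodes = int(nbc)
        out = simulate(cfg)
        q = quantify(out.dataset, cf=dataset_correction_factors(out.dataset))
        tru = out.truth["alpha"].reindex(q["sequence_id"]).to_numpy()
        out_stats[int(nbc)] = {
            "sd_alpha": float(np.nanstd(q["alpha"].to_numpy() - tru)),
            "sd_mean_ratio": float(np.nanstd(q["mean_ratio"].to_numpy() - tru)),
            "sd_aggregated_ratio": float(
                np.nanstd(q["aggregated_ratio"].to_numpy() - tru)
            ),
            "n": int(len(q)),
        }
    return out_stats


def classification_null_calibration(
    seed: int, n_null: int = 1000, n_controls: int = 200
) -> dict:
    """Fraction of purely basal sequences flagged active at BH-FDR 0.05 with
    a controls-based null; the binomial bound is 0.05 + 3 SE."""
    cfg = SimConfig(
        alphas=np.ones(n_null),
        n_sequences=n_null,
        n_barcodes=30,
        n_batches=3,
        n_controls=n_controls,
        seed=seed * 8 + 6,
    )
    ds = simulate_nb(cfg).dataset
    q = quantify(ds)
    alphas = q.set_index("sequence_id")["alpha"]
    null = null_from_controls(alphas.reindex(ds.sequences_of_class("negative_control")))
    res = classify(alphas.reindex(ds.sequences_of_class("candidate")), null)
    frac = float((res["fdr"].to_numpy() < 0.05).mean())
    return {
        "frac_flagged": frac,
        "bound": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / n_null)),
        "n": n_null,
    }


def subsampling_bias(
    seed: int, n_sequences: int = 60, rates=(15, 30, 45, 60, 75), n_reps: int = 3
) -> dict:
    """Bias of each estimator at reduced barcode counts, relative to the
    full-data estimate, with shared library-size factors (90 barcodes)."""
    cfg = default_paper_config(seed=seed * 8 + 7)
    cfg.alphas = np.linspace(0.2, 3.0, n_sequences)
    cfg.n_barcodes = 90
    out = simulate(cfg)
    cf = dataset_correction_factors(out.dataset)
    full = quantify(out.dataset, cf=cf).set_index("sequence_id")
    subs = subsample_barcodes(out.dataset, list(rates), n_reps, seed=seed * 8 + 7)
    results = {int(r): {} for r in rates}
    deltas = {int(r): {c: [] for c in ("alpha", "mean_ratio", "aggregated_ratio")} for r in rates}
    for rate, rep, sub in subs:
        q = quantify(sub, cf=cf).set_index("sequence_id")
        for col in ("alpha", "mean_ratio", "aggregated_ratio"):
            deltas[int(rate)][col].append((q[col] - full[col]).to_numpy())
    for rate in rates:
        for col, chunks in deltas[int(rate)].items():
            # replicate draws of one sequence are correlated; sequences are
            # the independent units, so average within sequence first
            per_seq = np.nanmean(np.column_stack(chunks), axis=1)
            per_seq = per_seq[np.isfinite(per_seq)]
            results[int(rate)][col] = {
                "mean_bias": float(per_seq.mean()),
                "se": float(per_seq.std(ddof=1) / np.sqrt(per_seq.size)),
                "n": int(per_seq.size),
            }
    return results


def control_offset_correction(
    seed: int, n_candidates: int = 150, n_controls: int = 40
) -> dict:
    """A global two-fold condition shift hitting every sequence (controls
    included): corrected candidates should look null, uncorrected analysis
    should call essentially everything differential."""
    rng = np.random.default_rng(seed * 8 + 8)
    cfg = SimConfig(
        alphas=rng.uniform(0.5, 2.0, n_candidates),
        n_barcodes=30,
        n_batches=3,
        n_conditions=2,
        condition_logfc=[0.0, float(np.log(2.0))],
        n_controls=n_controls,
        seed=seed * 8 + 9,
    )
    ds = simulate_nb(cfg).dataset
    hyp = Hypothesis(("condition",), ())
    res_c = compare_conditions(ds, hyp, use_controls=True)
    res_u = compare_conditions(ds, hyp, use_controls=False)
    return {
        "corrected_ks_pvalue": float(
            kstest(res_c["pvalue"].dropna(), "uniform").pvalue
        ),
        "corrected_frac_called": float((res_c["fdr"] < 0.05).mean()),
        "uncorrected_frac_called": float((res_u["fdr"] < 0.05).mean()),
        "n": n_candidates,
    }
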