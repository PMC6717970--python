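"""Estimation-layer checks: likelihood assembly, MLE oracles, rate
extraction, offsets, and the joint negative-control model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mpraglm import (
    CorrectionFactors,
    DesignSpec,
    FitContext,
    FitOptions,
    SimConfig,
    extract_alpha,
    fit_controls_joint,
    fit_sequence,
    sequence_loglik,
    simulate_nb,
)
from mpraglm.likelihood import nb_logpmf_mu

from conftest import make_paired_dataset


def _single_barcode_ctx(d, r):
    ds = make_paired_dataset([d], [r])
    return FitContext(ds, DesignSpec((), ())), np.asarray(d, float), np.asarray(r, float)


class TestSequenceLoglik:
    def test_identity_rate_reuses_dna_mean(self):
        # gamma = 0, unit factors: RNA mean equals the DNA mean, so the
        # loglik is the sum of NB terms at one common mean
        ctx, d, r = _single_barcode_ctx([5, 8], [6, 7])
        beta = np.array([2.0])
        mu = np.exp(2.0)
        expected = float(
            nb_logpmf_mu(d, mu, 3.0).sum() + nb_logpmf_mu(r, mu, 3.0).sum()
        )
        assert sequence_loglik(ctx, d, r, beta, np.array([0.0]), 3.0) == pytest.approx(
            expected
        )

    def test_barcode_permutation_invariance(self):
        ds = make_paired_dataset([[5, 9, 2]], [[7, 3, 4]], barcodes=["b1", "b2", "b3"])
        ctx = FitContext(ds, DesignSpec(("barcode",), ()))
        perm = [2, 0, 1]
        ds2 = make_paired_dataset(
            [[2, 5, 9]], [[4, 7, 3]], barcodes=["b3", "b1", "b2"]
        )
        ctx2 = FitContext(ds2, DesignSpec(("barcode",), ()))
        args = (np.array([1.0, 0.2, -0.1]), np.array([0.3]), 2.0)
        l1 = sequence_loglik(ctx, *ctx.counts("s1"), *args)
        l2 = sequence_loglik(ctx2, *ctx2.counts("s1"), *args)
        assert l1 == pytest.approx(l2)

    def test_nonfinite_coefficients_raise(self):
        ctx, d, r = _single_barcode_ctx([5], [5])
        with pytest.raises(FloatingPointError):
            sequence_loglik(ctx, d, r, np.array([np.inf]), np.array([0.0]), 1.0)


class TestFitSequence:
    def test_poisson_limit_single_barcode_ratio(self):
        # d=5, r=10, huge k: the rate MLE is the Poisson ratio log(10/5)
        ctx, d, r = _single_barcode_ctx([5], [10])
        fit = fit_sequence(ctx, d, r, FitOptions(fix_k=1e6))
        assert fit.converged
        assert fit.gamma_rna[0] == pytest.approx(np.log(2.0), abs=5e-3)

    def test_grid_search_oracle_poisson_limit(self):
        # exhaustive 2-D grid over (beta0, gamma0) at fixed k reproduces the
        # optimizer's solution to grid resolution
        ctx, d, r = _single_barcode_ctx([7], [21])
        k = 50.0
        betas = np.linspace(0.5, 3.5, 121)
        gammas = np.linspace(-0.5, 2.5, 121)
        ll = np.array(
            [
                [sequence_loglik(ctx, d, r, np.array([b]), np.array([g]), k) for g in gammas]
                for b in betas
            ]
        )
        ib, ig = np.unravel_index(np.argmax(ll), ll.shape)
        fit = fit_sequence(ctx, d, r, FitOptions(fix_k=k))
        assert fit.beta_dna[0] == pytest.approx(betas[ib], abs=0.03)
        assert fit.gamma_rna[0] == pytest.approx(gammas[ig], abs=0.03)

    def test_equal_counts_give_unit_rate(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(100, size=(1, 12))
        ds = make_paired_dataset(
            counts, counts, barcodes=[f"b{i}" for i in range(12)]
        )
        ctx = FitContext(ds, DesignSpec(("barcode",), ()))
        fit = fit_sequence(ctx, *ctx.counts("s1"))
        assert extract_alpha(fit)["all"] == pytest.approx(1.0, abs=1e-3)

    def test_rna_factor_doubling_halves_rate(self):
        out = simulate_nb(SimConfig(alphas=[1.5], n_barcodes=10, n_batches=2, seed=3))
        ds = out.dataset
        spec = DesignSpec(("barcode", "batch"), ())
        cf1 = CorrectionFactors.ones(ds.dna_counts.columns, ds.rna_counts.columns)
        cf2 = CorrectionFactors(s_dna=cf1.s_dna, s_rna=cf1.s_rna * 2)
        a = []
        for cf in (cf1, cf2):
            ctx = FitContext(ds, spec, cf)
            a.append(extract_alpha(fit_sequence(ctx, *ctx.counts("seq_0001")))["all"])
        assert a[0] / a[1] == pytest.approx(2.0, rel=1e-3)

    def test_recovery_on_model_matched_simulation(self):
        rng = np.random.default_rng(2)
        cfg = SimConfig(alphas=rng.uniform(0.2, 3.0, 40), n_barcodes=30, n_batches=3, seed=5)
        out = simulate_nb(cfg)
        ctx = FitContext(out.dataset, DesignSpec(("barcode", "batch"), ()))
        est = np.array(
            [
                extract_alpha(fit_sequence(ctx, *ctx.counts(s)))["all"]
                for s in out.dataset.sequence_ids
            ]
        )
        tru = out.truth["alpha"].to_numpy()
        assert np.median(np.abs(est / tru - 1)) < 0.05
        assert spearmanr(est, tru).statistic > 0.95

    def test_all_zero_dna_is_flagged_not_raised(self):
        ctx, d, r = _single_barcode_ctx([0, 0], [3, 4])
        fit = fit_sequence(ctx, d, r)
        assert not fit.converged
        assert np.isnan(fit.k_dispersion)
        with pytest.warns(UserWarning):
            assert np.isnan(extract_alpha(fit)["all"])

    def test_debug_trace_is_monotone_nonincreasing(self):
        ctx, d, r = _single_barcode_ctx([5, 9, 14], [8, 11, 30])
        fit = fit_sequence(ctx, d, r, FitOptions(debug=True))
        trace = np.array(fit.trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-9)

    def test_deterministic_given_inputs(self):
        out = simulate_nb(SimConfig(alphas=[0.8], n_barcodes=8, n_batches=2, seed=9))
        ctx = FitContext(out.dataset, DesignSpec(("barcode", "batch"), ()))
        f1 = fit_sequence(ctx, *ctx.counts("seq_0001"))
        f2 = fit_sequence(ctx, *ctx.counts("seq_0001"))
        np.testing.assert_array_equal(f1.beta_dna, f2.beta_dna)
        assert f1.loglik == f2.loglik


class TestExtractAlpha:
    def _fit_with(self, gamma, xr):
        from mpraglm import SequenceFit

        return SequenceFit(
            beta_dna=np.zeros(1),
            gamma_rna=np.asarray(gamma, float),
            k_dispersion=1.0,
            loglik=0.0,
            converged=True,
            n_iterations=1,
            fitted_dna=np.ones(1),
            xr=xr,
        )

    def test_zero_intercept_no_conditions(self):
        from mpraglm import build_design_matrix

        xr = build_design_matrix(pd.DataFrame({"z": ["a"]}), [])
        assert self._fit_with([0.0], xr).alpha_by_condition() == {"all": 1.0}

    def test_exp_additivity_over_condition_levels(self):
        from mpraglm import build_design_matrix

        xr = build_design_matrix(
            pd.DataFrame({"condition": ["A", "B"]}), ["condition"]
        )
        alphas = self._fit_with([np.log(2), np.log(3)], xr).alpha_by_condition(
            "condition"
        )
        assert alphas["A"] == pytest.approx(2.0)
        assert alphas["B"] == pytest.approx(6.0)

    def test_condition_subset_refit_consistency(self):
        # per-condition rates from a joint fit agree with refitting on the
        # single condition's data at high depth
        cfg = SimConfig(
            alphas=[1.0], n_barcodes=20, n_batches=2, n_conditions=2,
            condition_logfc=[0.0, 0.7], K_intercept=6.0, seed=17,
        )
        out = simulate_nb(cfg)
        ds = out.dataset
        ctx = FitContext(ds, DesignSpec(("barcode", "batch"), ("condition",)))
        joint = extract_alpha(fit_sequence(ctx, *ctx.counts("seq_0001")), "condition")
        sub = ds.subset_rna_columns(
            ds.rna_annotation.index[ds.rna_annotation["condition"] == "c2"]
        )
        ctx2 = FitContext(sub, DesignSpec(("barcode", "batch"), ()))
        alone = extract_alpha(fit_sequence(ctx2, *ctx2.counts("seq_0001")))["all"]
        assert joint["c2"] == pytest.approx(alone, rel=0.1)


class TestControlsJoint:
    def _controls_sim(self, delta, seed=23, n_controls=8):
        return simulate_nb(
            SimConfig(
                alphas=[1.0],
                n_sequences=1,
                n_barcodes=15,
                n_batches=2,
                n_conditions=2,
                condition_logfc=[0.0, delta],
                n_controls=n_controls,
                seed=seed,
            )
        )

    def test_recovers_shared_condition_effect(self):
        delta = 0.9
        out = self._controls_sim(delta)
        spec = DesignSpec(("barcode", "batch"), ("condition",))
        gamma = fit_controls_joint(out.dataset, spec)
        j = FitContext(out.dataset, spec).xr.column_names.index("condition[c2]")
        assert gamma[j] == pytest.approx(delta, abs=0.1)

    def test_single_condition_returns_intercept_only(self):
        out = simulate_nb(
            SimConfig(alphas=[1.0], n_barcodes=10, n_batches=2, n_controls=4, seed=2)
        )
        gamma = fit_controls_joint(out.dataset, DesignSpec(("barcode", "batch"), ()))
        assert gamma.shape == (1,)

    def test_control_order_invariance(self):
        out = self._controls_sim(0.5, seed=29, n_controls=5)
        spec = DesignSpec(("barcode", "batch"), ("condition",))
        ctrl = list(out.dataset.sequences_of_class("negative_control"))
        g1 = fit_controls_joint(out.dataset, spec, control_ids=ctrl)
        g2 = fit_controls_joint(out.dataset, spec, control_ids=ctrl[::-1])
        np.testing.assert_allclose(g1, g2, atol=1e-4)

    def test_requires_two_controls(self):
        out = simulate_nb(SimConfig(alphas=[1.0], n_barcodes=5, n_batches=1, seed=1))
        with pytest.raises(ValueError, match="without control"):
            fit_controls_joint(out.dataset, DesignSpec(("barcode",), ()))
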