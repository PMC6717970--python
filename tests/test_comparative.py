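"""Differential-activity machinery: LRT/Wald mechanics, calibration and
power on simulated condition effects, temporal and allelic designs, and the
negative-control offset correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from mpraglm import (
    DesignSpec,
    FitContext,
    FitOptions,
    Hypothesis,
    SimConfig,
    compare_conditions,
    fit_sequence,
    lrt,
    simulate_nb,
    temporal_test,
    wald,
)
from mpraglm.comparative import allelic_test


def _two_condition_sim(n, seed, logfc=None, n_controls=0, **kw):
    rng = np.random.default_rng(seed)
    return simulate_nb(
        SimConfig(
            alphas=rng.uniform(0.5, 2.0, n),
            n_barcodes=kw.pop("n_barcodes", 30),
            n_batches=3,
            n_conditions=2,
            condition_logfc=logfc,
            n_controls=n_controls,
            seed=seed + 1,
            **kw,
        )
    )


class TestLRTMechanics:
    def _dummy_fit(self, loglik):
        from mpraglm import SequenceFit

        return SequenceFit(
            beta_dna=np.zeros(1), gamma_rna=np.zeros(1), k_dispersion=1.0,
            loglik=loglik, converged=True, n_iterations=1, fitted_dna=np.ones(1),
        )

    def test_identical_fits_give_null_result(self):
        stat, p = lrt(self._dummy_fit(-10.0), self._dummy_fit(-10.0), df=1)
        assert stat == 0.0 and p == 1.0

    def test_chisquare_quantile(self):
        stat, p = lrt(self._dummy_fit(-10.0), self._dummy_fit(-10.0 - 3.841 / 2), df=1)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            stat, p = lrt(self._dummy_fit(-11.0), self._dummy_fit(-10.0), df=1)
        assert stat == 0.0 and p == 1.0

    def test_hypothesis_nesting_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            Hypothesis(("condition",), ("batch",))


class TestWald:
    def test_agrees_with_lrt_on_two_condition_data(self):
        # under mild effects the Wald and LRT p-values agree within 2x
        out = _two_condition_sim(12, seed=41)
        ds = out.dataset
        spec = DesignSpec(("barcode", "batch"), ("condition",))
        ctx = FitContext(ds, spec)
        res = compare_conditions(ds, Hypothesis(("condition",), ()))
        agree = 0
        for _, row in res.iterrows():
            d, r = ctx.counts(row["sequence_id"])
            fit = fit_sequence(ctx, d, r)
            _, p_wald = wald(ctx, d, r, fit, "condition[c2]")
            if max(p_wald, row["pvalue"]) <= 2 * min(p_wald, row["pvalue"]):
                agree += 1
        assert agree >= 9  # asymptotic equivalence on most sequences

    def test_unknown_coefficient_raises(self):
        out = _two_condition_sim(1, seed=43)
        ctx = FitContext(out.dataset, DesignSpec(("barcode", "batch"), ("condition",)))
        d, r = ctx.counts("seq_0001")
        fit = fit_sequence(ctx, d, r)
        with pytest.raises(KeyError):
            wald(ctx, d, r, fit, "condition[zzz]")


class TestCompareConditions:
    def test_null_pvalues_are_uniform(self):
        out = _two_condition_sim(150, seed=47)
        res = compare_conditions(out.dataset, Hypothesis(("condition",), ()))
        assert res["converged"].all()
        assert kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_identical_conditions_give_null_logfc(self):
        out = _two_condition_sim(20, seed=53)
        res = compare_conditions(out.dataset, Hypothesis(("condition",), ()))
        assert np.nanmedian(np.abs(res["logfc"])) < 0.15

    def test_power_and_fdr_on_partial_signal(self):
        # 20% of candidates carry a log2 fold-change of 1
        n = 100
        rng = np.random.default_rng(59)
        logfc = np.zeros((n, 2))
        hot = rng.choice(n, size=20, replace=False)
        logfc[hot, 1] = np.log(2.0)
        out = _two_condition_sim(n, seed=59, logfc=logfc)
        res = compare_conditions(out.dataset, Hypothesis(("condition",), ()))
        called = res["fdr"].to_numpy() < 0.05
        truth = np.zeros(n, dtype=bool)
        truth[hot] = True
        assert called[truth].mean() >= 0.5  # power
        if called.any():
            assert (~truth[called]).mean() <= 0.10  # empirical FDR
        # effect sizes on the log2 scale near 1 for true positives
        assert np.median(res["logfc"].to_numpy()[truth]) == pytest.approx(1.0, abs=0.25)

    def test_statistic_invariant_to_reference_level(self):
        out = _two_condition_sim(10, seed=61, logfc=[0.0, 0.4])
        ds = out.dataset
        res1 = compare_conditions(ds, Hypothesis(("condition",), ()))
        # relabel levels so the lexical reference flips (c1<c2 vs z1>a2)
        ds.rna_annotation = ds.rna_annotation.replace(
            {"condition": {"c1": "z1", "c2": "a2"}}
        )
        res2 = compare_conditions(ds, Hypothesis(("condition",), ()))
        np.testing.assert_allclose(
            res1["statistic"], res2["statistic"], rtol=1e-3, atol=1e-3
        )

    def test_control_offset_removes_global_shift(self):
        # every sequence (controls included) doubles in condition 2: with
        # correction candidates look null, without it everything is called
        out = _two_condition_sim(
            60, seed=67, logfc=[0.0, np.log(2.0)], n_controls=20
        )
        hyp = Hypothesis(("condition",), ())
        res_c = compare_conditions(out.dataset, hyp, use_controls=True)
        res_u = compare_conditions(out.dataset, hyp, use_controls=False)
        assert kstest(res_c["pvalue"].dropna(), "uniform").pvalue > 0.01
        assert (res_u["fdr"] < 0.05).mean() > 0.9

    def test_controls_required_when_requested(self):
        out = _two_condition_sim(5, seed=71)
        with pytest.raises(ValueError, match="control"):
            compare_conditions(
                out.dataset, Hypothesis(("condition",), ()), use_controls=True
            )


class TestTemporal:
    def _temporal_sim(self, profiles, seed=73, n_barcodes=20):
        n, t = profiles.shape
        return simulate_nb(
            SimConfig(
                alphas=np.ones(n),
                n_sequences=n,
                n_barcodes=n_barcodes,
                n_batches=3,
                n_conditions=t,
                condition_logfc=profiles,
                seed=seed,
            )
        )

    def test_flat_profiles_are_calibrated(self):
        out = self._temporal_sim(np.zeros((80, 4)))
        ds = out.dataset
        ds.rna_annotation = ds.rna_annotation.rename(columns={"condition": "time"})
        res = temporal_test(ds)
        assert (res["df"] == 3).all()
        assert kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_impulse_profile_is_detected(self):
        # impulse-like activation across 7 timepoints at high depth
        impulse = np.array([[0, 0.4, 1.2, 1.5, 1.2, 0.6, 0.2]])
        out = self._temporal_sim(impulse, seed=79, n_barcodes=30)
        ds = out.dataset
        ds.rna_annotation = ds.rna_annotation.rename(columns={"condition": "time"})
        res = temporal_test(ds)
        assert res["pvalue"].iloc[0] < 1e-4

    def test_two_timepoints_reduce_to_condition_comparison(self):
        out = self._temporal_sim(np.tile([0.0, 0.5], (6, 1)), seed=83)
        ds = out.dataset
        ds.rna_annotation = ds.rna_annotation.rename(columns={"condition": "time"})
        res_t = temporal_test(ds)
        res_c = compare_conditions(ds, Hypothesis(("batch", "time"), ("batch",)))
        np.testing.assert_allclose(res_t["pvalue"], res_c["pvalue"], rtol=1e-6)


class TestAllelic:
    def _allelic_ds(
        self, effects, seed, n_bc_ref=8, n_bc_alt=8, depth=6.0, reps=3
    ):
        """Two alleles with distinct barcode sets sharing one DNA library.

        ``effects`` maps cell type name -> log allele effect (alt vs ref);
        a single shared pre-transduction DNA replicate serves every RNA
        sample, Mattioli-style.
        """
        rng = np.random.default_rng(seed)
        k = 10.0
        # wild type named so it is the lexical reference level
        bcs = [f"b{i:03d}" for i in range(n_bc_ref + n_bc_alt)]
        allele = ["ref"] * n_bc_ref + ["var"] * n_bc_alt
        dna_annot = pd.DataFrame(
            {"barcode": bcs, "allele": allele}, index=pd.Index(bcs, name="obs")
        )
        eta = depth + rng.normal(0, 0.3, len(bcs))
        mu_d = np.exp(eta)
        d = rng.negative_binomial(k, k / (k + mu_d)).astype(np.int64)
        rna_rows, mu_r = [], []
        for ct, effect in effects.items():
            for j in range(reps):
                for i, (bc, al) in enumerate(zip(bcs, allele)):
                    row = {"obs": f"{ct}:{bc}:r{j}", "barcode": bc, "allele": al}
                    if len(effects) > 1:
                        row["celltype"] = ct
                    rna_rows.append(row)
                    mu_r.append(np.exp(eta[i] + (effect if al == "var" else 0.0)))
        rna_annot = pd.DataFrame(rna_rows).set_index("obs")
        mapping = pd.Series(
            {r_["obs"]: r_["barcode"] for r_ in rna_rows}, name="dna_obs"
        )
        r = rng.negative_binomial(
            k, k / (k + np.asarray(mu_r))
        ).astype(np.int64)
        from mpraglm import MPRADataset

        return MPRADataset(
            dna_counts=pd.DataFrame([d], index=["pair1"], columns=dna_annot.index),
            rna_counts=pd.DataFrame([r], index=["pair1"], columns=rna_annot.index),
            dna_annotation=dna_annot,
            rna_annotation=rna_annot,
            rna_to_dna_map=mapping,
        )

    def test_identical_alleles_are_not_called(self):
        ps = []
        for seed in range(6):
            ds = self._allelic_ds({"K562": 0.0}, seed=101 + seed)
            res = allelic_test(ds, sequence_ids=["pair1"])
            ps.append(res["pvalue"].iloc[0])
        assert min(ps) > 0.001 and np.median(ps) > 0.05

    def test_asymmetric_barcode_design_recovers_effect(self):
        # reference allele carries many more barcodes than the alternative
        effect = -0.8
        ds = self._allelic_ds({"K562": effect}, seed=107, n_bc_ref=80, n_bc_alt=26)
        res = allelic_test(ds, sequence_ids=["pair1"])
        assert res["pvalue"].iloc[0] < 1e-3
        assert res["logfc"].iloc[0] * np.log(2) == pytest.approx(effect, rel=0.1)

    def test_wrong_level_count_raises(self):
        ds = self._allelic_ds({"K562": 0.0}, seed=109)
        ds.rna_annotation["allele"] = "only_one"
        with pytest.raises(ValueError, match="exactly 2"):
            allelic_test(ds)

    def test_interaction_mode_detects_celltype_specific_effect(self):
        # allele effect -0.8 in HepG2 vs -0.1 in K562, one shared DNA library
        ds = self._allelic_ds(
            {"HepG2": -0.8, "K562": -0.1},
            seed=113,
            n_bc_ref=30,
            n_bc_alt=30,
            depth=7.0,
        )
        res = allelic_test(
            ds, celltype_factor="celltype", mode="interaction", sequence_ids=["pair1"]
        )
        assert res["pvalue"].iloc[0] < 0.01
        null = self._allelic_ds(
            {"HepG2": -0.5, "K562": -0.5}, seed=131, n_bc_ref=30, n_bc_alt=30
        )
        res0 = allelic_test(
            null, celltype_factor="celltype", mode="interaction", sequence_ids=["pair1"]
        )
        assert res0["pvalue"].iloc[0] > 0.01
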