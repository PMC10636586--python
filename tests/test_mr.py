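"""Mendelian randomization estimators, clumping, harmonization, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import warnings

from pygsem import mr
from pygsem.simulate import (TruthModel, plant_instruments, simulate_sumstats,
                             simulate_true_effects)
from pygsem.sumstats import SumstatsTable

from conftest import ld_ref_frame


def make_iset(bx, by, sxse=None, syse=None, **meta):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    n = len(bx)
    sxse = np.full(n, 0.01) if sxse is None else np.asarray(sxse, dtype=float)
    syse = np.full(n, 0.01) if syse is None else np.asarray(syse, dtype=float)
    table = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n)],
        "CHR": 1, "BP": np.arange(n) * 1_000_000,
        "A1": "A", "A2": "G",
        "beta_exp": bx, "se_exp": sxse, "p_exp": 1e-10,
        "n_exp": 1.0 / sxse ** 2,
        "beta_out": by, "se_out": syse, "p_out": 0.5,
        "n_out": 1.0 / syse ** 2,
    })
    return mr.InstrumentSet(table, p_threshold=5e-8, window_kb=10_000,
                            r2_cap=0.001, **meta)


def _mk_sumstats(rows):
    df = pd.DataFrame(rows)
    df["Z"] = df["BETA"] / df["SE"]
    return SumstatsTable(df, name="exp", validate=False)


def _row(snp, chr_, bp, p, beta=0.1, a1="A", a2="G"):
    return {"SNP": snp, "CHR": chr_, "BP": bp, "A1": a1, "A2": a2,
            "BETA": beta, "SE": 0.01, "P": p, "N": 1e5}


class TestSelectInstruments:
    def test_correlated_nearby_snps_clumped_to_best(self):
        # 5,000 kb apart, r2 = 0.2 > cap: only the smaller p survives
        t = _mk_sumstats([_row("rs1", 1, 1_000_000, 1e-10),
                          _row("rs2", 1, 6_000_000, 1e-9)])
        ld_ref = pd.DataFrame({"SNP": ["rs1", "rs2"], "BLOCK": [0, 0],
                               "R2": [0.2, 0.2]})
        out = mr.select_instruments(t, ld_ref)
        assert list(out.table["SNP"]) == ["rs1"]

    def test_different_chromosomes_never_clumped(self):
        t = _mk_sumstats([_row("rs1", 1, 1_000_000, 1e-10),
                          _row("rs2", 2, 1_000_000, 1e-9)])
        ld_ref = pd.DataFrame({"SNP": ["rs1", "rs2"], "BLOCK": [0, 0],
                               "R2": [0.9, 0.9]})
        out = mr.select_instruments(t, ld_ref)
        assert len(out) == 2

    def test_independent_blocks_within_window_both_kept(self):
        t = _mk_sumstats([_row("rs1", 1, 1_000_000, 1e-10),
                          _row("rs2", 1, 2_000_000, 1e-9)])
        ld_ref = pd.DataFrame({"SNP": ["rs1", "rs2"], "BLOCK": [0, 1],
                               "R2": [0.5, 0.5]})
        out = mr.select_instruments(t, ld_ref)
        assert len(out) == 2

    def test_threshold_strict(self):
        t = _mk_sumstats([_row("rs1", 1, 1, 5e-8), _row("rs2", 1, 2_000_000, 4.9e-8)])
        out = mr.select_instruments(t, None)
        assert list(out.table["SNP"]) == ["rs2"]

    def test_planted_instruments_all_survive_clumping(self, ld_small):
        truth = TruthModel.from_standardized(
            [[0.3], [0.3]], [[1.0]], [0.02, 0.02], [1e5, 1e5],
            trait_names=["a", "b"])
        eff = simulate_true_effects(truth, ld_small, 1.0, seed=61)
        eff, reg = plant_instruments(truth, ld_small, 11, 0.05, seed=62,
                                     exposure=("trait", 0), outcome=("trait", 1),
                                     causal_effect=0.5, true_effects=eff)
        tabs = simulate_sumstats(eff, truth, ld_small, seed=63,
                                 protect=reg.snp_indices)
        a = SumstatsTable(tabs[0], name="a")
        out = mr.select_instruments(a, ld_ref_frame(ld_small))
        assert set(reg.snp_ids) <= set(out.table["SNP"])

    def test_no_significant_snps_gives_empty_set(self):
        t = _mk_sumstats([_row("rs1", 1, 1, 0.5)])
        out = mr.select_instruments(t, None)
        assert len(out) == 0


class TestHarmonizeIO:
    def test_swapped_outcome_alleles_flip_beta(self):
        iset = make_iset([0.1, 0.2, 0.3], [0, 0, 0]).table
        iset = iset.drop(columns=["beta_out", "se_out", "p_out", "n_out"])
        instruments = mr.InstrumentSet(iset, 5e-8, 10_000, 0.001)
        out_rows = []
        for i, r in iset.iterrows():
            out_rows.append({"SNP": r["SNP"], "CHR": 1, "BP": r["BP"],
                             "A1": "G", "A2": "A", "BETA": -0.05, "SE": 0.01,
                             "P": 0.01, "N": 1e5})
        outcome = _mk_sumstats(out_rows)
        h = mr.harmonize_io(instruments, outcome)
        np.testing.assert_allclose(h.table["beta_out"], 0.05)
        np.testing.assert_allclose(h.table["beta_exp"], [0.1, 0.2, 0.3])

    def test_absent_instruments_dropped(self):
        base = make_iset([0.1, 0.2, 0.3], [0, 0, 0]).table
        base = base.drop(columns=["beta_out", "se_out", "p_out", "n_out"])
        instruments = mr.InstrumentSet(base, 5e-8, 10_000, 0.001)
        outcome = _mk_sumstats([{"SNP": "rs0", "CHR": 1, "BP": 0, "A1": "A",
                                 "A2": "G", "BETA": 0.02, "SE": 0.01,
                                 "P": 0.01, "N": 1e5},
                                {"SNP": "rs1", "CHR": 1, "BP": 0, "A1": "A",
                                 "A2": "G", "BETA": 0.02, "SE": 0.01,
                                 "P": 0.01, "N": 1e5}])
        h = mr.harmonize_io(instruments, outcome)
        assert set(h.table["SNP"]) == {"rs0", "rs1"}

    def test_too_few_survivors_fail(self):
        base = make_iset([0.1], [0.0]).table.drop(
            columns=["beta_out", "se_out", "p_out", "n_out"])
        instruments = mr.InstrumentSet(base, 5e-8, 10_000, 0.001)
        outcome = _mk_sumstats([{"SNP": "rs0", "CHR": 1, "BP": 0, "A1": "A",
                                 "A2": "G", "BETA": 0.02, "SE": 0.01,
                                 "P": 0.01, "N": 1e5}])
        with pytest.raises(ValueError, match="instrument"):
            mr.harmonize_io(instruments, outcome)


class TestIVW:
    def test_matches_closed_form_weighted_regression(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.2, 12)
        by = 0.4 * bx + rng.normal(0, 0.01, 12)
        syse = rng.uniform(0.005, 0.02, 12)
        iset = make_iset(bx, by, syse=syse)
        res = mr.mr_ivw(iset)
        w = 1.0 / syse ** 2
        closed = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        assert res.beta == pytest.approx(closed, abs=1e-12)

    def test_exact_proportionality_q_zero(self):
        iset = make_iset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20],
                         syse=[0.01, 0.01, 0.02])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mr.mr_ivw(iset)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.2, 15)
        by = 0.4 * bx + rng.normal(0, 0.05, 15)
        iset = make_iset(bx, by)
        re = mr.mr_ivw(iset, random_effects=True)
        fe = mr.mr_ivw(iset, random_effects=False)
        assert re.se >= fe.se

    def test_wald_ratio_single_instrument(self):
        res = mr.wald_ratio(0.5, 0.2, 0.01)
        assert res.beta == pytest.approx(0.4)

    def test_too_few_instruments_fail(self):
        with pytest.raises(ValueError):
            mr.mr_ivw(make_iset([0.1], [0.05]))


class TestEgger:
    def test_proportional_instruments_zero_intercept(self):
        iset = make_iset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20],
                         syse=[0.01, 0.01, 0.02])
        res = mr.mr_egger(iset)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_recovered_noiseless(self):
        # weighted regression on noiseless planted effects: exact recovery
        bx = np.linspace(0.05, 0.3, 10)
        by = 0.4 * bx + 0.05
        res = mr.mr_egger(make_iset(bx, by))
        assert res.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert res.beta == pytest.approx(0.4, abs=1e-10)

    def test_i2gx_tends_to_one_as_exposure_se_vanishes(self):
        bx = np.linspace(0.05, 0.3, 10)
        by = 0.4 * bx
        res_tiny = mr.mr_egger(make_iset(bx, by, sxse=np.full(10, 1e-6)))
        res_big = mr.mr_egger(make_iset(bx, by, sxse=np.full(10, 0.05)))
        assert res_tiny.i2_gx > 0.999999
        assert res_big.i2_gx < res_tiny.i2_gx


class TestWeightedMedian:
    def test_equal_ratios_give_that_ratio(self):
        iset = make_iset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        res = mr.mr_weighted_median(iset, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_symmetric_ratio_set_gives_middle(self):
        iset = make_iset([0.1, 0.1, 0.1], [0.04, 0.05, 0.06])
        res = mr.mr_weighted_median(iset, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-10)

    def test_majority_valid_consistency(self):
        # 5 valid instruments at ratio 0.5, 2 invalid at 5.0, equal weights
        bx = np.full(7, 0.2)
        by = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 1.0, 1.0])
        res = mr.mr_weighted_median(make_iset(bx, by), n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=0.05)

    def test_direct_weighted_median_oracle(self):
        values = np.array([0.2, 0.5, 0.8])
        weights = np.array([1.0, 1.0, 2.0])
        # cumulative weights minus half-weight: 0.125, 0.375, 0.75
        expected = np.interp(0.5, [0.125, 0.375, 0.75], values)
        assert mr._weighted_median(values, weights) == pytest.approx(expected)


class TestWeightedMode:
    def test_equal_ratios_give_that_ratio(self):
        iset = make_iset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        res = mr.mr_weighted_mode(iset, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=1e-3)

    def test_plurality_cluster_wins(self):
        bx = np.full(10, 0.2)
        by = np.concatenate([np.full(7, 0.1), np.full(3, 0.4)])
        by = by + np.random.default_rng(2).normal(0, 0.002, 10)
        res = mr.mr_weighted_mode(make_iset(bx, by), n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=0.1)

    def test_huge_bandwidth_approaches_weighted_mean(self):
        bx = np.full(5, 0.2)
        by = np.array([0.06, 0.08, 0.10, 0.12, 0.14])
        iset = make_iset(bx, by)
        res = mr.mr_weighted_mode(iset, bandwidth_factor=500.0, n_boot=50, seed=1)
        ratio, rse = mr._ratio_estimates(iset)
        wmean = np.average(ratio, weights=1 / rse ** 2)
        assert res.beta == pytest.approx(wmean, abs=0.02)


class TestRAPS:
    def test_collapses_to_ivw_without_measurement_error(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.3, 20)
        by = 0.4 * bx + rng.normal(0, 0.01, 20)
        iset = make_iset(bx, by, sxse=np.full(20, 1e-12))
        fe = mr.mr_ivw(iset, random_effects=False)
        raps = mr.mr_raps(iset, overdispersion=False)
        assert raps.beta == pytest.approx(fe.beta, abs=1e-3)

    def test_less_biased_than_ivw_with_weak_instruments(self):
        """Measurement error in bx dilutes IVW; the profile score corrects it."""
        rng = np.random.default_rng(10)
        n_rep, n_inst = 50, 40
        bias_ivw, bias_raps = [], []
        for _ in range(n_rep):
            true_bx = rng.normal(0, 0.02, n_inst)
            sx = np.full(n_inst, 0.01)       # z ~ 2-3: weak instruments
            bx = true_bx + rng.normal(0, sx)
            by = 0.5 * true_bx + rng.normal(0, 0.01, n_inst)
            iset = make_iset(bx, by, sxse=sx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bias_ivw.append(mr.mr_ivw(iset).beta - 0.5)
                bias_raps.append(mr.mr_raps(iset, overdispersion=False).beta - 0.5)
        assert abs(np.mean(bias_raps)) < abs(np.mean(bias_ivw))

    def test_balanced_pleiotropy_absorbed_by_overdispersion(self):
        rng = np.random.default_rng(11)
        n = 30
        bx = rng.uniform(0.1, 0.3, n)
        pleio = rng.normal(0, 0.03, n)
        by = 0.5 * bx + pleio + rng.normal(0, 0.005, n)
        res = mr.mr_raps(make_iset(bx, by, syse=np.full(n, 0.005)),
                         overdispersion=True)
        assert res.overdispersion > 0
        assert abs(res.beta - 0.5) < 2.5 * res.se


class TestCochranQ:
    def test_proportional_data_q_zero_p_one(self):
        iset = make_iset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        q, df, p = mr.cochran_q(iset, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        bx = np.array([0.1, 0.2])
        by = np.array([0.06, 0.08])
        syse = np.array([0.01, 0.02])
        iset = make_iset(bx, by, syse=syse)
        w = 1 / syse ** 2
        beta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        q, df, p = mr.cochran_q(iset, beta)
        assert df == 1
        expected = np.sum(w * (by - beta * bx) ** 2)
        assert q == pytest.approx(expected, rel=1e-12)

    def test_planted_outliers_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(50):
            bx = rng.uniform(0.1, 0.3, 12)
            by = 0.5 * bx + rng.normal(0, 0.01, 12)
            by[:3] += rng.choice([-1, 1], 3) * 0.08   # heterogeneous outliers
            iset = make_iset(bx, by)
            beta = mr.mr_ivw(iset).beta
            _, _, p = mr.cochran_q(iset, beta)
            hits += p < 0.05
        assert hits >= 45   # >= 90% of 50 seeds

    def test_undefined_df_flagged(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.1])
        with pytest.warns(UserWarning, match="undefined"):
            q, df, p = mr.cochran_q(iset, 0.5, with_intercept=True)
        assert np.isnan(q)


class TestSteiger:
    def test_strictly_greater_exposure_r2_kept(self):
        # instrument 1 strongly exposure-first, instrument 2 equal r2
        bx = np.array([0.10, 0.05])
        by = np.array([0.01, 0.05])
        iset = make_iset(bx, by)
        out = mr.steiger_filter(iset)
        assert bool(out.table["steiger_keep"][0])
        assert not bool(out.table["steiger_keep"][1])   # equal r2 -> dropped

    def test_reverse_causal_planted_snps_dropped(self, ld_small):
        rng_seeds = range(50)
        dropped = 0
        truth = TruthModel.from_standardized(
            [[0.3], [0.3]], [[1.0]], [0.02, 0.02], [1e5, 1e5],
            trait_names=["a", "b"])
        for seed in rng_seeds:
            eff = simulate_true_effects(truth, ld_small, 1.0, seed=3000 + seed)
            # outcome-first SNP: large effect on b, a receives only 0.3x
            eff, reg = plant_instruments(truth, ld_small, 1, 0.05,
                                         seed=4000 + seed,
                                         exposure=("trait", 1),
                                         outcome=("trait", 0),
                                         causal_effect=0.3, true_effects=eff)
            tabs = simulate_sumstats(eff, truth, ld_small, seed=5000 + seed,
                                     protect=reg.snp_indices)
            a = SumstatsTable(tabs[0], name="a")
            b = SumstatsTable(tabs[1], name="b")
            idx = reg.snp_ids[0]
            arow = a.df.set_index("SNP").loc[idx]
            brow = b.df.set_index("SNP").loc[idx]
            t = pd.DataFrame([{
                "SNP": idx, "CHR": 1, "BP": 0, "A1": "A", "A2": "G",
                "beta_exp": arow["BETA"], "se_exp": arow["SE"],
                "p_exp": arow["P"], "n_exp": arow["N"],
                "beta_out": brow["BETA"], "se_out": brow["SE"],
                "p_out": brow["P"], "n_out": brow["N"]}])
            iset = mr.InstrumentSet(t, 5e-8, 10_000, 0.001)
            out = mr.steiger_filter(iset)
            dropped += not bool(out.table["steiger_keep"][0])
        assert dropped >= 0.95 * 50

    def test_missing_n_fails(self):
        t = make_iset([0.1, 0.2], [0.05, 0.1]).table.drop(columns=["n_out"])
        iset = mr.InstrumentSet(t, 5e-8, 10_000, 0.001)
        with pytest.raises(ValueError, match="sample size"):
            mr.steiger_filter(iset)


class TestInvariances:
    @pytest.mark.parametrize("method", ["ivw", "egger", "wmedian", "wmode", "raps"])
    def test_order_and_sign_flip_invariance(self, method):
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        iset = make_iset(bx, by)
        perm = rng.permutation(10)
        flip = rng.choice([-1.0, 1.0], 10)
        iset2 = make_iset((bx * flip)[perm], (by * flip)[perm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = mr.MRModel(iset, seed=3).fit(method)
            r2 = mr.MRModel(iset2, seed=3).fit(method)
        tol = 1e-10 if method in ("ivw", "egger") else 5e-2
        assert r1.beta == pytest.approx(r2.beta, abs=tol)


class TestBidirectional:
    def test_relaxed_threshold_never_fewer_instruments(self, ld_small):
        truth = TruthModel.from_standardized(
            [[0.3], [0.3]], [[1.0]], [0.05, 0.05], [5e4, 5e4],
            trait_names=["a", "b"])
        eff = simulate_true_effects(truth, ld_small, 1.0, seed=91)
        eff, reg = plant_instruments(truth, ld_small, 10, 0.03, seed=92,
                                     exposure=("trait", 0), outcome=("trait", 1),
                                     causal_effect=0.5, true_effects=eff)
        tabs = simulate_sumstats(eff, truth, ld_small, seed=93,
                                 protect=reg.snp_indices)
        a = SumstatsTable(tabs[0], name="a")
        strict = mr.select_instruments(a, ld_ref_frame(ld_small), 5e-8)
        relaxed = mr.select_instruments(a, ld_ref_frame(ld_small), 5e-7)
        assert len(relaxed) >= len(strict)

    def test_one_direction_without_instruments_reported_not_fatal(self, ld_small):
        truth = TruthModel.from_standardized(
            [[0.3], [0.3]], [[1.0]], [0.02, 0.02], [2e4, 2e4],
            trait_names=["a", "b"])
        eff = simulate_true_effects(truth, ld_small, 1.0, seed=94)
        # instruments only for a
        eff, reg = plant_instruments(truth, ld_small, 10, 0.06, seed=95,
                                     exposure=("trait", 0), outcome=("trait", 1),
                                     causal_effect=0.5, true_effects=eff)
        tabs = simulate_sumstats(eff, truth, ld_small, seed=96,
                                 protect=reg.snp_indices)
        a = SumstatsTable(tabs[0], name="a")
        b = SumstatsTable(tabs[1], name="b")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mr.bidirectional_mr(a, b, ld_ref_frame(ld_small), seed=5,
                                      methods=("ivw",))
        assert res.forward.status == "ok"
        assert len(res.forward.results) == 1
        frame = res.to_frame()
        assert (frame["exposure"] == "a").any()
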