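"""DE engine: size factors, dispersions, Wald contrasts, shrinkage, BH."""

import numpy as np
import pandas as pd
import pytest

import shutoffseq.conditions as cond
from shutoffseq.conditions import ContrastSpec
from shutoffseq.de import (
    ContrastResult,
    NormalizationError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    merge_contrasts,
    run_contrasts,
    shrink_lfc,
)
from shutoffseq.de import test_contrast as nb_wald_contrast
from shutoffseq.simulate import build_design, default_config, generate_truth, simulate_counts


def _two_group_design(n, cond_a="untreated", cond_b="bic_1h"):
    design = build_design(n)
    return design[design["condition"].isin([cond_a, cond_b])].reset_index(drop=True)


def _nb_counts(rng, mu, alpha, size):
    if alpha == 0:
        return rng.poisson(mu, size=size)
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]},
                              index=["g1", "g2", "g3"])
        norm = estimate_size_factors(counts)
        assert np.allclose(norm.size_factors, [1.0, 1.0])

    def test_threefold_sample_recovers_centered_closed_form(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 500, size=200)
        counts = pd.DataFrame({"a": base, "b": 3 * base})
        norm = estimate_size_factors(counts)
        assert np.allclose(norm.size_factors, [3 ** -0.5, 3 ** 0.5])
        # centered: geometric mean 1
        assert np.isclose(np.exp(np.log(norm.size_factors).mean()), 1.0)

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((3, 2), dtype=int), columns=["a", "b"])
        with pytest.raises(NormalizationError):
            estimate_size_factors(counts)


class TestDispersions:
    def _fixture(self, alpha, n_rep=50, n_genes=200, mean=100.0, seed=0):
        rng = np.random.default_rng(seed)
        x = _nb_counts(rng, mean, alpha, (n_genes, n_rep))
        counts = pd.DataFrame(x, columns=[f"s{i}" for i in range(n_rep)])
        design = pd.DataFrame(
            {"sample_id": counts.columns, "condition": "untreated",
             "protocol": "none", "treatment": "untreated", "time_h": 0.0,
             "replicate": range(n_rep)}
        )
        norm = estimate_size_factors(counts)
        return counts, norm, design

    def test_poisson_counts_give_near_zero_dispersion(self):
        counts, norm, design = self._fixture(alpha=0.0)
        disp = estimate_dispersions(counts, norm, design, trend_weight=0.0)
        assert disp.alpha.median() <= 0.01

    def test_nb_dispersion_recovered_within_20pct(self):
        counts, norm, design = self._fixture(alpha=0.5, seed=3)
        disp = estimate_dispersions(counts, norm, design, trend_weight=0.0)
        assert abs(disp.alpha.mean() - 0.5) <= 0.1

    def test_constant_replicates_floored_and_flagged(self):
        counts = pd.DataFrame({"a": [50, 7], "b": [50, 7], "c": [50, 7]})
        design = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "condition": "untreated",
             "protocol": "none", "treatment": "untreated", "time_h": 0.0,
             "replicate": [1, 2, 3]}
        )
        norm = estimate_size_factors(counts)
        disp = estimate_dispersions(counts, norm, design, trend_weight=0.0)
        assert np.allclose(disp.alpha, 1e-8)
        assert disp.clamped.all()

    def test_single_replicate_everywhere_rejected(self):
        counts = pd.DataFrame({"a": [5], "b": [7]})
        design = pd.DataFrame(
            {"sample_id": ["a", "b"], "condition": ["untreated", "bic_1h"],
             "protocol": ["none", "bic"], "treatment": ["untreated", "bic"],
             "time_h": [0.0, 1.0], "replicate": [1, 1]}
        )
        norm = estimate_size_factors(counts)
        with pytest.raises(NormalizationError):
            estimate_dispersions(counts, norm, design)


class TestWaldContrast:
    def test_twofold_difference_recovered(self):
        # symmetric DE (10% up, 10% down) keeps median-of-ratios unbiased
        rng = np.random.default_rng(5)
        n_genes, n_rep = 500, 5
        n_up = 50
        mu_b = np.full(n_genes, 200.0)
        mu_b[:n_up] = 400.0
        mu_b[n_up:2 * n_up] = 100.0
        a = _nb_counts(rng, 200.0, 0.05, (n_genes, n_rep))
        b = np.column_stack(
            [_nb_counts(rng, mu_b, 0.05, n_genes) for _ in range(n_rep)]
        )
        counts = pd.DataFrame(
            np.hstack([a, b]),
            columns=[f"untreated_r{i}" for i in range(n_rep)]
            + [f"bic_1h_r{i}" for i in range(n_rep)],
        )
        design = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "condition": ["untreated"] * n_rep + ["bic_1h"] * n_rep,
                "protocol": "x", "treatment": "x", "time_h": 0.0,
                "replicate": list(range(n_rep)) * 2,
            }
        )
        norm = estimate_size_factors(counts)
        disp = estimate_dispersions(counts, norm, design)
        res = nb_wald_contrast(counts, norm, disp,
                            ContrastSpec("t", "bic_1h", "untreated"), design)
        assert 0.9 <= res.table["l2fc_mle"].iloc[:n_up].median() <= 1.1
        # strong effect at high counts: essentially everything significant
        assert (res.table["fdr"].iloc[:n_up] < 0.05).mean() > 0.9
        assert abs(res.table["l2fc_mle"].iloc[n_up:].median()) < 0.05

    def test_gene_all_zero_in_both_groups_is_na(self, ):
        counts = pd.DataFrame(
            {"a1": [10, 0], "a2": [12, 0], "b1": [9, 0], "b2": [11, 0]},
            index=["g1", "g2"],
        )
        design = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "condition": ["untreated", "untreated", "bic_1h", "bic_1h"],
             "protocol": "x", "treatment": "x", "time_h": 0.0,
             "replicate": [1, 2, 1, 2]}
        )
        norm = estimate_size_factors(counts)
        disp = estimate_dispersions(counts, norm, design)
        res = nb_wald_contrast(counts, norm, disp,
                            ContrastSpec("t", "bic_1h", "untreated"), design)
        assert res.table.loc["g2", "status"] == "NA"
        assert res.table.loc["g2", ["l2fc_mle", "pvalue", "fdr"]].isna().all()
        assert res.table.loc["g1", "status"] == "ok"

    def test_zero_in_one_group_flagged_with_continuity_correction(self):
        counts = pd.DataFrame(
            {"a1": [10, 30], "a2": [12, 35], "b1": [9, 0], "b2": [11, 0]},
            index=["g1", "g2"],
        )
        design = pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "condition": ["untreated", "untreated", "bic_1h", "bic_1h"],
             "protocol": "x", "treatment": "x", "time_h": 0.0,
             "replicate": [1, 2, 1, 2]}
        )
        norm = estimate_size_factors(counts)
        disp = estimate_dispersions(counts, norm, design)
        res = nb_wald_contrast(counts, norm, disp,
                            ContrastSpec("t", "bic_1h", "untreated"), design)
        assert bool(res.table.loc["g2", "flagged"])
        assert np.isfinite(res.table.loc["g2", "l2fc_mle"])
        assert res.table.loc["g2", "l2fc_mle"] < -3  # strong depletion

    def test_unknown_condition_rejected(self, small_experiment):
        exp = small_experiment
        norm = estimate_size_factors(exp.counts, exp.design)
        disp = estimate_dispersions(exp.counts, norm, exp.design)
        with pytest.raises(ValueError):
            nb_wald_contrast(exp.counts, norm, disp,
                          ContrastSpec("t", "bic_9h", "untreated"), exp.design)


class TestScalingInvariance:
    def test_rescaling_one_sample_moves_its_factor_and_not_the_statistics(self):
        # well-expressed genes: NB information is dispersion-dominated there,
        # so the statistics are insensitive to the raw scale of one sample
        cfg = default_config(n_genes=300, n_replicates=4, seed=13,
                             baseline_meanlog=6.0, baseline_sdlog=0.5)
        truth = generate_truth(cfg)
        design = _two_group_design(4)
        counts = simulate_counts(truth, design, cfg)
        scaled = counts.copy()
        target = counts.columns[0]
        scaled[target] = counts[target] * 3

        norm0 = estimate_size_factors(counts)
        norm1 = estimate_size_factors(scaled)
        other = counts.columns[1]
        ratio0 = norm0.size_factors[target] / norm0.size_factors[other]
        ratio1 = norm1.size_factors[target] / norm1.size_factors[other]
        assert np.isclose(ratio1, 3 * ratio0, rtol=1e-9)

        spec = ContrastSpec("t", "bic_1h", "untreated")
        disp0 = estimate_dispersions(counts, norm0, design)
        disp1 = estimate_dispersions(scaled, norm1, design)
        r0 = nb_wald_contrast(counts, norm0, disp0, spec, design).table
        r1 = nb_wald_contrast(scaled, norm1, disp1, spec, design).table
        ok = (r0["status"] == "ok") & (r1["status"] == "ok")
        # invariance is approximate for NB inference (the rescaled sample
        # genuinely carries less relative shot noise); fold changes move by
        # far less than any decision threshold and calls are stable
        assert np.allclose(r0.loc[ok, "l2fc_mle"], r1.loc[ok, "l2fc_mle"], atol=0.05)
        dp = (r0.loc[ok, "pvalue"] - r1.loc[ok, "pvalue"]).abs()
        assert (dp > 0.05).mean() < 0.02
        calls0 = r0.loc[ok, "fdr"] < 0.05
        calls1 = r1.loc[ok, "fdr"] < 0.05
        assert (calls0 == calls1).mean() >= 0.99


class TestShrinkage:
    @staticmethod
    def _table(lfc, se):
        t = pd.DataFrame(
            {"base_mean": 100.0, "l2fc_mle": lfc, "l2fc_shrunk": np.nan,
             "se": se, "pvalue": 0.5, "fdr": 0.5, "status": "ok", "flagged": False},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return ContrastResult(ContrastSpec("t", "a", "b"), t)

    def test_zero_stays_zero_and_na_passes_through(self):
        res = self._table([0.0, 2.0], [0.1, 0.1])
        res.table.loc["g1", "status"] = "NA"
        res.table.loc["g1", ["l2fc_mle", "se"]] = np.nan
        shrink_lfc(res, prior_scale=0.5)
        assert res.table.loc["g0", "l2fc_shrunk"] == 0.0
        assert np.isnan(res.table.loc["g1", "l2fc_shrunk"])

    def test_noisy_estimate_shrinks_hard(self):
        res = self._table([2.0], [10.0])  # se >> prior scale
        shrink_lfc(res, prior_scale=0.5)
        assert abs(res.table["l2fc_shrunk"].iloc[0]) < 0.5 * 2.0

    def test_precise_estimate_nearly_unshrunk(self):
        res = self._table([2.0], [1e-6])
        shrink_lfc(res, prior_scale=0.5)
        assert np.isclose(res.table["l2fc_shrunk"].iloc[0], 2.0, atol=1e-6)

    def test_matches_conjugate_posterior_mode(self):
        rng = np.random.default_rng(8)
        lfc = rng.normal(0, 2, 50)
        se = rng.uniform(0.05, 3, 50)
        res = self._table(lfc, se)
        tau = 0.8
        shrink_lfc(res, prior_scale=tau)
        expected = lfc * tau**2 / (tau**2 + se**2)
        assert np.allclose(res.table["l2fc_shrunk"], expected, atol=1e-8)
        # shrinkage never flips sign, never grows magnitude
        assert np.all(np.sign(res.table["l2fc_shrunk"]) == np.sign(lfc))
        assert np.all(np.abs(res.table["l2fc_shrunk"]) <= np.abs(lfc) + 1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_worked_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(out, [0.03, 0.03, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_excluded_from_m(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.02, 0.04]))
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2, 3]], [0.03, 0.03, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestMergedTable:
    def test_union_of_analysis_ready_genes(self, small_experiment):
        exp = small_experiment
        results = run_contrasts(exp.counts, exp.design)
        merged = merge_contrasts(results)
        # set-union oracle straight from the per-contrast status columns
        union = set()
        for res in results.values():
            union |= set(res.table.index[res.table["status"] == "ok"])
        assert set(merged.index) == union

    def test_pydeseq2_cross_check_on_size_factors_and_lfc(self):
        # independent engine as oracle on a small two-condition fixture
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        cfg = default_config(n_genes=300, n_replicates=5, seed=17)
        truth = generate_truth(cfg)
        design = _two_group_design(5, "untreated", "bic_2h")
        counts = simulate_counts(truth, design, cfg)

        meta = pd.DataFrame({"condition": design["condition"].to_numpy()},
                            index=design["sample_id"])
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.fit_size_factors()
        ref_sf = pd.Series(dds.obs["size_factors"].to_numpy(), index=counts.columns)
        ref_sf = ref_sf / np.exp(np.log(ref_sf).mean())  # center like ours

        norm = estimate_size_factors(counts)
        assert np.allclose(norm.size_factors, ref_sf, rtol=1e-6)

        dds.deseq2()
        from pydeseq2.ds import DeseqStats

        stats = DeseqStats(dds, contrast=["condition", "bic_2h", "untreated"], quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"]

        disp = estimate_dispersions(counts, norm, design)
        mine = nb_wald_contrast(counts, norm, disp,
                             ContrastSpec("t", "bic_2h", "untreated"), design)
        both = pd.DataFrame({"ref": ref, "mine": mine.table["l2fc_mle"]}).dropna()
        assert both["ref"].corr(both["mine"]) > 0.98
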