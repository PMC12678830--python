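"""Generator behaviour: configured means, labels, determinism, NB sampling."""

import numpy as np
import pandas as pd
import pytest

import shutoffseq.conditions as cond
from shutoffseq.simulate import (
    ConfigurationError,
    EffectComponent,
    build_design,
    condition_means,
    default_config,
    generate_truth,
    simulate_counts,
    truth_eval,
)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            default_config(archetype_fractions={"unresponsive": 0.5, "late.induced": 0.3})

    def test_multipliers_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            default_config(
                effect_components=(EffectComponent("bad", 1.0, passive=0.0),)
            )

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ConfigurationError):
            default_config(archetype_fractions={"immediate": 1.0})


class TestTruth:
    def test_unresponsive_genes_have_constant_condition_means(self):
        cfg = default_config(n_genes=50, archetype_fractions={"unresponsive": 1.0}, seed=3)
        truth = generate_truth(cfg)
        means = condition_means(truth)
        assert np.allclose(means.to_numpy(), means.iloc[:, [0]].to_numpy())

    def test_active_effect_is_a_multiplier_on_the_ttx_condition(self):
        cfg = default_config(
            n_genes=20,
            archetype_fractions={"late.induced": 1.0},
            effect_components=(EffectComponent("x", 1.0, passive=1.0, active=0.25),),
            seed=0,
        )
        truth = generate_truth(cfg)
        means = condition_means(truth)
        assert np.allclose(means[cond.LP_TTX_NMDA], 0.25 * means[cond.LP_TTX])
        # and the late kinetics: rising from 1 h to 2 h, peak fold F at 2 h
        assert np.allclose(means[cond.BIC_2H], cfg.induction_fold * means[cond.UNTREATED])
        assert (means[cond.BIC_2H] > means[cond.BIC_1H]).all()

    def test_archetype_proportions_are_quota_exact_across_seeds(self):
        cfg = default_config(n_genes=10_000)
        counts = {}
        for seed in (11, 12):
            truth = generate_truth(default_config(n_genes=10_000, seed=seed))
            counts[seed] = truth["archetype"].value_counts()
        for arch, frac in cfg.archetype_fractions.items():
            for seed in (11, 12):
                assert abs(counts[seed].get(arch, 0) - frac * 10_000) <= 1
        # lambda draws differ between seeds
        t1 = generate_truth(default_config(n_genes=100, seed=11))
        t2 = generate_truth(default_config(n_genes=100, seed=12))
        assert not np.allclose(t1["baseline"], t2["baseline"])

    def test_every_gene_has_one_archetype_and_full_effect_triple(self):
        truth = generate_truth(default_config(n_genes=500, seed=2))
        assert truth["archetype"].notna().all()
        for col in ("passive_effect", "active_effect", "tboa_effect"):
            assert truth[col].notna().all() and (truth[col] > 0).all()


class TestCounts:
    def test_determinism_bit_identical(self):
        cfg = default_config(n_genes=100, n_replicates=3, seed=9)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        d = build_design(3)
        c1 = simulate_counts(t1, d, cfg)
        c2 = simulate_counts(t2, d, cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_poisson_limit_variance_equals_mean(self):
        # alpha = 0: per-gene variance/mean ratio near 1 at 200 replicates
        cfg = default_config(
            n_genes=300, n_replicates=200, dispersion_mean=0.0,
            lib_size_range=(1.0, 1.0), baseline_meanlog=4.5, baseline_sdlog=0.5,
            archetype_fractions={"unresponsive": 1.0}, seed=21,
        )
        truth = generate_truth(cfg)
        design = build_design(200)
        design = design[design["condition"] == "untreated"].reset_index(drop=True)
        x = simulate_counts(truth, design, cfg)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        big = m >= 50
        ratio = (v[big] / m[big]).to_numpy()
        assert np.mean((ratio > 0.8) & (ratio < 1.25)) >= 0.95

    def test_mean_fidelity_at_many_replicates(self):
        cfg = default_config(
            n_genes=200, n_replicates=500, lib_size_range=(1.0, 1.0),
            baseline_meanlog=5.0, baseline_sdlog=0.5, seed=5,
        )
        truth = generate_truth(cfg)
        design = build_design(500)
        design = design[design["condition"].isin(["untreated", "lp_ttx"])].reset_index(drop=True)
        x = simulate_counts(truth, design, cfg)
        for c in ("untreated", "lp_ttx"):
            cols = design.loc[design["condition"] == c, "sample_id"]
            realized = x[cols].mean(axis=1)
            expected = truth[f"mean.{c}"]
            big = expected >= 50
            rel = np.abs(realized[big] / expected[big] - 1)
            assert rel.max() < 0.05

    def test_zero_replicates_gives_empty_matrix_with_gene_index(self):
        cfg = default_config(n_genes=40, n_replicates=0, seed=1)
        truth = generate_truth(cfg)
        x = simulate_counts(truth, build_design(0), cfg)
        assert x.shape == (40, 0)
        assert list(x.index) == list(truth.index)

    def test_unknown_condition_in_design_rejected(self):
        cfg = default_config(n_genes=10, seed=1)
        truth = generate_truth(cfg)
        design = build_design(2)
        design.loc[0, "condition"] = "bic_4h"
        with pytest.raises(ConfigurationError):
            simulate_counts(truth, design, cfg)


class TestTruthEval:
    @staticmethod
    def _perfect_annotation(truth):
        cls = truth["archetype"].replace({"transient.induced": "transient"})
        ann = pd.DataFrame({"activity_class": cls, "protocol": truth["protocol"]},
                           index=truth.index)
        for comp in ("passive", "active", "tboa"):
            eff = truth[f"{comp}_effect"]
            ann[f"{comp}_call"] = np.where(eff < 1, "down", np.where(eff > 1, "up", "ns"))
        ann["evaluable"] = True
        return ann

    def test_perfect_calls_score_perfectly(self):
        truth = generate_truth(default_config(n_genes=400, seed=4))
        ev = truth_eval(self._perfect_annotation(truth), truth)
        for comp in ("passive", "active", "tboa"):
            assert ev["shutoff"][comp]["sensitivity"] == 1.0
            assert ev["shutoff"][comp]["specificity"] == 1.0
            assert ev["shutoff"][comp]["fdr"] == 0.0
        for arch, scores in ev["activity"].items():
            if isinstance(scores, dict):
                assert scores["sensitivity"] == 1.0

    def test_all_resistant_calls_have_zero_sensitivity(self):
        truth = generate_truth(default_config(n_genes=400, seed=4))
        ann = self._perfect_annotation(truth)
        for comp in ("passive", "active", "tboa"):
            ann[f"{comp}_call"] = "ns"
        ev = truth_eval(ann, truth)
        for comp in ("passive", "active", "tboa"):
            assert ev["shutoff"][comp]["sensitivity"] == 0.0

    def test_mismatched_gene_universe_rejected(self):
        truth = generate_truth(default_config(n_genes=50, seed=4))
        ann = self._perfect_annotation(truth).iloc[:40]
        with pytest.raises(ValueError):
            truth_eval(ann, truth)
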