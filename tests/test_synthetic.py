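"""Generator behavior: determinism, ranges, and the effects it must encode."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import batkit as bk
from batkit.synthetic import (
    CONDITIONS, ConfigurationError, condition_parameters,
    event_population_probabilities, expected_population_fractions,
    expected_response,
)


class TestSampleCohort:
    def test_fields_in_range_and_ids_unique(self):
        cfg = bk.CohortConfig(n_donors=6, seed=1)
        donors = bk.sample_cohort(cfg)
        assert len({d.donor_id for d in donors}) == 6
        for d in donors:
            assert 0.0 <= d.rho <= 1.0
            assert cfg.basophil_freq_range[0] <= d.basophil_freq \
                <= cfg.basophil_freq_range[1]
            assert cfg.baseline_activation_range[0] <= d.baseline_activation \
                <= cfg.baseline_activation_range[1]
            assert d.baseline_activation < d.reactivity <= 1.0
            assert 1 <= d.gina_step <= 5

    def test_same_seed_same_cohort(self):
        cfg = bk.CohortConfig(n_donors=8, seed=3)
        assert bk.sample_cohort(cfg) == bk.sample_cohort(cfg)

    def test_rho_spans_both_responder_classes(self):
        # the BAT-Fc target layout must always produce strong and weak
        # blockade donors in a validation-sized cohort
        for seed in range(100):
            donors = bk.sample_cohort(bk.CohortConfig(n_donors=22, seed=seed))
            rhos = [d.rho for d in donors]
            assert max(rhos) > 0.7 and min(rhos) < 0.3

    @pytest.mark.parametrize("field,value,match", [
        ("n_donors", 1, "n_donors"),
        ("events_per_sample", 10, "events_per_sample"),
        ("missing_fraction_control", 1.5, "missing_fraction_control"),
        ("bat_fc_range", (2.0, 1.0), "bat_fc_range"),
    ])
    def test_invalid_config_names_field(self, field, value, match):
        with pytest.raises(ConfigurationError, match=match):
            bk.CohortConfig(**{field: value})


class TestSimulateEvents:
    def test_deterministic_given_seed(self, small_cohort):
        cfg, donors = small_cohort
        a = bk.simulate_events(donors[0], "ALG", 5000, 7, cfg)
        b = bk.simulate_events(donors[0], "ALG", 5000, 7, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_condition_rejected(self, small_cohort):
        cfg, donors = small_cohort
        with pytest.raises(ValueError):
            bk.simulate_events(donors[0], "HEAT", 1000, 0, cfg)

    def test_population_shares_sum_to_one(self, small_cohort):
        cfg, donors = small_cohort
        for d in donors:
            for c in CONDITIONS:
                probs = event_population_probabilities(d, c, cfg)
                assert math.isclose(sum(probs.values()), 1.0, abs_tol=1e-12)
                assert all(0.0 <= p <= 1.0 for p in probs.values())

    def test_control_activation_matches_baseline(self, small_cohort, gate_cfg):
        from batkit.gating import count_populations

        cfg, donors = small_cohort
        d = donors[0]
        events = bk.simulate_events(d, "CTRL", 50_000, 11, cfg)
        pc = count_populations(events, gate_cfg)
        p = d.baseline_activation
        se = math.sqrt(p * (1 - p) / pc.n_basophil_intact)
        assert abs(pc.frac_cd63pos_of_basophils - p) < 3 * se

    def test_allergen_raises_activation_and_altered_share(self, small_cohort,
                                                          gate_cfg):
        from batkit.gating import count_populations

        cfg, donors = small_cohort
        d = donors[1]
        ctrl = count_populations(bk.simulate_events(d, "CTRL", 50_000, 5, cfg),
                                 gate_cfg)
        alg = count_populations(bk.simulate_events(d, "ALG", 50_000, 5, cfg),
                                gate_cfg)
        assert alg.frac_cd63pos_of_basophils > ctrl.frac_cd63pos_of_basophils
        n_put = alg.n_basophil_intact + alg.n_basophil_altered
        miss = cfg.missing_fraction_allergen
        se = math.sqrt(miss * (1 - miss) / n_put)
        assert abs(alg.frac_altered_of_putative - miss) < 3 * se

    def test_full_blockade_indistinguishable_from_control(self, small_cohort,
                                                          gate_cfg):
        """rho = 1: allergen+omalizumab activation equals baseline
        (two-proportion z-test, alpha = 0.01, 50k events)."""
        from batkit.gating import count_populations

        cfg, donors = small_cohort
        d = dataclasses.replace(donors[2], rho=1.0)
        ctrl = count_populations(bk.simulate_events(d, "CTRL", 50_000, 9, cfg),
                                 gate_cfg)
        oma = count_populations(
            bk.simulate_events(d, "ALG_OMA", 50_000, 9, cfg), gate_cfg)
        x1, n1 = ctrl.n_cd63pos, ctrl.n_basophil_intact
        x2, n2 = oma.n_cd63pos, oma.n_basophil_intact
        p_pool = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / math.sqrt(
            p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert abs(z) < stats.norm.ppf(0.995)

    def test_blockade_monotone_in_rho(self, small_cohort):
        cfg, donors = small_cohort
        base = donors[3]
        activated = [
            condition_parameters(dataclasses.replace(base, rho=r),
                                 "ALG_OMA", cfg)[0]
            for r in np.linspace(0, 1, 21)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(activated, activated[1:]))

    def test_expected_fractions_internally_consistent(self, small_cohort):
        cfg, donors = small_cohort
        f = expected_population_fractions(donors[0], "ALG", cfg)
        assert 0.9 < f["singlet_of_total"] < 1.0
        assert f["altered_of_putative"] == pytest.approx(
            cfg.missing_fraction_allergen)


class TestSimulateExpression:
    def test_length_mismatch_rejected(self, small_cohort):
        cfg, donors = small_cohort
        with pytest.raises(ValueError, match="mismatch"):
            bk.simulate_expression(donors, [1.0], bk.ExpressionConfig())

    def test_null_slope_correlation_centered_on_zero(self, small_cohort):
        cfg, donors = small_cohort
        fc = [expected_response(d, cfg).bat_fc for d in donors]
        ecfg = bk.ExpressionConfig(rsad2_slope=0.0, n_genes=10)
        rhos = []
        for rep in range(100):
            counts = bk.simulate_expression(
                donors, fc, dataclasses.replace(ecfg, seed=rep))
            rhos.append(stats.spearmanr(counts.loc["RSAD2"], fc).statistic)
        assert abs(np.mean(rhos)) < 0.12

    def test_negative_slope_detected(self):
        # slope -2, dispersion 0.1, n=19: the negative correlation should be
        # visible in the raw counts in the vast majority of replicates
        cfg = bk.CohortConfig(n_donors=19, seed=0)
        donors = bk.sample_cohort(cfg)
        fc = [expected_response(d, cfg).bat_fc for d in donors]
        ecfg = bk.ExpressionConfig(rsad2_slope=-2.0, dispersion=0.1, n_genes=10)
        neg = sum(
            stats.spearmanr(
                bk.simulate_expression(
                    donors, fc, dataclasses.replace(ecfg, seed=rep)
                ).loc["RSAD2"], fc).statistic < 0
            for rep in range(100)
        )
        assert neg > 80

    def test_deterministic(self, small_cohort):
        cfg, donors = small_cohort
        fc = [1.0] * len(donors)
        ecfg = bk.ExpressionConfig(seed=4)
        pd.testing.assert_frame_equal(
            bk.simulate_expression(donors, fc, ecfg),
            bk.simulate_expression(donors, fc, ecfg))


class TestSimulateCt:
    def test_twofold_expression_is_one_cycle(self):
        counts = pd.DataFrame({"S1": [100, 200]}, index=["G1", "G2"])
        ecfg = bk.ExpressionConfig(ct_noise_sd=0.0, ct_slope=1.0)
        ct = bk.simulate_ct(counts, ecfg).set_index("gene")
        assert ct.loc["G1", "ct"] - ct.loc["G2", "ct"] == pytest.approx(1.0)

    def test_zero_and_late_ct_censored(self):
        counts = pd.DataFrame({"S1": [0, 1000, 1]},
                              index=["ZERO", "OK", "LOW"])
        ecfg = bk.ExpressionConfig(ct_noise_sd=0.0, ct_intercept=41.0)
        ct = bk.simulate_ct(counts, ecfg).set_index("gene")
        assert bool(ct.loc["ZERO", "censored"]) and np.isnan(ct.loc["ZERO", "ct"])
        assert not ct.loc["OK", "censored"]
        # count 1 -> Ct 41 > 40 -> negative well
        assert bool(ct.loc["LOW", "censored"])

    def test_ddct_roundtrip_recovers_relative_expression(self, small_cohort):
        """Noiseless Ct: 2^-ddCt equals the reference-normalized count ratio."""
        from batkit.expression import ddct_expression

        cfg, donors = small_cohort
        fc = [expected_response(d, cfg).bat_fc for d in donors]
        ecfg = bk.ExpressionConfig(ct_noise_sd=0.0, seed=2)
        counts = bk.simulate_expression(donors, fc, ecfg)
        sub = counts.loc[list(ecfg.reference_genes) + ["RSAD2"]]
        rel = ddct_expression(bk.simulate_ct(sub, ecfg),
                              target_genes=["RSAD2"])
        refs = counts.loc[list(ecfg.reference_genes)]
        norm = counts.loc["RSAD2"] / np.exp(np.log(refs).mean(axis=0))
        expected = norm / 2 ** (np.log2(norm).mean())
        assert np.allclose(rel["RSAD2"].to_numpy(),
                           expected[rel.index].to_numpy(), rtol=1e-6)


class TestSimulateClinical:
    def test_zero_noise_trajectories(self):
        df = bk.simulate_clinical(4, 2, seed=0, noise_sd=0.0)
        g = df.groupby(["group", "timepoint"])["rsad2_rel_expr"].mean()
        assert g["responder", 6] < g["responder", 3]
        assert g["non_responder", 6] == pytest.approx(g["non_responder", 3])
        assert g["responder", 0] > g["non_responder", 0]

    def test_deterministic(self):
        a = bk.simulate_clinical(4, 2, seed=5)
        b = bk.simulate_clinical(4, 2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_large_n_rise_is_significant(self):
        from batkit.association import wilcoxon_paired

        df = bk.simulate_clinical(50, 50, seed=1)
        wide = df.pivot_table(index=["subject_id", "group"],
                              columns="timepoint", values="rsad2_rel_expr")
        for group in ("responder", "non_responder"):
            sub = wide.xs(group, level="group")
            assert wilcoxon_paired(sub[0], sub[3]).p < 0.05
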