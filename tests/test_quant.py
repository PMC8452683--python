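"""qPCR quantification tests: curve fitting, Efficiency^dCt arithmetic,
geometric-mean normalization, tissue calls, copy-number folds."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitoduo import (
    SynthConfig,
    call_tissue_mitotype,
    copy_number_fold,
    detection_limit,
    fit_standard_curve,
    normalize,
    process_plate,
    quantify,
    simulate_phenotypes,
    simulate_qpcr,
    tissue_truth,
)


def perfect_dilutions(efficiency=2.0, ct0=20.0, amounts=(10, 1, 0.1, 0.01)):
    return [(a, ct0 - math.log(a, efficiency)) for a in amounts]


class TestStandardCurve:
    def test_perfect_twofold_chemistry(self):
        curve = fit_standard_curve([(a, 20.0 + math.log10(a) * -3.3219) for a in (10, 1, 0.1)])
        assert curve.efficiency == pytest.approx(2.0, abs=1e-4)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3 distinct"):
            fit_standard_curve([(1, 20), (0.1, 23)])

    def test_noiseless_plate_recovers_configured_efficiency(self):
        cfg = SynthConfig(seed=4)
        cfg.qpcr.noise_sd = 0.0
        truth = tissue_truth(2, seed=4)
        plate = simulate_qpcr(truth, cfg)
        std = plate[(plate.role == "standard") & (plate.target == "18S")]
        curve = fit_standard_curve(list(zip(std.known_amount_ng, std.ct)))
        assert curve.efficiency == pytest.approx(cfg.qpcr.efficiency, rel=1e-6)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_implausible_efficiency_flagged(self):
        # slope -1 implies an impossible 10-fold-per-cycle chemistry
        curve = fit_standard_curve([(a, 20 - math.log10(a)) for a in (10, 1, 0.1)])
        assert curve.efficiency == pytest.approx(10.0, rel=1e-6)
        assert "efficiency_out_of_range" in curve.flags


class TestQuantify:
    def test_reference_ct_returns_reference_amount(self):
        curve = fit_standard_curve(perfect_dilutions())
        assert quantify(curve.intercept, curve) == pytest.approx(1.0, rel=1e-9)

    def test_efficiency_two_shift(self):
        curve = fit_standard_curve(perfect_dilutions(efficiency=2.0))
        amount = quantify(curve.intercept - math.log2(10), curve, reference=(curve.intercept, 1.0))
        assert amount == pytest.approx(10.0, rel=1e-6)

    def test_degenerate_efficiency_rejected(self):
        curve = fit_standard_curve(perfect_dilutions())
        curve.efficiency = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            quantify(25.0, curve)


class TestNormalize:
    def test_geometric_mean_example(self):
        assert normalize(4.0, 2.0, 8.0) == pytest.approx(1.0)

    def test_self_normalization(self):
        assert normalize(3.0, 3.0, 3.0) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100),
           st.floats(0.01, 100))
    def test_scale_invariance_and_symmetry(self, t, h1, h2, c):
        assert normalize(t * c, h1 * c, h2 * c) == pytest.approx(normalize(t, h1, h2))
        assert normalize(t, h1, h2) == pytest.approx(normalize(t, h2, h1))

    def test_zero_housekeeping_rejected(self):
        with pytest.raises(ValueError, match="housekeeping"):
            normalize(1.0, 0.0, 2.0)


class TestTissueCall:
    def test_homoplasmic_f(self):
        c = call_tissue_mitotype(0.5, 0.0, detection_limit=1e-4)
        assert c.call == "homoplasmic_F"

    def test_two_orders_heteroplasmy(self):
        c = call_tissue_mitotype(1.0, 0.01, detection_limit=1e-4)
        assert c.call == "heteroplasmic"
        assert c.log10_imbalance == pytest.approx(2.0)
        assert c.imbalance_bucket == "1-2"

    def test_extreme_imbalance_bucket(self):
        c = call_tissue_mitotype(1.0, 1e-3, detection_limit=1e-5)
        assert c.imbalance_bucket == ">2"

    def test_both_undetected_fails(self):
        assert call_tissue_mitotype(0.0, 0.0, detection_limit=1e-4).call == "FAIL"

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            call_tissue_mitotype(-1.0, 0.1, 1e-4)


class TestCopyNumberFold:
    def test_identical_groups_unity(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95]
        f = copy_number_fold(x, x, seed=0)
        assert f.fold == pytest.approx(1.0)
        assert f.ci_low <= 1.0 <= f.ci_high

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            copy_number_fold([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], seed=0)

    def test_synthetic_defaults_within_published_band(self):
        tab = simulate_phenotypes(SynthConfig(seed=9))
        m = tab.loc[tab.mitotype == "M", "cytb_copy"]
        f = tab.loc[tab.mitotype == "F", "cytb_copy"]
        fold = copy_number_fold(m, f, seed=9)
        assert 2.0 <= fold.fold <= 5.0


class TestPlatePipeline:
    def test_noiseless_roundtrip(self):
        cfg = SynthConfig(seed=2)
        cfg.qpcr.noise_sd = 0.0
        truth = tissue_truth(6, seed=2)
        plate = simulate_qpcr(truth, cfg)
        quant_df, _, curves = process_plate(plate)
        merged = quant_df.merge(truth, on=["sample", "tissue", "target"])
        present = merged[merged.amount_ng_y > 0]
        rel = (present.amount_ng_x - present.amount_ng_y).abs() / present.amount_ng_y
        assert rel.max() < 1e-6

    def test_replicate_discord_flagged(self):
        cfg = SynthConfig(seed=2)
        cfg.qpcr.noise_sd = 0.0
        truth = tissue_truth(1, seed=2)
        plate = simulate_qpcr(truth, cfg)
        idx = plate[(plate.role == "unknown") & (plate.replicate == 1)
                    & plate.ct.notna()].index[0]
        plate.loc[idx, "ct"] += 2.5  # force a discordant duplicate
        quant_df, _, _ = process_plate(plate)
        assert quant_df["flags"].str.contains("replicate_discord").any()

    def test_homoplasmic_call_accuracy(self):
        """>=99% correct homoplasmy calls over 1,000 simulated samples at
        default noise."""
        cfg = SynthConfig(seed=13)
        truth = tissue_truth(1000, seed=13)
        plate = simulate_qpcr(truth, cfg)
        _, calls, _ = process_plate(plate)
        tt = truth.drop_duplicates("sample").set_index("sample").truth
        merged = calls.set_index("sample").join(tt)
        assert (merged.call == merged.truth).mean() >= 0.99
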