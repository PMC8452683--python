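"""Generator tests: genome structure, divergence calibration, reads,
qPCR closed forms, phenotype effects, population screen."""
import math

import numpy as np
import pandas as pd
import pytest

from mitoduo import (
    SynthConfig,
    TABLE1,
    build_reference_genome,
    diverge_lineages,
    make_lineage_pair,
    revcomp,
    simulate_phenotypes,
    simulate_population_screen,
    simulate_qpcr,
    simulate_reads,
    tissue_truth,
)
from mitoduo.genome import STOP_CODONS


class TestReferenceGenome:
    def test_feature_inventory(self, reference):
        kinds = pd.Series([f.kind for f in reference.features]).value_counts()
        assert kinds["CDS"] == 12
        assert kinds["tRNA"] == 22
        assert kinds["rRNA"] == 2
        assert kinds["NCR"] == 2
        assert len(reference) == 17428

    def test_cox1_reading_frame(self, reference):
        cds = reference.cds_sequence("cox1")
        assert len(cds) % 3 == 0
        assert cds[:3] == "ATG"
        assert cds[-3:] in STOP_CODONS

    def test_same_seed_is_byte_identical(self, default_config, reference):
        again = build_reference_genome(SynthConfig(seed=default_config.seed))
        assert again.sequence == reference.sequence
        assert again.features == reference.features

    def test_different_seeds_differ(self, reference):
        other = build_reference_genome(SynthConfig(seed=2))
        assert other.sequence != reference.sequence

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            build_reference_genome(SynthConfig(seed=1, genome_length=500))


class TestDivergeLineages:
    def test_zero_divergence_identity(self, reference):
        cfg = SynthConfig(seed=1, divergence_target=0.0, structural_events=False)
        p = diverge_lineages(reference, cfg)
        assert p.genome_m.sequence == reference.sequence
        assert p.aligned_f == p.aligned_m

    def test_alignment_reconstructs_both_genomes(self, pair):
        assert pair.aligned_f.replace("-", "") == pair.genome_f.sequence
        assert pair.aligned_m.replace("-", "") == pair.genome_m.sequence
        assert len(pair.aligned_f) == len(pair.aligned_m)

    def test_event_log_matches_alignment(self, pair):
        mismatches = sum(1 for a, b in zip(pair.aligned_f, pair.aligned_m)
                         if a != b and a != "-" and b != "-")
        assert mismatches == pair.n_substitutions
        ins_cols = sum(1 for a in pair.aligned_f if a == "-")
        assert ins_cols == sum(e[2] for e in pair.event_log if e[0] == "ins")

    def test_realized_divergence_near_target(self, pair, default_config):
        # single-seed binomial noise is ~0.0017; 0.01 is a ~6-sigma band
        assert abs(pair.realized_divergence - default_config.divergence_target) < 0.01

    def test_structural_events_sizes(self, pair):
        ins = {e[4]: e[2] for e in pair.event_log if e[0] == "ins"}
        assert ins == {"16S": 127, "cox1": 30}
        assert len(pair.genome_m) == len(pair.genome_f) + 157

    def test_m_features_consistent(self, pair):
        assert pair.genome_m.feature("16S").length == pair.genome_f.feature("16S").length + 127
        assert pair.genome_m.feature("cox1").length == pair.genome_f.feature("cox1").length + 30

    def test_reading_frames_safe_in_both_genomes(self, pair):
        for g in (pair.genome_f, pair.genome_m):
            for f in g.features:
                if f.kind == "CDS":
                    g.protein(f.name)  # raises on internal stop

    def test_determinism(self, pair, default_config):
        again = make_lineage_pair(SynthConfig(seed=default_config.seed))
        assert again.genome_m.sequence == pair.genome_m.sequence
        assert again.event_log == pair.event_log


class TestSimulateReads:
    def test_read_count_tracks_coverage(self, pair):
        cfg = SynthConfig(seed=5, coverage=30.0, read_length=100)
        reads = simulate_reads(pair, cfg)
        expect = 30.0 * len(pair.genome_f) / 100  # ~5228
        assert abs(len(reads) - expect) < 5 * math.sqrt(expect)

    def test_pure_f_mixture(self, pair):
        cfg = SynthConfig(seed=5, coverage=2.0, mixture=0.0)
        assert all(r.truth == "F" for r in simulate_reads(pair, cfg).reads)

    def test_error_free_reads_are_genome_substrings(self, pair):
        cfg = SynthConfig(seed=5, coverage=1.0, mixture=0.5, error_rate=0.0)
        doubled = {"F": pair.genome_f.sequence * 2, "M": pair.genome_m.sequence * 2}
        for r in simulate_reads(pair, cfg).reads[:200]:
            src = doubled[r.truth]
            assert r.sequence in src or revcomp(r.sequence) in src

    def test_mixture_fraction_recovered(self, pair):
        cfg = SynthConfig(seed=5, coverage=10.0, mixture=0.3)
        reads = simulate_reads(pair, cfg)
        frac = reads.truth_fraction_m()
        assert abs(frac - 0.3) < 4 * math.sqrt(0.3 * 0.7 / len(reads))

    def test_read_longer_than_genome_rejected(self, pair):
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(pair, SynthConfig(seed=1, read_length=20000))


class TestSimulateQpcr:
    @staticmethod
    def _noiseless_config(seed=3, efficiency=2.0):
        cfg = SynthConfig(seed=seed)
        cfg.qpcr.noise_sd = 0.0
        cfg.qpcr.efficiency = efficiency
        return cfg

    def test_standard_point_ct_matches_sample_of_same_amount(self):
        cfg = self._noiseless_config()
        truth = pd.DataFrame([("s1", "gills", "18S", 1.0)],
                             columns=["sample", "tissue", "target", "amount_ng"])
        plate = simulate_qpcr(truth, cfg)
        std_ct = plate[(plate.role == "standard") & (plate.known_amount_ng == 1.0)].ct.iloc[0]
        unk_ct = plate[plate.role == "unknown"].ct.iloc[0]
        assert unk_ct == pytest.approx(std_ct, abs=1e-12)

    def test_tenfold_dilution_shifts_ct_by_log2_10(self):
        cfg = self._noiseless_config(efficiency=2.0)
        truth = pd.DataFrame([("s1", "g", "18S", 1.0), ("s2", "g", "18S", 0.1)],
                             columns=["sample", "tissue", "target", "amount_ng"])
        plate = simulate_qpcr(truth, cfg)
        unk = plate[plate.role == "unknown"].groupby("sample").ct.mean()
        assert unk["s2"] - unk["s1"] == pytest.approx(math.log2(10), abs=1e-9)

    def test_absent_target_reports_no_amplification(self):
        cfg = self._noiseless_config()
        truth = pd.DataFrame([("s1", "g", "cytbF", 0.5), ("s1", "g", "cytbM", 0.0)],
                             columns=["sample", "tissue", "target", "amount_ng"])
        plate = simulate_qpcr(truth, cfg)
        m_wells = plate[(plate.role == "unknown") & (plate.target == "cytbM")]
        assert m_wells.ct.isna().all()

    def test_negative_amount_rejected(self):
        truth = pd.DataFrame([("s1", "g", "18S", -1.0)],
                             columns=["sample", "tissue", "target", "amount_ng"])
        with pytest.raises(ValueError, match=">= 0"):
            simulate_qpcr(truth, SynthConfig(seed=1))


class TestSimulatePhenotypes:
    def test_null_effects_equal_means(self):
        cfg = SynthConfig(seed=11)
        e = cfg.effects
        e.ets_mito_factor = e.cox_mito_factor = e.cs_sex_factor = 1.0
        e.copy_number_fold = 1.0
        tab = simulate_phenotypes(cfg)
        for col in ("ETS", "COX", "CS"):
            means = tab.groupby(["sex", "mitotype"])[col].mean()
            # sigma 0.25 at n=1000/cell: SE of the mean ~0.8% of the mean
            assert means.max() / means.min() < 1.05

    def test_configured_reductions_present(self):
        tab = simulate_phenotypes(SynthConfig(seed=11))
        by_mito = tab.groupby("mitotype")[["ETS", "COX"]].mean()
        assert 1 - by_mito.loc["M", "ETS"] / by_mito.loc["F", "ETS"] == pytest.approx(0.31, abs=0.03)
        assert 1 - by_mito.loc["M", "COX"] / by_mito.loc["F", "COX"] == pytest.approx(0.33, abs=0.03)
        by_sex = tab.groupby("sex")["CS"].mean()
        assert 1 - by_sex["female"] / by_sex["male"] == pytest.approx(0.42, abs=0.03)

    def test_copy_number_elevated_in_m_carriers(self):
        tab = simulate_phenotypes(SynthConfig(seed=11))
        by = tab.groupby("mitotype")["cytb_copy"].median()
        assert 2.0 < by["M"] / by["F"] < 5.0

    def test_invalid_effect_block_rejected(self):
        cfg = SynthConfig(seed=1)
        cfg.effects.ets_mito_factor = -0.5
        with pytest.raises(ValueError, match="must be > 0"):
            cfg.validate()


class TestPopulationScreen:
    def test_zero_probability_zero_carriers(self):
        pops = pd.DataFrame({"population": ["a", "b"], "n": [50, 80],
                             "carrier_probability": [0.0, 0.0]})
        out = simulate_population_screen(pops, seed=3)
        assert (out.carriers_M == 0).all()
        assert (out.carriers_F == out.n).all()

    def test_negative_n_rejected(self):
        pops = pd.DataFrame({"population": ["a"], "n": [-5],
                             "carrier_probability": [0.1]})
        with pytest.raises(ValueError, match=">= 0"):
            simulate_population_screen(pops, seed=3)

    def test_binomial_counts_reasonable(self):
        pops = pd.DataFrame({"population": ["a"], "n": [10000],
                             "carrier_probability": [0.1]})
        out = simulate_population_screen(pops, seed=3)
        assert abs(out.carriers_M.iloc[0] - 1000) < 150

    def test_fixture_transcribes_published_table(self):
        out = simulate_population_screen(fixture=True)
        iceland = out[out.population == "Iceland"].iloc[0]
        assert (iceland.n, iceland.carriers_M) == (60, 10)
        total = out[out.population == "total"].iloc[0]
        assert (total.n, total.carriers_F, total.carriers_M) == (315, 300, 15)
        body = out[out.population != "total"]
        assert body.n.sum() == total.n
        assert (body.n == body.carriers_F + body.carriers_M).all()
        assert len(body) == len(TABLE1)
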