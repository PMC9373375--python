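import numpy as np
import pytest

from clonarch.ccf import expected_vaf
from clonarch.io import read_cohort
from clonarch.simulate import (
    ClinicalEffects,
    GeneSpec,
    SimulationConfig,
    config_from_dict,
    simulate_cohort,
    simulate_reads,
    write_cohort,
)


class TestSimulateReads:
    def test_clonal_pure_diploid_converges_to_half(self):
        rng = np.random.default_rng(0)
        t, n = simulate_reads(1.0, 1.0, 2, 10**6, rng)
        assert t / n == pytest.approx(0.5, abs=0.002)

    def test_subclonal_converges_to_analytic_vaf(self):
        # VAF = 0.5 * 0.4 * 1/2 = 0.10
        rng = np.random.default_rng(0)
        t, n = simulate_reads(0.4, 0.5, 2, 10**6, rng)
        assert t / n == pytest.approx(0.10, abs=0.002)

    def test_deterministic_under_fixed_seed(self):
        a = simulate_reads(0.7, 0.6, 3, 100, np.random.default_rng(5))
        b = simulate_reads(0.7, 0.6, 3, 100, np.random.default_rng(5))
        assert a == b

    def test_invalid_inputs_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_reads(0.0, 0.5, 2, 100, rng)
        with pytest.raises(ValueError):
            simulate_reads(0.5, 0.5, 0, 100, rng)

    def test_empirical_vaf_matches_model_within_3se(self):
        # pooled alt fraction over replicates converges to the analytic VAF
        rng = np.random.default_rng(12)
        for _ in range(10):
            ccf = float(rng.uniform(0.1, 1.0))
            purity = float(rng.uniform(0.2, 1.0))
            cn = int(rng.integers(1, 5))
            depth, reps = 1000, 50
            v = expected_vaf(purity, ccf, cn)
            alt = sum(simulate_reads(ccf, purity, cn, depth, rng)[0] for _ in range(reps))
            se = np.sqrt(v * (1 - v) / (depth * reps))
            assert abs(alt / (depth * reps) - v) <= 3 * se


class TestSimulateCohort:
    def test_bias_one_makes_every_mutation_clonal(self):
        cfg = SimulationConfig(
            n_patients=100, genes=[GeneSpec("G1", 0.5, 1.0)], seed=0
        )
        _, truth = simulate_cohort(cfg)
        assert truth and all(t.true_label == "clonal" for t in truth)

    def test_truth_label_iff_ccf_one(self, small_cohort):
        _, _, truth = small_cohort
        for t in truth:
            assert (t.true_label == "clonal") == (t.true_ccf == 1.0)
            if t.true_label == "subclonal":
                assert t.true_ccf < 0.9

    def test_mutation_count_within_binomial_band(self):
        cfg = SimulationConfig(
            n_patients=200, genes=[GeneSpec("G2", 0.3, 0.8)], seed=1
        )
        bundle, _ = simulate_cohort(cfg)
        n = len([m for m in bundle.mutations if m.gene == "G2"])
        sd = np.sqrt(200 * 0.3 * 0.7)
        assert abs(n - 60) <= 3 * sd

    def test_depth_floor_respected(self, small_cohort):
        _, bundle, _ = small_cohort
        assert min(m.t_depth for m in bundle.mutations) >= 30

    def test_zero_patients_or_genes_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_patients=0)
        with pytest.raises(ValueError):
            SimulationConfig(genes=[])

    def test_subclonal_range_must_be_below_threshold(self):
        with pytest.raises(ValueError):
            SimulationConfig(subclonal_ccf_range=(0.2, 0.95))

    def test_msi_burden_multiplier_raises_rates(self):
        eff = ClinicalEffects(msi_burden_multiplier=3.0)
        cfg = SimulationConfig(
            n_patients=600,
            genes=[GeneSpec(f"G{i}", 0.1, 0.8) for i in range(10)],
            clinical_effects=eff,
            msi_rate=0.3,
            seed=2,
        )
        bundle, _ = simulate_cohort(cfg)
        msi = {c.sample_id for c in bundle.clinical if c.msi_status == "MSI"}
        counts = {}
        for m in bundle.mutations:
            counts[m.sample_id] = counts.get(m.sample_id, 0) + 1
        ids = [c.sample_id for c in bundle.clinical]
        msi_mean = np.mean([counts.get(s, 0) for s in ids if s in msi])
        mss_mean = np.mean([counts.get(s, 0) for s in ids if s not in msi])
        assert msi_mean > 2 * mss_mean


class TestWriteCohort:
    def test_round_trip_preserves_counts(self, small_cohort, tmp_path):
        _, bundle, truth = small_cohort
        paths = write_cohort(bundle, truth, tmp_path)
        back, reports = read_cohort(
            paths["maf"], paths["segments"], paths["purity"], paths["clinical"]
        )
        assert len(back.mutations) == len(bundle.mutations)
        assert len(back.purities) == len(bundle.purities)
        assert len(back.clinical) == len(bundle.clinical)
        assert all(r.n_skipped == 0 for r in reports.values())
        truth_lines = paths["truth"].read_text().strip().splitlines()
        assert len(truth_lines) - 1 == len(bundle.mutations)

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_patients=50, seed=9)
        for d in ("a", "b"):
            bundle, truth = simulate_cohort(SimulationConfig(n_patients=50, seed=9))
            write_cohort(bundle, truth, tmp_path / d)
        for name in ("maf.tsv", "segments.tsv", "purity.tsv", "clinical.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestConfigFromDict:
    def test_nested_genes_and_effects(self):
        cfg = config_from_dict(
            {
                "n_patients": 10,
                "genes": [{"name": "A", "rate": 0.5, "clonal_bias": 0.9}],
                "clinical_effects": {"log_hr": {"A:subclonal": 1.1}},
                "purity_range": [0.4, 0.8],
            }
        )
        assert cfg.genes[0].name == "A"
        assert cfg.clinical_effects.log_hr["A:subclonal"] == 1.1
        assert cfg.purity_range == (0.4, 0.8)
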