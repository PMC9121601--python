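"""The synthetic-study generator: determinism, self-consistency, truth labels."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from regvar import io_formats
from regvar.ase import ase_binomial_test
from regvar.assoc_stats import eqtl_scan
from regvar.ld import r_squared
from regvar.synthetic_data import (
    ScenarioConfig,
    generate_ase_counts,
    generate_eqtl_expression,
    generate_ld_panel,
    generate_reference,
    generate_regulatory_scenario,
    solve_consensus_probability,
)


class TestReference:
    def test_same_seed_identical(self):
        a = generate_reference(500, 0.5, 42)
        b = generate_reference(500, 0.5, 42)
        assert a.sequence == b.sequence

    def test_gc_content_concentrates(self):
        seq = generate_reference(100_000, 0.5, 1).sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.01)

    def test_short_length_is_error(self):
        with pytest.raises(ValueError):
            generate_reference(10, 0.5, 1)

    def test_gc_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            generate_reference(1000, 1.5, 1)


def test_consensus_probability_solver_inverts_information():
    for bits in (0.8, 1.2, 1.5, 1.8):
        q = solve_consensus_probability(bits)
        rest = (1 - q) / 3
        ic = 2 + q * np.log2(q) + 3 * rest * np.log2(rest)
        assert ic == pytest.approx(bits, abs=1e-6)


class TestLdPanel:
    def test_realized_r2_near_targets(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            cfg = ScenarioConfig(seed=seed, n_samples_panel=500)
            _, truth = generate_ld_panel(cfg)
            high = truth[truth.target_r2 == cfg.partner_r2_high].realized_r2.iloc[0]
            if abs(high - cfg.partner_r2_high) <= 0.15:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_target_one_gives_identical_partner(self):
        cfg = ScenarioConfig(seed=3, partner_r2_high=1.0, n_samples_panel=60)
        panel, truth = generate_ld_panel(cfg)
        row = truth[truth.target_r2 == 1.0].iloc[0]
        assert row.realized_r2 == pytest.approx(1.0)
        idx_col = panel.column("idx1")
        assert np.array_equal(idx_col, panel.column(row.snp_id))

    def test_bad_target_is_error(self):
        cfg = ScenarioConfig(seed=1)
        panel, _ = generate_ld_panel(cfg)
        from regvar.synthetic_data import _partner_haplotype

        with pytest.raises(ValueError):
            _partner_haplotype(np.random.default_rng(0), panel.column("idx1"), 0.3, 1.5)


class TestScenario:
    def test_byte_identical_regeneration(self, tmp_path, default_scenario):
        cfg, files, _ = default_scenario
        files2, _ = generate_regulatory_scenario(cfg, tmp_path / "again")
        for name in ("reference", "vcf", "motifs", "index_snps", "ase_counts",
                     "truth_snps", "config"):
            a, b = getattr(files, name), getattr(files2, name)
            assert filecmp.cmp(a, b, shallow=False), f"{name} differs between runs"
        for tf, path in files.peaks.items():
            assert filecmp.cmp(path, files2.peaks[tf], shallow=False)
        for ds, path in files.expression.items():
            assert filecmp.cmp(path, files2.expression[ds], shallow=False)

    def test_files_parse_back_and_truth_complete(self, default_scenario):
        cfg, files, truth = default_scenario
        ref = io_formats.parse_fasta(files.reference)
        assert len(ref) == 1 and len(ref[0]) == cfg.reference_length
        variants, panel = io_formats.parse_vcf(files.vcf)
        assert panel.skipped_records == 0
        # every VCF SNP appears in the truth table exactly once
        truth_ids = list(truth.snps.snp_id)
        assert sorted(v.id for v in variants) == sorted(truth_ids)
        assert len(set(truth_ids)) == len(truth_ids)
        pwms = io_formats.parse_meme_motifs(files.motifs)
        assert len(pwms) == cfg.n_tfs
        for tf, path in files.peaks.items():
            peaks = io_formats.parse_bed(path)
            assert len(peaks) == cfg.n_peaks_per_tf
            assert all(p.tf_name == tf for p in peaks)

    def test_realized_r2_recorded_from_ld_module(self, default_scenario):
        cfg, files, truth = default_scenario
        _, panel = io_formats.parse_vcf(files.vcf)
        for row in truth.snps.itertuples():
            if row.klass == "index":
                continue
            got = r_squared(panel.column(row.index_id), panel.column(row.snp_id)).r2
            assert got == pytest.approx(row.realized_r2, abs=1e-6)

    def test_disrupting_snps_inside_same_tf_peaks(self, default_scenario):
        cfg, files, truth = default_scenario
        for row in truth.disrupting.itertuples():
            peaks = io_formats.parse_bed(files.peaks[row.tf])
            pos0 = row.pos - 1
            assert any(p.start <= pos0 < p.end for p in peaks)

    def test_reference_matches_vcf_ref_alleles(self, default_scenario):
        cfg, files, truth = default_scenario
        seq = io_formats.parse_fasta(files.reference)[0].sequence
        for row in truth.snps.itertuples():
            assert seq[row.pos - 1] == row.ref

    def test_overdemanding_config_is_error(self):
        with pytest.raises(ValueError, match="blocks"):
            ScenarioConfig(seed=1, reference_length=1000)

    def test_zero_disrupting_snps_supported(self, tmp_path):
        cfg = ScenarioConfig(seed=5, n_disrupting_snps=0, n_consensus_snps=0)
        _, truth = generate_regulatory_scenario(cfg, tmp_path / "none")
        assert truth.disrupting.empty


class TestEqtlGenerator:
    def test_noiseless_limit_recovers_beta(self, rng):
        cfg = ScenarioConfig(seed=1, noise_sd=1e-8, n_eqtl_datasets=1,
                             n_null_genes=0, n_consensus_snps=1, n_disrupting_snps=1)
        truth = pd.DataFrame(
            [{"snp_id": "s1", "gene_id": "g1", "dataset_id": "DS1", "beta": 1.0}]
        )
        [ds] = generate_eqtl_expression(cfg, truth, ["g1"], ["s1"], rng)
        [a] = eqtl_scan(ds, [("s1", "g1")])
        assert a.beta == pytest.approx(1.0, abs=1e-3)

    def test_null_pvalues_uniform(self, rng):
        cfg = ScenarioConfig(seed=1, n_eqtl_datasets=1, n_samples_per_dataset=100)
        n_null = 1000
        genes = [f"n{i}" for i in range(n_null)]
        truth = pd.DataFrame(columns=["snp_id", "gene_id", "dataset_id", "beta"])
        [ds] = generate_eqtl_expression(cfg, truth, genes, ["s1"], rng)
        ps = [a.p_value for a in eqtl_scan(ds, [("s1", g) for g in genes])]
        from scipy import stats

        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05


class TestConsensusRecovery:
    def test_tallies_usually_equal_truth(self, rng):
        """Planted consensus structure (3 shared SNPs, 2 dataset-specific)
        is recovered by the tally in most seeds. Null (snp, gene, dataset)
        cells each clear the raw p < 0.01 rule with probability 0.01, so an
        exact-match rate near 0.99^8 ~ 0.92 is the analytic expectation; the
        assertion uses a >3-sigma lower bound on 30 seeds."""
        from regvar.assoc_stats import SignificanceRule, consensus_tally

        matches = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = ScenarioConfig(seed=seed)
            local = np.random.default_rng(seed + 1000)
            snps = [f"s{i}" for i in range(5)]
            genes = [f"g{i}" for i in range(5)]
            ds_ids = [f"DS{d + 1}" for d in range(cfg.n_eqtl_datasets)]
            rows = []
            for i, (s, g) in enumerate(zip(snps, genes)):
                active = ds_ids if i < 3 else [ds_ids[i % len(ds_ids)]]
                rows.extend(
                    {"snp_id": s, "gene_id": g, "dataset_id": d, "beta": cfg.eqtl_beta}
                    for d in active
                )
            truth = pd.DataFrame(rows)
            datasets = generate_eqtl_expression(cfg, truth, genes, snps, local)
            assocs = []
            for ds in datasets:
                assocs.extend(eqtl_scan(ds, list(zip(snps, genes))))
            summary = consensus_tally(assocs, SignificanceRule("p", 0.01), snps)
            expected = {1: 5, 2: 3, 3: 3, 4: 3, 5: 3}
            if summary.tallies == expected:
                matches += 1
        assert matches >= int(0.8 * n_seeds)


class TestAseGenerator:
    def test_strong_imbalance_detected(self, rng):
        cfg = ScenarioConfig(seed=1, ase_depth=100, ase_imbalance_delta=0.4)
        counts = generate_ase_counts(cfg, [f"s{i}" for i in range(200)], [True] * 200, rng)
        ps = [
            ase_binomial_test(int(r.count_allele1), int(r.count_allele2))
            for r in counts.itertuples()
        ]
        assert np.mean(np.asarray(ps) < 0.05) >= 0.99

    def test_depth_too_low_is_error(self, rng):
        cfg = ScenarioConfig(seed=1, ase_depth=5)
        with pytest.raises(ValueError, match="ase_depth"):
            generate_ase_counts(cfg, ["s"], [False], rng)

    def test_delta_out_of_range_is_error(self, rng):
        cfg = ScenarioConfig(seed=1, ase_imbalance_delta=0.6)
        with pytest.raises(ValueError, match="outside"):
            generate_ase_counts(cfg, ["s"], [True], rng)
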