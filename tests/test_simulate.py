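import itertools

import numpy as np
import pandas as pd
import pytest

from zicreg import io as zio
from zicreg.core import ValidationError
from zicreg.motifs import calibrate_threshold, scan_peaks
from zicreg.peaks import compute_repeat_fraction
from zicreg.simulate import (
    STAGE_A,
    STAGE_B,
    SimulationConfig,
    generate,
    generate_genome,
)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValidationError):
            SimulationConfig(frac_shared_peaks=1.5)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SimulationConfig(distance_mixture=(0.5, 0.5, 0.5))

    def test_de_effect_at_least_one(self):
        with pytest.raises(ValidationError):
            SimulationConfig(de_effect=0.5)

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == small_config


class TestGenerateGenome:
    def test_no_genes_still_yields_sequence(self):
        cfg = SimulationConfig(
            genome_size=200_000, n_chroms=1, n_genes=0, n_peaks_per_stage=10
        )
        sizes, genome, genes, _ = generate_genome(cfg, np.random.default_rng(0))
        assert genes == []
        assert genome["chr1"].size == 200_000

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(
            genome_size=300_000, n_chroms=2, n_genes=10, n_peaks_per_stage=10,
            min_gene_spacing=5_000,
        )
        out1 = generate_genome(cfg, np.random.default_rng(3))
        out2 = generate_genome(cfg, np.random.default_rng(3))
        for a, b in zip(out1[1].values(), out2[1].values()):
            np.testing.assert_array_equal(a, b)
        assert [g.interval for g in out1[2]] == [g.interval for g in out2[2]]

    def test_pairwise_tss_spacing_respected(self):
        cfg = SimulationConfig(
            genome_size=10_000_000, n_chroms=1, n_genes=50,
            n_peaks_per_stage=10, min_gene_spacing=20_000,
        )
        _, _, genes, _ = generate_genome(cfg, np.random.default_rng(4))
        assert len(genes) == 50
        for a, b in itertools.combinations(genes, 2):
            if a.chrom == b.chrom:
                assert abs(a.tss - b.tss) >= 20_000

    def test_infeasible_spacing_raises_helpful_error(self):
        cfg = SimulationConfig(
            genome_size=100_000, n_chroms=1, n_genes=50, n_peaks_per_stage=10
        )
        with pytest.raises(ValidationError, match="larger genome"):
            generate_genome(cfg, np.random.default_rng(0))


class TestGeneratePeaks:
    def test_fully_shared_config_puts_every_site_in_both_stages(self):
        cfg = SimulationConfig(
            genome_size=1_000_000, n_chroms=1, n_genes=20, n_peaks_per_stage=60,
            frac_shared_peaks=1.0, min_gene_spacing=8_000, summit_jitter=0, seed=5,
        )
        ds = generate(cfg)
        sa = {(p.peak_id, p.summit) for p in ds.peaks[STAGE_A]}
        sb = {(p.peak_id, p.summit) for p in ds.peaks[STAGE_B]}
        assert sa == sb and len(sa) == 60
        assert (ds.manifest_peaks["true_class"] == "I").all()

    def test_shared_count_within_binomial_ci(self, small_dataset):
        """Class I count is Binomial(n, frac_shared); check its 99% CI."""
        cfg = small_dataset.config
        n, p = cfg.n_peaks_per_stage, cfg.frac_shared_peaks
        n_shared = int((small_dataset.manifest_peaks["true_class"] == "I").sum())
        ci = 2.576 * np.sqrt(n * p * (1 - p))
        assert abs(n_shared - n * p) <= ci

    def test_class_counts_match_stage_lists(self, small_dataset):
        mp = small_dataset.manifest_peaks
        n_I = int((mp.true_class == "I").sum())
        n_II = int((mp.true_class == "II").sum())
        n_III = int((mp.true_class == "III").sum())
        assert len(small_dataset.peaks[STAGE_A]) == n_I + n_II
        assert len(small_dataset.peaks[STAGE_B]) == n_I + n_III

    def test_repeat_sites_have_high_repeat_fraction(self, small_dataset):
        mp = small_dataset.manifest_peaks
        by_id = {p.peak_id: p for p in small_dataset.peaks[STAGE_A]}
        for row in mp.loc[mp.is_repeat].itertuples(index=False):
            peak = by_id.get(row.site_id)
            if peak is None:
                continue
            frac = compute_repeat_fraction(peak, small_dataset.repeat_mask)
            assert frac > 0.70

    def test_planted_motifs_present_in_sequence(self, small_dataset):
        seqs = small_dataset.sequences()
        consensus = small_dataset.config.consensus
        mp = small_dataset.manifest_peaks
        for row in mp.loc[mp.motif_planted].itertuples(index=False):
            summit = int(row.summit_a if not pd.isna(row.summit_a) else row.summit_b)
            start = summit + int(row.motif_offset)
            assert seqs[row.chrom][start : start + len(consensus)] == consensus

    def test_zero_plant_rate_leaves_only_chance_hits(self):
        """With no planted motifs the scan fraction matches the calibrated
        chance rate predicted on random background windows."""
        from zicreg.motifs import background_hit_rate
        import zicreg

        cfg = SimulationConfig(
            genome_size=1_000_000, n_chroms=1, n_genes=20, n_peaks_per_stage=200,
            motif_plant_rate=0.0, min_gene_spacing=8_000, repeat_frac_rate=0.0,
            seed=9,
        )
        ds = generate(cfg)
        pwm = zicreg.zic3_consensus_pwm()
        thr = calibrate_threshold(pwm, n=5000, seed=1).threshold
        _, frac = scan_peaks(pwm, thr, ds.peaks[STAGE_A], ds.sequences())
        chance = background_hit_rate(pwm, thr, n=1000, rng=2)
        ci = 2.576 * np.sqrt(max(chance, 0.005) * (1 - min(chance, 0.995)) / 200)
        mc = 2.576 * np.sqrt(max(chance, 0.005) * (1 - min(chance, 0.995)) / 1000)
        assert abs(frac - chance) <= ci + mc


class TestGenerateExpression:
    def test_noise_free_targets_have_exact_fold_change(self):
        cfg = SimulationConfig(
            genome_size=1_000_000, n_chroms=1, n_genes=30, n_peaks_per_stage=80,
            de_effect=2.0, noise_sd=0.0, min_gene_spacing=8_000, seed=13,
        )
        ds = generate(cfg)
        truth = dict(zip(ds.manifest_genes.gene_id, ds.manifest_genes.target_8hpf))
        table = ds.expression[STAGE_A]
        targets = table.loc[table.gene_id.map(truth)]
        assert (targets["fold_change"] == 2.0).all()
        nulls = table.loc[~table.gene_id.map(truth)]
        assert (nulls["fold_change"] == 1.0).all()

    def test_null_effect_makes_groups_indistinguishable(self):
        """de_effect=1 and matching p-laws: targets and non-targets come
        from the same distribution, so downstream recall tracks the filter's
        false-positive rate."""
        cfg = SimulationConfig(
            genome_size=1_000_000, n_chroms=1, n_genes=40, n_peaks_per_stage=80,
            de_effect=1.0, target_p_alpha=1.0, min_gene_spacing=8_000, seed=17,
        )
        ds = generate(cfg)
        from zicreg.targets import select_de_genes

        table = ds.expression[STAGE_A]
        truth = dict(zip(ds.manifest_genes.gene_id, ds.manifest_genes.target_8hpf))
        de = set(select_de_genes(table, preset="8hpf")["gene_id"])
        n_t = sum(truth.values())
        n_n = len(truth) - n_t
        rate_t = len([g for g in de if truth[g]]) / max(n_t, 1)
        rate_n = len([g for g in de if not truth[g]]) / max(n_n, 1)
        # both are small false-positive-like rates under the null
        assert rate_t <= 0.3 and rate_n <= 0.3


class TestManifestConsistency:
    def test_emitted_files_rescan_to_manifest_counts(self, tmp_path, small_dataset):
        """Counts recoverable from the emitted files equal the manifest."""
        paths = small_dataset.write(tmp_path)
        mp = pd.read_csv(paths["manifest_peaks"], sep="\t")
        pa = zio.read_peaks(paths[f"peaks_{STAGE_A}"], stage=STAGE_A)
        pb = zio.read_peaks(paths[f"peaks_{STAGE_B}"], stage=STAGE_B)
        assert len(pa) == mp["true_class"].isin(["I", "II"]).sum()
        assert len(pb) == mp["true_class"].isin(["I", "III"]).sum()
        assert mp["site_id"].is_unique
        mc = pd.read_csv(paths["manifest_cnes"], sep="\t")
        ident = zio.read_track(paths["identity"], kind="identity")
        cfg = small_dataset.config
        island_bases = sum(
            e - s
            for c in ident.chroms
            for s, e, v in ident.steps(c)
            if v == cfg.cne_identity
        )
        assert island_bases == int((mc["end"] - mc["start"]).sum())
        mg = pd.read_csv(paths["manifest_genes"], sep="\t")
        genes = zio.read_gene_annotation(paths["genes"])
        assert len(genes) == len(mg)

    def test_full_determinism_of_generate(self, small_config):
        a = generate(small_config)
        b = generate(small_config)
        pd.testing.assert_frame_equal(a.manifest_peaks, b.manifest_peaks)
        pd.testing.assert_frame_equal(a.manifest_genes, b.manifest_genes)
        pd.testing.assert_frame_equal(a.expression[STAGE_A], b.expression[STAGE_A])
        assert a.signal[STAGE_A].library_size == b.signal[STAGE_A].library_size
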