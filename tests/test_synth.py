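"""Generator contracts: determinism, planting, expression statistics."""

import numpy as np
import pytest

from reggrammar import expression as ex
from reggrammar import synth


def small_config(**kw):
    defaults = dict(n_genes=120, n_motifs=8, n_rules=6, cds_length=300)
    defaults.update(kw)
    return synth.GeneratorConfig(**defaults)


class TestGenome:
    def test_degenerate_grammar_pure_background(self):
        cfg = small_config(n_motifs=0, n_rules=0)
        genes, truth = synth.generate_genome(cfg, seed=0)
        assert truth.planted_rules == []
        assert all(g.motif_positions == {} for g in genes)

    def test_determinism(self):
        cfg = small_config()
        a, _ = synth.generate_genome(cfg, seed=5)
        b, _ = synth.generate_genome(small_config(), seed=5)
        assert all(x.regions == y.regions for x, y in zip(a, b))

    def test_cds_structure(self):
        genes, _ = synth.generate_genome(small_config(), seed=1)
        for g in genes[:20]:
            cds = g.regions["cds"]
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in synth.STOP_CODONS

    def test_rules_present_in_min_genes(self):
        cfg = small_config()
        genes, truth = synth.generate_genome(cfg, seed=2)
        for rule in truth.planted_rules:
            carriers = sum(
                all(g.carries(m) for m in rule.motif_ids) for g in genes
            )
            assert carriers >= cfg.min_rule_genes

    def test_rules_reference_at_least_two_motifs(self):
        _, truth = synth.generate_genome(small_config(), seed=3)
        assert all(len(r.motif_ids) >= 2 for r in truth.planted_rules)

    def test_motif_longer_than_region_rejected(self):
        cfg = small_config(motif_length=60)  # > utr3 length 50
        with pytest.raises(ValueError):
            synth.generate_genome(cfg, seed=0)

    def test_planted_instances_self_recovered_by_own_pwm(self):
        """Scanning each region with the planted PWM at the planting
        threshold finds every recorded instance (100% self-recovery)."""
        genes, truth = synth.generate_genome(small_config(), seed=4)
        pwms = truth.motif_map()
        checked = 0
        for g in genes[:40]:
            for mid, (region, offset) in g.motif_positions.items():
                pwm = pwms[mid].pwm
                thr = synth.plant_threshold(pwm, 0.8)
                hits = synth.scan_pwm(pwm, g.regions[region], thr)
                assert offset in hits
                checked += 1
        assert checked > 20

    def test_cross_region_fraction_near_configured(self):
        cfg = synth.GeneratorConfig(n_genes=10, n_motifs=40, n_rules=50)
        _, truth = synth.generate_genome(cfg, seed=6)
        motifs = truth.motif_map()
        frac = np.mean([len(r.regions(motifs)) > 1 for r in truth.planted_rules])
        assert abs(frac - cfg.cross_region_fraction) < 0.1


class TestExpression:
    def test_no_noise_rsd_zero(self):
        cfg = small_config(noise_sd_between_experiments=0.0,
                           noise_sd_residual=0.0)
        genes, truth = synth.generate_genome(cfg, seed=0)
        expr = synth.generate_expression(genes, truth, 10, seed=1, config=cfg)
        summ = ex.summarize(expr)
        assert np.allclose(summ["rsd"], 0.0, atol=1e-12)

    def test_strictly_positive_and_tpm_normalized(self):
        cfg = small_config()
        genes, truth = synth.generate_genome(cfg, seed=0)
        expr = synth.generate_expression(genes, truth, 5, seed=1, config=cfg)
        assert (expr.values > 0).all()
        np.testing.assert_allclose(expr.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_too_few_experiments_rejected(self):
        cfg = small_config()
        genes, truth = synth.generate_genome(cfg, seed=0)
        with pytest.raises(ValueError):
            synth.generate_expression(genes, truth, 1, seed=1, config=cfg)

    def test_determinism(self):
        cfg = small_config()
        genes, truth = synth.generate_genome(cfg, seed=0)
        a = synth.generate_expression(genes, truth, 5, seed=9, config=cfg)
        truth.noise_sd_residual = None  # reset the auto-calibrated value
        b = synth.generate_expression(genes, truth, 5, seed=9, config=cfg)
        np.testing.assert_array_equal(a.values, b.values)


class TestCohortCalibration:
    """Statistical shape of the default study conditions, at reduced n."""

    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = synth.GeneratorConfig(n_genes=800)
        return synth.generate_cohort(cfg, n_experiments=60, seed=11), cfg

    def test_rsd_fraction(self, cohort):
        c, _ = cohort
        summ = ex.summarize(c.expression)
        assert (summ["rsd"] < 1).mean() >= 0.79

    def test_dynamic_range_spans_orders_of_magnitude(self, cohort):
        c, _ = cohort
        med = ex.summarize(c.expression)["median_tpm"]
        assert np.log10(med.max()) - np.log10(med.min()) >= 3.5

    def test_variance_ratio_median(self, cohort):
        c, _ = cohort
        vr = ex.variance_ratio(c.expression)["ratio"]
        finite = vr[np.isfinite(vr)]
        assert np.median(finite) >= 100


class TestOrthologs:
    def _genes(self, n=40):
        cfg = small_config(n_genes=n)
        genes, _ = synth.generate_genome(cfg, seed=0)
        return genes

    def test_zero_rate_identical_sequences(self):
        genes = self._genes(5)
        alns, _ = synth.generate_orthologs(genes, 4, 0.0, seed=1, mean_rate=0.0)
        for g in genes:
            seqs = alns[g.gene_id]["promoter"].sequences
            assert len(set(seqs)) == 1

    def test_invalid_correlation_rejected(self):
        genes = self._genes(5)
        with pytest.raises(ValueError):
            synth.generate_orthologs(genes, 4, 1.0, seed=1)
        with pytest.raises(ValueError):
            synth.generate_orthologs(genes, 2, 0.3, seed=1)

    def test_zero_correlation_true_rates_uncorrelated(self):
        genes = self._genes(300)
        _, rates = synth.generate_orthologs(genes, 3, 0.0, seed=2)
        wide = rates.pivot(index="gene_id", columns="region", values="true_rate")
        r = np.corrcoef(wide["promoter"], wide["cds"])[0, 1]
        assert abs(r) < 0.12  # |r| ~ 1/sqrt(n) noise at n=300

    def test_planted_correlation_of_true_rates(self):
        genes = self._genes(400)
        _, rates = synth.generate_orthologs(genes, 3, 0.45, seed=3)
        wide = rates.pivot(index="gene_id", columns="region", values="true_rate")
        r = np.corrcoef(wide["promoter"], wide["cds"])[0, 1]
        assert r == pytest.approx(0.45, abs=0.12)


class TestWriters:
    def test_write_cohort_outputs(self, tmp_path):
        cfg = small_config(n_genes=20)
        cohort = synth.generate_cohort(cfg, n_experiments=4, seed=0)
        paths = synth.write_cohort(cohort, tmp_path)
        from Bio import SeqIO

        records = list(SeqIO.parse(paths["fasta_promoter"], "fasta"))
        assert len(records) == 20
        assert str(records[0].seq) == cohort.genes[0].regions["promoter"]
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["motifs"]) == cfg.n_motifs
        from reggrammar.motifs import read_meme

        motifs = read_meme(paths["meme"])
        assert len(motifs) == cfg.n_motifs
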