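import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from homeocaps.aflp import summarize_matrix
from homeocaps.genotyping import Genotype, Tier
from homeocaps.expression import Expression
from homeocaps.pipeline import run_study
from homeocaps.simulate import (
    SimulationConfig,
    aflp_fixture_from_counts,
    caps_fixture_from_counts,
    fixture_from_counts,
    simulate_aflp_matrix,
    simulate_cohort,
    simulate_parental_alleles,
)

QUIET = dict(
    loss_prob_paternal=0.0,
    loss_prob_maternal=0.0,
    silencing_prob=0.0,
    parental_polymorphism_prob=0.0,
    band_dropout_prob=0.0,
    size_jitter_rel=0.0,
)


def run_pipeline(ds):
    return run_study(ds.alleles, ds.observations, ds.individuals, ds.config.enzyme_panel, ds.config.gel)


class TestParentalAlleles:
    def test_zero_divergence_identical(self):
        cfg = SimulationConfig(seed=3, n_loci=5, divergence=0.0)
        for la in simulate_parental_alleles(cfg):
            assert la.maternal_allele.residues == la.paternal_allele.residues

    def test_divergence_matches_binomial_expectation(self):
        cfg = SimulationConfig(seed=5, n_loci=100, locus_length=1000, divergence=0.01)
        alleles = simulate_parental_alleles(cfg)
        diffs = [
            sum(a != b for a, b in zip(la.maternal_allele.residues, la.paternal_allele.residues))
            for la in alleles
        ]
        n = 100 * 1000
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(np.mean(diffs) / 1000 - 0.01) <= 3 * se

    def test_determinism(self):
        cfg = SimulationConfig(seed=11, n_loci=4)
        a = simulate_parental_alleles(cfg)
        b = simulate_parental_alleles(cfg)
        assert [x.maternal_allele.residues for x in a] == [x.maternal_allele.residues for x in b]
        assert [x.paternal_allele.residues for x in a] == [x.paternal_allele.residues for x in b]


class TestSimulateCohort:
    def test_f1_mode_everything_additive_and_expressed(self):
        cfg = SimulationConfig(seed=2, n_loci=30, n_polyploids=0, n_f1=6, **QUIET)
        ds = simulate_cohort(cfg)
        res = run_pipeline(ds)
        assert res.informative_loci  # the study must be scorable at all
        for call in res.genotype_calls.values():
            assert call.value is Genotype.ADDITIVE
        for ecall in res.expression_calls.values():
            assert ecall.value is Expression.BOTH_EXPRESSED

    def test_noise_free_exact_label_recovery(self):
        cfg = SimulationConfig(
            seed=9, n_loci=30, n_polyploids=40,
            loss_prob_paternal=0.05, loss_prob_maternal=0.05, silencing_prob=0.05,
            parental_polymorphism_prob=0.0, band_dropout_prob=0.0, size_jitter_rel=0.0,
        )
        ds = simulate_cohort(cfg)
        res = run_pipeline(ds)
        state_to_call = {
            "additive": Genotype.ADDITIVE,
            "maternal_only": Genotype.LOSS_PATERNAL,
            "paternal_only": Genotype.LOSS_MATERNAL,
        }
        assert res.genotype_calls  # nonempty
        for (ind, lid), call in res.genotype_calls.items():
            assert call.value is state_to_call[ds.truth.genotype_state[(ind, lid)]]

    def test_never_both_homeologs_lost(self):
        cfg = SimulationConfig(
            seed=13, n_loci=10, n_polyploids=30,
            loss_prob_paternal=0.9, loss_prob_maternal=0.9,
            silencing_prob=0.0, parental_polymorphism_prob=0.0,
            band_dropout_prob=0.0, size_jitter_rel=0.0,
        )
        ds = simulate_cohort(cfg)
        assert all(state in ("additive", "maternal_only", "paternal_only") for state in ds.truth.genotype_state.values())
        assert ds.suppressed_double_losses  # at these rates suppression must have fired

    def test_forced_parental_polymorphism_excludes_every_locus(self):
        cfg = SimulationConfig(
            seed=4, n_loci=10, n_polyploids=5, parental_polymorphism_prob=1.0,
            loss_prob_paternal=0.0, loss_prob_maternal=0.0, silencing_prob=0.0,
            band_dropout_prob=0.0, size_jitter_rel=0.0,
        )
        ds = simulate_cohort(cfg)
        res = run_pipeline(ds)
        assert res.summary.genes_excluded == len(res.locus_summaries)
        assert res.summary.genes_with_loss == 0

    def test_no_silencing_call_for_lost_homeolog(self):
        cfg = SimulationConfig(
            seed=21, n_loci=15, n_polyploids=30,
            loss_prob_paternal=0.2, loss_prob_maternal=0.1, silencing_prob=0.2,
            parental_polymorphism_prob=0.0, band_dropout_prob=0.0, size_jitter_rel=0.0,
        )
        ds = simulate_cohort(cfg)
        res = run_pipeline(ds)
        for (ind, lid), ecall in res.expression_calls.items():
            if ecall.value in (Expression.SILENCED_MATERNAL, Expression.SILENCED_PATERNAL):
                assert ds.truth.genotype_state[(ind, lid)] == "additive"

    def test_loss_rate_recovery_matches_realized_truth_exactly(self):
        cfg = SimulationConfig(
            seed=17, n_loci=30, n_polyploids=40,
            loss_prob_paternal=0.1, loss_prob_maternal=0.05,
            silencing_prob=0.0, parental_polymorphism_prob=0.0,
            band_dropout_prob=0.0, size_jitter_rel=0.0,
        )
        ds = simulate_cohort(cfg)
        res = run_pipeline(ds)
        informative = set(res.informative_loci)
        true_pat = sum(
            1 for (ind, lid), s in ds.truth.genotype_state.items()
            if lid in informative and s == "maternal_only"
        )
        true_mat = sum(
            1 for (ind, lid), s in ds.truth.genotype_state.items()
            if lid in informative and s == "paternal_only"
        )
        called_pat = sum(c.value is Genotype.LOSS_PATERNAL for c in res.genotype_calls.values())
        called_mat = sum(c.value is Genotype.LOSS_MATERNAL for c in res.genotype_calls.values())
        assert (called_pat, called_mat) == (true_pat, true_mat)

    def test_truth_unperturbed_by_noise_settings(self):
        base = SimulationConfig(seed=8, n_loci=10, n_polyploids=10, parental_polymorphism_prob=0.0)
        noisy = dataclasses.replace(base, band_dropout_prob=0.3, size_jitter_rel=0.04)
        assert simulate_cohort(base).truth.genotype_state == simulate_cohort(noisy).truth.genotype_state

    def test_determinism_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_loci=8, n_polyploids=10)
        simulate_cohort(cfg).write(tmp_path / "a")
        simulate_cohort(cfg).write(tmp_path / "b")
        for name in ("alleles.fasta", "individuals.tsv", "observations.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_bias_ordering_in_expectation(self):
        """Paternal-biased loss probabilities yield paternal-biased pipeline percentages on average."""
        pat_pcts, mat_pcts = [], []
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed, n_loci=10, n_polyploids=20, locus_length=300,
                loss_prob_paternal=0.08, loss_prob_maternal=0.02,
                silencing_prob=0.0, parental_polymorphism_prob=0.0,
                band_dropout_prob=0.0, size_jitter_rel=0.0,
            )
            ds = simulate_cohort(cfg)
            res = run_pipeline(ds)
            if not res.locus_summaries:
                continue
            t = res.summary.loss_tally
            pat_pcts.append(t.paternal_loss_percent)
            mat_pcts.append(t.maternal_loss_percent)
        assert np.mean(pat_pcts) > np.mean(mat_pcts)


class TestAFLPSimulation:
    def test_all_monomorphic_config(self):
        m = simulate_aflp_matrix(n_fragments=50, class_freqs={"monomorphic": 1.0}, seed=1)
        assert summarize_matrix(m).percentages["monomorphic"] == 100.0

    def test_class_frequency_recovery_within_3se(self):
        freqs = {"monomorphic": 0.35, "other": 0.65}
        n = 10_000
        m = simulate_aflp_matrix(n_fragments=n, class_freqs=freqs, seed=2)
        s = summarize_matrix(m)
        p_hat = s.counts["monomorphic"] / n
        se = np.sqrt(0.35 * 0.65 / n)
        assert abs(p_hat - 0.35) <= 3 * se

    def test_determinism(self):
        a = simulate_aflp_matrix(n_fragments=100, seed=5)
        b = simulate_aflp_matrix(n_fragments=100, seed=5)
        assert np.array_equal(a.presence, b.presence)


class TestFixturesFromCounts:
    def test_caps_fixture_reproduces_gene_tallies(self):
        ds = caps_fixture_from_counts(genes=5, loss_genes=2, excluded_genes=1,
                                      paternal_loss_genes=2, maternal_loss_genes=1,
                                      silenced_genes=1)
        res = run_pipeline(ds)
        from homeocaps.stats import tally_gene_status
        assert tally_gene_status(res.locus_summaries) == (2, 2, 1)

    def test_inconsistent_aflp_spec_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            aflp_fixture_from_counts(total=10, monomorphic=11)

    def test_inconsistent_caps_spec_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            caps_fixture_from_counts(genes=5, loss_genes=2, excluded_genes=4)
        with pytest.raises(ValueError, match="inconsistent"):
            caps_fixture_from_counts(genes=30, loss_genes=9, paternal_loss_genes=3, maternal_loss_genes=3)

    def test_dispatcher_routes_on_keys(self):
        from homeocaps.aflp import FragmentMatrix
        from homeocaps.simulate import SyntheticDataset
        assert isinstance(fixture_from_counts(total=10, monomorphic=10), FragmentMatrix)
        assert isinstance(fixture_from_counts(genes=5, loss_genes=0, excluded_genes=0,
                                              paternal_loss_genes=0, maternal_loss_genes=0,
                                              silenced_genes=0), SyntheticDataset)
        with pytest.raises(ValueError):
            fixture_from_counts(bananas=3)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError, match="loss_prob_paternal"):
        SimulationConfig(loss_prob_paternal=1.2)


def test_silencing_false_positive_rate_bounded_by_dropout():
    """At truly additive-and-expressed loci, a homeolog is falsely called
    silenced only when every one of its diagnostic transcript bands drops out,
    so the per-homeolog false-positive rate is bounded by the dropout
    probability."""
    for p in (0.01, 0.05):
        fp = n_homeologs = 0
        seed = 0
        while n_homeologs < 2000:
            cfg = SimulationConfig(
                seed=1000 + seed, n_loci=10, n_polyploids=25, locus_length=400,
                loss_prob_paternal=0.0, loss_prob_maternal=0.0, silencing_prob=0.0,
                parental_polymorphism_prob=0.0, band_dropout_prob=p, size_jitter_rel=0.0,
            )
            seed += 1
            ds = simulate_cohort(cfg)
            res = run_pipeline(ds)
            for ecall in res.expression_calls.values():
                n_homeologs += 2  # each lane reads out both retained homeologs
                if ecall.value in (Expression.SILENCED_MATERNAL, Expression.SILENCED_PATERNAL):
                    fp += 1
        # 3-sigma slack on the binomial bound
        assert fp / n_homeologs <= p + 3 * np.sqrt(p * (1 - p) / n_homeologs)
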