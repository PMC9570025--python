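"""Synthetic-data generator: determinism, grammar soundness, noise model."""

import numpy as np
import pytest
from scipy import stats

from venomsig.io_formats import RunConfig
from venomsig.maturation import Strategy, mature_candidates
from venomsig.pipeline import run_analysis
from venomsig.spectral_evidence import consensus_signals
from venomsig.specificity import expression_contrast
from venomsig.synthetic_data import (
    evaluate_recovery,
    generate_precursors,
    simulate_bundle,
    simulate_expression,
    simulate_peaklists,
    simulate_psms,
)


class TestGeneratePrecursors:
    def test_requested_count_and_determinism(self):
        a = generate_precursors(12, seed=7)
        b = generate_precursors(12, seed=7)
        assert len(a.precursors) == 12
        assert a.precursors == b.precursors
        assert a.labels == b.labels

    def test_different_seeds_differ(self):
        a = generate_precursors(6, seed=1)
        b = generate_precursors(6, seed=2)
        assert a.precursors != b.precursors

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_grammar_soundness_auto_recovers_planted(self, seed):
        """AUTO enumeration always contains the planted mature product."""
        truth = generate_precursors(25, seed=seed)
        for p in truth.precursors:
            auto = {
                (m.sequence, m.amidated)
                for m in mature_candidates(p, Strategy.AUTO)
            }
            for planted in truth.mature[p.id]:
                assert (planted.sequence, planted.amidated) in auto

    def test_amp_with_amidation_cassette(self):
        truth = generate_precursors(
            8, class_mix={"AMP": 1.0}, allelic_fraction=0.0, seed=3
        )
        amidated = [
            truth.mature[p.id][0] for p in truth.precursors
            if truth.mature[p.id][0].amidated
        ]
        assert amidated, "expected at least one Gly-amidation cassette"
        for m in amidated:
            assert m.n_disulfides == 0  # AMPs are non-disulfide-bridged

    def test_toxin_cores_have_even_cysteines(self):
        truth = generate_precursors(
            10, class_mix={"neurotoxin": 1.0}, allelic_fraction=0.0, seed=5
        )
        for peps in truth.mature.values():
            for m in peps:
                assert m.sequence.count("C") % 2 == 0

    def test_allelic_markers_expand_to_two_products(self):
        truth = generate_precursors(
            30, allelic_fraction=1.0, seed=9, min_mass_separation_da=0.5
        )
        n_allelic = sum("/" in p.sequence for p in truth.precursors)
        assert n_allelic > 0
        for p in truth.precursors:
            if "/" in p.sequence:
                assert len(truth.mature[p.id]) == 2

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_precursors(3, class_mix={"AMP": 0.5})

    def test_mass_separation(self):
        truth = generate_precursors(30, seed=2)
        masses = sorted(m for ms in truth.masses.values() for m in ms)
        gaps = np.diff(masses)
        assert (gaps >= 1.0).all()


class TestSimulatePeaklists:
    def test_panel_design(self):
        truth = generate_precursors(5, seed=0)
        pls = simulate_peaklists(truth, seed=0)
        assert len(pls) == 20  # 10 specimens x 2 replicates
        assert sum(pl.group == "male" for pl in pls) == 4

    def test_noise_free_presence_matches_truth(self):
        truth = generate_precursors(15, seed=4)
        pls = simulate_peaklists(
            truth, p_detect_present=1.0, p_detect_absent=0.0,
            jitter_sd_da=0.0, spurious_rate=0.0, seed=1,
        )
        masses = {m for ms in truth.masses.values() for m in ms}
        for pl in pls:
            assert set(pl.signals) <= masses

    def test_binomial_retention_law(self):
        """Retention of a planted signal across n=8 spectra at the 50%
        occurrence threshold follows the closed-form binomial tail."""
        n, p, trials = 8, 0.8, 2000
        expected = stats.binom.sf(3, n, p)  # P(X >= 4)
        rng = np.random.default_rng(2024)
        retained = 0
        from venomsig.spectral_evidence import PeakList

        for _ in range(trials):
            pls = [
                PeakList(
                    f"f{i}", "female",
                    (5000.0,) if rng.random() < p else (), str(i),
                )
                for i in range(n)
            ]
            sigs = consensus_signals(pls, 0.15, 0.5)
            retained += bool(sigs)
        observed = retained / trials
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(observed - expected) < 3 * se

    def test_spurious_only_rarely_reaches_consensus(self):
        truth = generate_precursors(1, seed=0)
        # label everything absent so only spurious peaks remain
        pls = simulate_peaklists(
            truth, p_detect_present=0.0, p_detect_absent=0.0,
            jitter_sd_da=0.0, spurious_rate=5.0, seed=8,
        )
        female = [pl for pl in pls if pl.group == "female"]
        assert consensus_signals(female, 0.15, 0.5) == []


class TestSimulateExpression:
    def test_noise_free_directions_recovered(self):
        truth = generate_precursors(20, seed=6)
        expr = simulate_expression(truth, dispersion=0.0, seed=1)
        for pid, tri in expr.items():
            direction, _ = expression_contrast(tri, 2.0)
            expected = {
                "up_in_males": "male_up",
                "down_in_males": "female_up",
                "unspecific": "flat",
            }[truth.labels[pid]]
            assert direction == expected

    def test_high_fold_direction_recovery(self):
        """At 100-fold enrichment and realistic dispersion, >=95% of
        specific precursors keep their planted direction."""
        truth = generate_precursors(
            500,
            label_mix={"up_in_males": 0.5, "down_in_males": 0.5, "unspecific": 0.0},
            seed=10,
            min_mass_separation_da=0.0,
        )
        expr = simulate_expression(truth, fold_specific=100, dispersion=0.5, seed=2)
        hits = 0
        for pid, tri in expr.items():
            direction, _ = expression_contrast(tri, 2.0)
            expected = (
                "male_up" if truth.labels[pid] == "up_in_males" else "female_up"
            )
            hits += direction == expected
        assert hits / len(expr) >= 0.95


class TestEvaluateRecovery:
    def test_perfect_calls(self):
        truth = generate_precursors(10, seed=0)
        rec = evaluate_recovery(dict(truth.labels), truth)
        present = rec.dropna()
        assert (present["precision"] == 1.0).all()
        assert (present["recall"] == 1.0).all()

    def test_all_unspecific_calls(self):
        truth = generate_precursors(
            10,
            label_mix={"up_in_males": 0.5, "down_in_males": 0.5, "unspecific": 0.0},
            seed=1,
        )
        calls = {pid: "unspecific" for pid in truth.labels}
        rec = evaluate_recovery(calls, truth)
        assert rec.loc["up_in_males", "recall"] == 0.0
        assert rec.loc["down_in_males", "recall"] == 0.0

    def test_id_mismatch_rejected(self):
        truth = generate_precursors(3, seed=0)
        with pytest.raises(ValueError, match="same precursor ids"):
            evaluate_recovery({"other": "unspecific"}, truth)


class TestEndToEnd:
    def test_noise_free_run_reproduces_truth_exactly(self):
        truth = generate_precursors(30, seed=11)
        pls = simulate_peaklists(
            truth, p_detect_present=1.0, p_detect_absent=0.0,
            jitter_sd_da=0.0, spurious_rate=0.0, seed=1,
        )
        expr = simulate_expression(truth, dispersion=0.0, seed=2)
        psms = simulate_psms(truth, seed=3)
        result = run_analysis(truth.precursors, pls, expr, psms, config=RunConfig())
        calls = {c.precursor_id: c.call for c in result.calls}
        assert calls == truth.labels

    def test_failing_psms_are_filtered_out(self):
        truth = generate_precursors(10, seed=11)
        pls = simulate_peaklists(truth, seed=1)
        expr = simulate_expression(truth, seed=2)
        psms = simulate_psms(truth, fail_fraction=1.0, seed=3)
        result = run_analysis(truth.precursors, pls, expr, psms)
        assert set(result.report["call"]) == {"filtered"}


class TestBundle:
    def test_bundle_round_trips_through_pipeline(self, tmp_path):
        from venomsig import io_formats

        truth = simulate_bundle(tmp_path, n=8, seed=5)
        precursors = io_formats.read_precursor_fasta(
            tmp_path / "precursors.fasta", tmp_path / "annotations.tsv"
        )
        assert precursors == truth.precursors
        result = run_analysis(
            precursors,
            io_formats.read_peaklists(tmp_path / "peaklists.tsv"),
            io_formats.read_expression_table(tmp_path / "expression.tsv"),
            io_formats.read_psm_table(tmp_path / "psms.tsv"),
        )
        assert len(result.report) == 8

    def test_same_seed_identical_bytes(self, tmp_path):
        simulate_bundle(tmp_path / "a", n=6, seed=9)
        simulate_bundle(tmp_path / "b", n=6, seed=9)
        for name in ("precursors.fasta", "peaklists.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
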