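import math
import time

import numpy as np
import pytest

from homeosplit import (
    IntractableSearchError,
    best_split,
    complement_pattern,
    estimate_p1,
    exhaustive_candidates,
    find_questionable_sites,
    heuristic_candidates,
    majority_split,
    questionable_set_from_sites,
    simulate_contig,
    simulate_dataset,
    site_log_prob,
    split_all_contigs,
    split_log_likelihood,
    summarize_sites,
)
from homeosplit.splitter import P_EPS

from conftest import make_contig
from oracles import brute_force_split_probability, random_small_instance


class TestComplementPattern:
    def test_near_balanced_site_complements_to_the_other_majority(self):
        # Global counts A:43, G:44: choosing G for Ck1 leaves A for Ck2.
        counts = np.array([[[10, 0, 32, 0]], [[33, 0, 12, 0]]])
        contig = make_contig(counts)
        summaries = summarize_sites(contig)
        assert complement_pattern([3], summaries).tolist() == [1]
        assert complement_pattern([1], summaries).tolist() == [3]

    def test_majority_pattern_complements_to_global_mf2(self, fig2_contig):
        contig, qset = fig2_contig
        summaries = summarize_sites(contig, qset.questionable_sites)
        mf1 = [s.mf1_global for s in summaries]
        mf2 = [s.mf2_global for s in summaries]
        assert complement_pattern(mf1, summaries).tolist() == mf2
        assert complement_pattern(mf2, summaries).tolist() == mf1

    def test_single_nucleotide_site_cannot_be_complemented(self):
        contig = make_contig([[[20, 0, 0, 0]]])
        summaries = summarize_sites(contig)
        with pytest.raises(ValueError, match="complement"):
            complement_pattern([1], summaries)


class TestEstimateP1:
    def test_worked_two_site_proportions(self, fig2_contig):
        contig, qset = fig2_contig
        p1 = estimate_p1(contig, qset, [2, 1])  # pattern "CA"
        assert p1[0] == pytest.approx(np.mean([5 / 20, 10 / 42]), abs=1e-12)
        assert p1[1] == pytest.approx(np.mean([16 / 20, 33 / 45]), abs=1e-12)

    def test_balanced_sites_give_half(self):
        contig = make_contig([[[10, 10, 0, 0], [25, 25, 0, 0]]])
        qset = questionable_set_from_sites(contig, [0, 1])
        assert estimate_p1(contig, qset, [1, 1])[0] == pytest.approx(0.5)

    def test_low_coverage_accession_is_missing(self):
        contig = make_contig([[[5, 4, 0, 0]]])  # coverage 9 < 10
        qset = questionable_set_from_sites(contig, [0])
        assert np.isnan(estimate_p1(contig, qset, [1])[0])


class TestSiteLogProb:
    def test_symmetric_closed_form(self):
        # (C(6,3) * 0.5^6)^2 = 0.3125^2 = 0.09765625
        value = site_log_prob([3, 3, 0, 0], 1, 2, 0.5, 0.5)
        assert value == pytest.approx(math.log(0.09765625), abs=1e-12)

    def test_empty_site_has_probability_one(self):
        assert site_log_prob([0, 0, 0, 0], 1, 2, 0.3, 0.7) == 0.0

    def test_error_nucleotide_split_loses_to_the_real_one(self):
        # 49 A, 50 C, 1 T: explaining the T as a homeolog forces the C copy
        # to be wildly improbable; the A/C split must win by a wide margin.
        contig = make_contig([[[49, 50, 0, 1]]])
        qset = questionable_set_from_sites(contig, [0])
        ll_t = split_log_likelihood(contig, qset, [4]).log_likelihood
        ll_a = split_log_likelihood(contig, qset, [1]).log_likelihood
        assert ll_a > ll_t + 50

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"count_vector": [1, -1, 0, 0], "ck1_nuc": 1, "ck2_nuc": 2, "p1a": 0.5, "p2a": 0.5},
            {"count_vector": [1, 1, 0, 0], "ck1_nuc": 2, "ck2_nuc": 2, "p1a": 0.5, "p2a": 0.5},
            {"count_vector": [1, 1, 0, 0], "ck1_nuc": 1, "ck2_nuc": 2, "p1a": 0.0, "p2a": 1.0},
        ],
    )
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            site_log_prob(**kwargs)


class TestSplitLogLikelihood:
    def test_single_accession_closed_form(self):
        contig = make_contig([[[10, 10, 0, 0]]])
        qset = questionable_set_from_sites(contig, [0])
        result = split_log_likelihood(contig, qset, [1])
        expected = 2 * math.log(math.comb(20, 10) * 0.5**20)
        assert result.log_likelihood == pytest.approx(expected, rel=1e-12)
        assert result.ck2.tolist() == [2]

    def test_empty_questionable_set_is_an_error(self):
        contig = make_contig([[[10, 10, 0, 0]]])
        qset = questionable_set_from_sites(contig, [])
        with pytest.raises(ValueError, match="no questionable site"):
            split_log_likelihood(contig, qset, [])

    def test_agrees_with_direct_probability_product(self):
        rng = np.random.default_rng(41)
        for _ in range(40):
            contig, qset, pattern = random_small_instance(rng)
            result = split_log_likelihood(contig, qset, pattern)
            expected = math.log(brute_force_split_probability(contig, qset, pattern))
            assert result.log_likelihood == pytest.approx(expected, rel=1e-9)

    def test_matches_scalar_operation_composition(self):
        """The vectorised likelihood equals the sum of scalar site terms."""
        rng = np.random.default_rng(13)
        contig, qset, pattern = random_small_instance(
            rng, max_sites=3, max_accessions=3
        )
        result = split_log_likelihood(contig, qset, pattern)
        p1 = estimate_p1(contig, qset, pattern)
        total = 0.0
        for a in range(contig.n_accessions):
            if np.isnan(p1[a]):
                continue
            p1c = min(max(p1[a], P_EPS), 1 - P_EPS)
            for j, s in enumerate(qset.questionable_sites):
                total += site_log_prob(
                    contig.counts[a, s], int(result.ck1[j]), int(result.ck2[j]),
                    p1c, 1 - p1c,
                )
        assert result.log_likelihood == pytest.approx(total, rel=1e-12)

    def test_sequences_differ_only_at_questionable_sites(self):
        contig, truth = simulate_contig(
            length=80, n_divergent=4, n_accessions=8, coverage_lambda=25, seed=3
        )
        qset = find_questionable_sites(contig)
        result = best_split(contig, qset)
        qs = set(qset.questionable_sites.tolist())
        for s, (b0, b1, b2) in enumerate(zip(contig.ref_seq, result.seq1, result.seq2)):
            if s not in qs:
                assert b0 == b1 == b2


class TestCandidates:
    def test_opposite_majorities_give_three_candidates(self, fig2_contig):
        contig, qset = fig2_contig
        candidates = heuristic_candidates(contig, qset)
        assert candidates[0].tolist() == [2, 3]  # global majority first
        # accession 1 majority [A,G], accession 2 majority [C,A]
        assert {tuple(c) for c in candidates} == {(2, 3), (1, 3), (2, 1)}

    def test_identical_majorities_collapse_to_one_candidate(self):
        counts = np.tile([30, 10, 0, 0], (4, 2, 1)).reshape(4, 2, 4)
        contig = make_contig(counts)
        qset = questionable_set_from_sites(contig, [0, 1])
        assert len(heuristic_candidates(contig, qset)) == 1

    def test_heuristic_candidate_count_is_at_most_m_plus_one(self):
        for seed in range(5):
            contig, _ = simulate_contig(
                length=60, n_divergent=4, n_accessions=7, coverage_lambda=15,
                seed=seed,
            )
            qset = find_questionable_sites(contig)
            if qset.n_questionable == 0:
                continue
            assert len(heuristic_candidates(contig, qset)) <= contig.n_accessions + 1

    def test_exhaustive_two_by_two_sites(self):
        counts = np.tile([[10, 10, 0, 0], [0, 12, 0, 9]], (3, 1, 1))
        contig = make_contig(counts)
        qset = questionable_set_from_sites(contig, [0, 1])
        candidates = exhaustive_candidates(contig, qset)
        assert {tuple(c) for c in candidates} == {
            (1, 2), (1, 4), (2, 2), (2, 4)
        }

    def test_exhaustive_three_nucleotide_site(self):
        contig = make_contig([[[10, 10, 10, 1]]])
        qset = questionable_set_from_sites(contig, [0])
        assert {tuple(c) for c in exhaustive_candidates(contig, qset)} == {
            (1,), (2,), (3,)
        }

    def test_alphabets_never_include_unobserved_nucleotides(self):
        for seed in range(5):
            contig, _ = simulate_contig(
                length=60, n_divergent=4, n_accessions=6, coverage_lambda=20,
                seed=seed + 50,
            )
            qset = find_questionable_sites(contig)
            if qset.n_questionable == 0:
                continue
            observed = contig.counts.sum(axis=0) > 0  # (N, 4)
            for pattern in exhaustive_candidates(contig, qset):
                for j, s in enumerate(qset.questionable_sites):
                    assert observed[s, pattern[j] - 1]

    def test_combination_cap_raises_intractable(self):
        counts = np.tile([10, 10, 0, 0], (2, 12, 1)).reshape(2, 12, 4)
        contig = make_contig(counts)
        qset = questionable_set_from_sites(contig, range(12))
        with pytest.raises(IntractableSearchError, match="heuristic"):
            exhaustive_candidates(contig, qset, max_combinations=2**10)


class TestBestSplit:
    def test_recovers_planted_pairs_under_strong_bias(self):
        contig, truth = simulate_contig(
            length=120, n_divergent=6, n_accessions=15, coverage_lambda=30,
            error_rate=0.0,
            bias_distribution={"kind": "uniform", "low": 0.7, "high": 0.95, "flip": True},
            seed=23,
        )
        qset = find_questionable_sites(contig)
        result = best_split(contig, qset)
        planted = dict(truth.divergent_sites)
        for j, s in enumerate(qset.questionable_sites):
            assert {int(result.ck1[j]), int(result.ck2[j])} == set(planted[int(s)])

    def test_symmetric_tie_returns_the_majority_pattern(self):
        contig = make_contig([[[10, 10, 0, 0]]])
        qset = questionable_set_from_sites(contig, [0])
        result = best_split(contig, qset, mode="exhaustive")
        assert result.ck1.tolist() == [1]  # global majority (A by tie-break)
        assert result.ck2.tolist() == [2]

    def test_exhaustive_dominates_heuristic(self):
        for seed in range(8):
            contig, _ = simulate_contig(
                length=60, n_divergent=4, n_accessions=8, coverage_lambda=25,
                seed=seed + 100,
            )
            qset = find_questionable_sites(contig)
            if qset.n_questionable == 0 or qset.n_questionable > 8:
                continue
            ll_ex = best_split(contig, qset, mode="exhaustive").log_likelihood
            ll_he = best_split(contig, qset, mode="heuristic").log_likelihood
            assert ll_ex >= ll_he - 1e-9

    def test_auto_mode_resolves_by_tractability(self):
        contig, _ = simulate_contig(
            length=60, n_divergent=3, n_accessions=6, coverage_lambda=30, seed=9
        )
        qset = find_questionable_sites(contig)
        assert best_split(contig, qset, mode="auto").method == "exhaustive"
        assert (
            best_split(contig, qset, mode="auto", max_combinations=1).method
            == "heuristic"
        )

    def test_non_questionable_contig_is_an_error(self):
        contig = make_contig([[[20, 0, 0, 0]]])
        qset = find_questionable_sites(contig)
        with pytest.raises(ValueError, match="not questionable"):
            best_split(contig, qset)


class TestMajoritySplit:
    def test_ck1_equals_the_input_consensus(self):
        contig, _ = simulate_contig(
            length=80, n_divergent=5, n_accessions=10, coverage_lambda=30, seed=31
        )
        qset = find_questionable_sites(contig)
        result = majority_split(contig, qset)
        assert result.seq1 == contig.ref_seq
        assert result.method == "majority"

    def test_balanced_site_majority_differs_from_likelihood_choice(self, fig2_contig):
        # Pooled counts favour G at the blurred site, but the per-accession
        # expression bias makes the "CA"/complement split more likely.
        contig, qset = fig2_contig
        maj = majority_split(contig, qset)
        best = best_split(contig, qset, mode="exhaustive")
        assert maj.ck1.tolist() == [2, 3]
        assert best.ck1.tolist() != maj.ck1.tolist()
        assert best.log_likelihood > maj.log_likelihood

    def test_uniform_bias_direction_matches_best_split(self):
        contig, _ = simulate_contig(
            length=100, n_divergent=5, n_accessions=10, coverage_lambda=30,
            error_rate=0.0,
            bias_distribution={"kind": "uniform", "low": 0.7, "high": 0.9, "flip": False},
            seed=47,
        )
        qset = find_questionable_sites(contig)
        assert (
            majority_split(contig, qset).ck1.tolist()
            == best_split(contig, qset).ck1.tolist()
        )


class TestSplitAllContigs:
    def test_record_counts_and_report(self):
        dataset, truths = simulate_dataset(
            n_contigs=10, fraction_mixed=0.5, length=80, n_divergent=4,
            n_accessions=10, coverage_lambda=30, seed=77,
        )
        records, report = split_all_contigs(dataset, mode="heuristic")
        n_mixed = sum(t.is_mixed for t in truths)
        assert n_mixed == 5
        assert len(report) == 10
        split_rows = report[report["method"] != "none"]
        assert len(split_rows) == n_mixed
        assert len(records) == (10 - n_mixed) + 2 * n_mixed
        ids = [rid for rid, _ in records]
        for t in truths:
            if t.is_mixed:
                assert f"{t.contig_id}_1" in ids and f"{t.contig_id}_2" in ids
            else:
                assert t.contig_id in ids

    def test_runtime_scales_roughly_linearly(self):
        """4x the contigs should cost clearly less than quadratic time."""

        def run(n_contigs, seed):
            dataset, _ = simulate_dataset(
                n_contigs=n_contigs, fraction_mixed=0.5, length=150,
                n_divergent=6, n_accessions=10, coverage_lambda=25, seed=seed,
            )
            best = np.inf
            for _ in range(2):
                start = time.perf_counter()
                split_all_contigs(dataset, mode="heuristic")
                best = min(best, time.perf_counter() - start)
            return best

        t_small = run(6, seed=1)
        t_large = run(24, seed=2)
        assert t_large < 10 * max(t_small, 1e-3)
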