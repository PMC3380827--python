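"""Homozygosity-mapping statistic, permutation null and interval extraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_asshom, random_small_panel
from polledmap import mapping, simulate
from polledmap.mapping import GenotypePanel


def panel_from_rows(rows, classes, chrom=None, bp=None):
    """Small panel from explicit genotype rows (animals x markers)."""
    G = np.array(rows, dtype=np.int8)
    n_animals, n_markers = G.shape
    chrom = chrom or ["1"] * n_markers
    bp = bp or list(1000 * (1 + np.arange(n_markers)))
    animals = pd.DataFrame({"id": [f"a{i}" for i in range(n_animals)],
                            "breed": "b", "polled_class": classes})
    markers = pd.DataFrame({"id": [f"m{i}" for i in range(n_markers)],
                            "chrom": chrom, "bp": bp})
    return GenotypePanel(animals=animals, markers=markers, genotypes=G)


class TestHomozygousRun:
    def test_run_bounded_by_heterozygous_markers(self):
        # homozygous at markers 3..11, het at 2 and 12 (0-based)
        row = [0, 0, 1] + [0] * 9 + [1, 0]
        panel = panel_from_rows([row], ["PP"])
        assert mapping.homozygous_run(panel, 0, 7) == (3, 11)

    def test_heterozygous_query_gives_empty_run(self):
        panel = panel_from_rows([[0, 1, 0]], ["PP"])
        assert mapping.homozygous_run(panel, 0, 1) is None

    def test_fully_homozygous_chromosome(self):
        panel = panel_from_rows([[0] * 6], ["PP"])
        assert mapping.homozygous_run(panel, 0, 3) == (0, 5)

    def test_run_does_not_cross_chromosomes(self):
        panel = panel_from_rows([[0, 0, 0, 0]], ["PP"],
                                chrom=["1", "1", "2", "2"], bp=[1, 2, 1, 2])
        assert mapping.homozygous_run(panel, 0, 1) == (0, 1)

    def test_missing_inside_run_is_transparent(self):
        panel = panel_from_rows([[0, -1, 0, 1]], ["PP"])
        assert mapping.homozygous_run(panel, 0, 0) == (0, 2)
        assert mapping.homozygous_run(panel, 0, 1) is None  # missing at query


class TestCaseScore:
    def test_closed_form_ten_markers_at_half_frequency(self):
        # run of 10 markers, control frequency 1/2 everywhere:
        # p_hom = 0.5, score = 10 * -log10(0.5)
        case = [0] * 10
        controls = [[0] * 10, [2] * 10]  # f = 0.5 at every marker
        panel = panel_from_rows([case] + controls, ["PP", "pp", "pp"])
        s = mapping.case_score(panel, 0, 4)
        assert s == pytest.approx(10 * np.log10(2), abs=1e-12)

    def test_heterozygous_query_scores_zero(self):
        panel = panel_from_rows([[0, 1, 0], [0, 2, 0], [2, 0, 2]],
                                ["PP", "pp", "pp"])
        assert mapping.case_score(panel, 0, 1) == 0.0

    def test_monomorphic_run_scores_zero(self):
        # controls all homozygous reference: f = 0, p_hom = 1, no information
        panel = panel_from_rows([[0, 0, 0], [0, 0, 0], [0, 0, 0]],
                                ["PP", "pp", "pp"])
        assert mapping.case_score(panel, 0, 1) == 0.0


class TestHarmonicMean:
    @pytest.mark.parametrize("scores,expected", [
        ([2.0, 2.0, 2.0], 2.0),
        ([4.0, 0.0, 4.0], 0.0),   # one zero annihilates
        ([1.0, 3.0], 1.5),        # 2 / (1 + 1/3)
    ])
    def test_examples(self, scores, expected):
        s = np.array(scores)[:, None]
        assert mapping.harmonic_mean_scores(s)[0] == pytest.approx(expected)


class TestStatisticProperties:
    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            panel = random_small_panel(rng, n_animals=int(rng.integers(4, 11)),
                                       n_markers=int(rng.integers(6, 21)))
            expected = brute_force_asshom(panel)
            got = mapping.asshom_profile(panel)
            np.testing.assert_allclose(got, expected, rtol=0, atol=1e-12)

    def test_positive_iff_all_cases_homozygous(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            panel = random_small_panel(rng)
            S = mapping.asshom_profile(panel)
            G = panel.genotypes[panel.case_indices]
            all_hom = ((G == 0) | (G == 2)).all(axis=0)
            # S > 0 implies every case homozygous; where some case is not,
            # S must be 0 (the converse may fail only at zero-weight runs)
            assert not np.any((S > 0) & ~all_hom)
            assert np.all(S[~all_hom] == 0)

    def test_invariant_under_case_relabelling(self, planted_panel):
        S1 = mapping.asshom_profile(planted_panel)
        rng = np.random.default_rng(0)
        order = np.arange(planted_panel.n_animals)
        cases = planted_panel.case_indices
        order[cases] = rng.permutation(cases)
        shuffled = GenotypePanel(
            animals=planted_panel.animals.iloc[order].reset_index(drop=True),
            markers=planted_panel.markers,
            genotypes=planted_panel.genotypes[order])
        np.testing.assert_allclose(mapping.asshom_profile(shuffled), S1)


class TestPermutationNull:
    def test_threshold_is_kth_largest_maximum(self, planted_panel):
        n_perm, alpha = 200, 0.05
        threshold, maxima = mapping.permutation_threshold(planted_panel, n_perm,
                                                          alpha, seed=3)
        k = int(alpha * n_perm)
        assert threshold == np.sort(maxima)[::-1][k - 1]
        assert len(maxima) == n_perm

    def test_alpha_below_resolution_errors(self, planted_panel):
        with pytest.raises(ValueError):
            mapping.permutation_threshold(planted_panel, 100, 0.001, seed=1)

    def test_planted_core_exceeds_threshold(self, planted_spec, planted_panel):
        result = mapping.map_locus(planted_panel, n_perm=300, alpha=0.01, seed=5)
        core = simulate.planted_core_indices(planted_spec, planted_panel)
        assert (result.stats[core] > result.threshold).all()
        assert (result.pvalues[core] <= 0.01).all()


class TestCandidateInterval:
    def test_planted_panel_core_and_flankers(self, planted_spec, planted_panel):
        result = mapping.map_locus(planted_panel, n_perm=300, alpha=0.01, seed=5)
        report = mapping.extract_candidate_interval(result, planted_panel)
        core = simulate.planted_core_indices(planted_spec, planted_panel)
        bp = planted_panel.markers["bp"].to_numpy()
        assert report.core_marker_count == 9
        assert report.core_interval.start == bp[core[0]]
        assert report.core_interval.end == bp[core[-1]]
        left, right = report.flanking_markers
        assert left[1] < bp[core[0]] and right[1] > bp[core[-1]]
        assert not report.degenerate

    def test_single_marker_core(self):
        # one shared homozygous marker between two case-variable markers
        rows = [[1, 0, 1], [1, 0, 1], [0, 0, 2], [2, 2, 0]]
        panel = panel_from_rows(rows, ["PP", "PP", "pp", "pp"])
        result = mapping.AsshomResult(
            stats=mapping.asshom_profile(panel), pvalues=np.ones(3),
            threshold=0.0, n_permutations=0, alpha=1.0, maxima=np.array([]),
            peak_index=1)
        report = mapping.extract_candidate_interval(result, panel)
        assert report.core_marker_count == 1
        assert report.candidate_interval.start == 1000
        assert report.candidate_interval.end == 3000

    def test_degenerate_fully_homozygous_chromosome(self):
        rows = [[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]
        panel = panel_from_rows(rows, ["PP", "PP", "pp", "pp"])
        result = mapping.AsshomResult(
            stats=np.zeros(3), pvalues=np.ones(3), threshold=0.0,
            n_permutations=0, alpha=1.0, maxima=np.array([]), peak_index=1)
        report = mapping.extract_candidate_interval(result, panel)
        assert report.degenerate
        assert report.core_marker_count == 3

    def test_no_significant_marker_warns_and_returns_empty(self, planted_panel):
        result = mapping.AsshomResult(
            stats=np.zeros(planted_panel.n_markers),
            pvalues=np.ones(planted_panel.n_markers), threshold=1.0,
            n_permutations=0, alpha=1.0, maxima=np.array([]), peak_index=None)
        with pytest.warns(UserWarning):
            report = mapping.extract_candidate_interval(result, planted_panel)
        assert report.candidate_interval is None
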