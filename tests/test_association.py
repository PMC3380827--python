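"""Perfect association, compound heterozygotes, recombination, declarations."""

import numpy as np
import pandas as pd
import pytest

from polledmap import association, catalog, simulate


class TestPerfectAssociation:
    def test_holds_on_generated_table(self, population):
        table, _ = population
        report = association.perfect_association_test(table)
        assert report.holds and not report.violations
        assert report.n_evaluated == 1616

    @pytest.mark.parametrize("mutate", [
        lambda t: t.assign(phenotype=np.where(t.index == t[t["pc_copies"] == 1]
                                              .index[0], "horned", t["phenotype"])),
        lambda t: t.assign(phenotype=np.where(t.index == t[(t["pc_copies"] == 0)
                                              & (t["pf_copies"] == 0)].index[0],
                                              "polled", t["phenotype"])),
    ])
    def test_any_single_injected_violation_fails(self, population, mutate):
        table, _ = population
        report = association.perfect_association_test(mutate(table.copy()))
        assert not report.holds
        assert len(report.violations) == 1

    def test_order_invariance(self, population):
        table, _ = population
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert (association.perfect_association_test(shuffled).holds
                == association.perfect_association_test(table).holds)

    def test_empty_table_vacuous_and_degenerate(self):
        empty, _ = simulate.generate_population_table(0, 0, 0, 0, 0, 0, seed=1)
        report = association.perfect_association_test(empty)
        assert report.holds and report.degenerate

    def test_untyped_horned_animals_excluded(self, population):
        table, _ = population
        t = table.copy()
        t.loc[t.index[:5], "pc_copies"] = np.nan
        report = association.perfect_association_test(t)
        assert report.n_evaluated == len(t) - 5


class TestCompoundHeterozygotes:
    def test_exactly_the_planted_compounds(self, population):
        table, _ = population
        hits = association.compound_heterozygote_scan(table)
        assert len(hits) == 3
        assert (hits["pc_copies"] == 1).all() and (hits["pf_copies"] == 1).all()
        assert (hits["predicted_offspring_vs_horned_mates"] == "all polled").all()

    def test_homozygotes_not_listed(self, population):
        table, _ = population
        hits = association.compound_heterozygote_scan(table)
        assert not set(table[table["pc_copies"] == 2]["animal"]) & set(hits["animal"])


class TestBlockRecombination:
    def test_faithful_table_has_no_recombinants(self, population):
        table, _ = population
        assert association.block_recombination_check(
            table, catalog.FRIESIAN_BLOCK) == []

    def test_injected_recombinant_listed(self, population):
        table, _ = population
        t = table.copy()
        victim = t[t["pf_copies"] == 1].index[0]
        t.loc[victim, "gt_P_80kbID"] = 0  # P_5ID variant but reference at P_80kbID
        assert association.block_recombination_check(
            t, catalog.FRIESIAN_BLOCK) == [t.loc[victim, "animal"]]

    def test_consistent_heterozygote_not_listed_and_untyped_skipped(self, population):
        table, _ = population
        t = table.head(20).copy()
        t.loc[t.index[0], "gt_P_5ID"] = np.nan
        with pytest.warns(UserWarning):
            out = association.block_recombination_check(t, catalog.FRIESIAN_BLOCK)
        assert out == []


class TestDeclareGenotype:
    def test_twelve_polled_offspring_declares_pp(self):
        ped = simulate.simulate_progeny_records("BULL", "PP", 12, seed=1)
        declared, prob = association.declare_genotype(ped, "BULL")
        assert declared == "PP"
        assert prob == pytest.approx(0.5 ** 12)  # 2.44e-4

    def test_one_horned_offspring_declares_pp_carrier(self):
        ped = simulate.simulate_progeny_records("BULL", "Pp", 30, seed=2)
        assert (ped["phenotype"] == "horned").sum() > 1
        declared, prob = association.declare_genotype(ped, "BULL")
        assert declared == "Pp" and prob is None

    def test_below_threshold_undeclared(self):
        ped = simulate.simulate_progeny_records("BULL", "PP", 5, seed=1)
        assert association.declare_genotype(ped, "BULL")[0] == "undeclared"

    def test_horned_proband_errors(self):
        ped = pd.DataFrame([{"animal": "H", "sire": "0", "dam": "0",
                             "phenotype": "horned"}])
        with pytest.raises(ValueError):
            association.declare_genotype(ped, "H")

    def test_misclassification_decreases_with_offspring_count(self):
        probs = []
        for n in (12, 13, 14, 15):
            ped = simulate.simulate_progeny_records("B", "PP", n, seed=1)
            probs.append(association.declare_genotype(ped, "B")[1])
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestGenotypeDistribution:
    def test_wildtype_homozygote_percentage(self, population):
        table, _ = population
        dist = association.genotype_distribution_summary(table)
        assert dist["counts"].loc[0, 0] == 1261
        assert dist["percent"].loc[0, 0] == pytest.approx(78.03, abs=0.01)

    def test_percentages_sum_to_hundred(self, population):
        table, _ = population
        dist = association.genotype_distribution_summary(table)
        assert dist["percent"].to_numpy().sum() == pytest.approx(100, abs=0.1)

    def test_single_animal_is_hundred_percent(self):
        table, _ = simulate.generate_population_table(1, 0, 0, 0, 0, 0, seed=1)
        dist = association.genotype_distribution_summary(table)
        assert dist["percent"].loc[0, 0] == 100.0


def test_generator_analyzer_round_trip_over_seeds():
    """Dominance in the generator implies perfect association downstream."""
    for seed in range(3):
        table, _ = simulate.generate_population_table(
            n_prs_hom=50, n_pc_het=10, n_pc_hom=5, n_pf_het=8, n_pf_hom=2,
            n_compound=2, seed=seed)
        assert association.perfect_association_test(table).holds
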