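"""Generator contracts: planted structure, determinism, Hardy-Weinberg."""

import numpy as np
import pytest
from scipy import stats

from polledmap import catalog, simulate
from polledmap.intervals import Convention, GenomicInterval


class TestGenotypePanel:
    def test_planted_core_homozygous_identical_in_all_cases(self, planted_spec,
                                                            planted_panel):
        core = simulate.planted_core_indices(planted_spec, planted_panel)
        assert len(core) == planted_spec.shared_haplotype_markers == 9
        G = planted_panel.genotypes[planted_panel.case_indices]
        for k in core:
            col = G[:, k]
            assert len(np.unique(col)) == 1 and col[0] in (0, 2)

    def test_carriers_heterozygous_at_core(self):
        spec = simulate.PanelSpec(seed=5, n_carriers=6)
        panel = simulate.generate_genotype_panel(spec)
        core = simulate.planted_core_indices(spec, panel)
        het_rows = panel.class_indices("Pp")
        assert (panel.genotypes[np.ix_(het_rows, core)] == 1).all()

    def test_same_seed_identical_panel(self, planted_spec, planted_panel):
        again = simulate.generate_genotype_panel(planted_spec)
        assert np.array_equal(again.genotypes, planted_panel.genotypes)
        assert again.markers.equals(planted_panel.markers)
        assert again.animals.equals(planted_panel.animals)

    def test_null_panel_has_no_planted_signal(self):
        spec = simulate.PanelSpec(seed=5, shared_haplotype_markers=0, n_cases=30)
        panel = simulate.generate_genotype_panel(spec)
        G = panel.genotypes[panel.case_indices]
        # no 9-marker window where all 30 cases share one homozygous genotype
        ident = np.array([(len(np.unique(G[:, k])) == 1) and G[0, k] in (0, 2)
                          for k in range(panel.n_markers)])
        runs = np.convolve(ident.astype(int), np.ones(9, dtype=int), mode="valid")
        assert runs.max() < 9

    def test_controls_follow_hardy_weinberg(self):
        spec = simulate.PanelSpec(seed=11, n_controls=600, n_breeds=1, fst=0.0,
                                  shared_haplotype_markers=0,
                                  n_chromosomes=1, markers_per_chromosome=60)
        panel = simulate.generate_genotype_panel(spec)
        G = panel.genotypes[panel.control_indices]
        pvals = []
        for k in range(panel.n_markers):
            col = G[:, k]
            n = len(col)
            f = col.mean() / 2
            expected = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            observed = np.array([(col == c).sum() for c in (0, 1, 2)])
            keep = expected > 1
            chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            pvals.append(stats.chi2.sf(chi2, df=keep.sum() - 1))
        # genotype frequencies match HWE within sampling error across markers
        assert np.mean(np.array(pvals) < 0.01) < 0.1

    def test_too_many_shared_markers_errors(self):
        with pytest.raises(ValueError):
            simulate.generate_genotype_panel(simulate.PanelSpec(
                seed=1, shared_haplotype_markers=50))


@pytest.fixture(scope="module")
def table():
    return simulate.generate_variant_tables(simulate.ReseqSpec(seed=3))


class TestVariantTables:
    def test_causal_vafs_follow_genotype_class(self, table):
        cls = table.samples.set_index("id")["polled_class"]
        grp = table.samples.set_index("id")["group"]
        for v in catalog.HF_CANDIDATES:
            recs = table.records[table.records["id"] == v.id]
            assert len(recs) > 0
            for _, r in recs.iterrows():
                assert grp[r["sample"]] == "HF"      # absent in other groups
                assert cls[r["sample"]] != "pp"      # absent in horned sires
                centre = 1.0 if cls[r["sample"]] == "PP" else 0.5
                assert abs(r["vaf"] - centre) < 0.1

    def test_vaf_bounds_and_depths(self, table):
        r = table.records
        assert r["vaf"].between(0, 1).all()
        assert (r["alt_count"] <= r["depth"]).all()
        assert (r["depth"] >= 1).all()

    def test_determinism(self, table):
        again = simulate.generate_variant_tables(simulate.ReseqSpec(seed=3))
        assert again.records.equals(table.records)

    def test_no_causals_means_no_survivors_expected(self):
        from polledmap import filtering
        spec = simulate.ReseqSpec(seed=3, groups=(
            simulate.GroupSpec("G", n_pp=3, n_carrier=1, n_horned=4),))
        table = simulate.generate_variant_tables(spec)
        assert len(filtering.concordance_filter(table)) == 0


class TestReadTracks:
    def test_duplication_density_and_determinism(self):
        dup = catalog.P_80KBID_INTERVAL
        ref, tgt = simulate.generate_read_tracks(dup, catalog.TARGET_REGION,
                                                 rate_per_bp=0.2, copy_ratio=2.0,
                                                 seed=4)
        for tr in (ref, tgt):
            assert np.all(np.diff(tr.positions) >= 0)
        inside = (tgt.positions >= dup.start) & (tgt.positions < dup.end)
        ref_inside = (ref.positions >= dup.start) & (ref.positions < dup.end)
        ratio = inside.sum() / ref_inside.sum()
        assert ratio == pytest.approx(2.0, rel=0.1)
        ref2, tgt2 = simulate.generate_read_tracks(dup, catalog.TARGET_REGION,
                                                   rate_per_bp=0.2, copy_ratio=2.0,
                                                   seed=4)
        assert np.array_equal(tgt.positions, tgt2.positions)

    def test_neutral_ratio_gives_flat_tracks(self):
        dup = catalog.P_80KBID_INTERVAL
        ref, tgt = simulate.generate_read_tracks(dup, catalog.TARGET_REGION,
                                                 rate_per_bp=0.1, copy_ratio=1.0,
                                                 seed=4)
        inside = ((tgt.positions >= dup.start) & (tgt.positions < dup.end)).mean()
        frac = (dup.end - dup.start) / (catalog.TARGET_REGION.end
                                        - catalog.TARGET_REGION.start)
        assert inside == pytest.approx(frac, rel=0.15)

    def test_invalid_copy_ratio(self):
        with pytest.raises(ValueError):
            simulate.generate_read_tracks(catalog.P_80KBID_INTERVAL,
                                          catalog.TARGET_REGION, 0.1, 0.0, 1)


class TestPopulationTable:
    def test_counts_and_dominance(self, population):
        table, _ = population
        assert len(table) == 1616
        carriers = table[(table["pc_copies"] + table["pf_copies"]) >= 1]
        assert (carriers["phenotype"] == "polled").all()
        noncarriers = table[(table["pc_copies"] + table["pf_copies"]) == 0]
        assert (noncarriers["phenotype"] == "horned").all()

    def test_compound_heterozygotes_planted(self, population):
        table, _ = population
        compound = table[(table["pc_copies"] == 1) & (table["pf_copies"] == 1)]
        assert len(compound) == 3

    def test_pedigree_links_carriers_to_founders(self, population):
        table, ped = population
        ped_idx = ped.set_index("animal")
        pc = table[table["pc_copies"] >= 1]["animal"]
        assert all(ped_idx.loc[a, "sire"].startswith("FOUNDER_PC") for a in pc[:20])

    def test_all_zero_counts_empty(self):
        table, _ = simulate.generate_population_table(0, 0, 0, 0, 0, 0, seed=1)
        assert len(table) == 0
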