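"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the mapping statistic and the concordance filter by
direct enumeration (explicit loops over animals/markers and variant-sample-rule
triples) so the vectorised implementations can be checked against them exactly.
"""

import numpy as np
import pandas as pd
import pytest

from polledmap import filtering, mapping, simulate

HOM = (0, 2)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_asshom(panel: mapping.GenotypePanel) -> np.ndarray:
    """Mapping statistic by exhaustive run enumeration, one marker at a time."""
    w = mapping.hom_weights(mapping.control_allele_freqs(panel))
    chrom = panel.markers["chrom"].to_numpy()
    cases = panel.case_indices
    M = panel.n_markers
    S = np.zeros(M)
    for m in range(M):
        scores = []
        for a in cases:
            g = panel.genotypes[a]
            if g[m] not in HOM:
                scores.append(0.0)
                continue
            i = m
            while i - 1 >= 0 and chrom[i - 1] == chrom[m] and g[i - 1] != 1:
                i -= 1
            j = m
            while j + 1 < M and chrom[j + 1] == chrom[m] and g[j + 1] != 1:
                j += 1
            scores.append(sum(w[k] for k in range(i, j + 1) if g[k] in HOM))
        if scores and all(s > 0 for s in scores):
            S[m] = len(scores) / sum(1.0 / s for s in scores)
    return S


def brute_force_filter(table: filtering.VariantTable,
                       config: filtering.FilterConfig) -> list:
    """Concordance filter by explicit (site, sample, rule) checks."""
    cls = dict(zip(table.samples["id"], table.samples["polled_class"]))
    survivors = []
    for (chrom, pos), site in table.records.groupby(["chrom", "pos"], sort=True):
        recs = {r["sample"]: r for _, r in site.iterrows()}
        if any(cls.get(s) in ("PP", "Pp") and r["depth"] < config.min_depth
               for s, r in recs.items()):
            continue
        row0 = site.iloc[0]
        if config.require_non_reference and row0["alt"] == row0["ref"]:
            continue
        ok = True
        for sid, c in cls.items():
            r = recs.get(sid)
            if c == "PP":
                if r is None or not (config.pp_band[0] <= r["vaf"] <= config.pp_band[1]):
                    ok = False
            elif c == "Pp":
                if r is None or not (config.het_band[0] <= r["vaf"] <= config.het_band[1]):
                    ok = False
            elif c == "pp" and config.require_absent_in_controls and r is not None:
                ok = False
        if ok:
            survivors.append((chrom, pos))
    return sorted(survivors)


# ---------------------------------------------------------------------------
# Random inputs for oracle equivalence
# ---------------------------------------------------------------------------

def random_small_panel(rng: np.random.Generator, n_animals=8, n_markers=16,
                       missing_rate=0.1) -> mapping.GenotypePanel:
    """Random two-chromosome panel with missing genotypes and mixed classes."""
    classes = ["PP", "PP", "pp", "pp"] + list(
        rng.choice(["PP", "Pp", "pp"], size=n_animals - 4))
    animals = pd.DataFrame({"id": [f"a{i}" for i in range(n_animals)],
                            "breed": "b0", "polled_class": classes})
    half = n_markers // 2
    markers = pd.DataFrame({
        "id": [f"m{i}" for i in range(n_markers)],
        "chrom": ["1"] * half + ["2"] * (n_markers - half),
        "bp": list(1000 * (1 + np.arange(half)))
              + list(1000 * (1 + np.arange(n_markers - half)))})
    G = rng.integers(0, 3, size=(n_animals, n_markers)).astype(np.int8)
    G[rng.random(G.shape) < missing_rate] = -1
    return mapping.GenotypePanel(animals=animals, markers=markers, genotypes=G)


def random_variant_table(rng: np.random.Generator, n_sites=40,
                         n_samples=16) -> filtering.VariantTable:
    """Random table with record dropout, boundary VAFs and low-depth sites."""
    classes = (["PP"] * 4 + ["Pp"] * 2 + ["pp"] * 4
               + list(rng.choice(["PP", "Pp", "pp"], size=n_samples - 10)))
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(n_samples)],
                            "group": "G", "polled_class": classes})
    rows = []
    for k in range(n_sites):
        pos = 1000 + 13 * k
        ref, alt = ("A", "A") if rng.random() < 0.05 else ("A", "C")
        for sid in samples["id"]:
            if rng.random() < 0.35:
                continue  # undetected in this sample
            vaf = float(rng.choice([0.0, 0.05, 0.35, 0.40, 0.5, 0.60, 0.65,
                                    0.94, 0.95, 0.99, 1.0]))
            depth = int(rng.choice([15, 19, 20, 25, 40]))
            rows.append({"chrom": "1", "pos": pos, "id": f"v{k}", "ref": ref,
                         "alt": alt, "kind": "snp", "sample": sid,
                         "depth": depth, "alt_count": int(round(vaf * depth)),
                         "vaf": vaf})
    records = pd.DataFrame(rows, columns=filtering.RECORD_COLUMNS)
    return filtering.VariantTable(records=records, samples=samples)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_spec() -> simulate.PanelSpec:
    return simulate.PanelSpec(seed=42)


@pytest.fixture(scope="session")
def planted_panel(planted_spec) -> mapping.GenotypePanel:
    return simulate.generate_genotype_panel(planted_spec)


@pytest.fixture(scope="session")
def sire_table() -> filtering.VariantTable:
    return simulate.sixteen_sire_fixture()


@pytest.fixture(scope="session")
def sire_partitions(sire_table):
    return {g: list(sire_table.samples[sire_table.samples["group"] == g]["id"])
            for g in ("HF", "nonHF")}


@pytest.fixture(scope="session")
def population():
    return simulate.generate_population_table(seed=7)
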