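"""Shared fixtures: one default synthetic panel reused across the suite."""

import pandas as pd
import pytest

from panforge import ortho
from panforge.synth import SimulationConfig, simulate_pangenome, write_dataset


@pytest.fixture(scope="session")
def panel():
    """Default 10-strain panel with plasmids, phage regions and CRISPRs."""
    return simulate_pangenome(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def panel_dir(panel, tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    write_dataset(panel, out)
    return out


@pytest.fixture(scope="session")
def panel_proteins(panel):
    """Truth proteins of the default panel, with strain and family maps."""
    proteins, strain_of = {}, {}
    for strain in panel.strains:
        for g in panel.truth.gene_models[strain]:
            proteins[g.gene_id] = g.protein
            strain_of[g.gene_id] = strain
    return proteins, strain_of


@pytest.fixture(scope="session")
def panel_ogs(panel, panel_proteins):
    """Ortholog groups inferred from the default panel's truth proteins."""
    proteins, strain_of = panel_proteins
    return ortho.cluster_proteins(proteins, strain_of)


@pytest.fixture(scope="session")
def small_panel():
    """A 5-strain panel small enough for repeated pipeline runs."""
    return simulate_pangenome(SimulationConfig(
        n_strains=5, n_core_families=40, n_accessory_families=12,
        n_islands=1, island_size=6, mean_gene_len=150,
        fragmentation=6, seed=11))


@pytest.fixture(scope="session")
def small_panel_dir(small_panel, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_panel")
    write_dataset(small_panel, out)
    return out


def truth_presence_matrix(panel) -> pd.DataFrame:
    """Family x strain presence matrix straight from the generator truth."""
    strains = panel.strains
    fams = sorted({f for f in panel.truth.family_of_gene.values()})
    rows = {}
    present = {
        s: {panel.truth.family_of_gene[g.gene_id]
            for g in panel.truth.gene_models[s]}
        for s in strains}
    for fam in fams:
        rows[fam] = [int(fam in present[s]) for s in strains]
    return pd.DataFrame.from_dict(rows, orient="index", columns=strains,
                                  dtype=int)
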