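"""Generator contracts: determinism, planted structure, file round-trip."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from panforge import io as pio
from panforge.synth import (OdParams, PredictorError, SimulationConfig,
                            read_dataset, simulate_growth_curves,
                            simulate_pangenome, write_dataset)

SMALL = dict(n_strains=4, n_core_families=30, n_accessory_families=10,
             n_islands=1, island_size=5, mean_gene_len=120, fragmentation=5)


def _tree_digest(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*")) if p.is_file()}


def test_same_seed_byte_identical_output(tmp_path):
    for sub in ("a", "b"):
        ds = simulate_pangenome(SimulationConfig(**SMALL, seed=13))
        write_dataset(ds, tmp_path / sub)
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")


def test_different_seed_changes_output():
    a = simulate_pangenome(SimulationConfig(**SMALL, seed=1))
    b = simulate_pangenome(SimulationConfig(**SMALL, seed=2))
    assert a.contigs != b.contigs


def test_every_strain_carries_all_core_families():
    cfg = SimulationConfig(n_strains=5, n_core_families=100,
                           n_accessory_families=50, n_islands=2,
                           island_size=10, mean_gene_len=120, seed=7)
    ds = simulate_pangenome(cfg)
    core = {f"CORE{i:04d}" for i in range(100)}
    for strain in ds.strains:
        fams = {ds.truth.family_of_gene[g.gene_id]
                for g in ds.truth.gene_models[strain]}
        assert core <= fams


def test_accessory_presence_matches_binomial_interval():
    """Observed per-family presence frequencies sit inside the exact
    binomial 99% interval of the configured probability for >=95% of
    accessory families."""
    p, n = 0.3, 30
    cfg = SimulationConfig(
        n_strains=n, n_core_families=5, n_accessory_families=40,
        n_islands=0, island_size=0, mean_gene_len=80,
        accessory_presence_prob=p, fragmentation=3, seed=5)
    ds = simulate_pangenome(cfg)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    ok = 0
    for i in range(40):
        fam = f"ACC{i:04d}"
        count = sum(
            any(ds.truth.family_of_gene[g.gene_id] == fam
                for g in ds.truth.gene_models[s])
            for s in ds.strains)
        ok += lo <= count <= hi
    assert ok >= 0.95 * 40


def test_within_family_identity_exceeds_between_family(panel, panel_proteins):
    proteins, _ = panel_proteins
    truth = panel.truth
    rng = np.random.default_rng(0)
    ids = sorted(proteins)

    def identity(a, b):
        m = min(len(a), len(b))
        return sum(x == y for x, y in zip(a[:m], b[:m])) / m

    fams = {}
    for g in ids:
        fams.setdefault(truth.family_of_gene[g], []).append(g)
    multi = [v for v in fams.values() if len(v) >= 2]
    within, between = [], []
    for _ in range(50):
        fam = multi[rng.integers(len(multi))]
        a, b = rng.choice(fam, 2, replace=False)
        within.append(identity(proteins[a], proteins[b]))
        f1, f2 = rng.choice(len(multi), 2, replace=False)
        between.append(identity(proteins[multi[f1][0]], proteins[multi[f2][0]]))
    assert min(within) > max(between)


def test_inseparable_divergence_config_rejected():
    with pytest.raises(ValueError, match="separable"):
        SimulationConfig(within_family_divergence=0.7,
                         between_family_min_divergence=0.6).validate()


def test_phage_intervals_hit_target_gc(panel):
    gc_sum = at_sum = 0
    for strain in panel.strains:
        for cid, s, e in panel.truth.phage_intervals[strain]:
            seq = panel.contigs[strain][cid][s:e]
            gc_sum += seq.count("G") + seq.count("C")
            at_sum += seq.count("A") + seq.count("T")
    mean_gc = gc_sum / (gc_sum + at_sum)
    assert abs(mean_gc - panel.config.phage_gc) < 0.01


def test_plasmid_contigs_have_exact_terminal_overlap(panel):
    k = panel.config.plasmid_terminal_overlap
    for strain in panel.strains:
        for cid in panel.truth.plasmid_contigs[strain]:
            seq = panel.contigs[strain][cid]
            assert seq[:k] == seq[-k:]


def test_growth_curves_respect_labels_and_sampling(panel):
    od = panel.od_table
    n_points = 24 * 60 // 20 + 1
    assert n_points == 73
    for (strain, sugar), grp in od[od["strain"] != "BLANK"].groupby(
            ["strain", "sugar"]):
        assert len(grp) == 73
        label = panel.truth.phenotype_labels[strain][sugar]
        blank = od[od["strain"] == "BLANK"].set_index("minute")["od"]
        peak = (grp.set_index("minute")["od"] - blank).max()
        if label:
            assert peak > 0.8
        else:
            assert peak <= 0.8


def test_growth_curve_time_grid():
    cfg = SimulationConfig(**SMALL, seed=3)
    ds = simulate_pangenome(cfg)
    table = simulate_growth_curves(ds.truth, OdParams(), seed=1)
    minutes = sorted(table[table["strain"] == "BLANK"]["minute"])
    assert minutes == list(range(0, 24 * 60 + 1, 20))


def test_dataset_round_trip(tmp_path):
    ds = simulate_pangenome(SimulationConfig(**SMALL, seed=21))
    write_dataset(ds, tmp_path)
    back = read_dataset(tmp_path)
    assert back.contigs == ds.contigs
    assert back.predictor_tracks == ds.predictor_tracks
    assert back.known_plasmids == ds.known_plasmids
    assert back.truth.to_json() == ds.truth.to_json()
    assert back.reference.sequence == ds.reference.sequence
    assert [g.gene_id for g in back.reference.genes] == \
        [g.gene_id for g in ds.reference.genes]
    assert back.od_table.equals(ds.od_table)
    assert back.config == ds.config


def test_gff3_coordinates_one_based_inclusive(tmp_path):
    feats = [pio.GffFeature(contig="c1", start=0, end=90, strand="+",
                            feature_id="g1")]
    path = tmp_path / "t.gff3"
    pio.write_gff3(path, feats)
    line = [l for l in path.read_text().splitlines()
            if not l.startswith("#")][0]
    cols = line.split("\t")
    assert (cols[3], cols[4]) == ("1", "90")
    assert pio.read_gff3(path) == feats


def test_empty_accessory_set_still_valid(tmp_path):
    cfg = SimulationConfig(n_strains=3, n_core_families=20,
                           n_accessory_families=0, n_islands=0,
                           island_size=0, mean_gene_len=80,
                           n_plasmids_per_strain=0, fragmentation=3, seed=2)
    ds = simulate_pangenome(cfg)
    write_dataset(ds, tmp_path)
    fams = {f for f in ds.truth.family_of_gene.values()}
    assert fams == {f"CORE{i:04d}" for i in range(20)}


def test_predictor_error_model_applied():
    err = PredictorError(miss_rate=0.2, spurious_rate=0.1,
                         boundary_jitter_bp=12)
    ds = simulate_pangenome(SimulationConfig(**SMALL, predictor_error=err,
                                             n_predictors=4, seed=9))
    strain = ds.strains[0]
    truth_n = len(ds.truth.gene_models[strain])
    sizes = [len(feats) for feats in ds.predictor_tracks[strain].values()]
    # misses shrink some tracks below truth; spurious can add some back
    assert any(s != truth_n for s in sizes)
    # jitter moves starts but never stops (strand-aware)
    stops_truth = {(g.contig, g.strand, g.stop_coord)
                   for g in ds.truth.gene_models[strain]}
    for feats in ds.predictor_tracks[strain].values():
        jittered = [f for f in feats
                    if (f.contig, f.strand,
                        f.end if f.strand == "+" else f.start) in stops_truth]
        assert len(jittered) >= 0.6 * truth_n
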