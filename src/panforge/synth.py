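"""Synthetic strain panels with a planted pan-genome structure.

The generator emulates, at desk scale, a panel of draft genomes of a single
bacterial species: a conserved core shared by every strain, accessory gene
families (some organised into contiguous "islands" of co-occurring
cassettes), small plasmids with a replication gene and an exact circular
terminal overlap, prophage-like regions whose GC content is shifted below
the chromosomal background, CRISPR arrays of fixed-length direct repeats
separated by unique spacers, and binary growth phenotypes causally tied to
cassette presence (with optional label noise).

Protein families evolve by substitution only: each family has a random
ancestor, and every strain's copy substitutes residues independently at the
configured divergence. Nucleotide genes are produced by back-translating the
ancestor once with codon choice biased toward the target GC, then mutating
only the codons of substituted residues — so within-family nucleotide
identity stays high while the GC target is held.

Everything is drawn from a single seeded generator; the same config and
seed reproduce the output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from panforge import io as pio
from panforge.models import GeneModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sugars assayed in the growth experiments the phenotype table mirrors.
SUGARS = [
    "galactose", "cellobiose", "dulcitol", "mannitol", "sorbose", "mannose",
    "saccharose", "sorbitol", "trehalose", "maltose", "myoinositol",
    "ribose", "xylose", "lactose", "glucose", "galactosamine",
    "Ca-gluconate", "melezitose", "melibiose",
]

_CORE_ANNOTATIONS = [
    "DNA polymerase III subunit alpha", "elongation factor Tu",
    "30S ribosomal protein S4", "phosphoglycerate kinase",
    "DNA gyrase subunit A", "signal recognition particle protein",
    "UDP-N-acetylglucosamine 1-carboxyvinyltransferase",
    "hypothetical protein",
]

_CASSETTE_ANNOTATIONS = [
    "PTS system lactose-specific transporter subunit IIBC",
    "6-phospho-beta-galactosidase",
    "PTS system galactitol-specific transporter subunit IIC",
    "tagatose-6-phosphate kinase",
    "sorbitol-6-phosphate 2-dehydrogenase",
    "PTS system cellobiose-specific transporter subunit IIA",
    "maltose-6'-phosphate glucosidase",
    "sugar ABC transporter permease",
    "transcriptional antiterminator, BglG family",
    "hypothetical protein",
]

_PLASMID_REP_ANNOTATION = "replication initiator protein RepA"
_PLASMID_CARGO_ANNOTATIONS = [
    "mobilization protein MobA",
    "hypothetical protein (plasmid)",
]


@dataclasses.dataclass
class PredictorError:
    """Per-predictor error model applied to truth gene tracks."""

    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    boundary_jitter_bp: int = 0


@dataclasses.dataclass
class CrisprParams:
    repeat_len: int = 36
    n_repeats: int = 6
    spacer_len: int = 30


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the generator; defaults give a small but complete panel."""

    n_strains: int = 10
    n_core_families: int = 100
    n_accessory_families: int = 50
    accessory_presence_prob: float = 0.5
    n_islands: int = 2
    island_size: int = 10
    mean_gene_len: int = 250  # amino acids
    within_family_divergence: float = 0.10
    between_family_min_divergence: float = 0.60
    n_plasmids_per_strain: int = 1
    plasmid_terminal_overlap: int = 150
    phage_gc: float = 0.40
    background_gc: float = 0.46
    n_phage_regions: int = 1
    phage_region_genes: int = 10
    fragmentation: int = 12  # chromosomal contigs per genome
    predictor_error: PredictorError = dataclasses.field(default_factory=PredictorError)
    n_predictors: int = 4
    crispr: CrisprParams = dataclasses.field(default_factory=CrisprParams)
    crispr_types: int = 3
    phenotypes: Optional[list[tuple[str, list[str], float]]] = None
    label_noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "accessory_presence_prob": self.accessory_presence_prob,
            "within_family_divergence": self.within_family_divergence,
            "between_family_min_divergence": self.between_family_min_divergence,
            "phage_gc": self.phage_gc,
            "background_gc": self.background_gc,
            "miss_rate": self.predictor_error.miss_rate,
            "label_noise_rate": self.label_noise_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_core_families < 1:
            raise ValueError("n_core_families must be >= 1")
        if self.crispr.repeat_len <= 0:
            raise ValueError("crispr repeat_len must be > 0")
        if self.within_family_divergence >= self.between_family_min_divergence:
            raise ValueError(
                "families not separable: within_family_divergence must be "
                "smaller than between_family_min_divergence"
            )
        if self.n_islands * self.island_size > self.n_accessory_families:
            raise ValueError("islands require more accessory families than configured")


@dataclasses.dataclass
class TruthSet:
    """Ground truth of one simulated panel, for parameter-recovery tests."""

    family_of_gene: dict[str, str]
    island_families: list[list[str]]
    plasmid_contigs: dict[str, list[str]]
    phage_intervals: dict[str, list[tuple[str, int, int]]]
    causal_families: dict[str, list[str]]
    crispr_arrays: dict[str, list[tuple[str, list[str]]]]
    phenotype_labels: dict[str, dict[str, int]]
    contig_order: dict[str, list[str]]
    annotation_of_family: dict[str, str]
    gene_models: dict[str, list[GeneModel]]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gene_models"] = {
            s: [dataclasses.asdict(g) for g in gs]
            for s, gs in self.gene_models.items()
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        d["gene_models"] = {
            s: [GeneModel(**g) for g in gs] for s, gs in d["gene_models"].items()
        }
        d["phage_intervals"] = {
            s: [tuple(iv) for iv in ivs] for s, ivs in d["phage_intervals"].items()
        }
        d["crispr_arrays"] = {
            s: [(rep, list(sp)) for rep, sp in arrs]
            for s, arrs in d["crispr_arrays"].items()
        }
        return cls(**d)


@dataclasses.dataclass
class ReferenceGenome:
    """Single circular reference chromosome with located genes."""

    sequence: str
    genes: list[GeneModel]

    @property
    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}


@dataclasses.dataclass
class Dataset:
    """One simulated panel: sequences, tracks, reference, phenotype data."""

    config: SimulationConfig
    contigs: dict[str, dict[str, str]]  # strain -> contig -> sequence
    predictor_tracks: dict[str, dict[str, list[pio.GffFeature]]]
    reference: ReferenceGenome
    known_plasmids: dict[str, str]
    od_table: pd.DataFrame
    truth: TruthSet

    @property
    def strains(self) -> list[str]:
        return sorted(self.contigs)

    @property
    def genes(self) -> dict[str, list[GeneModel]]:
        return self.truth.gene_models

    def proteins(self, strain: str) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.truth.gene_models[strain]}


# --- codon machinery -------------------------------------------------------

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_OF:
    _CODONS_OF[_aa].sort()
_STOPS = sorted(_TABLE11.stop_codons)


def _gc_frac(codon: str) -> float:
    return (codon.count("G") + codon.count("C")) / 3.0


class CodonSampler:
    """Back-translation with codon choice biased to a target GC fraction.

    Codon weights are softmax(beta * gc) within each synonymous set; beta is
    solved by bisection so the expected GC over a uniform amino-acid
    composition equals the target.
    """

    def __init__(self, target_gc: float):
        self.target_gc = target_gc
        self.beta = self._solve_beta(target_gc)
        self._cum: dict[str, tuple[np.ndarray, list[str]]] = {}
        for aa, codons in _CODONS_OF.items():
            w = np.exp(self.beta * np.array([_gc_frac(c) for c in codons]))
            w /= w.sum()
            self._cum[aa] = (np.cumsum(w), codons)
        w = np.exp(self.beta * np.array([_gc_frac(c) for c in _STOPS]))
        w /= w.sum()
        self._cum["*"] = (np.cumsum(w), _STOPS)

    @staticmethod
    def _expected_gc(beta: float) -> float:
        tot = 0.0
        for codons in _CODONS_OF.values():
            g = np.array([_gc_frac(c) for c in codons])
            w = np.exp(beta * g)
            tot += float((w * g).sum() / w.sum())
        return tot / len(_CODONS_OF)

    @classmethod
    def _solve_beta(cls, target: float) -> float:
        lo, hi = -40.0, 40.0
        flo, fhi = cls._expected_gc(lo), cls._expected_gc(hi)
        if target <= flo:
            return lo
        if target >= fhi:
            return hi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if cls._expected_gc(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def sample_codon(self, aa: str, rng: np.random.Generator) -> str:
        cum, codons = self._cum[aa]
        return codons[int(np.searchsorted(cum, rng.random()))]

    def back_translate(self, protein: str, rng: np.random.Generator) -> str:
        """CDS for ``protein`` plus a stop codon; first Met forced to ATG."""
        parts = []
        for i, aa in enumerate(protein):
            if i == 0 and aa == "M":
                parts.append("ATG")
            else:
                parts.append(self.sample_codon(aa, rng))
        parts.append(self.sample_codon("*", rng))
        return "".join(parts)


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length - 1)
    )
    return "M" + body


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    """Substitute residues (never the initiator Met) at ``rate``; returns
    the mutated protein and the list of substituted positions."""
    chars = list(protein)
    hit = np.flatnonzero(rng.random(len(chars)) < rate)
    changed = []
    for i in hit:
        if i == 0:
            continue
        old = chars[i]
        choices = AMINO_ACIDS.replace(old, "")
        chars[i] = choices[int(rng.integers(0, len(choices)))]
        changed.append(int(i))
    return "".join(chars), changed


# --- the generator ---------------------------------------------------------


@dataclasses.dataclass
class _Family:
    fam_id: str
    ancestor: str
    canonical_cds: str  # back-translated ancestor incl. stop, background GC
    annotation: str


def _strain_name(i: int) -> str:
    return f"S{i:03d}"


def simulate_pangenome(config: SimulationConfig) -> Dataset:
    """Generate a full synthetic panel. Deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg_sampler = CodonSampler(config.background_gc)
    phage_sampler = CodonSampler(config.phage_gc)

    strains = [_strain_name(i) for i in range(config.n_strains)]

    # -- families ----------------------------------------------------------
    core_ids = [f"CORE{i:04d}" for i in range(config.n_core_families)]
    acc_ids = [f"ACC{i:04d}" for i in range(config.n_accessory_families)]
    n_island_fams = config.n_islands * config.island_size
    island_families = [
        acc_ids[k * config.island_size:(k + 1) * config.island_size]
        for k in range(config.n_islands)
    ]
    free_acc = acc_ids[n_island_fams:]
    island_fam_set = {f for isl in island_families for f in isl}

    families: dict[str, _Family] = {}

    def _make_family(fam_id: str, annotation: str) -> None:
        length = max(80, int(rng.normal(config.mean_gene_len, config.mean_gene_len * 0.15)))
        prot = _random_protein(length, rng)
        families[fam_id] = _Family(fam_id, prot, bg_sampler.back_translate(prot, rng), annotation)

    for i, fid in enumerate(core_ids):
        _make_family(fid, _CORE_ANNOTATIONS[i % len(_CORE_ANNOTATIONS)])
    for i, fid in enumerate(acc_ids):
        ann = (_CASSETTE_ANNOTATIONS[i % len(_CASSETTE_ANNOTATIONS)]
               if fid in island_fam_set else
               _CASSETTE_ANNOTATIONS[(i + 5) % len(_CASSETTE_ANNOTATIONS)])
        _make_family(fid, ann)

    plasmid_fam_ids: list[list[str]] = []
    for p in range(config.n_plasmids_per_strain):
        fams_p = [f"PLASMID{p}_REP"]
        _make_family(fams_p[0], _PLASMID_REP_ANNOTATION)
        for c, ann in enumerate(_PLASMID_CARGO_ANNOTATIONS):
            fid = f"PLASMID{p}_CARGO{c}"
            _make_family(fid, ann)
            fams_p.append(fid)
        plasmid_fam_ids.append(fams_p)

    # -- shared chromosomal layout ----------------------------------------
    backbone = core_ids + free_acc
    layout = [backbone[i] for i in rng.permutation(len(backbone))]
    # islands are inserted at backbone boundaries, rightmost first, so no
    # island can land inside another and each stays contiguous
    insert_points = sorted(
        (int(rng.integers(0, len(backbone) + 1)) for _ in island_families),
        reverse=True)
    for pos, isl in zip(insert_points, reversed(island_families)):
        layout[pos:pos] = isl

    # -- reference chromosome (ancestor genome, every chromosomal family) --
    ref_parts: list[str] = [random_dna(int(rng.integers(60, 200)), config.background_gc, rng)]
    ref_genes: list[GeneModel] = []
    pos = len(ref_parts[0])
    for fam_id in layout:
        fam = families[fam_id]
        cds = fam.canonical_cds
        strand = "+" if rng.random() < 0.5 else "-"
        oriented = cds if strand == "+" else pio.reverse_complement(cds)
        ref_genes.append(GeneModel(
            gene_id=f"REF|{fam_id}", strain="REF", contig="REF",
            start=pos, end=pos + len(oriented), strand=strand,
            protein=fam.ancestor, annotation=fam.annotation,
        ))
        pos += len(oriented)
        spacer = random_dna(int(rng.integers(60, 200)), config.background_gc, rng)
        ref_parts.append(oriented)
        ref_parts.append(spacer)
        pos += len(spacer)
    reference = ReferenceGenome("".join(ref_parts), ref_genes)

    # -- canonical plasmids (the "known plasmid" set) ----------------------
    known_plasmids: dict[str, str] = {}
    plasmid_layouts: list[dict] = []
    for p, fams_p in enumerate(plasmid_fam_ids):
        spacers = [random_dna(int(rng.integers(60, 150)), config.background_gc, rng)
                   for _ in range(len(fams_p) + 1)]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in fams_p]
        parts = [spacers[0]]
        for fid, strand in zip(fams_p, strands):
            cds = families[fid].canonical_cds
            parts.append(cds if strand == "+" else pio.reverse_complement(cds))
            parts.append(spacers[len(parts) // 2])
        core_seq = "".join(parts)
        known_plasmids[f"pKnown{p}"] = core_seq + core_seq[:config.plasmid_terminal_overlap]
        plasmid_layouts.append({"fams": fams_p, "spacers": spacers, "strands": strands})

    # -- per-strain accessory presence ------------------------------------
    island_present = {
        s: [bool(rng.random() < config.accessory_presence_prob)
            for _ in range(config.n_islands)]
        for s in strains
    }
    free_present = {
        s: {f: bool(rng.random() < config.accessory_presence_prob) for f in free_acc}
        for s in strains
    }

    def _has_family(strain: str, fam_id: str) -> bool:
        if fam_id in island_fam_set:
            for k, isl in enumerate(island_families):
                if fam_id in isl:
                    return island_present[strain][k]
        if fam_id in free_present[strain]:
            return free_present[strain][fam_id]
        return True  # core

    # -- CRISPR types ------------------------------------------------------
    cr = config.crispr
    repeat_seq = random_dna(cr.repeat_len, config.background_gc, rng)
    type_spacers = {
        t: [random_dna(cr.spacer_len, config.background_gc, rng)
            for _ in range(cr.n_repeats - 1)]
        for t in range(1, config.crispr_types + 1)
    }
    crispr_type_of = {
        s: (i % (config.crispr_types + 1)) for i, s in enumerate(strains)
    }

    # -- phenotypes --------------------------------------------------------
    if config.phenotypes is None:
        phenotypes = [
            (SUGARS[k], list(island_families[k]), config.label_noise_rate)
            for k in range(min(config.n_islands, len(SUGARS)))
        ]
    else:
        phenotypes = [(s, list(f), n) for s, f, n in config.phenotypes]
    causal_families = {sugar: list(fams) for sugar, fams, _ in phenotypes}
    phenotype_labels: dict[str, dict[str, int]] = {s: {} for s in strains}
    for sugar, fams, noise in phenotypes:
        for s in strains:
            label = int(all(_has_family(s, f) for f in fams))
            if rng.random() < noise:
                label = 1 - label
            phenotype_labels[s][sugar] = label

    # -- build each strain genome -----------------------------------------
    contigs: dict[str, dict[str, str]] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    family_of_gene: dict[str, str] = {}
    plasmid_contigs: dict[str, list[str]] = {}
    phage_intervals: dict[str, list[tuple[str, int, int]]] = {}
    crispr_arrays: dict[str, list[tuple[str, list[str]]]] = {}
    contig_order: dict[str, list[str]] = {}

    for strain in strains:
        present = [f for f in layout if _has_family(strain, f)]

        # phage region: contiguous run of gene slots, re-encoded at phage GC
        phage_slots: set[int] = set()
        n_ph = min(config.phage_region_genes, len(present))
        for _ in range(config.n_phage_regions):
            if n_ph == 0:
                break
            start_slot = int(rng.integers(0, len(present) - n_ph + 1))
            phage_slots.update(range(start_slot, start_slot + n_ph))

        parts: list[str] = []
        genome_genes: list[tuple[int, int, str, str, str, str]] = []
        gaps: list[tuple[int, int, bool]] = []  # (start, end, cuttable)
        pos = 0
        first_spacer = random_dna(int(rng.integers(60, 200)), config.background_gc, rng)
        parts.append(first_spacer)
        gaps.append((0, len(first_spacer), True))
        pos = len(first_spacer)
        for slot, fam_id in enumerate(present):
            fam = families[fam_id]
            mutated, changed = _mutate_protein(
                fam.ancestor, config.within_family_divergence, rng)
            if slot in phage_slots:
                cds = phage_sampler.back_translate(mutated, rng)
            else:
                codons = [fam.canonical_cds[i:i + 3]
                          for i in range(0, len(fam.canonical_cds), 3)]
                for i in changed:
                    codons[i] = bg_sampler.sample_codon(mutated[i], rng)
                cds = "".join(codons)
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = cds if strand == "+" else pio.reverse_complement(cds)
            genome_genes.append(
                (pos, pos + len(oriented), strand, fam_id, mutated, fam.annotation))
            parts.append(oriented)
            pos += len(oriented)
            in_phage_gap = slot in phage_slots and (slot + 1) in phage_slots
            gc = config.phage_gc if in_phage_gap else config.background_gc
            spacer = random_dna(int(rng.integers(60, 200)), gc, rng)
            # gaps inside phage regions are kept intact so planted intervals
            # stay on one contig
            gaps.append((pos, pos + len(spacer), slot not in phage_slots
                         and (slot + 1) not in phage_slots))
            parts.append(spacer)
            pos += len(spacer)

        genome = "".join(parts)

        # phage nucleotide intervals (genome coordinates)
        ph_iv_genome: list[tuple[int, int]] = []
        if phage_slots:
            sorted_slots = sorted(phage_slots)
            run_start = sorted_slots[0]
            prev = sorted_slots[0]
            for sl in sorted_slots[1:] + [None]:
                if sl is None or sl != prev + 1:
                    ph_iv_genome.append(
                        (genome_genes[run_start][0], genome_genes[prev][1]))
                    run_start = sl
                prev = sl if sl is not None else prev

        # CRISPR array inserted mid-gap into a cuttable gap
        ctype = crispr_type_of[strain]
        array_iv: Optional[tuple[int, int]] = None
        if ctype > 0:
            spacer_list = type_spacers[ctype]
            array_seq = repeat_seq + "".join(
                sp + repeat_seq for sp in spacer_list)
            cuttable = [g for g in gaps if g[2] and g[1] - g[0] >= 40]
            gidx = int(rng.integers(0, len(cuttable)))
            g0, g1, _ = cuttable[gidx]
            insert_at = (g0 + g1) // 2
            genome = genome[:insert_at] + array_seq + genome[insert_at:]
            array_iv = (insert_at, insert_at + len(array_seq))
            shift = len(array_seq)
            genome_genes = [
                (s + shift if s >= insert_at else s,
                 e + shift if e > insert_at else e, st, f, p, a)
                for s, e, st, f, p, a in genome_genes]
            ph_iv_genome = [
                (s + shift if s >= insert_at else s,
                 e + shift if e > insert_at else e)
                for s, e in ph_iv_genome]
            gaps = [(s + shift if s >= insert_at else s,
                     e + shift if e > insert_at else e, c)
                    for s, e, c in gaps]
            crispr_arrays[strain] = [(repeat_seq, list(spacer_list))]
        else:
            crispr_arrays[strain] = []

        # fragmentation: cut points inside cuttable intergenic gaps,
        # avoiding the CRISPR insertion
        n_cuts = max(0, min(config.fragmentation - 1, len(gaps) - 1))
        cuttable_idx = [i for i, g in enumerate(gaps) if g[2]]
        if array_iv is not None:
            cuttable_idx = [
                i for i in cuttable_idx
                if gaps[i][1] <= array_iv[0] or gaps[i][0] >= array_iv[1]
            ]
        chosen = sorted(
            rng.choice(len(cuttable_idx), size=min(n_cuts, len(cuttable_idx)),
                       replace=False).tolist())
        cut_points = []
        for ci in chosen:
            g0, g1, _ = gaps[cuttable_idx[ci]]
            cut_points.append(int(rng.integers(g0 + 1, g1)))
        cut_points = sorted(set(cut_points))

        bounds = [0] + cut_points + [len(genome)]
        n_contigs = len(bounds) - 1
        perm = rng.permutation(n_contigs)
        # ids assigned in shuffled output order so names don't leak the order
        id_of_true_idx = {int(t): f"{strain}_c{k:04d}"
                          for k, t in enumerate(perm)}
        contig_order[strain] = [id_of_true_idx[i] for i in range(n_contigs)]
        strain_contigs: dict[str, str] = {}
        for k in range(n_contigs):
            true_idx = int(perm[k])
            cid = id_of_true_idx[true_idx]
            strain_contigs[cid] = genome[bounds[true_idx]:bounds[true_idx + 1]]
        # emit in id order for stable files
        strain_contigs = dict(sorted(strain_contigs.items()))

        def _locate(gstart: int, gend: int) -> tuple[str, int, int]:
            for i in range(n_contigs):
                if bounds[i] <= gstart and gend <= bounds[i + 1]:
                    return id_of_true_idx[i], gstart - bounds[i], gend - bounds[i]
            raise AssertionError("feature split by a cut")

        genes_here: list[GeneModel] = []
        for gstart, gend, strand, fam_id, prot, ann in genome_genes:
            cid, s, e = _locate(gstart, gend)
            gid = f"{strain}|{fam_id}"
            genes_here.append(GeneModel(
                gene_id=gid, strain=strain, contig=cid, start=s, end=e,
                strand=strand, protein=prot, annotation=ann))
            family_of_gene[gid] = fam_id
        phage_intervals[strain] = []
        for s, e in ph_iv_genome:
            cid, cs, ce = _locate(s, e)
            phage_intervals[strain].append((cid, cs, ce))
        if array_iv is not None:
            _locate(*array_iv)  # asserts the array survived fragmentation intact

        # plasmid contigs: canonical layout, strain-mutated CDSs
        plasmid_contigs[strain] = []
        for p, lay in enumerate(plasmid_layouts):
            parts_p = [lay["spacers"][0]]
            offset = len(lay["spacers"][0])
            p_genes: list[tuple[int, int, str, str, str, str]] = []
            for gi, (fid, strand) in enumerate(zip(lay["fams"], lay["strands"])):
                fam = families[fid]
                mutated, changed = _mutate_protein(
                    fam.ancestor, config.within_family_divergence, rng)
                codons = [fam.canonical_cds[i:i + 3]
                          for i in range(0, len(fam.canonical_cds), 3)]
                for i in changed:
                    codons[i] = bg_sampler.sample_codon(mutated[i], rng)
                cds = "".join(codons)
                oriented = cds if strand == "+" else pio.reverse_complement(cds)
                p_genes.append((offset, offset + len(oriented), strand,
                                fid, mutated, fam.annotation))
                parts_p.append(oriented)
                offset += len(oriented)
                sp = lay["spacers"][gi + 1]
                parts_p.append(sp)
                offset += len(sp)
            core_seq = "".join(parts_p)
            pseq = core_seq + core_seq[:config.plasmid_terminal_overlap]
            cid = f"{strain}_p{p:02d}"
            strain_contigs[cid] = pseq
            plasmid_contigs[strain].append(cid)
            for s, e, strand, fid, prot, ann in p_genes:
                gid = f"{strain}|{fid}"
                genes_here.append(GeneModel(
                    gene_id=gid, strain=strain, contig=cid, start=s, end=e,
                    strand=strand, protein=prot, annotation=ann))
                family_of_gene[gid] = fid

        contigs[strain] = strain_contigs
        gene_models[strain] = genes_here

    truth = TruthSet(
        family_of_gene=family_of_gene,
        island_families=[list(isl) for isl in island_families],
        plasmid_contigs=plasmid_contigs,
        phage_intervals=phage_intervals,
        causal_families=causal_families,
        crispr_arrays=crispr_arrays,
        phenotype_labels=phenotype_labels,
        contig_order=contig_order,
        annotation_of_family={f.fam_id: f.annotation for f in families.values()},
        gene_models=gene_models,
    )

    # predictor tracks ------------------------------------------------------
    tracks: dict[str, dict[str, list[pio.GffFeature]]] = {}
    for strain in strains:
        tracks[strain] = _predictor_tracks(
            strain, gene_models[strain], contigs[strain], config, rng)

    od_table = simulate_growth_curves(
        truth, rng=rng, sugars=[s for s, _, _ in phenotypes])

    return Dataset(
        config=config,
        contigs=contigs,
        predictor_tracks=tracks,
        reference=reference,
        known_plasmids=known_plasmids,
        od_table=od_table,
        truth=truth,
    )


def _predictor_tracks(
    strain: str,
    genes: list[GeneModel],
    strain_contigs: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[pio.GffFeature]]:
    err = config.predictor_error
    jitter_codons = err.boundary_jitter_bp // 3
    out: dict[str, list[pio.GffFeature]] = {}
    for p in range(config.n_predictors):
        pred = f"pred{p}"
        feats: list[pio.GffFeature] = []
        n = 0
        for g in genes:
            if rng.random() < err.miss_rate:
                continue
            start, end = g.start, g.end
            if jitter_codons > 0:
                delta = 3 * int(rng.integers(-jitter_codons, jitter_codons + 1))
                clen = len(strain_contigs[g.contig])
                max_trim = 3 * (((end - start) - 90) // 3)
                if g.strand == "+":
                    # positive delta trims the start; negative extends upstream
                    delta = min(delta, max_trim)
                    delta = max(delta, -3 * (start // 3))
                    start += delta
                else:
                    delta = min(delta, max_trim)
                    delta = max(delta, -3 * ((clen - end) // 3))
                    end -= delta
            feats.append(pio.GffFeature(
                contig=g.contig, start=start, end=end, strand=g.strand,
                feature_id=f"{strain}|{pred}|{n}", source=pred))
            n += 1
        n_spurious = int(rng.poisson(err.spurious_rate * len(genes)))
        cids = sorted(strain_contigs)
        lens = np.array([len(strain_contigs[c]) for c in cids], dtype=float)
        for _ in range(n_spurious):
            cid = cids[int(rng.choice(len(cids), p=lens / lens.sum()))]
            clen = len(strain_contigs[cid])
            length = 3 * int(rng.integers(30, 200))
            if clen <= length + 1:
                continue
            start = int(rng.integers(0, clen - length))
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(pio.GffFeature(
                contig=cid, start=start, end=start + length, strand=strand,
                feature_id=f"{strain}|{pred}|{n}", source=pred))
            n += 1
        out[pred] = feats
    return out


@dataclasses.dataclass
class OdParams:
    """Shape of simulated growth curves (logistic, 24 h at 20-min readings)."""

    interval_min: int = 20
    duration_h: int = 24
    blank: float = 0.05
    noise_sd: float = 0.004
    growth_plateau: tuple[float, float] = (0.95, 1.20)
    nogrowth_plateau: tuple[float, float] = (0.15, 0.45)
    rate_per_h: tuple[float, float] = (0.5, 0.9)
    midpoint_h: tuple[float, float] = (4.0, 10.0)


def simulate_growth_curves(
    truth: TruthSet,
    od_params: OdParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    sugars: list[str] | None = None,
) -> pd.DataFrame:
    """OD time series per strain x sugar, plus a BLANK medium-only series.

    Strains labelled positive for a sugar plateau above the growth
    threshold (0.8, blank-corrected); negative strains stay below it.
    """
    p = od_params or OdParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    minutes = np.arange(0, p.duration_h * 60 + 1, p.interval_min)
    t_h = minutes / 60.0
    rows = []
    strains = sorted(truth.phenotype_labels)
    if sugars is None:
        sugars = sorted({s for labels in truth.phenotype_labels.values() for s in labels})
    blank_curve = p.blank + rng.normal(0, p.noise_sd / 2, size=len(minutes))
    for m, v in zip(minutes, blank_curve):
        rows.append(("BLANK", "BLANK", int(m), round(float(v), 4)))
    for strain in strains:
        for sugar in sugars:
            label = truth.phenotype_labels[strain][sugar]
            lo, hi = p.growth_plateau if label else p.nogrowth_plateau
            plateau = rng.uniform(lo, hi)
            rate = rng.uniform(*p.rate_per_h)
            mid = rng.uniform(*p.midpoint_h)
            od = p.blank + plateau / (1 + np.exp(-rate * (t_h - mid)))
            od = od + rng.normal(0, p.noise_sd, size=len(minutes))
            for m, v in zip(minutes, od):
                rows.append((strain, sugar, int(m), round(float(v), 4)))
    return pd.DataFrame(rows, columns=["strain", "sugar", "minute", "od"])


# --- persistence -----------------------------------------------------------


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Write the panel as FASTA/GFF3/TSV/JSON; lossless for `read_dataset`."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    (out / "proteins").mkdir(exist_ok=True)
    (out / "reference").mkdir(exist_ok=True)
    for strain in dataset.strains:
        pio.write_fasta(out / "genomes" / f"{strain}.fasta",
                        sorted(dataset.contigs[strain].items()))
        pio.write_fasta(
            out / "proteins" / f"{strain}.faa",
            [(g.gene_id, g.protein) for g in dataset.truth.gene_models[strain]])
        for pred, feats in sorted(dataset.predictor_tracks[strain].items()):
            pio.write_gff3(out / "tracks" / f"{strain}.{pred}.gff3", feats)
    pio.write_fasta(out / "reference" / "reference.fasta",
                    [("REF", dataset.reference.sequence)])
    pio.write_gff3(
        out / "reference" / "reference.gff3",
        [pio.GffFeature(contig="REF", start=g.start, end=g.end,
                        strand=g.strand, feature_id=g.gene_id,
                        attributes={"product": g.annotation.replace(";", ",")})
         for g in dataset.reference.genes])
    pio.write_fasta(out / "reference" / "reference.faa",
                    [(g.gene_id, g.protein) for g in dataset.reference.genes])
    pio.write_fasta(out / "known_plasmids.fasta",
                    sorted(dataset.known_plasmids.items()))
    dataset.od_table.to_csv(out / "growth_od.tsv", sep="\t", index=False)
    pheno = pd.DataFrame(
        [(s, sugar, lab)
         for s, d in sorted(dataset.truth.phenotype_labels.items())
         for sugar, lab in sorted(d.items())],
        columns=["strain", "sugar", "label"])
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(dataset.truth.to_json())
    (out / "config.json").write_text(json.dumps(
        dataclasses.asdict(dataset.config), indent=1, sort_keys=True))


def read_dataset(in_dir: str | Path) -> Dataset:
    """Re-read a panel written by :func:`write_dataset`."""
    src = Path(in_dir)
    cfg_d = json.loads((src / "config.json").read_text())
    cfg_d["predictor_error"] = PredictorError(**cfg_d["predictor_error"])
    cfg_d["crispr"] = CrisprParams(**cfg_d["crispr"])
    if cfg_d.get("phenotypes") is not None:
        cfg_d["phenotypes"] = [
            (s, list(f), n) for s, f, n in cfg_d["phenotypes"]]
    config = SimulationConfig(**cfg_d)
    truth = TruthSet.from_json((src / "truth.json").read_text())
    contigs = {}
    tracks: dict[str, dict[str, list[pio.GffFeature]]] = {}
    for fa in sorted((src / "genomes").glob("*.fasta")):
        strain = fa.stem
        contigs[strain] = pio.read_fasta(fa)
        tracks[strain] = {}
    for gff in sorted((src / "tracks").glob("*.gff3")):
        strain, pred = gff.stem.rsplit(".", 1)
        tracks[strain][pred] = pio.read_gff3(gff)
    ref_seq = pio.read_fasta(src / "reference" / "reference.fasta")["REF"]
    ref_prot = pio.read_fasta(src / "reference" / "reference.faa")
    ref_genes = []
    for f in pio.read_gff3(src / "reference" / "reference.gff3"):
        ref_genes.append(GeneModel(
            gene_id=f.feature_id, strain="REF", contig="REF",
            start=f.start, end=f.end, strand=f.strand,
            protein=ref_prot[f.feature_id],
            annotation=f.attributes.get("product", "")))
    return Dataset(
        config=config,
        contigs=contigs,
        predictor_tracks=tracks,
        reference=ReferenceGenome(ref_seq, ref_genes),
        known_plasmids=pio.read_fasta(src / "known_plasmids.fasta"),
        od_table=pd.read_csv(src / "growth_od.tsv", sep="\t"),
        truth=truth,
    )
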