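"""Gene presence/absence analysis: pan/core/variome.

The unit of analysis is the ortholog group (OG). Presence in a strain is
binary regardless of copy number; copy counts stay available on the OG
records. Pan- and core-genome accumulation curves are computed over random
orderings of the genomes: pan(n) is the union of OGs over the first n
genomes, core(n) the intersection. Variable regions are maximal runs of
consecutively ranked OGs (pseudo-assembly order) whose presence frequency
stays at or below a cutoff — the signature of accessory islands.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from panforge.ortho import OrthologGroup


@dataclasses.dataclass
class AccumulationCurve:
    """Pan/core OG counts as genomes are added, over seeded permutations."""

    n_genomes: np.ndarray  # 1..N
    pan_per_perm: np.ndarray  # (n_permutations, N)
    core_per_perm: np.ndarray
    seed: int

    @property
    def pan_mean(self) -> np.ndarray:
        return self.pan_per_perm.mean(axis=0)

    @property
    def pan_sd(self) -> np.ndarray:
        return self.pan_per_perm.std(axis=0, ddof=0)

    @property
    def core_mean(self) -> np.ndarray:
        return self.core_per_perm.mean(axis=0)

    @property
    def core_sd(self) -> np.ndarray:
        return self.core_per_perm.std(axis=0, ddof=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_genomes": self.n_genomes,
            "pan_mean": self.pan_mean, "pan_sd": self.pan_sd,
            "core_mean": self.core_mean, "core_sd": self.core_sd,
        })


@dataclasses.dataclass
class VariableRegion:
    rank_start: int
    rank_end: int  # inclusive
    og_ids: list[str]
    mean_presence: float

    @property
    def n_ogs(self) -> int:
        return len(self.og_ids)


def build_matrix(
    ogs: Sequence[OrthologGroup],
    strains: Sequence[str],
    include_singletons: bool = False,
) -> pd.DataFrame:
    """OG x strain binary matrix (int 0/1 entries, OG ids as the index).

    Singleton OGs — one member in one genome — are excluded by default,
    matching the pan-genome counting convention that drops families seen in
    a single annotated genome (often gene fragments or overpredictions).
    """
    strains = list(strains)
    known = set()
    for og in ogs:
        known.update(og.strain_counts)
    for s in strains:
        if s not in known:
            warnings.warn(f"strain {s} absent from every OG; zero column")
    rows = {}
    for og in ogs:
        if not include_singletons and sum(og.strain_counts.values()) == 1:
            continue
        rows[og.og_id] = [int(og.strain_counts.get(s, 0) > 0) for s in strains]
    m = pd.DataFrame.from_dict(rows, orient="index", columns=strains, dtype=int)
    if m.empty:
        m = pd.DataFrame(columns=strains, dtype=int)
    return m.sort_index()


def accumulation_curves(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
) -> AccumulationCurve:
    """Pan/core accumulation over ``n_permutations`` random genome orders."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if matrix.shape[1] < 1:
        raise ValueError("need at least one strain")
    rng = np.random.default_rng(seed)
    presence = matrix.to_numpy(dtype=bool)  # OG x strain
    n = presence.shape[1]
    pan = np.zeros((n_permutations, n), dtype=int)
    core = np.zeros((n_permutations, n), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n)
        u = np.zeros(presence.shape[0], dtype=bool)
        i = np.ones(presence.shape[0], dtype=bool)
        for j, col in enumerate(order):
            u |= presence[:, col]
            i &= presence[:, col]
            pan[p, j] = int(u.sum())
            core[p, j] = int(i.sum())
    return AccumulationCurve(
        n_genomes=np.arange(1, n + 1), pan_per_perm=pan,
        core_per_perm=core, seed=seed)


def single_copy_core(
    matrix: pd.DataFrame, ogs: Sequence[OrthologGroup]
) -> list[str]:
    """OGs with exactly one member in every strain of the matrix."""
    strains = list(matrix.columns)
    out = []
    for og in ogs:
        if all(og.strain_counts.get(s, 0) == 1 for s in strains):
            out.append(og.og_id)
    return sorted(out)


def find_variable_regions(
    matrix: pd.DataFrame,
    og_ranks: Mapping[str, int],
    min_run: int = 10,
    max_presence: float = 0.9,
) -> list[VariableRegion]:
    """Maximal runs of >= ``min_run`` consecutively ranked OGs, each present
    in <= ``max_presence`` of strains."""
    ranked = sorted(
        (rank, og) for og, rank in og_ranks.items() if og in matrix.index)
    freq = matrix.mean(axis=1)
    regions: list[VariableRegion] = []
    run: list[tuple[int, str]] = []

    def _close() -> None:
        if len(run) >= min_run:
            ids = [og for _, og in run]
            regions.append(VariableRegion(
                rank_start=run[0][0], rank_end=run[-1][0], og_ids=ids,
                mean_presence=float(freq[ids].mean())))

    prev_rank = None
    for rank, og in ranked:
        variable = freq[og] <= max_presence
        contiguous = prev_rank is not None and rank == prev_rank + 1
        if variable and (not run or contiguous):
            run.append((rank, og))
        elif variable:
            _close()
            run = [(rank, og)]
        else:
            _close()
            run = []
        prev_rank = rank
    _close()
    return regions


def cassette_presence(
    matrix: pd.DataFrame,
    cassettes: Mapping[str, Sequence[str]],
    min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Cassette x strain table: a named OG set counts as present in a strain
    when >= ``min_fraction`` of its OGs are present there."""
    rows = {}
    for name, og_ids in sorted(cassettes.items()):
        ids = [og for og in og_ids if og in matrix.index]
        if not ids:
            rows[name] = [0] * matrix.shape[1]
            continue
        frac = matrix.loc[ids].mean(axis=0)
        rows[name] = (frac >= min_fraction).astype(int).tolist()
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(matrix.columns), dtype=int)
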