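"""Gene-trait matching (GTM).

Binary growth calls are made from blank-corrected OD curves (growth when
the maximum exceeds 0.8). For each trait, a random forest is trained on OG
presence/absence features; per-OG importance is the normalized mean
impurity decrease (importances sum to 1 over features), and OGs with
importance strictly above a threshold (default 0.005) are reported, ranked
descending. Each selected OG is coloured by its presence fraction among
the positive-class strains: green when overrepresented (> 75%), red when
underrepresented (< 25%), black otherwise.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

GROWTH = "growth"
NO_GROWTH = "no_growth"
MISSING = "missing"


@dataclasses.dataclass
class GtmTraitReport:
    trait: str
    n_positive: int
    n_negative: int
    table: pd.DataFrame  # og, importance, presence_fraction, color, annotation
    importances: pd.Series  # full per-OG importances (sum to 1)


def call_growth(
    od_table: pd.DataFrame,
    threshold: float = 0.8,
    blank_strain: str = "BLANK",
) -> pd.DataFrame:
    """Binary growth calls from an OD table (strain, sugar, minute, od).

    The blank (medium-only) series is subtracted reading-by-reading; a
    strain grows on a sugar iff its blank-corrected maximum exceeds the
    threshold strictly. Curves with no readings are marked missing.
    """
    blank = (od_table[od_table["strain"] == blank_strain]
             .set_index("minute")["od"])
    rows = []
    grouped = od_table[od_table["strain"] != blank_strain].groupby(
        ["strain", "sugar"], sort=True)
    for (strain, sugar), grp in grouped:
        grp = grp.dropna(subset=["od"])
        if grp.empty:
            rows.append((strain, sugar, MISSING))
            continue
        corrected = grp["od"].to_numpy() - blank.reindex(
            grp["minute"]).fillna(blank.mean()).to_numpy()
        call = GROWTH if float(np.max(corrected)) > threshold else NO_GROWTH
        rows.append((strain, sugar, call))
    return pd.DataFrame(rows, columns=["strain", "sugar", "call"])


def color_classify(presence_fraction: float) -> str:
    """Fig-style enrichment colour: green > 0.75, red < 0.25, else black."""
    if not 0.0 <= presence_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if presence_fraction > 0.75:
        return "green"
    if presence_fraction < 0.25:
        return "red"
    return "black"


def gene_trait_match(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    annotation_of: Mapping[str, str] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
    importance_threshold: float = 0.005,
    positive_only_fraction: bool = True,
) -> GtmTraitReport:
    """Random-forest importance ranking of OGs for one trait.

    ``matrix`` is the OG x strain presence matrix; ``phenotypes`` holds
    (strain, sugar, call) rows as produced by :func:`call_growth`. Strains
    with a missing call are dropped for this trait only. Refuses
    single-class phenotypes. ``positive_only_fraction`` selects whether the
    colouring fraction is computed among positive-class strains (default)
    or as the positive-vs-negative presence contrast.
    """
    ph = phenotypes[(phenotypes["sugar"] == trait)
                    & (phenotypes["call"] != MISSING)]
    ph = ph[ph["strain"].isin(matrix.columns)]
    strains = sorted(ph["strain"])
    labels = ph.set_index("strain")["call"].reindex(strains)
    y = (labels == GROWTH).to_numpy(dtype=int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"trait {trait!r} has a single phenotype class "
            f"({n_pos} growth / {n_neg} no-growth): no discriminative signal")
    x = matrix[strains].to_numpy(dtype=float).T  # strains x OGs

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        class_weight="balanced_subsample",
        n_jobs=1,
    )
    forest.fit(x, y)
    imp = pd.Series(forest.feature_importances_, index=matrix.index)

    pos_strains = [s for s, lab in zip(strains, y) if lab == 1]
    neg_strains = [s for s, lab in zip(strains, y) if lab == 0]
    selected = imp[imp > importance_threshold].sort_values(ascending=False)
    rows = []
    for og, importance in selected.items():
        frac_pos = float(matrix.loc[og, pos_strains].mean())
        if positive_only_fraction:
            frac = frac_pos
        else:
            frac_neg = float(matrix.loc[og, neg_strains].mean())
            frac = 0.5 + (frac_pos - frac_neg) / 2.0
        rows.append((og, float(importance), frac, color_classify(frac),
                     (annotation_of or {}).get(og, "")))
    table = pd.DataFrame(
        rows, columns=["og", "importance", "presence_fraction",
                       "color", "annotation"])
    return GtmTraitReport(
        trait=trait, n_positive=n_pos, n_negative=n_neg,
        table=table, importances=imp)


def gtm_all_traits(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    annotation_of: Mapping[str, str] | None = None,
    n_trees: int = 1000,
    seed: int = 0,
    importance_threshold: float = 0.005,
) -> dict[str, GtmTraitReport]:
    """GTM for every trait in the phenotype table; single-class traits are
    skipped (reported as None would lose counts, so they are simply
    omitted)."""
    out: dict[str, GtmTraitReport] = {}
    for i, trait in enumerate(sorted(phenotypes["sugar"].unique())):
        try:
            out[trait] = gene_trait_match(
                matrix, phenotypes, trait, annotation_of=annotation_of,
                n_trees=n_trees, seed=seed + i,
                importance_threshold=importance_threshold)
        except ValueError:
            continue
    return out


def report_html(reports: Mapping[str, GtmTraitReport]) -> str:
    """Single HTML summary: one row block per trait, coloured cells."""
    parts = [
        "<html><head><title>Gene-trait matching</title></head><body>",
        "<h1>Gene-trait matching summary</h1>",
        "<table border='1' cellspacing='0'>",
        "<tr><th>trait</th><th>positive</th><th>negative</th>"
        "<th>OG</th><th>importance</th><th>annotation</th></tr>",
    ]
    for trait in sorted(reports):
        r = reports[trait]
        if r.table.empty:
            parts.append(
                f"<tr><td>{trait}</td><td>{r.n_positive}</td>"
                f"<td>{r.n_negative}</td><td colspan='3'>no OG above "
                f"threshold</td></tr>")
        for _, row in r.table.iterrows():
            parts.append(
                f"<tr><td>{trait}</td><td>{r.n_positive}</td>"
                f"<td>{r.n_negative}</td>"
                f"<td style='background:{row.color};color:white'>{row.og}</td>"
                f"<td>{row.importance:.4f}</td><td>{row.annotation}</td></tr>")
    parts.append("</table></body></html>")
    return "\n".join(parts)
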