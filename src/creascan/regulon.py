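"""DEG filtering, regulon assembly and repressor/activator co-occurrence.

A differential-expression table (gene_id, log2fc, padj; mutant vs reference)
is thresholded at fold change >= 4 (|log2FC| >= 2, inclusive) and adjusted
p < 0.01 (strict) to define up- and down-regulated sets per condition.  The
regulon is the combination of these sets across conditions, either as a union
(any condition responds) or an intersection (all conditions respond).

The co-occurrence report asks, for the genes carrying an adjacent repressor
site pair, how often each activator's binding motif is also present in the
promoter, versus its genome-wide occurrence (disjoint 2x2 Fisher test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import genes_with_feature
from .stats import EnrichmentError, _feature_enrichment_rows

DEFAULT_MIN_FOLD_CHANGE = 4.0
DEFAULT_MAX_PADJ = 0.01

DE_COLUMNS = ["gene_id", "log2fc", "padj"]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE result TSV with columns gene_id, log2fc, padj.

    Extra columns are ignored; log2fc/padj are coerced to float (blank padj
    becomes NaN, meaning the adjusted p was not reported for that gene).
    """
    table = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    table = table[DE_COLUMNS].copy()
    table["gene_id"] = table["gene_id"].astype(str)
    table["log2fc"] = pd.to_numeric(table["log2fc"])
    table["padj"] = pd.to_numeric(table["padj"])
    return table


def filter_degs(
    de_table: pd.DataFrame,
    min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
    max_padj: float = DEFAULT_MAX_PADJ,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a DE table into (up, down) significant gene sets.

    up: log2fc >= log2(min_fold_change) and padj < max_padj;
    down: log2fc <= -log2(min_fold_change) and padj < max_padj.
    The fold-change boundary is inclusive, the padj boundary strict.  Rows
    with missing padj are excluded; a non-finite log2fc is an error.
    """
    if min_fold_change <= 1:
        raise ValueError("min_fold_change must be > 1")
    if de_table.empty:
        return frozenset(), frozenset()
    if de_table["gene_id"].duplicated().any():
        dup = de_table.loc[de_table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup!r}")
    lfc = de_table["log2fc"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        bad = de_table.loc[~np.isfinite(lfc), "gene_id"].iloc[0]
        raise ValueError(f"non-finite log2fc for gene {bad!r}")
    padj = de_table["padj"].to_numpy(dtype=float)
    threshold = math.log2(min_fold_change)
    significant = np.isfinite(padj) & (padj < max_padj)
    genes = de_table["gene_id"]
    up = frozenset(genes[significant & (lfc >= threshold)])
    down = frozenset(genes[significant & (lfc <= -threshold)])
    return up, down


@dataclass
class RegulonSet:
    """Combined DEG set across conditions, with per-condition membership."""

    conditions: tuple[str, ...]
    direction: str
    combine: str
    per_condition: dict[str, frozenset[str]]
    genes: frozenset[str]


def build_regulon(
    per_condition_deg_sets: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    direction: str = "up",
    combine: str = "union",
    conditions: Sequence[str] | None = None,
) -> RegulonSet:
    """Combine per-condition (up, down) DEG sets into one regulon.

    ``direction`` selects up, down, or both (their union per condition);
    ``combine`` is union (responds in any condition) or intersection
    (responds in every condition).  ``conditions`` restricts and orders the
    conditions used; unknown labels are an error.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if not per_condition_deg_sets:
        raise ValueError("at least one condition is required")
    if conditions is None:
        labels = tuple(per_condition_deg_sets)
    else:
        unknown = [c for c in conditions if c not in per_condition_deg_sets]
        if unknown:
            raise KeyError(f"unknown condition label(s): {unknown}")
        labels = tuple(conditions)

    selected: dict[str, frozenset[str]] = {}
    for label in labels:
        up, down = per_condition_deg_sets[label]
        up, down = frozenset(up), frozenset(down)
        if up & down:
            raise ValueError(
                f"condition {label!r}: up and down sets overlap "
                f"({sorted(up & down)[:5]})"
            )
        if direction == "up":
            selected[label] = up
        elif direction == "down":
            selected[label] = down
        else:
            selected[label] = up | down

    sets = list(selected.values())
    if combine == "union":
        combined: frozenset[str] = frozenset().union(*sets)
    else:
        combined = sets[0]
        for other in sets[1:]:
            combined &= other
    return RegulonSet(
        conditions=labels,
        direction=direction,
        combine=combine,
        per_condition=selected,
        genes=frozenset(combined),
    )


def regulon_membership_frame(regulon: RegulonSet) -> pd.DataFrame:
    """Gene-by-condition 0/1 membership matrix plus the combined column."""
    genes = sorted(frozenset().union(regulon.genes, *regulon.per_condition.values()))
    data = {"gene_id": genes}
    for label in regulon.conditions:
        members = regulon.per_condition[label]
        data[label] = [int(g in members) for g in genes]
    data["combined"] = [int(g in regulon.genes) for g in genes]
    return pd.DataFrame(data)


def cooccurrence_report(
    creA_pair_genes: Iterable[str],
    presence_table: pd.DataFrame,
    activator_motifs: Sequence[str],
    background_genes: Iterable[str],
) -> pd.DataFrame:
    """Activator-motif co-occurrence in promoters of repressor pair genes.

    For each activator (in the configured order): the fraction of
    ``creA_pair_genes`` whose promoter has at least one activator site, the
    full-genome fraction, the percent increase, and the disjoint-2x2 Fisher
    p with BH correction across activators.
    """
    gene_set = frozenset(creA_pair_genes)
    background = frozenset(background_genes)
    if not background:
        raise EnrichmentError("empty background")
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:5]
        raise EnrichmentError(f"pair genes not within background, e.g. {extra}")
    available = set(presence_table["motif"].unique())
    missing = [m for m in activator_motifs if m not in available]
    if missing:
        raise EnrichmentError(
            f"activator motif(s) absent from presence table: {missing}"
        )
    features = [
        (name, genes_with_feature(presence_table, name, "single") & background)
        for name in activator_motifs
    ]
    return _feature_enrichment_rows(gene_set, background, features)
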