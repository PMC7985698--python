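"""Cross-species regulon comparison over ortholog clusters.

The unit of comparison is the ortholog cluster (OrthoMCL-style): a species
"hits" a cluster when at least one of its regulon genes belongs to it.  For a
collection of species regulons, the exact intersection counts (UpSet
semantics: how many clusters are hit by exactly this combination of species)
summarize regulon overlap, together with per-species totals and the percent
of each species' clusters shared with at least one other species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ClusterMap = dict[str, frozenset[tuple[str, str]]]


def read_cluster_table(path: str | Path) -> ClusterMap:
    """Read a (cluster_id, species, gene_id) TSV into a cluster map.

    A (species, gene) pair may belong to at most one cluster.
    """
    table = pd.read_csv(path, sep="\t")
    cid_col, sp_col, gene_col = table.columns[:3]
    clusters: dict[str, set[tuple[str, str]]] = {}
    seen: dict[tuple[str, str], str] = {}
    for cid, sp, gene in zip(table[cid_col], table[sp_col], table[gene_col]):
        member = (str(sp), str(gene))
        cid = str(cid)
        if member in seen and seen[member] != cid:
            raise ValueError(
                f"{member} belongs to clusters {seen[member]!r} and {cid!r}"
            )
        seen[member] = cid
        clusters.setdefault(cid, set()).add(member)
    return {cid: frozenset(members) for cid, members in clusters.items()}


def map_to_clusters(
    regulon: Iterable[str],
    species: str,
    cluster_map: Mapping[str, frozenset[tuple[str, str]]],
) -> tuple[frozenset[str], frozenset[str]]:
    """(clusters_hit, unclustered) for one species' regulon gene set."""
    genes = frozenset(regulon)
    index: dict[str, str] = {}
    for cid, members in cluster_map.items():
        for sp, gene in members:
            if sp == species:
                index[gene] = cid
    clusters_hit = frozenset(index[g] for g in genes if g in index)
    unclustered = frozenset(g for g in genes if g not in index)
    return clusters_hit, unclustered


@dataclass(frozen=True)
class SpeciesRegulon:
    """One species' regulon, with its derived cluster hits."""

    species: str
    genes: frozenset[str]
    clusters_hit: frozenset[str]
    unclustered: frozenset[str] = frozenset()

    @classmethod
    def from_cluster_map(
        cls,
        species: str,
        genes: Iterable[str],
        cluster_map: Mapping[str, frozenset[tuple[str, str]]],
    ) -> "SpeciesRegulon":
        genes = frozenset(genes)
        hit, unclustered = map_to_clusters(genes, species, cluster_map)
        return cls(species, genes, hit, unclustered)


@dataclass
class IntersectionCounts:
    """Exact per-combination cluster counts (UpSet semantics)."""

    species: tuple[str, ...]
    exact: dict[frozenset[str], int]
    per_species_total: dict[str, int]
    percent_shared: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """UpSet matrix: one row per non-empty combination, with a bitmask
        column over the species order and the exact count."""
        rows = []
        for r in range(1, len(self.species) + 1):
            for combo in itertools.combinations(self.species, r):
                key = frozenset(combo)
                mask = "".join(
                    "1" if sp in key else "0" for sp in self.species
                )
                rows.append(
                    {
                        "combination": "&".join(combo),
                        "bitmask": mask,
                        "degree": r,
                        "count": self.exact.get(key, 0),
                    }
                )
        return pd.DataFrame(
            rows, columns=["combination", "bitmask", "degree", "count"]
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "clusters_hit": self.per_species_total[sp],
                "percent_shared": self.percent_shared[sp],
            }
            for sp in self.species
        ]
        return pd.DataFrame(
            rows, columns=["species", "clusters_hit", "percent_shared"]
        )


def intersection_counts(
    regulons: Sequence[SpeciesRegulon],
) -> IntersectionCounts:
    """Exact intersection counts of cluster hits across species regulons.

    For every non-empty species subset S, counts the clusters hit by exactly
    the species in S.  Also reports per-species totals and the percent of
    each species' clusters shared by more than one species.  Output does not
    depend on the input order beyond row labelling.
    """
    if len(regulons) < 2:
        raise ValueError("at least two species regulons are required")
    labels = [r.species for r in regulons]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate species labels: {labels}")

    hits = {r.species: r.clusters_hit for r in regulons}
    all_clusters = frozenset().union(*hits.values())
    exact: dict[frozenset[str], int] = {}
    shared_by_species: dict[str, int] = {sp: 0 for sp in labels}
    for cluster in all_clusters:
        combo = frozenset(sp for sp in labels if cluster in hits[sp])
        exact[combo] = exact.get(combo, 0) + 1
        if len(combo) > 1:
            for sp in combo:
                shared_by_species[sp] += 1

    per_species_total = {sp: len(hits[sp]) for sp in labels}
    percent_shared = {
        sp: (
            100.0 * shared_by_species[sp] / per_species_total[sp]
            if per_species_total[sp]
            else 0.0
        )
        for sp in labels
    }
    return IntersectionCounts(
        species=tuple(labels),
        exact=exact,
        per_species_total=per_species_total,
        percent_shared=percent_shared,
    )
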